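"""Feature schema for robot-measured kinematic/kinetic (RMK) variables.

The robotic assay tracks 17 metrics per arm — reaching macro-metrics (aim,
path deviation, speeds, duration, three smoothness/jerk measures), six
sub-movement micro-metrics, a circle-drawing ellipse ratio, and static and
dynamic resistance — each measured on both the stroke-affected and the
non-affected side, plus one kinetic variable (mean vertical shoulder
strength, "Mean Z") measured on the affected side only.  With the default
schema this yields 2 x 17 + 1 = 35 model features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The 17 bilateral metrics, by their conventional abbreviations.
BILATERAL_METRICS: tuple[str, ...] = (
    "Aim",
    "Deviation",
    "Mean Speed",
    "Peak Speed",
    "Duration",
    "Smooth M/P",
    "Smooth J1",
    "Smooth J2",
    "Ellipse",
    "Numb Subm",
    "Dur Subm",
    "Overlap Subm",
    "Max Subm",
    "Sigma Subm",
    "Dist Subm",
    "Plbck Mean",
    "Rnd Dyn Mean Dist",
)

#: Metrics measured on the affected side only (sensor ceiling on the
#: non-affected arm makes the bilateral measurement uninformative).
AFFECTED_ONLY_METRICS: tuple[str, ...] = ("Mean Z",)

AFFECTED_SUFFIX = " Aff"
NON_AFFECTED_SUFFIX = " NonAff"

#: Clinical scale columns and their documented score ranges.
SCALE_RANGES: dict[str, tuple[float, float]] = {
    "FM": (0, 66),   # Fugl-Meyer upper-extremity motor score
    "MP": (0, 70),   # Motor Power
    "NIH": (0, 42),  # NIH stroke scale (higher = more severe)
    "MR": (0, 5),    # modified Rankin (integer; higher = more disabled)
}

SCALE_NAMES: tuple[str, ...] = tuple(SCALE_RANGES)

#: Scales where a higher score means greater impairment.
INVERTED_SCALES: frozenset[str] = frozenset({"NIH", "MR"})

#: Visit days allowed on an assessment record.
ALLOWED_DAYS: frozenset[int] = frozenset({3, 7, 14, 21, 30, 90})

#: Days on which the modified Rankin scale is administered.
MR_DAYS: frozenset[int] = frozenset({30, 90})

ID_COLUMNS: tuple[str, ...] = ("patient_id", "site", "day")


@dataclass(frozen=True)
class RMKSchema:
    """Naming scheme for the RMK feature set.

    Parameters
    ----------
    metric_names
        Metrics measured on both sides.
    affected_only
        Metrics measured on the affected side only.
    affected_suffix, non_affected_suffix
        Suffixes appended to metric names to form column labels, matching
        common clinical-export dialects ("Aim Aff", "Aim NonAff", ...).
    """

    metric_names: tuple[str, ...] = BILATERAL_METRICS
    affected_only: tuple[str, ...] = AFFECTED_ONLY_METRICS
    affected_suffix: str = AFFECTED_SUFFIX
    non_affected_suffix: str = NON_AFFECTED_SUFFIX

    def __post_init__(self) -> None:
        names = self.features
        if len(set(names)) != len(names):
            raise ValueError("schema produces duplicate feature names")
        overlap = set(self.metric_names) & set(self.affected_only)
        if overlap:
            raise ValueError(f"metrics listed as both bilateral and affected-only: {sorted(overlap)}")

    @property
    def features(self) -> tuple[str, ...]:
        """All model feature names (35 with the default schema)."""
        out: list[str] = []
        for m in self.metric_names:
            out.append(m + self.affected_suffix)
            out.append(m + self.non_affected_suffix)
        for m in self.affected_only:
            out.append(m + self.affected_suffix)
        return tuple(out)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def affected_features(self) -> tuple[str, ...]:
        return tuple(f for f in self.features if f.endswith(self.affected_suffix))

    def columns(self) -> tuple[str, ...]:
        """Full CSV column order: ids, features, then the four scales."""
        return ID_COLUMNS + self.features + SCALE_NAMES


DEFAULT_SCHEMA = RMKSchema()
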