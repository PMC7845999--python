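import numpy as np
import pandas as pd
import pytest

from kinemark.cohort import (
    Cohort,
    assemble_training_records,
    normalize_minmax,
    split_completers,
    subset_by_patients,
)
from kinemark.schema import DEFAULT_SCHEMA, SCALE_NAMES
from kinemark.simulate import GeneratorConfig, generate_cohort


def make_tiny_cohort(n_patients=4, days=(7, 90), seed=0, missing=()):
    """Hand-sized raw cohort: random feature values, simple scores.

    ``missing`` is a list of (patient index, day, column) cells to blank.
    """
    rng = np.random.default_rng(seed)
    feats = DEFAULT_SCHEMA.features
    rows = []
    for i in range(n_patients):
        for day in days:
            row = {"patient_id": f"P{i:02d}", "site": "Burke", "day": day}
            for f in feats:
                row[f] = float(np.round(rng.uniform(0, 10), 4))
            row["FM"] = float(rng.integers(5, 60))
            row["MP"] = float(rng.integers(5, 65))
            row["NIH"] = float(rng.integers(0, 20))
            row["MR"] = float(rng.integers(0, 5)) if day in (30, 90) else np.nan
            rows.append(row)
    data = pd.DataFrame(rows)
    for (i, day, col) in missing:
        data.loc[(data["patient_id"] == f"P{i:02d}") & (data["day"] == day), col] = np.nan
    return Cohort(schema=DEFAULT_SCHEMA, data=data)


@pytest.fixture
def tiny_cohort():
    return make_tiny_cohort()


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (seed 1) with its ground truth."""
    return generate_cohort(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def normalized_cohort(default_cohort):
    cohort, truth = default_cohort
    return normalize_minmax(cohort), truth


@pytest.fixture(scope="session")
def completer_split(normalized_cohort):
    cohort, _ = normalized_cohort
    return split_completers(cohort)


@pytest.fixture(scope="session")
def fm_table(normalized_cohort, completer_split):
    cohort, _ = normalized_cohort
    completers, _ = completer_split
    return assemble_training_records(subset_by_patients(cohort, completers), "FM")
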