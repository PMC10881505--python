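import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from aftid import Dataset, SemiCompetingRecord, SimulationConfig, simulate_cohort

#: a complete, valid covariate assignment used wherever the test only cares
#: about outcome structure
DEFAULT_COVS = {
    "age_group": 2,
    "gender": 1,
    "bmi_group": 2,
    "grade": 1,
    "tumor_size_group": 2,
    "chemo_group": 2,
    "stage": 1,
    "site": 1,
    "stage_site": 1,
    "radiotherapy": 0,
    "chemotherapy": 1,
    "morphology": 1,
    "metastasis": 0,
    "pt_stage": 2,
    "pn_stage": 1,
}


def make_record(rid, y1, d1, y2, d2, **covs) -> SemiCompetingRecord:
    merged = dict(DEFAULT_COVS)
    merged.update(covs)
    return SemiCompetingRecord(id=str(rid), y1=y1, d1=d1, y2=y2, d2=d2, covariates=merged)


def make_dataset(rows) -> Dataset:
    """rows: iterable of (y1, d1, y2, d2) or (y1, d1, y2, d2, covs-dict)."""
    records = []
    for i, row in enumerate(rows):
        covs = row[4] if len(row) > 4 else {}
        records.append(make_record(f"R{i + 1}", *row[:4], **covs))
    return Dataset(records)


@pytest.fixture(scope="session")
def sim_cohort():
    """A mid-size simulated cohort shared across read-only tests."""
    return simulate_cohort(SimulationConfig(n=400), seed=2024)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(31415)
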