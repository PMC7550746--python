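import datetime as dt

import numpy as np
import pandas as pd
import pytest

from wristband import synthetic_cohort as sc
from wristband.exposure_data import ChemicalRecord, ExposureMatrix


def make_matrix(values, batches=None, participants=None, timepoint="week12",
                chemicals=None):
    """Small hand-built exposure matrix for unit tests."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    participants = participants or [f"P{i}" for i in range(n)]
    chemicals = chemicals or [f"chem{j}" for j in range(m)]
    batches = batches or ["B1"] * n
    idx = pd.Index([f"{p}:{timepoint}" for p in participants], name="sample_id")
    samples = pd.DataFrame(
        {
            "participant_id": participants,
            "timepoint": timepoint,
            "batch": batches,
            "start_date": dt.date(2017, 10, 1),
            "duration_days": 7.0,
            "gestational_age_start": 13.0,
            "wristband_size": "regular",
            "season": "fall",
        },
        index=idx,
    )
    return ExposureMatrix(pd.DataFrame(values, index=idx, columns=chemicals), samples)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (seed 11)."""
    cfg = sc.default_config(seed=11)
    matrix, cov, records, truth = sc.simulate_cohort(cfg)
    return cfg, matrix, cov, records, truth


@pytest.fixture()
def tiny_records():
    return [
        ChemicalRecord("chem0", "chem0", "50-00-0",
                       frozenset({"chemicals in commerce", "pesticides"})),
        ChemicalRecord("chem1", "chem1", "50-01-1", frozenset({"personal care products"})),
        ChemicalRecord("chem2", "chem2", "50-02-2", frozenset({"PAHs"})),
    ]
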