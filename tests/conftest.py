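import datetime as dt

import matplotlib
import numpy as np
import pandas as pd
import pytest

matplotlib.use("Agg")

from edscore.cohort import COLUMNS, Cohort
from edscore.simulate import GeneratorConfig, apply_missingness, generate_cohort


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(n_patients=30_000, seed=424242)


@pytest.fixture(scope="session")
def complete_cohort(default_config) -> Cohort:
    """A complete (unmasked) synthetic cohort shared across tests."""
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def masked_cohort(default_config, complete_cohort) -> Cohort:
    """The same cohort with the default missingness applied (MAR)."""
    return apply_missingness(complete_cohort, default_config)


def make_cohort_frame(rows: list[dict]) -> pd.DataFrame:
    """Small hand-built cohort frames for engineered fixtures."""
    base = {
        "patient_id": None, "age": 60.0, "sex": "F", "sbp": 120.0,
        "heart_rate": 80.0, "respiratory_rate": 16.0, "spo2": 98.0,
        "temperature": 36.8, "fio2": 0.21, "alert": 1.0, "urea": 6.0,
        "leukocytes": 9.0, "icu_admission": 0.0, "disposition": "admitted",
        "died_24h": 0.0, "presentation_date": dt.date(2019, 6, 1),
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(base)
        rec["patient_id"] = f"X{i:04d}"
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out, columns=COLUMNS)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240117)
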