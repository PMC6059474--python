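import numpy as np
import pandas as pd
import pytest

from seslt import build_life_table


def gompertz_q(a: float = -9.0, b: float = 0.085) -> np.ndarray:
    """Smooth reference-style death probabilities over ages 0-99."""
    ages = np.arange(100)
    return 1.0 - np.exp(-np.exp(a + b * ages))


@pytest.fixture(scope="session")
def reference_lt():
    return build_life_table(gompertz_q(), stratum="ref", year=2000)


@pytest.fixture(scope="session")
def toy_tables():
    """Three toy strata with constant annual survival 0.90 / 0.80 / 0.95."""
    out = {}
    for stratum, p in [("A", 0.90), ("B", 0.80), ("C", 0.95)]:
        out[stratum] = build_life_table(np.full(100, 1.0 - p), stratum=stratum, year=2000)
    return out


def make_cohort(rows):
    """Cohort frame from (time_months, status, extras...) tuples.

    Each row: dict with at least time_months and status; remaining columns
    get sensible defaults.
    """
    defaults = {
        "diag_year": 2000,
        "diag_age": 60,
        "sex": "m",
        "race": "all",
        "county": "C0",
        "stratum": "A",
        "cause": "",
        "source": "registry",
        "n_primaries": 1,
    }
    recs = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec.update(row)
        rec["patient_id"] = i
        recs.append(rec)
    return pd.DataFrame(recs)
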