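import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from guyton_bedside.schema import DRUGS, FEATURE_COLUMNS, OUTCOMES
from guyton_bedside.synthetic import SyntheticConfig, generate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    """Two patients, 10 minutes at 1 Hz: fast enough for unit tests."""
    return SyntheticConfig(n_patients=2, duration_s=600, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


def make_feature_table(
    n_rows: int,
    rng: np.random.Generator,
    target_fn=None,
    n_patients: int = 8,
) -> pd.DataFrame:
    """Model-ready table with iid dose columns and configurable targets.

    Unlike the generator's cohorts, doses here are iid across rows, so
    modeling tests can plant signals without time/dose collinearity.
    ``target_fn(df) -> Series`` fills every outcome column; default is
    standard-normal noise independent of all features.
    """
    df = pd.DataFrame({
        "time_s": rng.integers(0, 172_800, n_rows),
        "patient_id": rng.integers(0, n_patients, n_rows),
        "age_years": rng.uniform(0.2, 18.0, n_rows),
        "weight_kg": rng.uniform(3.0, 80.0, n_rows),
    })
    for drug in DRUGS:
        df[drug] = rng.uniform(0.0, 1.0, n_rows)
    for outcome in OUTCOMES:
        if target_fn is None:
            df[outcome] = rng.normal(0.0, 1.0, n_rows)
        else:
            df[outcome] = np.asarray(target_fn(df), dtype=float)
    return df[[*FEATURE_COLUMNS, *OUTCOMES]]
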