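import numpy as np
import pandas as pd
import pytest

from cognorm.battery import SUBTESTS
from cognorm.cohort_sim import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Single-session healthy cohort, n=600, fixed seed."""
    return simulate_cohort(SimulationConfig(n_subjects=600, seed=42))


@pytest.fixture(scope="session")
def retest_cohort() -> pd.DataFrame:
    """Two-session healthy cohort, n=1200, fixed seed."""
    return simulate_cohort(
        SimulationConfig(n_subjects=1200, seed=7, two_sessions=True)
    )


def toy_cohort(raws: dict[str, list[float]], ages=None) -> pd.DataFrame:
    """Tiny hand-built cohort with the required schema columns."""
    n = len(next(iter(raws.values())))
    base = {
        "subject_id": [f"T{i:03d}" for i in range(n)],
        "age": ages if ages is not None else [30.0] * n,
        "gender": ["F"] * n,
        "education_years": [16.0] * n,
        "group": ["healthy"] * n,
        "session": [1] * n,
    }
    for s in SUBTESTS:
        base[s] = raws.get(s, list(np.linspace(5, 25, n)))
    return pd.DataFrame(base)
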