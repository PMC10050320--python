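import pandas as pd
import pytest

from ambival import cohort, design


@pytest.fixture(scope="session")
def full_design() -> pd.DataFrame:
    return design.generate_design()


@pytest.fixture(scope="session")
def schedule(full_design):
    return design.schedule_blocks(full_design, order=1, rng_seed=123)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = cohort.CohortConfig(n_ptsd=3)
    return cohort.sample_population(6, cfg, seed=11)


@pytest.fixture(scope="session")
def one_subject(small_cohort):
    return small_cohort[0]
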