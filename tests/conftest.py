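import numpy as np
import pytest

from prognae.synthetic import SimulationConfig, simulate_cohorts
from prognae.types import OmicsMatrix, SurvivalTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """A down-scaled study (fast) with a strong planted subtype."""
    cfg = SimulationConfig(n_train=80, n_internal_cna=60, n_external_expr=60,
                           n_genes_expr=300, n_genes_cna=120,
                           frac_informative=0.1, seed=7)
    return simulate_cohorts(cfg)


@pytest.fixture
def toy_matrix():
    return OmicsMatrix(["g1", "g2", "g3"], ["s1", "s2"],
                       [[0.0, 2.0], [4.0, 8.0], [1.0, 1.0]])


def make_survival(rng, n, hr_group=None, baseline_scale=10.0, censor_scale=20.0):
    """Exponential survival helper for tests; ``hr_group`` is an optional
    binary array multiplying the hazard by 3 where 1."""
    rate = np.full(n, 1.0 / baseline_scale)
    if hr_group is not None:
        rate = rate * np.where(np.asarray(hr_group) == 1, 3.0, 1.0)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.exponential(censor_scale, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


@pytest.fixture
def survival_factory():
    return make_survival
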