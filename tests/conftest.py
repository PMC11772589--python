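import numpy as np
import pytest

import trimodalqtl as tq


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cohort():
    """A 50-donor cohort with a moderate allelic fold change, shared across
    sampler tests to amortise simulation cost."""
    cfg = tq.SimulationConfig(seed=11, n_donors=50, mean_depth=200, log_afc=np.log(1.5))
    panel = tq.simulate_genotypes(cfg, n_variants=2)
    return cfg, panel


def make_window(rng, n=100, k=8, effects=None, resid_sd=1.0):
    """Standardized genotype-like design plus three centered traits."""
    x = rng.standard_normal((n, k))
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    b = np.zeros((k, 3)) if effects is None else np.asarray(effects, dtype=float)
    y = x @ b + resid_sd * rng.standard_normal((n, 3))
    y = y - y.mean(axis=0)
    return x, y
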