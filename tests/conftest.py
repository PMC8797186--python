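import numpy as np
import pytest

import levyforage as lf


@pytest.fixture
def rng():
    """Fresh deterministic generator per test."""
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def brownian_ensemble():
    """Shared ensemble of Brownian-like walkers (u = 5) at lifespan 1M on
    sparse uniform landscapes; reused by several statistical checks."""
    rng = np.random.default_rng(1000)
    recs = []
    for _ in range(50):
        env = lf.make_uniform_environment(1000, rng=rng)
        dist = lf.MoveLengthDistribution.build(5.0, 1000, rng=rng)
        org = lf.DigitalOrganism(dist=dist, lam=1_000_000, s=1)
        recs.append(lf.run_lifespan(org, env, rng))
    return recs
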