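import numpy as np
import pandas as pd
import pytest

import phytoniche as pn


@pytest.fixture(scope="session")
def noisy_scenario():
    """Default reservoir survey (196 samples, noise_cv=0.3)."""
    cfg = pn.default_scenario(seed=101, noise_cv=0.3)
    env = pn.generate_environment(cfg)
    truth = pn.generate_true_biomass(env, cfg)
    pig = pn.generate_pigments(truth, cfg)
    counts = pn.generate_counts(truth, cfg)
    return cfg, env, truth, pig, counts


@pytest.fixture(scope="session")
def noiseless_scenario():
    """Same survey with all measurement noise off (generator noise on the
    environment remains; pigment/biomass noise_cv = 0)."""
    cfg = pn.default_scenario(seed=202, noise_cv=0.0)
    env = pn.generate_environment(cfg)
    truth = pn.generate_true_biomass(env, cfg)
    pig = pn.generate_pigments(truth, cfg)
    return cfg, env, truth, pig


def gaussian_niche_data(n=300, mu=25.0, sigma=3.0, lo=15.0, hi=33.0,
                        cv=0.0, seed=0, scale=100.0):
    """Single-variable Gaussian niche samples, optionally with
    mean-preserving lognormal noise."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(lo, hi, n)
    c = scale * np.exp(-((x - mu) ** 2) / (2 * sigma ** 2))
    if cv > 0:
        s = np.sqrt(np.log1p(cv ** 2))
        c = c * rng.lognormal(-0.5 * s ** 2, s, n)
    return x, c
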