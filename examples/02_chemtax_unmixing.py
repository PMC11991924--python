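"""Decompose a pigment table into group chlorophyll-a contributions.

Generates a noisy survey, perturbs the true ratio matrix (as if starting
from literature ratios rather than the local ones), runs the successive-
runs protocol and compares the recovered community to the known truth.
"""

import numpy as np
import pandas as pd

import phytoniche as pn

cfg = pn.default_scenario(seed=7, noise_cv=0.3)
env = pn.generate_environment(cfg)
truth = pn.generate_true_biomass(env, cfg)
pig = pn.generate_pigments(truth, cfg)

rng = np.random.default_rng(0)
init = cfg.ratio_matrix_true.copy()
vals = init.to_numpy().copy()
vals[:, :-1] *= rng.uniform(0.85, 1.15, vals[:, :-1].shape)
init = pd.DataFrame(vals, index=init.index, columns=init.columns)
init["tchla"] = 1.0

result = pn.successive_runs(pig, init, n_runs=10, ratio_limit=0.5)
print("RMSE after each of the 10 chained runs:")
print("  " + "  ".join(f"{r:.4f}" for r in result.rmse_trajectory))

groups = list(cfg.groups)
r = {g: np.corrcoef(result.composition[g], truth[g])[0, 1] for g in groups}
print("correlation of recovered vs true group chlorophyll a:")
for g in groups:
    print(f"  {g:16s} r = {r[g]:.3f}")
# The non-increasing RMSE trajectory is the successive-runs protocol doing
# its job; high per-group correlations mean the bounded factorization
# attributes chlorophyll a to the right groups despite 30% pigment noise
# and a mis-specified starting matrix.
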