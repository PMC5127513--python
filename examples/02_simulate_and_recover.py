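"""Parameter recovery on synthetic summary statistics.

Draws two-sample GWAS summary statistics around a known causal effect
(log-OR ln 1.5 per SD of exposure) and shows that IVW pooling recovers it;
with block-correlated instruments, the GLS estimator keeps honest standard
errors while naive IVW understates them.
"""

import math

import numpy as np

from mrkit.mr import fit
from mrkit.simulate import SimulationConfig, block_ld, simulate_sumstats
from mrkit.sumstats import harmonise

cfg = SimulationConfig(
    n_individuals=1,  # summary-statistic route only
    eaf=np.array([0.46, 0.89, 0.79, 0.40]),
    gamma=np.array([0.09, 0.11, 0.09, 0.07]),
    n_outcome=50_000,
    outcome_case_share=0.15,
    seed=1,
)
e, o, ld = simulate_sumstats(cfg)
res = fit(harmonise(e, o).pairs)
print(f"independent instruments: true OR {math.exp(cfg.theta):.2f}, "
      f"estimated OR {math.exp(res.theta):.3f} "
      f"(95% CI {math.exp(res.ci95[0]):.3f}-{math.exp(res.ci95[1]):.3f})")

cfg_ld = SimulationConfig(
    n_individuals=1,
    eaf=np.full(12, 0.4),
    gamma=np.full(12, 0.09),
    ld=block_ld([3, 3, 3, 3], [0.7] * 4),
    n_outcome=50_000,
    outcome_case_share=0.15,
    seed=2,
)
thetas_ivw, ses_ivw, thetas_gls = [], [], []
for rep in range(200):
    rng = np.random.default_rng(100 + rep)
    e, o, ld = simulate_sumstats(cfg_ld, rng)
    pairs = harmonise(e, o).pairs
    ivw = fit(pairs, method="ivw")
    gls = fit(pairs, method="gls", ld=ld)
    thetas_ivw.append(ivw.theta)
    ses_ivw.append(ivw.se)
    thetas_gls.append(gls.theta)

print("\ncorrelated instruments (blocks of 3, rho = 0.7), 200 replicates:")
print(f"  naive IVW: empirical SD of theta = {np.std(thetas_ivw):.4f}, "
      f"mean reported SE = {np.mean(ses_ivw):.4f}  <- anti-conservative")
print(f"  GLS with the LD matrix: mean theta = {np.mean(thetas_gls):.4f} "
      f"(truth {cfg_ld.theta:.4f})")
print(
    "\nWhen instruments are correlated, ignoring the LD makes the reported "
    "SE smaller than the true sampling spread; the GLS estimator corrects it."
)
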