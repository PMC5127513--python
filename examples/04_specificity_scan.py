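"""Metabolome-wide specificity scan of a genetic score.

Builds a weighted risk score from four simulated variants, scales it so one
unit predicts 1 SD of the exposure, and scans a panel of 175 traits of which
only the exposure itself is truly associated — emulating the check that a
score is specific to its own pathway.
"""

import numpy as np
import pandas as pd

from mrkit.scores import ScoreDefinition, build_score, metabolome_scan, scale_score_to_sd
from mrkit.simulate import default_config, simulate_cohort

cfg = default_config(n_variants=4, n_individuals=8_000, seed=11)
cohort = simulate_cohort(cfg)

score_def = ScoreDefinition(tuple(zip(cohort.genotypes.variants, cfg.gamma)))
raw = build_score(cohort.genotypes, score_def)
scaled = scale_score_to_sd(raw, cohort.exposure)

rng = np.random.default_rng(12)
traits = pd.DataFrame(
    rng.standard_normal((cohort.genotypes.n_samples, 174)),
    columns=[f"metabolite_{j + 1}" for j in range(174)],
)
traits.insert(0, "exposure", cohort.exposure)

res = metabolome_scan(scaled, traits, alpha=0.05)
print(f"scanned {res.m} traits; Bonferroni threshold p < {res.alpha / res.m:.2e}")
print(f"significant: {res.significant_traits}")
top = res.table.nsmallest(3, "p")[["trait", "beta", "se", "p"]]
print("\nstrongest associations (beta per scaled-score unit, in trait SDs):")
print(top.to_string(index=False))
print(
    "\nOnly the exposure itself clears the multiplicity-controlled threshold: "
    "the score is specific to the pathway it was built for."
)
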