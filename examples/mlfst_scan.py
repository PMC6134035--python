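"""Maximum-likelihood local F_ST across populations of varying drift.

Simulates a 12-population region whose populations were generated with
increasing drift parameters F, then estimates each population's ML-F_ST
against the pooled regional mean and prints the two side by side — the
estimates should track the generating values.
"""

import numpy as np

from fragdiv.mlfst import (
    estimate_mlfst,
    regional_mean_frequencies,
    single_individual_mlfst,
)
from fragdiv.synthetic import simulate_balding_nichols

rng = np.random.default_rng(11)
freqs = [rng.dirichlet([1.0] * 5) for _ in range(300)]
f_true = list(np.round(np.linspace(0.02, 0.30, 12), 3))
gm = simulate_balding_nichols(freqs, f_true, [25] * 12, seed=12)

rf = regional_mean_frequencies(gm, "region", mode="pooled")
print(f"{'population':>10} {'generating F':>13} {'ML-F_ST':>9} {'loci':>5}")
for pop, f in zip(gm.population_ids(), f_true):
    est = estimate_mlfst(gm, pop, rf)
    print(f"{pop:>10} {f:>13.3f} {est.f_hat:>9.4f} {est.n_loci:>5}")
# ML-F_ST measures how far each population has drifted from the regional
# mean allele frequencies; it rises with the generating F.

single = single_individual_mlfst(gm, rf, seed=1)
full = [estimate_mlfst(gm, p, rf).f_hat for p in gm.population_ids()]
ones = [single[p].f_hat for p in gm.population_ids()]
r = np.corrcoef(full, ones)[0, 1]
print(f"\nsingle-individual vs full-sample ML-F_ST correlation: r = {r:.2f}")
# Even one diploid individual per population preserves the ranking,
# showing the statistic is not a sample-size artifact.
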