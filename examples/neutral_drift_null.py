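"""The neutral-theory null: drift couples abundance to longevity.

Runs the zero-sum Moran model (community of 100 individuals, per-birth
speciation probability 0.01, 500,000 steps) and measures the rank
correlation between each species' time-averaged abundance and its lifetime.
Under pure drift, rare species random walk to extinction sooner, so the
correlation must be strongly positive — this is the expectation the
regression battery tests, and rejects, on fossil plankton data.
"""

import scipy.stats

from paleorange import SimConfig, neutral_drift_sim

cfg = SimConfig(seed=123, J=100, nu=0.01, n_steps=500_000)
res = neutral_drift_sim(cfg)
done = res.species[res.species.completed]

rho, p = scipy.stats.spearmanr(done.mean_abundance, done.longevity_my)
print(f"completed species lifetimes: {len(done)}")
print(f"median simulated longevity: {done.longevity_my.median():.1f} my")
print(f"Spearman rho(mean abundance, longevity) = {rho:.3f}  (p = {p:.2e})")
print("\nA strongly positive rho is the neutral-drift signature: if real")
print("assemblages were governed by drift alone, the same correlation would")
print("appear in their vetted ranges and abundance summaries.")
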