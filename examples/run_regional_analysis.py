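"""Full regional analysis on a study-shaped synthetic dataset.

Generates an eastern-equatorial-Pacific-like occurrence table (14 dated
samples, ~2,500 species-level specimens each), runs vetting -> abundance
metrics -> the regression/ANOVA/mixed-model battery, and prints the headline
statistics a real regional dataset would yield.
"""

import logging

from paleorange import RunConfig, analyze_table, fixture_so_eep

logging.basicConfig(level=logging.INFO, format="%(levelname)s: %(message)s")

table = fixture_so_eep("EEP", seed=2)
result = analyze_table(table, cfg=RunConfig(dataset_label="EEP", seed=2))
s = result["summary"]

print(f"\nsamples: {s['n_samples']}, species-level taxa: {s['n_species_level_taxa']}")
print(f"vetting statuses: {s['status_counts']}")
print(f"included species: {s['n_included']}")
print(f"median longevity: {s['median_longevity']:.2f} my "
      "(estimated duration between error-bar midpoints)")
print(f"median mean abundance: {s['median_mean_abundance']:.3f}% of assemblage")

for key, name in (("ols_ln_mean", "ln mean abundance"), ("ols_ln_max", "ln max abundance")):
    m = s[key]
    print(f"longevity ~ {name}: slope {m['slope']:+.3f} my/ln-unit, "
          f"R^2 {m['r_squared']:.3f}, p {m['p_value']:.3f}")

a = s["anova_order"]
print(f"ANOVA longevity by order: F = {a['f_stat']:.3f}, p = {a['p_value']:.3f}")
c = s["model_comparison"]
print(f"mixed (biogeography random intercept) vs abundance-only: "
      f"delta AICc = {c['delta_aicc']:+.2f} -> prefer {c['preferred']}")

print("\nAn R^2 near zero with p > 0.05 means abundance carries no measurable")
print("signal of extinction risk in this dataset; a positive delta AICc means")
print("adding biogeography does not improve the longevity model.")
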