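# paleorange

Does being rare make a species more likely to go extinct?  Ecological
neutral theory says yes: if all individuals have identical demographic
rates, small populations random walk to extinction sooner, so abundance and
longevity should be positively correlated.  `paleorange` is a library for
testing that prediction in the fossil record of marine microplankton, where
deep-sea drill cores provide age-dated samples with thousands of counted
specimens each.

It is aimed at paleobiologists and macroecologists working with
occurrence-count matrices (dated sediment samples × taxa), and provides:

- **Range vetting** — first/last occurrences with gap-based error bars.
  For species *i*, the mean gap *g<sub>i</sub>* is the average length (in
  samples) of the zero-count runs between its occurrences; the error bar is
  *e<sub>i</sub>* = max(1, ⌈*g<sub>i</sub>*⌉) samples, extended older than
  the first occurrence and younger than the last.  Species touching the
  section edges, with error bars running off the section, or whose range is
  more than doubled by its error bars are excluded.  Longevity is
  *L<sub>i</sub>* = midpoint(FO bar) − midpoint(LO bar), in millions of
  years (my).
- **Abundance metrics** — percent relative abundance
  *p<sub>ij</sub>* = 100·*n<sub>ij</sub>*/*N<sub>j</sub>* within each
  sample (species-level taxa only), per-species mean/max/SD over the range
  (zeros inside the range included), natural-log transforms, per-sample
  richness, and Good–Turing/Chao sample coverage
  *C* = 1 − (f₁/n)·[(n−1)f₁/((n−1)f₁ + 2f₂)].
- **A statistics battery** — OLS of longevity on ln abundance with residual
  diagnostics, one-way ANOVA by taxonomic order (Collodaria / Nassellaria /
  Spumellaria) and by biogeographic category (endemic / cosmopolitan), a
  linear mixed model (abundance fixed, biogeography random intercept, ML),
  and AICc model comparison.
- **Synthetic generators** — a zero-sum Moran neutral-drift simulator, a
  niche generator with a tunable abundance–longevity coupling and recorded
  truth, and Southern-Ocean / eastern-equatorial-Pacific–shaped fixtures,
  so the whole pipeline is testable without any data downloads.

## Worked example

```sh
python examples/run_regional_analysis.py
```

builds an EEP-like dataset (14 samples, 10.3–0 Ma, ~2,500 species-level
specimens per sample) and runs the full analysis:

```
included species: 228
median longevity: 3.96 my (estimated duration between error-bar midpoints)
median mean abundance: 0.138% of assemblage
longevity ~ ln mean abundance: slope +0.180 my/ln-unit, R^2 0.015, p 0.067
longevity ~ ln max abundance: slope +0.341 my/ln-unit, R^2 0.060, p 0.000
ANOVA longevity by order: F = 0.616, p = 0.541
mixed (biogeography random intercept) vs abundance-only: delta AICc = +2.07 -> prefer ols_ln_mean_matched
```

The fixture is generated with *zero* abundance–longevity coupling, and the
battery reports exactly that: R² < 0.1 in every regression, no order-level
or biogeographic signal, and a positive ΔAICc meaning the extra biogeography
term buys nothing.  `examples/neutral_drift_null.py` shows the opposite
regime — under pure drift, Spearman ρ(abundance, longevity) ≈ 0.84 — and
`examples/coupling_recovery.py` demonstrates that a planted coupling of
1.5 my per ln-unit is recovered through the full pipeline.

Real datasets enter through three plain CSV/TSV files (counts matrix with
sample ids in the first column; sample → site/age map; taxon → order /
biogeography / species-level map):

```python
from paleorange import read_counts, analyze_table, RunConfig
table = read_counts("counts.csv", "ages.csv", "meta.csv")
result = analyze_table(table, cfg=RunConfig(dataset_label="SO"))
```

or from the shell: `paleorange run --config run.yaml` and
`paleorange simulate --fixture SO --seed 1 --out data/`.

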