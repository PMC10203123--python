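# Methods

## The estimation problem

A regional occurrence dataset is an age-ordered sequence of dated sediment
samples, each with specimen counts per taxon.  Observed first and last
occurrences (FO/LO) bound a species' stratigraphic range, but both are
biased inward: a species existed before its oldest fossil and after its
youngest.  The package estimates a species' longevity with an error-bar
construction driven by the species' own sampling record, and then asks
whether relative abundance predicts that longevity.

## Range vetting and longevity

Samples are sorted oldest→youngest into one composite sequence; ties in age
are broken by (site, sample id) so runs are deterministic.  For each
species-level taxon:

1. **Gap statistic.** The mean gap *g* is the average length, in samples,
   of the maximal zero-count runs strictly between FO and LO.  Gaps are
   measured in samples, not Ma, because the minimum error is defined as
   one *sample*; conversion to time happens only when the bar is laid onto
   the age grid.  An alternative reading — total zero samples divided by
   the number of occurrence pairs — is possible; the run-mean was chosen
   because a "gap" is naturally one unbroken hiatus, and the choice is
   isolated in `vetting.mean_gap` if a user wants to swap it.
2. **Error bar.** *e* = ⌈*g*⌉ samples, with a floor of 1 for gap-free
   records.  The FO bar spans from the sample *e* positions older than the
   FO to the FO; the LO bar from the LO to the sample *e* positions
   younger.  Bars extend outward only: the uncertainty being modelled is
   true origination (older than observed) and true extinction (younger
   than observed).
3. **Exclusions**, applied in order (the order affects only which reason is
   recorded, never membership): listed reworked/misidentified occurrences
   are zeroed; species with any occurrence in the two oldest or two
   youngest samples of the composite are dropped (`excluded_edge`); species
   whose bars run off either end of the section are dropped
   (`excluded_overflow` — possibly extant or pre-dating the section);
   species whose outer bar-to-bar span strictly exceeds twice the raw
   FO–LO span are dropped (`excluded_doubling` — range too poorly
   constrained).  "More than doubled" is read strictly, so a span exactly
   twice the raw range survives, and a single-sample range (raw span 0)
   never does.
4. **Longevity** is the difference of bar midpoints, in my.  It is
   invariant under uniform age translation, scales linearly with age
   dilation, and for gap-free species is always ≥ the raw observed range.

The edge window (2 samples) and the error floor (1 sample) are exposed as
`RunConfig.edge_samples` and `--min-error-samples` but should rarely move.

## Abundance metrics

Relative abundance is percent of the *species-level* assemblage:
genus-level and higher columns are carried in the data files but excluded
from numerator and denominator alike, and from every downstream statistic.
Per-species summaries (mean, max, SD) are taken over **all** samples within
[FO, LO], counting zero-count samples as zeros: a counted sample inside the
range that lacks the species is a genuine observation of rarity, and
omitting those zeros would inflate the mean of sparsely occurring species
by orders of magnitude.  The SD uses the n−1 denominator; species observed
in a single sample get SD 0, whose log is undefined, so they drop from the
SD regression only (counted and logged).  Natural logs act on percent
units.

Sample coverage uses the Good–Turing/Chao estimator
C = 1 − (f₁/n)·[(n−1)f₁/((n−1)f₁ + 2f₂)] on species-level counts.  It is 1
when a sample has no singletons and 0 when every specimen is a singleton.

## The statistics battery

* **OLS**: longevity ~ ln(abundance metric), two-sided slope test, α=0.05.
  Residual diagnostics (Shapiro–Wilk, Breusch–Pagan, a runs test on
  residual signs ordered by fitted value) are advisory output only.
* **ANOVA**: classical one-way fixed effects, longevity by taxonomic order
  or by biogeographic category.  Groups with fewer than two members are a
  hard error in the primitive; the pipeline drops such groups before
  calling it.  The degenerate all-values-equal case returns F = 0.
* **Mixed model**: longevity ~ ln mean abundance with a random intercept on
  the 2-level biogeographic factor, fitted by maximum likelihood (REML
  would invalidate AIC comparison across different fixed structures).  A
  2-level random effect is weakly identified: singular fits (variance → 0)
  are reported, not raised, and a fixed-effects ANCOVA variant
  (`stats.ancova_fixed`) is provided for sensitivity.  Optimizers that land
  exactly on the zero-variance boundary report a degenerate likelihood, so
  the implementation falls back from L-BFGS to Powell when the
  log-likelihood is non-finite; at the boundary the likelihood equals the
  OLS likelihood, which the tests verify.
* **AICc** = 2k − 2ℓ + 2k(k+1)/(n−k−1), with k counting variance terms
  (OLS k=3, mixed k=4).  Model comparison reports
  Δ = AICc(complex) − AICc(simple); positive Δ prefers the simpler model.
  On null data a redundant parameter costs ≈ +1 on average (the 2-point
  penalty minus E[χ²₁] = 1 of likelihood gain).
* No multiple-testing correction; all p-values are reported side by side.

## Synthetic data: what it emulates, and what it does not

**Neutral drift** is a zero-sum Moran model: per step, one uniformly random
individual dies and is replaced by the offspring of a uniformly random
survivor or, with probability ν, by a new species.  Species lifetimes and
time-averaged abundances are tracked exactly (O(1) incremental
integrals).  One step maps to 0.08 my by default, set from the measured
median completed lifetime at (J=100, ν=0.01) — about 100 steps — so the
median simulated longevity lands near 8 my, the scale of long-lived
polycystine plankton.  The model is the canonical neutral null, not a
per-capita environmental-stochasticity variant; it demonstrates the
qualitative drift prediction (abundance–longevity correlation) rather than
any quantitative rate.

**The niche generator** plants the truth the pipeline must recover:
ln mean abundance ~ Normal(μ, σ) (defaults −3.0, 2.0, spanning roughly four
orders of magnitude like real assemblages), true longevity
L = L₀ + β·ln(a) + ε with ε Normal(0, 2 my) truncated so L > 0.5 my, ranges
placed uniformly (allowed to overhang the study window and clipped — the
situation the edge filter exists for, and what keeps every sample
occupied), counts multinomial per sample with a lognormal within-range
wiggle.  L₀ defaults to 15 my: high enough that the truncation floor
touches <1% of species, keeping the generating slope β identifiable —
with a lower intercept the truncation visibly attenuates recovered slopes.

**Fixtures** reproduce the shapes of the two study systems (a 97-sample
Southern-Ocean-like composite over 22.65–0.04 Ma with ~7,190 species-level
specimens and 100–200 species per sample; a 14-sample EEP-like single-site
series over 10.3–0 Ma with ~2,500 specimens and ~350 species per sample),
with coverage > 0.9 throughout, order codes in realistic C/N/S proportions
and a few genus-level columns that every analysis must ignore.  They are
generated with zero abundance–longevity coupling.

What the generators do **not** emulate: time-averaging within a sample
(each sample is one instantaneous multinomial draw), preservation bias
between taxa, age-model error, autocorrelated abundance trajectories
(outside the Moran model), or real taxonomic structure.  Passing tests on
synthetic data therefore validate the *machinery* — vetting logic,
estimator calibration, sign and size recovery under known truth — not any
empirical claim about real assemblages.

## Numerical and degenerate-input choices

- Counts must be nonnegative integers; violations name the offending cell.
- A sample with zero species-level specimens is a hard error for relative
  abundance (it cannot be normalized).
- Age ties across sites are broken lexicographically; input row order never
  affects results.
- Zero-variance predictors and mismatched response vectors are hard errors
  in the regression layer.
- All randomness flows from a single integer seed per generator/run; equal
  seeds give bit-identical outputs.

## Problem sizes

The test suite and the acceptance script run the Moran demonstrator at
5×10⁵ steps (~5,000 completed lifetimes), calibration at 2,000 OLS
replicates, recovery at 200–500 generator seeds with 200 species each, and
full-pipeline smoke runs on both fixtures; the whole suite completes in
well under a minute on one CPU.

## Known limitations

- The vetting error bar is a biostratigraphic convention, not a
  probabilistic confidence interval; no Strauss–Sadler/Marshall-style
  range extension is attempted.
- The 2-level random intercept is fragile by construction; treat the mixed
  model's variance component as descriptive and lean on the ANCOVA variant
  when it matters.
- Composite sections pool sites into one age-ordered sequence; per-site
  edge filtering is not implemented.
- ln-abundance summaries are undefined for species with zero SD, which
  silently shrinks the SD regression's n (reported in the summary).
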