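# Methods

This package implements, as a tested pipeline over synthetic data, the chain
of analyses that links histologic renal epithelial senescence to a urinary
biomarker and then to kidney-disease progression: cell-level quantification,
a urinary proteomics screen, a radial spatial-transcriptomics enrichment
statistic, and survival modelling of a sustained renal-decline endpoint.

## Senescence quantification

A cell is called senescent when its nucleus stains P21+ (CDKN1A product,
cell-cycle inhibitor) and KI67- (no proliferation marker).  The per-biopsy
senescent fraction is 100 × (P21+KI67- epithelial cells) / (all epithelial
cells), with counts **pooled across sections before division** — averaging
per-section percentages would weight a 10-cell fragment equally with a
3000-cell section.  Only epithelial (pancytokeratin/CD10+) cells enter either
count.  P21/clusterin co-expression is summarised from the second staining
panel as an odds ratio ad/bc on the 2×2 table of nuclear P21 × cytoplasmic
clusterin, with a Woolf log-method 95% CI (Haldane–Anscombe +0.5 when a cell
is empty) and a two-sided Fisher exact p-value.

## Clinical quantities

eGFR uses the 2009 CKD-EPI creatinine equation,
141 · min(Scr/κ,1)^α · max(Scr/κ,1)^−1.209 · 0.993^age · 1.018[F],
with serum creatinine in mg/dL.  The race coefficient is disabled by default
(a `race_factor` slot allows the 1.159 multiplier); the cohorts this
emulates were predominantly White with ethnicity partly unrecorded, so the
equation is applied race-agnostically.  Urinary analytes are expressed per
creatinine (µg/mmol).  Times are days from recruitment.

## Proteomics screen

Label-free urinary intensities carry two nuisance scales; normalisation
divides each intensity by the sample's alcohol-dehydrogenase spike-in signal
(instrument response), then by urinary creatinine (urine concentration).
Proteins without ≥ 2 unique peptides in any sample are discarded.  Each
retained protein with ≥ 80% completeness is correlated against the
senescent-epithelium percentage with Spearman's rho (average ranks on ties),
p-values from the t-approximation t = ρ√((n−2)/(1−ρ²)) (an exact permutation
test is available for n ≤ 10), and Benjamini–Hochberg adjustment across the
tested family only (constant or low-completeness proteins are reported as NA
and do not inflate the family size).  The shortlist keeps adjusted p < 0.05
and ρ strictly > 0.5, then flags membership of a packaged SASP protein list.
The packaged list is a synthetic stand-in (see `data/sasp_list_synthetic.txt`)
and should be replaced with a real SASP-atlas export for real analyses.

qPCR relative expression uses ΔCt = Ct(target) − mean Ct(HPRT1, PPIA) and
reports 2^(−ΔΔCt) against the control-group mean, so controls map to 1 and
upregulation to values > 1.  (Sources sometimes print the exponent without
the sign; this convention is the one under which an upregulated transcript
yields a value above 1.)

## Radial spatial enrichment

Cells are CDKN1A+ when ≥ 2 CDKN1A transcripts fall within their segmentation
boundary (the 2-transcript floor guards against assay noise and segmentation
error).  For a query population (e.g. CDKN1A+ proximal-tubule cells), CLU
transcripts are binned into annuli (r−1, r] µm, r = 1…50, around every query
centroid.  The aggregated count per annulus gets a +1 pseudocount and is
divided by the annulus area π(r² − (r−1)²) and the number of query cells,
giving a density q(r); a background density b(r) is computed identically
around 10,000 cells sampled uniformly without replacement (seeded; the whole
population is used when it is smaller).  The profile is e(r) = log2(q/b).

Numerical choices worth stating:

* All distances are µm (a 50 mm radius would exceed a needle biopsy by two
  orders of magnitude, so millimetre readings of the protocol are treated as
  µm).
* The pseudocount is applied to counts *before* density normalisation, so
  that a query set equal to the background population gives e(r) ≡ 0
  exactly; applying log2(ratio+1) instead would break that null property.
* "Number of cells in the search area" is read as the number of query
  (respectively background) centroids, N_q; the alternative reading — cells
  encountered inside each annulus — is available as
  `normalize_by="annulus_cells"`.
* Query cells are not excluded from the background pool, and no edge
  correction is applied at tissue boundaries; both match the emulated
  procedure and bias query and background identically under the null.
* Transcripts at exactly the centroid fall in the innermost annulus.

Differential expression between CDKN1A+ and CDKN1A− cells uses the two-sided
Wilcoxon rank-sum test (exact for small tie-free samples, otherwise the
normal approximation with tie correction), BH adjustment across genes, and
log2 fold change of group means with a +1 pseudocount.

## Outcome analysis

The outcome cohort excludes participants at low progression risk (baseline
eGFR ≥ 60 mL/min AND uACR ≤ 30 mg/mmol) and those with baseline
eGFR < 20 mL/min (already at or near the endpoint).  The composite
progression endpoint is the earliest of: start of renal replacement therapy;
eGFR < 15 mL/min sustained > 90 days; eGFR below 60% of baseline sustained
> 90 days.  "Sustained" is measurement-driven, with no interpolation: a
below-threshold measurement m is an event when every later measurement up to
and including the first one more than 90 days after m is also below the
threshold, and such a confirmatory measurement exists.  Death censors;
otherwise censoring is at last follow-up.

The uCCR threshold is chosen on the biopsy cohorts: ROC of uCCR against
membership of the top tertile of senescent-epithelium percentage (tertile
cut at the 2/3 quantile, linear interpolation, ties upward), AUC computed
exactly as the Mann–Whitney U statistic over n₁n₂, 95% CI by seeded
stratified bootstrap (2000 replicates; DeLong optional), and the threshold
maximising sensitivity among those with specificity ≥ 0.9 (ties toward
higher specificity, then lower threshold).

Survival models use lifelines: Kaplan–Meier curves with the two-group
log-rank test, and Cox proportional hazards with Efron tie handling, Wald
CIs, Harrell's c-index, and a proportional-hazards check correlating scaled
Schoenfeld residuals with event rank time.  ln(uACR) floors uACR at
0.1 mg/mmol.  The c-index contribution of uCCR is reported by refitting the
same records without the biomarker covariate.

## Synthetic data generator

The generator is the package's study stand-in; every stage above is
validated against it.  All generators are pure functions of (config, seed),
with one global seed split into fixed per-generator substreams.

* **Cohort.**  Latent senescence lives on the logit scale (keeping
  percentages in [0,100]): logit s = logit(0.052) + 0.02·(age−56) −
  0.012·(eGFR−45) + N(0, 0.45).  Age ~ N(56, 14) clipped to [19, 81] and
  baseline eGFR ~ lognormal(ln 45, 0.79) clipped to [8, 133] match the
  emulated cohort's medians and ranges; the intercept reproduces a ~5%
  median senescent fraction.  uCCR and uACR couple to senescence through
  Gaussian copulas on rank-based normal scores — the copula correlation
  r = 2·sin(πρ_s/6) makes the Spearman target exact in distribution; the
  uCCR target defaults to 0.6.  uCCR ~ exp(3.98 + 1.2 z) puts ~24% of
  participants above 124.5 µg/mmol.  Serum creatinine is obtained by exact
  piecewise inversion of CKD-EPI.
* **Biopsy cells.**  Epithelial cells (75%) are senescent with probability
  s/100 exactly; non-senescent epithelia split 1% double-positive, 5%
  proliferating, 94% double-negative.  The estimator is therefore unbiased
  by construction, which the tests verify over replicates.
* **Proteome.**  331 proteins, 8 true markers.  Marker j's log signal is
  μ_j + β_j·z(senescence) + σ·ε with σ the measurement-noise SD (default 1)
  and β_j set from a per-marker Spearman target via the copula relation, so
  σ → 0 drives marker correlations to 1.  Default targets span 0.50–0.75;
  the clusterin analogue sits at 0.65, the upper edge of the emulated
  0.5–0.6 observations, chosen by a power analysis: at n = 51 the
  probability that an observed rho exceeds the strict 0.5 shortlist cut is
  ≈ 0.83 for a generated 0.60 but ≈ 0.93 at 0.65, and reliable recovery
  (≥ 90% of replicates) requires the latter.  Non-marker proteins are
  independent lognormals.  Observed intensities are multiplied by a
  per-sample urine-concentration factor (shared with the creatinine column)
  and an instrument-response factor (shared with the ADH spike-in), which
  normalisation must remove; 2% of intensities are missing at random and
  ~5% of noise proteins carry a single unique peptide to exercise the
  filter.  Unlike the real screen — where many urinary proteins co-vary
  with kidney damage — the synthetic noise proteins are fully independent
  of senescence, so the screen's discovery count is smaller than a real
  study's; passing tests show ranking and error control, not real-urine
  covariance structure.
* **Spatial field.**  3000 cells uniform on a 500×500 µm field (PT 50%,
  LOH/DCT 30%, other 20%; ~0.012 cells/µm², a plausible subcellular-
  resolution platform density).  15% of PT cells (half that rate elsewhere)
  receive ≥ 2 CDKN1A transcripts.  CLU transcripts are a homogeneous
  Poisson background (0.02/µm²) plus an additive uniform-in-disc Poisson
  bump (0.1/µm² within 20 µm) around every CDKN1A+ PT centroid — additivity
  matches the enrichment statistic's density ratio.  Per-cell CLU counts
  are transcripts within a 7 µm cell radius.  No tissue architecture
  (tubular geometry, lumina, boundary effects) is modelled.
* **Outcomes.**  Exponential event times under a proportional-hazards model:
  baseline hazard 1e-4/day (≈ 10% three-year risk at the covariate
  reference, matching the emulated low-uCCR progression rate), log-HR
  defaults ln(2.2) for high uCCR and small fixed slopes for eGFR, ln(uACR),
  age and SBP so multivariable adjustment is exercised.  Censoring is
  independent (administrative at 3 years, random loss 1e-4/day, death
  4e-5/day).  eGFR visit series (every 120 days) decline linearly to ~50%
  of baseline at the event and continue past it so the sustained rule can
  confirm; visits carry 3% multiplicative noise, and serum creatinine is
  derived from each visit eGFR by inverting CKD-EPI.

## Problem sizes and verification

The test suite checks each operation against an independent oracle at small
n (hand arithmetic, closed forms, exhaustive enumeration of permutations,
rank assignments and hypergeometric tables, and a quadratic-time all-pairs
reference for the radial statistic, exact to the bit on random fields), and
each simulation-level property at the scale where its Monte-Carlo error is
well inside the asserted margin: 50 null spatial fields of 3000 cells
(mean |e| ≈ 0.06 against a 0.15 bound), 100 screen replicates at n = 51,
200 null-screen replicates for FDR control, and 10 outcome replicates at
n = 2000 with the hazard ratio averaged on the log scale.  These sizes are
the package's chosen verification conditions and keep the whole suite to a
few minutes.

## Known limitations

* The generator's independence assumptions (noise proteins, censoring) are
  idealisations; calibration results transfer to real data only insofar as
  those hold.
* The radial statistic shares the emulated procedure's known biases: no
  edge correction and a pseudocount that shrinks log-ratios toward zero in
  sparse annuli.
* The endpoint rule is measurement-driven; sparse visit schedules delay
  event detection relative to the underlying crossing time.
* Competing risks are out of scope — death is censoring, as in the
  emulated analysis.
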