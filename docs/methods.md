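# Methods

This note documents the models, estimators, defaults and known limitations
behind `cbcsig`. It describes what the code computes; every empirical figure
quoted here is recomputed by the test suite or by `scripts/acceptance.py`.

## Cutoff Behavioral Criteria

Each behavioral measure carries a direction flag. For measures where *low*
values indicate an affected (anxious) animal — time, entries and distance in
anxiogenic zones — the cutoff is the 20th percentile of the control
distribution; for measures where *high* values do — latencies to anxiogenic
zones, time in protected zones, mean startle, sensitization — the 80th.
Percentiles are estimated by linear interpolation between order statistics
(numpy's default); a nearest-rank (inverted CDF) option is available because
small control groups make the estimator choice visible. Binary scoring is
strict: a value exactly at the cutoff is unaffected. This tie rule is
conservative and deterministic; with ~19 controls ties are measure-zero for
continuous metrics but matter for degenerate (constant) control
distributions, where no animal can be flagged.

The default registry contains 20 avoidance measures — 5 per open field test
(latency to center, center entries, center time, total distance, center
distance) × bright and dim, 3 per elevated plus maze (open-arm latency,
open-arm time, closed-arm time) × bright and dim, 4 for the light-dark box
(distance, latency to the light side, light-side entries, light-side time) —
which is the only registry consistent with an avoidance composite bounded by
20. Mean startle and sensitization are scored the same way (80th percentile)
but summed into a separate startle sub-score and reported alongside the 0–20
avoidance score; the total used for classification is their sum by default.
This resolves an ambiguity in composite definitions that cap the score at 20
while also plotting startle sub-scores: the package reports both sub-scores
and a configurable total rather than forcing one reading.

Classification uses the observed control range: vulnerable ⇔ total >
max(control totals), with equality resilient. Thresholds are derived from
all control animals present at scoring time, including controls later
excluded from sequencing.

Sequencing selection takes the k lowest- and k highest-scoring stress
animals (default 3 + 3) and k controls (default 6) evenly spaced by rank
across the control score distribution; ties break lexicographically by
animal id so selection is deterministic.

## Startle metrics

Activity is a uniformly sampled, non-negative signal (a percent pixel-change
surrogate). Amplitude for one pulse is max(activity in [onset, onset+50 ms])
− mean(activity in [onset−1 s, onset)). Two decisions deserve note, both
configurable because the common phrasing "the 50 ms surrounding the pulse"
is ambiguous: the response window *follows* onset (startle latency follows
the pulse; a centered window would dilute the response with pre-pulse
baseline), and baseline is a per-trial pre-pulse mean rather than a
per-session constant. Amplitudes are not floored at zero — the difference
formula permits negatives — with flooring available as an option.
Sensitization is 100·(mean of pulses 13–15 − mean of pulses 1–3)/(mean of
pulses 1–3); it is undefined (an error) when the first-triad mean is zero,
and is scale-invariant by construction.

## Physiology

Percent weight change is 100·(w₁ − w₀)/w₀ (negative = loss). Correlations
are sample Pearson r with two-sided p from the t distribution on n−2 df;
animals with missing values are dropped pairwise with a logged warning,
mirroring cohorts with incomplete weight records. Variance explained is
100·r², rounded to the nearest integer by default (r = 0.5512 → 30).

## Expression quantification and the DE engine

TPM divides counts by gene length and scales each sample to one million;
columns conserve 10⁶ exactly and the transform log₂(TPM+1) is used wherever
expression meets behavior. Library sizes are normalized by median-of-ratios
size factors with a total-count fallback when no gene is expressed in every
sample.

The DE engine is deliberately simple and documented as a replaceable
stand-in — the signature logic accepts DEG tables from any engine, and
empirical-Bayes engines (posterior probability of differential expression)
map onto the `adjusted_p` column as 1 − PPDE. Per gene:

* group means m₁, m₂ of size-factor-normalized counts;
* method-of-moments dispersion φ̂ = (pooled within-group variance − pooled
  mean)/pooled mean², clipped at 0 and **winsorized at 3× the common
  dispersion** (the across-gene mean of the unclipped estimates, the less
  biased choice); winsorization is the standard moderation against the df≈4
  noise of per-gene variance estimates at n = 3 per group;
* shrinkage φ* = 0.5·φ̂ + 0.5·φ̄ toward the common dispersion;
* Wald statistic z = ln((m₂+½)/(m₁+½)) / √((1/m₁′ + φ*)/n₁ + (1/m₂′ + φ*)/n₂)
  by the delta method from Var = μ + φμ²;
* reference distribution t with effective df = 1.5·(n₁+n₂−2)/(1−s)² where
  s = 0.5 is the shrinkage weight (24 at n = 3/3). The Satterthwaite value
  for shrinkage alone is (n₁+n₂−2)/(1−s)² = 16; winsorization further
  reduces the variance of the moderated dispersion, and the 1.5 inflation
  was calibrated by simulation against the nominal type-I error;
* Benjamini–Hochberg adjustment; significant ⇔ adjusted p < 0.05.

Measured operating characteristics at n = 3 vs 3, 400 genes, baseline mean
100 (100 replicates; recomputed by the acceptance script): raw type-I error
0.045–0.055 across dispersions {0.01, 0.05, 0.2}; empirical FDR ≤ 0.09 with
20 planted genes; power ≥ 0.95 for a single log2FC = 2 gene at dispersion
0.05. A plain standard-normal reference inflates the FDR to ~0.17 at
dispersion 0.2; an unmoderated t(4) reference destroys power at these
sample sizes.

BH adjustment is implemented as the standard step-up with monotonicity
enforcement and capping at 1, and agrees exactly with
`statsmodels.stats.multitest.multipletests(method="fdr_bh")`. Note that BH
adjustment is **not** idempotent as a function: re-adjusting (0.2, 0.9) —
itself a valid BH output of (0.1, 0.9) — yields (0.4, 0.9). Any
implementation for which re-adjustment is always a no-op is incorrect.

Sample QC mirrors PCA-based exclusion: samples are projected onto the first
two principal components and flagged when their nearest-neighbor distance
exceeds k× (default 3×) the median nearest-neighbor distance. The rule is a
stated, deterministic stand-in for by-eye cluster inspection.

## Signature overlap

Gene identity is the pair (case-preserved symbol, normalized name), where
normalization case-folds, collapses whitespace, strips balanced
parenthetical aliases (including nested ones) and trims edge punctuation.
The rule exists because symbol-only matching merges genuinely distinct rows
that share a symbol — the packaged tables contain "Rpl19 / Ribosomal
Protein L19" and "Rpl19 / Ribosomal protein L9-like", and a symbol-only
intersection would inflate the resilience overlap from 5 to 6. A regression
test pins this. Rows labeled "Unknown" are retained but flagged unnamed;
the packaged C-vs-SL table prints 25 rows of which 24 have assigned names —
the table is preserved as printed rather than edited.

Overlaps are set-based and ignore fold-change direction by default (Venn
logic); a direction-consistent mode intersects only genes regulated the same
way in both parent contrasts.

The outlier-driven filter re-tests a significant gene after removing the
single sample with the largest absolute within-group z-score; the gene is
flagged when the re-test is no longer significant. The published criterion
for "driven by outlier values" was visual/supplementary; this leave-one-out
re-significance rule is a stated, reproducible stand-in, and the removed
sample, both p-values and the decision are logged. Callers should pass the
DE run's common dispersion as the test's dispersion context: the gene's own
moment estimate is inflated by the very outlier under scrutiny, which would
make outlier-driven significance nearly undetectable.

## Synthetic cohorts

The generator emulates the analyzed design: 19 controls and 20 stress
animals, the stress group a latent mixture with vulnerable fraction 0.3.
Mechanics:

* Latent anxiety a = Δ·1[vulnerable] + δ, δ ~ N(0,1), with Δ =
  `anxiety_shift_sd` (default 3, in control-SD units).
* Avoidance metric value, in standardized affected-direction units:
  Δ·1[vulnerable] + w·δ + √(1−w²)·ε with metric loading w = 0.4 and
  ε ~ N(0,1) i.i.d. Controls therefore follow each metric's stated control
  distribution exactly (Gaussian by default; a moment-matched lognormal is
  available for latencies), vulnerable animals are shifted by exactly Δ
  control-SDs on every avoidance metric, and metrics correlate within
  animal through δ, reproducing the consistent-across-assays avoidance
  phenotype. The loading 0.4 was chosen so that control composite totals
  span roughly 0–10 with ~19 controls (matching the reported spread of
  control scores) while vulnerable animals at Δ = 3 score near the top of
  the scale.
* Startle traces: 15 pulses of 110 dB at 15–30 s intervals on a noisy
  baseline; transient height = gain·intensity/110, peaking exactly at onset
  and decaying within 40 ms, so the noise-free closed loop through the
  startle module returns the injected height exactly. Per-animal gain is
  log-normal and **independent of the latent class** — in the emulated
  design group differences are carried by avoidance, not startle, so the
  generator does not build a startle–phenotype association in.
* Physiology: body weight ~ N(400, 25²) g; percent weight change N(+0.5, 1)
  for controls and N(−5, 2²) for stress; corticosterone (ng/mL) 30 min into
  stress N(60, 20²)/N(450, 90²) (control/stress) and at 3 h N(50, 15²)/
  N(300, 80²), with the 3-h value constructed to correlate with the
  cohort-standardized latent anxiety at `cort_behavior_r` (default 0.55).
  The correlation is imposed on the standardized latent score, so it is
  exact in expectation for a homogeneous cohort; in mixed cohorts the
  group-level mean differences add between-group correlation on top.
* Counts: gene-wise negative binomial via gamma–Poisson with the requested
  dispersion, library sizes uniform on ±20%, gene lengths log-uniform on
  500–5000 bp unless supplied, and planted genes multiplied by 2^log2FC in
  the named sample groups. A gene shifted in stress-low only produces the
  resilience overlap pattern; shifted in stress-high only, the
  susceptibility pattern.

One master seed is split into per-stage substreams (assignment, metrics,
traces, physiology), so outputs are byte-identical across reruns and stages
are individually reproducible.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: test-order and habituation effects across the
two-day battery, floor/ceiling effects and skew of real behavioral metrics
beyond the optional lognormal, video artifacts in activity traces,
gene–gene expression correlation, mean–dispersion trends, batch effects,
and any real biological coupling between behavior and expression other than
the planted fold changes. The control means/SDs in the default registry are
placeholders with realistic orders of magnitude, not measured values, and
are fully user-configurable.

## Problem sizes and numerical choices

Simulation-based tests and the acceptance script use 100 replicates for
operating characteristics, 400 genes (baseline mean 100) for DE calibration
and power, 300 genes for end-to-end recovery at 5 control + 3 + 3 samples,
and full 39-animal cohorts for classification recovery; threshold
calibration uses 10,000 controls. These sizes give stable estimates in
seconds on one CPU. Degenerate inputs are errors rather than silent
defaults throughout (all-zero count columns, empty stimulus schedules,
zero-variance correlations, sub-minimum group sizes); the single deliberate
soft behavior is the outlier filter under a degenerate design (removal
leaving <2 samples per group), which flags with a warning rather than
failing a pipeline run.

## Known limitations

* The composite total's treatment of startle (added to, not folded into,
  the 0–20 scale) is one of two defensible readings; both sub-scores are
  always reported so either total can be formed.
* The DE stand-in is a calibrated moderated Wald test, not an
  empirical-Bayes posterior model; at dispersions ≫ 0.2 or counts ≪ 10 per
  group its calibration degrades and power at n = 3/3 falls quickly.
* Correlation recovery between corticosterone and composite scores at the
  study's n (18) is dominated by sampling noise: the Fisher-z standard
  deviation at n = 18 is ≈ 0.26, so single-cohort estimates of a true 0.55
  correlation scatter widely; tests assert the median across seeds, not
  tight per-seed bounds.
* Gene names are opaque strings; no annotation database is consulted.
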