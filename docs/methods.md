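# Methods

## Problem and setting

`cogscreen` analyses the diagnostic accuracy of discrete cognitive screening
totals — primarily the Montreal Cognitive Assessment (MoCA), a 0–30 integer
score on which lower values indicate greater impairment — in a memory-clinic
setting. Four diagnostic groups are modelled: registry-recruited normal
controls (NC), consecutively referred clinic patients whose work-up was
normal (NF), and patients with mild or major neurocognitive disorder (Mild
NCD, Major NCD; their union is the patient pool). The clinically relevant
contrasts are Mild+Major NCD vs NF and Mild NCD vs NF (the screen must
separate impaired patients from clinic attendees who turn out to be
healthy), with NC serving as the normative reference for the
percentile-based cut-off and the dual-cutoff construction.

Throughout, the orientation is fixed: a cut-off `t` classifies a subject as
positive (impaired) iff score ≤ `t`, written `t/(t+1)`. Sensitivity is the
fraction of patients at or below the cut-off, specificity the fraction of
non-patients above it, and the correct classification rate (CCR) is the
unweighted mean (sens + spec)/2 = (J + 1)/2 with Youden's J = sens + spec − 1.

## Cut-off strategies

Four single-cut-off strategies are implemented over the per-threshold metric
grid (thresholds −1..30 for integer scores, so both degenerate classifiers
are present; for continuous z-scores the grid is the sorted unique observed
values plus one anchor below the minimum, which reproduces "≤ −1.36"-style
cut-off labels):

* **fixed** — an externally given conventional cut-off (default 25/26, the
  instrument's original recommendation), evaluated, not searched.
* **balanced** — argmin |sens − spec| over the grid.
* **youden** — argmax J over the grid.
* **percentile** — derived from controls alone: the empirical q-quantile
  (linear-interpolation convention, numpy's default type-7) of NC scores,
  then `floor(quantile)`, so ≈ q of healthy subjects fall at or below the
  cut-off and target specificity is ≈ 1 − q. Default q = 0.10. The floor
  (rather than a "largest t with cumulative frequency ≤ q" rule) matters on
  discrete data: with controls distributed like round(Normal(26.5, 2.4)),
  ~12% of controls score ≤ 23 while ~5% score ≤ 22, and the quantile at 23.4
  must select 23, not 22.

Ties in the balanced and Youden searches are broken toward the lower
threshold — the higher-specificity side — reflecting the priority of
avoiding false-positive classifications in screening for irreversible
conditions. One published table reports a "balanced" cut-off one point above
the strict argmin of |sens − spec| for the pooled patient group; the
balancing rule there is ambiguous, and this package implements the strict
argmin.

## ROC and AUC

The ROC curve is the empirical polygon over the threshold grid. AUC is the
Mann–Whitney estimator (probability that a random patient scores below a
random control, ties counted ½), computed by midranks; it equals trapezoidal
integration of the package's own ROC polygon to machine precision, and the
test suite asserts both this equivalence and agreement with an exhaustive
pair-enumeration oracle.

Correlated AUCs of two markers measured on the same subjects are compared by
a paired, class-stratified bootstrap: subjects are resampled with
replacement within each class (every replicate keeps the original class
sizes), the AUC difference is standardized by its bootstrap SD, and a
two-sided p-value is taken from the normal approximation,
p = 2(1 − Φ(|D|)). Default B = 2000; the replicate count, seed and method
tag are recorded in every result. DeLong's analytic variance is deliberately
not offered — the bootstrap is the procedure this pipeline standardizes on.
AUC confidence intervals are percentile bootstrap (the interval method used
in the original analysis is not stated; outputs are labelled accordingly).

## Dual cut-offs with an indecisive area

From the cumulative frequency curves — sens(s) = fraction of patients
scoring ≤ s, spec(s) = fraction of controls scoring > s — two cut-offs are
placed for target rates (default 90%/90%):

* lower (not healthy): the largest s with spec(s) ≥ target specificity;
* upper (not pathological): the smallest s with sens(s) ≥ target sensitivity.

Scores in (lower, upper] form the indecisive area, where classification is
deferred to a comprehensive assessment or re-screening. The strict ≥ rule
guarantees the targets on the defining samples and is the default; a
`nearest` mode instead picks the score whose achieved rate is closest to the
target (ties to the conservative side), matching the looser reading of an
"approximately 90%" aim under which a cut-off achieving 88% specificity can
be preferred to one achieving 93%. For non-overlapping groups the lower
cut-off can exceed the upper one; the indecisive set is then empty, every
score is decided, and "not pathological" takes precedence in the
doubly-satisfied band — a totality convention for a case the clinical data
never produce. Raising both targets can only widen the indecisive set
(enforced as a property test).

## Score adjustments

The instrument's education correction adds one point when formal education
is below 12 years, capped at the 30-point maximum (the cap is the
instrument's standard scoring convention), and is applied exactly once: the
adjusted score is always recomputed from the raw score inside the pipeline
and never read from input files. Analyses use the education-adjusted score
by default (`--no-edu-adjust` to disable).

Demographically corrected z-scores are `(raw − predicted)/residual_sd` with
a linear prediction in age, education and a male indicator. The published
normative coefficients are not reproducible from the study report, so the
model is configuration; the bundled `PLACEHOLDER_NORM_MODEL` is synthetic —
slopes of −0.05 points/year of age, +0.15 points/year of education, −0.2
points for men, with intercept 28.2404 and residual SD 2.455 solved
analytically so that simulated NC cohorts yield z ≈ Normal(0, 1). When an
input file already carries z values they win over any supplied model (the
original study computed them externally) and a warning is logged.

## Synthetic cohort generator

The generator defines the study conditions for every end-to-end test: group
sizes 283 (NC), 49 (NF), 159 (Mild), 288 (Major); MoCA 26.5 (2.4) / 26.5
(2.2) / 22.0 (3.6) per group with the patient pool at 19.1 (4.5); MMSE 29.2
(0.9) / 29.0 (1.0) / 27.2 (2.2) with pooled 25.1 (3.5); z-scores 0.0 / 0.1 /
−1.5 / −2.1 (SD 1.0); truncated-normal demographics within age 65–91 and
education 7–20 with the published per-group means, SDs and sex fractions.
Only pooled patient moments are published, so the Major group's parameters
are solved at runtime from mixture-moment identities
(`complement_moments`); for MoCA this gives mean 17.50, SD 4.13.

Scores are drawn as round(Normal(mean, sd)) — half away from zero — and
clipped to [0, 30]; demographics are truncated normals rounded to whole
years; sex is Bernoulli; the z-score is drawn directly from its group normal
unless a normative model is supplied, in which case it is computed from the
simulated raw score and demographics. A single global seed drives
deterministic per-group substreams, so any subset of groups is reproducible.

Two deliberate simplifications: scores are drawn independently within
subject (real MoCA/MMSE totals correlate, so cross-score comparisons on
synthetic data understate that correlation — which makes the paired
bootstrap conservative rather than anticonservative), and patient scores are
symmetric Gaussians where the clinical distributions are left-skewed (the
published patient range reaches down to 2 points). Passing tests therefore
demonstrate correctness of the estimators under a second-moment emulation,
not distributional fidelity to clinic data; AUC tolerances of ±0.02 in the
end-to-end checks absorb most of the Gaussian-vs-skew gap.

**Ceiling censoring.** Clipping at the 30-point ceiling censors the upper
tail, so a score with nominal mean close to 30 realizes a slightly lower
mean and SD than its Gaussian target: Normal(29.2, 0.9) MMSE loses ≈ 0.07
points of mean and ≈ 9% of SD; Normal(26.5, 2.4) MoCA loses ≈ 0.07 points
and ≈ 5% of SD. These are exact properties of the specified transform, not
sampling error, and `discrete_score_moments` returns the realized moments in
closed form. Parameter-recovery tests compare empirical moments to these
exact values (mean within 3 SE, SD within 2% at n = 10,000) and to the
nominal targets wherever the ceiling is more than 3 SD away (3 SE / 5%
bands); z-scores, which are not discretized, recover their targets directly.

## Inference components

* Sensitivity/specificity intervals: exact Clopper–Pearson (beta-quantile)
  intervals, endpoints 0 and 1 by convention at the boundaries. The original
  report's interval method is unstated and its printed intervals are far
  narrower than binomial intervals at the stated n; no attempt is made to
  match them — outputs are method-tagged instead.
* Paired accuracy comparison: McNemar's test on per-subject correctness
  indicators; exact two-sided binomial when the discordant count b + c < 25
  (standard small-sample practice), otherwise chi-squared with continuity
  correction; p = 1 by convention with no discordant pairs.
* Multiplicity: Holm step-down adjustment, applied within each user-declared
  comparison family (which comparisons form a family is an analysis choice,
  not something the package can infer).
* Generic intervals: stratified percentile bootstrap (not BCa — simplicity
  and determinism), seed and B recorded.

## Problem sizes and determinism

End-to-end checks use n = 10,000 per simulated group, at which the Monte
Carlo SE of an AUC is ≈ 0.003 and of a percentage ≈ 0.3 points — an order of
magnitude inside the acceptance bands — while the whole suite runs in well
under a minute. The null-calibration check of the paired bootstrap uses 100
replicate datasets of 200 + 200 subjects with B = 300. All randomness flows
through explicit `numpy.random.Generator` seeds; identical configuration and
seed give byte-identical outputs.

## Known limitations

* The generator cannot reproduce the original cohort's exact operating
  points (raw data are unavailable); published sensitivity/specificity at
  specific cut-offs are recovered only up to the Gaussian emulation.
* No within-subject correlation between MoCA and MMSE unless configured.
* The indecisive-area construction is purely rate-targeted; no costs or
  utilities are modelled for the deferred-decision zone.
* Predictive values are computed from (sens, spec, prevalence) analytically;
  they inherit the memory-clinic prevalence (90.1% for the patient pool) and
  must be re-derived for low-prevalence screening settings.
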