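# Methods

This note documents the models and procedures implemented in `dilimet`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Clinical typing

The R-score is the ratio of fold-elevations of ALT and ALP over their
upper normal limits (UNLs).  The UNL defaults, 56 U/L (ALT) and 147 U/L
(ALP), are taken to coincide with the rule thresholds (a recovered patient
is one with both enzymes below their UNLs); both are overridable.  The
rule set is applied in the order recovered → cholestatic → hepatocellular
→ mixed.  The printed inequalities leave two gaps, which we resolve
explicitly rather than silently: R exactly 2 with elevated enzymes maps to
*mixed*, and an elevated-enzyme record matching no rule (e.g. R < 2 with
normal ALP but elevated ALT) is labelled *unclassifiable*.  Whether R
should be computed from first-elevation or peak enzyme values is a known
clinical ambiguity; the package computes per-sample R-scores and leaves
that choice to the caller.

## QC-SVRC drift correction

Per feature and batch, an ε-insensitive support-vector regression (RBF
kernel) of pooled-QC intensity on injection order models the instrumental
trend.  Parameters:

- **C** (regularization) — fixed at the median QC intensity (AU); no search.
- **ε** (tube half-width) — grid of 8 linear steps over 2.5–8 % of the
  median QC intensity, matching expected instrumental precision.
- **γ** (kernel width) — 13 log-spaced steps over [1, 10⁴], after
  rescaling injection order to [0, 1] within each batch so the width range
  is comparable across batch sizes.
- Selection — leave-one-out RMSECV, exhaustively over the 8 × 13 grid;
  ties break to the smallest γ, then the smallest ε (smoother trend).

Correction is multiplicative, `x · C / trend(order)`, which normalizes
every injection to the QC reference level and keeps intensities positive.
Trend values at or below 1 % of C are floored there (with a provenance
warning) rather than allowed to blow the ratio up.  A batch needs at least
4 QC injections; all-equal QC intensities short-circuit to a constant
trend.  ESI⁺ and ESI⁻ data are corrected independently within their own
batches and combined afterwards.

One observed property worth knowing: when a feature's QC values are pure
scatter (no coherent trend), the LOO-RMSECV surface is nearly flat and the
grid's argmin occasionally lands on a near-interpolating (large-γ) node,
whose in-sample trend absorbs part of the QC scatter.  Such features can
then evade the downstream D-ratio\* filter.  In the synthetic studies the
filter still catches the majority of planted QC-unstable features, and the
tests assert exactly that (≥ half), not perfect capture.

## Quality filters

- **D-ratio\*** = 100 · robust\_sd(QC) / robust\_sd(study), with
  robust\_sd = 1.4826 × median absolute deviation; features above 20 % are
  removed, computed after within-batch correction.  Because each batch's
  QC is pooled from its own samples, QC values are centered per batch
  before dispersion is measured; otherwise pool-composition differences
  would masquerade as technical variance.  Zero study dispersion yields a
  +∞ marker (feature removed).
- **Blank filter** — a feature is removed iff 10 × max(blank) >
  median(study), applied to post-correction intensities (the choice of
  pre- vs post-correction intensities is undeclared upstream; post is the
  default and the stage order is configurable in code).
- **Group-intensity filter** — keep a feature iff the median intensity in
  at least one phenotype group strictly exceeds 15000 AU.
- **Between-batch scaling** — per feature and batch *b*, divide by
  s\_b = median(bridge in *b*) / median(bridge pooled); bridge duplicates
  are then dropped from every batch but the last.  Requires ≥ 3 bridge
  samples per batch; a zero pooled median flags the feature out.

All filters are idempotent.

## Univariate screening and PCA

Welch's unequal-variance two-sided *t*-test per feature,
Benjamini–Hochberg step-up adjustment *within* each comparison (the three
pairwise comparisons are not pooled), significance at adjusted p < 0.05.
Two equal constant groups return (t = 0, p = 1) rather than NaN.  PCA is
computed by SVD of the autoscaled study submatrix (autoscaling: mean 0,
sample SD 1 per feature, ddof = 1; constant features dropped).

## One-vs-rest PLS-DA with subjectwise double cross-validation

Each of the three binary models codes y as 0/1 (decision threshold 0.5)
and is fitted by NIPALS with per-component deflation of X; the regression
vector is W(PᵀW)⁻¹Qᵀ.  Non-convergence of a latent variable within 500
iterations at tolerance 1e-10 is an error; rank exhaustion truncates the
LV count.  VIP follows the standard definition (y-variance–weighted
squared weights; mean VIP² = 1 identically).

Cross-validation is *subjectwise*: patients, not samples, are randomized
to folds, stratified on the patient-level majority label, redrawing (up to
100 times) until every training split contains every class.  Double CV
uses k\_outer = 7 and k\_inner = 5 (fold counts are not prescribed by the
method's sources; these balance patient counts at the study's scale and
are configurable); the inner loop selects the LV count by CV
classification accuracy (ties to fewer LVs, max 10), and autoscaling is
refit inside every training split to avoid leakage.  Every sample receives
exactly one out-of-sample prediction; the tested patients are asserted
absent from every model that predicts them.

Significance: labels are permuted at the *patient* level (preserving the
repeated-measures structure), the full 2CV pipeline is re-run per
permutation, and p = (1 + #{permuted AUROC ≥ observed}) / (n\_perm + 1);
100 permutations by default (50 in the slowest test to stay within the
suite's runtime; the floor of the p-value scales accordingly).  Note that
a *single* permuted 2CV AUROC is widely dispersed (SD ≈ 0.1 at this cohort
size, because a random patient relabelling can correlate by chance with
the three real clusters); calibration statements therefore refer to the
permutation distribution's center, not to one draw.

Mixed-type samples are never trained on; the three full models (LV count
selected on all training data) predict them.  A combined PLS2 model with
2 LVs on the union of VIP > 1 features provides the loading/score
overview.

## Ternary phenotype mapping

The three predictions are clipped to [0, 1] and divided by their sum,
giving (cholestatic, hepatocellular, recovered) shares on the 2-simplex;
an all-zero triple maps to the centroid with an explicit indeterminate
flag so plots never silently drop samples (the upstream description of the
normalization says only "relative constrained values"; sum-normalization
is the minimal reading and is declared here).  The simplex is embedded as
an equilateral triangle of side 1 — cholestatic (0,0), hepatocellular
(1,0), recovered (½, √3⁄2) — and the recovery distance is the Euclidean
distance to the recovered vertex, dimensionless in [0, 1].  Trajectories
order a patient's coordinates by timepoint; duplicate (patient, timepoint)
pairs are an error.

## Synthetic-study generator

The generator is first-class, tested code; it defines the conditions under
which the pipeline's behaviour is asserted.

Intensity model per sample s, feature f:

```
x(s,f) = baseline_f · 2^(w_s · effect_f(label_s)) · bio_{patient(s),f}
         · drift_f(order_s) · lognormal(1, noise_cv)
```

- **Baselines** log-uniform over [10⁴, 10⁶] AU, so the 15000 AU filter is
  exercised on both sides.
- **Effects** (log2, vs the recovered baseline): bile-acid-like features
  +2.0 cholestatic / +0.3 hepatocellular; phospholipid-like −0.8 / −2.0;
  amino-acid-like +0.2 / +1.8 (15 %, 15 % and 10 % of features).  The
  source study reports the discriminant metabolite classes but not effect
  sizes; these magnitudes are free simulation parameters chosen to give
  clearly separable yet noisy phenotypes.  A third, hepatocellular-leaning
  class is required at all: bile-acid and phospholipid effects alone
  cannot separate hepatocellular from cholestatic in both directions.
- **Mixed patients** get a convex blend of the two injury effect vectors
  with patient-level weight uniform on [0.3, 0.7].
- **Recovery**: effect weights decay geometrically, w_t = (1 − rate)^t,
  default rate 0.25 — patients improve visibly across 2–5 follow-up
  samples, as in the cohort emulated (1–9 samples per patient, mean ≈ 3.6).
  A sample whose weight has fallen to ≤ 0.5 is relabelled (and given
  chemistry of) *recovered*.
- **Biological variation**: one multiplier per patient and feature, shared
  across the patient's timepoints, |1 + b_f·z| with z ~ N(0,1) and b_f
  uniform on [0.7, 1.1].  The folded-Gaussian form gives the large
  inter-individual dispersion of untargeted serum panels *without*
  displacing the pooled-QC level (an arithmetic mean) far above the study
  median — under a comparably dispersed lognormal the pool sits at
  e^(σ²/2) times the median and the D-ratio\* of even well-behaved
  features saturates near its threshold.  Real serum features are more
  right-skewed than this; that skewness is a property the generator does
  not emulate, so passing tests say nothing about D-ratio behaviour on
  extremely skewed real features.
- **Drift**: per feature and batch, a smooth random curve — one slow
  sinusoid (0.6–1.2 cycles per batch, the conditioning/recovery cycle of
  an ESI source) plus a random cubic — rescaled so the peak deviation
  equals the requested amplitude (default 0.3, per-feature spread ±30 %)
  and clipped positive.  Linear and exponential-decay families are also
  available.  The drift family deliberately does not share the
  corrector's functional form.
- **QCs** are the batch-wise pooled mean of the study samples' true
  signal, injected under the same drift and noise: first injection, every
  8 (batch 1) / 10 (batch 2) study samples, and at batch end.  Five
  planted *contaminant* features carry near-baseline blank signal (normal
  blanks sit at 0.1–1 % of baseline, i.e. carry-over level), and five
  planted *QC-unstable* features receive extra QC-only variance (CV 1.0,
  e.g. chemical instability in the pooled aliquot) so both filters have
  planted truths to recover.
- **Clinical chemistry** is drawn per sample from lognormals anchored at
  the emulated cohort's group means (e.g. cholestatic ALT 103 / ALP 341
  U/L; hepatocellular 744 / 128; mixed 133 / 138; recovered 28 / 87), with
  rejection sampling until the rule-based classifier reproduces the
  planted label (cap 1000 draws, then the deterministic anchor), which
  guarantees the ≥ 95 % label-agreement contract.
- **Determinism**: one `numpy` Generator seeded from `StudyDesign.seed`
  drives everything; identical inputs give bit-identical studies.

What the generator does *not* emulate: correlated features (metabolites
within a pathway co-vary in reality; features here are independent given
the class), right-skewed abundance distributions (above), missing peaks,
retention-time drift, adducts/isotopes, and MS/MS structure.  Passing
tests demonstrate the pipeline's correctness and calibration under the
declared generative model, not performance on real cohorts.

## Problem sizes and runtime choices

The default study is ~60 patients (18 per modelling phenotype + 6 mixed),
2–5 samples each (~210 study samples), 300 features, two batches — the
scale of the emulated cohort.  The test suite preprocesses this study once
(session fixture); the slowest single step is the 8 × 13 × LOO grid search
over 300 features × 2 batches (~1 minute on one CPU, using the libsvm
backend directly to avoid per-fit estimator overhead — verified against
the public SVR estimator by a brute-force oracle test).  Permutation
testing in the suite uses 50 permutations per class.

## Known limitations

- The QC-SVRC + D-ratio\* combination can hide QC instability when the
  grid search lands on a near-interpolating trend (see above).
- PLS-DA is linear; phenotypes separable only nonlinearly are out of
  reach by construction.
- The ternary mapping renormalizes by the sum of the three constrained
  predictions; samples with all three predictions ≤ 0 are genuinely
  indeterminate and flagged rather than placed meaningfully.
- Missing intensities are permitted on input but the default policy is to
  drop affected features before modelling; no imputation is provided.
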