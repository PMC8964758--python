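# Methods

## Problem setting

`breathvoc` implements an exhaled-breath volatilomics analysis for
hepatocellular carcinoma (HCC): given GC–MS peak areas (arbitrary units,
AU) of volatile organic compounds (VOCs) in the breath of HCC patients,
cirrhotic patients and healthy volunteers, it (i) builds an analysis-ready
VOC matrix, (ii) finds small VOC panels that separate cases from controls,
(iii) reads disease severity off the classifier geometry, and (iv)
evaluates pre/post-treatment VOC changes as a response marker. Because no
public breath dataset accompanies this design, a synthetic-cohort
generator with planted ground truth drives all testing.

## Preprocessing

Per-day ambient blanks are subtracted from same-day samples on the raw AU
scale and floored at zero: an ambient reading exceeding the breath signal
means no endogenous signal, and negative peak areas are physically
meaningless. Compound identifications are accepted when the spectral
matching score is ≥ 0.80 and the retention-index difference is ≤ 20 units
(both inclusive). Compounds detected (corrected AU > 0) in strictly more
than 5% of samples are retained. Abundances are transformed as
log2(1 + AU): the pseudo-count keeps absent compounds at exactly 0 while
being negligible relative to detected peak areas (~10⁵–10⁸ AU). Per-day
tables are aligned on compound name (post-library identity), with absent
compounds backfilled as 0 AU. Train/test splitting accepts explicit id
lists (for published-style splits) or a seeded stratified fraction.

## Classifier

The classifier is a soft-margin SVM with RBF kernel
K(x, x′) = exp(−γ‖x−x′‖²) on z-scored features (means/SDs from the
training data only). Defaults are single-setting — γ = 1/(d·Var) ("scale")
and C = 1 — with no nested tuning; both are exposed in
`ClassifierConfig`. The positive (HCC) side of the boundary has positive
decision values; an exact 0 is classified as control.

The control group mixes many cirrhotics with few healthy volunteers;
SMOTE balances the minority control subgroup up to the majority subgroup
count by interpolating synthetic points uniformly between a minority
sample and one of its k = 5 nearest minority neighbors (Euclidean, in
standardized coordinates). During leave-one-out (LOO) cross-validation,
standardization and SMOTE are both refit inside every training fold;
applying either before the split would leak the held-out sample into its
own training data. LOO predictions are pooled into a single confusion
table (accuracy, sensitivity, specificity; HCC positive).

Alongside the confusion counts, LOO evaluation records the mean held-out
signed margin, mean of y·f(x) over the n held-out predictions. This is
needed because subset ranking by the three fractions alone degenerates on
well-separated panels: many subsets tie at 1.000 and the ordering would
otherwise be decided by compound-name spelling. The margin orders exact
metric ties by how confidently a panel separates; compound-name order
remains the final deterministic tie-break.

## Combination search

All candidate VOC subsets of size k are scored by LOO CV and ranked by
accuracy, sensitivity or specificity (ties as above). A literal
exhaustive search over all 6-of-64 subsets (~7.5×10⁷, each costing n
classifier fits) is computationally implausible, so three strategies are
provided: `exhaustive` (budget-guarded; the reference at desk scale),
`greedy` forward selection, and `beam` search. The per-k best-metric
curve supports panel-size selection: the smallest k attaining maximal
accuracy and sensitivity whose specificity is within a margin (default 5
points) of the specificity maximum over all k. Top-10 tables per ranking
key and per-key VOC appearance frequencies summarize the search.

## Severity from boundary distance

For an HCC sample x the severity statistic is the signed RKHS distance
d(x) = f(x)/‖w‖_H with ‖w‖_H² = Σᵢⱼ αᵢαⱼyᵢyⱼK(xᵢ,xⱼ); per-BCLC-stage
means ± SD and a Spearman trend over stage rank are reported. One
property of RBF classifiers matters here: the decision value is local.
A sample far beyond the boundary loses kernel similarity to every support
vector, so f(x) relaxes toward the bias and the distance *folds back* —
with the default bandwidth, per-stage means plateau after mid stages even
when the planted severity keeps growing. The staging analysis therefore
uses a wide kernel, γ = 1/(8·n_features) on standardized features, chosen
so the kernel length-scale exceeds the severity span; the classification
default is unchanged. This is a genuine limitation of distance-based
severity reading, not an artifact of the implementation.

## Treatment response

Pre/post deltas are analyzed on the raw AU scale (matching the ×10⁶ AU
reporting convention): a paired t test over all treated patients per
compound, a Mann–Whitney U test comparing deltas between responders and
non-responders, and responder classification from the response-defining
change (the reduction pre − post when responders decrease more) via an
ROC over midpoint cutoffs with the Mann–Whitney AUC (ties ½). The
operating cutoff maximizes Youden's J (ties toward higher specificity)
unless a fixed cutoff is supplied; a delta at least the cutoff counts as
a predicted responder (boundary inclusive). Modality subgroups
(TACE/PLAT) are reported when both responder classes are present.

## Statistical procedures

Welch's t is the default two-group test ("independent t-test" leaves the
variance assumption open; the pooled form is available). Pearson
chi-square is uncorrected by default with a Yates flag. McNemar is
continuity-corrected by default and exact (binomial) when requested or
when discordant pairs number < 25. The univariate VOC screen applies no
multiplicity adjustment — the headline count of significant VOCs is
deliberately unadjusted — but a clearly-labeled Benjamini–Hochberg column
is emitted as an extension. The enrollment-size formula is
ceil(z²₁₋α/₂ p(1−p)/m²) for estimating a sensitivity p to within margin m.

## Synthetic cohort generator

The generator emulates the three study tables (peak areas, metadata,
per-day blanks) with planted truth:

- **Abundance model**: log2(AU) = baseline_c + severity·effect_c +
  day effect + N(0, noise_sd). Log-normal abundances match the log2
  analysis scale; additive day effects on the log scale emulate batch
  drift across collection days. Defaults: noise_sd 0.75, day SD 0.25, 60
  collection days (3–5 participants/day over 242 runs), baselines
  uniform in log2 AU 17–23 (~10⁵–10⁷ AU) with acetone pinned near
  9×10⁷ AU.
- **Cohort design**: 97 HCC / 78 cirrhosis / 33 healthy; BCLC stage
  counts 12/31/23/23/8 apportioned exactly (largest remainder); severity
  enters as a nondecreasing per-stage multiplier (default 0.5–1.5) on the
  planted effects, giving ground truth for the distance-vs-stage check.
- **Planted markers**: 6 strong (1.5 log2 units) and 12 weaker (0.8)
  effects among the prevalent compounds, signs mixed. With graded
  detection prevalence (0.99 for 18 major compounds, 0.90 for the other
  46 analysis compounds, 0.02 for 25 rare ones) the default cohort
  reproduces the study's marginal behavior: 64 of 89 compounds pass the
  5% filter and ~17 of 64 are univariately significant.
- **Non-detection** is an exact 0 AU, independent per sample/compound —
  this is what the prevalence filter consumes. Blanks are additive on the
  raw AU scale, so blank subtraction recovers the endogenous signal
  exactly.
- **Treatment arm**: 34 treated patients (TACE 20, PLAT 14; responders
  11/11), post samples re-drawn with 0.2 log2 repeat-measurement noise
  plus compound-specific AU-scale shifts at the observed group means/SDs
  (acetone −73.38±56.76 responders vs −17.11±58.86 non-responders, ×10⁶
  AU; dimethyl sulfide +2.2±2.6 vs +0.3±0.9).

What the generator does **not** emulate: chromatographic drift,
co-elution, censored (below-LOQ) intensities rather than hard zeros,
correlated compound families, or covariate structure (age, smoking,
Child–Pugh class). Passing tests therefore show the pipeline recovers
planted structure under idealized independence assumptions, not that the
study's biological findings replicate.

## Replicated validation experiments and problem sizes

`breathvoc.validation` re-runs the pipeline on generated cohorts at fixed
design points, chosen to keep each experiment in the minutes range on a
single core:

- *Marker recovery*: 6 planted markers (±1.5 log2, noise 1.0) among 16
  VOCs, 60/60 samples, greedy forward search to k=6 with a wide selection
  kernel (γ = 0.05; see the staging discussion — near the default
  bandwidth the accuracy gradient that distinguishes markers from noise
  compounds flattens once the panel separates well), 20 seeds; reported
  as the fraction of replicates whose top panel contains ≥5 markers.
  Recovering the *last* of six equally weighted markers is intrinsically
  hard at this sample size: its marginal accuracy contribution (≈2 points)
  is comparable to the sampling noise of a LOO estimate on 120 samples,
  so near-perfect recovery rates should not be expected from any
  CV-metric-driven selection.
- *Stage monotonicity*: gradient (0.5, 0.75, 1.0, 1.25, 1.5), 20 HCC per
  stage vs 100 controls, wide-kernel staging model, 20 seeds; fraction
  with strictly increasing per-stage mean distances.
- *Response power*: Mann–Whitney on deltas simulated at the observed
  means/SDs with n = 22/12, 200 replicates. At these group statistics
  (standardized difference ≈ 0.98) the true power is ≈ 0.72–0.75; the
  experiment reports the simulated value, whatever it is.
- *Null calibration*: univariate screen on 50 null cohorts × 64 VOCs;
  total significant count compared to Binomial(3200, 0.05).

## Numerical choices and degenerate inputs

Zero-variance features standardize with scale 1; two constant equal
groups give t = 0, p = 1, and constant nonzero paired differences report
an infinite statistic with p at the floating-point floor. All-tied
Mann–Whitney data give U = n₁n₂/2, p = 1. A decision value of exactly 0
classifies as control (conservative). Degenerate models (‖w‖_H = 0) raise
rather than return distances. Every stochastic component draws from a
named substream of one root seed, so stages can be toggled without
perturbing each other and identical configurations are bit-reproducible.

## Known limitations

- The RKHS distance is only an ordinal severity proxy; it saturates under
  narrow kernels (see above) and is not calibrated to stage probability.
- Greedy and beam searches can miss interacting subsets that exhaustive
  enumeration would find; they are heuristics for pool sizes where
  enumeration is impossible.
- LOO CV on small, imbalanced cohorts is pessimistically biased (the
  held-out class is under-represented in its fold), and subset selection
  by CV metrics remains subject to winner's-curse optimism; the train/test
  split exists precisely to check the selected panel out-of-sample.
- The unadjusted univariate screen controls only per-test error, by
  design; the FDR column is provided for users who want otherwise.
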