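# Methods

This note documents the models, estimators, defaults and design choices
behind `hrvpipe`, and what the synthetic-data validation does and does
not establish.

## Signal model and preparation

The pipeline starts at detected beats: a recording is a strictly
increasing sequence of beat times (s) with RR intervals (ms).  No ECG
waveform processing or beat detection is performed.

**Instantaneous HR and smoothing.**  HR_i = 60000/RR_i (bpm) is treated
as a piecewise-constant function of time, each beat's value holding over
the interval it spans.  The low-pass-filtered signal X(t) is the
time-weighted mean of this function over a centred window
[t − τ/2, t + τ/2), evaluated on a uniform grid (defaults τ = 2 s,
fs = 20 Hz).  Time-weighting, rather than an equally-weighted mean of
the beat samples falling in the window, is deliberate: at 20 Hz the
window contents change only when a beat enters or leaves, so a
sample-mean output is piecewise constant and duplicate-saturated, which
degenerates the nearest-neighbour entropy estimator downstream.  The
time-weighted average is continuous-valued and has the same first-order
moving-average frequency response (gain |sinc(fτ)|, ≈ 0.64 at 0.25 Hz).
Portions of a window covered by no beat are excluded from the average;
a window with zero coverage yields an explicit missing value (NaN) that
is never interpolated.

**Signal quality.**  The SQI of an interval is the fraction of its
duration covered by valid beats, where a beat is valid if it is not
artifact-flagged, its RR lies in [250, 1800] ms, and its ratio to the
previous RR lies in [0.7, 1.3].  This definition is monotone in
artifact burden, equals 1 on clean recordings and 0 when nothing valid
covers the window, and maps directly onto the 0.9 inclusion threshold.

**Window rules.**  begin = minutes 10–20 of the recording (interval
[600 s, 1200 s)), replaced by minutes 20–30 if its SQI < 0.9, absent if
both fail; end = the final 10 minutes, replaced by the penultimate 10
minutes on the same rule.  Windows are anchored to the recording start
and end.  A returned window always carries SQI ≥ 0.9.  Recordings of
different lengths (the two study arms recorded sessions of different
durations) flow through identical rules; no duration normalization is
applied, mirroring the measurement design rather than correcting it.

## Entropy estimators

**Sample entropy.**  SampEn(m, r) = −ln(A/B) with B the number of
template pairs (i < j) matching at length m under the Chebyshev metric
within tolerance r, and A the same pairs still matching at length
m + 1.  Self-matches are excluded.  Defaults m = 2, r = 0.2·SD — the
field-standard convention.  With SD-relative r the statistic is
invariant under affine rescaling.  Templates containing missing samples
are excluded.  A = 0 or B = 0 yields an explicit undefined result with
a reason, not an infinity.

**Differential entropy.**  Kozachenko–Leonenko k-NN estimator (k = 5),
dimensions 1 and 2, Euclidean balls:
H = ψ(n) − ψ(k) + ln V_d + (d/n) Σ ln ε_i.  k-NN was chosen over
binning because the HR signal is continuous-valued and a partition
would impose an arbitrary scale; k = 5 balances bias and variance at
the n ≈ 12 000 of a 10-minute window.  Inputs where more than 10% of
points have zero k-NN distance are rejected with advice to jitter.

**Entropy rate.**  h(τ) = H(X(t), X(t−τ)) − H(X(t−τ)), formed from all
lag pairs where both samples are present.  On Gaussian AR fixtures the
estimate agrees with the closed form 0.5·ln(2πe(1−ρ²)) to well within
0.08 nats at n = 12 000, and deleting 10% of samples at random (the
SQI = 0.9 regime) shifts it by well under 0.02 nats: missing data are
dropped from pair formation, never imputed, so the cost of missingness
is variance, not bias.  Units are nats throughout; differential
entropies (and hence the rate) may be negative and are scale-dependent.

Both headline biomarkers are computed on the same 20-Hz smoothed HR
signal (configurable); the battery's entropy metrics are computed on
the NN series.

## The 94-metric battery

The registry fixes the census at 25 temporal, 6 frequency, 54
complexity/information and 9 specialized metrics.  Metrics named in the
study protocol (Mean NN, SDNN, RMSSD, pNN50/20, SDANN at 1/2/5 min,
HTI, TINN, the six spectral metrics, SD1/SD2, CSI/CVI, ApEn/SampEn,
Shannon/fuzzy/multiscale entropy, DFA α1/α2, MFDFA, correlation and
fractal dimensions, Lempel–Ziv, entropy rate, HRT onset/slope, CV,
centroid frequency, bandwidth) are implemented under their standard
definitions.  The full published metric list is not available, so the
remaining slots are filled with documented conventional variants
(percentile indices, SDNN-index segments, multiscale-entropy scales
1–10, MFDFA h(q) for q = −5…5, lagged/derived fractal and entropy
variants); each such slot is tagged `inferred_panel_member` in the
registry rather than presented as part of the published panel.

Notable estimator choices:

* **Spectral metrics** use a Lomb–Scargle periodogram of the unevenly
  sampled NN series (no interpolation/resampling), scaled so the
  integral over frequency approximates the series variance.  Band
  powers are in ms²; LFnu + HFnu = 100 by construction whenever
  LF + HF > 0.
* **DFA** uses linear detrending with α1 over scales 4–16 beats and α2
  over 16–64; white noise reproduces α ≈ 0.5.
* **Lempel–Ziv** complexity uses the 1976 production count on the
  median-binarized (or tertile-coded) series, normalized by n/log_a(n).
* **HRT** requires annotated ectopic beats with a compensatory-pause
  pattern; without them the two HRT metrics are missing with a reason
  code, so a clean 10-minute window yields ≥ 85 of 94 defined values.
* Per-metric failures are isolated: one failing metric never aborts the
  vector.  An outlier screen flags values beyond 5 IQR of the column
  median; flags are reported, values never silently removed.

## Harmonization

Each metric is residualized by OLS on maternal age, gestational age
(visit-specific) and BMI, then z-scored (population SD).  Listwise
deletion is applied to incomplete covariate rows, per timepoint, before
fitting; fits with fewer than 5 subjects are refused as unidentifiable.
Residualization is fit pooled across groups within each timepoint so
that between-group signal survives for the downstream models.  Because
OLS residuals are orthogonal to the regressors in-sample, the |r| < 0.1
validation criterion is met by construction; the validation report also
carries a Mantel-style correlation between the pre- and post-adjustment
metric-metric correlation matrices to confirm the intercorrelation
structure is preserved.

## PCA and the unified index

A separate PCA is fitted per timepoint on the adjusted matrix
(complete-case subjects).  k_selected is the minimal component count
whose cumulative explained variance reaches 0.80; with n ≤ 28 subjects
and 94 metrics the decomposition is rank-deficient by construction, so
k is capped at the rank and the cap is logged, not raised.  Components
are oriented so the largest-|loading| metric is positive, making scores
deterministic.  The unified HRV index is the unweighted sum of the
selected components' scores (a variance-weighted variant exists behind
a flag, off by default).  Correlation structure is compared between
timepoints with a subject-permutation test on |Δ mean absolute
correlation| (seeded, add-one p-value; at least 100 permutations
required) — the publication behind this design does not state its test,
so a distribution-free permutation scheme honest about the dependence
structure was chosen.  Domain contributions are reported both for PC1
and for all selected components, since either reading of "contributions
to the principal components" is defensible.

## Inference

Continuous two-group tests are gated per group by Shapiro–Wilk at
α = 0.05 (both normal → t-test, else Mann–Whitney U; the per-group gate
is the conservative reading).  The hypothesis is directional
(intervention > control), so tests default to one-sided in that
direction; sidedness is always an explicit argument.  Cohen's d uses
the pooled SD; r = √(t²/(t² + df)) for t-tests and |z|/√N (normal
approximation of U, no tie correction) for rank tests.  2×2 categorical
tables use Fisher's exact test with explicit sidedness; larger tables
use Pearson's chi-squared (two-sided only).  A saturated outcome column
(both groups all-yes) is a valid table with p = 1, not an error.

Mixed models are REML random-intercept fits
(`outcome ~ group × time + (1 | subject)`), using the two extreme
timepoints (first-begin, last-end) by default for maximal
interpretability; covariates can be added as a sensitivity mode, with
gestational age treated as time-varying.  Fixed-effect p-values use a
t reference with inner-outer degrees of freedom (between-subject terms:
n_subjects − 2; within-subject terms: n_obs − n_subjects − terms − 1)
rather than the asymptotic normal: the Wald z is anti-conservative at
n ≈ 28 (measured type-I error ≈ 6.8% at the nominal 5% over 800 null
replicates; ≈ 5.3% with the t reference, matching the exact change-score
t-test this design reduces to).  Singular fits are flagged but
their estimates returned.  Power and sample size use the noncentral-t
distribution (ncp = d√(n/2), df = 2n − 2); the normal-approximation
sample size n = ⌈2(z₁₋α/₂ + z_P)²/d²⌉ is reported alongside the exact
noncentral-t search, which is typically one subject larger.

## Synthetic cohort

The RR generator is an additive model, not an
integral-pulse-frequency-modulation model:
RR_i = mean_rr + lf_amp·sin(2π f_LF t) + hf_amp·sin(2π f_HF t) + e_i,
with e_i an AR(1) process of stationary SD `noise_sd`, a 200-ms floor,
and defaults mean_rr = 800 ms, LF 25 ms @ 0.10 Hz, HF 15 ms @ 0.25 Hz,
ar = 0.5, noise 20 ms — amplitudes and frequencies inside the
conventional LF (0.04–0.15 Hz) and HF (0.15–0.4 Hz) bands.  Complexity
is tuned through a latent z-score that lowers the AR coefficient
(−0.15 per z) and raises the noise SD (+20% per z), both of which raise
the entropy rate monotonically.  Group effects (baseline shift at both
visits, interaction added at the last visit) and standardized covariate
slopes act on that latent score.  Artifacts are ectopic-like RR
halvings/doublings (flagged) plus dropouts realised as two intervals
merged into one; an artifact-free recording passes the SQI ≥ 0.9 gate
in every window.  Covariates: age ~ U(25, 42) y, BMI ~ U(18, 30),
gestational age U(16, 22) wk at the first visit plus U(12, 18) wk by
the last — the ranges of the study population.  Recording durations
default to 105 min (intervention) and 45 min (control), matching the
two arms' session lengths.

The matrix-route generator draws subjects × metrics matrices from a
linear latent-factor model F L′ + effects + noise.  Loadings are scaled
1/√k so columns have unit factor variance — ground-truth effects are
genuine z-unit shifts of the metric scale — and a subject's factor
values are half stable trait, half per-timepoint innovation, giving the
random intercept a real within-subject component.  Group effects apply
to the complexity-domain columns.

**What the synthetic validation shows — and does not.**  Passing
recovery tests establishes that the pipeline's statistics behave
correctly (nominal type-I error ≈ 5% for the interaction under the
null; ≥ 80% sign recovery of a 1-z interaction at n = 14/group; factor
count recovered by the 80% rule at low noise; confounder leakage
removed exactly).  The generator does not emulate nonstationarity,
respiration–cardiac coupling, circadian drift, true ectopy physiology
or measurement error in covariates, so these results validate the
instrument, not any claim about real cohorts.  Factor-count recovery by
the 80% rule is exact at k = 2; at larger k with only 28 subjects the
sampled factor variances are unbalanced enough that the rule
occasionally selects k ± 1 — a property of the rule at small n, not of
the implementation.

## Problem sizes used in the shipped validation

Entropy closed-form checks use n = 12 000 samples (one 10-minute window
at 20 Hz); SampEn closed-form at n = 5 000; brute-force agreement at
n = 60.  Pipeline recovery uses the matrix route at n = 14 per group
with 200 null replicates, 50 effect replicates and 30 factor-recovery
replicates — replicate counts chosen so Monte-Carlo error is small
relative to the bands being checked while the whole suite stays quick
to run.

## Known limitations

* SampEn values on the 20-Hz smoothed HR are much lower than values
  computed on beat-domain NN series, because adjacent grid samples are
  strongly dependent; comparisons are therefore meaningful within a
  fixed convention only (the convention is configurable and recorded).
* The entropy rate inherits the scale-dependence of differential
  entropy: it is comparable across recordings only on a common
  amplitude scale.
* The Lomb–Scargle normalization is approximate for strongly irregular
  beat grids; normalized band quantities (LFnu, HFnu, LF/HF, centroid)
  are unaffected.
* TINN's triangular fit uses an exhaustive search over histogram bins
  and is sensitive to bin placement on short windows, as is HTI.
* The permutation test for correlation-structure differences permutes
  subjects, which is exact under exchangeability of subjects between
  timepoints but only approximate when subjects appear at both
  timepoints (the within-subject dependence is broken by design).
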