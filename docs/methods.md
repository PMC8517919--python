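# Methods

`burstnet` analyses regional electrophysiological recordings — source-space
MEG "virtual sensor" time courses, one per atlas region — under the
transient-burst model of beta-band activity: apparent sustained beta power
arises from brief, high-amplitude, pan-spectral events, and functional
connectivity from the temporal coincidence of those events across regions.
This note records the models, the tunable parameters, the numerical
choices, and what the synthetic benchmark does and does not establish.

## Signal conditioning

Regional time courses are conditioned in a fixed order: band-pass filter →
leakage correction → downsample → standardize.

- **Band-pass**: 4th-order Butterworth (default 1–48 Hz), applied
  forward–backward (`sosfiltfilt`) so that burst timing is not lag-shifted.
  Zero-phase application doubles the effective order; `order` refers to the
  design prototype.
- **Leakage correction** uses multivariate symmetric orthogonalization.
  Source-reconstructed time courses mix at zero lag; we replace the R×T
  data matrix with the closest matrix (Frobenius norm) whose rows are
  mutually orthogonal. Stage one is the analytic polar factor (closest
  orthonormal rows); stage two alternates optimal per-row lengths with the
  polar factor of the re-scaled data, which monotonically decreases the
  distance to the input. Convergence: relative change of the distance
  below 1e−9, cap 200 iterations (in practice < 10). Rows are mean-centred
  first, so output rows are exactly uncorrelated in the Pearson sense as
  well as orthogonal. Rank-deficient input (e.g. duplicated regions) is
  rejected with the offending row pair named. Orthogonalization runs on
  the concatenated recording per subject, not per epoch: the 10 s epochs
  are clean segments of one stationary recording, and per-epoch runs would
  make the mixing correction discontinuous at the seams.
- **Downsampling** is polyphase with anti-aliasing (`resample_poly`),
  default target 100 Hz; epoch boundaries and event indices are rescaled
  and rounded to the nearest output sample.
- **Standardization**: per-region mean 0, variance 1.

## Burst detection: time-delay-embedded HMM

Each region is processed independently. The series is lag-embedded over a
230 ms window (23 lags at 100 Hz; the lag count must be odd so the window
centre is a sample), and a K-state HMM (default K = 3) is fit on the
embedded vectors. Emissions are zero-mean Gaussians with full covariance
over the 23-dimensional embedded space — means are fixed at zero because
the series are standardized, so each state is characterised purely by an
autocovariance (spectro-temporal) signature. This is what lets one state
latch onto transient pan-spectral events.

Inference is maximum-likelihood EM (Baum–Welch) with scaled
forward–backward recursions. We chose EM over variational Bayes as the
single engine: with thousands of samples per state and weak priors the
posteriors coincide for practical purposes, EM's objective is exactly
monotone (giving a sharp correctness diagnostic, asserted in tests), and
the implementation is cross-checkable against `hmmlearn` and against
brute-force path enumeration at small T. Details:

- Initialisation: responsibilities from a randomized k-means on (a
  subsample of) the embedded vectors; sticky transition start (0.9
  diagonal). Default 3 restarts, best final log-likelihood kept.
- Epochs are embedded separately and treated as independent sequences with
  shared parameters, so no transition spans an epoch boundary and the
  (L−1)/2 samples at each epoch edge are trimmed (the posterior exposes a
  map from embedded columns to original sample indices).
- Covariance collapse: the M-step attempts a Cholesky factorisation and
  escalates a diagonal jitter on failure; repairs are counted on the
  returned posterior.
- Numerical scaling: per-frame renormalised recursions; no underflow at
  24 000 samples (asserted).
- Viterbi decoding is exposed for diagnostics; ties break to the lowest
  state index. Burst binarization does not use Viterbi (below).

The **burst state** is the state whose posterior probability course has
the highest Pearson correlation with the beta amplitude envelope; the
correlations for all states are reported, constant courses are excluded,
and exact ties resolve to the lowest index. The envelope is a Morlet
wavelet amplitude: wavelets from MNE (7 cycles, zero-mean) at 1 Hz steps
over 13–30 Hz, moduli averaged across frequencies. The transform is
computed with a channel-batched FFT convolution that a test pins to
`mne.time_frequency.tfr_array_morlet` to 1e−10.

Binarization: burst at sample t iff the burst state's probability strictly
exceeds 2/3. Maximal runs of the indicator within epochs are burst
*visits*; no minimum duration is imposed.

## Burst metrics

Per region: **burst amplitude** = mean over visits of the per-visit
envelope maximum (undefined and flagged for an empty train); **non-burst
amplitude** = mean envelope over non-burst samples (the mean, not per-gap
maxima — maxima of arbitrary-length gaps are ill-defined); **total burst
time** = Σ visit lengths / record length; **burst duration** = mean visit
length; **burst count** = visits per second. Global per-subject values are
unweighted means across regions, excluding (and counting) regions with
undefined values.

## Coincidence connectivity

Connectivity between regions i and j is the Jaccard index of their binary
burst trains, Σ(Bᵢ∧Bⱼ)/Σ(Bᵢ∨Bⱼ) ∈ [0, 1], computed over the concatenated
recording. Pairs with an empty union get J = 0 plus a mask bit (not NaN),
which keeps group averaging defined. The connectome diagonal is fixed at
0; 78 regions give 3003 unique edges. Edge selection at fraction f keeps
the ⌊f · n_edges⌋ largest edges, ties broken lexicographically by label.

## Trial-locked dynamics

Task trains are epoched ±3 s around each button press (edge-clipped trials
dropped and counted). The burst-probability course at trial time t is the
fraction of trials bursting at t. Window statistics use a rebound (PMBR)
window of 0.45–0.85 s and a movement (MRBD) window of (−0.3, 0.1) s; the
MRBD bounds are our choice (bracketing movement execution around the
press) and are exposed in the `WindowSpec` config. PMBR burst amplitude
includes every visit that intersects the window (fell within, began, or
ended during it), averaged per trial then across trials; **modulation** is
the mean course over the PMBR window minus the mean over the MRBD window.
The coincidence course applies the Jaccard index across the trial
dimension at each trial time point.

## Group statistics

Two-sided Wilcoxon rank-sum tests throughout: exact null distribution when
n_x + n_y ≤ 20 and tie-free, otherwise normal approximation with tie and
continuity corrections. Benjamini–Hochberg correction within each family:
the three resting global metrics; the 12-test task battery (left/right
cortex × left/right press × probability/amplitude/modulation); global
connectivity stands alone. Spearman correlations with symptom severity use
midranks, with exact permutation p for tie-free n ≤ 9; patient-only and
combined-cohort correlations are reported separately, the latter always
flagged as likely driven solely by a group difference.

## Classification

Subjects are represented by the vectorized upper triangle of their
connectome. Recursive random-forest feature selection: on each of
`n_resamples` stratified 80% subsamples, iteratively drop features with
importance below the mean importance and refit until stable or a floor of
5 features; the consensus set is the features kept in ≥ 50% of chains
(fallback to top-5 by vote if empty). Defaults: 500 trees, permutation
importance (5 repeats), 10 resamples — all exposed in `ClassifierConfig`,
since the selection procedure's constants are conventions. Evaluation is
stratified 10-fold cross-validation with selection and standardization fit
inside each training fold only (a test spies on the selection calls to
prove no held-out row reaches them); a linear SVM (C = 1) is scored by
ROC-AUC on the held-out fold. The label-permutation test reruns the whole
pipeline per permutation; p = (1 + #{null ≥ observed})/(1 + n_perm).
A linear kernel keeps the selected edges interpretable as a subnetwork.

## Synthetic data generator

The generator is the test bed: it produces cohorts with known ground
truth. Per region, the background is 1/f-coloured Gaussian noise (spectral
slope −1 by default, unit variance); bursts are Tukey-windowed sinusoidal
packets with carrier frequency drawn uniformly from 13–30 Hz plus a 0.3
broadband component, amplitude 3× the background SD with a 10% per-visit
and 15% between-subject log-normal jitter. Visit durations are log-normal
(mean 0.3 s, log-SD 0.4); visits arrive at 0.6/s per region, giving a
planted occupancy of ≈ 1 − e^(−0.18) ≈ 0.165 after overlap merging —
conventions from the empirical burst literature, since the real cohort's
burst rates are not published. Resting bursts are placed within 10 s
epochs (24 by default).

Pairwise coincidence is planted directly: for each region pair, a shared
event process (rate = region rate × the pair's co-occurrence entry) places
identical intervals in both regions; an independent process tops each
region up to the nominal rate. The patient group multiplies burst
amplitudes by 0.8 and pairwise co-occurrence by 0.7; at rest the
independent rate is raised to keep total occupancy unchanged (the planted
pathology is coordination and amplitude, not burst density). Task
recordings modulate the *centre* of each candidate burst by a
piecewise-constant rate profile around each press — suppression ×0.2 in
(−0.3, 0.1) s, elevation ×2 in (0.45, 0.85) s — via thinning; centring
(rather than onset placement) makes the recovered occupancy course
symmetric about each planted window. Patients get the profile's deviation
from 1 shrunk by 0.5 (blunted modulation) and the coincidence reduction
without occupancy compensation. Symptom scores are
baseline − slope · z(planted mean coincidence) + noise, truncated at 0,
so severity decreases with planted connectivity and patients score higher.

What the generator does **not** emulate: sensor-level physics (forward
fields, head motion, ECG/EOG artefacts), spatially structured leakage,
autocorrelated burst trains beyond the planted point process, or the real
cohort's effect sizes. Passing recovery tests therefore demonstrates that
the pipeline detects effects of the planted kind and direction at
realistic signal-to-noise — not that the real-data effect sizes would be
reproduced.

## Problem sizes for the recovery and calibration studies

The planted-effect studies run the generator → metrics → connectivity →
statistics chain with burst trains taken from the generator's ground
truth; the HMM detection path is validated separately (exact-inference
oracles; two-regime autoregressive recovery ≥ 90%; detected-vs-planted
visit overlap with Dice ≥ 0.7 on rendered recordings). Fitting ~78 × 40
HMMs per seed for 100 seeds would add nothing to either question.
Cohort sizes: resting — 10 regions, 100 s records, 20 subjects per group,
100 seeds; task — 2 motor regions, 30 trials, 20 per group, 100 seeds.
Calibrations: rank-sum type-I error over 2000 null draws at n = 20/20;
null-classifier AUC over 100 seeds (20 subjects × 40 features, reduced
forest constants); permutation-p uniformity over 30 runs × 15
permutations. The reproduction script (`scripts/acceptance.py`) runs the
same studies at 60 seeds per rate, which estimates each rate to within a
few percentage points in well under half the suite's runtime.

## Known limitations

- The HMM is univariate per region; coincident bursts need not imply a
  functional interaction, and a noise-dominated region still nominates a
  "burst" state (the reported state–envelope correlations should be
  inspected).
- Orthogonalization removes genuine zero-lag coupling along with leakage.
- EM finds local optima; restarts mitigate but do not guarantee the global
  one. Determinism holds for fixed seeds.
- The consensus feature set of the rRF-FS procedure is not invariant to
  adding/removing noise features, because random forests consume RNG state
  as a function of the full column set.
- Group-level (multi-subject) HMMs, amplitude-envelope-correlation
  connectivity and graph-theoretic summaries are out of scope.
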