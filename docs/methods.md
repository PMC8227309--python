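# Methods

This note describes the models, parameters and numerical choices behind
`eegscore`, and what the synthetic cohort does and does not establish
about real recordings.

## The analysis chain

The package implements a complete EEG-to-behaviour analysis for a
two-group learning experiment (text vs video presentation of the same
material). Each participant contributes one session — 30 s eyes closed
(EC), 30 s eyes open (EO), then three 150-s learning tasks (LT) — on an
8-channel dry-electrode montage (FP2, FP1, C4, C3, P8, P7, O2, O1;
10–20 positions) sampled at 256 Hz, plus a 0–100 test score and an exam
time after each LT.

Stages, in order:

1. **Filtering.** 0.1–100 Hz Butterworth bandpass, design order 4 per
   edge, applied forward–backward (zero phase). Offline analysis has no
   causality constraint, and zero-phase application avoids phase
   distortion of band power; the effective attenuation is the squared
   magnitude response. If a requested corner would reach Nyquist the
   chain clamps it to 0.99 × Nyquist and logs the change; the low-level
   `bandpass` function instead rejects such corners outright.
2. **Cleaning (simplified stationary ASR).** Artifact subspace
   reconstruction is specified here as: PCA of the covariance of a
   clean calibration segment (EO by default, configurable to EC); for
   each component, the mean and SD of its RMS over non-overlapping 1-s
   calibration windows; during cleaning, any component whose RMS in a
   1-s analysis window exceeds `mean + kappa * SD` (kappa = 15) is
   zeroed in component space before back-projection. Since the PCA
   basis is orthonormal there is no cross-projection between retained
   and rejected components, so zeroing is the exact "reconstruct from
   retained components" operation. Windows with no flagged component
   are copied through bit-identically, which makes the operation
   idempotent and guarantees output energy ≤ input energy in flagged
   windows. Sliding-window and Riemannian ASR variants are out of
   scope: the stationary form keeps every contract testable
   (untouched-window fraction, RMS reduction, idempotence).
3. **Band power.** Per non-overlapping 1-s window and channel, a plain
   rectangular-window FFT periodogram, one-sided scaling chosen so a
   sinusoid of amplitude A at an integer frequency contributes exactly
   A²/2. Bands are delta 1–4, theta 4–7, alpha 8–12, beta 13–29,
   gamma 30–50 Hz, all half-open `[low, high)` with bins assigned by
   bin-center frequency; the 7–8 and 12–13 Hz gaps belong to no band.
   No taper and no overlap are used — the 1-s rectangular window is the
   literal specification, and with 1-Hz bins every band boundary falls
   on a bin edge. Trailing partial windows are discarded, so a 150-s LT
   yields exactly 150 windows.
4. **Features.** Two families, 200 columns total, one row per
   (participant, repetition):
   * 40 *normalized band powers* `<CH>_<band>`: LT power normalized to
     the EO baseline, `P_N(t) = (P_LT(t) − mean(P_EO)) / mean(P_EO)`,
     averaged over the 150 LT windows. Values are ≥ −1 by construction.
   * 160 *power ratios* `<CH>_<A>/<B>`: the per-window ratio of raw
     (unnormalized) LT band powers for each of the 20 ordered band
     pairs, averaged over windows. Averaging the per-window ratio
     series (rather than taking the ratio of window-averaged powers)
     follows the time-indexed definition of the ratio; the alternative
     is close in practice but not identical, and the choice is fixed
     here. Windows with a zero denominator are dropped and counted; a
     channel losing more than 10% of its windows is an error.
5. **Group statistics.** Two-sample t-tests (video vs text) for every
   repetition × channel × descriptor (5 bands + 20 ratios):
   3 × 8 × 25 = 600 tests, each reported with direction (V>T / V<T /
   V=T at α = 0.05). Student's pooled-variance test is the default
   (Welch available via a flag). No multiple-testing correction is
   applied anywhere by default — the method interprets raw p < 0.05,
   and that behaviour is preserved deliberately; a Benjamini–Hochberg
   option exists but is off, and users should expect ~30 false
   positives among 600 null tests at α = 0.05.
6. **Feature selection.** Pearson correlation of each of the 200
   features with the score, pooling all rows of both groups and all
   repetitions (the rows are treated as unlabeled observations).
   Features with two-sided p < 0.05 are kept, sorted ascending by p
   (ties broken lexicographically by name for reproducibility). When a
   ratio and its channel-matched inverse both survive, the larger-p one
   is pruned as redundant — the two carry the same information up to a
   monotone transform.
7. **Prediction.** Multivariate linear regression fit in closed form:
   the pseudoinverse solution of the least-squares problem, identical
   to the normal-equation solution for full-rank designs and still
   defined (minimum norm) for rank-deficient ones. Evaluation is
   Monte-Carlo cross-validation: for each feature count k = 1..K
   (default K = 4), 10 independent random 70:30 row splits — with 60
   rows that is exactly 42 train / 18 test — and the accuracy
   `Acc_k = 100 − mean |mean(pred) − mean(real)|` over each split's
   test rows. The "k-fold" and "fixed 42/18 split" descriptions of
   such protocols are incompatible if read literally; repeated random
   splitting is the reading implemented, since it matches both the
   fixed split sizes and the fresh random data drawn per iteration.
   Splits are defined over row identities (participant, repetition),
   not positions, so row order is irrelevant. Rows are split at the
   observation level by default (only that yields 42/18 from 60); a
   stricter participant-level grouping mode is available. Predictions
   are not clipped to [0, 100] unless requested, keeping the accuracy
   linear in the coefficients. A per-sample mean absolute error is
   recorded separately under a distinct name — it is *not* the
   accuracy metric, which compares test-set means.
8. **Group prediction summary.** The best-k model, refit on the
   complement of each of 30 random test-size subsamples, predicts the
   subsample; predictions are pooled by true group label to compare
   per-group mean real vs predicted scores. Refit-per-subsample is the
   only self-consistent protocol when the subsample must be disjoint
   from the training data.
9. **Performance metrics.** Per (group, repetition) mean score and exam
   time; score improvement `SI_r = SV_r − ST_r` (signed points) and
   time improvement `TI_r = (1 − TV_r/TT_r)·100` (percent). A relative
   score improvement `(1 − ST/SV)·100` is reported alongside under
   `relative_SI`, because summary tables in this literature sometimes
   print the ratio form; both are always emitted and clearly labelled,
   neither substitutes for the other. Rendered tables round
   improvements to integer percent; raw values are kept in the CSV/JSON
   outputs.
10. **Factor tests.** Friedman tests on a replicated two-way layout:
    columns = group, row blocks = difficulty (repetition), participants
    as replicates within each cell. All `columns × replicates` values in
    a block are ranked together; the column-factor statistic is the
    replicated generalization of the Friedman chi-square (df =
    columns − 1, standard tie correction), which reduces to the
    classical statistic at one replicate. The difficulty factor is
    tested by exchanging the roles of rows and columns. This is
    implemented in-package because the common library routine neither
    accepts replicated cells nor two treatments; it is cross-checked
    against that routine in the unreplicated ≥3-treatment case where
    both are defined.

## The synthetic cohort

The generator emulates the study conditions — 10 text + 10 video
participants, three repetitions, 256 Hz, the full EC/EO/LT session —
so every stage runs and is verified without any recorded data.

Signal model per channel: 1/f Gaussian background (white noise whose
FFT magnitudes are shaped by `f^(−exponent/2)`, exponent 1, rescaled to
a 10 µV RMS) plus one sinusoid per band at the band-center frequency
with random phase. Sinusoids are chosen deliberately: their band power
is analytically `A²/2`, which gives the spectral stages closed-form
oracles. Base amplitudes follow the textbook pattern (posterior alpha
dominance with an eyes-closed alpha surge, frontal delta/theta), and
during the learning task the video group sits at a slightly higher
alpha/theta working point than the text group — the mental-fatigue
index that links EEG to performance in this design.

Amplitude variability is layered as lognormal multipliers: a global
per-participant scale (σ = 0.20, every band and channel together — the
dominant real-world effect of skull/electrode differences), per-band
(σ = 0.06) and per-band-per-channel (σ = 0.08) trait residuals, and
per-segment state fluctuations (σ = 0.05 shared, σ = 0.10 per channel).
The layering matters: the global scale cancels in band ratios and in
baseline normalization, so ratio features vary less than raw power
(as in real EEG), while the per-channel residuals ensure no two
channels are duplicates of each other — without them, every channel's
alpha/theta ratio would be a perfect copy and feature selection could
not distinguish the designated channel from its neighbours.

Scores are `intercept + Σ coef·feature + N(0, noise_sd)`, clipped to
[0, 100], with the default model
`60 + 6·C3_alpha/theta − 30·FP1_delta + N(0, 5)` — a positive loading
on the alpha/theta (inverse-fatigue) ratio and a negative loading on
frontal delta (drowsiness), matching the directions this literature
reports. The coefficients are sized so the two features contribute
comparable score variance to the noise and the clipping probability is
negligible. Exam times are lognormal (σ = 0.15) around
repetition-dependent bases (40/55/90 s) with the video group 18%
faster. Artifacts, when enabled, are raised-cosine transients of
100–300 ms and `amplitude × EO-channel-SD` height (default 30×) on
random non-empty channel subsets, Poisson-placed at a configurable
events/min rate within the learning tasks only — baselines stay clean
so ASR calibration remains valid, which mirrors how calibration data
are chosen in practice.

Everything is a pure function of `(spec, seed, indices)`; recordings
are bit-identical across calls, and each stage derives its own
substream so re-running a stage in isolation reproduces the full run.

What passing tests on this cohort do **not** show: the generator has no
eye-blink/EMG physiology, no volume conduction, no event-related
potentials, no non-stationarity beyond segment-level amplitude changes,
and its group effect is planted. Results on it validate the *pipeline's
arithmetic and statistical behaviour* (power calibration, selection
consistency, regression recovery, type-I rates), not any neuroscientific
claim about real learners.

## Problem sizes and numerical choices

* Monte-Carlo checks use the cohort size the design fixes (20
  participants, 60 rows). Replicate counts are 100 for rate checks in
  the test suite and 200 for sampling-theory checks that condition on
  one cohort's features; the acceptance script reports the same rates
  at 40 fresh-cohort replicates, a sample size at which an underlying
  ≥80% rate is still distinguishable from failure.
* Least-squares uses `numpy.linalg.pinv` (SVD); agreement with QR-based
  reference solvers is asserted at 1e-8.
* Degenerate inputs are errors, not silent fixes: empty groups,
  constant scores, underdetermined fits, zero EO baseline cells, and
  calibration segments shorter than 10 windows are all rejected with
  messages naming the offending quantity. Constant feature columns are
  skipped (and logged) by the correlation stage, since r is undefined.
* EDF files are written with a symmetric physical range just above the
  per-file absolute maximum, so the 16-bit quantization error is
  bounded by `2·max|x|·1.0001/65535`; the CSV dialect round-trips
  exactly and is preferred for fixture-level work.

## Known limitations

* The stationary ASR variant under-cleans drifting artifacts that a
  sliding-calibration implementation would track; it is specified for
  testability, not maximal cleaning power.
* Correlation-based selection over 200 highly collinear features is
  intentionally uncorrected for multiplicity and will admit many
  correlated proxies of a true effect; the redundancy pruning removes
  only exact inverse pairs, nothing else.
* Accuracy as `100 − |difference of test-set means|` rewards unbiased
  group-level prediction, not per-subject precision; the per-sample MAE
  column exists precisely because the two can diverge.
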