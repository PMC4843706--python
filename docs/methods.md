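# Methods

## Problem setting

During repetitive motor training (here: the sequential visual isometric
pinch task, SVIPT, where pinch force steers a cursor toward target
fields), performance fluctuates strongly from trial to trial. The
question this package operationalizes is whether the oscillatory EEG
state *before* a trial carries information predictive of the upcoming
trial's performance — and, because supervised decompositions overfit
readily at 63 channels, how to tell a genuinely informative component
from a spurious one.

The pipeline: score each trial's force trajectory, clean the EEG, learn
spatial filters whose projected bandpower covaries with the performance
score, and subject every candidate component to a selection battery
under chronological cross-validation.

## Forward model and the supervised decomposition

Sensor data follow the linear forward model `x(t) = A s(t) + n(t)`:
`M` neural sources `s(t)` project to `N_c` sensors through the mixing
matrix `A`, plus noise. SPoC (Source Power Comodulation, the
eigenvalue variant) seeks a spatial filter `w` maximizing

    Cov[ Var[wᵀx](e), z(e) ]   subject to   Var[wᵀx] = 1,

where `Var[wᵀx](e)` is the per-epoch bandpower of the projected,
narrowband-filtered signal and `z(e)` the standardized per-trial target.
With per-epoch covariances `C(e)`, `C̄ = mean C(e)` and
`C_z = mean z̃(e) C(e)`, this is the generalized eigenproblem
`C_z w = λ C̄ w`; each eigenvalue is the covariance its component
achieves. We solve it by symmetric whitening (`eigh` of
`C̄^{-1/2} C_z C̄^{-1/2}`), with an eigenvalue floor of
`1e-10 · trace(C̄)` guarding rank deficiency, then rescale every filter
to exact unit projected training variance. Signs are fixed by making
the dominant entry of each activation pattern (`a = C̄ w`) positive, so
fold-wise pattern comparisons are well defined. Predictions on unseen
epochs are `z_est(e) = wᵀ C_te(e) w`; fold patterns are
`a_j = C_te,j w_tr`.

Per-epoch covariances are plain sample covariances (per-channel mean
removed, `ddof=1`), not trace-normalized — the prediction rule uses raw
variance. An optional shrinkage parameter blends `C̄` toward a scaled
identity for ill-conditioned channel counts; it defaults to off.

## Performance scores

Five scores per trial: RT (go-cue to start-field exit, ms), DUR
(go-cue to first target hit, s), CPL (total variation of the force
trace over that window), ISJ (integral of the squared third derivative
of force), and NJ = ISJ · DUR^(5/2) / CPL². The NJ exponent is
printed-formula 5/2 by default but configurable (a fully dimensionless
variant uses 5). Jerk is estimated by third-difference stencils —
central in the interior, one-sided at the boundaries — all exact for
cubic trajectories; naive repeated gradient estimation amplifies
boundary error as the sampling rate grows, which these stencils avoid.
All scores except RT are z-scored per task condition (population SD,
`ddof=0`) before pooling; RT is pooled raw.

## Preprocessing

Butterworth filters of 5th order, zero-phase (forward–backward, which
doubles the effective order) for offline analysis; a causal option
exists for online settings. Epochs are half-open sample windows
relative to the go-cue. Three rejection rules: (1) min-max — strict
`> 60 µV` peak-to-peak on frontal channels (labels starting Fp/AF/F,
configurable); (2) variance — per channel, reject epochs whose variance
exceeds `P90 + 2·(P90 − P10)` of the epoch-variance distribution (the
rule is deliberately an *upper outlier* test: always discarding the top
decile would contradict its artifact-removal intent); (3) behavioral —
the active metric must lie inside fixed bounds (RT 150–900 ms and NJ
0–1300 on raw values; ISJ ±1.5, CPL ±0.6, DUR −1.5…2 on standardized
values, since those printed ranges are z-score-like). Datasets keep at
least 150 trials or are discarded (convergence requirement of the
decomposition).

## Evaluation battery

Chronological 5-fold cross-validation: contiguous time-ordered blocks,
earlier folds taking the remainder, training labels standardized with
training-fold statistics only. Scores per component:

* `R_all` — Pearson correlation of concatenated out-of-fold predictions
  with the truth; `R_folds` — mean fold-wise correlation. Pearson (not
  rank) correlation matches the covariance objective. High `R_all` with
  low `R_folds` flags a session-trend follower; both high indicates
  trial-by-trial information (`classify_predictor` defaults:
  `|R_all| ≥ 0.2`, single-trial if `|R_folds| ≥ 0.5·|R_all|` with
  consistent sign).
* `H_folds` — folds whose correlation sign matches `R_all` (a zero
  counts as a match).
* `z-AUC` — midrank ROC area of predictions against a median split of
  the truth; chance 0.5. Midranks make the score well defined under
  ties without discarding median-tied trials.
* `AAUC_SNR` — label-noise stress: training labels are corrupted with
  white noise at SNR levels {−20, −15, −10, −5, 0, 5, 10} dB
  (`SNR_dB = 10·log10(Var(z̃)/Var(ε))`), three noisy label sets per
  level; predictions are always scored against the *clean* target —
  only under this reading does added label noise degrade separability.
  The score is the mean excess of z-AUC over 0.5 across the grid, so a
  component at chance scores 0 and a perfect one 0.5. Grid, reps and
  normalization are configurable.

Selection requires all of: `z-AUC ≥ 0.59`, `AAUC_SNR ≥ 0.18`,
`H_folds = K`, and `N_e ≥ 150`. The two correlation scores are
characterization, not selection criteria (they are strongly collinear
with z-AUC). Candidate ranks come from the eigenvalue spectrum: remove
a least-squares line from the descending eigenvalues and keep positive
eigenvalues whose residual exceeds `1.5·σ(residuals)`; a numerically
perfect line selects nothing.

## Band grid and scan

The default grid places 60 logarithmically spaced lower edges between
1 Hz and 100 Hz with constant 20 % relative bandwidth and drops bands
touching the 45–55 Hz power-line zone, emitting 55 overlapping bands.
Edges, count, bandwidth and exclusion are all parameters. The scan
zero-phase filters the broadband epochs per band, computes per-epoch
covariances once per band, and reuses them across folds and noise
repetitions, which keeps the stress test cheap. Per-cell failures are
recorded and do not abort the scan; reruns with identical config and
seed are bit-identical. A channel-wise log-bandpower OLS regression
runs as baseline (one component per cell); log power is standard for
linear models on power, raw variance is available as an option.

## Synthetic scenes

The generator emulates the study geometry: 63 channels, 400 trials,
500 Hz, 750 ms pre-go epochs, one planted source (10 ± 1 Hz) with
random unit-norm mixing pattern, baseline power 1, white sensor noise
of variance 0.1. Sources are narrowband Butterworth-filtered noise
carriers normalized to exact unit variance within each epoch, scaled by
`σ(e) = √baseline · exp(g·d(e))` with log-power gain `g = 0.25`. The
driver `d` is an exact-correlation blend of the standardized target and
an orthogonalized noise draw, so the empirical correlation between
per-epoch log bandpower and the target equals `comodulation_r` on every
realization. The exponential law guarantees positive power; keeping
`g` small keeps raw power near-linear in the target, the regime the
covariance objective rewards. (Calibrating a large exponential gain
against the realized-bandpower estimation noise instead would push the
power–target relation deep into lognormal territory and cap the
attainable Pearson correlation of predictions near 0.3 — unusable as a
recovery testbed.) A source may couple to a linear session trend
rather than the trial-wise target, and the target itself can carry a
trend component; that pair of switches builds the
session-trend-vs-single-trial discrimination fixtures. Optional 1/f
temporal noise is available; the default is white so the sensor
covariance has the closed form `A diag(power) Aᵀ + noise·I`.

What the scenes do *not* emulate: realistic head-model lead fields,
eye/muscle artifacts, nonstationary noise floors, rank switching of
competing sources, or continuous (non-epoched) recordings. Passing
recovery and selection tests on these scenes demonstrates correctness
of the machinery, not expected effect sizes on real recordings, where
median correlations are far lower.

Force-trial fixtures are piecewise-linear ramps (optionally
overshooting and settling) with events placed consistently: go-cue at
0, start-field exit at the end of the ramp, first hit at the settle
point — so path length and timing metrics have closed-form values.

## Numerical and design choices

* Population SD (`ddof=0`) for all target standardization; sample
  covariance (`ddof=1`) within epochs — the convention is fixed and
  immaterial as long as it is consistent.
* Fold partition by `array_split`: 403 trials at K=5 give
  {81, 81, 81, 80, 80}.
* Degenerate inputs are flagged, not silently passed: constant targets
  raise, zero-variance predictions give NaN correlations, single-class
  median splits give NaN z-AUC, CPL = 0 makes NJ undefined.
* All stochastic steps (scene generation, label-noise draws) flow from
  a single integer seed through `numpy.random.default_rng`; no global
  RNG state is touched.
* Test problem sizes are scaled to the study geometry where the check
  depends on it (63-channel recovery) and to small scenes (8–24
  channels, 200 trials) where only the mechanism is under test.

## Known limitations

The grid scan evaluates each band independently; combining predictors
across bands is out of scope. No regularized or transfer-learning
variants of the decomposition are provided. The variance-rejection
rule's literal specification is ambiguous; the implemented upper-outlier
interpretation is configurable. Continuous-recording ingestion is a
thin optional MNE wrapper and is not exercised against real BrainVision
files in the test suite.
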