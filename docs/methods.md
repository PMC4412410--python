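# Methods

`motorpls` implements a two-sided dimensionality-reduction analysis of
rhythmic motor output against spike-timing motor signals, in the setting of
tethered insect flight: a hawkmoth's paired downstroke muscles (left and
right DLM) each fire exactly one spike per wingstroke, and the question is
whether the pair encodes yaw torque as a single *muscle synergy* (one linear
combination of the two spike timings) or *independently* (both timings
needed). This note documents the model, the algorithms, the synthetic study
conditions, the numerical choices, and what passing tests do and do not
establish.

## Data model

The unit of analysis is the wingstroke (~50 ms at a 20 Hz tethered wingbeat,
sampled at 10 kHz). Two matrices are built per recording:

* **U** (N x 2): spike times of the left and right muscle relative to each
  wingstroke's onset, in ms. Columns are standardised to mean 0 and unit
  variance (population scaling, so the variance is exactly 1).
* **M** (N x 500): the torque waveform of each wingstroke (500 samples per
  50 ms window). Columns are centred — the column mean is the ensemble
  average waveform (STA) — and the whole matrix is divided by a single
  scalar `s`, the RMS of the centred ensemble, so raw waveforms are
  recovered exactly as `M*s + STA`. The per-cycle mean torque is kept
  separately.

Instrument dynamics are removed first: the torquemeter is a forced, damped
rotational oscillator `I*phidd + C*phid + kappa*phi = tau(t)`, calibrated by
least squares (driven regression of torque on the angle and its smoothed
central-difference derivatives, or damped-sinusoid fits of free decays) and
inverted by evaluating the left-hand side on the measured angle. The first
and last two samples of an inverted record are marked invalid. The 0.1 s at
each end of a calibration trial are excluded from the regression because the
startup transient, filtered and unfiltered quantities disagreeing there,
otherwise biases the inertia estimate by several percent.

## Alignment

Wingstroke onsets come from one of three sources:

* a **trigger channel**, when the rig provides one (the synthetic rig does);
* the **Hilbert phase** of the torque record, band-passed 3–35 Hz with an
  order-8 Chebyshev type II filter (40 dB stopband, configurable) applied
  forward–backward so onsets are not delayed; onsets are the ascending zero
  crossings of the analytic-signal phase, linearly interpolated between
  samples. Generous reflection padding is used because the 3 Hz band edge
  gives the filter a long transient. Note that the phase-zero convention
  places the onset at the *peak* of the band-passed torque;
* the **reference muscle's spike** ("spike-triggered"): windows start at the
  right DLM's spike inside each phase-defined cycle.

Spike timings in U are always measured from the cycle onset; the alignment
mode only moves the waveform windows. Windows are fixed-duration even when
the instantaneous period deviates from nominal. Cycles missing exactly one
spike on any channel, or whose window leaves the record, are dropped and
counted in the run log. A recording is analysed only if the reference
channel's mean rate strictly exceeds 18 spikes/s.

Two alignment caveats are worth knowing, both genuine properties of the
method rather than artefacts of this implementation. Spike-triggered
windows fold the reference muscle's timing into the waveforms themselves
(shifting a window by t_R adds a component proportional to t_R times the
STA's derivative), which adds an extra timing-correlated waveform dimension
beyond the generative ones. Phase-derived onsets jitter with any
score-correlated content inside the segmentation band (for example the
mean-torque component of a feature), which likewise perturbs the apparent
feature count. For this reason the end-to-end pipeline prefers trigger
onsets when the dataset provides them, and the robustness of conclusions to
spike- versus phase-alignment is something a user should check on their own
data, as the significance procedure is sensitive to these extra dimensions
by design.

## Feature extraction (SIMPLS)

With `S0 = M^T U` the cross-covariance, components are extracted greedily.
At step i the leading singular-vector pair (r_i, c_i) of the deflated S
gives the unit-norm torque score `k_i = M r_i / ||M r_i||`, the motor
feature `p_i = M^T k_i`, and the signal loading/score `q_i = U^T k_i`,
`d_i = U q_i`. The deflation direction `v_i = p_i / ||p_i||` is
re-orthogonalised against all previous v's by modified Gram–Schmidt (applied
twice for numerical stability) and `S <- S - v_i v_i^T S`; d_i is
orthogonalised against all previous torque scores. Extraction stops early
when `||S||_F / ||S0||_F < 1e-10`. The SVD of the deflated S is a full
decomposition with the leading pair selected. Features carry the sign that
makes their largest-magnitude element positive; comparisons against
reference implementations are up to a common sign.

One algebraic subtlety: the projection deflation `S - v v^T S` is *not*
identical to recomputing S from the score-residual matrices
`M_res = (I - K K^T) M`, `U_res = (I - K K^T) U`; what holds exactly is
`M_res^T U_res = S0 - P Q^T`. Both deflations are implemented
(`deflation="projection"`, the default and the standard SIMPLS choice, and
`deflation="residual"`); for two timing variables the components they
extract agree closely but not to machine precision beyond the first.

Explained variance is accounted sequentially: U's columns are regressed
(with intercept) on the first i scores, and feature i's incremental value is
the gain in R². A normalised mode divides by the 10-feature cumulative
value so animals can be pooled. One-sided PCA of M (eigendecomposition of
its covariance) is provided for comparison, with the same accounting.

**Significance** is by permutation: rows of M are shuffled against U
(optionally both shuffled), the decomposition re-run, and the per-column
maximum single-feature explained variance recorded; the threshold is the
99.5% quantile of 1000 such maxima (all configurable). Using the per-column
maximum is a conservative, family-wise control across the 10 extracted
features; per-rank thresholds are available as an option. Chance levels
here depend strongly on the effective dimensionality of M's noise: with
white per-sample noise and b ≈ N the permuted-data fit can reach R² ≈ 0.5
by chance (the greedy search over a ~N-dimensional waveform space overfits
any fixed target), while smooth, low-dimensional residual variation keeps
the chance floor near d_eff/N. Real torque records are band-limited by
physics; the synthetic generator matches that (below).

## Encoding models and comparison

Four model families map timings to predictors, all with intercepts:
independence (t_L, t_R), differential synergy (standardised raw difference
t_L − t_R; difference-of-standardised available via option), empirical
synergy (projection of the standardised timings onto the leading eigenvector
of their 2x2 correlation matrix, right-muscle loading positive), and
redundancy (one muscle's timing). Each predicts three responses per
recording: mean torque, and the first two feature scores. Performance is
the leave-one-out PRESS, computed by the exact hat-matrix identity
`e_i / (1 - h_ii)` (verified against explicit refitting). Across replicate
animals, each reduced model is paired against independence with paired
t-tests under a Holm correction per response, Wilcoxon signed-rank as a
robustness check; with fewer than three animals only descriptive PRESS
tables are produced. The repeated-measures ANOVA with
multiple-comparison-to-best post hoc used in some statistical packages is
deliberately replaced by these paired tests: they answer the same question
(is a reduced model separable from the full one?) with a procedure that is
fully specified and reproducible here.

## Reconstruction

Waveforms are rebuilt as `M' = STA + s * K P^T` with the first two features
(any count up to the fitted components is supported), using either measured
scores (a projection — the best rank-2 account of the data) or scores
predicted from an encoding model's design matrix (a true decoder). The
mean-torque baseline adds the model-predicted per-cycle mean to the
mean-removed STA, so each row's mean equals its prediction. Errors are
nRMSE (residual RMS over measured RMS, offset-sensitive) and residual
variance 1 − r² (offset-insensitive, phase-sensitive). Decile analysis
ranks cycles by mean torque into 10 groups (ties broken by cycle order; the
remainder goes to the lowest-torque groups), and the primary decile error
compares decile-mean measured and reconstructed waveforms; per-cycle
averaging is available. A model's error ratio is the mean over deciles of
its decile RMSE divided by the two-feature reconstruction's. In
cross-validation (70% of each decile for training, default 1000 repetitions,
reducible), the centring, scaling, SIMPLS fit and score regressions are all
refit on the training rows only; when both numerator and denominator errors
vanish (noiseless data), the ratio is defined as 1.

## Synthetic study conditions

The generator is the package's ground-truth instrument. Per cycle it draws
(t_L, t_R) from a truncated bivariate normal (means 14 and 12 ms after
onset, SD 2 ms each — an ~8 ms modulation window at ±2 SD), forms true
scores by a 2x2 map W applied to the *population*-standardised timings, and
emits `row = STA + scores @ F + noise`, where F holds two orthonormal
features oscillating at four times the wingbeat frequency with distinct
phases (the first with a DC admixture so mean torque is informative), and
the STA mixes the wingbeat fundamental (cosine phase, so the analytic-phase
zero lands on the nominal onset) with a 4x harmonic. Cycles are
concatenated, padded with STA-only cycles at both ends, and passed through
the oscillator forward model (natural frequency ~100 Hz, damping ratio 0.3,
in the calibration-defined arbitrary units) to produce the angle record,
with synchronized spike tables and an EMG synthesiser (stereotyped pulse per
spike plus noise) to exercise detection.

Defaults that define the study conditions, and why:

* **Timing correlation 0.65.** The left–right correlation during *active
  visually driven turning*. The choice is constrained from above by the
  analysis itself: the independent timing variance per muscle is
  (1 − rho)/2 of its total, and this must clear the permutation chance
  floor (~3% of a column's variance at N = 500) with margin for the second
  feature to be detectably encoded in *both* muscles. At rho = 0.9 the
  independent share (5%) sits at the floor and no generator of this
  structure can exhibit the phenomenon the analysis is designed to detect.
* **Independent-regime map `diag(1, 0.7) · R(15°)` in the whitened
  sum/difference timing basis** (score SD 0.8). Symmetric or
  whitened-orthogonal maps provably align the measured score directions
  exactly with the timing sum and difference axes, in which case one
  synergy model per score is trivially adequate and the independence test
  degenerates. The 15° tilt makes each encoded dimension genuinely oblique
  to both synergy axes — each muscle contributes to each feature — and the
  0.7 amplitude ratio separates the two singular values so the measured
  directions are stable across animals. Left–right asymmetry is expected
  in a frame triggered on one muscle.
* **Noise: SD 0.024, low-passed at 100 Hz.** Band-limited because residual
  torque fluctuation (steering muscles, aerodynamics, tether vibration) is
  smooth on the 0.1 ms sample scale; white noise at b ≈ N would push the
  permutation chance floor to ~0.5 R² and is unphysical. The amplitude
  leaves the two-feature reconstruction ~75–80% of the per-cycle post-STA
  variance and keeps the recovered feature plane within ~3° of the truth.
* **Regimes.** `synergy_dt` puts all score variance on the standardised
  timing difference; `redundancy` on the right muscle alone; `null` has a
  zero map. True scores are defined on population-standardised timings so
  that the differential-synergy regime's encoded direction is *exactly*
  proportional to the raw timing difference; defining it on
  sample-standardised timings leaks O(1/sqrt(2N)) sampling error into the
  direction, which the paired PRESS test is sensitive enough to flag as a
  spurious rejection of the true model.

What the generator does not emulate: wingbeat-frequency drift and
cycle-length variability, slow non-stationarity (fatigue, arousal), burst
or missing spikes, steering-muscle torque correlated across cycles,
multi-axis dynamics, and any nonlinearity in the timing-to-torque map.
Passing tests therefore show that the pipeline recovers the right structure
when its linear, stationary assumptions hold — not that real recordings
satisfy those assumptions.

## Problem sizes used in the test suite

Unit and acceptance tests run the default 500-cycle experiment for the
significance procedure (1000 permutations in the acceptance test, 300 in
the faster unit variant), 20 batches of 7 animals x 500 cycles for the
model-selection checks, 50 replicates at 300 permutations for the null
calibration, and 20 random parameter draws for oscillator calibration.
These sizes were chosen so each statistical claim is tested at the power
its margin requires; the cross-validation repetition count is configurable
and the library default remains 1000.

## Known limitations

* The measured second score mixes signal and noise roughly in proportion to
  its singular-value share; at low SNR its direction wanders, which widens
  the spread of PRESS comparisons involving it.
* The deflation-identity discrepancy above means `Q` is not exactly the
  loading matrix of a residual-based factorisation when more than one
  component is extracted.
* PRESS model comparison assumes one spike per muscle per cycle; burst
  firing would need a different parameterisation of U.
* The torquemeter model is a single second-order mode; tether compliance
  beyond that, or roll/pitch coupling, is out of scope.
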