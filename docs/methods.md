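# Methods

This note records the modelling choices, defaults and numerical decisions
behind `nirsmap`, and what the test suite does and does not establish.

## Optical model (MBLL)

Optical-density change is defined with the base-10 logarithm of the
intensity ratio against a reference sample (default: the first), so the
reference sample is exactly zero in every channel and wavelength. The
inversion to (ΔHbO, ΔHbR) solves the 2×2 extinction system per sample;
configuration is rejected if the extinction matrix's condition number
exceeds `max_condition` (default 1e6).

* **Extinction coefficients** (μM⁻¹·mm⁻¹, 760/830 nm) default to the
  Gratzer/Cope compilation values; they are device-independent constants and
  overridable in the config.
* **DPF** defaults to 6.0 at both wavelengths — a common adult-head value.
  GLM-based channelwise inference is robust to a constant-DPF assumption
  because each channel is scaled, not reshaped, by it.
* **Source–detector distance has no default.** It is geometry the package
  cannot guess; the example config records 2 mm (the separation printed for
  the original rig, plausibly a typo for 2 cm) but the value must always be
  supplied explicitly.

## Design matrix

`build_design` produces `[task, baseline, dct_1..dct_m]`:

* The **task regressor** is the block boxcar (boundaries floored to sample
  indices, half-open intervals) causally convolved with a double-gamma
  kernel and truncated to the record. The convolved column is
  peak-normalized to 1 so the task coefficient reads directly as the peak
  evoked response in μM.
* The **double-gamma kernel** uses gamma shapes `1 + delay/dispersion` with
  scale `dispersion`, so `peak_delay_s` (default 6 s) is exactly the mode of
  the positive lobe and `undershoot_delay_s` (16 s) the mode of the
  undershoot, ratio 1/6, support 32 s. Parameters are config-overridable.
* The **DCT high-pass set** uses the DCT-II basis
  cos(π r (2k+1)/2N), unit-normalized. The set size is an explicit parameter
  (default 3, giving L = 5 regressors). A cut-off-frequency mode
  (`m = ⌊2·T·f_c⌋`) is also provided, but note that a very low cut-off
  (e.g. 0.0006 Hz on a 552 s record) floors to zero columns — the
  package then demands an explicit choice rather than guessing.
* The DCT columns need the total record length N, which is known in advance
  from the protocol; this is a declared precondition of the online loop, not
  lookahead into the data.

## Prewhitening

The regression error is modelled AR(1). ρ is estimated online as the running
lag-1 autocorrelation of the raw post-fit residuals
(Σe(k)e(k−1)/Σe(k−1)²), clipped to |ρ| ≤ 0.99, refreshed every sample, and
held at zero during a burn-in (default 30 samples) while the estimator's own
transient dominates the residual stream. The transform subtracts ρ times the
previous *raw* pair from the current one; the first sample passes through.
A fixed training-data ρ can be configured instead (`fixed_rho`), which
freezes estimation. The online framework assumes the coefficient vector
changes slowly between consecutive samples; for block designs at ~2 Hz this
is benign.

## Kalman estimator

State = GLM coefficient vector under a random walk (A = I, Q = qI), scalar
observation with variance r. Defaults q = (0.01)², r = (0.5)², read as plain
variances in the working units (the source quotes them as "(1%/sec)²" and
"(0.5 μM/sec)²"; the percentage form is not literally a μM² quantity, so the
numerals are adopted as variances and exposed in config — ReML estimation of
q and r from training data is out of scope). The state starts at zero;
P(0) = p0·I with p0 = 1e4 (weakly informative; the initial covariance is
not pinned down by the source).

Numerical choices:

* Covariance update uses the simple form (I − KH)P⁻ followed by explicit
  symmetrization each step; over ≥1000 random steps the smallest eigenvalue
  stays ≥ −1e−8.
* The running RSS for σ̂² uses the exact recursive least-squares identity
  RSS(k) = RSS(k−1) + Δy(k)² · r/E(k) (innovation × post-update residual).
  In the q = 0 limit this equals the batch residual sum of squares at the
  current estimate — which is what the σ̂² definition requires — whereas
  accumulating squared post-update residuals would undercount it by
  ~L·ln N/N.
* **Diffuse/OLS mode** (`KalmanConfig.diffuse()`: q = 0, p0 = 1e8) makes the
  filter recursive ordinary least squares; per-step coefficients and t agree
  with a batch OLS oracle to ~1e−8/1e−7 on well-conditioned designs. This is
  the central correctness oracle, and also the mode used for calibration
  checks (below).

All channels are updated in parallel (vectorized over a leading channel
axis); channels never couple.

## Testing and multiplicity

t(k) = cᵀβ̂ / √(σ̂²·cᵀGram⁻¹c) with dof = k − L, one-tailed for activation
(a positive task coefficient indicates a response; deactivation mapping is
out of scope). A channel is testable once dof ≥ 1 **and** its Gram matrix is
invertible — for a block design this is after task onset, since the task
column is zero during the preparation period; untestable channels carry NaN
and never raise inside the loop.

The correction formula p_b = (1 − (1 − p_in)^j)/j behaves like 1/j for large
j but deflates only mildly for small j (p_b(0.05, 8) ≈ 0.042, not 0.05/8 ≈
0.006). Consequence: under the `per_step` policy the family-wise error of a
multi-channel montage is close to 1 − (1 − p_in)^(channels), and exact
active-set recovery is only expected for small montages; the `cumulative`
policy (default), where j counts every test performed since the start,
is far stricter and is the conservative choice for long runs.

Because the t statistic uses the OLS-form variance cᵀGram⁻¹c, it has its
nominal t distribution only in the q = 0 limit. With process noise q > 0 the
final-step coefficient wanders with steady-state sd ≈ 2× the OLS formula's
value at the defaults, so nominal-rate calibration checks (type-I error,
whitening effect, drift bias) are run in diffuse/OLS mode; the tracking mode
keeps the same machinery but its running t is an index, not an exactly
calibrated statistic. This trade-off is inherited from the framework itself.

## Synthetic generator

The generator emulates a 24-channel, 1.81 Hz, 552 s block-design session
(42 s preparation + 10 × (21 s task + 30 s rest)) with:

* task response: amplitude × the same peak-normalized task regressor the
  design uses (so the true β₁ equals the amplitude, default 1.0 μM — a
  typical motor-task ΔHbO response);
* physiological sinusoids: cardiac 1.1 Hz (above the 0.905 Hz Nyquist
  frequency — kept intentionally so realistic aliasing is exercised),
  respiratory 0.3 Hz, Mayer wave 0.1 Hz, amplitudes 0.10/0.15/0.25 μM (the
  source gives no numeric amplitudes; these sit in the conventionally
  reported 0.1–0.3 μM range);
* very-low-frequency drift: a 0.002 Hz sinusoid with per-channel random
  phase plus a random walk (σ = 0.01 μM/step). The default sine amplitude is
  **5 μM**: in real recordings optode-shift/baseline drift dominates the
  ~1 μM response (it is visible by eye on raw traces), and the measured
  sensitivity of the task coefficient to this drift under the default
  protocol is only ≈ 0.04–0.08 μM bias per μM of drift amplitude — a drift
  comparable to the response would be statistically invisible, which is a
  genuine (and documented) property of this protocol, not a test condition;
* AR(1) measurement noise with innovation σ (default 0.5 μM), initialized at
  its stationary distribution;
* an optional forward-model path that maps (ΔHbO, ΔHbR = −0.3·ΔHbO) through
  the MBLL to dual-wavelength intensities for end-to-end tests. The −0.3
  coupling is the conventional inverse HbR/HbO ratio.

Every component is offset to start at zero, mirroring the referencing step
of real data; each trace equals the sum of its reported components exactly,
and everything is deterministic given the seed. The generator does **not**
model motion spikes, nonlinear (balloon-type) hemodynamics, spatial noise
correlation, or inter-subject response-shape variability — a green test
establishes correct behaviour under the stated linear-additive world only.

## Verification harness

`verify_against_ols` replays a record in diffuse/OLS mode and compares every
step against a batch OLS + t oracle. Steps whose partial Gram matrix has
condition number above 1e7 are skipped and counted: on NIRS designs the
drift columns are mutually near-collinear over early partial records, the
OLS solution there is numerically indeterminate, and no meaningful
comparison exists. On well-conditioned synthetic designs all steps from
dof = 1 onward are compared.

## Known limitations

* q and r come from configuration; no ReML/training-data estimation.
* AR order is fixed at 1; no extended-Kalman sinusoidal noise modelling.
* The activation map is channelwise; no spatial interpolation, cluster
  inference or anatomical registration.
* Detection times on synthetic data are indicative only; they depend on the
  simulated noise world and cannot be compared quantitatively to recordings
  of human subjects.
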