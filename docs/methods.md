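# Methods

This note documents the models, numerical choices and open design
decisions behind `gaitfatigue`, in the spirit of a statistics package's
methods appendix. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The measurement model

A walking trial yields, per muscle and leg, a surface-EMG channel
sampled at 1–2 kHz, a 100 Hz vertical heel-marker trajectory, and
(optionally) per-cycle sagittal joint angles. Two conditions are
compared: walking at comfortable speed before, and immediately after,
an incremental treadmill protocol that ramps speed (70→150 % of
comfortable) and incline (2→12°) in seven contiguous 3-minute stages
until exhaustion.

### Preprocessing

- **Band-pass**: 10–250 Hz, 4th-order Butterworth, applied as
  second-order sections. Zero-phase (forward–backward) application is
  the default; it doubles the effective attenuation while keeping the
  design order at 4, and introduces no group delay (verified by
  cross-correlation in the tests). The design order, not the effective
  one, is what the filter spec names.
- **Heel strikes**: local minima of the vertical heel trajectory with a
  prominence of 25 % of the trajectory's peak-to-peak amplitude and a
  minimum inter-strike interval of 0.4 s. This is the simplest
  marker-only event detector; it recovers the generator's ground-truth
  strike times to within one sample at 100 Hz.
- **Cycle screen**: heelstrike-to-heelstrike cycles of the same foot;
  durations outside [0.5, 1.5] s (bounds inclusive — only strict
  violations are excluded) are flagged invalid with a stated reason.
  There is no interactive correction step: exclusion + audit replaces
  manual editing, so runs are reproducible.

### Features

- **Median frequency** per cycle: raw (boxcar) periodogram of the
  band-passed — not rectified, not enveloped — cycle; cumulative power
  restricted to 10–250 Hz; linear interpolation between frequency bins
  at the half-power point. Welch averaging within a cycle was rejected
  (cycles of ~1 s are too short to segment further), and the
  median-across-cycles already suppresses periodogram variance. The MF
  is computed on the whole cycle, not only the active phase; a
  band-restricted spectrum makes the result invariant to amplitude
  scaling by construction.
- **Trial MF**: median over valid cycles; even counts use the midpoint
  convention.
- **RMS**: 101 ms centred moving-RMS window (edges truncated to the
  available samples); each valid cycle linearly interpolated onto 101
  nodes (endpoints preserved) and averaged. The **active phase** is
  determined once on this cycle-averaged waveform — not per cycle —
  as the samples strictly above the activation threshold
  `mean_rest + 2·SD_rest`, where the resting recording passes through
  the identical filter + envelope chain. The reported RMS is the mean
  over active samples; a waveform that never crosses threshold yields a
  missing value, logged.
- **SNR gate**: SNR = active-phase mean of the averaged envelope divided
  by the resting mean RMS; channels with SNR < 5 are excluded
  ("at least 5" → the boundary is included). The denominator choice is
  a design decision — the threshold value itself is a documented
  alternative denominator available in the code — because no closed
  formula for "SNR during walking" is standard.

## Protocol arithmetic

Stage windows are half-open on the right: stage *k* covers
`[180(k−1), 180k)` seconds, and the full 1260 s maps to stage 7, so a
stop at exactly 12:00 lies in stage 5. Percent grade is interpreted as
rise-over-run, `100·tan(degrees)`; the sine convention was rejected
because it disagrees with the schedule's printed 21.3 % at 12°
(100·sin 12° = 20.8). Comfortable speed is `mean(0.5 + 0.01·t)` over
the three ramp-stop times. The bundled 18-child reference cohort table
is used as input data; summaries are recomputed from its rows as
printed, which can differ in the last digit from summaries computed on
un-rounded source measurements (e.g. mean speed 1.10 vs a published
1.11 m/s) — the package reports the recomputed values.

## Mixed-effects model

`y ~ C(condition)*C(muscle) + C(condition)*C(leg)` with a random
intercept per subject, fitted by REML (delegated to statsmodels
`MixedLM`; optimizers are tried in the order lbfgs, bfgs, powell, cg
until convergence). Factors with a single observed level drop out of
the formula automatically. Which interactions belong in the RMS model
is genuinely open; the default includes the two reported for MF and is
configurable.

- **EMMs** average the model's cell predictions over the other factors'
  levels with *equal weights*, regardless of cell counts — the
  estimated-marginal-means convention — so unbalanced missingness
  (AFO-occluded channels) does not tilt the means. Missing cells are
  handled by row-wise deletion inside the unbalanced model.
- **Inference**: Wald t tests on the fixed-effect covariance with
  residual degrees of freedom (nobs − rank). Satterthwaite/Kenward-
  Roger fractional df are deliberately out of scope; in the balanced
  paired design the t *statistic* equals the paired t exactly (this is
  an oracle test), and only the df convention differs.
- **Bonferroni**: adjusted p = min(1, m·p) with m the family size.

## 1D non-parametric waveform mapping

Paired differences `d_i = a_i − b_i` over 101 nodes; node-wise
`t = mean(d) / (sd(d)/√n)`. The permutation scheme is independent ±1
sign flips of each subject's difference curve — the standard
exchangeability move for a paired design. When `2^n ≤ n_iter` all sign
patterns are enumerated exactly; otherwise `n_iter` patterns are
sampled with the observed labelling always included. The critical
threshold is the `⌈(1−α)N⌉`-th smallest permuted max-|t| (an order
statistic, giving family-wise error of exactly `⌊αN⌋/N` under the
continuous null — 0.05 at N = 1000). Permutation is vectorized using
the identity that `Σ(s_i d_i)² = Σd_i²` under sign flips, so only the
permuted mean needs recomputing.

Clusters are maximal runs with `|t|` above threshold. Extent is the
node span (end − start) in % of the cycle, with nodes at 1 % spacing
and **no sub-node endpoint interpolation**; the "≤5 % of the cycle"
exclusion is strict, so an extent of exactly 5.0 is *not* considered.
Cluster p-values are the permutation tail probability of the cluster's
max |t| under the global max-statistic distribution (floored at 1/N).
These two definitions are documented alternatives, not a
re-implementation of any existing mapping package's internals.

The normality screen applies the skewness+kurtosis omnibus test to the
differences at every node and chooses the non-parametric route if any
node rejects at α; with fewer than 8 subjects it is skipped (warned)
and the non-parametric route is used.

## Synthetic-data generator

The generator is a phenomenological emulator, not a physiological
motor-unit model; that is a deliberate non-goal.

- **EMG carrier**: Gaussian noise shaped in the frequency domain by the
  power density `S(f) ∝ exp(−(f−c)²/(2w²))` with centre `c` equal to
  the target MF and width `w = 0.25c`. The symmetry of `S` makes the
  median frequency equal `c` analytically; truncation at the 10/250 Hz
  band edges contributes < 10⁻³ of the mass at the default widths.
  *Fatigue* is a compression of the frequency axis by a factor in
  (0, 1] (realised MF = c × scale) plus an optional amplitude factor —
  chosen because measured fatigue manifests exactly as such an MF
  shift; the mechanism is the simulator's own.
- **Modulation and noise floor**: the unit-RMS carrier is multiplied by
  a smooth stride-periodic burst envelope (stance-dominant, values in
  [0, 1]) and summed with flat-band 10–250 Hz noise whose slowly
  wandering envelope has mean 0.002 V. With the default walking
  amplitude of 0.05 V this puts walking SNR near 15–25 (comfortably
  above the gate, as a good clinical recording would be) and biases the
  measured cycle MF by well under 1 Hz. Real recordings' noise
  magnitudes are not published for this protocol, so these defaults are
  the package's calibration choice, fixed once.
- **Heel trajectory**: one raised-cosine bump per stride; exactly
  n+1 minima at known sample times, right foot offset by half a period,
  half-period flanks before the first and after the last strike.
- **Kinematics**: smooth per-joint templates plus a low-order (k ≤ 6)
  random Fourier series over the cycle, scaled so every node has the
  requested SD — the noise is spatially correlated and smooth, which is
  precisely the regime the waveform statistics assume. Defaults:
  1.0° per-cycle noise, 3° subject-level variation — typical treadmill
  inter-cycle/inter-subject sagittal variability. Condition offsets can
  be restricted to a stated %-cycle window.
- **Cohorts**: subject random MF intercepts (SD 10 Hz), residual SD
  8 Hz, muscle baselines in the 58–105 Hz range (proximal lower,
  distal shank muscles higher), a fixed condition effect (default
  −10.4 Hz), and optional AFO-occlusion of affected-side shank
  channels. The measurement-level sampler (`sample_feature_frame`)
  exists alongside the full signal-level route (`simulate_session`);
  estimator-validation suites use the former for speed, the end-to-end
  pipeline tests the latter.
- **Seeding**: one seed per artifact; per-channel/per-condition streams
  are spawned deterministically via `numpy.random.SeedSequence`, so
  fixed seeds reproduce signals bit-identically.

### What passing tests do and do not show

The generator exercises the statistical structure the analysis assumes
(band-shaped spectra, stride-periodic amplitude modulation, smooth
correlated kinematic noise, subject-level random effects). It does not
emulate electrode lift-off transients, sweat-induced impedance drift,
crosstalk between adjacent muscles, or within-trial fatigue build-up.
Passing the suites therefore validates the *estimators and inference
machinery* under the stated model, not the robustness of the pipeline
to every artefact of real gait-lab recordings; cohort-specific fitted
values from any real study require that study's raw recordings.

## Problem sizes

Validation suites run at the analysis' study conditions: trials of 125
gait cycles per leg; waveform inference on n = 18 subject curves with
1000 permutation iterations and 200 replicates for error-rate checks;
mixed-model recovery over 100 replicate cohorts of 18 subjects.
End-to-end pipeline demonstrations use smaller synthetic cohorts
(4–6 subjects, 8–12 strides at 1 kHz), which the package treats as its
default demonstration scale.

## Known limitations

- Fractional (Satterthwaite-type) denominator df are not reproduced.
- Cluster endpoints are reported at node resolution (1 % of cycle).
- The C3D reader is an optional capability and is exercised only
  lightly; vendor-specific EMG containers are unsupported.
- Within-trial (cycle-by-cycle) fatigue tracking is out of scope by
  design.
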