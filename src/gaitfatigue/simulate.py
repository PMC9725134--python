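"""Synthetic gait-lab data with controllable ground truth.

Generates everything the analysis consumes — gait-modulated sEMG with a
prescribed median frequency, resting recordings, heel-marker vertical
trajectories with known strike times, smooth joint-angle waveforms and
whole cohorts with known condition effects — so every downstream stage
can be tested against construction-time truth.

EMG carrier model
-----------------
The carrier is filtered Gaussian noise shaped in the frequency domain by
a Gaussian spectral density

    S(f) ∝ exp(-(f - c)^2 / (2 w^2)),   c = target MF,  w = width

whose symmetry makes the median frequency analytically equal to the
centre ``c`` (band-edge truncation is negligible for the default width
``w = 0.25 c``).  Muscle fatigue is emulated purely phenomenologically
as a compression of the frequency axis by ``fatigue_spectral_scale``
(realised MF = c x scale) plus an optional amplitude factor; this
mechanism is the simulator's own, chosen because fatigue manifests in
measured data as exactly such an MF shift.  The carrier is
amplitude-modulated by a stride-periodic burst envelope and summed with
a band-limited resting-noise floor whose envelope level is controllable.

Kinematic noise is a low-order random Fourier series over the cycle, so
the waveforms are smooth and spatially correlated, as the 1D
permutation-mapping statistics assume.

All randomness flows from one seed per artifact via
``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .channels import (
    AFO_OCCLUDED_MUSCLES,
    CONDITIONS,
    MUSCLES,
    SIDES,
    SignalChannel,
)

ANALYSIS_BAND_HZ = (10.0, 250.0)

#: Baseline comfortable-condition median frequencies (Hz) per muscle,
#: realistic for paediatric lower-limb walking sEMG: proximal muscles in
#: the 55-70 Hz range, distal shank muscles higher (80-105 Hz).
BASELINE_MF_HZ: dict[str, float] = {
    "RecF": 60.0, "VasL": 58.0, "SemT": 60.0, "BicF": 70.0,
    "GasM": 92.0, "Sole": 85.0, "TibA": 84.0, "PerL": 105.0,
}


# ---------------------------------------------------------------------------
# specs


@dataclass
class SubjectSpec:
    """One simulated child: affected side, function level, speed, sensors."""

    subject_id: str
    affected_side: str = "left"
    gmfcs: str = "I"
    age_years: float = 10.0
    comfortable_speed_mps: float = 1.1
    muscles: tuple[str, ...] = MUSCLES
    #: (muscle, side) channels without data, e.g. occluded by the AFO shell.
    missing_channels: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.affected_side not in SIDES:
            raise ValueError(f"affected_side must be in {SIDES}")
        if self.gmfcs not in ("I", "II"):
            raise ValueError("gmfcs must be 'I' or 'II'")
        if not self.comfortable_speed_mps > 0:
            raise ValueError("comfortable_speed_mps must be positive")
        if not self.age_years > 0:
            raise ValueError("age_years must be positive")
        unknown = set(self.muscles) - set(MUSCLES)
        if unknown or not self.muscles:
            raise ValueError(f"muscles must be a nonempty subset of {MUSCLES}")
        declared = {(m, s) for m in self.muscles for s in SIDES}
        if not set(self.missing_channels) <= declared:
            raise ValueError("missing_channels must be a subset of declared channels")

    def channels(self) -> list[tuple[str, str]]:
        """(muscle, side) pairs with data, in deterministic order."""
        return [
            (m, s)
            for m in self.muscles
            for s in SIDES
            if (m, s) not in set(self.missing_channels)
        ]


@dataclass
class EmgGenSpec:
    """Generative parameters of one synthetic EMG channel."""

    sampling_rate_hz: float = 2000.0
    target_mf_hz: float = 100.0
    amplitude_v: float = 0.05
    rest_noise_mean_v: float = 0.002
    rest_noise_sd_v: float = 0.0004
    fatigue_spectral_scale: float = 1.0
    fatigue_amplitude_scale: float = 1.0
    spectral_width_frac: float = 0.25
    burst_envelope: Optional[np.ndarray] = None  # 101 nodes on 0-100% cycle
    seed: int = 0

    def __post_init__(self) -> None:
        if not ANALYSIS_BAND_HZ[0] < self.target_mf_hz < ANALYSIS_BAND_HZ[1]:
            raise ValueError(
                f"target_mf_hz must lie strictly inside {ANALYSIS_BAND_HZ}, "
                f"got {self.target_mf_hz}"
            )
        if not 0 < self.fatigue_spectral_scale <= 1:
            raise ValueError("fatigue_spectral_scale must be in (0, 1]")
        if self.sampling_rate_hz < 2 * ANALYSIS_BAND_HZ[1]:
            raise ValueError(
                f"sampling rate must be >= {2 * ANALYSIS_BAND_HZ[1]} Hz "
                f"(2x band upper edge), got {self.sampling_rate_hz}"
            )
        if self.burst_envelope is not None:
            env = np.asarray(self.burst_envelope, dtype=float)
            if env.ndim != 1 or env.size != 101 or np.any(env < 0):
                raise ValueError("burst_envelope must be 101 non-negative nodes")
            self.burst_envelope = env
        if not self.amplitude_v > self.rest_noise_mean_v:
            raise ValueError("amplitude_v must exceed the resting noise level")


@dataclass
class TrialSpec:
    """One walking trial: stride count, cadence, condition, kinematic offsets."""

    n_strides_per_leg: int = 125
    cadence_hz: float = 1.0  # strides per second per leg
    condition: str = "comfortable"
    kinematic_offset_deg: dict = field(default_factory=dict)  # joint -> degrees
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strides_per_leg < 1:
            raise ValueError("n_strides_per_leg must be >= 1")
        if not self.cadence_hz > 0:
            raise ValueError("cadence_hz must be positive")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be in {CONDITIONS}")

    @property
    def stride_period_s(self) -> float:
        return 1.0 / self.cadence_hz

    @property
    def pad_s(self) -> float:
        return max(1.0, self.stride_period_s)

    @property
    def duration_s(self) -> float:
        # pad | left strides (right offset by half a period) | pad
        return self.pad_s + (self.n_strides_per_leg + 0.5) * self.stride_period_s + self.pad_s

    def start_time_s(self, side: str) -> float:
        t0 = self.pad_s
        return t0 if side == "left" else t0 + 0.5 * self.stride_period_s


# ---------------------------------------------------------------------------
# low-level signal builders


def band_carrier(
    n: int,
    sampling_rate_hz: float,
    center_hz: float,
    width_hz: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-RMS Gaussian noise with a Gaussian power spectrum at ``center_hz``."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate_hz)
    # amplitude response = sqrt of the target power density
    gain = np.exp(-((freqs - center_hz) ** 2) / (4.0 * width_hz**2))
    x = np.fft.irfft(spectrum * gain, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def flat_band_carrier(
    n: int,
    sampling_rate_hz: float,
    rng: np.random.Generator,
    band_hz: tuple[float, float] = ANALYSIS_BAND_HZ,
) -> np.ndarray:
    """Unit-RMS noise with flat power over ``band_hz`` and none outside."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate_hz)
    gain = ((freqs >= band_hz[0]) & (freqs <= band_hz[1])).astype(float)
    x = np.fft.irfft(spectrum * gain, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _slow_modulation(n: int, sampling_rate_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth ~1 Hz unit-SD process used to let the noise floor wander."""
    coarse_rate = 4.0
    m = max(int(np.ceil(n / sampling_rate_hz * coarse_rate)) + 2, 4)
    coarse = rng.standard_normal(m)
    t_coarse = np.arange(m) / coarse_rate
    t = np.arange(n) / sampling_rate_hz
    slow = np.interp(t, t_coarse, coarse)
    sd = np.std(slow)
    return slow / sd if sd > 0 else slow


def default_burst_envelope() -> np.ndarray:
    """Smooth stance-dominant activation profile on 101 cycle nodes, in [0, 1]."""
    p = np.linspace(0.0, 100.0, 101)
    env = np.exp(-((p - 15.0) ** 2) / (2 * 10.0**2)) + 0.5 * np.exp(
        -((p - 50.0) ** 2) / (2 * 14.0**2)
    )
    return env / env.max()


def _rest_noise(
    n: int, sampling_rate_hz: float, mean_v: float, sd_v: float, rng: np.random.Generator
) -> np.ndarray:
    base = flat_band_carrier(n, sampling_rate_hz, rng)
    if mean_v <= 0:
        return np.zeros(n)
    sigma = mean_v + sd_v * _slow_modulation(n, sampling_rate_hz, rng)
    sigma = np.clip(sigma, 0.05 * mean_v, None)
    return sigma * base


# ---------------------------------------------------------------------------
# artifact-level generators


def generate_emg_channel(
    spec: EmgGenSpec,
    trial: TrialSpec,
    muscle: str = "RecF",
    side: str = "left",
    is_affected: Optional[bool] = None,
) -> SignalChannel:
    """Synthetic walking sEMG for one muscle and leg.

    Zero-mean band-shaped noise with median frequency ``target_mf_hz``
    (times ``fatigue_spectral_scale`` in the fatigued condition),
    amplitude-modulated by the burst envelope once per stride, plus the
    resting-noise floor.  Ground truth (realised MF, stride phase origin)
    is recorded in ``meta``.
    """
    fs = spec.sampling_rate_hz
    n = int(round(trial.duration_s * fs))
    fatigued = trial.condition == "fatigued"
    scale = spec.fatigue_spectral_scale if fatigued else 1.0
    center = spec.target_mf_hz * scale
    width = spec.spectral_width_frac * center

    seq = np.random.SeedSequence(entropy=spec.seed, spawn_key=(hash_label(muscle, side),))
    rng_carrier, rng_noise = (np.random.default_rng(s) for s in seq.spawn(2))

    carrier = band_carrier(n, fs, center, width, rng_carrier)

    env_nodes = (
        spec.burst_envelope if spec.burst_envelope is not None else default_burst_envelope()
    )
    t = np.arange(n) / fs
    t0 = trial.start_time_s(side)
    phase = ((t - t0) / trial.stride_period_s) % 1.0 * 100.0
    env = np.interp(phase, np.linspace(0.0, 100.0, 101), env_nodes)
    env[(t < t0) | (t > t0 + trial.n_strides_per_leg * trial.stride_period_s)] = 0.0

    amplitude = spec.amplitude_v * (spec.fatigue_amplitude_scale if fatigued else 1.0)
    values = amplitude * env * carrier + _rest_noise(
        n, fs, spec.rest_noise_mean_v, spec.rest_noise_sd_v, rng_noise
    )
    return SignalChannel(
        values=values,
        sampling_rate_hz=fs,
        label=muscle,
        side=side,
        units="V",
        is_affected=is_affected,
        meta={"true_mf_hz": center, "condition": trial.condition},
    )


def generate_resting_channel(
    spec: EmgGenSpec,
    duration_s: float = 10.0,
    muscle: str = "RecF",
    side: str = "left",
) -> SignalChannel:
    """Supine resting-state recording: the noise floor alone."""
    fs = spec.sampling_rate_hz
    n = int(round(duration_s * fs))
    seq = np.random.SeedSequence(entropy=spec.seed, spawn_key=(hash_label(muscle, side), 1))
    rng = np.random.default_rng(seq)
    values = _rest_noise(n, fs, spec.rest_noise_mean_v, spec.rest_noise_sd_v, rng)
    return SignalChannel(values=values, sampling_rate_hz=fs, label=muscle, side=side, units="V")


def hash_label(muscle: str, side: str) -> int:
    """Deterministic small integer for per-channel seed spawning."""
    idx_m = MUSCLES.index(muscle) if muscle in MUSCLES else len(MUSCLES)
    idx_s = SIDES.index(side) if side in SIDES else len(SIDES)
    return idx_m * 4 + idx_s


def generate_heel_trajectory(
    trial: TrialSpec,
    side: str = "left",
    sampling_rate_hz: float = 100.0,
    amplitude_mm: float = 40.0,
    baseline_mm: float = 30.0,
) -> SignalChannel:
    """Vertical heel-marker trajectory with known strike times.

    A raised-cosine bump per stride gives exactly ``n_strides_per_leg + 1``
    local minima for the requested foot, one per heel strike; the right
    foot is offset by half a stride period.  Before the first and after
    the last strike the curve rises for half a period and then holds, so
    every minimum is surrounded by full flanks.  Ground-truth strike
    indices are stored in ``meta["true_strike_indices"]``.
    """
    T = trial.stride_period_s
    fs = sampling_rate_hz
    n = int(round(trial.duration_s * fs))
    t = np.arange(n) / fs
    t0 = trial.start_time_s(side)
    t_last = t0 + trial.n_strides_per_leg * T

    z = baseline_mm + 0.5 * amplitude_mm * (1.0 - np.cos(2 * np.pi * (t - t0) / T))
    z[t < t0 - T / 2] = baseline_mm + amplitude_mm
    z[t > t_last + T / 2] = baseline_mm + amplitude_mm

    strikes = np.round((t0 + np.arange(trial.n_strides_per_leg + 1) * T) * fs).astype(int)
    return SignalChannel(
        values=z,
        sampling_rate_hz=fs,
        label="heel_z",
        side=side,
        units="mm",
        meta={"true_strike_indices": strikes},
    )


# ---------------------------------------------------------------------------
# kinematics

#: Smooth sagittal joint-angle templates (degrees) over 0-100% of the cycle.
def _joint_template(joint: str, p: np.ndarray) -> np.ndarray:
    r = p / 100.0
    if joint == "hip":  # flexion at contact, extension in late stance
        return 25.0 * np.cos(2 * np.pi * r) + 5.0
    if joint == "knee":  # loading-response bump + large swing flexion
        return (
            8.0
            + 12.0 * np.exp(-((p - 15.0) ** 2) / (2 * 8.0**2))
            + 50.0 * np.exp(-((p - 72.0) ** 2) / (2 * 9.0**2))
        )
    if joint == "ankle":  # dorsi/plantarflexion excursion
        return (
            5.0 * np.sin(2 * np.pi * r)
            - 12.0 * np.exp(-((p - 62.0) ** 2) / (2 * 6.0**2))
            + 2.0
        )
    raise ValueError(f"unknown joint {joint!r} (expected hip, knee or ankle)")


def smooth_cycle_noise(
    rng: np.random.Generator, sd_deg: float, n_nodes: int = 101, order: int = 6
) -> np.ndarray:
    """Low-order random Fourier series over the cycle, scaled to node SD ``sd_deg``."""
    p = np.linspace(0.0, 1.0, n_nodes)
    noise = np.zeros(n_nodes)
    for k in range(order + 1):
        w = 1.0 / (1.0 + k)
        a, b = rng.standard_normal(2)
        noise += w * (a * np.cos(2 * np.pi * k * p) + b * np.sin(2 * np.pi * k * p))
    # normalize by the process SD (over coefficient draws) rather than the
    # realized SD, so independence between draws is preserved
    var = sum((1.0 / (1.0 + k)) ** 2 for k in range(order + 1))
    return noise * (sd_deg / np.sqrt(var))


def generate_kinematic_waveform(
    trial: TrialSpec,
    joint: str,
    noise_sd_deg: float = 1.0,
    offset_window_pct: tuple[float, float] = (0.0, 100.0),
    seed: Optional[int] = None,
) -> np.ndarray:
    """Per-cycle joint-angle curves: template + smooth noise (+ offset).

    Returns an ``(n_strides, 101)`` array.  The condition offset
    ``trial.kinematic_offset_deg[joint]`` is added on the nodes whose
    cycle percentage lies inside ``offset_window_pct`` (inclusive).
    """
    if trial.n_strides_per_leg < 2:
        raise ValueError("need n_strides_per_leg >= 2 for waveform sets")
    p = np.linspace(0.0, 100.0, 101)
    template = _joint_template(joint, p)
    offset = float(trial.kinematic_offset_deg.get(joint, 0.0))
    lo, hi = offset_window_pct
    window = (p >= lo) & (p <= hi)
    rng = np.random.default_rng(trial.seed if seed is None else seed)
    curves = np.empty((trial.n_strides_per_leg, 101))
    for i in range(trial.n_strides_per_leg):
        curves[i] = template + smooth_cycle_noise(rng, noise_sd_deg)
        curves[i, window] += offset
    return curves


def generate_paired_waveforms(
    n_subjects: int,
    offset_deg: float = 0.0,
    offset_window_pct: tuple[float, float] = (0.0, 100.0),
    noise_sd_deg: float = 1.0,
    subject_sd_deg: float = 3.0,
    joint: str = "ankle",
    seed: int = 0,
):
    """Paired per-subject mean curves for the two walking conditions.

    Each subject's curve is the joint template plus a smooth subject-level
    deviation; the two conditions add independent smooth noise, and the
    fatigued condition additionally shifts by ``offset_deg`` inside
    ``offset_window_pct``.  Returns a
    :class:`gaitfatigue.snpm.PairedWaveformSet` with ``curves_a`` =
    comfortable and ``curves_b`` = fatigued.
    """
    from .snpm import PairedWaveformSet

    p = np.linspace(0.0, 100.0, 101)
    template = _joint_template(joint, p)
    window = (p >= offset_window_pct[0]) & (p <= offset_window_pct[1])
    rng = np.random.default_rng(seed)
    a = np.empty((n_subjects, 101))
    b = np.empty((n_subjects, 101))
    for i in range(n_subjects):
        base = template + smooth_cycle_noise(rng, subject_sd_deg)
        a[i] = base + smooth_cycle_noise(rng, noise_sd_deg)
        b[i] = base + smooth_cycle_noise(rng, noise_sd_deg)
        b[i, window] += offset_deg
    return PairedWaveformSet(curves_a=a, curves_b=b)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class Cohort:
    """Simulated cohort with recorded ground truth for parameter recovery."""

    subjects: list[SubjectSpec]
    condition_effect_mf_hz: float
    affected_leg_extra_hz: float
    subject_sd_hz: float
    residual_sd_hz: float
    baseline_mf_hz: dict[str, float]
    rms_mean_v: float
    rms_sd_v: float
    seed: int


def generate_cohort(
    n_subjects: int = 18,
    effect_mf_hz: float = -10.4,
    affected_leg_extra_hz: float = 0.0,
    subject_sd_hz: float = 10.0,
    residual_sd_hz: float = 8.0,
    with_missing_channels: bool = True,
    seed: int = 0,
) -> Cohort:
    """Cohort of subject specs with a known fatigue effect on MF.

    ``effect_mf_hz`` is the fixed condition effect (fatigued minus
    comfortable); subject-level random intercepts have SD
    ``subject_sd_hz``.  With ``with_missing_channels`` the affected-side
    shank muscles are occluded, as an ankle-foot orthosis would.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        affected = "left" if rng.random() < 0.5 else "right"
        missing: tuple[tuple[str, str], ...] = ()
        if with_missing_channels:
            missing = tuple((m, affected) for m in AFO_OCCLUDED_MUSCLES)
        subjects.append(
            SubjectSpec(
                subject_id=f"S{i + 1:02d}",
                affected_side=affected,
                gmfcs="I" if rng.random() < 16 / 18 else "II",
                age_years=float(rng.uniform(4, 18)),
                comfortable_speed_mps=float(np.clip(rng.normal(1.11, 0.22), 0.4, None)),
                muscles=MUSCLES,
                missing_channels=missing,
            )
        )
    return Cohort(
        subjects=subjects,
        condition_effect_mf_hz=effect_mf_hz,
        affected_leg_extra_hz=affected_leg_extra_hz,
        subject_sd_hz=subject_sd_hz,
        residual_sd_hz=residual_sd_hz,
        baseline_mf_hz=dict(BASELINE_MF_HZ),
        rms_mean_v=0.03,
        rms_sd_v=0.01,
        seed=seed,
    )


def sample_feature_frame(cohort: Cohort, seed: int = 0) -> pd.DataFrame:
    """One stochastic draw of the cohort's per-muscle feature table.

    ``mf_hz`` = muscle baseline + subject intercept + condition effect
    (+ extra decrease on the affected leg when fatigued) + residual noise.
    This is the measurement-level stand-in used for estimator validation;
    the full signal-level route goes through :func:`simulate_session`.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cohort.seed, spawn_key=(2, seed)))
    rows = []
    for subj in cohort.subjects:
        u = rng.normal(0.0, cohort.subject_sd_hz)
        u_rms = rng.normal(0.0, cohort.rms_sd_v / 2)
        for muscle, side in subj.channels():
            leg = "affected" if side == subj.affected_side else "unaffected"
            for condition in CONDITIONS:
                shift = 0.0
                if condition == "fatigued":
                    shift = cohort.condition_effect_mf_hz
                    if leg == "affected":
                        shift += cohort.affected_leg_extra_hz
                mf = (
                    cohort.baseline_mf_hz[muscle]
                    + u
                    + shift
                    + rng.normal(0.0, cohort.residual_sd_hz)
                )
                rms = max(
                    cohort.rms_mean_v + u_rms + rng.normal(0.0, cohort.rms_sd_v), 1e-4
                )
                rows.append(
                    {
                        "subject": subj.subject_id,
                        "muscle": muscle,
                        "leg": leg,
                        "condition": condition,
                        "mf_hz": mf,
                        "rms_v": rms,
                        "snr": 15.0,
                        "n_cycles": 125,
                    }
                )
    return pd.DataFrame(rows)


def simulate_session(
    subject: SubjectSpec,
    n_strides: int = 12,
    sampling_rate_hz: float = 1000.0,
    cadence_hz: float = 1.0,
    fatigue_spectral_scale: float = 0.85,
    fatigue_amplitude_scale: float = 1.0,
    kinematic_offset_deg: Optional[dict] = None,
    amplitude_v: float = 0.05,
    rest_noise_mean_v: float = 0.002,
    seed: int = 0,
):
    """Complete two-condition session (EMG, heel markers, kinematics, rest).

    Returns a :class:`gaitfatigue.session.Session`.  Per-channel and
    per-condition seeds are spawned deterministically from ``seed``.
    """
    from .session import Session, Trial

    base_seq = np.random.SeedSequence(seed)
    cond_seeds = {c: int(s.generate_state(1)[0] % 2**31) for c, s in
                  zip(CONDITIONS, base_seq.spawn(2))}
    trials = {}
    resting: list[SignalChannel] = []
    for ci, condition in enumerate(CONDITIONS):
        trial_spec = TrialSpec(
            n_strides_per_leg=n_strides,
            cadence_hz=cadence_hz,
            condition=condition,
            kinematic_offset_deg=(kinematic_offset_deg or {}) if condition == "fatigued" else {},
            seed=cond_seeds[condition],
        )
        emg_channels = []
        for muscle, side in subject.channels():
            gen = EmgGenSpec(
                sampling_rate_hz=sampling_rate_hz,
                target_mf_hz=BASELINE_MF_HZ[muscle],
                amplitude_v=amplitude_v,
                rest_noise_mean_v=rest_noise_mean_v,
                fatigue_spectral_scale=fatigue_spectral_scale,
                fatigue_amplitude_scale=fatigue_amplitude_scale,
                seed=cond_seeds[condition],
            )
            emg_channels.append(
                generate_emg_channel(
                    gen, trial_spec, muscle=muscle, side=side,
                    is_affected=(side == subject.affected_side),
                )
            )
            if ci == 0:
                resting.append(
                    generate_resting_channel(gen, duration_s=5.0, muscle=muscle, side=side)
                )
        heel = {
            side: generate_heel_trajectory(trial_spec, side=side) for side in SIDES
        }
        kinematics = {
            (joint, side): generate_kinematic_waveform(
                trial_spec, joint,
                seed=cond_seeds[condition] + 7 * j + (0 if side == "left" else 1),
            )
            for j, joint in enumerate(("hip", "knee", "ankle"))
            for side in SIDES
        }
        trials[condition] = Trial(emg=emg_channels, heel=heel, kinematics=kinematics)
    return Session(subject=subject, trials=trials, resting=resting)
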