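"""Per-muscle fatigue features: median frequency, RMS and SNR gating.

Median frequency (MF) is the frequency splitting the cycle's EMG power
spectrum (periodogram of the band-passed signal, restricted to the
10–250 Hz analysis band) into equal-power halves; the per-trial MF is the
median over all valid gait cycles.  MF falls as muscle-fibre conduction
velocity slows with fatigue.

Amplitude is summarised as RMS: the band-passed signal is enveloped with
a 101 ms moving RMS window, each valid cycle is time-normalized to 101
samples (0–100% of the gait cycle) and the cycles are averaged.  The
muscle's active phase is the part of that averaged waveform above the
activation threshold — resting-state envelope mean plus two standard
deviations ("noise") — and the reported RMS is the mean over active
samples.  Channels whose walking signal-to-noise ratio falls below 5 are
excluded from analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .channels import SignalChannel
from .preprocess import FilterSpec, GaitCycleSet, bandpass

logger = logging.getLogger(__name__)

ANALYSIS_BAND_HZ: tuple[float, float] = (10.0, 250.0)
RMS_WINDOW_MS: float = 101.0
N_NODES: int = 101
THRESHOLD_N_SD: float = 2.0
SNR_MIN: float = 5.0


def cycle_median_frequency(
    cycle_values: np.ndarray,
    sampling_rate_hz: float,
    band_hz: tuple[float, float] = ANALYSIS_BAND_HZ,
) -> float:
    """Median frequency of one gait cycle's band-passed EMG, in Hz.

    Raw (boxcar) periodogram of the cycle, cumulative power restricted to
    ``band_hz``, linear interpolation between frequency bins at the
    half-power point.  Returns NaN for an all-zero (or zero-band-power)
    cycle, which is reported as missing upstream.
    """
    x = np.asarray(cycle_values, dtype=float)
    if x.size < 2:
        return float("nan")
    freqs, power = sps.periodogram(x, fs=sampling_rate_hz, window="boxcar")
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    freqs, power = freqs[in_band], power[in_band]
    total = power.sum()
    if freqs.size == 0 or total <= 0:
        return float("nan")
    cum = np.cumsum(power)
    half = total / 2.0
    i = int(np.searchsorted(cum, half))
    if i == 0:
        return float(freqs[0])
    # linear interpolation of the cumulative power between adjacent bins
    frac = (half - cum[i - 1]) / (cum[i] - cum[i - 1])
    return float(freqs[i - 1] + frac * (freqs[i] - freqs[i - 1]))


def trial_median_frequency(cycle_mfs: Sequence[float]) -> float:
    """Median MF over valid cycles; even counts use the midpoint convention.

    NaN entries (undefined per-cycle MFs) are dropped; returns NaN when no
    cycle has a defined MF.
    """
    mfs = np.asarray(list(cycle_mfs), dtype=float)
    mfs = mfs[np.isfinite(mfs)]
    if mfs.size == 0:
        return float("nan")
    return float(np.median(mfs))


def rms_envelope(channel: SignalChannel, window_ms: float = RMS_WINDOW_MS) -> SignalChannel:
    """Moving-RMS envelope with a centered window, same length as the input.

    At the edges the window is truncated to the available samples.
    """
    n = channel.n_samples
    w = int(round(window_ms / 1000.0 * channel.sampling_rate_hz))
    w = max(w, 1)
    if w >= n:
        raise ValueError(f"RMS window ({w} samples) must be shorter than the signal ({n})")
    sq = channel.values**2
    kernel = np.ones(w)
    num = np.convolve(sq, kernel, mode="same")
    counts = np.convolve(np.ones(n), kernel, mode="same")
    return channel.with_values(np.sqrt(num / counts))


def time_normalize(cycle_values: np.ndarray, n_nodes: int = N_NODES) -> np.ndarray:
    """Linear interpolation onto ``n_nodes`` points spanning 0–100% of the cycle.

    Endpoint values are preserved; a 101-sample input maps to itself.
    """
    y = np.asarray(cycle_values, dtype=float)
    if y.size < 2:
        raise ValueError("cycle must have at least 2 samples")
    x_old = np.linspace(0.0, 1.0, y.size)
    x_new = np.linspace(0.0, 1.0, n_nodes)
    return np.interp(x_new, x_old, y)


@dataclass(frozen=True)
class RestingStats:
    """Resting-state envelope statistics defining the activation threshold."""

    mean_rms_v: float
    sd_rms_v: float

    def __post_init__(self) -> None:
        if self.sd_rms_v < 0:
            raise ValueError("sd_rms_v must be >= 0")

    @property
    def threshold_v(self) -> float:
        """Activation threshold ("noise"): resting mean RMS + 2 SD."""
        return self.mean_rms_v + THRESHOLD_N_SD * self.sd_rms_v


def resting_stats(
    resting: SignalChannel,
    filter_spec: FilterSpec = FilterSpec(),
    window_ms: float = RMS_WINDOW_MS,
    min_duration_s: float = 2.0,
) -> RestingStats:
    """Resting-envelope mean and SD from a supine resting recording.

    The resting signal passes through the same band-pass and moving-RMS
    chain as the walking data before the statistics are taken.
    """
    if resting.duration_s < min_duration_s:
        raise ValueError(
            f"resting recording too short: {resting.duration_s:.2f} s < {min_duration_s} s"
        )
    env = rms_envelope(bandpass(resting, filter_spec), window_ms).values
    return RestingStats(mean_rms_v=float(np.mean(env)), sd_rms_v=float(np.std(env, ddof=1)))


def active_phase_rms(mean_waveform: np.ndarray, rest: RestingStats) -> float:
    """Mean of the cycle-averaged envelope over its active phase, in Volt.

    Active samples are those strictly above the activation threshold.
    Returns NaN (logged) when no sample exceeds the threshold.
    """
    wf = np.asarray(mean_waveform, dtype=float)
    active = wf > rest.threshold_v
    if not np.any(active):
        logger.info("no active phase: waveform never exceeds threshold %.4g V", rest.threshold_v)
        return float("nan")
    return float(np.mean(wf[active]))


@dataclass(frozen=True)
class GateDecision:
    """SNR-based inclusion decision for one channel."""

    snr: float
    included: bool
    reason: str = ""


def snr_gate(
    active_mean_v: float, rest: RestingStats, snr_min: float = SNR_MIN
) -> GateDecision:
    """Include a muscle iff its walking SNR is at least ``snr_min``.

    SNR = mean of the cycle-averaged envelope over the active phase,
    divided by the resting mean RMS.  A zero resting mean yields infinite
    SNR (included, with a warning).
    """
    if not np.isfinite(active_mean_v):
        return GateDecision(snr=float("nan"), included=False, reason="no active phase")
    if rest.mean_rms_v == 0:
        logger.warning("snr_gate: resting mean RMS is zero; SNR infinite, including")
        return GateDecision(snr=float("inf"), included=True, reason="zero resting mean")
    snr = active_mean_v / rest.mean_rms_v
    included = snr >= snr_min
    reason = "" if included else f"SNR {snr:.2f} < {snr_min:g}"
    return GateDecision(snr=float(snr), included=included, reason=reason)


@dataclass
class MuscleFeature:
    """Fatigue features for one muscle x side x condition."""

    muscle: str
    side: str
    condition: str
    mf_hz: float
    rms_v: float
    snr: float
    n_cycles: int
    included: bool = True
    is_affected: Optional[bool] = None
    mean_waveform: Optional[np.ndarray] = None


def extract_channel_features(
    emg: SignalChannel,
    cycle_set: GaitCycleSet,
    rest: Optional[RestingStats],
    condition: str,
    filter_spec: FilterSpec = FilterSpec(),
    window_ms: float = RMS_WINDOW_MS,
    snr_min: float = SNR_MIN,
    prefiltered: bool = False,
) -> MuscleFeature:
    """Full feature chain for a single EMG channel.

    ``cycle_set`` must be expressed in the EMG channel's sample indices.
    ``rest`` may be None (no resting recording): RMS/SNR are then
    undefined and the channel is retained with ``snr = nan``.
    """
    filt = emg if prefiltered else bandpass(emg, filter_spec)
    env = rms_envelope(filt, window_ms)

    mfs: list[float] = []
    waveforms: list[np.ndarray] = []
    for (a, b), ok in zip(cycle_set.cycles, cycle_set.valid):
        if not ok:
            continue
        mfs.append(cycle_median_frequency(filt.values[a:b], filt.sampling_rate_hz))
        waveforms.append(time_normalize(env.values[a:b]))
    n_valid = len(waveforms)
    mf = trial_median_frequency(mfs)
    if n_valid == 0:
        logger.warning("channel %s: no valid cycles", emg.key)
        return MuscleFeature(
            muscle=emg.label, side=emg.side or "", condition=condition,
            mf_hz=float("nan"), rms_v=float("nan"), snr=float("nan"),
            n_cycles=0, included=False, is_affected=emg.is_affected,
        )
    mean_wf = np.mean(np.vstack(waveforms), axis=0)

    if rest is None:
        logger.warning("channel %s: no resting recording; SNR gating impossible", emg.key)
        rms = float("nan")
        decision = GateDecision(snr=float("nan"), included=True, reason="no resting recording")
    else:
        rms = active_phase_rms(mean_wf, rest)
        decision = snr_gate(rms, rest, snr_min)
        if not decision.included:
            logger.info("channel %s excluded: %s", emg.key, decision.reason)
    return MuscleFeature(
        muscle=emg.label,
        side=emg.side or "",
        condition=condition,
        mf_hz=mf,
        rms_v=rms,
        snr=decision.snr,
        n_cycles=n_valid,
        included=decision.included,
        is_affected=emg.is_affected,
        mean_waveform=mean_wf,
    )
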