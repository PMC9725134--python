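"""EMG band-pass filtering, heel-strike detection and gait-cycle screening.

Raw sEMG is band-pass filtered 10–250 Hz with a 4th-order Butterworth
filter (zero-phase by default, i.e. applied forward and backward, which
doubles the effective order; the design order stays 4).  Gait cycles run
heel strike to heel strike of the same foot, detected as local minima of
the vertical heel-marker trajectory.  Cycles with durations outside
[0.5, 1.5] s (inclusive) are flagged invalid — such cycles almost always
stem from a missed or spurious strike — and every exclusion is audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .channels import SignalChannel

logger = logging.getLogger(__name__)

MIN_CYCLE_S: float = 0.5
MAX_CYCLE_S: float = 1.5


class InsufficientGaitError(ValueError):
    """Raised when fewer than two heel strikes can be found."""


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass filter design: 10–250 Hz, 4th-order Butterworth."""

    low_hz: float = 10.0
    high_hz: float = 250.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("require 0 < low_hz < high_hz")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def sos(self, sampling_rate_hz: float):
        if sampling_rate_hz <= 2 * self.high_hz:
            raise ValueError(
                f"sampling rate {sampling_rate_hz} Hz violates Nyquist for "
                f"high edge {self.high_hz} Hz (need > {2 * self.high_hz} Hz)"
            )
        return signal.butter(
            self.order,
            [self.low_hz, self.high_hz],
            btype="bandpass",
            fs=sampling_rate_hz,
            output="sos",
        )


def bandpass(channel: SignalChannel, spec: FilterSpec = FilterSpec()) -> SignalChannel:
    """Band-pass filter a channel; zero-phase when ``spec.zero_phase``."""
    sos = spec.sos(channel.sampling_rate_hz)
    if spec.zero_phase:
        filtered = signal.sosfiltfilt(sos, channel.values)
    else:
        filtered = signal.sosfilt(sos, channel.values)
    return channel.with_values(filtered)


def detect_heel_strikes(
    heel_z: SignalChannel,
    prominence_frac: float = 0.25,
    min_interval_s: float = 0.4,
) -> np.ndarray:
    """Heel-strike sample indices: prominent local minima of vertical position.

    ``prominence_frac`` scales the required prominence by the trajectory's
    peak-to-peak amplitude; ``min_interval_s`` is the shortest admissible
    inter-strike interval.
    """
    z = heel_z.values
    amplitude = float(np.ptp(z))
    if amplitude == 0:
        raise InsufficientGaitError("insufficient gait: constant heel trajectory")
    distance = max(1, int(round(min_interval_s * heel_z.sampling_rate_hz)))
    strikes, _ = signal.find_peaks(
        -z, prominence=prominence_frac * amplitude, distance=distance
    )
    if strikes.size < 2:
        raise InsufficientGaitError(
            f"insufficient gait: found {strikes.size} heel strikes, need >= 2"
        )
    return strikes.astype(int)


@dataclass
class GaitCycleSet:
    """Heel-strike indices and the derived heelstrike-to-heelstrike cycles."""

    heel_strike_indices: np.ndarray
    sampling_rate_hz: float
    cycles: list[tuple[int, int]] = field(default_factory=list)
    durations_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    valid: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    min_duration_s: float = MIN_CYCLE_S
    max_duration_s: float = MAX_CYCLE_S

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def n_valid(self) -> int:
        return int(np.sum(self.valid))

    def valid_cycles(self) -> list[tuple[int, int]]:
        return [c for c, ok in zip(self.cycles, self.valid) if ok]


def segment_cycles(
    strikes: np.ndarray,
    sampling_rate_hz: float,
    min_duration_s: float = MIN_CYCLE_S,
    max_duration_s: float = MAX_CYCLE_S,
) -> GaitCycleSet:
    """Cut heelstrike-to-heelstrike cycles and flag validity by duration.

    ``n`` strikes yield ``n - 1`` half-open cycles ``[strike_k, strike_k+1)``.
    A cycle is valid when its duration lies in
    ``[min_duration_s, max_duration_s]`` (bounds inclusive).
    """
    strikes = np.asarray(strikes, dtype=int)
    if strikes.size < 2:
        raise InsufficientGaitError("need at least two heel strikes to segment")
    if np.any(np.diff(strikes) <= 0):
        raise ValueError("heel-strike indices must be strictly increasing")
    cycles = [(int(a), int(b)) for a, b in zip(strikes[:-1], strikes[1:])]
    durations = np.diff(strikes) / sampling_rate_hz
    valid = (durations >= min_duration_s) & (durations <= max_duration_s)
    return GaitCycleSet(
        heel_strike_indices=strikes,
        sampling_rate_hz=sampling_rate_hz,
        cycles=cycles,
        durations_s=durations,
        valid=valid,
        min_duration_s=min_duration_s,
        max_duration_s=max_duration_s,
    )


@dataclass
class CycleAudit:
    """Per-trial account of included and excluded gait cycles."""

    n_cycles: int
    n_valid: int
    exclusions: list[tuple[int, str]]  # (cycle index, reason)

    @property
    def n_invalid(self) -> int:
        return self.n_cycles - self.n_valid

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.exclusions, columns=["cycle", "reason"])


def audit_cycles(cycle_set: GaitCycleSet) -> CycleAudit:
    """Audit a segmented trial: every invalid cycle gets a stated reason."""
    if cycle_set.n_cycles == 0:
        logger.warning("audit_cycles: empty cycle set")
        return CycleAudit(n_cycles=0, n_valid=0, exclusions=[])
    exclusions: list[tuple[int, str]] = []
    for i, (dur, ok) in enumerate(zip(cycle_set.durations_s, cycle_set.valid)):
        if ok:
            continue
        if dur < cycle_set.min_duration_s:
            reason = f"duration<{cycle_set.min_duration_s:g}s"
        else:
            reason = f"duration>{cycle_set.max_duration_s:g}s"
        exclusions.append((i, reason))
    return CycleAudit(
        n_cycles=cycle_set.n_cycles, n_valid=cycle_set.n_valid, exclusions=exclusions
    )
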