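"""Core signal container shared by every stage of the pipeline.

A :class:`SignalChannel` is a uniformly sampled 1D signal with a sampling
rate, physical units and gait-specific labels (muscle or marker name, body
side, whether the side is the clinically affected one).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Muscle short labels used throughout: rectus femoris, vastus lateralis,
#: semitendinosus, biceps femoris, gastrocnemius medialis, soleus,
#: tibialis anterior, peroneus longus.
MUSCLES: tuple[str, ...] = (
    "RecF", "VasL", "SemT", "BicF", "GasM", "Sole", "TibA", "PerL",
)

MUSCLE_FULL_NAMES: dict[str, str] = {
    "RecF": "m. rectus femoris",
    "VasL": "m. vastus lateralis",
    "SemT": "m. semitendinosus",
    "BicF": "m. biceps femoris",
    "GasM": "m. gastrocnemius medialis",
    "Sole": "m. soleus",
    "TibA": "m. tibialis anterior",
    "PerL": "m. peroneus longus",
}

#: Lower-leg muscles typically occluded by an ankle-foot orthosis on the
#: affected side (no skin space for the sensor under the brace shell).
AFO_OCCLUDED_MUSCLES: tuple[str, ...] = ("GasM", "Sole", "PerL")

SIDES: tuple[str, str] = ("left", "right")
CONDITIONS: tuple[str, str] = ("comfortable", "fatigued")


@dataclass
class SignalChannel:
    """Uniformly sampled 1D signal.

    Parameters
    ----------
    values
        Sample values. EMG in Volt, marker positions in mm, angles in deg.
    sampling_rate_hz
        Positive sampling rate.
    label
        Muscle short label (one of :data:`MUSCLES`) or a marker/joint name.
    side
        ``"left"`` or ``"right"`` where applicable.
    units
        Physical units of ``values``.
    is_affected
        Whether ``side`` is the clinically affected side.
    meta
        Free-form provenance (e.g. generator ground truth).
    """

    values: np.ndarray
    sampling_rate_hz: float
    label: str = ""
    side: Optional[str] = None
    units: str = "V"
    is_affected: Optional[bool] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("SignalChannel values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"channel {self.label!r} contains non-finite samples")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.side is not None and self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def time(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.sampling_rate_hz

    def with_values(self, values: np.ndarray) -> "SignalChannel":
        """Copy of this channel carrying new sample values."""
        return replace(self, values=np.asarray(values, dtype=float))

    @property
    def key(self) -> str:
        """Stable column name: e.g. ``"TibA_left"``."""
        return f"{self.label}_{self.side}" if self.side else self.label
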