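"""Incremental treadmill fatigue protocol.

The protocol ramps both speed and incline in seven contiguous 3-minute
stages until the child cannot continue.  Treadmill speed per stage is a
fixed fraction of the individually determined comfortable walking speed;
the incline is prescribed in degrees and reported as percent grade
(``100 * tan(deg)``).  Perceived exertion is rated on the pictorial OMNI
scale (0 = totally not tired .. 10 = very, very tired) before and after.

Comfortable speed itself is determined by a slow treadmill ramp
(0.5 m/s start, +0.01 m/s per second) repeated three times; the mean
speed at the three stop signals is the comfortable walking speed.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

#: Per-stage treadmill speed as a fraction of comfortable walking speed.
STAGE_SPEED_FRACTIONS: tuple[float, ...] = (0.70, 0.85, 1.00, 1.15, 1.35, 1.40, 1.50)

#: Per-stage treadmill incline in degrees.
STAGE_INCLINES_DEG: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 12.0)

STAGE_DURATION_S: float = 180.0
N_STAGES: int = len(STAGE_SPEED_FRACTIONS)
TOTAL_DURATION_S: float = N_STAGES * STAGE_DURATION_S  # 1260 s

RAMP_START_MPS: float = 0.5
RAMP_RATE_MPS2: float = 0.01

OMNI_REST_CUTOFF: int = 2  # a pre-protocol score above this triggers a longer rest


def comfortable_speed(stop_times_s: Iterable[float]) -> float:
    """Comfortable walking speed from three ramp stop times.

    The treadmill starts at 0.5 m/s and accelerates 0.01 m/s every second;
    the speed at each stop signal is ``0.5 + 0.01 * t``.  The mean over the
    three repeats is the comfortable walking speed.
    """
    times = np.asarray(list(stop_times_s), dtype=float)
    if times.size != 3:
        raise ValueError(f"expected three ramp stop times, got {times.size}")
    if np.any(times < 0):
        raise ValueError("ramp stop times must be non-negative")
    return float(np.mean(RAMP_START_MPS + RAMP_RATE_MPS2 * times))


def stage_speed(comfortable_mps: float, stage: int) -> float:
    """Treadmill belt speed (m/s) prescribed at ``stage`` (1..7)."""
    if not 1 <= stage <= N_STAGES:
        raise ValueError(f"stage must be in 1..{N_STAGES}, got {stage}")
    return comfortable_mps * STAGE_SPEED_FRACTIONS[stage - 1]


def incline_percent(incline_deg: float) -> float:
    """Percent grade for a treadmill incline angle, to one decimal.

    Grade is rise over run, ``100 * tan(angle)``.
    """
    if not 0 <= incline_deg < 90:
        raise ValueError("incline must be in [0, 90) degrees")
    return round(100.0 * math.tan(math.radians(incline_deg)), 1)


def stage_from_time(fulfilled_s: float) -> int:
    """Protocol stage whose 3-minute window contains the fulfilled time.

    Windows are half-open: stage ``k`` covers ``[180*(k-1), 180*k)``
    seconds, so a stop at exactly 3:00 lies in stage 2 and a stop at
    exactly 12:00 in stage 5.  The full 21:00 maps to stage 7.
    """
    if not 0 <= fulfilled_s <= TOTAL_DURATION_S:
        raise ValueError(
            f"fulfilled time must be in [0, {TOTAL_DURATION_S:.0f}] s, got {fulfilled_s}"
        )
    if fulfilled_s == TOTAL_DURATION_S:
        return N_STAGES
    return int(fulfilled_s // STAGE_DURATION_S) + 1


def omni_gate(score_before: int) -> bool:
    """Whether a longer pre-protocol rest is required (OMNI score > 2)."""
    if not (isinstance(score_before, (int, np.integer)) and 0 <= score_before <= 10):
        raise ValueError(f"OMNI score must be an integer in [0, 10], got {score_before!r}")
    return score_before > OMNI_REST_CUTOFF


def parse_min_sec(text: str) -> float:
    """Parse a ``"mm:ss"`` string (e.g. ``"15:53"``) to seconds."""
    parts = str(text).strip().split(":")
    if len(parts) != 2:
        raise ValueError(f"expected 'mm:ss', got {text!r}")
    minutes, seconds = int(parts[0]), int(parts[1])
    if not 0 <= seconds < 60 or minutes < 0:
        raise ValueError(f"invalid mm:ss time {text!r}")
    return 60.0 * minutes + seconds


def format_min_sec(seconds: float) -> str:
    seconds = int(round(seconds))
    return f"{seconds // 60:02d}:{seconds % 60:02d}"


def schedule(comfortable_mps: float) -> pd.DataFrame:
    """Full per-stage schedule for one child: times, speeds and inclines."""
    rows = []
    for k in range(1, N_STAGES + 1):
        rows.append(
            {
                "stage": k,
                "start_s": STAGE_DURATION_S * (k - 1),
                "end_s": STAGE_DURATION_S * k,
                "speed_fraction": STAGE_SPEED_FRACTIONS[k - 1],
                "speed_mps": stage_speed(comfortable_mps, k),
                "incline_deg": STAGE_INCLINES_DEG[k - 1],
                "incline_pct": incline_percent(STAGE_INCLINES_DEG[k - 1]),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ProtocolResult:
    """Outcome of one fatigue-protocol run."""

    fulfilled_time_s: float
    stage_reached: int
    omni_before: Optional[int] = None
    omni_after: Optional[int] = None

    def __post_init__(self) -> None:
        expected = stage_from_time(self.fulfilled_time_s)
        if self.stage_reached != expected:
            raise ValueError(
                f"stage_reached={self.stage_reached} inconsistent with fulfilled "
                f"time {self.fulfilled_time_s:.0f} s (schedule stage {expected})"
            )
        for score in (self.omni_before, self.omni_after):
            if score is not None and not 0 <= int(score) <= 10:
                raise ValueError(f"OMNI score out of [0, 10]: {score}")


def load_reference_cohort() -> pd.DataFrame:
    """Bundled reference cohort: 18 children with unilateral spastic CP.

    The published validation cohort for this protocol (GMFCS I–II, drop
    foot supported by an AFO or adapted shoes).  Columns include the
    fulfilled protocol time (``mm:ss``), the stage reached and the
    post-protocol OMNI score.  A ``fulfilled_time_s`` column is added.
    """
    with importlib.resources.files("gaitfatigue.data").joinpath(
        "reference_cohort.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    df["fulfilled_time_s"] = df["fulfilled_time"].map(parse_min_sec)
    return df


def cohort_summary(cohort: pd.DataFrame) -> dict:
    """Descriptive statistics of a protocol cohort table (sample SDs).

    Values are recomputed from the table rows as given (no rounding
    adjustments), so they may differ in the last digit from summaries
    computed on un-rounded source data.
    """
    out = {
        "n": int(len(cohort)),
        "age_mean_y": float(cohort["age_years"].mean()),
        "age_sd_y": float(cohort["age_years"].std(ddof=1)),
        "speed_mean_mps": float(cohort["comfortable_speed_mps"].mean()),
        "speed_sd_mps": float(cohort["comfortable_speed_mps"].std(ddof=1)),
        "fulfilled_mean_s": float(cohort["fulfilled_time_s"].mean()),
        "fulfilled_sd_s": float(cohort["fulfilled_time_s"].std(ddof=1)),
        "omni_mean": float(cohort["omni_after"].mean()),
        "omni_sd": float(cohort["omni_after"].std(ddof=1)),
    }
    if "sex" in cohort:
        out["n_female"] = int((cohort["sex"] == "F").sum())
    return out
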