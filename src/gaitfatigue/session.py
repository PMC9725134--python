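"""On-disk session format and optional C3D ingestion.

A session directory holds one JSON metadata document plus columnar CSV
signal files (full ``%.17g`` precision, so the write→read round trip is
lossless for float64):

* ``session.json`` — subject fields, conditions, per-file channel
  declarations, sampling rates, flags.
* ``resting.csv`` — time + one column per resting EMG channel (V).
* ``trial_<condition>_emg.csv`` — time + walking EMG channels (V).
* ``trial_<condition>_heel.csv`` — time + heel-marker height per side (mm).
* ``kin_<condition>.csv`` — long table of per-cycle joint-angle curves
  (joint, side, cycle, node_pct, angle_deg).

EMG is stored in Volt, marker positions in mm and joint angles in
degrees.  C3D motion files can be ingested when the optional ``ezc3d``
dependency is installed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .channels import MUSCLES, SIDES, SignalChannel
from .protocol import ProtocolResult
from .simulate import SubjectSpec

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.17g"


class SessionFormatError(ValueError):
    """Malformed session directory or metadata."""


@dataclass
class Trial:
    """One condition's recordings."""

    emg: list[SignalChannel]
    heel: dict[str, SignalChannel] = field(default_factory=dict)
    #: (joint, side) -> (n_cycles, 101) per-cycle angle curves in degrees
    kinematics: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)


@dataclass
class Session:
    """A subject's full recording set across conditions."""

    subject: SubjectSpec
    trials: dict[str, Trial]
    resting: list[SignalChannel] = field(default_factory=list)
    protocol: Optional[ProtocolResult] = None

    def __post_init__(self) -> None:
        for condition, trial in self.trials.items():
            rates = {c.sampling_rate_hz for c in trial.emg}
            if len(rates) > 1:
                raise SessionFormatError(
                    f"mixed EMG sampling rates in condition {condition!r}: {sorted(rates)}"
                )

    def resting_for(self, muscle: str, side: str) -> Optional[SignalChannel]:
        for ch in self.resting:
            if ch.label == muscle and ch.side == side:
                return ch
        return None

    def unpaired_channels(self) -> list[str]:
        """Walking EMG channels without a matching resting channel."""
        out = []
        for trial in self.trials.values():
            for ch in trial.emg:
                if self.resting_for(ch.label, ch.side or "") is None:
                    out.append(ch.key)
        return sorted(set(out))


def _channel_frame(channels: list[SignalChannel]) -> pd.DataFrame:
    rate = channels[0].sampling_rate_hz
    n = channels[0].n_samples
    data = {"time_s": np.arange(n) / rate}
    for ch in channels:
        if ch.n_samples != n:
            raise SessionFormatError(f"channel {ch.key} length differs within one file")
        data[ch.key] = ch.values
    return pd.DataFrame(data)


def _kin_frame(kinematics: dict[tuple[str, str], np.ndarray]) -> pd.DataFrame:
    rows = []
    node_pct = np.linspace(0.0, 100.0, 101)
    for (joint, side), curves in sorted(kinematics.items()):
        curves = np.asarray(curves, dtype=float)
        for c in range(curves.shape[0]):
            rows.append(
                pd.DataFrame(
                    {
                        "joint": joint,
                        "side": side,
                        "cycle": c,
                        "node_pct": node_pct,
                        "angle_deg": curves[c],
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def write_session(session: Session, path: str | Path, overwrite: bool = False) -> dict:
    """Write a session directory; returns the manifest dict.

    Refuses to overwrite an existing ``session.json`` unless
    ``overwrite`` is set.
    """
    path = Path(path)
    meta_path = path / "session.json"
    if meta_path.exists() and not overwrite:
        raise FileExistsError(f"{meta_path} exists; pass overwrite=True to replace it")
    path.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "format_version": 1,
        "subject": dataclasses.asdict(session.subject),
        "conditions": sorted(session.trials),
        "files": {},
        "snr_gating_possible": bool(session.resting),
    }
    if not session.resting:
        logger.warning("session has no resting recording: SNR gating will be impossible")
    unpaired = session.unpaired_channels()
    if unpaired:
        manifest["unpaired_channels"] = unpaired

    if session.resting:
        df = _channel_frame(session.resting)
        df.to_csv(path / "resting.csv", index=False, float_format=FLOAT_FMT)
        manifest["files"]["resting.csv"] = {
            "sampling_rate_hz": session.resting[0].sampling_rate_hz,
            "channels": [
                {"label": c.label, "side": c.side, "units": c.units} for c in session.resting
            ],
        }

    for condition, trial in session.trials.items():
        if trial.emg:
            name = f"trial_{condition}_emg.csv"
            _channel_frame(trial.emg).to_csv(path / name, index=False, float_format=FLOAT_FMT)
            manifest["files"][name] = {
                "sampling_rate_hz": trial.emg[0].sampling_rate_hz,
                "channels": [
                    {
                        "label": c.label,
                        "side": c.side,
                        "units": c.units,
                        "is_affected": c.is_affected,
                    }
                    for c in trial.emg
                ],
            }
        if trial.heel:
            name = f"trial_{condition}_heel.csv"
            heel_channels = [trial.heel[s] for s in sorted(trial.heel)]
            _channel_frame(heel_channels).to_csv(
                path / name, index=False, float_format=FLOAT_FMT
            )
            manifest["files"][name] = {
                "sampling_rate_hz": heel_channels[0].sampling_rate_hz,
                "channels": [
                    {"label": c.label, "side": c.side, "units": c.units} for c in heel_channels
                ],
            }
        if trial.kinematics:
            name = f"kin_{condition}.csv"
            _kin_frame(trial.kinematics).to_csv(path / name, index=False, float_format=FLOAT_FMT)
            manifest["files"][name] = {"kind": "kinematics"}

    if session.protocol is not None:
        manifest["protocol"] = dataclasses.asdict(session.protocol)

    with open(meta_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _read_channels(path: Path, decl: dict, expect_units: Optional[str] = None) -> list[SignalChannel]:
    df = pd.read_csv(path, float_precision="round_trip")
    declared = decl["channels"]
    if len(df.columns) != len(declared) + 1:
        raise SessionFormatError(
            f"{path.name}: {len(df.columns) - 1} channel columns but metadata declares "
            f"{len(declared)}"
        )
    rate = float(decl["sampling_rate_hz"])
    if rate <= 0:
        raise SessionFormatError(f"{path.name}: non-positive sampling rate {rate}")
    channels = []
    for spec in declared:
        label, side = spec["label"], spec.get("side")
        if spec.get("units", "V") == "V" and label not in MUSCLES:
            raise SessionFormatError(
                f"{path.name}: unknown muscle label {label!r}; allowed: {sorted(MUSCLES)}"
            )
        if side is not None and side not in SIDES:
            raise SessionFormatError(f"{path.name}: bad side {side!r}")
        col = f"{label}_{side}" if side else label
        if col not in df.columns:
            raise SessionFormatError(f"{path.name}: missing declared column {col!r}")
        channels.append(
            SignalChannel(
                values=df[col].to_numpy(),
                sampling_rate_hz=rate,
                label=label,
                side=side,
                units=spec.get("units", "V"),
                is_affected=spec.get("is_affected"),
            )
        )
    return channels


def read_session(path: str | Path) -> Session:
    """Load and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    meta_path = path / "session.json"
    if not meta_path.exists():
        raise SessionFormatError(f"no session.json manifest in {path}")
    with open(meta_path) as fh:
        manifest = json.load(fh)

    try:
        subject = SubjectSpec(
            **{
                **manifest["subject"],
                "muscles": tuple(manifest["subject"]["muscles"]),
                "missing_channels": tuple(
                    tuple(x) for x in manifest["subject"]["missing_channels"]
                ),
            }
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SessionFormatError(f"malformed subject metadata: {exc}") from exc

    resting: list[SignalChannel] = []
    if "resting.csv" in manifest.get("files", {}):
        resting = _read_channels(path / "resting.csv", manifest["files"]["resting.csv"])

    trials: dict[str, Trial] = {}
    for condition in manifest.get("conditions", []):
        emg_name = f"trial_{condition}_emg.csv"
        heel_name = f"trial_{condition}_heel.csv"
        kin_name = f"kin_{condition}.csv"
        emg = (
            _read_channels(path / emg_name, manifest["files"][emg_name])
            if emg_name in manifest["files"]
            else []
        )
        heel: dict[str, SignalChannel] = {}
        if heel_name in manifest["files"]:
            decl = manifest["files"][heel_name]
            df = pd.read_csv(path / heel_name, float_precision="round_trip")
            rate = float(decl["sampling_rate_hz"])
            for spec in decl["channels"]:
                col = f"{spec['label']}_{spec['side']}"
                if col not in df.columns:
                    raise SessionFormatError(f"{heel_name}: missing column {col!r}")
                heel[spec["side"]] = SignalChannel(
                    values=df[col].to_numpy(),
                    sampling_rate_hz=rate,
                    label=spec["label"],
                    side=spec["side"],
                    units=spec.get("units", "mm"),
                )
        kinematics: dict[tuple[str, str], np.ndarray] = {}
        if kin_name in manifest["files"]:
            kdf = pd.read_csv(path / kin_name, float_precision="round_trip")
            for (joint, side), grp in kdf.groupby(["joint", "side"], sort=True):
                curves = (
                    grp.pivot(index="cycle", columns="node_pct", values="angle_deg")
                    .sort_index()
                    .to_numpy()
                )
                kinematics[(joint, side)] = curves
        trials[condition] = Trial(emg=emg, heel=heel, kinematics=kinematics)

    protocol = None
    if "protocol" in manifest:
        protocol = ProtocolResult(**manifest["protocol"])
    return Session(subject=subject, trials=trials, resting=resting, protocol=protocol)


class OptionalDependencyError(ImportError):
    """An optional capability's dependency is not installed."""


def import_c3d(path: str | Path, mapping: dict) -> Trial:
    """Ingest a C3D motion file as a :class:`Trial` fragment.

    ``mapping`` names which analog channels are which muscles and which
    point label is the heel marker per side, e.g.::

        {"emg": {"Voltage.EMG1": ("TibA", "left")},
         "heel": {"left": "LHEE", "right": "RHEE"},
         "affected_side": "left"}

    Marker heights are converted to mm honouring the file's POINT:UNITS
    header.  Requires the optional ``ezc3d`` dependency.
    """
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - exercised via monkeypatch
        raise OptionalDependencyError(
            "C3D import requires the optional dependency 'ezc3d' "
            "(pip install gaitfatigue[c3d])"
        ) from exc

    c3d = ezc3d.c3d(str(path))
    analog_labels = [s.strip() for s in c3d["parameters"]["ANALOG"]["LABELS"]["value"]]
    analog_rate = float(c3d["parameters"]["ANALOG"]["RATE"]["value"][0])
    analogs = c3d["data"]["analogs"][0]  # (n_channels, n_samples)
    affected = mapping.get("affected_side")

    emg = []
    for source, (muscle, side) in mapping.get("emg", {}).items():
        if source not in analog_labels:
            raise KeyError(
                f"mapping references absent analog channel {source!r}; "
                f"available: {analog_labels}"
            )
        emg.append(
            SignalChannel(
                values=analogs[analog_labels.index(source)],
                sampling_rate_hz=analog_rate,
                label=muscle,
                side=side,
                units="V",
                is_affected=(side == affected) if affected else None,
            )
        )

    point_labels = [s.strip() for s in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    point_rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    units = c3d["parameters"]["POINT"]["UNITS"]["value"][0].strip().lower()
    to_mm = 1000.0 if units == "m" else 1.0
    points = c3d["data"]["points"]  # (4, n_points, n_frames)

    heel = {}
    for side, marker in mapping.get("heel", {}).items():
        if marker not in point_labels:
            raise KeyError(
                f"mapping references absent marker {marker!r}; available: {point_labels}"
            )
        z = points[2, point_labels.index(marker), :] * to_mm
        heel[side] = SignalChannel(
            values=z, sampling_rate_hz=point_rate, label="heel_z", side=side, units="mm"
        )
    return Trial(emg=emg, heel=heel)
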