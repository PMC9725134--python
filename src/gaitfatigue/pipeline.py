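"""End-to-end orchestration: sessions → features → models → report.

:class:`RunConfig` gathers every tunable with defaults equal to the
protocol's published analysis constants (10–250 Hz 4th-order band-pass,
101 ms RMS window, 101-node time normalization, threshold = resting
mean + 2 SD, SNR ≥ 5, α = 0.05, 1000 permutation iterations, >5%-of-
cycle cluster rule).  :func:`run_pipeline` is fully deterministic given
the config's seed and logs every exclusion.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .channels import CONDITIONS, SIDES
from .features import (
    N_NODES,
    RMS_WINDOW_MS,
    SNR_MIN,
    THRESHOLD_N_SD,
    extract_channel_features,
    resting_stats,
)
from .lme import LmeFit, condition_contrast, emm_table, fit_random_intercept, pairwise_bonferroni
from .preprocess import FilterSpec, audit_cycles, detect_heel_strikes, segment_cycles
from .session import Session
from .simulate import generate_cohort, simulate_session
from .snpm import (
    DEFAULT_ALPHA,
    DEFAULT_ITERATIONS,
    MIN_EXTENT_PCT,
    PairedWaveformSet,
    SnpmOutcome,
    snpm_paired_test,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline tunables; defaults are the published analysis constants."""

    seed: int = 0
    # synthetic cohort (used when no session directory is given)
    n_subjects: int = 6
    n_strides: int = 12
    sampling_rate_hz: float = 1000.0
    fatigue_spectral_scale: float = 0.85
    # preprocessing
    filter_low_hz: float = 10.0
    filter_high_hz: float = 250.0
    filter_order: int = 4
    prominence_frac: float = 0.25
    min_strike_interval_s: float = 0.4
    # features
    rms_window_ms: float = RMS_WINDOW_MS
    n_nodes: int = N_NODES
    threshold_n_sd: float = THRESHOLD_N_SD
    snr_min: float = SNR_MIN
    # models
    lme_formula: Optional[str] = None
    snpm_alpha: float = DEFAULT_ALPHA
    snpm_iterations: int = DEFAULT_ITERATIONS
    snpm_min_extent_pct: float = MIN_EXTENT_PCT
    # paths
    session_dirs: list = field(default_factory=list)
    outdir: str = "results"

    @property
    def filter_spec(self) -> FilterSpec:
        return FilterSpec(
            low_hz=self.filter_low_hz, high_hz=self.filter_high_hz, order=self.filter_order
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def self_test(self) -> None:
        """Assert the analysis defaults match the published constants."""
        defaults = RunConfig()
        expect = {
            "filter_low_hz": 10.0, "filter_high_hz": 250.0, "filter_order": 4,
            "rms_window_ms": 101.0, "n_nodes": 101, "threshold_n_sd": 2.0,
            "snr_min": 5.0, "snpm_alpha": 0.05, "snpm_iterations": 1000,
            "snpm_min_extent_pct": 5.0,
        }
        for key, value in expect.items():
            actual = getattr(defaults, key)
            if actual != value:
                raise AssertionError(f"default {key}={actual} differs from published {value}")


@dataclass
class SessionFeatures:
    """Per-session feature extraction output plus bookkeeping."""

    frame: pd.DataFrame
    audits: pd.DataFrame
    n_channels_in: int
    n_included: int
    n_excluded: int


def extract_session_features(session: Session, config: RunConfig = RunConfig()) -> SessionFeatures:
    """Features for every EMG channel of every condition of one session.

    Heel strikes are detected per side at the marker rate and mapped into
    EMG sample indices via time.  Exclusions (invalid cycles, SNR gate)
    are logged and counted; nothing is dropped silently.
    """
    fspec = config.filter_spec
    rest_cache: dict[tuple[str, str], object] = {}
    rows, audit_rows = [], []
    n_in = n_inc = n_exc = 0

    for condition, trial in session.trials.items():
        strikes_s: dict[str, np.ndarray] = {}
        for side, heel in trial.heel.items():
            idx = detect_heel_strikes(
                heel,
                prominence_frac=config.prominence_frac,
                min_interval_s=config.min_strike_interval_s,
            )
            strikes_s[side] = idx / heel.sampling_rate_hz

        for emg in trial.emg:
            n_in += 1
            side = emg.side or "left"
            if side not in strikes_s:
                logger.warning("channel %s: no heel trajectory for side %s", emg.key, side)
                n_exc += 1
                continue
            emg_strikes = np.round(strikes_s[side] * emg.sampling_rate_hz).astype(int)
            emg_strikes = emg_strikes[emg_strikes < emg.n_samples]
            cycle_set = segment_cycles(emg_strikes, emg.sampling_rate_hz)
            audit = audit_cycles(cycle_set)
            audit_rows.append(
                {
                    "subject": session.subject.subject_id,
                    "condition": condition,
                    "channel": emg.key,
                    "n_cycles": audit.n_cycles,
                    "n_valid": audit.n_valid,
                    "n_invalid": audit.n_invalid,
                }
            )
            rest_ch = session.resting_for(emg.label, side)
            rest = None
            if rest_ch is not None:
                key = (emg.label, side)
                if key not in rest_cache:
                    rest_cache[key] = resting_stats(rest_ch, fspec, config.rms_window_ms)
                rest = rest_cache[key]
            feat = extract_channel_features(
                emg, cycle_set, rest, condition,
                filter_spec=fspec, window_ms=config.rms_window_ms, snr_min=config.snr_min,
            )
            n_inc += int(feat.included)
            n_exc += int(not feat.included)
            rows.append(
                {
                    "subject": session.subject.subject_id,
                    "muscle": feat.muscle,
                    "leg": "affected" if feat.is_affected else "unaffected",
                    "condition": condition,
                    "mf_hz": feat.mf_hz,
                    "rms_v": feat.rms_v,
                    "snr": feat.snr,
                    "n_cycles": feat.n_cycles,
                    "included": feat.included,
                }
            )
    return SessionFeatures(
        frame=pd.DataFrame(rows),
        audits=pd.DataFrame(audit_rows),
        n_channels_in=n_in,
        n_included=n_inc,
        n_excluded=n_exc,
    )


@dataclass
class PipelineResults:
    """Everything :func:`run_pipeline` produces."""

    features: pd.DataFrame
    audits: pd.DataFrame
    mf_fit: Optional[LmeFit]
    rms_fit: Optional[LmeFit]
    mf_emm: Optional[pd.DataFrame]
    rms_emm: Optional[pd.DataFrame]
    mf_condition: Optional[dict]
    mf_pairwise_by_muscle: Optional[pd.DataFrame]
    snpm: dict[tuple[str, str], SnpmOutcome]
    kin_mean_curves: dict[tuple[str, str, str], np.ndarray]
    config: RunConfig


def _sessions_for(config: RunConfig) -> list[Session]:
    if config.session_dirs:
        from .session import read_session

        return [read_session(p) for p in config.session_dirs]
    cohort = generate_cohort(n_subjects=config.n_subjects, seed=config.seed)
    seq = np.random.SeedSequence(config.seed)
    return [
        simulate_session(
            subj,
            n_strides=config.n_strides,
            sampling_rate_hz=config.sampling_rate_hz,
            fatigue_spectral_scale=config.fatigue_spectral_scale,
            seed=int(s.generate_state(1)[0] % 2**31),
        )
        for subj, s in zip(cohort.subjects, seq.spawn(len(cohort.subjects)))
    ]


def run_pipeline(config: RunConfig = RunConfig()) -> PipelineResults:
    """Run the full analysis: features → mixed models → waveform tests."""
    config.self_test()
    sessions = _sessions_for(config)
    logger.info("pipeline: %d sessions", len(sessions))

    parts = [extract_session_features(s, config) for s in sessions]
    features = pd.concat([p.frame for p in parts], ignore_index=True)
    audits = pd.concat([p.audits for p in parts], ignore_index=True)
    n_in = sum(p.n_channels_in for p in parts)
    n_acc = sum(p.n_included for p in parts)
    logger.info("channels: %d in, %d included, %d excluded", n_in, n_acc, n_in - n_acc)

    included = features[features["included"]]
    mf_fit = rms_fit = None
    mf_emm = rms_emm = None
    mf_cond = None
    mf_pair = None
    if included["subject"].nunique() >= 2:
        n_per_muscle = included[included["condition"] == "comfortable"].groupby("muscle")[
            "subject"
        ].count() * 2
        mf_fit = fit_random_intercept(included, "mf_hz", config.lme_formula)
        mf_emm = emm_table(mf_fit, n_per_muscle)
        mf_cond = condition_contrast(mf_fit)
        mf_pair = pairwise_bonferroni(mf_fit, by="muscle")
        if np.isfinite(included["rms_v"]).all():
            rms_fit = fit_random_intercept(included, "rms_v", config.lme_formula)
            rms_emm = emm_table(rms_fit, n_per_muscle)

    # kinematics: subject-mean curves per joint x side, then paired tests
    snpm_results: dict[tuple[str, str], SnpmOutcome] = {}
    mean_curves: dict[tuple[str, str, str], np.ndarray] = {}
    joints_sides = sorted(
        {key for s in sessions for t in s.trials.values() for key in t.kinematics}
    )
    rng_seq = np.random.SeedSequence(entropy=config.seed, spawn_key=(99,))
    seeds = iter(rng_seq.spawn(len(joints_sides)))
    for joint, side in joints_sides:
        per_cond: dict[str, list[np.ndarray]] = {c: [] for c in CONDITIONS}
        for sess in sessions:
            for condition in CONDITIONS:
                trial = sess.trials.get(condition)
                if trial and (joint, side) in trial.kinematics:
                    per_cond[condition].append(
                        np.mean(trial.kinematics[(joint, side)], axis=0)
                    )
        if any(len(v) < 2 for v in per_cond.values()):
            continue
        a = np.vstack(per_cond["comfortable"])
        b = np.vstack(per_cond["fatigued"])
        for condition, mat in (("comfortable", a), ("fatigued", b)):
            mean_curves[(joint, side, condition)] = mat
        waveforms = PairedWaveformSet(curves_a=a, curves_b=b)
        seed = int(next(seeds).generate_state(1)[0] % 2**31)
        snpm_results[(joint, side)] = snpm_paired_test(
            waveforms, alpha=config.snpm_alpha, n_iter=config.snpm_iterations, seed=seed
        )

    return PipelineResults(
        features=features,
        audits=audits,
        mf_fit=mf_fit,
        rms_fit=rms_fit,
        mf_emm=mf_emm,
        rms_emm=rms_emm,
        mf_condition=mf_cond,
        mf_pairwise_by_muscle=mf_pair,
        snpm=snpm_results,
        kin_mean_curves=mean_curves,
        config=config,
    )


def make_report(results: PipelineResults, outdir: str | Path) -> list[Path]:
    """Write delimited result tables and vector figures; returns the paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(df: Optional[pd.DataFrame], name: str) -> None:
        if df is None:
            logger.warning("report: section %s missing, skipped", name)
            return
        p = outdir / name
        df.to_csv(p, index=False)
        written.append(p)

    _write(results.features, "features.csv")
    _write(results.audits, "cycle_audit.csv")
    _write(results.mf_emm, "mf_emm.csv")
    _write(results.rms_emm, "rms_emm.csv")
    _write(results.mf_pairwise_by_muscle, "mf_pairwise_by_muscle.csv")
    if results.mf_condition is not None:
        _write(pd.DataFrame([results.mf_condition]), "mf_condition_contrast.csv")

    cluster_rows = []
    for (joint, side), outcome in results.snpm.items():
        for c in outcome.clusters:
            cluster_rows.append(
                {
                    "joint": joint, "side": side, "start_pct": c.start_pct,
                    "end_pct": c.end_pct, "extent_pct": c.extent_pct,
                    "p": c.p, "considered": c.considered,
                    "critical_t": outcome.critical_t,
                }
            )
    _write(pd.DataFrame(cluster_rows,
                        columns=["joint", "side", "start_pct", "end_pct",
                                 "extent_pct", "p", "considered", "critical_t"]),
           "snpm_clusters.csv")

    # change-per-muscle dot plot (MF and, when present, RMS)
    feats = results.features[results.features["included"]]
    for metric, panel in (("mf_hz", "A"), ("rms_v", "B")):
        wide = feats.pivot_table(
            index=["subject", "muscle", "leg"], columns="condition", values=metric
        ).dropna()
        if wide.empty or not {"comfortable", "fatigued"} <= set(wide.columns):
            logger.warning("report: no paired %s data; panel %s skipped", metric, panel)
            continue
        change = (wide["fatigued"] - wide["comfortable"]).rename("change").reset_index()
        fig, ax = plt.subplots(figsize=(5, 4))
        muscles = sorted(change["muscle"].unique())
        for i, muscle in enumerate(muscles):
            vals = change.loc[change["muscle"] == muscle, "change"]
            ax.plot(vals, np.full(len(vals), i), "o", color="0.6", ms=4)
            mean = vals.mean()
            ax.plot(mean, i, "ks", ms=6)
            if len(vals) > 1:
                half = 1.96 * vals.std(ddof=1) / np.sqrt(len(vals))
                ax.plot([mean - half, mean + half], [i, i], "k-", lw=1.5)
        ax.axvline(0, color="k", lw=0.5)
        ax.set_yticks(range(len(muscles)), muscles)
        ax.set_xlabel(f"change in {metric} (fatigued - comfortable)")
        fig.tight_layout()
        p = outdir / f"change_{metric}.svg"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)

    # mean +/- SD kinematic curves per condition
    if results.kin_mean_curves:
        keys = sorted({(j, s) for (j, s, _) in results.kin_mean_curves})
        fig, axes = plt.subplots(len(keys), 1, figsize=(5, 2.2 * len(keys)), squeeze=False)
        x = np.linspace(0, 100, 101)
        for ax, (joint, side) in zip(axes.ravel(), keys):
            for condition, color in (("comfortable", "k"), ("fatigued", "0.6")):
                mat = results.kin_mean_curves.get((joint, side, condition))
                if mat is None:
                    continue
                mean, sd = mat.mean(axis=0), mat.std(axis=0, ddof=1)
                ax.plot(x, mean, color=color, label=condition)
                ax.fill_between(x, mean - sd, mean + sd, color=color, alpha=0.2)
            ax.set_ylabel(f"{joint} {side} (deg)")
        axes.ravel()[0].legend(fontsize=8)
        axes.ravel()[-1].set_xlabel("% gait cycle")
        fig.tight_layout()
        p = outdir / "kinematics.svg"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)
    return written
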