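"""Random-intercept linear mixed-effects models for the fatigue features.

The MF (Hz) and RMS (V) feature tables are modelled with condition
(comfortable / fatigued), leg (affected / unaffected) and muscle as fixed
factors — by default including the muscle x condition and leg x condition
interactions — and a random intercept per subject, fitted by REML.
Estimated marginal means (EMMs) average the model's cell predictions
over the other factors' levels with equal weights, regardless of cell
counts; pairwise contrasts are Wald t tests on the fixed-effect
covariance with Bonferroni adjustment.

Missing cells (e.g. AFO-occluded channels) are handled by the unbalanced
mixed model via row-wise deletion.  Denominator degrees of freedom are
residual df (nobs − rank); small-sample Satterthwaite-type corrections
are deliberately not attempted.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrix
from scipy import stats

logger = logging.getLogger(__name__)

FACTORS = ("condition", "muscle", "leg")


class RankDeficiencyError(ValueError):
    """The fixed-effects design matrix is not full rank."""


@dataclass
class LmeFit:
    """A fitted random-intercept model plus the pieces contrasts need."""

    result: "sm.regression.mixed_linear_model.MixedLMResults"
    formula: str
    response: str
    data: pd.DataFrame

    @property
    def k_fe(self) -> int:
        return self.result.model.k_fe

    @property
    def fixed_effects(self) -> pd.Series:
        return self.result.fe_params

    @property
    def cov_fixed(self) -> np.ndarray:
        return np.asarray(self.result.cov_params().iloc[: self.k_fe, : self.k_fe])

    @property
    def sigma2_subject(self) -> float:
        """Between-subject (random intercept) variance component."""
        return float(self.result.cov_re.iloc[0, 0])

    @property
    def sigma2_residual(self) -> float:
        return float(self.result.scale)

    @property
    def residual_df(self) -> float:
        return float(self.result.model.nobs - self.k_fe)

    @property
    def converged(self) -> bool:
        return bool(self.result.converged)

    def design_rows(self, grid: pd.DataFrame) -> np.ndarray:
        info = self.result.model.data.design_info
        return np.asarray(dmatrix(info, grid, return_type="matrix"))


def _default_formula(frame: pd.DataFrame, response: str) -> str:
    """Condition always enters; other factors and their condition
    interactions only when they have >= 2 observed levels."""
    terms = ["C(condition)"]
    for factor in ("muscle", "leg"):
        if frame[factor].nunique() > 1:
            terms += [f"C({factor})", f"C(condition):C({factor})"]
    return f"{response} ~ " + " + ".join(terms)


def _validate_frame(frame: pd.DataFrame, response: str) -> pd.DataFrame:
    required = {"subject", *FACTORS, response}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"feature frame lacks columns: {sorted(missing)}")
    dup = frame.duplicated(subset=["subject", "muscle", "leg", "condition"])
    if dup.any():
        raise ValueError(
            f"multiple rows for the same subject x muscle x leg x condition "
            f"({int(dup.sum())} duplicates)"
        )
    n_bad = int((~np.isfinite(frame[response])).sum())
    if n_bad:
        logger.info("dropping %d rows with missing %s", n_bad, response)
    out = frame[np.isfinite(frame[response])].copy()
    if out["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    return out


def fit_random_intercept(
    frame: pd.DataFrame,
    response: str = "mf_hz",
    formula: Optional[str] = None,
) -> LmeFit:
    """Fit the random-intercept model by REML.

    Raises :class:`RankDeficiencyError` when fixed-effect columns are
    aliased, and ``RuntimeError`` on non-convergence.
    """
    frame = _validate_frame(frame, response)
    formula = formula or _default_formula(frame, response)

    model = sm.MixedLM.from_formula(formula, groups="subject", data=frame)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # name the aliased columns: those whose removal restores full rank
        names = model.exog_names
        aliased = []
        for j in range(exog.shape[1]):
            sub = np.delete(exog, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                aliased.append(names[j])
        raise RankDeficiencyError(
            f"fixed-effects design is rank deficient (rank {rank} < {exog.shape[1]}); "
            f"aliased terms: {aliased}"
        )

    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "powell", "cg"):
            try:
                candidate = model.fit(reml=True, method=method)
            except np.linalg.LinAlgError:
                continue
            if candidate.converged:
                result = candidate
                break
            result = result or candidate
    if result is None or not result.converged:
        raise RuntimeError(
            f"REML estimation did not converge for {formula!r}"
        )
    return LmeFit(result=result, formula=formula, response=response, data=frame)


def _level_grid(fit: LmeFit) -> pd.DataFrame:
    levels = {f: sorted(fit.data[f].unique()) for f in FACTORS}
    rows = [
        dict(zip(FACTORS, combo))
        for combo in itertools.product(*(levels[f] for f in FACTORS))
    ]
    return pd.DataFrame(rows)


def _emm_row(fit: LmeFit, grid: pd.DataFrame) -> np.ndarray:
    """Equal-weight average of design rows over the grid."""
    X = fit.design_rows(grid)
    return X.mean(axis=0)


def estimate_contrast(
    fit: LmeFit, L: np.ndarray, df: Optional[float] = None
) -> tuple[float, float, float, float]:
    """Wald t test of a single fixed-effect contrast.

    Returns (estimate, se, t, p).  ``df`` defaults to the residual df.
    """
    beta = np.asarray(fit.fixed_effects)
    est = float(L @ beta)
    se = float(np.sqrt(L @ fit.cov_fixed @ L))
    df = fit.residual_df if df is None else df
    t = est / se
    p = 2 * stats.t.sf(abs(t), df)
    return est, se, t, float(p)


def marginal_means(
    fit: LmeFit,
    by: Sequence[str] = ("muscle", "condition"),
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Estimated marginal means over a factor grid.

    Model predictions are averaged over the levels of every factor not in
    ``by`` with equal weights; standard errors and CIs come from the
    fixed-effect covariance with residual df.  Cells with no observed
    data are flagged ``extrapolated``.
    """
    full = _level_grid(fit)
    observed = set(map(tuple, fit.data[list(FACTORS)].itertuples(index=False)))
    tcrit = stats.t.ppf(0.5 + conf_level / 2, fit.residual_df)
    rows = []
    cells = full[list(by)].drop_duplicates().reset_index(drop=True)
    for _, cell in cells.iterrows():
        sub = full
        for f in by:
            sub = sub[sub[f] == cell[f]]
        L = _emm_row(fit, sub)
        est, se, _, _ = estimate_contrast(fit, L)
        n_cell = int(
            sum(tuple(r) in observed for r in sub[list(FACTORS)].itertuples(index=False))
        )
        rows.append(
            {
                **{f: cell[f] for f in by},
                "mean": est,
                "se": se,
                "df": fit.residual_df,
                "ci_lower": est - tcrit * se,
                "ci_upper": est + tcrit * se,
                "extrapolated": n_cell == 0,
            }
        )
    out = pd.DataFrame(rows)
    if out["extrapolated"].any():
        logger.warning("EMMs include cells with no observed data (extrapolated)")
    return out


def condition_contrast(
    fit: LmeFit, df: Optional[float] = None, conf_level: float = 0.95
) -> dict:
    """Overall fatigued − comfortable effect, averaged over muscle and leg."""
    full = _level_grid(fit)
    L_fat = _emm_row(fit, full[full["condition"] == "fatigued"])
    L_com = _emm_row(fit, full[full["condition"] == "comfortable"])
    est, se, t, p = estimate_contrast(fit, L_fat - L_com, df=df)
    use_df = fit.residual_df if df is None else df
    tcrit = stats.t.ppf(0.5 + conf_level / 2, use_df)
    return {
        "contrast": "fatigued - comfortable",
        "estimate": est,
        "se": se,
        "t": t,
        "df": use_df,
        "p_raw": p,
        "ci_lower": est - tcrit * se,
        "ci_upper": est + tcrit * se,
    }


def pairwise_bonferroni(
    fit: LmeFit,
    by: Optional[str] = None,
    m: Optional[int] = None,
    df: Optional[float] = None,
) -> pd.DataFrame:
    """Fatigued − comfortable contrasts with Bonferroni adjustment.

    With ``by=None`` the family is the single overall condition contrast;
    with ``by="muscle"`` (or ``"leg"``) one contrast per level of that
    factor.  Adjusted p = min(1, m * p_raw) with ``m`` the family size
    (overridable).
    """
    full = _level_grid(fit)
    if by is None:
        families = [("overall", full)]
    else:
        levels = sorted(fit.data[by].unique())
        if not levels:
            raise ValueError(f"empty contrast family: no levels of {by!r}")
        families = [(lvl, full[full[by] == lvl]) for lvl in levels]
    if not families:
        raise ValueError("empty contrast family")
    m = len(families) if m is None else m

    rows = []
    for label, sub in families:
        L = _emm_row(fit, sub[sub["condition"] == "fatigued"]) - _emm_row(
            fit, sub[sub["condition"] == "comfortable"]
        )
        est, se, t, p = estimate_contrast(fit, L, df=df)
        rows.append(
            {
                "level": label,
                "contrast": "fatigued - comfortable",
                "estimate": est,
                "se": se,
                "t": t,
                "df": fit.residual_df if df is None else df,
                "p_raw": p,
                "p_adj": min(1.0, m * p),
                "significant": min(1.0, m * p) < 0.05,
            }
        )
    return pd.DataFrame(rows)


def emm_table(fit: LmeFit, n_per_muscle: Optional[pd.Series] = None) -> pd.DataFrame:
    """Report-shaped EMM table: muscle, N, condition, mean, SE, CI bounds."""
    emm = marginal_means(fit, by=("muscle", "condition"))
    emm = emm.rename(
        columns={"mean": "mean", "se": "std_error", "ci_lower": "ci_lower", "ci_upper": "ci_upper"}
    )
    if n_per_muscle is not None:
        emm.insert(1, "N", emm["muscle"].map(n_per_muscle).astype("Int64"))
    order = {m: i for i, m in enumerate(
        ("RecF", "VasL", "SemT", "BicF", "GasM", "Sole", "TibA", "PerL"))}
    emm = emm.sort_values(
        by=["muscle", "condition"],
        key=lambda s: s.map(order) if s.name == "muscle" else s,
        kind="stable",
    ).reset_index(drop=True)
    return emm
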