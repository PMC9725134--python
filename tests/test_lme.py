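"""Random-intercept mixed model: oracles, marginal means, Bonferroni."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gaitfatigue as gf
from gaitfatigue.lme import (
    RankDeficiencyError,
    condition_contrast,
    emm_table,
    fit_random_intercept,
    marginal_means,
    pairwise_bonferroni,
)


def _paired_frame(n=12, effect=-8.0, sigma_u=5.0, sigma_e=3.0, seed=0):
    """One muscle, one leg, two conditions: the balanced paired design."""
    rng = np.random.default_rng(seed)
    u = rng.normal(0, sigma_u, n)
    rows = []
    for i in range(n):
        for cond, shift in (("comfortable", 0.0), ("fatigued", effect)):
            rows.append(
                {
                    "subject": f"S{i:02d}",
                    "muscle": "TibA",
                    "leg": "affected",
                    "condition": cond,
                    "mf_hz": 80.0 + u[i] + shift + rng.normal(0, sigma_e),
                }
            )
    return pd.DataFrame(rows)


class TestPairedOracle:
    def test_estimate_equals_paired_mean_difference(self):
        df = _paired_frame()
        fit = fit_random_intercept(df, "mf_hz")
        wide = df.pivot(index="subject", columns="condition", values="mf_hz")
        d = wide["fatigued"] - wide["comfortable"]
        cc = condition_contrast(fit)
        assert cc["estimate"] == pytest.approx(d.mean(), abs=1e-8)

    def test_statistic_and_p_match_paired_t(self):
        df = _paired_frame(seed=1)
        n = df["subject"].nunique()
        fit = fit_random_intercept(df, "mf_hz")
        wide = df.pivot(index="subject", columns="condition", values="mf_hz")
        oracle = stats.ttest_rel(wide["fatigued"], wide["comfortable"])
        cc = condition_contrast(fit, df=n - 1)
        assert cc["t"] == pytest.approx(oracle.statistic, rel=1e-4)
        assert cc["p_raw"] == pytest.approx(oracle.pvalue, rel=1e-3)


class TestOlsOracle:
    def test_zero_subject_variance_matches_ols(self):
        """With sigma_u = 0 the mixed model collapses onto OLS."""
        import statsmodels.formula.api as smf

        cohort = gf.generate_cohort(
            n_subjects=10, effect_mf_hz=-10.0, subject_sd_hz=0.0,
            residual_sd_hz=5.0, with_missing_channels=False, seed=2,
        )
        frame = gf.sample_feature_frame(cohort, seed=0)
        fit = fit_random_intercept(frame, "mf_hz")
        ols = smf.ols(fit.formula, data=frame).fit()
        assert fit.sigma2_subject < 1.0
        assert np.allclose(fit.fixed_effects, ols.params, atol=1e-4)


class TestRecovery:
    def test_condition_effect_recovered_within_ci(self):
        cohort = gf.generate_cohort(n_subjects=18, effect_mf_hz=-10.4, seed=3)
        covered = 0
        for rep in range(20):
            frame = gf.sample_feature_frame(cohort, seed=rep)
            fit = fit_random_intercept(frame, "mf_hz")
            cc = condition_contrast(fit)
            covered += cc["ci_lower"] <= -10.4 <= cc["ci_upper"]
        # quick screen at 20 replicates (binomial floor for nominal 95%
        # coverage); the 100-replicate check runs in the acceptance suite
        assert covered >= 15

    def test_variance_components_nonnegative(self):
        frame = gf.sample_feature_frame(gf.generate_cohort(n_subjects=8, seed=4), seed=0)
        fit = fit_random_intercept(frame, "mf_hz")
        assert fit.sigma2_subject >= 0 and fit.sigma2_residual > 0

    def test_row_order_invariance(self):
        frame = gf.sample_feature_frame(gf.generate_cohort(n_subjects=6, seed=5), seed=0)
        shuffled = frame.sample(frac=1.0, random_state=0).reset_index(drop=True)
        f1 = fit_random_intercept(frame, "mf_hz")
        f2 = fit_random_intercept(shuffled, "mf_hz")
        assert np.allclose(f1.fixed_effects, f2.fixed_effects, atol=1e-5)


class TestMarginalMeans:
    def test_intercept_only_equals_grand_mean(self):
        frame = gf.sample_feature_frame(gf.generate_cohort(n_subjects=6, seed=6), seed=0)
        fit = fit_random_intercept(frame, "mf_hz", formula="mf_hz ~ 1")
        emm = marginal_means(fit, by=("condition",))
        grand = fit.fixed_effects.iloc[0]
        assert np.allclose(emm["mean"], grand)

    def test_additive_model_gives_constant_condition_gap(self):
        frame = gf.sample_feature_frame(gf.generate_cohort(n_subjects=8, seed=7), seed=0)
        fit = fit_random_intercept(
            frame, "mf_hz", formula="mf_hz ~ C(condition) + C(muscle) + C(leg)"
        )
        emm = marginal_means(fit, by=("muscle", "condition"))
        wide = emm.pivot(index="muscle", columns="condition", values="mean")
        gaps = wide["fatigued"] - wide["comfortable"]
        assert np.allclose(gaps, gaps.iloc[0], atol=1e-8)

    def test_constructed_cell_means_recovered(self):
        """Cells built to 84.5 / 70.0 Hz come back from the EMMs."""
        rng = np.random.default_rng(8)
        rows = []
        for i in range(30):
            u = rng.normal(0, 2.0)
            for cond, mean in (("comfortable", 84.5), ("fatigued", 70.0)):
                rows.append(
                    {"subject": f"S{i}", "muscle": "TibA", "leg": "unaffected",
                     "condition": cond, "mf_hz": mean + u + rng.normal(0, 1.0)}
                )
        fit = fit_random_intercept(pd.DataFrame(rows), "mf_hz")
        emm = marginal_means(fit, by=("muscle", "condition")).set_index("condition")
        assert emm.loc["comfortable", "mean"] == pytest.approx(84.5, abs=1.0)
        assert emm.loc["fatigued", "mean"] == pytest.approx(70.0, abs=1.0)

    def test_emm_table_shape(self):
        frame = gf.sample_feature_frame(gf.generate_cohort(n_subjects=6, seed=9), seed=0)
        fit = fit_random_intercept(frame, "mf_hz")
        table = emm_table(fit)
        assert len(table) == 16  # 8 muscles x 2 conditions
        assert (table["ci_lower"] <= table["ci_upper"]).all()


@pytest.fixture(scope="module")
def fit():
    frame = gf.sample_feature_frame(gf.generate_cohort(n_subjects=8, seed=10), seed=0)
    return fit_random_intercept(frame, "mf_hz")


class TestBonferroni:
    def test_single_contrast_unadjusted(self, fit):
        row = pairwise_bonferroni(fit).iloc[0]
        assert row["p_adj"] == pytest.approx(row["p_raw"])

    def test_adjustment_multiplies_and_caps(self, fit):
        table = pairwise_bonferroni(fit, by="muscle")
        m = len(table)
        assert m == 8
        assert np.allclose(table["p_adj"], np.minimum(1.0, m * table["p_raw"]))

    def test_explicit_family_size(self, fit):
        table = pairwise_bonferroni(fit, by="muscle", m=16)
        assert np.allclose(table["p_adj"], np.minimum(1.0, 16 * table["p_raw"]))


class TestValidation:
    def test_duplicate_cells_rejected(self):
        df = _paired_frame()
        dup = pd.concat([df, df.iloc[:1]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            fit_random_intercept(dup, "mf_hz")

    def test_rank_deficiency_names_aliased_terms(self):
        # leg perfectly confounded with condition
        df = _paired_frame()
        df.loc[df["condition"] == "fatigued", "leg"] = "unaffected"
        with pytest.raises(RankDeficiencyError, match="aliased"):
            fit_random_intercept(df, "mf_hz")

    def test_missing_rows_dropped_not_fatal(self):
        frame = gf.sample_feature_frame(gf.generate_cohort(n_subjects=6, seed=11), seed=0)
        frame.loc[frame.index[:5], "mf_hz"] = np.nan
        fit = fit_random_intercept(frame, "mf_hz")
        assert fit.result.model.nobs == len(frame) - 5

    def test_single_subject_rejected(self):
        df = _paired_frame(n=1)
        with pytest.raises(ValueError, match="subject"):
            fit_random_intercept(df, "mf_hz")
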