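"""Compositional regression: fits, LS means, changes, interaction, bootstrap."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.multivariate.manova import MANOVA

from timeuse_coda import (
    bootstrap_cis,
    compositional_mean,
    fit,
    ilr,
    interaction_test,
    ls_means,
    make_pivot_basis,
    random_basis,
    wave_difference,
)
from timeuse_coda.coda_core import PART_COLUMNS
from timeuse_coda.errors import BootstrapError, EstimationError, UsageError
from timeuse_coda.regression import build_design, factor_levels
from tests.conftest import two_factor_config


def wave_frame(df, wave):
    out = df[df["wave"] == wave].copy()
    out["final_weight"] = out["weight"]
    return out


class TestFit:
    def test_intercept_only_equals_compositional_mean(self, small_survey):
        df, _, _ = small_survey
        sub = wave_frame(df, 2009)
        model = fit(sub, predictors=())
        from timeuse_coda import ilr_inverse

        np.testing.assert_allclose(
            ilr_inverse(model.coef[0], model.basis),
            compositional_mean(sub[list(PART_COLUMNS)].to_numpy(), sub["final_weight"].to_numpy()),
            rtol=1e-10,
        )

    def test_matches_statsmodels_wls(self, small_survey):
        df, _, _ = small_survey
        sub = wave_frame(df, 2015)
        model = fit(sub, predictors=("sex", "education"))
        levels = factor_levels(sub, ("sex", "education"))
        x, names = build_design(sub, levels)
        y = ilr(sub[list(PART_COLUMNS)].to_numpy())
        for j in range(2):
            ref = sm.WLS(y[:, j], x, weights=sub["final_weight"].to_numpy()).fit()
            np.testing.assert_allclose(model.coef[:, j], ref.params, atol=1e-10)

    def test_weight_halving_invariance(self, small_survey):
        df, _, _ = small_survey
        sub = wave_frame(df, 2009)
        doubled = pd.concat([sub, sub], ignore_index=True)
        doubled["final_weight"] = doubled["final_weight"] / 2.0
        a = fit(sub, predictors=("sex", "education"))
        b = fit(doubled, predictors=("sex", "education"))
        np.testing.assert_allclose(a.coef, b.coef, atol=1e-10)

    def test_rank_deficient_design_names_columns(self, small_survey):
        df, _, _ = small_survey
        sub = wave_frame(df, 2009).copy()
        sub["sex_copy"] = sub["sex"]
        with pytest.raises(EstimationError, match="sex_copy"):
            fit(sub, predictors=("sex", "sex_copy"))

    def test_single_level_predictor_rejected(self, small_survey):
        df, _, _ = small_survey
        sub = wave_frame(df, 2009)
        sub = sub[sub["sex"] == "female"]
        with pytest.raises(EstimationError, match="sex"):
            fit(sub, predictors=("sex",))


class TestLsMeans:
    def test_one_factor_equals_subgroup_means(self, small_survey):
        """With a single factor the LS mean per level is that level's
        weighted compositional mean (the direct-subgroup oracle)."""
        df, _, _ = small_survey
        sub = wave_frame(df, 2009)
        model = fit(sub, predictors=("education",))
        table = ls_means(model, "education")
        for _, row in table.iterrows():
            grp = sub[sub["education"] == row["category"]]
            oracle = compositional_mean(
                grp[list(PART_COLUMNS)].to_numpy(), grp["final_weight"].to_numpy()
            )
            np.testing.assert_allclose(
                row[list(PART_COLUMNS)].to_numpy(dtype=float), oracle, atol=1e-9
            )

    def test_basis_invariance(self, small_survey, rng):
        df, _, _ = small_survey
        sub = wave_frame(df, 2015)
        bases = [make_pivot_basis(("sleep", "sb", "pa"))] + [random_basis(rng) for _ in range(2)]
        ref = fit(sub, predictors=("sex", "education"))
        t_ref = ls_means(ref, "sex")[list(PART_COLUMNS)].to_numpy(dtype=float)
        for b in bases:
            t = ls_means(fit(sub, predictors=("sex", "education"), basis=b), "sex")
            np.testing.assert_allclose(t[list(PART_COLUMNS)].to_numpy(dtype=float), t_ref, atol=1e-9)

    def test_observed_margins_average_to_common_constant(self, small_survey):
        """Share-weighted averages of observed-margin LS means agree across
        variables (they all equal the model's marginal prediction)."""
        df, _, _ = small_survey
        model = fit(wave_frame(df, 2009), predictors=("sex", "education"))
        consts = []
        for var in ("sex", "education"):
            z = np.array(
                [model.ls_mean_ilr(var, c, margins="observed") for c in model.levels[var]]
            )
            consts.append(model.level_shares[var] @ z)
        np.testing.assert_allclose(consts[0], consts[1], atol=1e-10)

    def test_margin_conventions_differ_when_unbalanced(self, small_survey):
        df, _, _ = small_survey
        model = fit(wave_frame(df, 2009), predictors=("sex", "education"))
        eq = model.ls_mean_composition("sex", "male", margins="equal")
        obs = model.ls_mean_composition("sex", "male", margins="observed")
        assert not np.allclose(eq, obs, atol=1e-6)

    def test_rows_sum_to_24(self, small_survey):
        df, _, _ = small_survey
        model = fit(wave_frame(df, 2009), predictors=("sex", "education"))
        table = ls_means(model, "education")
        np.testing.assert_allclose(table[list(PART_COLUMNS)].sum(axis=1), 24.0, atol=1e-9)

    def test_unknown_variable_and_category(self, small_survey):
        df, _, _ = small_survey
        model = fit(wave_frame(df, 2009), predictors=("sex",))
        with pytest.raises(UsageError):
            ls_means(model, "region")
        with pytest.raises(UsageError):
            model.ls_mean_composition("sex", "other")


class TestWaveDifference:
    def test_printed_style_contrast(self):
        d = wave_difference(
            np.array([9.50, 5.30, 9.20]), np.array([8.60, 5.96, 9.44])
        )
        assert d[1] == pytest.approx(0.66 * 60.0)
        assert d.sum() == pytest.approx(0.0, abs=1e-9)

    def test_identical_compositions(self):
        c = np.array([8.0, 8.0, 8.0])
        np.testing.assert_allclose(wave_difference(c, c), 0.0)

    def test_unclosed_input_rejected(self):
        with pytest.raises(UsageError):
            wave_difference(np.array([9.0, 5.0, 9.0]), np.array([8.6, 5.96, 9.44]))


class TestInteraction:
    @pytest.fixture
    def pooled(self):
        from timeuse_coda import generate_person_days

        df, _ = generate_person_days(two_factor_config(n=500, weight_sigma=0.0), seed=3)
        df["final_weight"] = 1.0
        return df

    def test_matches_statsmodels_manova(self, pooled):
        """Nested-model Pillai test == MANOVA term test on unweighted data."""
        mine = interaction_test(pooled, "sex", predictors=("sex", "education"))
        z = ilr(pooled[list(PART_COLUMNS)].to_numpy())
        d = pooled.copy()
        d["z1"], d["z2"] = z[:, 0], z[:, 1]
        d["wave"] = d["wave"].astype(str)
        mv = MANOVA.from_formula(
            "z1 + z2 ~ C(sex) + C(education) + C(wave) + C(sex):C(wave)", data=d
        ).mv_test()
        stat = mv.results["C(sex):C(wave)"]["stat"]
        assert mine.value == pytest.approx(stat.loc["Pillai's trace", "Value"], abs=1e-10)
        assert mine.p_value == pytest.approx(stat.loc["Pillai's trace", "Pr > F"], abs=1e-10)

    def test_basis_invariant(self, pooled, rng):
        ps = [
            interaction_test(pooled, "education", predictors=("sex", "education"), basis=b).p_value
            for b in (make_pivot_basis(), make_pivot_basis(("sb", "sleep", "pa")), random_basis(rng))
        ]
        assert max(ps) - min(ps) < 1e-9

    def test_planted_interaction_detected(self):
        from timeuse_coda import generate_person_days

        cfg = two_factor_config(n=10000, sex_effect_2015=(0.45, -0.30))
        df, gt = generate_person_days(cfg, seed=5)
        assert gt.interaction_present["sex"]
        df["final_weight"] = df["weight"]
        t = interaction_test(df, "sex", predictors=("sex", "education"))
        assert t.p_value < 1e-3

    def test_empty_cell_rejected(self, pooled):
        broken = pooled[~((pooled["sex"] == "male") & (pooled["wave"] == 2015))]
        with pytest.raises(EstimationError, match="male"):
            interaction_test(broken, "sex", predictors=("sex", "education"))

    def test_wilks_close_to_pillai_at_large_n(self, pooled):
        a = interaction_test(pooled, "sex", predictors=("sex", "education"), statistic="pillai")
        b = interaction_test(pooled, "sex", predictors=("sex", "education"), statistic="wilks")
        assert a.p_value == pytest.approx(b.p_value, abs=1e-3)


class TestBootstrap:
    @staticmethod
    def mean_statistic(df):
        w = df["weight"].to_numpy()
        m = compositional_mean(df[list(PART_COLUMNS)].to_numpy(), w)
        return list(PART_COLUMNS), m

    def test_same_seed_bit_identical(self, small_survey):
        df, _, _ = small_survey
        a = bootstrap_cis(self.mean_statistic, df, B=50, seed=9)
        b = bootstrap_cis(self.mean_statistic, df, B=50, seed=9)
        np.testing.assert_array_equal(a.replicates, b.replicates)
        np.testing.assert_array_equal(a.ci_low, b.ci_low)

    def test_degenerate_data_zero_width(self):
        df = pd.DataFrame(
            {"wave": [2009] * 8, "weight": 1.0, "pa_h": 10.0, "sb_h": 6.0, "sleep_h": 8.0}
        )
        res = bootstrap_cis(self.mean_statistic, df, B=20, seed=0)
        np.testing.assert_allclose(res.ci_low, res.ci_high)

    def test_stratified_by_wave(self, small_survey):
        """Every replicate preserves the per-wave sample sizes."""
        df, _, _ = small_survey
        sizes = df["wave"].value_counts()

        def count_stat(d):
            return ["n2009", "n2015"], np.array(
                [(d["wave"] == 2009).sum(), (d["wave"] == 2015).sum()]
            )

        res = bootstrap_cis(count_stat, df, B=10, seed=1)
        assert np.all(res.replicates[:, 0] == sizes[2009])
        assert np.all(res.replicates[:, 1] == sizes[2015])

    def test_failing_replicates_abort(self, small_survey):
        """A statistic that fails on (almost every) resample aborts the CI."""
        df, _, _ = small_survey

        def touchy_stat(d):
            # resamples with replacement almost surely repeat a participant
            if d["participant_id"].duplicated().any():
                raise EstimationError("degenerate resample")
            return ["x"], np.array([1.0])

        with pytest.raises(BootstrapError):
            bootstrap_cis(touchy_stat, df, B=20, seed=0)

    def test_b_less_than_two_rejected(self, small_survey):
        df, _, _ = small_survey
        with pytest.raises(UsageError):
            bootstrap_cis(self.mean_statistic, df, B=1, seed=0)
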