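"""Three-way ANOVA, SNK groupings, homogeneity PCA, screening, regressions."""

import numpy as np
import pandas as pd
import pytest

from seedstage.panel import (
    ATTRIBUTES,
    BalancedDesignError,
    PanelError,
    attribute_stage_regression,
    judge_screening,
    panel_homogeneity_pca,
    snk_test,
    three_way_anova,
    validate_score_table,
)
from seedstage.synth import CohortSpec, generate_panel_scores


def _table(scores_fn, judges=4, sessions=3, samples=5, attribute="color"):
    rows = []
    for j in range(1, judges + 1):
        for s in range(1, sessions + 1):
            for m in range(1, samples + 1):
                rows.append((j, s, f"MS{m}", attribute, float(scores_fn(j, s, m))))
    return pd.DataFrame(rows, columns=["judge", "session", "sample", "attribute", "score"])


class TestThreeWayAnova:
    def test_all_equal_scores_yield_zero_ss_and_na_tests(self):
        at = three_way_anova(_table(lambda j, s, m: 5.0), "color")
        assert at.frame.loc["sample", "SS"] == pytest.approx(0.0)
        assert np.isnan(at.frame.loc["sample", "F"])

    def test_pure_sample_effect_concentrates_ss(self):
        at = three_way_anova(_table(lambda j, s, m: float(m)), "color")
        f = at.frame
        assert f.loc["sample", "SS"] > 0
        for eff in ("session", "judge", "judge x session", "judge x sample",
                    "session x sample", "residual"):
            assert f.loc[eff, "SS"] == pytest.approx(0.0, abs=1e-9)

    def test_decomposition_sums_to_total(self):
        rng = np.random.default_rng(3)
        at = three_way_anova(_table(lambda j, s, m: rng.normal(5, 1)), "color")
        f = at.frame
        effects = [e for e in f.index if e != "total"]
        assert f.loc[effects, "SS"].sum() == pytest.approx(f.loc["total", "SS"], abs=1e-6)
        assert f.loc[effects, "df"].sum() == f.loc["total", "df"]

    def test_matches_statsmodels_type1(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(8)
        tbl = _table(lambda j, s, m: m + 0.3 * j + rng.normal(0, 0.5))
        mine = three_way_anova(tbl, "color").frame
        sub = tbl.copy()
        sub["judge"] = sub["judge"].astype(str)
        sub["session"] = sub["session"].astype(str)
        fit = smf.ols(
            "score ~ C(sample) + C(session) + C(judge) + C(sample):C(session)"
            " + C(judge):C(sample) + C(judge):C(session)",
            data=sub,
        ).fit()
        ref = anova_lm(fit, typ=1)
        pairs = {
            "sample": "C(sample)", "session": "C(session)", "judge": "C(judge)",
            "session x sample": "C(sample):C(session)",
            "judge x sample": "C(judge):C(sample)",
            "judge x session": "C(judge):C(session)",
            "residual": "Residual",
        }
        for eff, name in pairs.items():
            assert mine.loc[eff, "SS"] == pytest.approx(ref.loc[name, "sum_sq"], rel=1e-9)
            if name != "Residual":
                assert mine.loc[eff, "p"] == pytest.approx(ref.loc[name, "PR(>F)"], abs=1e-12)

    def test_missing_cell_reported(self):
        tbl = _table(lambda j, s, m: 5.0)
        tbl = tbl.drop(tbl.index[7])
        with pytest.raises(BalancedDesignError, match="missing"):
            three_way_anova(tbl, "color")

    def test_null_rejection_rate_near_alpha(self):
        """Monte-Carlo calibration: pure-noise scores reject sample at ~5%."""
        spec = CohortSpec(rng_seed=0)
        rng = np.random.default_rng(21)
        rej = 0
        n = 300
        for _ in range(n):
            tbl, _ = generate_panel_scores(
                spec, n_judges=8, n_sessions=4, sample_effect=False, rng=rng
            )
            at = three_way_anova(tbl[tbl["attribute"] == "color"], "color")
            rej += at.p_value("sample") < 0.05
        assert 0.02 <= rej / n <= 0.08


class TestSnk:
    def test_two_groups_match_pooled_t_test(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        agree = 0
        for i in range(40):
            a = rng.normal(0, 1, 8)
            b = rng.normal(rng.uniform(0, 1.5), 1, 8)
            snk = snk_test([a, b], alpha=0.05)
            t = stats.ttest_ind(a, b, equal_var=True)
            assert snk.different[0, 1] == (t.pvalue < 0.05)
            agree += 1
        assert agree == 40

    def test_identical_means_share_a_letter(self):
        g = snk_test([(5.0, 1.0, 10), (5.0, 1.0, 10), (5.0, 1.0, 10)])
        assert g.letters == ["a", "a", "a"]

    def test_well_separated_means_get_distinct_letters(self):
        g = snk_test([(1.0, 0.5, 10), (10.0, 0.5, 10), (20.0, 0.5, 10)])
        assert g.letters == ["a", "b", "c"]
        assert g.different[0, 1] and g.different[1, 2] and g.different[0, 2]

    def test_letters_are_valid_coloring(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            k = rng.integers(3, 7)
            groups = [(float(rng.uniform(0, 6)), 1.0, 10) for _ in range(k)]
            g = snk_test(groups)
            for i in range(k):
                for j in range(i + 1, k):
                    share = bool(set(g.letters[i]) & set(g.letters[j]))
                    assert share == (not g.different[i, j])

    def test_never_more_rejections_than_unadjusted_t(self):
        from scipy import stats

        rng = np.random.default_rng(13)
        for _ in range(25):
            k = int(rng.integers(3, 6))
            n = 8
            data = [rng.normal(rng.uniform(0, 2), 1, n) for _ in range(k)]
            g = snk_test(data, alpha=0.05)
            ms = np.mean([d.var(ddof=1) for d in data])
            df = k * (n - 1)
            tcrit = stats.t.ppf(0.975, df)
            for i in range(k):
                for j in range(i + 1, k):
                    tstat = abs(data[i].mean() - data[j].mean()) / np.sqrt(ms * 2 / n)
                    if g.different[i, j]:
                        assert tstat > tcrit  # SNK rejects => plain t rejects

    def test_single_group_rejected(self):
        with pytest.raises(PanelError):
            snk_test([(5.0, 1.0, 10)])


class TestHomogeneityPca:
    def _from_matrix(self, mat):
        rows = []
        for m, row in enumerate(mat, start=1):
            for j, v in enumerate(row, start=1):
                rows.append((j, 1, f"MS{m}", "color", float(v)))
        df = pd.DataFrame(rows, columns=["judge", "session", "sample", "attribute", "score"])
        return panel_homogeneity_pca(df, "color")

    def test_positive_scalings_diagnose_scale_effects(self):
        profile = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        gains = np.array([0.5, 1.0, 1.5, 2.0])
        mat = np.outer(profile, gains)
        res = self._from_matrix(mat)
        assert res.diagnosis == "scale_effects"
        assert res.explained_variance_pct[0] > 99.9

    def test_negated_judge_blocks_diagnose_disagreement(self):
        profile = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        mat = np.column_stack([profile, profile, 6 - profile, 6 - profile])
        res = self._from_matrix(mat)
        assert res.diagnosis == "disagreement"

    def test_shared_profile_with_noise_keeps_scale_effects(self):
        spec = CohortSpec(rng_seed=0)
        tbl, _ = generate_panel_scores(spec, n_judges=10, n_sessions=8,
                                       rng=np.random.default_rng(5))
        res = panel_homogeneity_pca(tbl, "vegetal")
        assert res.diagnosis == "scale_effects"
        assert res.explained_variance_pct[0] > 90.0

    def test_positive_rescaling_never_flips_diagnosis(self):
        spec = CohortSpec(rng_seed=0)
        tbl, _ = generate_panel_scores(spec, n_judges=6, n_sessions=4,
                                       rng=np.random.default_rng(9))
        base = panel_homogeneity_pca(tbl, "color").diagnosis
        scaled = tbl.copy()
        first = scaled["judge"] == 1
        scaled.loc[first, "score"] = np.clip(scaled.loc[first, "score"] * 0.5, 0, 10)
        assert panel_homogeneity_pca(scaled, "color").diagnosis == base

    def test_zero_variance_judge_dropped_with_warning(self):
        profile = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        mat = np.column_stack([profile, 2 * profile, 3 * profile, np.full(5, 4.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            res = self._from_matrix(mat)
        assert res.dropped_judges == [4]


class TestJudgeScreening:
    def _scores(self, noise_by_judge, sessions=6):
        rng = np.random.default_rng(0)
        rows = []
        for j, sd in enumerate(noise_by_judge, start=1):
            for s in range(1, sessions + 1):
                for m in range(1, 6):
                    for attr in ATTRIBUTES[:2]:
                        rows.append((j, s, f"MS{m}", attr, float(np.clip(5 + rng.normal(0, sd), 0, 10))))
        return pd.DataFrame(rows, columns=["judge", "session", "sample", "attribute", "score"])

    def test_identical_judges_fully_retained(self):
        # every judge shows the same within-cell dispersion pattern
        rows = []
        for j in range(1, 7):
            for s in range(1, 7):
                for m in range(1, 6):
                    rows.append((j, s, f"MS{m}", "color", 5.0 + (s % 2)))
        tbl = pd.DataFrame(rows, columns=["judge", "session", "sample", "attribute", "score"])
        assert judge_screening(tbl) == [1, 2, 3, 4, 5, 6]

    def test_planted_outlier_flagged(self):
        tbl = self._scores([0.3] * 7 + [3.0])
        assert judge_screening(tbl) == [1, 2, 3, 4, 5, 6, 7]

    def test_infinite_multiple_retains_everyone(self):
        tbl = self._scores([0.3] * 7 + [3.0])
        assert len(judge_screening(tbl, multiple=np.inf)) == 8

    def test_refuses_to_shrink_below_minimum(self):
        tbl = self._scores([0.1, 0.1, 5.0])
        with pytest.raises(PanelError):
            judge_screening(tbl, multiple=0.1)


class TestAttributeStageRegression:
    def test_exactly_linear_means_give_unit_r2(self):
        tbl = _table(lambda j, s, m: 1.0 + 0.8 * m)
        reg = attribute_stage_regression(tbl, "color")
        assert reg.r_squared == pytest.approx(1.0)
        assert reg.slope == pytest.approx(0.8)

    def test_constant_means_flagged_degenerate(self):
        reg = attribute_stage_regression(_table(lambda j, s, m: 4.0), "color")
        assert reg.degenerate and reg.r_squared == 0.0

    def test_generated_color_and_vegetal_track_stage(self):
        spec = CohortSpec(rng_seed=0)
        tbl, _ = generate_panel_scores(spec, rng=np.random.default_rng(17))
        for attr in ("color", "vegetal"):
            reg = attribute_stage_regression(tbl, attr)
            assert reg.r_squared > 0.90


class TestValidation:
    def test_unknown_attribute_rejected(self):
        tbl = _table(lambda j, s, m: 5.0).assign(attribute="sweetness")
        with pytest.raises(PanelError, match="unknown attributes"):
            validate_score_table(tbl)

    def test_out_of_scale_scores_rejected(self):
        tbl = _table(lambda j, s, m: 11.0)
        with pytest.raises(PanelError, match="0-10"):
            validate_score_table(tbl)
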