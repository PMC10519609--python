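"""Meta-analysis engine: per-study effects, DL pooling, sROC, selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from oralcyto.metadx import (
    EffectEstimate,
    MarkerResult,
    PooledEffect,
    SrocResult,
    SrocUndefinedError,
    Study2x2,
    StudyMeans,
    UndefinedEffectError,
    forest_table,
    pool,
    select_markers,
    sroc,
    study_log_or,
    study_mean_diff,
)
from oralcyto.simdata import MetaSimConfig, simulate_meta_studies


class TestStudyEffects:
    @pytest.mark.parametrize("counts,expected_or", [
        ((10, 10, 10, 10), 1.0),       # symmetric table
        ((20, 5, 8, 17), 8.5),         # (20*17)/(5*8)
        ((10, 0, 5, 5), 21.0),         # 0.5-corrected: (10.5*5.5)/(0.5*5.5)
    ])
    def test_log_odds_ratio(self, counts, expected_or):
        e = study_log_or(Study2x2("s", *counts))
        assert math.exp(e.y) == pytest.approx(expected_or)
        assert e.v > 0

    def test_empty_margin_is_undefined(self):
        with pytest.raises(UndefinedEffectError):
            study_log_or(Study2x2("s", 0, 0, 5, 5))

    def test_mean_difference_hand_case(self):
        e = study_mean_diff(StudyMeans("s", 30, 6, 9, 20, 8, 16))
        assert e.y == pytest.approx(10.0)
        assert e.v == pytest.approx(8.0)  # 36/9 + 64/16

    def test_equal_groups_give_zero_difference(self):
        e = study_mean_diff(StudyMeans("s", 5, 1, 10, 5, 1, 10))
        assert e.y == 0.0

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            StudyMeans("s", 5, 1, 1, 4, 1, 10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            study_mean_diff(StudyMeans("s", 5, 0, 10, 4, 0, 10))


class TestPooling:
    def test_single_study_passthrough(self):
        e = EffectEstimate(0.7, 0.1, "log_or")
        p = pool([e])
        assert p.theta == pytest.approx(0.7)
        assert p.Q == 0 and p.I2 == 0 and p.tau2 == 0

    def test_identical_effects_have_no_heterogeneity(self):
        effects = [EffectEstimate(math.log(2), 0.25, "log_or")] * 2
        p = pool(effects)
        assert p.estimate == pytest.approx(2.0)
        assert p.Q == pytest.approx(0.0) and p.I2 == 0.0

    def test_i_squared_hand_case(self):
        # 13 unit-variance effects engineered so Q = 24 exactly:
        # I2 = 100*(24 - 12)/24 = 50%
        ys = [math.sqrt(2)] * 6 + [-math.sqrt(2)] * 6 + [0.0]
        effects = [EffectEstimate(y, 1.0, "mean_diff") for y in ys]
        p = pool(effects)
        assert p.Q == pytest.approx(24.0)
        assert p.df == 12
        assert p.I2 == pytest.approx(50.0)

    def test_dl_equals_fixed_when_tau2_zero(self):
        # effects whose Q is below df, so the moment estimate truncates at 0
        effects = [EffectEstimate(0.5 + 0.01 * i, 1.0, "log_or") for i in range(5)]
        dl = pool(effects, "dl_random")
        fe = pool(effects, "fixed")
        assert dl.tau2 == 0.0
        assert dl.theta == pytest.approx(fe.theta)
        assert dl.se == pytest.approx(fe.se)

    def test_against_statsmodels_dl(self):
        from statsmodels.stats.meta_analysis import combine_effects

        studies = simulate_meta_studies(MetaSimConfig(k_studies=12, tau2=0.15, seed=3))
        effects = [study_log_or(s) for s in studies]
        p = pool(effects)
        ref = combine_effects(np.array([e.y for e in effects]),
                              np.array([e.v for e in effects]), method_re="dl")
        assert p.theta == pytest.approx(float(ref.mean_effect_re), rel=1e-10)
        assert p.tau2 == pytest.approx(float(ref.tau2), rel=1e-8)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.tuples(st.floats(-3, 3), st.floats(0.01, 4)),
                    min_size=1, max_size=8))
    def test_fixed_effect_is_variance_weighted_mean(self, pairs):
        effects = [EffectEstimate(y, v, "mean_diff") for y, v in pairs]
        p = pool(effects, "fixed")
        w = np.array([1 / v for _, v in pairs])
        y = np.array([y for y, _ in pairs])
        assert p.theta == pytest.approx(float(np.sum(w * y) / np.sum(w)))

    def test_mixed_scales_rejected(self):
        with pytest.raises(ValueError):
            pool([EffectEstimate(1, 1, "log_or"), EffectEstimate(1, 1, "mean_diff")])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool([])

    def test_forest_table_has_pooled_row(self):
        effects = [EffectEstimate(math.log(2), 0.2, "log_or", "a"),
                   EffectEstimate(math.log(3), 0.3, "log_or", "b")]
        p = pool(effects)
        tab = forest_table(effects, p)
        assert list(tab["study_id"]) == ["a", "b", "POOLED"]
        assert tab["weight_pct"].iloc[:2].sum() == pytest.approx(100.0)


class TestSroc:
    def test_chance_line_gives_half_auc(self):
        studies = [Study2x2(f"s{i}", 10 + i, 10 + i, 10 + i, 10 + i)
                   for i in range(5)]
        r = sroc(studies)
        assert r.auc == pytest.approx(0.5, abs=0.01)

    def test_duplicated_point_degenerates_to_intercept(self):
        s = Study2x2("s", 90, 10, 20, 80)
        r = sroc([s, s])
        D = logit(0.9) - logit(0.2)
        assert r.slope_b == 0.0
        assert r.intercept_a == pytest.approx(float(D))

    def test_symmetric_curve_matches_fine_grid_quadrature(self):
        # studies drawn exactly on a symmetric curve: the coarse-grid AUC
        # must match a 1e-5-step quadrature of the same fitted curve
        rng = np.random.default_rng(0)
        a = 2 * logit(0.9)
        studies = []
        for i in range(6):
            fpr = rng.uniform(0.1, 0.4)
            tpr = float(expit(a + logit(fpr)))
            n = 1000
            studies.append(Study2x2(f"s{i}", round(tpr * n), n - round(tpr * n),
                                    round(fpr * n), n - round(fpr * n)))
        r = sroc(studies)
        f = np.arange(1e-5, 1, 1e-5)
        oracle = np.trapezoid(
            expit((r.intercept_a + (1 + r.slope_b) * logit(f)) / (1 - r.slope_b)), f)
        assert r.auc == pytest.approx(float(oracle), abs=2e-3)

    def test_order_invariance(self):
        studies = simulate_meta_studies(MetaSimConfig(k_studies=8, seed=4))
        r1 = sroc(studies)
        r2 = sroc(list(reversed(studies)))
        assert r1.auc == pytest.approx(r2.auc)

    def test_undefined_slope_reports_fit(self):
        # FPR falling while TPR rises makes D grow faster than S -> b > 1
        studies = [Study2x2("a", 60, 40, 40, 60), Study2x2("b", 90, 10, 20, 80)]
        with pytest.raises(SrocUndefinedError) as exc:
            sroc(studies)
        assert abs(exc.value.slope) >= 1


def _pooled(estimate, p_value, p_het, k, scale="log_or"):
    return PooledEffect(estimate=estimate, ci_low=estimate * 0.5,
                        ci_high=estimate * 2, theta=math.log(max(estimate, 1e-9)),
                        se=0.1, p_value=p_value, Q=1.0, df=k - 1, p_het=p_het,
                        I2=0.0, tau2=0.0, k=k, model="dl_random", scale=scale)


class TestMarkerSelection:
    def test_printed_summary_rows(self):
        # pooled rows as printed for a strong marker (selected), a null one
        # (excluded) and a homogeneous continuous marker (selected)
        podoplanin = MarkerResult("Podoplanin", _pooled(10.16, 1e-5, 0.14, 5),
                                  SrocResult(0, 0, 0.828))
        p16 = MarkerResult("P16", _pooled(1.29, 0.6, 0.08, 6),
                           SrocResult(0, 0, 0.542))
        cd44 = MarkerResult("CD44", _pooled(24.1, 1e-4, 0.55, 3, scale="mean_diff"))
        assert select_markers([podoplanin, p16, cd44]) == ["Podoplanin", "CD44"]

    def test_too_few_studies_excluded(self):
        r = MarkerResult("X", _pooled(10.0, 1e-5, 0.5, 2), SrocResult(0, 0, 0.9))
        assert select_markers([r]) == []

    def test_empty_input(self):
        assert select_markers([]) == []
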