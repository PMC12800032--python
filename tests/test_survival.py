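"""Score transfer, optimal cutpoint, Kaplan-Meier, log-rank."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as ll_logrank

import ctcsig as cs
from ctcsig.expression import SignatureModel
from ctcsig.survival import _logrank_z


def model_from(coeffs):
    return SignatureModel(coefficients=pd.Series(coeffs, dtype=float),
                          intercept=0.0, lambda_=0.1)


class TestSignOnlyScore:
    def test_two_term_arithmetic(self):
        model = model_from({"g1": 2.5, "g2": -0.7})
        values = pd.DataFrame({"s1": [2.0, 0.5]}, index=["g1", "g2"])
        risk = cs.sign_only_score(model, values)
        assert risk.scores["s1"] == pytest.approx(2.0 - 0.5)
        assert risk.provenance == "sign_only"

    def test_linearity_all_positive(self):
        m, c = 4, 3.0
        model = model_from({f"g{i}": float(i + 1) for i in range(m)})
        values = pd.DataFrame({"s1": [c] * m}, index=[f"g{i}" for i in range(m)])
        assert cs.sign_only_score(model, values).scores["s1"] == pytest.approx(m * c)

    def test_invariant_to_positive_rescaling(self):
        model_a = model_from({"g1": 1.0, "g2": -2.0})
        model_b = model_from({"g1": 17.0, "g2": -0.04})
        values = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 5)),
                              index=["g1", "g2"])
        a = cs.sign_only_score(model_a, values).scores
        b = cs.sign_only_score(model_b, values).scores
        pd.testing.assert_series_equal(a, b)

    def test_absent_genes_dropped_and_logged(self):
        model = model_from({"g1": 1.0, "missing": 1.0})
        values = pd.DataFrame({"s1": [2.0]}, index=["g1"])
        risk = cs.sign_only_score(model, values)
        assert risk.dropped_genes == ["missing"]
        assert risk.scores["s1"] == pytest.approx(2.0)

    def test_no_genes_present_raises(self):
        model = model_from({"absent": 1.0})
        values = pd.DataFrame({"s1": [2.0]}, index=["g1"])
        with pytest.raises(ValueError):
            cs.sign_only_score(model, values)

    def test_recovers_latent_risk_on_synthetic_cohort(self, strong_signal_config):
        cohort = cs.generate_expression_cohort(strong_signal_config)
        norm = cs.hk_normalize(cohort)
        model = cs.fit_l1_model(norm, cohort.scores, seed=0)
        surv = cs.generate_survival_cohort(strong_signal_config)
        ext = cs.hk_normalize(surv.expression)
        risk = cs.sign_only_score(model, ext)
        r, _ = cs.pearson_with_p(risk.scores, surv.truth["latent_risk"])
        assert r > 0.3


class TestCnGeneScore:
    def test_additive_mapping(self):
        model = model_from({"seg1": 0.8})
        cn = pd.DataFrame({"s1": [1.0, 1.0]}, index=["gA", "gB"])
        risk = cs.cn_gene_score(model, {"seg1": ["gA", "gB"]}, cn)
        assert risk.scores["s1"] == pytest.approx(2.0)

    def test_unavailable_gene_excluded_and_logged(self):
        model = model_from({"seg1": 0.8})
        cn = pd.DataFrame({"s1": [1.0]}, index=["gA"])
        risk = cs.cn_gene_score(model, {"seg1": ["gA", "gMissing"]}, cn)
        assert risk.scores["s1"] == pytest.approx(1.0)
        assert risk.dropped_genes == ["gMissing"]

    def test_diploid_cohort_scores_zero(self):
        model = model_from({"seg1": 0.8, "seg2": -0.2})
        cn = pd.DataFrame(0.0, index=["gA", "gB"], columns=["s1", "s2"])
        risk = cs.cn_gene_score(model, {"seg1": ["gA"], "seg2": ["gB"]}, cn)
        assert (risk.scores == 0.0).all()

    def test_empty_mapping_raises(self):
        with pytest.raises(ValueError):
            cs.cn_gene_score(model_from({"seg1": 1.0}), {}, pd.DataFrame())


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        time = pd.Series([5.0, 10.0, 15.0])
        event = pd.Series([0, 0, 0])
        curve = cs.km_estimate(time, event)[0]
        assert (curve.survival == 1.0).all()
        assert cs.rfs_at(curve, 100.0) == 1.0

    def test_hand_product_limit(self):
        # all events at 1, 2, 3: S = 2/3 after t=1, 1/3 after t=2, 0 after t=3
        time = pd.Series([1.0, 2.0, 3.0])
        event = pd.Series([1, 1, 1])
        curve = cs.km_estimate(time, event)[0]
        assert cs.rfs_at(curve, 2.0) == pytest.approx(1 / 3)
        assert cs.rfs_at(curve, 1.5) == pytest.approx(2 / 3)
        assert cs.rfs_at(curve, 0.0) == 1.0

    def test_no_censoring_equals_empirical_survivor(self, rng):
        t = rng.exponential(10.0, size=50)
        time = pd.Series(t)
        event = pd.Series(1, index=time.index)
        curve = cs.km_estimate(time, event)[0]
        for q in [2.0, 5.0, 12.0]:
            assert cs.rfs_at(curve, q) == pytest.approx((t > q).mean())

    def test_survivor_function_invariants(self, small_survival):
        curves = cs.km_estimate(small_survival.time, small_survival.event)
        s = curves[0].survival
        assert s[0] <= 1.0 and (np.diff(s) <= 1e-12).all()
        assert ((0 <= s) & (s <= 1)).all()
        assert (curves[0].ci_lower <= curves[0].ci_upper + 1e-12).all()

    def test_carry_forward_beyond_last_time(self):
        time = pd.Series([1.0, 2.0])
        event = pd.Series([1, 0])
        curve = cs.km_estimate(time, event)[0]
        assert cs.rfs_at(curve, 1e6) == curve.survival[-1]

    def test_matches_exponential_survivor(self):
        cfg = cs.GeneratorConfig(seed=9, n_ctc_genes=6, n_bc_genes=2, n_emt_genes=2,
                                 n_driver_genes=2, n_survival=3000,
                                 survival_beta=0.0, censoring_rate=0.0,
                                 baseline_hazard=0.01)
        surv = cs.generate_survival_cohort(cfg)
        curve = cs.km_estimate(surv.time, surv.event)[0]
        t = 120.0
        # administrative censoring at 240 months doesn't bias S(120)
        assert cs.rfs_at(curve, t) == pytest.approx(np.exp(-0.01 * t), abs=0.03)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            cs.km_estimate(pd.Series([-1.0, 2.0]), pd.Series([1, 1]))


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        time = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        event = pd.Series([1, 1, 0, 1, 1, 0])
        groups = pd.Series(["a", "a", "a", "b", "b", "b"])
        res = cs.logrank_test(time, event, groups)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_oe_table(self):
        # A: events at 1,2,3; B: events at 4,5,6 (computed by hand below)
        time = pd.Series([1, 2, 3, 4, 5, 6], dtype=float)
        event = pd.Series([1] * 6)
        groups = pd.Series(["A"] * 3 + ["B"] * 3)
        res = cs.logrank_test(time, event, groups)
        # O_A = 3; E_A = 3/6 + 2/5 + 1/4 = 1.15
        assert res.observed["A"] == 3
        assert res.expected["A"] == pytest.approx(3 / 6 + 2 / 5 + 1 / 4)
        # variance terms: (1/2)(1/2), (2/5)(3/5), (1/4)(3/4) with d=1, n-d over n-1
        v = (0.5 * 0.5 * 5 / 5) + (0.4 * 0.6 * 4 / 4) + (0.25 * 0.75 * 3 / 3)
        z = (3 - 1.15) / np.sqrt(v)
        assert res.statistic == pytest.approx(z * z)

    def test_matches_lifelines(self, small_survival):
        scores = small_survival.truth["latent_risk"]
        groups = pd.Series(np.where(scores > scores.median(), "high", "low"),
                           index=scores.index)
        ours = cs.logrank_test(small_survival.time, small_survival.event, groups)
        theirs = ll_logrank(
            small_survival.time[groups == "low"], small_survival.time[groups == "high"],
            small_survival.event[groups == "low"], small_survival.event[groups == "high"])
        assert ours.statistic == pytest.approx(theirs.test_statistic, rel=1e-6)
        assert ours.p_value == pytest.approx(theirs.p_value, rel=1e-6)

    def test_symmetric_under_label_exchange(self, small_survival):
        scores = small_survival.truth["latent_risk"]
        g1 = pd.Series(np.where(scores > 0, "x", "y"), index=scores.index)
        g2 = g1.map({"x": "y", "y": "x"})
        a = cs.logrank_test(small_survival.time, small_survival.event, g1)
        b = cs.logrank_test(small_survival.time, small_survival.event, g2)
        assert a.statistic == pytest.approx(b.statistic)

    def test_oe_sums_to_zero(self, small_survival):
        scores = small_survival.truth["latent_risk"]
        groups = pd.Series(np.where(scores > 0, "hi", "lo"), index=scores.index)
        res = cs.logrank_test(small_survival.time, small_survival.event, groups)
        total = sum(res.observed[g] - res.expected[g] for g in res.observed)
        assert total == pytest.approx(0.0, abs=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            cs.logrank_test(pd.Series([1.0, 2.0]), pd.Series([1, 1]),
                            pd.Series(["a", "a"]))


class TestOptimalCutpoint:
    def test_threshold_falls_in_cluster_gap(self, rng):
        # two well-separated score clusters; high-cluster hazard 4x
        n = 60
        scores = pd.Series(np.concatenate([rng.normal(0, 0.3, n),
                                           rng.normal(5, 0.3, n)]))
        lam = np.where(scores > 2.5, 0.04, 0.01)
        time = pd.Series(rng.exponential(1 / lam))
        event = pd.Series(1, index=time.index)
        cut = cs.optimal_cutpoint(scores, time, event)
        assert 1.0 < cut.threshold < 4.0

    def test_equals_brute_force_scan(self, rng):
        # independent oracle: lifelines log-rank at every admissible midpoint
        n = 120
        scores = pd.Series(rng.normal(size=n))
        lam = 0.01 * np.exp(0.8 * scores)
        time = pd.Series(np.minimum(rng.exponential(1 / lam), 240.0))
        event = pd.Series((time < 240.0).astype(int), index=time.index)
        minprop = 0.1
        cut = cs.optimal_cutpoint(scores, time, event, minprop=minprop)

        distinct = np.unique(scores)
        best = (None, -1.0)
        for c in (distinct[:-1] + distinct[1:]) / 2:
            hi = scores > c
            if hi.sum() < minprop * n or (~hi).sum() < minprop * n:
                continue
            res = ll_logrank(time[~hi], time[hi], event[~hi], event[hi])
            z = np.sqrt(res.test_statistic)
            if z > best[1] + 1e-12:
                best = (c, z)
        assert cut.threshold == pytest.approx(best[0])
        assert cut.statistic == pytest.approx(best[1], rel=1e-6)

    def test_minprop_respected(self, rng):
        n = 50
        scores = pd.Series(rng.normal(size=n))
        time = pd.Series(rng.exponential(50, size=n))
        event = pd.Series(1, index=time.index)
        cut = cs.optimal_cutpoint(scores, time, event, minprop=0.2)
        assert cut.n_low >= 0.2 * n and cut.n_high >= 0.2 * n

    def test_degenerate_inputs_rejected(self, rng):
        n = 20
        time = pd.Series(rng.exponential(10, size=n))
        no_events = pd.Series(0, index=time.index)
        scores = pd.Series(rng.normal(size=n))
        with pytest.raises(ValueError):
            cs.optimal_cutpoint(scores, time, no_events)
        with pytest.raises(ValueError):
            cs.optimal_cutpoint(pd.Series(1.0, index=time.index), time,
                                pd.Series(1, index=time.index))


class TestLogRankCalibration:
    def test_type_i_error_near_nominal(self):
        # shared exponential in both groups: ~5% rejections at alpha = .05
        rng = np.random.default_rng(123)
        n, reps, alpha = 60, 500, 0.05
        rejections = 0
        for _ in range(reps):
            time = rng.exponential(50.0, size=n)
            event = np.ones(n, dtype=int)
            grp = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
            z = _logrank_z(time, event, grp == "a")
            if z * z > 3.841:
                rejections += 1
        assert 0.03 < rejections / reps < 0.07
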