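import numpy as np
import pandas as pd
import pytest

from mpfi.risk import (CALCULATORS, DMFS_CALCULATOR, LRFFS_CALCULATOR,
                       OS_CALCULATOR, apply_calculator, high_risk_sens_spec,
                       km_estimator, log_rank, stratify, survival_at)
from mpfi.synthetic import simulate_outcomes


class TestApplyCalculator:
    def test_lrffs_all_zero_predictors(self):
        x = {k: 0.0 for k in LRFFS_CALCULATOR.coefficients}
        p = apply_calculator(LRFFS_CALCULATOR, x)
        assert p == pytest.approx(1 / (1 + np.exp(2.173498)), rel=1e-9)

    def test_dmfs_all_zero_predictors(self):
        x = {k: 0.0 for k in DMFS_CALCULATOR.coefficients}
        p = apply_calculator(DMFS_CALCULATOR, x)
        assert p == pytest.approx(1 / (1 + np.exp(5.950312)), rel=1e-9)

    def test_logistic_midpoint_at_zero_score(self):
        # choose a predictor vector making Y exactly 0
        calc = DMFS_CALCULATOR
        x = {"PRE_ADC_kurtosis": 0.0,
             "PRE_SUV_peak": -calc.intercept / calc.coefficients["PRE_SUV_peak"]}
        assert apply_calculator(calc, x) == pytest.approx(0.5, rel=1e-12)

    @pytest.mark.parametrize("calc", list(CALCULATORS.values()), ids=lambda c: c.name)
    def test_monotone_in_each_coefficient_sign(self, calc):
        base = {k: 0.3 for k in calc.coefficients}
        p0 = apply_calculator(calc, base)
        for name, coef in calc.coefficients.items():
            bumped = dict(base)
            bumped[name] += 0.5
            p1 = apply_calculator(calc, bumped)
            if coef > 0:
                assert p1 > p0
            else:
                assert p1 < p0

    def test_dataframe_input_vectorises(self):
        df = pd.DataFrame(0.0, index=["a", "b"], columns=list(DMFS_CALCULATOR.coefficients))
        p = apply_calculator(DMFS_CALCULATOR, df)
        assert list(p.index) == ["a", "b"]
        np.testing.assert_allclose(p, 1 / (1 + np.exp(5.950312)))

    def test_missing_predictor_raises(self):
        with pytest.raises(KeyError):
            apply_calculator(DMFS_CALCULATOR, {"PRE_ADC_kurtosis": 1.0})


class TestStratify:
    def test_canonical_groups(self):
        g = stratify([0.1, 0.5, 0.9]).group
        assert list(g) == ["low", "medium", "high"]

    def test_boundaries_left_closed(self):
        g = stratify([0.33, 0.66, 0.32999, 0.65999]).group
        assert list(g) == ["medium", "high", "low", "medium"]

    def test_groups_partition_cohort(self, rng):
        p = rng.random(100)
        g = stratify(p).group
        assert g.isin(["low", "medium", "high"]).all()
        assert g.value_counts().sum() == 100

    def test_tertile_mode_balances_groups(self, rng):
        p = rng.random(99)
        g = stratify(p, mode="tertile").group
        assert set(g.value_counts()) == {33}

    def test_too_few_patients_raises(self):
        with pytest.raises(ValueError):
            stratify([0.5, 0.5])


class TestKmEstimator:
    def test_two_subject_product_limit_by_hand(self):
        curves = km_estimator([1.0, 2.0], [1, 1])
        km = curves["all"]
        assert survival_at(km, 1.0) == pytest.approx(0.5)
        assert survival_at(km, 2.0) == pytest.approx(0.0)

    def test_no_events_flat_at_one(self):
        km = km_estimator([1.0, 2.0, 3.0], [0, 0, 0])["all"]
        np.testing.assert_allclose(km["survival"], 1.0)

    def test_single_event_among_n(self):
        n = 8
        t = [1.0] + [5.0] * (n - 1)
        e = [1] + [0] * (n - 1)
        km = km_estimator(t, e)["all"]
        assert survival_at(km, 1.0) == pytest.approx(1 - 1 / n)

    def test_grouped_curves_keyed_by_label(self):
        curves = km_estimator([1, 2, 3, 4], [1, 1, 1, 1], ["a", "a", "b", "b"])
        assert set(curves) == {"a", "b"}

    def test_empty_group_impossible_by_construction(self):
        with pytest.raises(ValueError):
            km_estimator([], [], None)


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        t = [1.0, 2.0, 3.0] * 2
        e = [1, 0, 1] * 2
        g = ["a"] * 3 + ["b"] * 3
        chi2, p = log_rank(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_table(self):
        # groups a: events at 1, 3; b: event at 5, censored 2, 4, 6.
        t = [1.0, 3.0, 5.0, 2.0, 4.0, 6.0]
        e = [1, 1, 1, 0, 0, 0]
        g = ["a", "a", "b", "b", "b", "b"]
        chi2, _ = log_rank(t, e, g)
        # manual O-E/V: event times 1 (2a/4b at risk), 3 (1a/3b), 5 (0a/2b)
        # O_a = 2; E_a = 2/6 + 1/4 + 0 = 0.583333
        # V = sum of hypergeometric variances = 2/6*4/6 + 1/4*3/4 + 0 = 0.409722
        o_minus_e = 2 - (2 / 6 + 1 / 4)
        v = (2 * 4) / 36 + (1 * 3) / 16
        assert chi2 == pytest.approx(o_minus_e**2 / v, rel=1e-6)

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(17)
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            t = rng.exponential(1.0, 40)
            e = (rng.random(40) < 0.8).astype(int)
            g = np.where(rng.random(40) < 0.5, "a", "b")
            if e.sum() == 0 or len(set(g)) < 2:
                continue
            _, p = log_rank(t, e, g)
            rejections += p < 0.05
        assert 0.01 <= rejections / n_sims <= 0.11

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            log_rank([1, 2], [1, 1], ["a", "a"])
        with pytest.raises(ValueError):
            log_rank([1, 2], [0, 0], ["a", "b"])


class TestHighRiskSensSpec:
    def test_perfect_classification(self):
        groups = ["high", "high", "low", "medium"]
        events = [1, 1, 0, 0]
        assert high_risk_sens_spec(groups, events) == (1.0, 1.0)

    def test_matches_contingency_table_oracle(self, rng):
        groups = rng.choice(["low", "medium", "high"], 200)
        events = rng.integers(0, 2, 200)
        sens, spec = high_risk_sens_spec(groups, events)
        tp = np.sum((groups == "high") & (events == 1))
        fn = np.sum((groups != "high") & (events == 1))
        tn = np.sum((groups != "high") & (events == 0))
        fp = np.sum((groups == "high") & (events == 0))
        assert sens == pytest.approx(tp / (tp + fn))
        assert spec == pytest.approx(tn / (tn + fp))

    def test_independent_groups_match_base_rates(self):
        rng = np.random.default_rng(23)
        groups = rng.choice(["low", "medium", "high"], 20_000, p=[0.4, 0.4, 0.2])
        events = rng.integers(0, 2, 20_000)
        sens, spec = high_risk_sens_spec(groups, events)
        assert sens == pytest.approx(0.2, abs=0.02)
        assert spec == pytest.approx(0.8, abs=0.02)

    def test_degenerate_margins_raise(self):
        with pytest.raises(ValueError):
            high_risk_sens_spec(["high", "low"], [1, 1])


class TestCalculatorDrivenCohort:
    def test_simulated_cohort_orders_km_curves(self):
        # features spread widely so the calculator's own score separates risk
        rng = np.random.default_rng(31)
        X = pd.DataFrame(rng.normal(0, 2.0, (400, len(LRFFS_CALCULATOR.coefficients))),
                         columns=list(LRFFS_CALCULATOR.coefficients))
        probs = apply_calculator(LRFFS_CALCULATOR, X)
        out = simulate_outcomes(X, LRFFS_CALCULATOR.coefficients, seed=5,
                                intercept=LRFFS_CALCULATOR.intercept)
        groups = stratify(probs)
        assert groups.group.nunique() == 3
        curves = km_estimator(out["time"], out["event"], groups.group)
        s2 = {g: survival_at(curves[g], 2.0) for g in curves}
        assert s2["low"] >= s2["medium"] - 0.05 >= s2["high"] - 0.10
        chi2, p = log_rank(out["time"], out["event"], groups.group)
        assert p < 0.05
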