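import numpy as np
import pandas as pd
import pytest

from mpfi.features import (CLINICAL_FEATURES, IMAGING_FEATURES,
                           assemble_feature_table, delta_feature,
                           feature_columns, interobserver_correlation,
                           mann_whitney, observer_average, two_year_binary,
                           univariate_cox)


class TestObserverAverage:
    def test_arithmetic_mean(self):
        v, single = observer_average(1.0, 1.2)
        assert v == pytest.approx(1.1)
        assert not single

    def test_identical_observers_idempotent(self):
        v, _ = observer_average(0.85, 0.85)
        assert v == 0.85

    def test_random_pairs_match_oracle(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=2)
            assert observer_average(a, b)[0] == pytest.approx((a + b) / 2)

    def test_single_observer_fallback_flagged(self):
        v, single = observer_average(None, 2.0)
        assert v == 2.0 and single
        v, single = observer_average(np.nan, 2.0)
        assert v == 2.0 and single

    def test_both_missing_raises(self):
        with pytest.raises(ValueError):
            observer_average(None, np.nan)


class TestDeltaFeature:
    @pytest.mark.parametrize("pre,intra,expected", [
        (10.0, 12.0, 0.2),
        (5.0, 5.0, 0.0),
        (4.0, 1.0, -0.75),
    ])
    def test_fractional_change(self, pre, intra, expected):
        assert delta_feature(pre, intra) == pytest.approx(expected)

    def test_zero_pretreatment_undefined(self):
        assert np.isnan(delta_feature(0.0, 3.0))


class TestInterobserverCorrelation:
    def test_identical_observers_r_one(self, rng):
        v = rng.normal(size=10)
        r, _ = interobserver_correlation(v, v)
        assert r == pytest.approx(1.0)

    def test_negated_observers_r_minus_one(self, rng):
        v = rng.normal(size=10)
        r, _ = interobserver_correlation(v, -v)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self, rng):
        a, b = rng.normal(size=15), rng.normal(size=15)
        r, _ = interobserver_correlation(a, b)
        oracle = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        assert r == pytest.approx(oracle, rel=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            interobserver_correlation([1, 1, 1], [1, 2, 3])


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        # A={1,2}, B={3,4}: no A value beats any B value -> U_A = 0,
        # exact two-sided p = 2 * 1/C(4,2) = 1/3
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_group_swap_symmetry(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=9)
        u_ab, p_ab = mann_whitney(a, b)
        u_ba, p_ba = mann_whitney(b, a)
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))
        assert p_ab == pytest.approx(p_ba)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(99)
        ps = [mann_whitney(rng.normal(size=20), rng.normal(size=20))[1]
              for _ in range(300)]
        frac = np.mean(np.asarray(ps) < 0.05)
        assert 0.01 <= frac <= 0.10  # 3-sigma band around the nominal 5%

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


def _cox_score_chi2(x, time, event):
    """Independent score-test oracle at beta=0: for each event time, compare
    the covariate of the failing subject with the risk-set mean; the squared
    summed score over the summed risk-set variance is chi-square(1) — for a
    binary covariate this is exactly the two-group log-rank statistic."""
    x = np.asarray(x, float)
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    u = v = 0.0
    for i in np.where(e == 1)[0]:
        at_risk = t >= t[i]
        xm = x[at_risk].mean()
        u += x[i] - xm
        v += np.mean((x[at_risk] - xm) ** 2)
    return u**2 / v


class TestUnivariateCox:
    def test_null_simulation_beta_centred_at_zero(self):
        rng = np.random.default_rng(5)
        betas = []
        for _ in range(200):
            x = rng.normal(size=40)
            t = rng.exponential(1.0, 40)
            e = (rng.random(40) < 0.7).astype(int)
            betas.append(univariate_cox(x, t, e)["coef"])
        assert abs(np.mean(betas)) < 3 * np.std(betas) / np.sqrt(len(betas)) + 0.05

    def test_perfect_ordering_flags_separation(self):
        n = 20
        x = np.arange(n, dtype=float)
        t = n - x  # highest covariate fails first
        res = univariate_cox(x, t, np.ones(n, int))
        assert res["separation"]

    def test_score_test_equals_logrank_for_binary_feature(self):
        rng = np.random.default_rng(11)
        x = np.repeat([0.0, 1.0], 15)
        t = np.concatenate([rng.exponential(1.0, 15), rng.exponential(0.5, 15)])
        e = np.ones(30, int)
        from mpfi.risk import log_rank
        chi2, _ = log_rank(t, e, np.where(x > 0, "b", "a"))
        assert _cox_score_chi2(x, t, e) == pytest.approx(chi2, rel=1e-6)

    def test_known_hazard_recovered(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=400)
        t = rng.exponential(np.exp(-0.7 * x))
        res = univariate_cox(x, t, np.ones(400, int))
        assert res["coef"] == pytest.approx(0.7, abs=0.15)
        assert res["p"] < 1e-6


class TestTableAssembly:
    def _per_patient(self, n=4):
        rng = np.random.default_rng(0)
        out = {}
        for i in range(n):
            out[f"P{i}"] = {
                tp: {name: float(rng.uniform(1, 10)) for name in IMAGING_FEATURES}
                for tp in ("PRE", "INTRA")
            }
        return out

    def test_45_imaging_columns_plus_clinical(self):
        per_patient = self._per_patient()
        clinical = pd.DataFrame(
            {c: np.zeros(4) for c in CLINICAL_FEATURES},
            index=[f"P{i}" for i in range(4)])
        table = assemble_feature_table(per_patient, clinical)
        assert len(feature_columns()) == 45
        assert table.shape[1] == 45 + 7
        assert [c for c in table.columns if c.startswith("delta_")] == \
            [f"delta_{n}" for n in IMAGING_FEATURES]

    def test_delta_zero_when_timepoints_agree(self):
        pp = self._per_patient(2)
        pp["P0"]["INTRA"] = dict(pp["P0"]["PRE"])
        table = assemble_feature_table(pp)
        np.testing.assert_allclose(table.loc["P0", [f"delta_{n}" for n in IMAGING_FEATURES]],
                                   0.0, atol=1e-12)

    def test_delta_matches_definition(self):
        pp = self._per_patient(1)
        table = assemble_feature_table(pp)
        for n in IMAGING_FEATURES:
            pre, intra = pp["P0"]["PRE"][n], pp["P0"]["INTRA"][n]
            assert table.loc["P0", f"delta_{n}"] == pytest.approx((intra - pre) / pre)


class TestTwoYearBinary:
    def test_classification_rules(self):
        time = [0.5, 3.0, 1.0, 2.0, 2.5]
        event = [1, 0, 0, 0, 1]
        out = two_year_binary(time, event)
        assert out[0] == 1.0          # event inside the horizon
        assert out[1] == 0.0          # event-free past the horizon
        assert np.isnan(out[2])       # censored early -> excluded
        assert out[3] == 0.0          # followed exactly to the horizon
        assert out[4] == 0.0          # event after the horizon counts event-free
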