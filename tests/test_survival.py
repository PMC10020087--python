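"""Risk signature: Lasso-Cox, scoring, stratification, KM, log-rank."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from math import comb

from m6asplice.simulate import SimConfig, simulate_cohort
from m6asplice.survival import (
    CoxLassoRisk, RiskModel, SurvivalCohort, compare_psi_groups,
    correlate_expression_psi, cox_lasso, km_estimate, logrank_test,
    percentile_split, risk_score,
)


def toy_cohort(rng, n=200, betas=(1.0,), censor=0.0):
    cfg = SimConfig(n_patients=n, true_betas=tuple(betas), censor_rate=censor,
                    seed=int(rng.integers(1 << 30)))
    cohort, _ = simulate_cohort([f"e{i}" for i in range(len(betas))], cfg)
    return cohort


class TestRiskScore:
    def test_dot_product(self):
        model = RiskModel(["e1", "e2"],
                          pd.Series({"e1": 0.5, "e2": -1.0}), 0.0)
        psi = pd.DataFrame({"e1": [0.6], "e2": [0.2]})
        assert risk_score(model, psi).iloc[0] == pytest.approx(0.1)

    def test_zero_betas_zero_score(self):
        model = RiskModel(["e1"], pd.Series({"e1": 0.0}), 0.0)
        psi = pd.DataFrame({"e1": [0.3, 0.9]})
        assert (risk_score(model, psi) == 0.0).all()

    def test_affine_in_each_coordinate(self):
        model = RiskModel(["e1", "e2"],
                          pd.Series({"e1": 2.0, "e2": -3.0}), 0.0)
        grid = np.linspace(0, 1, 5)
        base = risk_score(model, pd.DataFrame({"e1": grid, "e2": 0.5})).values
        diffs = np.diff(base)
        assert np.allclose(diffs, diffs[0])

    def test_missing_event_column_raises(self):
        model = RiskModel(["e1"], pd.Series({"e1": 1.0}), 0.0)
        with pytest.raises(KeyError):
            risk_score(model, pd.DataFrame({"other": [0.1]}))


class TestPercentileSplit:
    def test_published_cohort_split_302_905(self, rng):
        scores = pd.Series(rng.normal(size=1207))
        labels = percentile_split(scores, q=0.75)
        assert (labels == "high").sum() == 302
        assert (labels == "low").sum() == 905

    def test_small_n(self, rng):
        labels = percentile_split(pd.Series([0.1, 0.5, 0.3, 0.2]))
        assert (labels == "high").sum() == 1
        assert labels.iloc[1] == "high"

    def test_all_tied_scores_split_by_stable_order(self, caplog):
        with caplog.at_level("WARNING"):
            labels = percentile_split(pd.Series([1.0] * 8))
        assert (labels == "high").sum() == 2
        assert list(labels[labels == "high"].index) == [0, 1]
        assert "tie" in caplog.text

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 7, 100, 1207, 4999, 5000])
    def test_group_sizes_sum_and_ceiling(self, n, rng):
        labels = percentile_split(pd.Series(rng.normal(size=n)))
        n_high = (labels == "high").sum()
        assert n_high == int(np.ceil(0.25 * n))
        assert n_high + (labels == "low").sum() == n


class TestKaplanMeier:
    def test_three_uncensored_events(self):
        km = km_estimate(pd.Series([1.0, 2.0, 3.0]), pd.Series([1, 1, 1]),
                         pd.Series(["g", "g", "g"]))["g"]
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert np.array_equal(km.at_risk, [3, 2, 1])

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate(pd.Series([1.0, 2.0]), pd.Series([0, 0]),
                         pd.Series(["g", "g"]))["g"]
        assert km.event_times.size == 0  # S never drops below 1

    def test_uncensored_km_equals_empirical_survival(self, rng):
        t = pd.Series(rng.exponential(5.0, size=500))
        km = km_estimate(t, pd.Series(np.ones(500, dtype=int)),
                         pd.Series(["g"] * 500))["g"]
        ecdf = np.array([(t > tt).mean() for tt in km.event_times])
        assert np.allclose(km.survival, ecdf, atol=1e-12)

    def test_curves_non_increasing_and_in_unit_interval(self, rng):
        cohort = toy_cohort(rng, n=300, betas=(1.0,), censor=0.3)
        labels = pd.Series(np.where(cohort.psi["e0"] > 0.5, "high", "low"),
                           index=cohort.psi.index)
        for km in km_estimate(cohort.time, cohort.event, labels).values():
            assert (np.diff(km.survival) <= 1e-12).all()
            assert ((km.survival >= 0) & (km.survival <= 1)).all()


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = pd.Series([1.0, 2, 3, 1, 2, 3])
        e = pd.Series([1, 1, 1, 1, 1, 1])
        g = pd.Series(["a", "a", "a", "b", "b", "b"])
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_lifetable(self):
        """Six patients, distinct times, no censoring: O/E/V by hand."""
        t = pd.Series([1.0, 2, 3, 4, 5, 6])
        e = pd.Series([1, 1, 1, 1, 1, 1])
        g = pd.Series(["a", "a", "a", "b", "b", "b"])
        # deaths at t=1..3 all in group a, t=4..6 in group b.  At-risk
        # (n_a, N): (3,6), (2,5), (1,4), then n_a = 0.  With single deaths,
        # E_a = sum n_a/N and V = sum (n_a/N)(1 - n_a/N).
        E = 3 / 6 + 2 / 5 + 1 / 4
        V = (3 / 6) * (3 / 6) + (2 / 5) * (3 / 5) + (1 / 4) * (3 / 4)
        expected = (3 - E) ** 2 / V  # = 5.0517
        chi2, _ = logrank_test(t, e, g)
        assert chi2 == pytest.approx(expected, rel=1e-9)

    def test_needs_exactly_two_groups(self):
        with pytest.raises(ValueError):
            logrank_test(pd.Series([1.0, 2]), pd.Series([1, 1]),
                         pd.Series(["a", "a"]))


class TestCompareGroups:
    def test_identical_samples_p_one(self):
        x = pd.DataFrame({"e1": [0.1, 0.5, 0.9]})
        assert compare_psi_groups(x, x.copy())["e1"] == 1.0

    def test_disjoint_supports_exact_tail(self, rng):
        hi = pd.DataFrame({"e1": rng.uniform(0.6, 1.0, 20)})
        lo = pd.DataFrame({"e1": rng.uniform(0.0, 0.4, 20)})
        p = compare_psi_groups(hi, lo)["e1"]
        assert p == pytest.approx(2 / comb(40, 20), rel=1e-9)

    def test_null_rejection_rate_nominal(self, rng):
        pvals = []
        for _ in range(300):
            a = pd.DataFrame({"e": rng.uniform(size=30)})
            b = pd.DataFrame({"e": rng.uniform(size=30)})
            pvals.append(compare_psi_groups(a, b)["e"])
        rate = np.mean(np.array(pvals) < 0.05)
        assert 0.02 <= rate <= 0.09


class TestCorrelation:
    def test_exact_linear_relation(self):
        x = pd.Series(np.linspace(0, 1, 50))
        r, p = correlate_expression_psi(x * 3 + 1, 0.5 * x + 0.1)
        assert r == pytest.approx(1.0)
        assert p < 1e-20

    def test_independent_variables_near_zero(self, rng):
        r, _ = correlate_expression_psi(
            pd.Series(rng.normal(size=2000)), pd.Series(rng.uniform(size=2000))
        )
        assert abs(r) < 0.07

    def test_constant_input_sentinel(self):
        r, p = correlate_expression_psi(
            pd.Series([1.0, 2.0, 3.0]), pd.Series([0.5, 0.5, 0.5])
        )
        assert np.isnan(r) and np.isnan(p)


class TestCoxLasso:
    def test_infinite_penalty_zeroes_all_coefficients(self, rng):
        cohort = toy_cohort(rng, n=300, betas=(1.5, -1.0), censor=0.2)
        model = cox_lasso(cohort, penalty=10.0)
        assert np.allclose(model.betas.values, 0.0)

    def test_all_censored_cohort_rejected(self):
        cohort = SurvivalCohort(
            pd.DataFrame({"e1": [0.1, 0.9, 0.5]}),
            pd.Series([1.0, 2.0, 3.0]),
            pd.Series([0, 0, 0]),
        )
        with pytest.raises(ValueError, match="censored"):
            cox_lasso(cohort, penalty=0.0)

    def test_patient_order_invariance(self, rng):
        cohort = toy_cohort(rng, n=200, betas=(1.5, -1.0), censor=0.2)
        perm = rng.permutation(cohort.n_patients)
        shuffled = SurvivalCohort(
            cohort.psi.iloc[perm], cohort.time.iloc[perm],
            cohort.event.iloc[perm],
        )
        m1 = cox_lasso(cohort, penalty=0.05)
        m2 = cox_lasso(shuffled, penalty=0.05)
        assert np.allclose(m1.betas.values, m2.betas.values, atol=1e-6)

    def test_cv_min_recovers_coefficients(self):
        cfg = SimConfig(n_patients=1000, true_betas=(1.5, -1.5, 0.0),
                        censor_rate=0.2, seed=42)
        cohort, _ = simulate_cohort(["e1", "e2", "e3"], cfg)
        model = cox_lasso(cohort, penalty=None, seed=0, cv_rule="min")
        b = model.betas
        assert b["e1"] > 0 and b["e2"] < 0
        assert abs(b["e1"] - 1.5) < 0.35
        assert abs(b["e2"] + 1.5) < 0.35

    def test_cv_1se_shrinks_null_coefficient(self):
        cfg = SimConfig(n_patients=1000, true_betas=(1.5, -1.5, 0.0),
                        censor_rate=0.2, seed=42)
        cohort, _ = simulate_cohort(["e1", "e2", "e3"], cfg)
        lasso = cox_lasso(cohort, penalty=None, seed=0, cv_rule="1se")
        unpen = cox_lasso(cohort, penalty=0.0)
        assert lasso.betas["e1"] > 0 and lasso.betas["e2"] < 0
        assert abs(lasso.betas["e3"]) <= abs(unpen.betas["e3"]) + 1e-9

    def test_single_covariate_sign_matches_hazard_direction(self, rng):
        cohort = toy_cohort(rng, n=400, betas=(1.2,), censor=0.1)
        model = cox_lasso(cohort, penalty=0.0)
        assert model.betas.iloc[0] > 0

    def test_missing_psi_dropped(self, rng):
        cohort = toy_cohort(rng, n=100, betas=(1.0,), censor=0.0)
        psi = cohort.psi.copy()
        psi.iloc[:10, 0] = np.nan
        c2 = SurvivalCohort(psi, cohort.time, cohort.event)
        model = cox_lasso(c2, penalty=0.0)
        assert np.isfinite(model.betas.iloc[0])


class TestModelObject:
    def test_fit_stratify_and_summary(self):
        cfg = SimConfig(n_patients=400, true_betas=(1.5, -1.5), censor_rate=0.2,
                        seed=9)
        cohort, _ = simulate_cohort(["e1", "e2"], cfg)
        res = CoxLassoRisk(cohort).fit(penalty=0.0)
        assert (res.groups == "high").sum() == 100
        chi2, p = res.logrank()
        assert p < 0.001  # a strong planted signal separates the strata
        text = res.summary()
        assert "coefficients" in text and "log-rank" in text

    def test_from_dataframe_constructor(self, rng):
        df = pd.DataFrame({
            "e1": rng.uniform(size=50),
            "time": rng.exponential(5, 50),
            "event": rng.integers(0, 2, 50) | 1,
        })
        model = CoxLassoRisk.from_dataframe(df)
        assert list(model.cohort.psi.columns) == ["e1"]
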