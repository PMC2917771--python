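import numpy as np
import pandas as pd
import pytest

import seedsurv as ss
from conftest import exp_ph_cohort


class TestMedianDichotomize:
    def test_even_split(self):
        assert list(ss.median_dichotomize([1, 2, 3, 4])) == ["low", "low", "high", "high"]

    def test_ties_at_median_go_low(self):
        assert list(ss.median_dichotomize([1, 2, 2, 3])) == ["low", "low", "low", "high"]

    def test_split_sizes_differ_by_at_most_ties(self, rng):
        for _ in range(20):
            x = rng.integers(0, 10, 31).astype(float)
            labels = ss.median_dichotomize(x)
            n_ties = int((x == np.median(x)).sum())
            n_low = int((labels == "low").sum())
            n_high = int((labels == "high").sum())
            # the tie block straddles the median, so the imbalance is at most
            # twice the tie count (exact split when there are no ties)
            assert abs(n_low - n_high) <= max(2 * n_ties, 1)

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            ss.median_dichotomize([3, 3, 3])


class TestRankNormalize:
    def test_simple(self):
        np.testing.assert_allclose(ss.rank_normalize([5, 7, 9]), [0, 0.5, 1])

    def test_average_rank_ties(self):
        np.testing.assert_allclose(ss.rank_normalize([1, 1, 3]), [0.25, 0.25, 1])

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_allclose(ss.rank_normalize(x), ss.rank_normalize(np.exp(x)))

    def test_missing_preserved(self):
        out = ss.rank_normalize([1.0, np.nan, 3.0, 2.0])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2, 3]], [0, 1, 0.5])


class TestKaplanMeier:
    def test_hand_product_limit(self):
        est = ss.km_estimate([1, 2, 3], [1, 0, 1])
        assert est.at(1) == pytest.approx(2 / 3)
        assert est.at(2.5) == pytest.approx(2 / 3)
        assert est.at(3) == pytest.approx(0.0)
        assert est.at(0.5) == 1.0

    def test_five_point_fixture(self):
        # times 2,4,4,6,8 events 1,1,0,1,0:
        # S(2)=4/5; at t=4 one event of 4 at risk -> 3/5 (censor counted after);
        # t=6: 2 at risk, event -> 3/10
        est = ss.km_estimate([2, 4, 4, 6, 8], [1, 1, 0, 1, 0])
        assert est.at(2) == pytest.approx(4 / 5)
        assert est.at(4) == pytest.approx(3 / 5)
        assert est.at(6) == pytest.approx(3 / 10)
        assert est.at(8) == pytest.approx(3 / 10)

    def test_all_censored_flat(self):
        est = ss.km_estimate([1, 2, 3], [0, 0, 0])
        assert est.at(5) == 1.0
        assert len(est.event_times) == 0

    def test_no_censoring_equals_empirical(self, rng):
        t = rng.exponential(10, 40)
        est = ss.km_estimate(t, np.ones(40, dtype=int))
        for q in [np.quantile(t, x) for x in (0.2, 0.5, 0.9)]:
            assert est.at(q) == pytest.approx((t > q).mean())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ss.km_estimate([], [])


class TestLogrank:
    def test_identical_groups_chi2_zero(self):
        t = [1, 2, 3, 4, 5, 6]
        e = [1, 0, 1, 1, 0, 1]
        chi2, p = ss.logrank_test(t + t, e + e, ["a"] * 6 + ["b"] * 6)
        assert chi2 == pytest.approx(0.0, abs=1e-10)

    def test_separated_groups_significant(self, rng):
        x, t, e = exp_ph_cohort(400, beta=np.log(4.0), rng=rng)
        chi2, p = ss.logrank_test(t, e, np.where(x > 0, "hi", "lo"))
        assert p < 0.001

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            ss.logrank_test([1, 2], [1, 1], ["a", "a"])

    def test_null_p_uniform_over_permutations(self, rng):
        from scipy import stats
        t = rng.exponential(10, 60)
        e = (rng.uniform(size=60) < 0.7).astype(int)
        ps = []
        for _ in range(200):
            g = rng.permutation(np.repeat(["a", "b"], 30))
            ps.append(ss.logrank_test(t, e, g)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


def efron_free_partial_loglik(beta, x, time, event):
    """Written-out Cox partial log-likelihood (no ties -> Breslow = Efron)."""
    order = np.argsort(time)
    x, time, event = x[order], time[order], event[order]
    ll = 0.0
    for i in range(len(x)):
        if event[i]:
            risk = np.exp(beta * x[i:])
            ll += beta * x[i] - np.log(risk.sum())
    return ll


class TestCoxFit:
    def test_brute_force_oracle_tiny(self):
        from scipy.optimize import minimize_scalar
        x = np.array([0.0, 1.0, 1.0, 0.0, 1.0, 0.0])
        t = np.array([3.0, 1.0, 5.0, 2.0, 4.0, 6.0])
        e = np.array([1, 1, 1, 1, 1, 1])
        res = minimize_scalar(lambda b: -efron_free_partial_loglik(b, x, t, e),
                              bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        fit = ss.cox_fit(pd.DataFrame({"x": x}), t, e)
        assert fit.beta[0] == pytest.approx(res.x, abs=1e-6)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-8)

    def test_null_covariate_ci_contains_one(self, rng):
        x = rng.normal(size=500)
        t = rng.exponential(10, 500)
        e = (rng.uniform(size=500) < 0.7).astype(int)
        fit = ss.cox_fit(pd.DataFrame({"x": x}), t, e)
        assert fit.ci_low[0] <= 1.0 <= fit.ci_high[0]

    def test_hr_recovery_binary(self, rng):
        x, t, e = exp_ph_cohort(500, beta=np.log(2.0), rng=rng)
        fit = ss.cox_fit(pd.DataFrame({"x": x}), t, e)
        assert 1.6 <= fit.hr[0] <= 2.5
        assert fit.ci_low[0] <= fit.hr[0] <= fit.ci_high[0]

    def test_binary_recode_reciprocal_hr(self, rng):
        x, t, e = exp_ph_cohort(200, beta=np.log(2.0), rng=rng)
        a = ss.cox_fit(pd.DataFrame({"x": x}), t, e)
        b = ss.cox_fit(pd.DataFrame({"x": 1.0 - x}), t, e)
        assert a.hr[0] == pytest.approx(1.0 / b.hr[0], rel=1e-6)
        assert a.ci_low[0] == pytest.approx(1.0 / b.ci_high[0], rel=1e-6)

    def test_rank_covariate_monotone_invariance(self, rng):
        """Rank-normalised expression gives identical fits for any strictly
        monotone transform of the raw values (the rationale for ranking)."""
        raw = rng.lognormal(size=120)
        t = rng.exponential(10 / (1 + raw), 120)
        e = (rng.uniform(size=120) < 0.7).astype(int)
        f1 = ss.cox_fit(pd.DataFrame({"g": ss.rank_normalize(raw)}), t, e)
        f2 = ss.cox_fit(pd.DataFrame({"g": ss.rank_normalize(np.log(raw))}), t, e)
        assert f1.beta[0] == pytest.approx(f2.beta[0], abs=1e-10)

    def test_constant_covariate_named(self, rng):
        t = rng.exponential(10, 20)
        with pytest.raises(ValueError, match="const_cov"):
            ss.cox_fit(pd.DataFrame({"const_cov": np.ones(20)}), t, np.ones(20, dtype=int))

    def test_no_events_rejected(self, rng):
        t = rng.exponential(10, 20)
        with pytest.raises(ValueError, match="event"):
            ss.cox_fit(pd.DataFrame({"x": rng.normal(size=20)}), t, np.zeros(20, dtype=int))

    def test_ci_coverage(self, rng):
        """95% Wald CI contains the true HR=2 in >= 90% of simulated cohorts."""
        covered = 0
        n_rep = 120
        for _ in range(n_rep):
            x, t, e = exp_ph_cohort(300, beta=np.log(2.0), rng=rng)
            fit = ss.cox_fit(pd.DataFrame({"x": x}), t, e)
            covered += fit.ci_low[0] <= 2.0 <= fit.ci_high[0]
        assert covered / n_rep >= 0.90


class TestBackwardSelect:
    def make_data(self, rng, n=800):
        x1 = rng.normal(size=n)          # true effect
        x2 = (rng.uniform(size=n) < 0.5).astype(float)  # true effect
        noise = rng.normal(size=n)       # no effect
        lp = 0.7 * x1 + 0.8 * x2
        t = rng.exponential(1.0 / (0.1 * np.exp(lp)))
        c = rng.uniform(0, np.quantile(t, 0.9) * 2, n)
        e = (t <= c).astype(int)
        return pd.DataFrame({"x1": x1, "x2": x2, "noise": noise}), np.minimum(t, c), e

    def test_noise_removed_true_kept(self, rng):
        X, t, e = self.make_data(rng)
        fit = ss.backward_select(X, t, e, p_exit=0.05)
        assert set(fit.retained) == {"x1", "x2"}

    def test_all_protected_returns_full_model(self, rng):
        X, t, e = self.make_data(rng, n=200)
        fit = ss.backward_select(X, t, e, protected=("x1", "x2", "noise"))
        assert fit.retained == ["x1", "x2", "noise"]

    def test_p_exit_one_removes_all_unprotected(self, rng):
        X, t, e = self.make_data(rng, n=200)
        fit = ss.backward_select(X, t, e, p_exit=1.0, protected=("x1",))
        assert fit.retained == ["x1"]

    def test_loglik_never_exceeds_full_model(self, rng):
        X, t, e = self.make_data(rng, n=300)
        full = ss.cox_fit(X, t, e)
        sel = ss.backward_select(X, t, e, p_exit=0.05)
        assert sel.loglik <= full.loglik + 1e-8

    def test_protected_must_exist(self, rng):
        X, t, e = self.make_data(rng, n=100)
        with pytest.raises(ValueError, match="absent|not in"):
            ss.backward_select(X, t, e, protected=("missing_var",))


def four_group_cohort(rng, n=400, hr_pp=3.0):
    """Two genes whose +/+ combination carries hr_pp times the hazard."""
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    pp = (a > np.median(a)) & (b > np.median(b))
    t = rng.exponential(1.0 / (0.1 * np.where(pp, hr_pp, 1.0)))
    c = rng.uniform(0, 25, n)
    return a, b, np.minimum(t, c), (t <= c).astype(int)


class TestHelmert:
    def test_null_ci_contains_one(self, rng):
        a, b, t, e = four_group_cohort(rng, hr_pp=1.0)
        res = ss.helmert_analysis(a, b, t, e)
        assert res.contrast_ci[0] <= 1.0 <= res.contrast_ci[1]

    def test_triple_hazard_recovered(self):
        rng = np.random.default_rng(2024)
        a, b, t, e = four_group_cohort(rng, hr_pp=3.0)
        res = ss.helmert_analysis(a, b, t, e)
        assert 2.2 <= res.contrast_hr <= 4.2
        assert res.contrast_ci[0] > 1.0

    def test_gene_order_symmetry(self, rng):
        a, b, t, e = four_group_cohort(rng)
        r1 = ss.helmert_analysis(a, b, t, e)
        r2 = ss.helmert_analysis(b, a, t, e)
        assert r1.contrast_hr == pytest.approx(r2.contrast_hr, rel=1e-6)
        assert r1.contrast_p == pytest.approx(r2.contrast_p, rel=1e-6)

    def test_contrast_equals_group_mean_difference(self, rng):
        """The final coefficient is exactly the +/+ log-hazard minus the mean
        of the other three groups' log-hazards (treatment-coded refit)."""
        a, b, t, e = four_group_cohort(rng)
        res = ss.helmert_analysis(a, b, t, e)
        groups = ss.two_gene_groups(a, b)
        X = pd.DataFrame({
            "g2": (groups == "+/-").astype(float),
            "g3": (groups == "-/+").astype(float),
            "g4": (groups == "+/+").astype(float),
        })
        fit = ss.cox_fit(X, t, e)
        mu = np.array([0.0, fit.beta[0], fit.beta[1], fit.beta[2]])
        expected = mu[3] - mu[:3].mean()
        assert np.log(res.contrast_hr) == pytest.approx(expected, abs=1e-5)

    def test_empty_group_rejected(self, rng):
        a = np.array([1.0, 2.0, 3.0, 4.0] * 5)
        b = a.copy()  # perfectly dependent -> no +/- or -/+ samples
        t = rng.exponential(10, 20)
        with pytest.raises(ValueError, match="sizes"):
            ss.helmert_analysis(a, b, t, np.ones(20, dtype=int))


class TestSignatureScore:
    def make_matrix(self, rng, n_probes=30, n_samples=40):
        vals = rng.normal(8, 2, (n_probes, n_samples))
        return ss.ExpressionMatrix(
            vals, [f"P{i}" for i in range(n_probes)],
            [f"S{j}" for j in range(n_samples)],
            gene_symbols=[f"G{i}" for i in range(n_probes)],
        )

    def test_single_gene_equals_rank_normalized(self, rng):
        m = self.make_matrix(rng)
        score = ss.signature_score(m, ["G3"])
        np.testing.assert_allclose(score, ss.rank_normalize(m.probe_values("P3")))

    def test_monotone_invariance(self, rng):
        m = self.make_matrix(rng)
        genes = ["G1", "G2", "G5"]
        s1 = ss.signature_score(m, genes)
        import dataclasses
        m2 = dataclasses.replace(m, values=np.exp(m.values / 4.0))
        np.testing.assert_allclose(s1, ss.signature_score(m2, genes), atol=1e-12)

    def test_missing_genes_tolerated_but_not_all(self, rng):
        m = self.make_matrix(rng)
        score = ss.signature_score(m, ["G1", "NOT_THERE"])
        assert len(score) == m.n_samples
        with pytest.raises(ValueError, match="no signature gene"):
            ss.signature_score(m, ["NOPE1", "NOPE2"])

    def test_iid_signature_scores_span_unit_interval(self, rng):
        m = self.make_matrix(rng, n_probes=60)
        score = ss.signature_score(m, [f"G{i}" for i in range(60)])
        assert score.min() == 0.0 and score.max() == 1.0
        assert 0.4 < np.median(score) < 0.6
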