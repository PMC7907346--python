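"""Likelihood correctness (against a brute-force oracle) and fitting behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize
from scipy.stats import poisson

from tssnmix import (TSSNMixture, ScenarioSpec, choose_K, fit_tss,
                     marginal_loglik, predict_abundance, simulate_dataset)


def brute_loglik(counts, beta0, beta1, alpha0, K):
    """Naive reference: plain nested loops in probability space, no log tricks."""
    p = 1.0 / (1.0 + math.exp(-alpha0))
    total = 0.0
    for i, row in enumerate(counts):
        lam = math.exp(beta0 + beta1 * i)
        s = 0.0
        for n in range(K + 1):
            term = math.exp(-lam) * lam ** n / math.factorial(n)
            for c in row:
                if c > n:
                    term = 0.0
                    break
                term *= (math.comb(n, c) * p ** c * (1.0 - p) ** (n - c))
            s += term
        total += math.log(s)
    return total


class TestMarginalLoglik:
    @pytest.mark.parametrize("counts,beta0,beta1,alpha0,K", [
        ([[0, 0, 0]], math.log(2.0), 0.0, 0.0, 50),
        ([[3]], math.log(3.0), 0.0, 0.5, 40),
        ([[1, 4], [2, 2], [0, 3]], math.log(4.0), 0.1, -0.4, 60),
        ([[5, 2, 7], [1, 0, 3], [4, 4, 4]], 1.2, -0.2, 0.8, 55),
        ([[0, 0], [0, 1]], -1.0, 0.3, -2.0, 45),
    ])
    def test_matches_brute_force_to_ten_digits(self, counts, beta0, beta1,
                                               alpha0, K):
        ours = marginal_loglik(counts, beta0, beta1, alpha0, K)
        ref = brute_loglik(counts, beta0, beta1, alpha0, K)
        assert ours == pytest.approx(ref, rel=1e-11)

    def test_truncation_has_converged(self):
        counts = [[3, 1], [2, 4], [5, 0]]
        m = int(np.max(counts))
        lo = marginal_loglik(counts, 1.5, 0.05, 0.2, 100 * m)
        hi = marginal_loglik(counts, 1.5, 0.05, 0.2, 200 * m)
        assert abs(hi - lo) < 1e-8

    def test_perfect_detection_collapses_to_poisson(self):
        ll = marginal_loglik([[3]], math.log(3.0), 0.0, 30.0, 60)
        assert ll == pytest.approx(poisson.logpmf(3, 3.0), abs=1e-9)

    def test_rejects_K_below_data(self):
        with pytest.raises(ValueError, match="K"):
            marginal_loglik([[5, 2]], 1.0, 0.0, 0.0, 4)

    @given(st.lists(st.lists(st.integers(0, 6), min_size=3, max_size=3),
                    min_size=2, max_size=3),
           st.floats(-1.0, 2.5), st.floats(-0.2, 0.2), st.floats(-2.0, 2.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_survey_order_within_year_is_irrelevant(self, counts, b0, b1, a0):
        arr = np.asarray(counts)
        ll = marginal_loglik(arr, b0, b1, a0, 50)
        perm = arr[:, ::-1]
        assert marginal_loglik(perm, b0, b1, a0, 50) == pytest.approx(ll,
                                                                      rel=1e-12)


class TestLoglikGradient:
    @given(st.lists(st.lists(st.integers(0, 8), min_size=2, max_size=4),
                    min_size=2, max_size=4),
           st.floats(-0.5, 2.5), st.floats(-0.2, 0.2), st.floats(-2.0, 2.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_analytic_gradient_matches_finite_differences(self, counts, b0,
                                                          b1, a0):
        from tssnmix.nmix import _Likelihood
        arr = np.array([row[:2] for row in counts])
        lik = _Likelihood(arr, 60)
        ll, grad = lik.loglik_grad(b0, b1, a0)
        assert ll == pytest.approx(lik.loglik(b0, b1, a0), rel=1e-12)
        x = np.array([b0, b1, a0])
        h = 1e-6
        for k in range(3):
            e = np.zeros(3)
            e[k] = h
            fd = (lik.loglik(*(x + e)) - lik.loglik(*(x - e))) / (2 * h)
            assert grad[k] == pytest.approx(fd, rel=1e-5, abs=1e-6)


class TestChooseK:
    @pytest.mark.parametrize("counts,expected", [
        ([[0, 0], [0, 0]], 100),
        ([[37, 2], [1, 5]], 137),
    ])
    def test_rule(self, counts, expected):
        assert choose_K(counts) == expected

    def test_invariant_to_permutations(self, rng):
        counts = rng.integers(0, 30, size=(5, 4))
        shuffled = rng.permutation(counts.ravel()).reshape(4, 5)
        assert choose_K(counts) == choose_K(shuffled)


class TestFitTss:
    def test_parameter_recovery_favorable(self, favorable_scenario):
        """Median estimates near truth at N=100, p=0.7, 20y x 5s (200 reps),
        fitted with a truncation bound adequate for the growing abundance."""
        t_hats, n_hats = [], []
        for r in range(200):
            ds = simulate_dataset(favorable_scenario, r)
            fit = fit_tss(ds.counts, K="adaptive")
            if fit.converged:
                t_hats.append(fit.t_hat)
                n_hats.append(fit.n_hat)
        assert len(t_hats) >= 190
        assert abs(np.median(t_hats) - 0.1) < 0.01
        assert 0.9 <= np.median(n_hats) / 100 <= 1.1

    def test_mle_dominates_truth(self, favorable_scenario):
        """The maximised log-likelihood is at least that of the generator values."""
        for r in range(10):
            ds = simulate_dataset(favorable_scenario, r)
            fit = fit_tss(ds.counts)
            assert fit.converged
            ll_truth = marginal_loglik(ds.counts, math.log(100), 0.1,
                                       math.log(0.7 / 0.3), fit.K)
            assert fit.loglik >= ll_truth - 1e-6

    def test_truncation_stable_estimates(self, favorable_fit):
        ds, fit = favorable_fit
        refit = fit_tss(ds.counts, K=2 * fit.K)
        assert abs(refit.beta0_hat - fit.beta0_hat) < 1e-4
        assert abs(refit.beta1_hat - fit.beta1_hat) < 1e-4
        assert abs(refit.alpha0_hat - fit.alpha0_hat) < 1e-3

    def test_nominal_coverage_in_easy_stable_scenario(self):
        """95% CI for initial abundance covers the truth in >= 90% of 500
        stable-population datasets at N=100, p=0.7, 20y x 5s."""
        sc = ScenarioSpec(trend_coeff=0.0, initial_abundance=100, n_years=20,
                          n_surveys=5, detection_prob=0.7, n_reps=500,
                          base_seed=2718)
        hits = total = 0
        for r in range(500):
            fit = fit_tss(simulate_dataset(sc, r).counts)
            if fit.converged:
                total += 1
                hits += fit.n_hat_ci[0] <= 100 <= fit.n_hat_ci[1]
        assert total >= 475
        assert hits / total >= 0.90

    def test_constant_counts_profile_to_observed_level(self):
        """With every cell equal to c and detection pinned near 1, the
        abundance intercept maximises at log(c) with a flat trend."""
        c, a0 = 7, 8.0
        counts = np.full((6, 3), c)

        def nll(x):
            return -marginal_loglik(counts, x[0], x[1], a0, 80)

        res = optimize.minimize(nll, [math.log(5.0), 0.05], method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10})
        assert res.x[0] == pytest.approx(math.log(c), abs=1e-3)
        assert res.x[1] == pytest.approx(0.0, abs=1e-3)

    def test_all_zero_counts_reports_nonconvergence(self):
        fit = fit_tss(np.zeros((5, 3), dtype=int))
        assert not fit.converged
        assert fit.reason == "all_zero_counts"

    def test_fit_invariants(self, favorable_fit):
        _, fit = favorable_fit
        assert fit.n_hat == pytest.approx(math.exp(fit.beta0_hat))
        assert fit.n_hat_ci[0] >= 0
        assert 0 <= fit.p_hat <= 1
        assert fit.n_hat_ci[0] <= fit.n_hat <= fit.n_hat_ci[1]
        assert fit.t_hat_ci[0] <= fit.t_hat <= fit.t_hat_ci[1]
        assert fit.p_hat_ci[0] <= fit.p_hat <= fit.p_hat_ci[1]
        assert np.isfinite(fit.loglik)

    def test_json_roundtrip(self, favorable_fit, tmp_path):
        from tssnmix import TssFit
        _, fit = favorable_fit
        path = tmp_path / "fit.json"
        fit.to_json(path)
        back = TssFit.from_json(path)
        assert back.beta0_hat == pytest.approx(fit.beta0_hat)
        assert np.allclose(back.vcov, fit.vcov)
        assert back.n_hat_ci == pytest.approx(fit.n_hat_ci)


class TestPredictAbundance:
    def test_year_one_is_n_hat(self, favorable_fit):
        _, fit = favorable_fit
        est, ci = predict_abundance(fit, 1)
        assert est == pytest.approx(fit.n_hat)
        assert ci[0] <= est <= ci[1]

    def test_closed_form_projection(self, favorable_fit):
        _, fit = favorable_fit
        proj = type(fit)(**{**fit.__dict__})
        proj.beta0_hat, proj.beta1_hat = math.log(20.0), 0.1
        est, _ = predict_abundance(proj, 10)
        assert est == pytest.approx(20 * math.exp(0.9), rel=1e-12)

    def test_flat_trend_constant_trajectory(self, favorable_fit):
        _, fit = favorable_fit
        flat = type(fit)(**{**fit.__dict__})
        flat.beta1_hat = 0.0
        vals = [predict_abundance(flat, y)[0] for y in (1, 5, 20)]
        assert vals[0] == pytest.approx(vals[1]) == pytest.approx(vals[2])

    def test_rejects_nonconverged(self, favorable_fit):
        _, fit = favorable_fit
        bad = type(fit)(**{**fit.__dict__})
        bad.converged = False
        with pytest.raises(ValueError):
            predict_abundance(bad, 1)


class TestSklearnSurface:
    def test_get_set_params_clone(self, favorable_scenario):
        from sklearn.base import clone
        est = TSSNMixture(K=700, n_restarts=2)
        assert est.get_params()["K"] == 700
        twin = clone(est)
        ds = simulate_dataset(favorable_scenario, 0)
        est.fit(ds.counts)
        twin.fit(ds.counts)
        assert twin.beta0_ == pytest.approx(est.beta0_)
        assert est.K_ == 700

    def test_predict_trajectory(self, favorable_scenario):
        ds = simulate_dataset(favorable_scenario, 0)
        est = TSSNMixture().fit(ds.counts)
        traj = est.predict()
        assert traj.shape == (20,)
        assert traj[0] == pytest.approx(est.n_hat_)
        est2, ci = est.predict_abundance(3)
        assert ci[0] <= est2 <= ci[1]

    def test_requires_two_years_two_surveys(self):
        with pytest.raises(ValueError):
            TSSNMixture().fit([[1, 2]])
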