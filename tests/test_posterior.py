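import math

import numpy as np
import pytest
from scipy.stats import norm

import banditaqm as baq


def grid_posterior_means(x, prior, n_mu=801, n_tau=800):
    """Independent oracle: posterior means of (mu, tau) by 2-D quadrature."""
    y = np.log(np.asarray(x, float))
    n, ybar = len(y), y.mean()
    ssy = ((y - ybar) ** 2).sum()
    half = 6.0 / math.sqrt(n)  # +-6 posterior sd covers the mu mass
    mus = np.linspace(max(prior.mu_low, ybar - half), min(prior.mu_high, ybar + half), n_mu)
    taus = np.linspace(prior.tau_low + 1e-6, prior.tau_high, n_tau)
    M, T = np.meshgrid(mus, taus, indexing="ij")
    logpost = n / 2 * np.log(T) - T / 2 * (ssy + n * (ybar - M) ** 2)
    w = np.exp(logpost - logpost.max())
    w /= w.sum()
    return float((w * M).sum()), float((w * T).sum())


class TestFitPosterior:
    def test_default_prior_box(self, prior):
        assert (prior.mu_low, prior.mu_high) == (-10.0, 10.0)
        assert (prior.tau_low, prior.tau_high) == (0.0, 5.0)

    def test_constant_data_centers_mu_at_log_one(self, desk_mcmc):
        fit = baq.fit_posterior([1.0] * 100, settings=desk_mcmc, seed=10)
        assert abs(np.median(fit.mu)) < 0.1

    def test_recovers_known_lognormal_and_matches_grid_oracle(self, prior, desk_mcmc):
        rng = np.random.default_rng(7)
        x = rng.lognormal(2.5, 1 / math.sqrt(4.0), 200)
        fit = baq.fit_posterior(x, prior, desk_mcmc, seed=11)
        assert 2.4 < fit.mu.mean() < 2.6
        assert 3.0 < fit.tau.mean() < 5.0
        mu_star, tau_star = grid_posterior_means(x, prior)
        assert fit.mu.mean() == pytest.approx(mu_star, abs=0.02)
        assert fit.tau.mean() == pytest.approx(tau_star, abs=0.1)

    def test_draws_respect_prior_box_and_settings(self, prior, desk_mcmc):
        rng = np.random.default_rng(3)
        fit = baq.fit_posterior(rng.lognormal(2.0, 0.8, 5), prior, desk_mcmc, seed=12)
        assert fit.mu.shape == (desk_mcmc.n_chains, desk_mcmc.n_samples)
        assert np.all((fit.mu >= prior.mu_low) & (fit.mu <= prior.mu_high))
        assert np.all((fit.tau > prior.tau_low) & (fit.tau <= prior.tau_high))

    def test_seed_reproducibility(self, desk_mcmc):
        x = [5.0, 8.0, 12.0]
        a = baq.fit_posterior(x, settings=desk_mcmc, seed=42)
        b = baq.fit_posterior(x, settings=desk_mcmc, seed=42)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.tau, b.tau)

    def test_nonpositive_data_rejected(self, desk_mcmc):
        with pytest.raises(baq.ValidationError):
            baq.fit_posterior([5.0, -1.0], settings=desk_mcmc)
        with pytest.raises(baq.ValidationError):
            baq.fit_posterior([], settings=desk_mcmc)

    def test_data_outside_prior_box_raises_inference_error(self, desk_mcmc):
        # log-data mass far outside the mu box
        with pytest.raises(baq.InferenceError):
            baq.fit_posterior(
                [1e8] * 50, baq.PriorSpec(-10, 10, 0, 5), desk_mcmc, seed=1
            )

    def test_well_mixed_chains_have_rhat_near_one(self, desk_mcmc):
        rng = np.random.default_rng(8)
        fit = baq.fit_posterior(rng.lognormal(2.9, 0.3, 60), settings=desk_mcmc, seed=13)
        rhat = fit.rhat()
        assert rhat["mu"] < 1.05 and rhat["tau"] < 1.05


class TestGelmanRubin:
    def test_identical_chains_give_unity(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=5000)
        r = baq.gelman_rubin(np.vstack([chain, chain, chain]))
        assert r == pytest.approx(1.0, abs=0.01)

    def test_iid_normal_chains_converge(self):
        rng = np.random.default_rng(1)
        r = baq.gelman_rubin(rng.normal(size=(3, 5000)))
        assert r < 1.05

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(size=(2, 1000))
        draws[1] += 10.0
        assert baq.gelman_rubin(draws) > 1.2

    def test_single_chain_rejected(self):
        with pytest.raises(baq.DiagnosticError):
            baq.gelman_rubin(np.zeros((1, 100)))


class TestPosteriorMeanConcentration:
    def test_variance_zero_limit(self):
        assert baq.posterior_mean_concentration(0.0, 1e12) == pytest.approx(1.0)

    def test_closed_form(self):
        expected = 10 * math.exp(0.25)
        assert baq.posterior_mean_concentration(math.log(10), 2.0) == pytest.approx(
            expected
        )

    def test_monotone_in_mu(self):
        mus = np.linspace(-1, 3, 50)
        vals = baq.posterior_mean_concentration(mus, np.full(50, 2.0))
        assert np.all(np.diff(vals) > 0)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(baq.ValidationError):
            baq.posterior_mean_concentration(0.0, 0.0)


def synthetic_fit(label, mu_draws, tau_draws, chains=3):
    mu = np.asarray(mu_draws, float).reshape(chains, -1)
    tau = np.asarray(tau_draws, float).reshape(chains, -1)
    return baq.PosteriorFit(
        label, mu, tau, baq.PriorSpec(), baq.McmcSettings(chains, mu.shape[1], 0), 0
    )


class TestSuccessProbabilities:
    def test_exchangeable_arms_split_evenly(self, desk_mcmc):
        x = np.random.default_rng(4).lognormal(2.8, 0.4, 80)
        fits = {
            t: baq.fit_posterior(x, settings=desk_mcmc, seed=99, treatment_id=t)
            for t in "ABC"
        }
        probs = baq.success_probabilities(fits)
        # identical data + identical seeds -> identical draws -> exact 3-way ties
        assert probs == {"A": pytest.approx(1 / 3), "B": pytest.approx(1 / 3),
                         "C": pytest.approx(1 / 3)}

    def test_simplex_with_tie_splitting(self, rng):
        n = 3000
        fits = {
            "A": synthetic_fit("A", rng.normal(2.0, 0.3, n), np.full(n, 3.0)),
            "B": synthetic_fit("B", rng.normal(2.1, 0.3, n), np.full(n, 3.0)),
            "C": synthetic_fit("C", rng.normal(2.2, 0.3, n), np.full(n, 3.0)),
        }
        probs = baq.success_probabilities(fits)
        assert abs(sum(probs.values()) - 1.0) < 1e-9
        assert all(p >= 0 for p in probs.values())

    def test_two_arm_matches_closed_form_normal_comparison(self, rng):
        n = 30000
        fits = {
            "a": synthetic_fit("a", rng.normal(2.0, 0.1, n), np.full(n, 2.0)),
            "b": synthetic_fit("b", rng.normal(2.2, 0.1, n), np.full(n, 2.0)),
        }
        # equal pinned tau: argmin on the natural mean reduces to argmin on mu
        expected = norm.cdf(0.2 / (0.1 * math.sqrt(2)))
        se = math.sqrt(expected * (1 - expected) / n)
        probs = baq.success_probabilities(fits)
        assert probs["a"] == pytest.approx(expected, abs=3 * se)

    def test_agrees_with_brute_force_tally(self, rng):
        n = 600
        fits = {
            t: synthetic_fit(t, rng.normal(m, 0.4, n), rng.uniform(1, 5, n))
            for t, m in [("A", 2.4), ("B", 2.6), ("C", 2.5)]
        }
        probs = baq.success_probabilities(fits)
        # brute force: per aligned draw, tally argmin of exp(mu + 1/(2 tau))
        tally = {t: 0.0 for t in fits}
        cols = {t: np.exp(f.stacked()[0] + 0.5 / f.stacked()[1]) for t, f in fits.items()}
        for i in range(n):
            vals = {t: cols[t][i] for t in fits}
            m = min(vals.values())
            winners = [t for t, v in vals.items() if v == m]
            for t in winners:
                tally[t] += 1 / len(winners)
        for t in fits:
            assert probs[t] == pytest.approx(tally[t] / n, abs=1e-12)

    def test_stochastic_dominance_under_data_shift(self, desk_mcmc):
        rng = np.random.default_rng(17)
        base = rng.lognormal(2.5, 0.3, 40)
        other = rng.lognormal(2.7, 0.3, 40)
        p_lo = baq.success_probabilities(
            baq.fit_posteriors({"A": base, "B": other}, settings=desk_mcmc, seed=21)
        )
        p_hi = baq.success_probabilities(
            baq.fit_posteriors({"A": base * 1.5, "B": other}, settings=desk_mcmc, seed=21)
        )
        assert p_hi["A"] <= p_lo["A"]

    def test_mismatched_draw_counts_rejected(self, rng):
        fits = {
            "A": synthetic_fit("A", rng.normal(2, 0.1, 300), np.full(300, 2.0)),
            "B": synthetic_fit("B", rng.normal(2, 0.1, 600), np.full(600, 2.0)),
        }
        with pytest.raises(baq.ValidationError, match="mismatched"):
            baq.success_probabilities(fits)

    def test_compare_on_log_mu_and_predictive(self, rng):
        n = 3000
        fits = {
            "A": synthetic_fit("A", rng.normal(2.0, 0.1, n), np.full(n, 2.0)),
            "B": synthetic_fit("B", rng.normal(2.6, 0.1, n), np.full(n, 2.0)),
        }
        assert baq.success_probabilities(fits, "log_mu")["A"] > 0.99
        p = baq.success_probabilities(
            fits, "predictive_draw", rng=np.random.default_rng(0)
        )
        assert abs(sum(p.values()) - 1.0) < 1e-9
        with pytest.raises(baq.ValidationError):
            baq.success_probabilities(fits, "predictive_draw")


class TestCoverage:
    def test_posterior_intervals_cover_truth_at_near_nominal_rate(self, prior, desk_mcmc):
        """95% central intervals over a grid of true (mu, tau) at n = 200."""
        rng = np.random.default_rng(31)
        hits_mu = hits_tau = trials = 0
        for mu_star in (1.0, 2.5):
            for tau_star in (1.0, 4.0):
                for rep in range(10):
                    x = rng.lognormal(mu_star, 1 / math.sqrt(tau_star), 200)
                    fit = baq.fit_posterior(
                        x, prior, desk_mcmc, seed=rng.integers(2**31)
                    )
                    lo, hi = np.quantile(fit.mu, [0.025, 0.975])
                    hits_mu += lo <= mu_star <= hi
                    lo, hi = np.quantile(fit.tau, [0.025, 0.975])
                    hits_tau += lo <= tau_star <= hi
                    trials += 1
        # 3 binomial se below nominal for 40 trials at 0.95
        assert hits_mu / trials >= 0.85
        assert hits_tau / trials >= 0.85
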