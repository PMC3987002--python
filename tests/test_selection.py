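"""NMIG spike-and-slab sampler: conditionals, recovery, and summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from spatsel import (
    MCMCSettings,
    ModelTerm,
    NMIGHyperparams,
    SpikeSlabLogisticRegression,
    conditional_eta_probability,
    fit_ssvs_logistic,
    inclusion_summary,
    modal_model,
    sample_tau2_conditional,
)
from conftest import make_strong_effect_data


class TestEtaConditional:
    def test_hand_computed_density_ratio_at_zero(self):
        # at beta = 0 the ratio reduces to sqrt(v0) / (1 + sqrt(v0))
        v0 = 0.00025
        expected = math.sqrt(v0) / (1.0 + math.sqrt(v0))
        got = conditional_eta_probability(0.0, 1.0, 0.5, v0)
        assert got == pytest.approx(expected, abs=1e-10)
        assert got == pytest.approx(0.01556, abs=1e-5)

    def test_matches_explicit_density_ratio(self):
        # independent oracle: normal pdfs evaluated directly
        beta, tau2, w, v0 = 0.8, 2.0, 0.3, 0.005
        num = w * stats.norm.pdf(beta, 0, math.sqrt(tau2))
        den = num + (1 - w) * stats.norm.pdf(beta, 0, math.sqrt(v0 * tau2))
        assert conditional_eta_probability(beta, tau2, w, v0) == pytest.approx(
            num / den, abs=1e-12)

    def test_large_effect_forces_slab(self):
        assert conditional_eta_probability(50.0, 1.0, 0.5, 0.00025) == pytest.approx(1.0)

    def test_degenerate_weights(self):
        assert conditional_eta_probability(0.3, 1.0, 1.0, 0.00025) == 1.0
        assert conditional_eta_probability(0.3, 1.0, 0.0, 0.00025) == 0.0

    @settings(derandomize=True, max_examples=40)
    @given(st.floats(0.0, 5.0), st.floats(0.0, 5.0),
           st.floats(0.05, 0.95), st.floats(0.05, 0.95))
    def test_monotone_in_beta_and_w(self, b1, b2, w1, w2):
        lo_b, hi_b = sorted((b1, b2))
        lo_w, hi_w = sorted((w1, w2))
        assert (conditional_eta_probability(hi_b, 1.0, 0.5, 0.00025)
                >= conditional_eta_probability(lo_b, 1.0, 0.5, 0.00025))
        assert (conditional_eta_probability(0.5, 1.0, hi_w, 0.00025)
                >= conditional_eta_probability(0.5, 1.0, lo_w, 0.00025))

    def test_invalid_tau2_rejected(self):
        with pytest.raises(ValueError):
            conditional_eta_probability(0.0, 0.0, 0.5, 0.00025)


class TestTau2Conditional:
    def test_ks_against_direct_inverse_gamma(self):
        # the Gibbs draw must match IG(a + q/2, b + beta^2/(2 eta))
        rng = np.random.default_rng(0)
        beta, eta, a, b = 0.7, 1.0, 5.0, 25.0
        draws = np.array([
            sample_tau2_conditional(rng, beta, eta, a, b) for _ in range(5000)
        ])
        shape = a + 0.5
        scale = b + beta ** 2 / 2.0
        ks = stats.kstest(draws, stats.invgamma(shape, scale=scale).cdf)
        assert ks.pvalue > 0.01

    def test_spike_state_inflates_scale(self):
        rng = np.random.default_rng(1)
        slab = np.median([sample_tau2_conditional(rng, 1.0, 1.0, 5, 25)
                          for _ in range(500)])
        spike = np.median([sample_tau2_conditional(rng, 1.0, 0.00025, 5, 25)
                           for _ in range(500)])
        assert spike > slab


class TestSampler:
    def test_strong_effect_recovered_nulls_excluded(self):
        probs_true, probs_null = [], []
        for seed in (0, 1, 2):
            X, y = make_strong_effect_data(seed, n=200, p=5, beta=2.0)
            est = SpikeSlabLogisticRegression(
                n_iter=1200, burn_in=400, thin=2, n_chains=1, random_state=seed
            ).fit(X, y)
            p = est.inclusion_probabilities_
            probs_true.append(p["x0"])
            probs_null.append(p[["x1", "x2", "x3", "x4"]].median())
        assert np.mean(probs_true) >= 0.5
        assert np.median(probs_null) < 0.5

    def test_global_null_prefers_null_or_intercept_only_model(self):
        hits = 0
        for seed in (0, 1, 2):
            rng = np.random.default_rng(100 + seed)
            X = pd.DataFrame(rng.standard_normal((150, 5)),
                             columns=[f"x{i}" for i in range(5)])
            y = rng.binomial(1, 0.475, 150)
            est = SpikeSlabLogisticRegression(
                n_iter=1200, burn_in=400, thin=2, n_chains=1,
                random_state=seed,
            ).fit(X, y)
            modal = modal_model(est.samples_)
            hits += modal <= {"random_intercept"}
        assert hits >= 2

    def test_flat_prior_posterior_matches_mle(self):
        # fixed large prior variance, no selection, no random intercept:
        # posterior mean must sit at the ML estimate up to MCMC error
        X, y = make_strong_effect_data(7, n=400, p=1, beta=1.0)
        terms = [ModelTerm(name="x0", columns=["x0"], selectable=False,
                           prior_variance=100.0)]
        est = SpikeSlabLogisticRegression(
            terms=terms, random_intercept=False, n_iter=3000, burn_in=1000,
            thin=2, n_chains=1, random_state=0,
        ).fit(X, y)
        import statsmodels.api as sm

        z = (X - X.mean()) / X.std(ddof=0)
        mle = sm.Logit(y, sm.add_constant(z)).fit(disp=0).params
        got = est.samples_.beta.mean(axis=0)
        assert got["x0"] == pytest.approx(mle["x0"], abs=0.15)
        assert got["(Intercept)"] == pytest.approx(mle["const"], abs=0.15)

    def test_prior_predictive_inclusion_matches_beta_mean(self):
        # with the likelihood disabled, P(eta=1) = E[w] = a_w / (a_w + b_w)
        X = pd.DataFrame(np.random.default_rng(0).standard_normal((30, 3)),
                         columns=["a", "b", "c"])
        est = SpikeSlabLogisticRegression(
            prior_only=True, random_intercept=False, a_w=1.0, b_w=1.0,
            n_iter=6000, burn_in=1000, thin=1, n_chains=1, random_state=5,
        ).fit(X, np.zeros(30))
        marginal = est.samples_.inclusion_indicators().to_numpy().mean()
        assert marginal == pytest.approx(0.5, abs=0.06)

    def test_deterministic_given_seed(self):
        X, y = make_strong_effect_data(3, n=60)
        kw = dict(n_iter=200, burn_in=100, thin=1, n_chains=2, random_state=42)
        a = SpikeSlabLogisticRegression(**kw).fit(X, y)
        b = SpikeSlabLogisticRegression(**kw).fit(X, y)
        pd.testing.assert_frame_equal(a.samples_.beta, b.samples_.beta)
        pd.testing.assert_frame_equal(a.samples_.eta, b.samples_.eta)

    def test_recorded_draw_bookkeeping(self):
        X, y = make_strong_effect_data(4, n=60)
        est = SpikeSlabLogisticRegression(
            n_iter=250, burn_in=50, thin=4, n_chains=2, random_state=0
        ).fit(X, y)
        s = est.samples_
        assert s.n_draws == 2 * len(range(50, 250, 4))
        assert set(np.unique(s.eta.to_numpy())) <= {0.00025, 1.0}
        assert np.all(np.isfinite(s.beta.to_numpy()))
        flat = s.to_frame()
        assert {"iteration", "chain", "parameter", "value"} == set(flat.columns)

    def test_input_validation(self):
        X, y = make_strong_effect_data(5, n=30)
        with pytest.raises(ValueError, match="binary"):
            SpikeSlabLogisticRegression(n_iter=10, burn_in=1).fit(X, y + 0.5)
        with pytest.raises(ValueError):
            SpikeSlabLogisticRegression(n_iter=0, burn_in=0).fit(X, y)
        with pytest.raises(ValueError, match="constant"):
            Xc = X.copy()
            Xc["x0"] = 1.0
            SpikeSlabLogisticRegression(n_iter=10, burn_in=1).fit(Xc, y)

    def test_functional_frontend_and_smooth_terms(self):
        X, y = make_strong_effect_data(6, n=120, p=2, beta=1.5)
        terms = [
            ModelTerm(name="x0", design=X[["x0"]]),
            ModelTerm(name="f(x1)", kind="smooth", design=X[["x1"]]),
            ModelTerm(name="random_intercept", kind="random_intercept"),
        ]
        samples = fit_ssvs_logistic(
            y, terms, hyper=NMIGHyperparams(),
            mcmc=MCMCSettings(n_iter=400, burn_in=200, thin=2, n_chains=1, seed=0),
        )
        assert set(samples.eta.columns) == {"x0", "f(x1)", "random_intercept"}
        # the smooth block shares one indicator across its basis columns
        assert len(samples.term_slices["f(x1)"]) > 1


class TestInclusionSummary:
    @staticmethod
    def _samples_with_probs(prob_by_term, coef=2.844, coef_sd=2.0, n=2000):
        rng = np.random.default_rng(0)
        eta = pd.DataFrame({
            t: np.where(rng.random(n) < p, 1.0, 0.00025)
            for t, p in prob_by_term.items()
        })
        beta = pd.DataFrame({
            "(Intercept)": np.zeros(n),
            **{t: coef + coef_sd * rng.standard_normal(n)
               for t in prob_by_term},
        })
        from spatsel.selection import PosteriorSamples

        return PosteriorSamples(
            beta=beta, eta=eta, tau2=eta * 0 + 1.0, w=np.full(n, 0.5),
            gamma=np.empty((n, 0)), tau_gamma=np.ones(n),
            chain=np.zeros(n, dtype=int),
            term_slices={t: np.array([i + 1]) for i, t in
                         enumerate(prob_by_term)},
            settings=MCMCSettings(n_iter=n, burn_in=0, thin=1, n_chains=1),
            hyper=NMIGHyperparams(),
        )

    def test_included_term_with_positive_interval_is_starred(self):
        s = self._samples_with_probs({"Pb": 0.61}, coef=2.844, coef_sd=0.5)
        summ = inclusion_summary(s)
        row = summ.table.loc["Pb"]
        assert row["classification"] == "included"
        assert row["ci_lo"] > 0
        assert row["well_estimated"]
        assert "Pb" in summ.to_text()

    def test_reported_band(self):
        s = self._samples_with_probs({"Educ": 0.334})
        row = inclusion_summary(s).table.loc["Educ"]
        assert row["classification"] == "reported"
        assert math.isnan(row["coef_mean"])

    def test_excluded_band(self):
        s = self._samples_with_probs({"x": 0.20})
        assert inclusion_summary(s).table.loc["x", "classification"] == "excluded"

    def test_threshold_tie_counts_as_included(self):
        from spatsel.selection import PosteriorSamples

        eta = pd.DataFrame({"x": [1.0, 0.00025] * 5})
        s = self._samples_with_probs({"x": 0.5})
        s.eta = eta
        assert inclusion_summary(s).table.loc["x", "classification"] == "included"
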