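"""Coupled ageing x growth model: joint density, recovery, prediction."""

import numpy as np
import pytest

from otogrowth.ageing import AgeingParams, derive_age_draws
from otogrowth.coupled import (GROWTH_PARAM_NAMES, assemble_coupled_model, fit_growth,
                               posterior_predict_length)
from otogrowth.growth import DAYS_PER_YEAR, GrowthParams, YFT_MODAL_PARAMS, vb_logk_length
from otogrowth.mcmc import PosteriorDraws, credible_interval, run_mcmc
from otogrowth.priors import default_priors
from otogrowth.simulate import simulate_tagging_dataset, traditional_age

from .conftest import deposition_informed_priors


def small_sensitivity_dataset(n_classes=30, seed=0, ageing=None):
    """Reduced tagging design: fewer, wider length classes for fast fits."""
    ageing = ageing or AgeingParams(rho=0.939, b_n=-2.5, b_e=-0.54, p=0.10)
    width = 126.0 / n_classes
    return simulate_tagging_dataset(ageing=ageing, class_width=width, per_class=1,
                                    n_readings=3, seed=seed)


class TestModelAssembly:
    def test_log_joint_equals_component_sum(self):
        """Joint log density = ageing prior + growth prior + likelihood terms."""
        recs, reads, _ = small_sensitivity_dataset(seed=1)
        priors = deposition_informed_priors()
        model = assemble_coupled_model(recs, reads, priors, mode="coupled")
        params = {"rho": 0.94, "b_n": -2.0, "b_e": -0.5, "p": 0.1, "linf": 150.0,
                  "k1": 0.25, "delta": 2.5, "alpha": 2.6, "beta": 12.0, "t0": -0.4,
                  "sigma_l": 8.8}
        latents = {"n": model.latent_blocks[0].init.copy()}
        total = model.log_prior(params) + model.unit_terms(params, latents).sum()
        manual = sum(priors[n].logpdf(params[n]) for n in params)
        a_tag, a_rec, _ = model.resolve_ages(latents, params)
        for sec, (idx, obs) in model.data.sections.items():
            mu = params["rho"] * a_rec[idx] + params["b_n"] + params["b_e"]
            manual += np.sum(-0.5 * np.log(2 * np.pi) - np.log(params["p"] * mu)
                             - 0.5 * ((obs - mu) / (params["p"] * mu)) ** 2)
        g = GrowthParams(linf=150.0, k1=0.25, delta=2.5, alpha=2.6, beta=12.0,
                         t0=-0.4, sigma_l=8.8)
        lens = np.array([f.length_rec for f in model.data.fish])
        mu_l = vb_logk_length(a_rec / DAYS_PER_YEAR, g)
        manual += np.sum(-0.5 * np.log(2 * np.pi * 8.8**2)
                         - 0.5 * ((lens - mu_l) / 8.8) ** 2)
        assert total == pytest.approx(manual, rel=1e-12)

    def test_classical_no_fish_is_prior_only(self):
        priors = default_priors()
        model = assemble_coupled_model([], priors=priors, mode="classical",
                                       ages_days=np.empty(0), fixed={"beta": 12.583})
        draws = fit_growth(model, n_chains=2, n_keep=3000, burn=500, seed=1)
        x = draws.pooled("t0")  # uniform(-3, 0) prior must come back
        grid = np.linspace(0.05, 0.95, 10)
        assert np.max(np.abs(np.quantile(x, grid) - (-3 + 3 * grid))) < 0.12

    def test_parameter_count_bookkeeping(self):
        recs, reads, _ = small_sensitivity_dataset(seed=2)
        model = assemble_coupled_model(recs, reads, deposition_informed_priors(),
                                       mode="coupled")
        assert len(model.param_blocks) == 4 + 7  # ageing + growth
        assert model.latent_blocks[0].init.size == len(recs)

    def test_modes_require_their_inputs(self):
        recs, reads, _ = small_sensitivity_dataset(seed=3)
        with pytest.raises(ValueError):
            assemble_coupled_model(recs, None, mode="coupled")
        with pytest.raises(ValueError):
            assemble_coupled_model(recs, mode="classical")
        with pytest.raises(ValueError):
            assemble_coupled_model(recs, reads, mode="sideways")


def recovery_consistent_priors():
    """Deposition-informed rho/b_e plus a GEV asymptotic-length prior fitted
    to maxima consistent with the generating curve (well-specified setting;
    the deliberate prior-data conflict of the sensitivity study is exercised
    separately in the acceptance suite)."""
    from otogrowth.priors import GEVParams, default_priors
    from otogrowth.simulate import simulate_length_maxima

    mx = simulate_length_maxima(GEVParams(loc=142.0, scale=9.0, shape=-0.1), seed=77)
    return default_priors(
        overrides={"rho": {"family": "trunc_normal", "mean": 0.939, "sd": 0.029,
                           "lo": 0.5, "hi": 1.5},
                   "b_e": {"family": "trunc_normal", "mean": -0.549, "sd": 2.469,
                           "lo": -20.0, "hi": 20.0}},
        maxima=mx["max_fork_length_cm"].values)


class TestParameterRecovery:
    def test_true_values_inside_credible_intervals(self):
        """Fits to data from known parameters: each free parameter's 95%
        interval covers its generating value in >=85% of scaled-down
        replicates."""
        truth = {"rho": 0.939, "b_n": -2.5, "b_e": -0.54, "p": 0.10,
                 "linf": YFT_MODAL_PARAMS.linf, "k1": YFT_MODAL_PARAMS.k1,
                 "delta": YFT_MODAL_PARAMS.delta, "alpha": YFT_MODAL_PARAMS.alpha,
                 "t0": YFT_MODAL_PARAMS.t0, "sigma_l": YFT_MODAL_PARAMS.sigma_l}
        n_rep = 20
        covered = {n: 0 for n in truth}
        priors = recovery_consistent_priors()
        for rep in range(n_rep):
            recs, reads, _ = small_sensitivity_dataset(n_classes=40, seed=100 + rep)
            model = assemble_coupled_model(recs, reads, priors,
                                           mode="coupled", fixed={"beta": 12.583})
            draws = fit_growth(model, n_chains=2, n_keep=1000, burn=3000, thin=2,
                               seed=rep, keep_latents=False)
            for n, tv in truth.items():
                lo, hi = credible_interval(draws.pooled(n))
                covered[n] += lo <= tv <= hi
        for n, hits in covered.items():
            assert hits >= int(0.85 * n_rep), (n, hits, covered)

    def test_posterior_contraction_with_sample_size(self):
        """Doubling the number of fish shrinks the posterior sd of k1 on average."""
        sds = {30: [], 60: []}
        for n_classes in sds:
            for rep in range(3):
                recs, reads, _ = small_sensitivity_dataset(n_classes=n_classes,
                                                           seed=300 + rep)
                model = assemble_coupled_model(recs, reads,
                                               deposition_informed_priors(),
                                               mode="coupled", fixed={"beta": 12.583})
                draws = fit_growth(model, n_chains=2, n_keep=600, burn=1200,
                                   seed=rep, keep_latents=False)
                sds[n_classes].append(np.std(draws.pooled("k1")))
        assert np.mean(sds[60]) < np.mean(sds[30])


class TestClassicalEquivalence:
    def test_error_free_ages_match_coupled_low_noise_fit(self):
        """Classical fit on exact ages ~ coupled fit when reading noise -> 0."""
        ageing = AgeingParams(rho=1.0, b_n=-1e-6, b_e=0.0, p=0.002)
        recs, reads, truth = small_sensitivity_dataset(n_classes=40, seed=7,
                                                       ageing=ageing)
        priors = default_priors(overrides={
            "rho": {"family": "trunc_normal", "mean": 1.0, "sd": 1e-5,
                    "lo": 0.5, "hi": 1.5},
            "b_n": {"family": "trunc_normal", "mean": -1e-6, "sd": 1e-6,
                    "lo": -15.0, "hi": 0.0},
            "b_e": {"family": "trunc_normal", "mean": 0.0, "sd": 1e-6,
                    "lo": -20.0, "hi": 20.0},
            "p": {"family": "uniform", "lo": 1e-4, "hi": 0.01},
        })
        coupled = assemble_coupled_model(recs, reads, priors, mode="coupled",
                                         fixed={"beta": 12.583})
        dc = fit_growth(coupled, n_chains=2, n_keep=1200, burn=1500, seed=8,
                        keep_latents=False)
        classical = assemble_coupled_model(
            recs, priors=priors, mode="classical",
            ages_days=truth["age_days"], fixed={"beta": 12.583})
        dk = fit_growth(classical, n_chains=2, n_keep=1200, burn=1500, seed=9)
        # compare the identified quantities; raw delta is a ridge coordinate
        # (delta x k1 trade-off) whose mean is dominated by Monte Carlo error
        for name in ("linf", "k1", "k2", "t0"):
            a, b = dc.pooled(name), dk.pooled(name)
            tol = 0.35 * max(a.std(), b.std())
            assert abs(a.mean() - b.mean()) < max(tol, 0.02 * abs(b.mean())), name


class TestPosteriorPrediction:
    def _degenerate_draws(self, sigma_l):
        g = YFT_MODAL_PARAMS.replace(sigma_l=sigma_l)
        params = {n: np.full((1, 200), getattr(g, n)) for n in GROWTH_PARAM_NAMES}
        return PosteriorDraws(params=params)

    def test_degenerate_draws_reproduce_curve(self):
        draws = self._degenerate_draws(sigma_l=1e-9)
        out = posterior_predict_length(draws, age=2.0, n_samples=100, seed=1)
        assert np.allclose(out["samples"], vb_logk_length(2.0, YFT_MODAL_PARAMS),
                           atol=1e-6)
        assert out["n_rejected"] == 0

    def test_predictive_variance_exceeds_curve_variance(self):
        rng = np.random.default_rng(2)
        params = {n: np.full((1, 500), getattr(YFT_MODAL_PARAMS, n))
                  for n in GROWTH_PARAM_NAMES}
        params["linf"] = params["linf"] + rng.normal(0, 5.0, (1, 500))
        draws = PosteriorDraws(params=params)
        out = posterior_predict_length(draws, age=3.0, n_samples=2000, seed=3)
        flat = {n: draws.params[n].reshape(-1) for n in GROWTH_PARAM_NAMES}
        curve = [vb_logk_length(3.0, GrowthParams(**{k: flat[k][j] for k in flat}))
                 for j in range(500)]
        assert np.var(out["samples"]) >= np.var(curve)

    def test_predictive_mean_matches_curve_mean(self):
        draws = self._degenerate_draws(sigma_l=8.809)
        out = posterior_predict_length(draws, age=2.0, n_samples=8000, seed=4)
        mu = vb_logk_length(2.0, YFT_MODAL_PARAMS)
        se = 8.809 / np.sqrt(8000)
        assert np.mean(out["samples"]) == pytest.approx(mu, abs=4 * se)

    def test_ages_below_t0_rejected_and_counted(self):
        draws = self._degenerate_draws(sigma_l=1.0)
        out = posterior_predict_length(draws, age=-1.0, n_samples=50, seed=5)
        assert out["n_rejected"] == 50
        assert out["samples"].size == 0

    def test_missing_growth_parameter_rejected(self):
        draws = PosteriorDraws(params={"linf": np.full((1, 100), 150.0)})
        with pytest.raises(ValueError):
            posterior_predict_length(draws, age=2.0)
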