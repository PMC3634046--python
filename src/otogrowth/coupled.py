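"""Coupled ageing-error x VB-logK growth model and posterior prediction.

The joint posterior factorises as

    [theta_A, p, theta_G, ages | counts, lengths]
        proportional to  pi(theta_A) pi(p) pi(theta_G)
                       x [counts | ages, theta_A, p]     (reading model)
                       x [lengths | ages, theta_G]       (Gaussian curve likelihood)

with the ageing parameters theta_A = {rho, b_n, b_e} and growth parameters
theta_G = {linf, k1, delta, alpha, beta, t0, sigma_l} independent a priori.
Latent ages (days) are shared between the two submodels, which is how
reading uncertainty propagates into growth estimates.

In *classical* mode the ages are fixed point estimates (e.g. the
traditional mean-count ages) and only theta_G is sampled.
"""

from __future__ import annotations

import numpy as np

from .ageing import AgeEstimationModel, FishRecord, _norm_logpdf
from .growth import DAYS_PER_YEAR, GrowthParams, vb_logk_length
from .mcmc import ParamBlock, PosteriorDraws, run_mcmc
from .priors import PriorConfig, default_priors

__all__ = [
    "CoupledModel",
    "ClassicalGrowthModel",
    "assemble_coupled_model",
    "fit_growth",
    "posterior_predict_length",
    "growth_params_from_draw",
]

GROWTH_PARAM_NAMES = ("linf", "k1", "delta", "alpha", "beta", "t0", "sigma_l")

_GROWTH_INIT = {"linf": 150.0, "k1": 0.3, "delta": 2.5, "alpha": 2.5, "beta": 10.0,
                "t0": -0.5, "sigma_l": 8.0}
_GROWTH_SCALE = {"linf": 3.0, "k1": 0.02, "delta": 0.2, "alpha": 0.1, "beta": 1.0,
                 "t0": 0.05, "sigma_l": 0.3}


def _growth_blocks(priors: PriorConfig, fixed: dict) -> list[ParamBlock]:
    blocks = []
    for name in GROWTH_PARAM_NAMES:
        if name in fixed:
            continue
        pr = priors[name]
        lo = pr.lo if np.isfinite(pr.lo) else -1e6
        hi = pr.hi if np.isfinite(pr.hi) else 1e6
        init = float(np.clip(_GROWTH_INIT[name], lo + 1e-9, hi - 1e-9))
        blocks.append(ParamBlock(name, lo, hi, init=init, scale=_GROWTH_SCALE[name]))
    return blocks


def _curve_params(params: dict, fixed: dict) -> tuple:
    g = {n: fixed.get(n, params.get(n)) for n in GROWTH_PARAM_NAMES}
    return g


def _length_terms(n, lengths_rec, has_rec, lengths_tag, tag_idx,
                  a_tag, a_rec, g: dict) -> np.ndarray:
    """Per-fish Gaussian log likelihood of observed fork lengths."""
    linf, k1, delta = g["linf"], g["k1"], g["delta"]
    alpha, beta, t0, sigma_l = g["alpha"], g["beta"], g["t0"], g["sigma_l"]
    k2 = delta * k1
    terms = np.zeros(n)

    def curve(age_years):
        s = age_years - t0
        trans = np.logaddexp(0.0, beta * (s - alpha)) - np.logaddexp(0.0, -beta * alpha)
        cum = k1 * s + ((k2 - k1) / beta * trans if beta > 0 else 0.5 * (k2 - k1) * s)
        return linf * (-np.expm1(-cum))

    ay_rec = a_rec / DAYS_PER_YEAR
    bad = ay_rec < t0
    mu = curve(np.where(bad, t0, ay_rec))
    ll = np.where(bad, -np.inf, _norm_logpdf(lengths_rec, mu, sigma_l))
    terms[has_rec] += ll[has_rec]
    if tag_idx.size:
        ay_tag = a_tag[tag_idx] / DAYS_PER_YEAR
        bad = (ay_tag < t0) | ~np.isfinite(ay_tag)
        mu = curve(np.where(bad, t0, ay_tag))
        terms[tag_idx] += np.where(bad, -np.inf, _norm_logpdf(lengths_tag, mu, sigma_l))
    return terms


class CoupledModel(AgeEstimationModel):
    """Ageing-error model extended with the VB-logK length likelihood."""

    def __init__(self, fish, readings, priors: PriorConfig | None = None,
                 deposition_posterior: PosteriorDraws | None = None,
                 fixed: dict | None = None, **kw):
        priors = priors if priors is not None else default_priors()
        super().__init__(fish, readings, priors, deposition_posterior, **kw)
        self.fixed = dict(fixed or {})
        self.param_blocks = self.param_blocks + _growth_blocks(self.priors, self.fixed)
        f = self.data.fish
        self._lengths_rec = np.array([fi.length_rec for fi in f])
        self._has_rec = np.isfinite(self._lengths_rec)
        self._tag_idx = np.array([i for i, fi in enumerate(f) if fi.length_tag is not None],
                                 dtype=int)
        self._lengths_tag = np.array([fi.length_tag for fi in f if fi.length_tag is not None])
        if not self._has_rec.any() and not self._tag_idx.size:
            raise ValueError("coupled model needs at least one length observation")
        # correlated ridge (rho x growth): sampled jointly with adapted covariance
        self.joint_block = ["rho"] + [n for n in GROWTH_PARAM_NAMES if n not in self.fixed]

    def log_prior(self, params: dict) -> float:
        lp = super().log_prior(params)
        for name in GROWTH_PARAM_NAMES:
            if name not in self.fixed:
                lp += self.priors[name].logpdf(params[name])
        return lp

    def unit_terms(self, params: dict, latents: dict) -> np.ndarray:
        terms = super().unit_terms(params, latents)
        a_tag, a_rec, _ = self.resolve_ages(latents, params)
        g = _curve_params(params, self.fixed)
        terms = terms + _length_terms(self.data.n, self._lengths_rec, self._has_rec,
                                      self._lengths_tag, self._tag_idx, a_tag, a_rec, g)
        return terms


class ClassicalGrowthModel:
    """Growth-only model with ages fixed at externally supplied estimates."""

    def __init__(self, fish, ages_days, priors: PriorConfig | None = None,
                 fixed: dict | None = None):
        self.priors = priors if priors is not None else default_priors()
        self.fixed = dict(fixed or {})
        fish = list(fish)
        ages = np.asarray(ages_days, dtype=float)
        if len(fish) and ages.shape != (len(fish),):
            raise ValueError("need one fixed age per fish")
        self._ages = ages
        self._lengths_rec = np.array([fi.length_rec for fi in fish]) if fish else np.empty(0)
        self._has_rec = np.isfinite(self._lengths_rec)
        self._tag_idx = np.empty(0, dtype=int)
        self._lengths_tag = np.empty(0)
        self._n = len(fish)
        self.param_blocks = _growth_blocks(self.priors, self.fixed)
        self.latent_blocks = []
        self.joint_block = [n for n in GROWTH_PARAM_NAMES if n not in self.fixed]

    def log_prior(self, params: dict) -> float:
        lp = 0.0
        for name in GROWTH_PARAM_NAMES:
            if name not in self.fixed:
                lp += self.priors[name].logpdf(params[name])
        return lp

    def unit_terms(self, params: dict, latents: dict) -> np.ndarray:
        if self._n == 0:
            return np.zeros(0)
        g = _curve_params(params, self.fixed)
        return _length_terms(self._n, self._lengths_rec, self._has_rec,
                             self._lengths_tag, self._tag_idx,
                             self._ages, self._ages, g)

    def log_density(self, params: dict, latents: dict | None = None) -> float:
        return self.log_prior(params) + self.unit_terms(params, latents or {}).sum()


def assemble_coupled_model(fish, readings=None, priors: PriorConfig | None = None,
                           mode: str = "coupled", ages_days=None,
                           deposition_posterior: PosteriorDraws | None = None,
                           fixed: dict | None = None, **kw):
    """Build the joint model in ``coupled`` or ``classical`` mode.

    Coupled mode needs readings; classical mode needs precomputed point
    ages (days) for every fish.
    """
    if mode == "coupled":
        if not readings:
            raise ValueError("coupled mode requires otolith readings")
        return CoupledModel(fish, readings, priors, deposition_posterior, fixed, **kw)
    if mode == "classical":
        if ages_days is None:
            raise ValueError("classical mode requires fixed point ages")
        return ClassicalGrowthModel(fish, ages_days, priors, fixed)
    raise ValueError(f"unknown mode {mode!r}")


def fit_growth(model, n_chains: int = 3, n_keep: int = 2000, burn: int = 2000,
               thin: int = 1, seed: int = 0, keep_latents: bool = True) -> PosteriorDraws:
    """Run MCMC on a coupled or classical model; adds derived k2 draws."""
    draws = run_mcmc(model, n_chains=n_chains, n_keep=n_keep, burn=burn, thin=thin,
                     seed=seed, keep_latents=keep_latents)
    fixed = getattr(model, "fixed", {})
    for name, val in fixed.items():
        draws.params[name] = np.full((draws.n_chains, draws.n_draws), float(val))
    if "k1" in draws.params and "delta" in draws.params:
        draws.add_derived("k2", lambda d: d["delta"] * d["k1"])
    return draws


def growth_params_from_draw(params: dict, i: tuple | None = None) -> GrowthParams:
    """Build :class:`GrowthParams` from one MCMC draw (index ``i``) or floats."""
    get = (lambda n: float(params[n][i])) if i is not None else (lambda n: float(params[n]))
    return GrowthParams(linf=get("linf"), k1=get("k1"), delta=get("delta"),
                        alpha=get("alpha"), beta=get("beta"), t0=get("t0"),
                        sigma_l=get("sigma_l"))


def posterior_predict_length(draws: PosteriorDraws, age: float, n_samples: int = 1000,
                             seed: int = 0) -> dict:
    """Posterior predictive fork lengths at ``age`` (years).

    For each sampled parameter draw, a length is drawn from
    Normal(L(age; theta_G), sigma_l^2).  Draws whose t0 exceeds ``age`` are
    rejected and counted.
    """
    for name in GROWTH_PARAM_NAMES:
        if name not in draws.params:
            raise ValueError(f"draws missing growth parameter {name!r}")
    rng = np.random.default_rng(seed)
    nc, nd = draws.n_chains, draws.n_draws
    flat = {n: draws.params[n].reshape(-1) for n in GROWTH_PARAM_NAMES}
    idx = rng.integers(0, nc * nd, size=n_samples)
    out, rejected = [], 0
    for j in idx:
        g = growth_params_from_draw({n: flat[n] for n in flat}, (j,))
        if age < g.t0:
            rejected += 1
            continue
        mu = vb_logk_length(age, g)
        out.append(rng.normal(mu, g.sigma_l))
    return {"samples": np.array(out), "n_rejected": rejected}
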