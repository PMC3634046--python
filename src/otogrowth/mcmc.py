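"""Adaptive Metropolis-within-Gibbs sampling and posterior summaries.

The models in this package share one structure: a handful of global
parameters and, optionally, per-fish latent variables (ages, times at
liberty) whose likelihood contributions are independent across fish given
the globals.  The sampler exploits that: global parameters are updated one
at a time with scalar Gaussian random-walk proposals, and each latent
vector is updated with element-wise random-walk proposals accepted
per element in a single vectorised pass.  Proposal scales adapt towards a
~44% acceptance rate during burn-in and are frozen afterwards, so the
post-burn-in chain is a valid Markov chain.

A model is any object exposing

- ``param_blocks`` -> list of :class:`ParamBlock`
- ``latent_blocks`` -> list of :class:`LatentBlock` (may be empty)
- ``log_prior(params: dict) -> float``
- ``unit_terms(params: dict, latents: dict) -> ndarray`` per-fish log
  likelihood plus per-fish latent log prior (shape ``(n_units,)``); the
  joint log density is ``log_prior + unit_terms.sum()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ParamBlock",
    "LatentBlock",
    "PosteriorDraws",
    "run_mcmc",
    "gelman_rubin",
    "posterior_mode",
    "credible_interval",
]


@dataclass
class ParamBlock:
    """One scalar model parameter: support bounds, initial value, proposal scale."""

    name: str
    lo: float
    hi: float
    init: float
    scale: float = 0.1


@dataclass
class LatentBlock:
    """A latent vector with element-wise bounds and initial values."""

    name: str
    lo: np.ndarray
    hi: np.ndarray
    init: np.ndarray
    scale: float = 10.0


@dataclass
class PosteriorDraws:
    """MCMC output: ``params[name]`` has shape (chains, draws); latent draws
    have shape (chains, draws, n_units)."""

    params: dict[str, np.ndarray]
    latents: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated, shape (chains*draws,) or (chains*draws, n)."""
        if name in self.params:
            return self.params[name].reshape(-1)
        arr = self.latents[name]
        return arr.reshape(-1, arr.shape[-1])

    def add_derived(self, name: str, fn) -> None:
        """Add a parameter computed from existing draws, e.g. k2 = delta*k1."""
        self.params[name] = fn(self.params)

    def summary(self, names=None):
        """Mode / mean / sd / 2.5% / 97.5% table as a pandas DataFrame."""
        import pandas as pd

        names = list(self.params) if names is None else list(names)
        rows = []
        for n in names:
            x = self.pooled(n)
            lo, hi = np.percentile(x, [2.5, 97.5])
            rows.append({"parameter": n, "mode": posterior_mode(x),
                         "mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1)),
                         "q2.5": float(lo), "q97.5": float(hi)})
        return pd.DataFrame(rows).set_index("parameter")


def _adapt(scale, acc_rate, step, target=0.44):
    return scale * np.exp(step * (acc_rate - target))


class _JointProposal:
    """Haario-style adaptive multivariate random walk over a parameter block.

    The empirical covariance of the block is accumulated during burn-in and
    the proposal is N(0, c^2 (Sigma + eps I)); the global scale c adapts
    towards ~23% acceptance and everything is frozen after burn-in.
    """

    def __init__(self, names, bounds):
        self.names = list(names)
        self.bounds = bounds
        d = len(self.names)
        self.n = 0
        self.mean = np.zeros(d)
        self.m2 = np.zeros((d, d))
        self.scale = 1.0
        self.chol = None
        self.acc = 0
        self.tries = 0

    def observe(self, params):
        x = np.array([params[n] for n in self.names])
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.m2 += np.outer(delta, x - self.mean)
        if self.n >= 50 and self.n % 25 == 0:
            d = len(self.names)
            cov = self.m2 / (self.n - 1) + 1e-10 * np.eye(d)
            try:
                self.chol = np.linalg.cholesky(2.38**2 / d * cov)
            except np.linalg.LinAlgError:
                self.chol = None

    def propose(self, params, rng):
        if self.chol is None:
            return None
        step = self.scale * self.chol @ rng.standard_normal(len(self.names))
        prop = dict(params)
        for n, dx in zip(self.names, step):
            prop[n] = params[n] + dx
            lo, hi = self.bounds[n]
            if prop[n] < lo or prop[n] > hi:
                return None
        return prop

    def adapt(self):
        if self.tries >= 25:
            rate = self.acc / self.tries
            self.scale *= np.exp(min(0.3, 5.0 / np.sqrt(self.n + 10.0)) * (rate - 0.23))
            self.acc = 0
            self.tries = 0


def _run_chain(model, n_keep, burn, thin, rng, keep_latents):
    pblocks = model.param_blocks
    lblocks = model.latent_blocks
    params = {b.name: float(np.clip(b.init, b.lo, b.hi)) for b in pblocks}
    latents = {b.name: np.clip(np.array(b.init, dtype=float), b.lo, b.hi) for b in lblocks}
    # jitter initial parameter values inside their support
    for b in pblocks:
        span = min(b.scale, (b.hi - b.lo) / 10 if np.isfinite(b.hi - b.lo) else b.scale)
        params[b.name] = float(np.clip(params[b.name] + 0.2 * span * rng.standard_normal(),
                                       b.lo, b.hi))
    pscale = {b.name: b.scale for b in pblocks}
    lscale = {b.name: np.full_like(latents[b.name], b.scale) for b in lblocks}
    joint = None
    joint_names = [n for n in getattr(model, "joint_block", []) if n in params]
    if len(joint_names) >= 2:
        bounds = {b.name: (b.lo, b.hi) for b in pblocks}
        joint = _JointProposal(joint_names, bounds)

    lp = model.log_prior(params)
    terms = model.unit_terms(params, latents)
    total = lp + terms.sum()
    if not np.isfinite(total):
        raise RuntimeError("initial state has non-finite log density; "
                           f"params={params}")

    n_iter = burn + n_keep * thin
    out_p = {b.name: np.empty(n_keep) for b in pblocks}
    out_l = ({b.name: np.empty((n_keep, latents[b.name].size)) for b in lblocks}
             if keep_latents else {})
    # windowed acceptance counters for adaptation
    acc_p = {b.name: 0 for b in pblocks}
    acc_l = {b.name: np.zeros(latents[b.name].size) for b in lblocks}
    window = 50

    for it in range(n_iter):
        adapting = it < burn
        for b in pblocks:
            name = b.name
            prop = params.copy()
            prop[name] = params[name] + pscale[name] * rng.standard_normal()
            if prop[name] < b.lo or prop[name] > b.hi:
                continue
            lp_new = model.log_prior(prop)
            if not np.isfinite(lp_new):
                continue
            terms_new = model.unit_terms(prop, latents)
            total_new = lp_new + terms_new.sum()
            if np.log(rng.random()) < total_new - total:
                params, lp, terms, total = prop, lp_new, terms_new, total_new
                acc_p[name] += 1
        if joint is not None:
            prop = joint.propose(params, rng)
            joint.tries += 1
            if prop is not None:
                lp_new = model.log_prior(prop)
                if np.isfinite(lp_new):
                    terms_new = model.unit_terms(prop, latents)
                    total_new = lp_new + terms_new.sum()
                    if np.log(rng.random()) < total_new - total:
                        params, lp, terms, total = prop, lp_new, terms_new, total_new
                        joint.acc += 1
            if adapting:
                joint.observe(params)
                joint.adapt()
        for b in lblocks:
            name = b.name
            cur = latents[name]
            prop = cur + lscale[name] * rng.standard_normal(cur.size)
            ok = (prop >= b.lo) & (prop <= b.hi)
            prop = np.where(ok, prop, cur)
            lat_new = dict(latents)
            lat_new[name] = prop
            terms_new = model.unit_terms(params, lat_new)
            accept = ok & (np.log(rng.random(cur.size)) < terms_new - terms)
            if accept.any():
                latents[name] = np.where(accept, prop, cur)
                terms = np.where(accept, terms_new, terms)
                total = lp + terms.sum()
            acc_l[name] += accept

        if adapting and (it + 1) % window == 0:
            step = min(0.5, 10.0 / np.sqrt(it + 1.0))
            for b in pblocks:
                pscale[b.name] = _adapt(pscale[b.name], acc_p[b.name] / window, step)
                acc_p[b.name] = 0
            for b in lblocks:
                lscale[b.name] = _adapt(lscale[b.name], acc_l[b.name] / window, step)
                acc_l[b.name][:] = 0

        if it >= burn and (it - burn) % thin == 0:
            j = (it - burn) // thin
            for name in out_p:
                out_p[name][j] = params[name]
            for name in out_l:
                out_l[name][j] = latents[name]
    return out_p, out_l


def run_mcmc(model, n_chains: int = 3, n_keep: int = 2000, burn: int = 1000,
             thin: int = 1, seed: int = 0, keep_latents: bool = True) -> PosteriorDraws:
    """Sample the model's joint posterior.

    ``n_keep`` draws per chain are retained after discarding ``burn``
    iterations and thinning by ``thin``.  Reproducible for a given ``seed``.
    """
    if n_chains < 1 or n_keep < 1 or burn < 0 or thin < 1:
        raise ValueError("invalid MCMC settings")
    chains_p, chains_l = [], []
    for c in range(n_chains):
        rng = np.random.default_rng([int(seed) % (2**31), c])
        out_p, out_l = _run_chain(model, n_keep, burn, thin, rng, keep_latents)
        chains_p.append(out_p)
        chains_l.append(out_l)
    params = {n: np.stack([cp[n] for cp in chains_p]) for n in chains_p[0]}
    latents = {n: np.stack([cl[n] for cl in chains_l]) for n in (chains_l[0] or {})}
    for n, arr in {**params, **latents}.items():
        if not np.all(np.isfinite(arr)):
            raise RuntimeError(f"non-finite draws for {n}")
    meta = {"n_chains": n_chains, "n_keep": n_keep, "burn": burn, "thin": thin,
            "seed": int(seed)}
    return PosteriorDraws(params=params, latents=latents, meta=meta)


def gelman_rubin(draws: PosteriorDraws | np.ndarray, split: bool = True) -> dict | float:
    """Potential scale reduction factor (between- over within-chain variance).

    Accepts either a :class:`PosteriorDraws` (returns a dict per parameter)
    or a (chains, draws) array (returns a float).  Chains are split in half
    by default so within-chain drift also inflates the statistic.
    """
    if isinstance(draws, PosteriorDraws):
        if draws.n_chains < 2:
            raise ValueError("Gelman-Rubin diagnostic requires at least 2 chains")
        return {n: gelman_rubin(a, split=split) for n, a in draws.params.items()}
    x = np.asarray(draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (chains >= 2, draws) array")
    if split:
        half = x.shape[1] // 2
        x = np.concatenate([x[:, :half], x[:, half:2 * half]], axis=0)
    m, n = x.shape
    chain_means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    b = n * chain_means.var(ddof=1)
    if w == 0:  # constant draws (e.g. a fixed parameter)
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def posterior_mode(draws, n_grid: int = 512) -> float:
    """Marginal posterior mode via a Gaussian KDE (Silverman bandwidth).

    The density is evaluated on a coarse grid over the sample range, then on
    a fine grid around the coarse argmax, with a final parabolic refinement.
    """
    x = np.ravel(np.asarray(draws, dtype=float))
    if x.size < 100:
        raise ValueError("need at least 100 draws for a KDE mode estimate")
    if np.ptp(x) == 0:
        return float(x[0])
    kde = stats.gaussian_kde(x, bw_method="silverman")
    bw = float(kde.factor * x.std(ddof=1))
    grid = np.linspace(x.min(), x.max(), n_grid)
    i = int(np.argmax(kde(grid)))
    lo = max(float(x.min()), grid[i] - 2 * bw)
    hi = min(float(x.max()), grid[i] + 2 * bw)
    grid = np.linspace(lo, hi, n_grid)
    dens = kde(grid)
    i = int(np.argmax(dens))
    # stabilise the argmax: quadratic fit to log density over +-1 bandwidth
    sel = np.abs(grid - grid[i]) <= bw
    if sel.sum() >= 5:
        g, ld = grid[sel], np.log(dens[sel])
        c2, c1, _ = np.polyfit(g - grid[i], ld, 2)
        if c2 < 0:
            vertex = grid[i] - c1 / (2 * c2)
            if lo <= vertex <= hi:
                return float(vertex)
    return float(grid[i])


def credible_interval(draws, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval from posterior draws."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    x = np.ravel(np.asarray(draws, dtype=float))
    if x.size == 0:
        raise ValueError("empty draws")
    a = (1 - level) / 2
    lo, hi = np.quantile(x, [a, 1 - a])
    return float(lo), float(hi)
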