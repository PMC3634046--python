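"""Age-length keys and catch-at-size to catch-at-age conversion.

An age-length key (ALK) gives P(age class | length bin).  It is derived
from a fitted growth model by Bayes inversion: on a fine age grid with a
uniform age prior over the plausible age range,

    P(length bin | age)  = Gaussian mass of Normal(L(age), sigma_l^2) over the bin
    P(age class | bin)  propto  sum over grid ages in the class of P(bin | age)

either at plug-in parameter values or averaged over posterior draws, which
propagates growth-parameter uncertainty into the key.  Rows (bins) are
normalised to 1, so converting a catch-at-size vector through the key
conserves total catch exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .coupled import GROWTH_PARAM_NAMES, growth_params_from_draw
from .growth import GrowthParams, vb_logk_length
from .mcmc import PosteriorDraws

__all__ = [
    "AgeLengthKey",
    "build_alk",
    "convert_catch",
    "compare_age_compositions",
]


@dataclass(frozen=True)
class AgeLengthKey:
    """P(age class | length bin) on left-closed length bins.

    ``length_edges`` has len(bins)+1 entries (cm); ``age_edges`` bounds the
    age classes (years, typically quarters); ``matrix`` is
    (n_bins, n_classes) with rows summing to 1.
    """

    length_edges: np.ndarray
    age_edges: np.ndarray
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape != (len(self.length_edges) - 1, len(self.age_edges) - 1):
            raise ValueError("ALK matrix shape inconsistent with bin edges")
        if np.any(m < 0) or np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("ALK rows must be non-negative and sum to 1")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{a:.2f}-{b:.2f}y" for a, b in zip(self.age_edges[:-1], self.age_edges[1:])]
        idx = pd.Index(self.length_edges[:-1], name="length_bin_lower_cm")
        return pd.DataFrame(self.matrix, index=idx, columns=cols)


def _bin_mass(lo, hi, mu, sigma):
    """P(lo <= length < hi) under Normal(mu, sigma^2); shapes broadcast."""
    return ndtr((hi - mu) / sigma) - ndtr((lo - mu) / sigma)


def _key_for_params(g: GrowthParams, length_edges, age_grid):
    mu = vb_logk_length(age_grid, g)  # (n_ages,)
    # mass[b, a] = P(length bin b | age a)
    mass = _bin_mass(length_edges[:-1, None], length_edges[1:, None], mu[None, :], g.sigma_l)
    return mass


def build_alk(draws: PosteriorDraws | GrowthParams, length_edges, age_edges,
              age_range=(0.0, 10.0), age_step: float = 0.01,
              n_mc: int = 200, seed: int = 0, mode: str = "posterior") -> AgeLengthKey:
    """Derive an age-length key from a fitted growth model.

    Parameters
    ----------
    draws
        Posterior draws containing all growth parameters, or a single
        :class:`GrowthParams` (implies plug-in mode).
    length_edges, age_edges
        Bin edges (cm) and age-class edges (years; quarters by default use
        ``np.arange(0, n_quarters+1) * 0.25``).
    age_range, age_step
        Uniform-age-prior support and grid resolution (years).
    n_mc
        Number of posterior draws averaged in ``posterior`` mode.
    mode
        ``posterior`` (average the per-draw keys) or ``plugin`` (single
        parameter set, the posterior modes or the supplied params).
    """
    length_edges = np.asarray(length_edges, dtype=float)
    age_edges = np.asarray(age_edges, dtype=float)
    if len(length_edges) < 2 or len(age_edges) < 2:
        raise ValueError("need at least one length bin and one age class")
    if np.any(np.diff(length_edges) <= 0) or np.any(np.diff(age_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    lo, hi = age_range
    age_grid = np.arange(lo + age_step / 2, hi, age_step)
    cls = np.digitize(age_grid, age_edges) - 1
    valid = (cls >= 0) & (cls < len(age_edges) - 1)
    if not valid.any():
        raise ValueError("age grid does not intersect the age classes")

    if isinstance(draws, GrowthParams):
        param_sets = [draws]
    elif mode == "plugin":
        from .mcmc import posterior_mode
        flat = {n: draws.pooled(n) for n in GROWTH_PARAM_NAMES}
        param_sets = [GrowthParams(**{
            "linf": posterior_mode(flat["linf"]), "k1": posterior_mode(flat["k1"]),
            "delta": posterior_mode(flat["delta"]), "alpha": posterior_mode(flat["alpha"]),
            "beta": posterior_mode(flat["beta"]), "t0": posterior_mode(flat["t0"]),
            "sigma_l": posterior_mode(flat["sigma_l"])})]
    else:
        rng = np.random.default_rng(seed)
        flat = {n: draws.pooled(n) for n in GROWTH_PARAM_NAMES}
        total = flat["linf"].size
        idx = rng.integers(0, total, size=min(n_mc, total))
        param_sets = [growth_params_from_draw(flat, (j,)) for j in idx]

    n_bins, n_cls = len(length_edges) - 1, len(age_edges) - 1
    acc = np.zeros((n_bins, n_cls))
    for g in param_sets:
        grid_ok = age_grid >= g.t0
        mass = np.zeros((n_bins, age_grid.size))
        mass[:, grid_ok] = _key_for_params(g, length_edges, age_grid[grid_ok])
        per_cls = np.zeros((n_bins, n_cls))
        for c in range(n_cls):
            sel = valid & (cls == c)
            per_cls[:, c] = mass[:, sel].sum(axis=1)
        rows = per_cls.sum(axis=1, keepdims=True)
        rows[rows == 0] = 1.0
        acc += per_cls / rows
    acc /= len(param_sets)
    rows = acc.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    acc = acc / rows
    return AgeLengthKey(length_edges=length_edges, age_edges=age_edges, matrix=acc)


def convert_catch(catch: pd.Series, alk: AgeLengthKey) -> pd.Series:
    """Convert catch-at-size to catch-at-age: C(age) = sum_b ALK[b, age] C(b).

    ``catch`` is indexed by the lower edge of each length bin; every bin
    must exist in the key.  Total catch is conserved exactly.
    """
    lower = np.asarray(alk.length_edges[:-1])
    pos = {round(float(v), 6): i for i, v in enumerate(lower)}
    missing = [b for b in catch.index if round(float(b), 6) not in pos]
    if missing:
        raise ValueError(f"catch bins not present in the ALK: {missing}")
    if np.any(np.asarray(catch.values, dtype=float) < 0):
        raise ValueError("catch quantities must be non-negative")
    out = np.zeros(alk.matrix.shape[1])
    for b, q in catch.items():
        out += alk.matrix[pos[round(float(b), 6)]] * float(q)
    labels = [f"{a:.2f}-{b:.2f}y" for a, b in zip(alk.age_edges[:-1], alk.age_edges[1:])]
    return pd.Series(out, index=labels, name="catch")


def compare_age_compositions(comp_a: np.ndarray, comp_b: np.ndarray,
                             length_lower=None) -> pd.DataFrame:
    """Per-length-bin divergence between two proportion-at-age tables.

    ``comp_a``/``comp_b`` are (n_bins, n_classes) arrays of age-class
    proportions (rows need not be pre-normalised).  Returns total-variation
    distance ``0.5 * sum |p - q|`` and a chi-square-style contrast per bin.
    """
    a = np.asarray(comp_a, dtype=float)
    b = np.asarray(comp_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("compositions must be 2-d arrays of identical shape")
    with np.errstate(invalid="ignore"):
        p = a / np.where(a.sum(axis=1, keepdims=True) == 0, 1, a.sum(axis=1, keepdims=True))
        q = b / np.where(b.sum(axis=1, keepdims=True) == 0, 1, b.sum(axis=1, keepdims=True))
    tv = 0.5 * np.abs(p - q).sum(axis=1)
    denom = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, (p - q) ** 2 / np.where(denom == 0, 1, denom), 0.0).sum(axis=1)
    idx = (pd.Index(length_lower, name="length_bin_lower_cm")
           if length_lower is not None else pd.RangeIndex(a.shape[0]))
    return pd.DataFrame({"tv_distance": tv, "chi2_contrast": chi2}, index=idx)
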