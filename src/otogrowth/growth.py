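"""Two-stanza Von Bertalanffy growth with a logistic growth-coefficient transition.

The VB-logK curve generalises the classic Von Bertalanffy model by letting the
growth-rate coefficient change smoothly from a juvenile value ``k1`` to an
adult value ``k2 = delta * k1``::

    k(a) = k1 + (k2 - k1) / (1 + exp(-beta * (a - t0 - alpha)))
    L(a) = linf * (1 - exp(-I(a))),   I(a) = integral of k(u) du from t0 to a

The integral has a closed form,

    I(a) = k1*(a - t0)
         + (k2 - k1)/beta * [log(1 + e^{beta*(a - t0 - alpha)}) - log(1 + e^{-beta*alpha})]

so the curve is exact, monotone in age, and passes through zero length at the
theoretical age ``t0``.  ``alpha`` is the inflection age of the coefficient
transition measured relative to ``t0`` and ``beta`` controls how abrupt the
transition is; ``beta -> 0`` or ``delta = 1`` recovers the classic single-K
model.

Observed fork lengths are modelled as Gaussian around the curve with a common
measurement standard deviation ``sigma_l``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "GrowthParams",
    "YFT_MODAL_PARAMS",
    "vb_logk_length",
    "vb_logk_rate",
    "invert_length",
    "mean_rate_between_lengths",
    "length_loglik",
    "growth_coefficient",
    "rate_extrema",
]

MONTHS_PER_YEAR = 12.0
DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the VB-logK growth curve.

    Attributes
    ----------
    linf : asymptotic fork length (cm)
    k1 : juvenile growth coefficient (1/year)
    delta : multiplier >= 0 such that the adult coefficient is k2 = delta * k1
    alpha : inflection age of the coefficient transition, relative to t0 (years)
    beta : transition rate (1/year)
    t0 : theoretical age at zero length (years)
    sigma_l : fork-length measurement standard deviation (cm)
    """

    linf: float
    k1: float
    delta: float
    alpha: float
    beta: float
    t0: float
    sigma_l: float

    def __post_init__(self) -> None:
        vals = (self.linf, self.k1, self.delta, self.alpha, self.beta, self.t0, self.sigma_l)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite growth parameter in {vals}")
        if self.linf <= 0 or self.k1 <= 0 or self.sigma_l <= 0:
            raise ValueError("linf, k1 and sigma_l must be positive")
        if self.delta < 0 or self.beta < 0 or self.alpha <= 0:
            raise ValueError("delta and beta must be >= 0 and alpha > 0")

    @property
    def k2(self) -> float:
        """Adult growth coefficient (1/year)."""
        return self.delta * self.k1

    @classmethod
    def from_k2(cls, *, linf: float, k1: float, k2: float, alpha: float, beta: float,
                t0: float, sigma_l: float) -> "GrowthParams":
        """Build from (k1, k2) instead of (k1, delta)."""
        return cls(linf=linf, k1=k1, delta=k2 / k1, alpha=alpha, beta=beta,
                   t0=t0, sigma_l=sigma_l)

    def replace(self, **kw) -> "GrowthParams":
        return replace(self, **kw)


#: Posterior-mode parameter set of the Indian Ocean yellowfin tuna case study,
#: used throughout as the reference two-stanza curve.
YFT_MODAL_PARAMS = GrowthParams.from_k2(
    linf=146.243, k1=0.246, k2=0.664, alpha=2.61, beta=12.583, t0=-0.43, sigma_l=8.809,
)


def _cum_k(age, p: GrowthParams):
    """Integral of the logistic growth coefficient from t0 to ``age``."""
    s = np.asarray(age, dtype=float) - p.t0
    # log(1 + e^x) via logaddexp for numerical stability at large |x|
    trans = np.logaddexp(0.0, p.beta * (s - p.alpha)) - np.logaddexp(0.0, -p.beta * p.alpha)
    if p.beta > 0:
        extra = (p.k2 - p.k1) / p.beta * trans
    else:
        # beta == 0: k is the constant midpoint of k1 and k2
        extra = 0.5 * (p.k2 - p.k1) * s
    return p.k1 * s + extra


def _check_age(age, p: GrowthParams) -> None:
    a = np.asarray(age, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("age must be finite")
    if np.any(a < p.t0 - 1e-12):
        raise ValueError(f"age {a} below theoretical age at zero length t0={p.t0}")


def vb_logk_length(age, params: GrowthParams):
    """Fork length (cm) at ``age`` (years) on the VB-logK curve.

    Vectorised over ``age``.  Raises for ages below ``t0``.
    """
    _check_age(age, params)
    out = params.linf * (-np.expm1(-_cum_k(age, params)))
    return float(out) if np.isscalar(age) else out


def growth_coefficient(age, params: GrowthParams):
    """Instantaneous growth coefficient k(a) (1/year)."""
    s = np.asarray(age, dtype=float) - params.t0
    k = params.k1 + (params.k2 - params.k1) * expit(params.beta * (s - params.alpha))
    return float(k) if np.isscalar(age) else k


def vb_logk_rate(age, params: GrowthParams):
    """Instantaneous growth rate dL/da (cm/year) at ``age`` (years)."""
    _check_age(age, params)
    out = (params.linf - vb_logk_length(age, params)) * growth_coefficient(age, params)
    return float(out) if np.isscalar(age) else out


def invert_length(length: float, params: GrowthParams,
                  age_bounds: tuple[float, float] | None = None) -> float:
    """Age (years) at which the curve attains ``length`` (cm).

    The curve is strictly increasing, so the solution is unique; it is found
    by root bracketing to |L(a) - length| well below 1e-6 cm.
    """
    if not math.isfinite(length) or length < 0:
        raise ValueError(f"length must be finite and >= 0, got {length}")
    if length >= params.linf:
        raise ValueError(f"length {length} >= asymptotic length {params.linf}: no finite age")
    lo, hi = age_bounds if age_bounds is not None else (params.t0, params.t0 + 50.0)
    f = lambda a: vb_logk_length(a, params) - length
    while f(hi) < 0:  # extend bracket for lengths very close to linf
        hi = params.t0 + 2 * (hi - params.t0)
        if hi - params.t0 > 1e4:
            raise ValueError(f"length {length} not reached within bracket")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))


def mean_rate_between_lengths(l_lo: float, l_hi: float, params: GrowthParams) -> float:
    """Mean growth rate (cm/month) between two fork lengths on the curve."""
    if not (0 <= l_lo < l_hi):
        raise ValueError("need 0 <= l_lo < l_hi")
    a_lo = invert_length(l_lo, params)
    a_hi = invert_length(l_hi, params)
    return (l_hi - l_lo) / (a_hi - a_lo) / MONTHS_PER_YEAR


def length_loglik(obs_length, age, params: GrowthParams):
    """Gaussian log density of observed length around the curve at ``age``."""
    obs = np.asarray(obs_length, dtype=float)
    if not np.all(np.isfinite(obs)):
        raise ValueError("observed length must be finite")
    mu = vb_logk_length(age, params)
    s = params.sigma_l
    out = -0.5 * np.log(2 * np.pi * s * s) - 0.5 * ((obs - mu) / s) ** 2
    return float(out) if np.isscalar(obs_length) and np.isscalar(age) else out


def rate_extrema(params: GrowthParams, age_max: float = 10.0,
                 grid_step: float = 1e-3) -> dict:
    """Locate the first-stanza rate minimum and the transition rate maximum.

    Scans dL/da on a fine age grid and polishes each extremum with a local
    bounded search.  Returns ages (years), rates (cm/month) and lengths (cm).
    """
    from scipy.optimize import minimize_scalar

    ages = np.arange(params.t0 + grid_step, age_max, grid_step)
    rates = vb_logk_rate(ages, params)
    # first-stanza local minimum: before the logistic transition midpoint
    pre = ages <= params.t0 + params.alpha
    i_min = int(np.argmin(rates[pre]))
    a0 = ages[pre][i_min]
    r = minimize_scalar(lambda a: vb_logk_rate(a, params),
                        bounds=(max(params.t0, a0 - 2 * grid_step), a0 + 2 * grid_step),
                        method="bounded", options={"xatol": 1e-10})
    a_min = float(r.x)
    i_max = int(np.argmax(rates))
    a1 = ages[i_max]
    r = minimize_scalar(lambda a: -vb_logk_rate(a, params),
                        bounds=(a1 - 2 * grid_step, a1 + 2 * grid_step),
                        method="bounded", options={"xatol": 1e-10})
    a_max_rate = float(r.x)
    return {
        "age_min": a_min,
        "rate_min": vb_logk_rate(a_min, params) / MONTHS_PER_YEAR,
        "length_at_min": vb_logk_length(a_min, params),
        "age_max": a_max_rate,
        "rate_max": vb_logk_rate(a_max_rate, params) / MONTHS_PER_YEAR,
        "length_at_max": vb_logk_length(a_max_rate, params),
    }
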