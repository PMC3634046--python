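"""Hierarchical ageing-error model for repeated otolith increment counts.

Increment deposition and reading are modelled in two stages.

*Deposition.*  For an OTC-marked fish the number of increments laid down
between the fluorescent mark and the otolith edge over a time at liberty of
``tal`` days has expectation ``rho * tal + b_e``: ``rho`` is the deposition
rate perceived by the reader (increments/day; 1 is the daily-deposition
hypothesis) and ``b_e`` a signed edge bias (increments lost or over-counted
at the compressed otolith margin).  Counts from the nucleus carry instead a
nucleus bias ``b_n`` (increments lost when the core is sanded away):

    E[nucleus->mark]  = rho * age_at_tagging + b_n
    E[mark->edge]     = rho * tal            + b_e
    E[nucleus->edge]  = rho * age_at_capture + b_n + b_e

*Reading.*  Each of the 2-5 repeat reads of a section is Gaussian around
the expected count with standard deviation ``p * expected`` - a
multiplicative error, because every increment carries the same independent
probability of misinterpretation so the absolute error grows with age.

Latent true ages (in days) are the quantities of interest.  Three data
configurations occur, resolved per fish:

- **A** - OTC fish with a precise recapture date and nucleus-to-mark reads:
  the latent is the age at tagging; age at capture = age at tagging + tal.
- **B** - fish with nucleus-to-edge reads and known tal: the latent is the
  age at capture; age at tagging = age at capture - tal.
- **C** - capture-only fish, or imprecise recapture date: only the age at
  capture is latent; an imprecise tal is itself a uniform latent between
  its logbook bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mcmc import LatentBlock, ParamBlock, PosteriorDraws, credible_interval, run_mcmc
from .priors import PriorConfig, default_priors, empirical_normal_prior

__all__ = [
    "SECTIONS",
    "FishRecord",
    "ReadingSet",
    "AgeingParams",
    "LatentAgeState",
    "reading_logpdf",
    "expected_section_count",
    "reading_cv",
    "date_cv",
    "filter_deposition_subsample",
    "DepositionModel",
    "fit_deposition_model",
    "test_daily_deposition",
    "AgeEstimationModel",
    "build_age_model",
    "fit_ages",
]

SECTIONS = ("nucleus_to_mark", "mark_to_edge", "nucleus_to_edge")

_LOG_2PI = math.log(2 * math.pi)


@dataclass(frozen=True)
class FishRecord:
    """One tagged or captured fish."""

    fish_id: str
    program: str = "RTTP"  # RTTP (mark-recapture) or WSTTP (capture only)
    otc_tagged: bool = False
    length_rec: float = float("nan")
    length_tag: float | None = None
    date_tag: str | None = None
    tal_min: float | None = None  # days
    tal_max: float | None = None

    def __post_init__(self):
        if self.program not in ("RTTP", "WSTTP"):
            raise ValueError(f"unknown program {self.program!r}")
        if not math.isnan(self.length_rec) and self.length_rec <= 0:
            raise ValueError("length_rec must be positive")
        if self.length_tag is not None and self.length_tag <= 0:
            raise ValueError("length_tag must be positive")
        if self.program == "WSTTP":
            if self.tal_min is not None or self.length_tag is not None:
                raise ValueError("WSTTP fish are capture-only: no tagging length or tal")
        if (self.tal_min is None) != (self.tal_max is None):
            raise ValueError("tal_min and tal_max must be given together")
        if self.tal_min is not None and not 0 <= self.tal_min <= self.tal_max:
            raise ValueError(f"need 0 <= tal_min <= tal_max, got ({self.tal_min}, {self.tal_max})")

    @property
    def has_tal(self) -> bool:
        return self.tal_min is not None


@dataclass(frozen=True)
class ReadingSet:
    """Repeated increment counts for one otolith section of one fish."""

    fish_id: str
    section: str
    counts: tuple

    def __post_init__(self):
        if self.section not in SECTIONS:
            raise ValueError(f"unknown section {self.section!r}; expected one of {SECTIONS}")
        c = tuple(float(x) for x in self.counts)
        if len(c) < 1:
            raise ValueError("need at least one count")
        if any(x < 0 or not math.isfinite(x) for x in c):
            raise ValueError("counts must be finite and non-negative")
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class AgeingParams:
    """Deposition rate and reading-error parameters."""

    rho: float
    b_n: float = 0.0
    b_e: float = 0.0
    p: float = 0.1

    def __post_init__(self):
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if not 0 <= self.p <= 0.5:
            raise ValueError("p must lie in [0, 0.5]")


@dataclass(frozen=True)
class LatentAgeState:
    """Latent true ages (days) and section increment counts for one fish."""

    a_rec: float
    a_tag: float | None = None
    tal: float | None = None
    n1: float | None = None
    n2: float | None = None
    n3: float | None = None

    def __post_init__(self):
        if self.a_rec <= 0:
            raise ValueError("age at capture must be positive")
        if self.a_tag is not None and self.tal is not None:
            if abs(self.a_rec - self.a_tag - self.tal) > 1e-9:
                raise ValueError("a_rec must equal a_tag + tal")


def reading_logpdf(observed_count, expected_count, p):
    """Log density of an observed count: Normal(expected, (p * expected)^2)."""
    obs = np.asarray(observed_count, dtype=float)
    mu = np.asarray(expected_count, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("expected_count must be positive")
    if not 0 < p <= 0.5:
        raise ValueError("p must lie in (0, 0.5]")
    sd = p * mu
    out = -0.5 * _LOG_2PI - np.log(sd) - 0.5 * ((obs - mu) / sd) ** 2
    return float(out) if out.ndim == 0 else out


def expected_section_count(section: str, state: LatentAgeState, params: AgeingParams) -> float:
    """Expected increment count for a section given latent ages."""
    if section == "mark_to_edge":
        if state.tal is None:
            raise ValueError("mark_to_edge expectation needs a time at liberty")
        return params.rho * state.tal + params.b_e
    if section == "nucleus_to_mark":
        if state.a_tag is None:
            raise ValueError("nucleus_to_mark expectation needs an age at tagging")
        return params.rho * state.a_tag + params.b_n
    if section == "nucleus_to_edge":
        return params.rho * state.a_rec + params.b_n + params.b_e
    raise ValueError(f"unknown section {section!r}")


def reading_cv(counts) -> float:
    """Coefficient of variation of repeat counts (sd / mean)."""
    c = np.asarray(counts, dtype=float)
    m = c.mean()
    if m <= 0:
        return float("inf")
    return float(np.std(c, ddof=1) / m) if c.size > 1 else 0.0


def date_cv(record: FishRecord) -> float:
    """CV of the time at liberty treated as uniform between its bounds."""
    if not record.has_tal:
        return float("inf")
    if record.tal_max == record.tal_min:
        return 0.0
    mean = 0.5 * (record.tal_min + record.tal_max)
    sd = (record.tal_max - record.tal_min) / math.sqrt(12.0)
    return sd / mean if mean > 0 else float("inf")


def filter_deposition_subsample(records, reading_sets, cv_read_max: float = 0.10,
                                cv_date_max: float = 0.05) -> list[str]:
    """Fish usable for the deposition regression.

    Keeps OTC-tagged fish whose mark-to-edge repeat reads have CV at or
    below ``cv_read_max`` and whose recapture date is precise (tal CV at or
    below ``cv_date_max``).  Order of the input records is preserved.
    """
    if not (0 < cv_read_max < 1 and 0 < cv_date_max < 1):
        raise ValueError("CV thresholds must lie in (0, 1)")
    m2e = {}
    for rs in reading_sets:
        if rs.section == "mark_to_edge":
            m2e.setdefault(rs.fish_id, []).extend(rs.counts)
    out = []
    for rec in records:
        if not rec.otc_tagged or rec.fish_id not in m2e:
            continue
        if reading_cv(m2e[rec.fish_id]) <= cv_read_max and date_cv(rec) <= cv_date_max:
            out.append(rec.fish_id)
    return out


def _norm_logpdf(obs, mu, sd):
    return -0.5 * _LOG_2PI - np.log(sd) - 0.5 * ((obs - mu) / sd) ** 2


# ---------------------------------------------------------------------------
# Deposition regression: counts[mark->edge] ~ Normal(rho*tal + b_e, (p*mu)^2)
# ---------------------------------------------------------------------------

class DepositionModel:
    """Bayesian regression of mark-to-edge counts on time at liberty."""

    def __init__(self, records, reading_sets, priors: PriorConfig | None = None):
        priors = priors if priors is not None else default_priors()
        self.priors = priors
        by_fish = {}
        for rs in reading_sets:
            if rs.section == "mark_to_edge":
                by_fish.setdefault(rs.fish_id, []).extend(rs.counts)
        recs = [r for r in records if r.fish_id in by_fish and r.has_tal]
        if len(recs) < 2:
            raise ValueError("deposition regression needs at least 2 fish with known tal "
                             "and mark-to-edge readings")
        self.fish_ids = [r.fish_id for r in recs]
        obs, idx = [], []
        for i, r in enumerate(recs):
            for c in by_fish[r.fish_id]:
                obs.append(c)
                idx.append(i)
        self._obs = np.array(obs)
        self._idx = np.array(idx)
        self._n = len(recs)
        self._tal_mid = np.array([(r.tal_min + r.tal_max) / 2 for r in recs])
        imprecise = np.array([r.tal_max > r.tal_min for r in recs])
        self._imprecise = imprecise
        self._tal_lo = np.array([r.tal_min for r in recs])
        self._tal_hi = np.array([r.tal_max for r in recs])

        self.param_blocks = [
            ParamBlock("rho", *self._support("rho"), init=1.0, scale=0.02),
            ParamBlock("b_e", *self._support("b_e"), init=priors["b_e"].mean(), scale=1.0),
            ParamBlock("p", 1e-6, self._support("p")[1], init=0.1, scale=0.02),
        ]
        self.latent_blocks = []
        self.joint_block = ["rho", "b_e", "p"]
        if imprecise.any():
            self.latent_blocks.append(LatentBlock(
                "tal", lo=self._tal_lo, hi=self._tal_hi, init=self._tal_mid, scale=20.0))

    def _support(self, name):
        pr = self.priors[name]
        return pr.lo, pr.hi

    def log_prior(self, params: dict) -> float:
        return (self.priors["rho"].logpdf(params["rho"])
                + self.priors["b_e"].logpdf(params["b_e"])
                + self.priors["p"].logpdf(params["p"]))

    def unit_terms(self, params: dict, latents: dict) -> np.ndarray:
        tal = latents.get("tal", self._tal_mid)
        if "tal" in latents:
            tal = np.where(self._imprecise, tal, self._tal_mid)
        mu = params["rho"] * tal + params["b_e"]
        terms = np.zeros(self._n)
        bad = mu <= 0
        if bad.any():
            terms[bad] = -np.inf
        sd = params["p"] * np.where(bad, 1.0, mu)
        ll = _norm_logpdf(self._obs, mu[self._idx], sd[self._idx])
        np.add.at(terms, self._idx, np.where(bad[self._idx], 0.0, ll))
        return terms

    def log_density(self, params: dict, latents: dict | None = None) -> float:
        return self.log_prior(params) + self.unit_terms(params, latents or {}).sum()


def fit_deposition_model(records, reading_sets, priors: PriorConfig | None = None,
                         n_chains: int = 3, n_keep: int = 2000, burn: int = 1500,
                         thin: int = 1, seed: int = 0) -> PosteriorDraws:
    """Fit the deposition regression; returns draws over {rho, b_e, p}."""
    model = DepositionModel(records, reading_sets, priors)
    return run_mcmc(model, n_chains=n_chains, n_keep=n_keep, burn=burn,
                    thin=thin, seed=seed, keep_latents=False)


def test_daily_deposition(draws: PosteriorDraws, level: float = 0.95) -> dict:
    """Credible interval for rho and whether daily deposition (rho = 1) is inside."""
    if "rho" not in draws.params:
        raise ValueError("draws do not contain rho")
    lo, hi = credible_interval(draws.pooled("rho"), level)
    return {"interval": (lo, hi), "contains_one": bool(lo <= 1.0 <= hi), "level": level}


# ---------------------------------------------------------------------------
# Multi-reading age estimation
# ---------------------------------------------------------------------------

@dataclass
class AgeingData:
    """Preprocessed per-fish case assignment and flattened reading arrays.

    The per-fish latent is the *true increment count* of the fish's primary
    section (nucleus-to-mark for case A, nucleus-to-edge otherwise); latent
    ages are derived from it, which keeps the latent measure in count units
    where the reading likelihood lives.
    """

    fish: list
    case: np.ndarray          # 'A' | 'B' | 'C' per fish
    tal_fixed: np.ndarray     # known tal (days) or nan
    tal_latent_idx: np.ndarray  # indices of fish whose tal is a latent
    tal_lo: np.ndarray
    tal_hi: np.ndarray
    n_lo: np.ndarray          # latent-count bounds
    n_hi: np.ndarray
    n_init: np.ndarray
    sections: dict = field(default_factory=dict)  # section -> (fish_idx, obs)

    @property
    def n(self) -> int:
        return len(self.fish)


def prepare_ageing_data(fish, readings, cv_date_max: float = 0.05,
                        age_max_days: float = 10 * 365.0) -> AgeingData:
    fish = list(fish)
    ids = {f.fish_id: i for i, f in enumerate(fish)}
    if len(ids) != len(fish):
        raise ValueError("duplicate fish ids")
    by_fish: dict[str, dict[str, list]] = {f.fish_id: {} for f in fish}
    for rs in readings:
        if rs.fish_id not in ids:
            continue
        by_fish[rs.fish_id].setdefault(rs.section, []).extend(rs.counts)
    if not any(by_fish.values()):
        raise ValueError("no readings for any fish")

    n = len(fish)
    case = np.empty(n, dtype="U1")
    tal_fixed = np.full(n, np.nan)
    tal_lat, tal_lo, tal_hi = [], [], []
    n_lo = np.full(n, 1.0)
    n_hi = np.full(n, 1.5 * age_max_days + 50.0)
    n_init = np.full(n, np.nan)

    for i, f in enumerate(fish):
        secs = by_fish[f.fish_id]
        if not secs:
            raise ValueError(f"fish {f.fish_id} has no readings")
        precise = f.has_tal and date_cv(f) <= cv_date_max
        if f.otc_tagged and precise and "nucleus_to_mark" in secs:
            case[i] = "A"
            tal_fixed[i] = 0.5 * (f.tal_min + f.tal_max)
            n_init[i] = max(np.mean(secs["nucleus_to_mark"]), 2.0)
        elif precise and "nucleus_to_edge" in secs:
            case[i] = "B"
            tal_fixed[i] = 0.5 * (f.tal_min + f.tal_max)
            n_init[i] = max(np.mean(secs["nucleus_to_edge"]), 2.0)
        else:
            case[i] = "C"
            if "nucleus_to_edge" not in secs:
                raise ValueError(f"fish {f.fish_id}: capture-only case needs "
                                 "nucleus_to_edge readings")
            if f.has_tal:
                tal_lat.append(i)
                tal_lo.append(f.tal_min)
                tal_hi.append(f.tal_max)
            n_init[i] = max(np.mean(secs["nucleus_to_edge"]), 2.0)

    if np.nanmin(n_init) < 20.0:
        import warnings

        warnings.warn("mean increment counts below 20: the continuous-count "
                      "normal reading model may be a poor approximation")
    sections = {}
    for s in SECTIONS:
        fi, obs = [], []
        for i, f in enumerate(fish):
            for c in by_fish[f.fish_id].get(s, []):
                fi.append(i)
                obs.append(c)
        if fi:
            sections[s] = (np.array(fi), np.array(obs, dtype=float))
    return AgeingData(fish=fish, case=case, tal_fixed=tal_fixed,
                      tal_latent_idx=np.array(tal_lat, dtype=int),
                      tal_lo=np.array(tal_lo, dtype=float),
                      tal_hi=np.array(tal_hi, dtype=float),
                      n_lo=n_lo, n_hi=n_hi, n_init=n_init,
                      sections=sections)


class AgeEstimationModel:
    """Joint model of reading errors and latent ages for a set of fish.

    When a deposition-step posterior is supplied, its draws of ``rho`` and
    ``b_e`` become moment-matched normal priors here; the nucleus bias
    keeps its informative prior since no data separate it from age.
    """

    def __init__(self, fish, readings, priors: PriorConfig | None = None,
                 deposition_posterior: PosteriorDraws | None = None,
                 cv_date_max: float = 0.05, age_max_days: float = 10 * 365.0):
        priors = PriorConfig(dict(priors if priors is not None else default_priors()))
        if deposition_posterior is not None:
            priors["rho"] = empirical_normal_prior("rho", deposition_posterior.pooled("rho"))
            priors["b_e"] = empirical_normal_prior("b_e", deposition_posterior.pooled("b_e"))
        self.priors = priors
        self.data = prepare_ageing_data(fish, readings, cv_date_max, age_max_days)
        d = self.data
        self.param_blocks = [
            ParamBlock("rho", priors["rho"].lo, priors["rho"].hi,
                       init=min(max(priors["rho"].mean(), 0.55), 1.45), scale=0.01),
            ParamBlock("b_n", priors["b_n"].lo, priors["b_n"].hi,
                       init=priors["b_n"].mean(), scale=1.0),
            ParamBlock("b_e", priors["b_e"].lo, priors["b_e"].hi,
                       init=priors["b_e"].mean(), scale=1.0),
            ParamBlock("p", 1e-6, priors["p"].hi, init=0.1, scale=0.02),
        ]
        self.latent_blocks = [
            LatentBlock("n", lo=d.n_lo, hi=d.n_hi, init=d.n_init, scale=30.0),
        ]
        if d.tal_latent_idx.size:
            self.latent_blocks.append(LatentBlock(
                "tal", lo=d.tal_lo, hi=d.tal_hi,
                init=0.5 * (d.tal_lo + d.tal_hi), scale=30.0))

    def log_prior(self, params: dict) -> float:
        pr = self.priors
        return (pr["rho"].logpdf(params["rho"]) + pr["b_n"].logpdf(params["b_n"])
                + pr["b_e"].logpdf(params["b_e"]) + pr["p"].logpdf(params["p"]))

    def resolve_ages(self, latents: dict, params: dict):
        """Per-fish (a_tag, a_rec, tal) arrays (days) derived from the latent
        true counts: a_tag = (n1 - b_n)/rho for case A, a_rec = (n3 - b_n -
        b_e)/rho otherwise."""
        d = self.data
        tal = d.tal_fixed.copy()
        if d.tal_latent_idx.size and "tal" in latents:
            tal[d.tal_latent_idx] = latents["tal"]
        nlat = latents["n"]
        rho, b_n, b_e = params["rho"], params["b_n"], params["b_e"]
        is_a = d.case == "A"
        a_tag = np.where(is_a, (nlat - b_n) / rho, (nlat - b_n - b_e) / rho - tal)
        a_rec = np.where(is_a, (nlat - b_n) / rho + tal, (nlat - b_n - b_e) / rho)
        return a_tag, a_rec, tal

    def unit_terms(self, params: dict, latents: dict) -> np.ndarray:
        d = self.data
        a_tag, a_rec, tal = self.resolve_ages(latents, params)
        rho, b_n, b_e, p = params["rho"], params["b_n"], params["b_e"], params["p"]
        terms = np.zeros(d.n)
        # structural constraints: positive capture age; capture after tagging
        # when the time at liberty is known
        bad_fish = ~(a_rec > 0)
        has_tal = np.isfinite(tal)
        bad_fish |= has_tal & (a_rec <= tal) & (d.case != "A")
        terms[bad_fish] = -np.inf
        for section, (idx, obs) in d.sections.items():
            if section == "nucleus_to_mark":
                mu_f = rho * a_tag + b_n
            elif section == "mark_to_edge":
                mu_f = rho * tal + b_e
            else:
                mu_f = rho * a_rec + b_n + b_e
            mu = mu_f[idx]
            bad = ~(mu > 0)
            sd = p * np.where(bad, 1.0, mu)
            ll = np.where(bad, -np.inf, _norm_logpdf(obs, mu, sd))
            np.add.at(terms, idx, ll)
        return terms

    def log_density(self, params: dict, latents: dict) -> float:
        return self.log_prior(params) + self.unit_terms(params, latents).sum()


def build_age_model(fish, readings, priors: PriorConfig | None = None,
                    deposition_posterior: PosteriorDraws | None = None,
                    **kw) -> AgeEstimationModel:
    """Assemble the age-estimation model for one fish or a list of fish."""
    if isinstance(fish, FishRecord):
        fish = [fish]
    return AgeEstimationModel(fish, readings, priors, deposition_posterior, **kw)


def derive_age_draws(model: AgeEstimationModel, draws: PosteriorDraws) -> None:
    """Attach per-fish age-at-capture (and tagging) draws in days.

    Ages are deterministic transforms of the latent counts and the ageing
    parameters; results land in ``draws.latents['a_rec']`` / ``['a_tag']``.
    """
    d = model.data
    nlat = draws.latents["n"]  # (chains, draws, n_fish)
    rho = draws.params["rho"][..., None]
    b_n = draws.params["b_n"][..., None]
    b_e = draws.params["b_e"][..., None]
    tal = np.broadcast_to(d.tal_fixed, nlat.shape).copy()
    if d.tal_latent_idx.size and "tal" in draws.latents:
        tal[..., d.tal_latent_idx] = draws.latents["tal"]
    is_a = d.case == "A"
    a_tag = np.where(is_a, (nlat - b_n) / rho, (nlat - b_n - b_e) / rho - tal)
    a_rec = np.where(is_a, (nlat - b_n) / rho + tal, (nlat - b_n - b_e) / rho)
    draws.latents["a_rec"] = a_rec
    draws.latents["a_tag"] = a_tag


def fit_ages(fish, readings, priors: PriorConfig | None = None,
             deposition_posterior: PosteriorDraws | None = None,
             n_chains: int = 3, n_keep: int = 2000, burn: int = 1500,
             thin: int = 1, seed: int = 0, **kw) -> PosteriorDraws:
    """Fit latent ages; draws.latents['a_rec'] holds per-fish age draws (days)."""
    model = build_age_model(fish, readings, priors, deposition_posterior, **kw)
    draws = run_mcmc(model, n_chains=n_chains, n_keep=n_keep, burn=burn,
                     thin=thin, seed=seed, keep_latents=True)
    derive_age_draws(model, draws)
    return draws
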