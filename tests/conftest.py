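import numpy as np
import pytest

from otogrowth.growth import GrowthParams, YFT_MODAL_PARAMS
from otogrowth.priors import default_priors


@pytest.fixture(scope="session")
def modal_params() -> GrowthParams:
    """Posterior-mode reference curve of the yellowfin case study."""
    return YFT_MODAL_PARAMS


@pytest.fixture
def rng():
    return np.random.default_rng(20241001)


def random_growth_params(rng, n=1):
    """Random valid VB-logK parameter draws spanning realistic fish growth."""
    out = []
    for _ in range(n):
        k1 = rng.uniform(0.05, 0.8)
        out.append(GrowthParams(
            linf=rng.uniform(40.0, 250.0),
            k1=k1,
            delta=rng.uniform(0.2, 6.0),
            alpha=rng.uniform(0.5, 5.0),
            beta=rng.uniform(0.5, 20.0),
            t0=rng.uniform(-2.0, 0.0),
            sigma_l=rng.uniform(0.5, 10.0),
        ))
    return out if n > 1 else out[0]


def informative_age_span(p, cap_years=25.0, cum_cap=12.0):
    """Upper test age below curve saturation (where L == linf in floats)."""
    return p.t0 + min(cap_years, cum_cap / max(p.k1, p.k2))


def deposition_informed_priors(rho_mean=0.939, rho_sd=0.029,
                               b_e_mean=-0.549, b_e_sd=2.469):
    """Priors with rho/b_e set from a deposition-step posterior summary."""
    return default_priors(overrides={
        "rho": {"family": "trunc_normal", "mean": rho_mean, "sd": rho_sd,
                "lo": 0.5, "hi": 1.5},
        "b_e": {"family": "trunc_normal", "mean": b_e_mean, "sd": b_e_sd,
                "lo": -20.0, "hi": 20.0},
    })
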