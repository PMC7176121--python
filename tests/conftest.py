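import numpy as np
import pytest

from prevalid import forward_model, golden_cases


@pytest.fixture(scope="session")
def golden():
    """The two packaged case studies, keyed by name."""
    return {c.name: c for c in golden_cases()}


@pytest.fixture(scope="session")
def valid_triples():
    """Random (pi, se, sp) triples bounded away from the degenerate edges.

    A margin keeps every parameter (and every solution-set denominator
    built from them) away from 0/1 boundaries where relative round-off in
    the rational expressions is unbounded.
    """
    rng = np.random.default_rng(12345)
    eps = 1e-6
    n = 10_000
    pi = rng.uniform(eps, 1 - eps, n)
    se = rng.uniform(eps, 1 - eps, n)
    sp = rng.uniform(eps, 1 - eps, n)
    p = se * pi + (1 - sp) * (1 - pi)
    keep = (p > eps) & (p < 1 - eps)
    return pi[keep], se[keep], sp[keep], p[keep]


def full_parameter_arrays(pi, se, sp):
    """All six parameters from (pi, se, sp) by the forward equations."""
    p = se * pi + (1 - sp) * (1 - pi)
    with np.errstate(divide="ignore", invalid="ignore"):
        ppv = np.where(p > 0, se * pi / np.where(p > 0, p, 1.0), np.nan)
        npv = np.where(p < 1, sp * (1 - pi) / np.where(p < 1, 1 - p, 1.0), np.nan)
    return {"pi": pi, "p": p, "se": se, "sp": sp, "ppv": ppv, "npv": npv}


@pytest.fixture(scope="session")
def scalar_profile():
    return forward_model(0.1, 0.8, 0.9)
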