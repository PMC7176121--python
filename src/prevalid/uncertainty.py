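"""Monte-Carlo propagation of input uncertainty to the derived parameters.

Every input parameter is a probability, so a beta distribution is the
natural uncertainty model.  For each input supplied with a 95% CI the beta
shape parameters are fitted by the method of moments: the mean is taken as
given and the standard deviation is read off the CI width as
``sd = (upper - lower) / (2 * 1.96)`` (symmetric normal-approximation
reading; only mean and CI are available).  Inputs without a CI — or with a
zero-width one — are held fixed.

Draws are sampled *independently* (the correlations among the parameters
are generally unknown), the closed-form solution set is applied to every
draw, and draws whose parameter combination is invalid are rejected.  Both
constraint regimes are evaluated on the same draw stream, yielding two
95% percentile uncertainty intervals (UIs) per derived parameter — one
under the [0, 1] range constraints, one under the stricter
better-than-chance constraints — together with the two rejection
percentages.  The better-than-chance region is nested inside the range
region, so its rejection percentage is never smaller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PARAM_NAMES, ParameterSpec, ValidityProfile
from .exceptions import (
    DegeneratePropagationError,
    DomainError,
    InfeasibleMomentsError,
)
from .solver import combo_key, solve, solve_many
from .constraints import chance_mask, range_mask

__all__ = ["BetaParams", "UncertaintyResult", "beta_from_mean_ci", "propagate"]

_Z95 = 1.96  # two-sided 95% normal quantile used to read sd off a CI


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters of a beta distribution (both strictly positive)."""

    alpha: float
    beta: float

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0):
            raise DomainError(
                f"beta shapes must be positive, got ({self.alpha}, {self.beta})"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def sd(self) -> float:
        a, b = self.alpha, self.beta
        return float(np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0))))


def beta_from_mean_ci(mean: float, ci_lower: float, ci_upper: float) -> BetaParams:
    """Method-of-moments beta fit from a mean and a 95% CI.

    With ``sd = (ci_upper - ci_lower) / (2 * 1.96)`` and ``v = sd**2``, the
    shapes are ``alpha = mean * k`` and ``beta = (1 - mean) * k`` where
    ``k = mean * (1 - mean) / v - 1``.  The fitted mean equals the input
    mean exactly.

    Raises :class:`InfeasibleMomentsError` when no beta distribution has
    that mean and variance (``v >= mean * (1 - mean)``, or a zero-width CI).
    """
    if not 0.0 < mean < 1.0:
        raise DomainError(f"mean must lie strictly inside (0, 1), got {mean}")
    if not 0.0 <= ci_lower <= mean <= ci_upper <= 1.0:
        raise DomainError(
            f"CI must satisfy 0 <= {ci_lower} <= {mean} <= {ci_upper} <= 1"
        )
    sd = (ci_upper - ci_lower) / (2.0 * _Z95)
    v = sd * sd
    if v == 0.0:
        raise InfeasibleMomentsError("zero-width CI: no spread to fit")
    m_var = mean * (1.0 - mean)
    if v >= m_var:
        raise InfeasibleMomentsError(
            f"CI-implied variance {v:.4g} >= mean*(1-mean) = {m_var:.4g}: "
            "no beta distribution matches these moments"
        )
    k = m_var / v - 1.0
    return BetaParams(alpha=mean * k, beta=(1.0 - mean) * k)


@dataclass(frozen=True)
class UncertaintyResult:
    """Point estimates plus 95% percentile UIs under both constraint regimes.

    ``ui_range`` / ``ui_chance`` map each parameter to its
    (2.5th, 97.5th) percentile over the accepted draws; ``ui_chance`` is
    ``None`` when every draw violated the better-than-chance constraints.
    ``low_acceptance_*`` flags fewer than 100 accepted draws.
    """

    point: ValidityProfile
    ui_range: dict[str, tuple[float, float]]
    ui_chance: dict[str, tuple[float, float]] | None
    rejection_pct_range: float
    rejection_pct_chance: float
    n_samples: int
    seed: int
    low_acceptance_range: bool = False
    low_acceptance_chance: bool = False

    def to_dict(self) -> dict:
        return {
            "point": self.point.to_dict(),
            "ui_range": {k: list(v) for k, v in self.ui_range.items()},
            "ui_chance": None
            if self.ui_chance is None
            else {k: list(v) for k, v in self.ui_chance.items()},
            "rejection_pct_range": self.rejection_pct_range,
            "rejection_pct_chance": self.rejection_pct_chance,
            "n_samples": self.n_samples,
            "seed": self.seed,
            "low_acceptance_range": self.low_acceptance_range,
            "low_acceptance_chance": self.low_acceptance_chance,
        }


def _sample(spec: ParameterSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.has_ci:
        shapes = beta_from_mean_ci(spec.value, spec.ci_lower, spec.ci_upper)
        return rng.beta(shapes.alpha, shapes.beta, size=n)
    return np.full(n, spec.value)


def propagate(
    p_spec: ParameterSpec,
    known_specs: tuple[ParameterSpec, ParameterSpec],
    n_samples: int = 100_000,
    seed: int | None = None,
    p_counts: tuple[int, int] | None = None,
) -> UncertaintyResult:
    """Propagate input uncertainty through one solution set.

    Parameters
    ----------
    p_spec
        The observed prevalence; sampled from its fitted beta if a CI is
        given, else held fixed (the default behaviour).
    known_specs
        The two other known parameters, each sampled or fixed the same way.
    n_samples
        Monte-Carlo draws (at least 1000).
    seed
        Seed for the random stream; required whenever anything is sampled.
    p_counts
        Optional ``(positives, total)`` raw counts; when given, P is drawn
        from Beta(positives + 1/2, total - positives + 1/2) — the Jeffreys
        posterior of a binomial proportion — instead of from ``p_spec``.

    Returns a fully reproducible :class:`UncertaintyResult`: the same seed
    yields bit-identical output.  Raises
    :class:`DegeneratePropagationError` when no draw satisfies even the
    range constraints.
    """
    if p_spec.name != "p":
        raise DomainError(f"p_spec must be named 'p', got {p_spec.name!r}")
    if len(known_specs) != 2:
        raise DomainError("exactly two known parameter specs required")
    a, b = known_specs
    key = combo_key(a.name, b.name)
    if key != (a.name, b.name):
        a, b = b, a  # canonical orientation
    if n_samples < 1000:
        raise DomainError(f"n_samples must be at least 1000, got {n_samples}")

    anything_random = (
        p_counts is not None or p_spec.has_ci or a.has_ci or b.has_ci
    )
    if anything_random and seed is None:
        raise DomainError("seed is required when any parameter is sampled")
    rng = np.random.default_rng(seed)

    point = solve(p_spec.value, {a.name: a.value, b.name: b.value}, strict=False)

    # one draw stream, fixed order: P first, then the pair in canonical order
    if p_counts is not None:
        pos, tot = p_counts
        if not 0 <= pos <= tot or tot < 1:
            raise DomainError(f"invalid counts ({pos}, {tot})")
        p_draws = rng.beta(pos + 0.5, tot - pos + 0.5, size=n_samples)
    else:
        p_draws = _sample(p_spec, n_samples, rng)
    x_draws = _sample(a, n_samples, rng)
    y_draws = _sample(b, n_samples, rng)

    sol = solve_many(p_draws, x_draws, y_draws, key)
    ok_range = range_mask(p_draws, x_draws, y_draws, key)
    ok_chance = chance_mask(p_draws, x_draws, y_draws, key)

    n_range = int(ok_range.sum())
    n_chance = int(ok_chance.sum())
    if n_range == 0:
        raise DegeneratePropagationError(
            "all draws rejected under the [0, 1] range constraints"
        )

    def _ui(mask: np.ndarray) -> dict[str, tuple[float, float]]:
        out = {}
        for name in PARAM_NAMES:
            lo, hi = np.percentile(sol[name][mask], [2.5, 97.5])
            out[name] = (float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0)))
        return out

    return UncertaintyResult(
        point=point,
        ui_range=_ui(ok_range),
        ui_chance=_ui(ok_chance) if n_chance > 0 else None,
        rejection_pct_range=100.0 * (1.0 - n_range / n_samples),
        rejection_pct_chance=100.0 * (1.0 - n_chance / n_samples),
        n_samples=n_samples,
        seed=-1 if seed is None else int(seed),
        low_acceptance_range=n_range < 100,
        low_acceptance_chance=n_chance < 100,
    )
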