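"""Validity constraints on input parameter combinations.

Not every triple (P, plus two known parameters) corresponds to a real
classifier: the derived parameters are probabilities and must lie in
[0, 1], which translates into inequality constraints on the inputs.  A
second, strictly more restrictive regime additionally demands that the
case-finding algorithm performs *better than chance* — it selects diseased
subjects with higher probability than non-diseased ones, i.e. SE + SP > 1
on the implied profile (equivalently PPV > pi and NPV > 1 - pi whenever
both margins are non-degenerate).

The inequalities are evaluated from the same (numerator, denominator)
expression pairs the solver uses, but through sign-safe products
(``num*den >= 0`` and ``(den-num)*den >= 0``) rather than division, so the
checks are exact up to round-off even where a denominator changes sign.
The correctness contract — report valid iff every derived parameter from a
non-strict solve lies in [0, 1] — is enforced by a dense grid oracle in the
test suite.

A worse-than-chance classifier is repaired, not discarded: relabelling its
positives as negatives (:func:`swap_labels`) yields a better-than-chance
classifier with the same information content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ValidityProfile, _require_probability
from .exceptions import DomainError
from .solver import combo_key, combo_label, row_expressions

__all__ = [
    "Violation",
    "ConstraintReport",
    "check_range",
    "check_better_than_chance",
    "range_mask",
    "chance_mask",
    "swap_labels",
]

#: Boundary tolerance: values within this of 0/1 count as inside [0, 1].
BOUNDARY_TOL = 1e-12


@dataclass(frozen=True)
class Violation:
    """One violated inequality with its evaluated sides.

    ``slack`` is lhs - rhs for >= constraints (negative when violated) and
    rhs - lhs for <= constraints, so slack < 0 always means "violated by
    that much".
    """

    inequality: str
    lhs: float
    rhs: float
    slack: float

    def __str__(self) -> str:
        return f"{self.inequality} [lhs={self.lhs:.6g}, rhs={self.rhs:.6g}]"


@dataclass(frozen=True)
class ConstraintReport:
    regime: str  # "range" or "better_than_chance"
    valid: bool
    violations: tuple[Violation, ...] = field(default_factory=tuple)

    def __post_init__(self):
        assert self.valid == (len(self.violations) == 0)


def _range_violations(
    p: float, x: float, y: float, key: tuple[str, str]
) -> list[Violation]:
    out: list[Violation] = []
    for name, expr in row_expressions(key).items():
        num, den = expr(p, x, y)
        num, den = float(num), float(den)
        if den == 0.0:
            out.append(
                Violation(
                    inequality=f"denominator of {name} ({combo_label(key)}) != 0",
                    lhs=0.0,
                    rhs=0.0,
                    slack=-np.inf,
                )
            )
            continue
        value = num / den
        tol2 = BOUNDARY_TOL * den * den
        if num * den < -tol2:  # value < 0
            out.append(Violation(f"{name} >= 0", value, 0.0, value))
        if (den - num) * den < -tol2:  # value > 1
            out.append(Violation(f"{name} <= 1", value, 1.0, 1.0 - value))
    return out


def check_range(p: float, known: dict[str, float], combo=None) -> ConstraintReport:
    """Do the inputs keep every derived parameter inside [0, 1]?

    ``known`` maps the two known parameter names to their point values; the
    combination is inferred from the names.  Reports, never raises.
    """
    (a, va), (b, vb) = _normalise(known)
    key = combo_key(a, b)
    p = _require_probability("p", p)
    violations = _range_violations(p, va, vb, key)
    return ConstraintReport("range", not violations, tuple(violations))


def check_better_than_chance(
    p: float, known: dict[str, float], combo=None
) -> ConstraintReport:
    """Range constraints plus SE + SP > 1 on the implied profile.

    The better-than-chance criterion is strict: SE + SP = 1 describes a
    classifier indistinguishable from coin-flipping and is rejected.
    Strictly more restrictive than :func:`check_range`.
    """
    (a, va), (b, vb) = _normalise(known)
    key = combo_key(a, b)
    p = _require_probability("p", p)
    violations = _range_violations(p, va, vb, key)
    if not violations:
        se_sp = _implied_se_sp(p, va, vb, key)
        if se_sp is not None and not se_sp > 1.0:
            violations.append(Violation("SE + SP > 1", se_sp, 1.0, se_sp - 1.0))
    return ConstraintReport("better_than_chance", not violations, tuple(violations))


def _implied_se_sp(p: float, x: float, y: float, key: tuple[str, str]) -> float | None:
    values = {key[0]: x, key[1]: y}
    for name in ("se", "sp"):
        if name not in values:
            num, den = row_expressions(key)[name](p, x, y)
            num, den = float(num), float(den)
            if den == 0.0:
                return None
            values[name] = num / den
    return values["se"] + values["sp"]


def _normalise(known: dict[str, float]) -> list[tuple[str, float]]:
    if len(known) != 2:
        raise DomainError(f"exactly two known parameters required, got {len(known)}")
    items = [(k, _require_probability(k, v)) for k, v in known.items()]
    key = combo_key(items[0][0], items[1][0])
    items.sort(key=lambda kv: key.index(kv[0]))
    return items


# --- vectorised masks (used by Monte-Carlo propagation and grid oracles) ---


def range_mask(
    p: np.ndarray, x: np.ndarray, y: np.ndarray, key: tuple[str, str]
) -> np.ndarray:
    """Boolean mask: True where all derived parameters lie in [0, 1].

    Array counterpart of :func:`check_range`; zero denominators are invalid.
    """
    p, x, y = np.broadcast_arrays(
        np.asarray(p, dtype=float), np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    )
    ok = np.ones(p.shape, dtype=bool)
    for _, expr in row_expressions(key).items():
        num, den = expr(p, x, y)
        num = np.broadcast_to(np.asarray(num, dtype=float), p.shape)
        den = np.broadcast_to(np.asarray(den, dtype=float), p.shape)
        tol2 = BOUNDARY_TOL * den * den
        ok &= den != 0.0
        ok &= num * den >= -tol2
        ok &= (den - num) * den >= -tol2
    return ok


def chance_mask(
    p: np.ndarray, x: np.ndarray, y: np.ndarray, key: tuple[str, str]
) -> np.ndarray:
    """Boolean mask for the better-than-chance regime (subset of range)."""
    p, x, y = np.broadcast_arrays(
        np.asarray(p, dtype=float), np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    )
    ok = range_mask(p, x, y, key)
    values = {key[0]: x, key[1]: y}
    exprs = row_expressions(key)
    se_sp = np.zeros(p.shape, dtype=float)
    for name in ("se", "sp"):
        if name in values:
            se_sp = se_sp + values[name]
        else:
            num, den = exprs[name](p, x, y)
            num = np.broadcast_to(np.asarray(num, dtype=float), p.shape)
            den = np.broadcast_to(np.asarray(den, dtype=float), p.shape)
            with np.errstate(divide="ignore", invalid="ignore"):
                v = np.where(den != 0.0, num / np.where(den != 0.0, den, 1.0), np.nan)
            se_sp = se_sp + v
    ok &= np.isfinite(se_sp) & (se_sp > 1.0)
    return ok


def swap_labels(profile: ValidityProfile) -> ValidityProfile:
    """Profile of the label-swapped classifier (positives <-> negatives).

    Relabelling turns positives into negatives: P' = 1-P, SE' = 1-SE,
    SP' = 1-SP, and the predictive values trade places through their
    complements (PPV' = 1-NPV, NPV' = 1-PPV); the true prevalence is
    untouched.  An involution; maps a worse-than-chance classifier
    (SE + SP < 1) to a better-than-chance one.
    """
    return ValidityProfile(
        pi=profile.pi,
        p=1.0 - profile.p,
        se=1.0 - profile.se,
        sp=1.0 - profile.sp,
        ppv=None if profile.npv is None else 1.0 - profile.npv,
        npv=None if profile.ppv is None else 1.0 - profile.ppv,
    )
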