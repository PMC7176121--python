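"""Core data model and forward equations.

A case-finding algorithm (CFA) classifies every subject of a database as
diseased or non-diseased.  Compared against an error-free ("gold standard")
reference, its performance is captured by a 2x2 table and summarised by six
linked parameters:

* ``pi``  — true prevalence, the proportion of truly diseased subjects,
* ``p``   — observed prevalence, the proportion of CFA-positives,
* ``se``  — sensitivity, P(CFA+ | diseased),
* ``sp``  — specificity, P(CFA- | non-diseased),
* ``ppv`` — positive predictive value, P(diseased | CFA+),
* ``npv`` — negative predictive value, P(non-diseased | CFA-).

They are tied together by the forward system

    P   = SE*pi + (1 - SP)*(1 - pi)
    PPV = SE*pi / P
    NPV = SP*(1 - pi) / (1 - P)

so that any three parameters including P determine the other three (see
:mod:`prevalid.solver`).  This module houses the containers, the forward
map from (pi, SE, SP), the conversion from raw 2x2 counts, and the
consistency check.

PPV is genuinely undefined when P = 0 (no positives to condition on) and
NPV when P = 1; such 0/0 ratios are represented as ``None``, never silently
coerced to 0 or 1.  Consistency is therefore checked on the cross-multiplied
identities ``PPV*P = SE*pi`` and ``NPV*(1-P) = SP*(1-pi)``, which hold by
convention in the undefined cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

from .exceptions import DomainError, UndefinedIndexError

__all__ = [
    "PARAM_NAMES",
    "ConfusionTable",
    "ValidityProfile",
    "ParameterSpec",
    "forward_model",
    "profile_from_counts",
    "check_consistency",
]

#: Canonical parameter order used throughout the package and its I/O.
PARAM_NAMES = ("pi", "p", "se", "sp", "ppv", "npv")


def _require_probability(name: str, value: float) -> float:
    """Validate that ``value`` is a finite number in the closed unit interval.

    Inputs are never clamped: silently repairing an out-of-range probability
    would mask user error.
    """
    try:
        value = float(value)
    except (TypeError, ValueError) as exc:
        raise DomainError(f"{name} must be a number, got {value!r}") from exc
    if not math.isfinite(value) or not 0.0 <= value <= 1.0:
        raise DomainError(f"{name} must lie in [0, 1], got {value}")
    return value


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 validation table of CFA classification against the gold standard.

    Cell counts are non-negative integers: ``tp`` true positives, ``fp``
    false positives, ``fn`` false negatives, ``tn`` true negatives.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise DomainError(f"{f.name} must be an integer, got {v!r}")
            if v < 0:
                raise DomainError(f"{f.name} must be non-negative, got {v}")
        if self.n < 1:
            raise DomainError("table must contain at least one subject")

    @property
    def n(self) -> int:
        """Total number of subjects."""
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}

    @classmethod
    def from_dict(cls, d: dict) -> "ConfusionTable":
        return cls(tp=int(d["tp"]), fp=int(d["fp"]), fn=int(d["fn"]), tn=int(d["tn"]))


@dataclass(frozen=True)
class ValidityProfile:
    """The six linked parameters of a CFA.

    ``ppv``/``npv`` may be ``None`` to mark a genuinely undefined 0/0
    conditional (no CFA-positives resp. no CFA-negatives).

    The container intentionally admits out-of-range values so that
    non-strict solving can hand back flagged results; use
    :meth:`out_of_range` to inspect and :func:`check_consistency` to verify
    the identities.  Profiles produced by :func:`forward_model` and
    :func:`profile_from_counts` are always in range and consistent.
    """

    pi: float
    p: float
    se: float
    sp: float
    ppv: float | None
    npv: float | None

    def __post_init__(self):
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if v is None:
                if name in ("ppv", "npv"):
                    continue
                raise DomainError(f"{name} may not be None")
            if not math.isfinite(float(v)):
                raise DomainError(f"{name} must be finite, got {v!r}")

    def out_of_range(self, tol: float = 0.0) -> tuple[str, ...]:
        """Names of parameters lying outside [0 - tol, 1 + tol]."""
        bad = []
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if v is not None and not (-tol <= v <= 1.0 + tol):
                bad.append(name)
        return tuple(bad)

    @property
    def is_proper(self) -> bool:
        """True when every defined parameter lies in [0, 1]."""
        return not self.out_of_range()

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "ValidityProfile":
        return cls(**{name: d[name] for name in PARAM_NAMES})


@dataclass(frozen=True)
class ParameterSpec:
    """One named parameter with a point value and optional 95% CI.

    The CI, when present, must bracket the point value inside [0, 1].
    """

    name: str
    value: float
    ci_lower: float | None = None
    ci_upper: float | None = None

    def __post_init__(self):
        if self.name not in PARAM_NAMES:
            raise DomainError(
                f"unknown parameter {self.name!r}; expected one of {PARAM_NAMES}"
            )
        _require_probability(self.name, self.value)
        if (self.ci_lower is None) != (self.ci_upper is None):
            raise DomainError("provide both CI bounds or neither")
        if self.ci_lower is not None:
            lo = _require_probability(f"{self.name} ci_lower", self.ci_lower)
            hi = _require_probability(f"{self.name} ci_upper", self.ci_upper)
            if not lo <= self.value <= hi:
                raise DomainError(
                    f"CI must bracket the value: {lo} <= {self.value} <= {hi} fails"
                )

    @property
    def has_ci(self) -> bool:
        return self.ci_lower is not None and self.ci_upper != self.ci_lower


def forward_model(pi: float, se: float, sp: float) -> ValidityProfile:
    """Complete the profile from true prevalence, sensitivity and specificity.

    Applies the forward equations: observed prevalence
    ``P = SE*pi + (1-SP)*(1-pi)``, then the predictive values as conditional
    probabilities.  PPV is ``None`` when P = 0 and NPV is ``None`` when
    P = 1 (0/0 by convention).

    Raises :class:`DomainError` for inputs outside [0, 1].
    """
    pi = _require_probability("pi", pi)
    se = _require_probability("se", se)
    sp = _require_probability("sp", sp)
    p = se * pi + (1.0 - sp) * (1.0 - pi)
    ppv = (se * pi / p) if p > 0.0 else None
    npv = (sp * (1.0 - pi) / (1.0 - p)) if p < 1.0 else None
    return ValidityProfile(pi=pi, p=p, se=se, sp=sp, ppv=ppv, npv=npv)


def profile_from_counts(table: ConfusionTable) -> ValidityProfile:
    """Convert 2x2 counts to the six-parameter profile.

    SE = TP/(TP+FN), SP = TN/(FP+TN), PPV = TP/(TP+FP), NPV = TN/(FN+TN),
    P = (TP+FP)/N, pi = (TP+FN)/N.  Any index whose conditioning margin is
    empty raises :class:`UndefinedIndexError` naming the index.
    """
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    n = table.n
    for index, margin in (
        ("se", tp + fn),
        ("sp", fp + tn),
        ("ppv", tp + fp),
        ("npv", fn + tn),
    ):
        if margin == 0:
            raise UndefinedIndexError(index)
    return ValidityProfile(
        pi=(tp + fn) / n,
        p=(tp + fp) / n,
        se=tp / (tp + fn),
        sp=tn / (fp + tn),
        ppv=tp / (tp + fp),
        npv=tn / (fn + tn),
    )


def check_consistency(
    profile: ValidityProfile, tol: float = 1e-9
) -> tuple[bool, list[str]]:
    """Verify the three forward identities on a profile.

    The predictive-value identities are checked in cross-multiplied form
    (``PPV*P = SE*pi`` and ``NPV*(1-P) = SP*(1-pi)``) so that undefined 0/0
    conditionals are consistent by convention.  Returns ``(ok, violations)``
    where ``violations`` names each failed identity with its residual.
    """
    pi, p, se, sp = profile.pi, profile.p, profile.se, profile.sp
    violations: list[str] = []

    r1 = p - (se * pi + (1.0 - sp) * (1.0 - pi))
    if abs(r1) > tol:
        violations.append(
            f"observed-prevalence identity P = SE*pi + (1-SP)*(1-pi) "
            f"(residual {r1:.3e})"
        )

    if profile.ppv is None:
        # undefined only when P = 0, where SE*pi = 0 too: consistent
        if p > tol or abs(se * pi) > tol:
            violations.append("ppv undefined although P > 0")
    else:
        r2 = profile.ppv * p - se * pi
        if abs(r2) > tol:
            violations.append(
                f"positive-predictive identity PPV*P = SE*pi (residual {r2:.3e})"
            )

    if profile.npv is None:
        if (1.0 - p) > tol or abs(sp * (1.0 - pi)) > tol:
            violations.append("npv undefined although P < 1")
    else:
        r3 = profile.npv * (1.0 - p) - sp * (1.0 - pi)
        if abs(r3) > tol:
            violations.append(
                f"negative-predictive identity NPV*(1-P) = SP*(1-pi) "
                f"(residual {r3:.3e})"
            )

    return (not violations, violations)
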