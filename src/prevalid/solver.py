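"""Closed-form solution sets: from P plus any two parameters to all six.

The forward system

    P   = SE*pi + (1 - SP)*(1 - pi)
    PPV = SE*pi / P
    NPV = SP*(1 - pi) / (1 - P)

can be inverted in closed form whenever the observed prevalence P and any
two of {pi, SE, SP, PPV, NPV} are known — ten distinct combinations in all.
Each combination has its own set of three rational expressions, implemented
here row by row with explicit denominator guards rather than re-derived on
the fly, so degenerate inputs (e.g. SE + SP = 1 for the {SE, SP} pair — the
classical Rogan-Gladen denominator) raise precise errors.

Every expression is stored as a (numerator, denominator) pair.  The solver
divides; the :mod:`prevalid.constraints` module reuses the same pairs to
test 0 <= num/den <= 1 via sign-safe products, without dividing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from .core import PARAM_NAMES, ValidityProfile, _require_probability
from .exceptions import (
    ConstraintViolationError,
    DegenerateCombinationError,
    DomainError,
)

__all__ = [
    "ALL_COMBOS",
    "combo_key",
    "combo_label",
    "solve",
    "solve_many",
    "rogan_gladen",
    "derive_over_interval",
    "IntervalResult",
]

# Order of the five free parameters (P is always known) fixes a canonical
# orientation (x, y) for each pair.
_ORDER = {"pi": 0, "se": 1, "sp": 2, "ppv": 3, "npv": 4}

#: The ten known-pairs, in the package's canonical enumeration.
ALL_COMBOS: tuple[tuple[str, str], ...] = (
    ("pi", "se"),
    ("pi", "sp"),
    ("pi", "ppv"),
    ("pi", "npv"),
    ("se", "sp"),
    ("se", "ppv"),
    ("se", "npv"),
    ("sp", "ppv"),
    ("sp", "npv"),
    ("ppv", "npv"),
)


def combo_key(a: str, b: str) -> tuple[str, str]:
    """Canonicalise an unordered pair of known parameter names.

    Both names must be drawn from {pi, se, sp, ppv, npv} (P is implicitly
    known) and be distinct.
    """
    for name in (a, b):
        if name not in _ORDER:
            raise DomainError(
                f"unknown or inadmissible parameter {name!r}; "
                "the pair is drawn from {pi, se, sp, ppv, npv}"
            )
    if a == b:
        raise DomainError(f"the two known parameters must differ, got {a!r} twice")
    return tuple(sorted((a, b), key=_ORDER.__getitem__))  # type: ignore[return-value]


def combo_label(key: tuple[str, str]) -> str:
    """Human-readable label, e.g. ``'P-SE-PPV'``."""
    pretty = {"pi": "pi", "p": "P", "se": "SE", "sp": "SP", "ppv": "PPV", "npv": "NPV"}
    return "-".join(["P"] + [pretty[k] for k in key])


# --- the ten solution sets -------------------------------------------------
#
# Each entry maps a derived parameter name to a callable
#   f(p, x, y) -> (numerator, denominator)
# where (x, y) is the known pair in canonical order.  The callables are
# plain arithmetic and accept scalars or numpy arrays alike.

Expr = Callable[[np.ndarray, np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]

_ROWS: dict[tuple[str, str], dict[str, Expr]] = {
    # known pi (=x), se (=y)
    ("pi", "se"): {
        "sp": lambda p, x, y: ((1 - x) - (p - y * x), 1 - x),
        "ppv": lambda p, x, y: (y * x, p),
        "npv": lambda p, x, y: ((1 - p) - x * (1 - y), 1 - p),
    },
    # known pi (=x), sp (=y)
    ("pi", "sp"): {
        "se": lambda p, x, y: (p - (1 - x) * (1 - y), x),
        "ppv": lambda p, x, y: (p - (1 - x) * (1 - y), p),
        "npv": lambda p, x, y: (y * (1 - x), 1 - p),
    },
    # known pi (=x), ppv (=y)
    ("pi", "ppv"): {
        "se": lambda p, x, y: (p * y, x),
        "sp": lambda p, x, y: ((1 - x) - p * (1 - y), 1 - x),
        "npv": lambda p, x, y: ((1 - p) - (x - p * y), 1 - p),
    },
    # known pi (=x), npv (=y)
    ("pi", "npv"): {
        "se": lambda p, x, y: (x - (1 - p) * (1 - y), x),
        "sp": lambda p, x, y: (y * (1 - p), 1 - x),
        "ppv": lambda p, x, y: (x - (1 - p) * (1 - y), p),
    },
    # known se (=x), sp (=y): pi is the Rogan-Gladen estimator
    ("se", "sp"): {
        "pi": lambda p, x, y: (p + y - 1, x + y - 1),
        "ppv": lambda p, x, y: (x * (p + y - 1), p * (x + y - 1)),
        "npv": lambda p, x, y: (y * (x - p), (1 - p) * (x + y - 1)),
    },
    # known se (=x), ppv (=y)
    ("se", "ppv"): {
        "pi": lambda p, x, y: (p * y, x),
        "sp": lambda p, x, y: ((x - p * y) - x * p * (1 - y), x - p * y),
        "npv": lambda p, x, y: (x * (1 - p) - (1 - x) * p * y, x * (1 - p)),
    },
    # known se (=x), npv (=y)
    ("se", "npv"): {
        "pi": lambda p, x, y: ((1 - p) * (1 - y), 1 - x),
        "sp": lambda p, x, y: (
            (1 - p) * (1 - x) * y,
            (1 - x) - (1 - p) * (1 - y),
        ),
        "ppv": lambda p, x, y: (x * (1 - p) * (1 - y), p * (1 - x)),
    },
    # known sp (=x), ppv (=y)
    ("sp", "ppv"): {
        "pi": lambda p, x, y: ((1 - x) - p * (1 - y), 1 - x),
        "se": lambda p, x, y: (p * y * (1 - x), (1 - x) - p * (1 - y)),
        "npv": lambda p, x, y: (p * x * (1 - y), (1 - p) * (1 - x)),
    },
    # known sp (=x), npv (=y)
    ("sp", "npv"): {
        "pi": lambda p, x, y: (x - (1 - p) * y, x),
        "se": lambda p, x, y: (
            p * x - (1 - x) * (1 - p) * y,
            x - (1 - p) * y,
        ),
        "ppv": lambda p, x, y: (p * x - (1 - x) * (1 - p) * y, p * x),
    },
    # known ppv (=x), npv (=y)
    ("ppv", "npv"): {
        "pi": lambda p, x, y: ((1 - p) * (1 - y) + p * x, 1.0 + 0.0 * p),
        "se": lambda p, x, y: (p * x, (1 - p) * (1 - y) + p * x),
        "sp": lambda p, x, y: (
            (1 - p) * y,
            1 - ((1 - p) * (1 - y) + p * x),
        ),
    },
}

# Tolerance for snapping derived values to the [0, 1] boundary: pure
# floating-point round-off, orders of magnitude below any scientific signal.
_SNAP = 1e-12


def row_expressions(key: tuple[str, str]) -> dict[str, Expr]:
    """The (numerator, denominator) expression pairs of one solution set."""
    return _ROWS[key]


def solve(
    p: float,
    known: dict[str, float],
    strict: bool = True,
    tol: float = 1e-9,
) -> ValidityProfile:
    """Derive the full six-parameter profile from P and two known parameters.

    Parameters
    ----------
    p
        Observed prevalence, in [0, 1].
    known
        Mapping with exactly two entries drawn from
        ``{pi, se, sp, ppv, npv}``, each a point value in [0, 1].
    strict
        When True (default), raise :class:`ConstraintViolationError` if any
        derived parameter leaves [0, 1]; when False, return the profile with
        the out-of-range values in place (inspect with
        ``profile.out_of_range()``).
    tol
        Consistency tolerance documented for the returned profile.

    Raises
    ------
    DegenerateCombinationError
        If a solution expression has a vanishing denominator (both modes).
    ConstraintViolationError
        In strict mode, when a derived value leaves [0, 1].
    """
    if len(known) != 2:
        raise DomainError(f"exactly two known parameters required, got {len(known)}")
    (a, va), (b, vb) = sorted(known.items(), key=lambda kv: _ORDER.get(kv[0], 99))
    key = combo_key(a, b)
    p = _require_probability("p", p)
    x = _require_probability(a, va)
    y = _require_probability(b, vb)

    values: dict[str, float] = {"p": p, a: x, b: y}
    for name, expr in _ROWS[key].items():
        num, den = expr(p, x, y)
        num, den = float(num), float(den)
        if den == 0.0:
            raise DegenerateCombinationError(
                f"{name} for known {combo_label(key)}",
                f"denominator of {name} vanishes for known {combo_label(key)} "
                f"at p={p}, {a}={x}, {b}={y}",
            )
        v = num / den
        # snap floating-point round-off at the boundaries
        if -_SNAP <= v < 0.0:
            v = 0.0
        elif 1.0 < v <= 1.0 + _SNAP:
            v = 1.0
        values[name] = v

    if strict:
        violations = [
            f"0 <= {name} <= 1 (got {values[name]:.6g})"
            for name in _ROWS[key]
            if not 0.0 <= values[name] <= 1.0
        ]
        if violations:
            raise ConstraintViolationError(violations)

    return ValidityProfile(**{name: values[name] for name in PARAM_NAMES})


def solve_many(
    p: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    key: tuple[str, str],
) -> dict[str, np.ndarray]:
    """Vectorised non-strict solve over arrays of inputs.

    Returns all six parameters as broadcast arrays; entries whose solution
    expression has a zero denominator are NaN.  No range checking is
    performed (see :mod:`prevalid.constraints` for masks).
    """
    p, x, y = np.broadcast_arrays(
        np.asarray(p, dtype=float), np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    )
    out = {"p": p.copy(), key[0]: x.copy(), key[1]: y.copy()}
    for name, expr in _ROWS[key].items():
        num, den = expr(p, x, y)
        num = np.broadcast_to(np.asarray(num, dtype=float), p.shape)
        den = np.broadcast_to(np.asarray(den, dtype=float), p.shape)
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(den != 0.0, num / np.where(den != 0.0, den, 1.0), np.nan)
        out[name] = v
    return out


def rogan_gladen(p: float, se: float, sp: float) -> float:
    """Misclassification-corrected (true) prevalence from P, SE and SP.

    The classical estimator ``pi = (P + SP - 1) / (SE + SP - 1)``; identical
    to the pi component of the {SE, SP} solution set.  The raw value is
    returned without range restriction (it exceeds [0, 1] when the inputs
    are incompatible; see :mod:`prevalid.constraints`).

    Raises :class:`DegenerateCombinationError` when SE + SP = 1
    (classifier uninformative).
    """
    p = _require_probability("p", p)
    se = _require_probability("se", se)
    sp = _require_probability("sp", sp)
    den = se + sp - 1.0
    if den == 0.0:
        raise DegenerateCombinationError(
            "SE + SP = 1", "SE + SP = 1: the classifier is uninformative"
        )
    return (p + sp - 1.0) / den


@dataclass(frozen=True)
class IntervalResult:
    """Ranges of the derived parameters over an input interval.

    ``ranges`` maps each derived parameter to its (min, max) over the valid
    grid points; ``invalid_points`` lists the interval-parameter values whose
    triple violated the [0, 1] range constraints and was excluded.
    """

    ranges: dict[str, tuple[float, float]]
    n_grid: int
    n_valid: int
    invalid_points: tuple[float, ...]


def derive_over_interval(
    p: float,
    fixed: tuple[str, float],
    interval_param: str,
    bounds: tuple[float, float],
    n_grid: int = 101,
) -> IntervalResult:
    """Ranges of the derived parameters as one input sweeps an interval.

    With P and ``fixed`` held constant, the ``interval_param`` is evaluated
    on an evenly spaced grid over ``bounds`` (both endpoints always
    included).  Each Table-row expression is monotone in each argument over
    a valid region, so the returned extrema coincide with endpoint values
    whenever the whole interval is valid.

    Grid points violating the [0, 1] range constraints are excluded and
    reported in the result; if no grid point is valid a
    :class:`ConstraintViolationError` is raised.
    """
    lo, hi = bounds
    lo = _require_probability(f"{interval_param} lower bound", lo)
    hi = _require_probability(f"{interval_param} upper bound", hi)
    if lo > hi:
        raise DomainError(f"interval bounds out of order: {lo} > {hi}")
    if n_grid < 2 and lo != hi:
        raise DomainError("n_grid must be at least 2")
    fixed_name, fixed_value = fixed
    key = combo_key(fixed_name, interval_param)
    p = _require_probability("p", p)
    fixed_value = _require_probability(fixed_name, fixed_value)

    grid = np.linspace(lo, hi, num=max(n_grid, 1))
    if key[0] == fixed_name:
        xs, ys = np.full_like(grid, fixed_value), grid
    else:
        xs, ys = grid, np.full_like(grid, fixed_value)
    sol = solve_many(np.full_like(grid, p), xs, ys, key)

    derived = [name for name in PARAM_NAMES if name not in ("p", fixed_name, interval_param)]
    valid = np.ones_like(grid, dtype=bool)
    for name in derived:
        v = sol[name]
        valid &= np.isfinite(v) & (v >= -_SNAP) & (v <= 1.0 + _SNAP)

    if not valid.any():
        raise ConstraintViolationError(
            [f"no valid grid point in {interval_param} in [{lo}, {hi}]"]
        )
    ranges = {
        name: (
            float(np.clip(sol[name][valid].min(), 0.0, 1.0)),
            float(np.clip(sol[name][valid].max(), 0.0, 1.0)),
        )
        for name in derived
    }
    return IntervalResult(
        ranges=ranges,
        n_grid=int(grid.size),
        n_valid=int(valid.sum()),
        invalid_points=tuple(float(g) for g in grid[~valid]),
    )
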