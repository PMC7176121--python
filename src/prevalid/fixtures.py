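"""Synthetic confusion tables and the two published validation case studies.

Every module in the package is testable without external data: expected or
multinomially sampled 2x2 tables are generated from a known ground-truth
triple (pi, SE, SP), and the two published case-finding-algorithm
validation studies — intussusception in Ontario paediatric records and
claims-based pneumonia detection in emergency-department encounters — ship
as golden cases carrying their printed summary numbers.

Because the published numbers are rounded (e.g. prevalences printed as
0.044% and 0.036%), golden expectations are compared with a
rounding-aware comparator: a computed value matches the printed string if
it rounds to it at the printed precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .core import ConfusionTable, ParameterSpec, _require_probability
from .exceptions import DomainError

__all__ = [
    "ExpectedCounts",
    "expected_counts",
    "sample_counts",
    "GoldenCase",
    "golden_cases",
    "rounds_to",
]


@dataclass(frozen=True)
class ExpectedCounts:
    """Exact (real-valued) expected cell counts of a 2x2 table.

    Companion form of :class:`~prevalid.core.ConfusionTable` whose cells
    need not be integers; convert with :meth:`as_table` when they are.
    """

    tp: float
    fp: float
    fn: float
    tn: float

    @property
    def n(self) -> float:
        return self.tp + self.fp + self.fn + self.tn

    def is_integral(self, tol: float = 1e-9) -> bool:
        return all(
            abs(c - round(c)) <= tol for c in (self.tp, self.fp, self.fn, self.tn)
        )

    def as_table(self, tol: float = 1e-9) -> ConfusionTable:
        if not self.is_integral(tol):
            raise DomainError(
                f"expected counts are not integral: "
                f"({self.tp}, {self.fp}, {self.fn}, {self.tn})"
            )
        return ConfusionTable(
            tp=round(self.tp), fp=round(self.fp), fn=round(self.fn), tn=round(self.tn)
        )


def expected_counts(pi: float, se: float, sp: float, n: int) -> ExpectedCounts:
    """Expected 2x2 cell counts for n subjects under (pi, SE, SP).

    TP = n*pi*SE, FN = n*pi*(1-SE), FP = n*(1-pi)*(1-SP), TN = n*(1-pi)*SP.
    When all four are integers, converting back through
    :func:`~prevalid.core.profile_from_counts` recovers the generating
    triple exactly.
    """
    pi = _require_probability("pi", pi)
    se = _require_probability("se", se)
    sp = _require_probability("sp", sp)
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    return ExpectedCounts(
        tp=n * pi * se,
        fn=n * pi * (1.0 - se),
        fp=n * (1.0 - pi) * (1.0 - sp),
        tn=n * (1.0 - pi) * sp,
    )


def sample_counts(
    pi: float, se: float, sp: float, n: int, seed: int | np.random.Generator
) -> ConfusionTable:
    """One multinomial draw of a 2x2 table under (pi, SE, SP).

    The four cells are drawn jointly with probabilities
    (pi*SE, pi*(1-SE), (1-pi)*(1-SP), (1-pi)*SP) for (TP, FN, FP, TN);
    totals always sum to n and the draw is reproducible by seed.
    """
    pi = _require_probability("pi", pi)
    se = _require_probability("se", se)
    sp = _require_probability("sp", sp)
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = [pi * se, pi * (1.0 - se), (1.0 - pi) * (1.0 - sp), (1.0 - pi) * sp]
    tp, fn, fp, tn = (int(c) for c in rng.multinomial(n, probs))
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class GoldenCase:
    """One published validation study with its printed numbers.

    ``specs`` holds the reported parameters (point values and 95% CIs) on
    the probability scale; ``expected`` the printed derived values as
    strings at their original precision (percent scale), checkable with
    :func:`rounds_to`.
    """

    name: str
    description: str
    n_subjects: int
    cfa_positives: int
    gold_positives: int
    specs: dict[str, ParameterSpec]
    expected: dict

    @property
    def observed_prevalence(self) -> float:
        return self.cfa_positives / self.n_subjects

    @property
    def true_prevalence(self) -> float:
        return self.gold_positives / self.n_subjects


def golden_cases() -> list[GoldenCase]:
    """The two packaged case studies (intussusception, pneumonia)."""
    raw = json.loads(
        resources.files("prevalid").joinpath("data/golden_cases.json").read_text()
    )
    cases = []
    for entry in raw:
        specs = {
            name: ParameterSpec(
                name=name,
                value=s["value"],
                ci_lower=s.get("ci_lower"),
                ci_upper=s.get("ci_upper"),
            )
            for name, s in entry["specs"].items()
        }
        cases.append(
            GoldenCase(
                name=entry["name"],
                description=entry["description"],
                n_subjects=entry["n_subjects"],
                cfa_positives=entry["cfa_positives"],
                gold_positives=entry["gold_positives"],
                specs=specs,
                expected=entry["expected"],
            )
        )
    return cases


def rounds_to(value: float, printed: str) -> bool:
    """Does ``value`` round to the ``printed`` decimal string?

    The number of decimals is read off the string itself, so ``"0.036"``
    demands 3-decimal agreement and ``"88.5"`` 1-decimal agreement.
    """
    printed = printed.strip()
    decimals = len(printed.split(".")[1]) if "." in printed else 0
    return f"{float(value):.{decimals}f}" == f"{float(printed):.{decimals}f}"
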