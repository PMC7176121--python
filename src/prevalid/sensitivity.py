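"""One-at-a-time (OAT) sensitivity analysis of the solution sets.

How badly does estimation error in an input parameter distort the derived
parameters?  Starting from a baseline classifier (true prevalence pi,
sensitivity SE, specificity SP — the full profile follows by the forward
equations), each of the three inputs of every solution set is perturbed one
at a time by +-1 standard error while the others stay at baseline, and the
solution set is re-solved.  The s.e. of a parameter with baseline value v
is the binomial-proportion standard error sqrt(v*(1-v)/n) at a nominal
validation sample size n (default 1000).

Biases of the derived parameters are expressed in units of their own
binomial s.e. (same formula, same n, evaluated at the derived baseline
value — the only self-consistent reading when no other scale is given) and
reported truncated at +-3 s.e.; the untruncated value is always retained.
Perturbed inputs are clipped into [0, 1] (flagged) and re-solved
non-strictly under the less restrictive [0, 1] range constraints; perturbed
triples that violate even those are recorded as invalid rather than
silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import PARAM_NAMES, ValidityProfile, forward_model, _require_probability
from .exceptions import DegenerateCombinationError, DomainError, ScenarioError
from .solver import ALL_COMBOS, combo_label, solve

__all__ = [
    "binomial_se",
    "SensitivityScenario",
    "oat_analysis",
    "scenario_suite",
    "SuiteResult",
    "rank_combos",
    "plot_oat",
]


def binomial_se(p: float, n: int) -> float:
    """Standard error of a binomial proportion: sqrt(p*(1-p)/n)."""
    p = _require_probability("p", p)
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool) or n < 1:
        raise DomainError(f"sample size must be a positive integer, got {n!r}")
    return math.sqrt(p * (1.0 - p) / n)


@dataclass(frozen=True)
class SensitivityScenario:
    """Baseline classifier for an OAT run.

    ``n_se`` is the nominal validation sample size behind every standard
    error; ``truncation`` caps the *reported* bias (in s.e. units).  The
    baseline must be better than chance (SE + SP > 1) and must yield all
    six parameters (0 < P < 1, so the predictive values exist).
    """

    pi: float
    se: float
    sp: float
    n_se: int = 1000
    truncation: float = 3.0

    def __post_init__(self):
        profile = forward_model(self.pi, self.se, self.sp)  # validates [0,1]
        if not self.se + self.sp > 1.0:
            raise ScenarioError(
                f"baseline must be better than chance: SE + SP = "
                f"{self.se + self.sp} <= 1"
            )
        if profile.ppv is None or profile.npv is None:
            raise ScenarioError(
                "baseline observed prevalence is 0 or 1: predictive values undefined"
            )
        if self.n_se < 1:
            raise ScenarioError(f"n_se must be >= 1, got {self.n_se}")
        if not self.truncation > 0:
            raise ScenarioError(f"truncation must be positive, got {self.truncation}")

    @property
    def baseline(self) -> ValidityProfile:
        return forward_model(self.pi, self.se, self.sp)


_COLUMNS = [
    "combo",
    "varied",
    "direction",
    "param",
    "baseline_value",
    "perturbed_value",
    "delta",
    "bias_se_units",
    "bias_reported",
    "truncated",
    "clipped",
    "invalid",
    "violation",
]


def oat_analysis(scenario: SensitivityScenario) -> pd.DataFrame:
    """Run the OAT perturbation over all ten solution sets.

    Returns a long-format table with one row per
    (combo, varied input, direction, derived parameter):

    ``bias_se_units``
        (perturbed - baseline) / s.e.(baseline), untruncated.
    ``bias_reported``
        The same, truncated at +-``scenario.truncation`` (``truncated``
        flags where the cap bit).
    ``clipped``
        The perturbed *input* left [0, 1] and was clipped.
    ``invalid``
        The perturbed triple violated the range constraints (or hit a
        degenerate denominator); biases are NaN and ``violation`` names
        the failure.
    """
    base = scenario.baseline
    base_values = base.to_dict()
    rows: list[dict] = []

    for key in ALL_COMBOS:
        label = combo_label(key)
        input_names = ("p",) + key
        derived = [n for n in PARAM_NAMES if n not in input_names]
        # baseline derived values through the same solution-set expressions
        # the perturbed runs use, so a zero perturbation gives exactly zero
        # bias (the forward profile agrees to round-off but not bit-exactly);
        # perfect-test baselines can make a set's denominator vanish at the
        # baseline itself (e.g. pi from {SE, NPV} at SE = 1) — the forward
        # values stand in there
        try:
            base_solved = solve(
                base_values["p"],
                {key[0]: base_values[key[0]], key[1]: base_values[key[1]]},
                strict=False,
            ).to_dict()
        except DegenerateCombinationError:
            base_solved = base_values
        for varied in input_names:
            v0 = base_values[varied]
            se_in = binomial_se(v0, scenario.n_se)
            for direction in (-1, +1):
                v_pert = v0 + direction * se_in
                clipped = not 0.0 <= v_pert <= 1.0
                v_pert = min(max(v_pert, 0.0), 1.0)
                inputs = {n: base_values[n] for n in input_names}
                inputs[varied] = v_pert

                profile = None
                violation = ""
                try:
                    profile = solve(
                        inputs["p"],
                        {key[0]: inputs[key[0]], key[1]: inputs[key[1]]},
                        strict=False,
                    )
                except DegenerateCombinationError as exc:
                    violation = str(exc)
                if profile is not None:
                    bad = profile.out_of_range()
                    if bad:
                        violation = "out of [0, 1]: " + ", ".join(bad)
                        profile = None

                for param in derived:
                    b_val = base_solved[param]
                    if profile is None:
                        rows.append(
                            dict(
                                combo=label,
                                varied=varied,
                                direction=direction,
                                param=param,
                                baseline_value=b_val,
                                perturbed_value=np.nan,
                                delta=np.nan,
                                bias_se_units=np.nan,
                                bias_reported=np.nan,
                                truncated=False,
                                clipped=clipped,
                                invalid=True,
                                violation=violation,
                            )
                        )
                        continue
                    p_val = getattr(profile, param)
                    delta = p_val - b_val
                    se_out = binomial_se(b_val, scenario.n_se)
                    if se_out > 0.0:
                        bias = delta / se_out
                    else:
                        bias = 0.0 if delta == 0.0 else math.copysign(np.inf, delta)
                    truncated = abs(bias) > scenario.truncation
                    reported = (
                        math.copysign(scenario.truncation, bias) if truncated else bias
                    )
                    rows.append(
                        dict(
                            combo=label,
                            varied=varied,
                            direction=direction,
                            param=param,
                            baseline_value=b_val,
                            perturbed_value=p_val,
                            delta=delta,
                            bias_se_units=bias,
                            bias_reported=reported,
                            truncated=truncated,
                            clipped=clipped,
                            invalid=False,
                            violation=violation,
                        )
                    )
    return pd.DataFrame(rows, columns=_COLUMNS)


@dataclass(frozen=True)
class SuiteResult:
    """Long-format OAT results over several baseline prevalences.

    ``best_combo`` is the solution set with the smallest worst-case
    |bias| (in s.e. units, untruncated) across all scenarios, varied
    inputs, directions and derived parameters; ``ranking`` tabulates that
    summary for every combo.
    """

    table: pd.DataFrame
    ranking: pd.DataFrame
    best_combo: str
    scenarios: tuple[SensitivityScenario, ...] = field(default_factory=tuple)


def rank_combos(table: pd.DataFrame) -> pd.DataFrame:
    """Summarise |bias| per combo (max and mean over finite entries).

    Invalid perturbations carry NaN biases and are excluded from the
    summaries; their count is reported alongside.
    """
    g = table.assign(abs_bias=table["bias_se_units"].abs()).groupby("combo")
    out = g.agg(
        max_abs_bias=("abs_bias", "max"),
        mean_abs_bias=("abs_bias", "mean"),
        n_invalid=("invalid", "sum"),
    )
    return out.sort_values(["max_abs_bias", "mean_abs_bias"]).reset_index()


def scenario_suite(
    pis: list[float],
    se: float,
    sp: float,
    n_se: int = 1000,
    truncation: float = 3.0,
) -> SuiteResult:
    """Run :func:`oat_analysis` for several baseline true prevalences.

    Emits one long-format table (extra column ``scenario_pi``) shaped for
    per-scenario, per-combo panel plots, and identifies the solution set
    with the smallest maximum |bias| across the derived parameters.
    """
    if not pis:
        raise DomainError("at least one baseline true prevalence is required")
    scenarios = tuple(
        SensitivityScenario(pi=pi, se=se, sp=sp, n_se=n_se, truncation=truncation)
        for pi in pis
    )
    parts = []
    for sc in scenarios:
        t = oat_analysis(sc)
        t.insert(0, "scenario_pi", sc.pi)
        parts.append(t)
    table = pd.concat(parts, ignore_index=True)
    ranking = rank_combos(table)
    return SuiteResult(
        table=table,
        ranking=ranking,
        best_combo=str(ranking.iloc[0]["combo"]),
        scenarios=scenarios,
    )


def plot_oat(table: pd.DataFrame, path: str, scenario_pi: float | None = None) -> None:
    """Render the OAT biases as per-combo bar panels (optional output).

    One subplot per solution set; for every (varied input, derived
    parameter) pair a vertical bar spans the reported bias from the -1 s.e.
    to the +1 s.e. perturbation.  Requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if scenario_pi is not None and "scenario_pi" in table.columns:
        table = table[table["scenario_pi"] == scenario_pi]
    combos = list(dict.fromkeys(table["combo"]))
    ncols = 2
    nrows = (len(combos) + 1) // ncols
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(11, 2.6 * nrows), sharey=True, squeeze=False
    )
    trunc = np.nanmax(np.abs(table["bias_reported"])) if len(table) else 3.0
    for ax, combo in zip(axes.flat, combos):
        sub = table[(table["combo"] == combo) & (~table["invalid"])]
        labels, lows, highs = [], [], []
        for (varied, param), grp in sub.groupby(["varied", "param"], sort=True):
            by_dir = grp.set_index("direction")["bias_reported"]
            labels.append(f"{varied}→{param}")
            lows.append(by_dir.get(-1, 0.0))
            highs.append(by_dir.get(+1, 0.0))
        xs = np.arange(len(labels))
        lo = np.minimum(lows, highs)
        hi = np.maximum(lows, highs)
        ax.bar(xs, hi - lo, bottom=lo, width=0.6, color="#4878a8")
        ax.axhline(0.0, color="k", lw=0.6)
        ax.set_xticks(xs)
        ax.set_xticklabels(labels, rotation=90, fontsize=6)
        ax.set_title(combo, fontsize=8)
        ax.set_ylim(-1.1 * trunc, 1.1 * trunc)
    for ax in axes.flat[len(combos):]:
        ax.axis("off")
    fig.suptitle("OAT bias of derived parameters (s.e. units)", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
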