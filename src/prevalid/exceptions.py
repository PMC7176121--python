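"""Exception hierarchy.

All errors raised by the package derive from :class:`PrevalidError` so callers
can catch everything with one clause while still distinguishing the failure
modes that matter scientifically (domain violations, undefined indices,
degenerate algebraic combinations, infeasible moment fits, constraint
violations).
"""


class PrevalidError(Exception):
    """Base class for all package errors."""


class DomainError(PrevalidError, ValueError):
    """An input lies outside its mathematical domain (e.g. a probability
    outside [0, 1], or a non-positive sample size)."""


class UndefinedIndexError(PrevalidError, ZeroDivisionError):
    """A validity index is undefined because its conditioning margin is
    empty (0/0 in the 2x2 table).  Carries the name of the index."""

    def __init__(self, index: str, message: str | None = None):
        self.index = index
        super().__init__(message or f"{index} is undefined: empty margin (0/0)")


class DegenerateCombinationError(PrevalidError, ZeroDivisionError):
    """A closed-form solution expression has a vanishing denominator, e.g.
    SE + SP = 1 in the Rogan-Gladen estimator (uninformative classifier)."""

    def __init__(self, expression: str, message: str | None = None):
        self.expression = expression
        super().__init__(message or f"degenerate combination: {expression}")


class ConstraintViolationError(PrevalidError, ValueError):
    """Strict-mode solving rejected inputs whose derived parameters leave
    [0, 1].  Carries the list of violated inequalities."""

    def __init__(self, violations, message: str | None = None):
        self.violations = list(violations)
        names = "; ".join(str(v) for v in self.violations)
        super().__init__(message or f"constraint violation(s): {names}")


class InfeasibleMomentsError(PrevalidError, ValueError):
    """No beta distribution matches the requested mean and CI-implied
    variance (variance >= mean*(1-mean))."""


class DegeneratePropagationError(PrevalidError, RuntimeError):
    """Monte-Carlo propagation rejected every draw under the active
    constraint regime."""


class ScenarioError(PrevalidError, ValueError):
    """A sensitivity-analysis baseline scenario is itself invalid."""
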