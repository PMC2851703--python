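"""Bayes-theorem conversions between prior, P value and minimum posterior.

The single relation behind everything here is

    posterior odds of H0  =  prior odds of H0  x  minimum Bayes factor,

with odds(prob) = prob / (1 - prob).  Because the Bayes factor plugged in
is a *lower bound*, the resulting posterior probability of H0 is itself a
lower bound, and the solved-for prior is the *maximum* prior compatible
with a posterior target (resp. the solved-for P value is the maximum one).

Probabilities are handled as proportions in (0, 1) throughout; percent
formatting with explicit half-away-from-zero rounding is a presentation
concern (`percent`).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum

import pandas as pd

from .calibration import (
    CalibrationMethod,
    Method,
    MinBayesFactorResult,
    PValue,
    min_bf,
    inverse_p_from_bf,
)
from .errors import NoSolutionError

__all__ = [
    "Role",
    "HypothesisProbability",
    "Odds",
    "SolveResult",
    "odds",
    "prob_from_odds",
    "posterior_from",
    "max_prior_from",
    "required_bf",
    "max_p",
    "solve",
    "table1",
    "percent",
]


class Role(str, Enum):
    PRIOR = "prior"
    POSTERIOR = "posterior"


@dataclass(frozen=True)
class HypothesisProbability:
    """Probability of the null hypothesis, before or after the data.

    Degenerate values 0 and 1 are rejected: their odds are undefined and a
    dogmatic prior cannot be moved by any Bayes factor.
    """

    value: float
    role: Role = Role.PRIOR

    def __post_init__(self) -> None:
        if not 0.0 < self.value < 1.0:
            raise ValueError(f"probability must lie strictly in (0, 1), got {self.value}")
        object.__setattr__(self, "role", Role(self.role))


@dataclass(frozen=True)
class Odds:
    value: float

    def __post_init__(self) -> None:
        if self.value <= 0.0:
            raise ValueError(f"odds must be positive, got {self.value}")

    @property
    def probability(self) -> float:
        return self.value / (1.0 + self.value)


def odds(prob: float) -> float:
    """prob / (1 - prob)."""
    if not 0.0 < prob < 1.0:
        raise ValueError(f"probability must lie strictly in (0, 1), got {prob}")
    return prob / (1.0 - prob)


def prob_from_odds(o: float) -> float:
    """o / (1 + o)."""
    if o <= 0.0:
        raise ValueError(f"odds must be positive, got {o}")
    return o / (1.0 + o)


def _prob_value(q: float | HypothesisProbability) -> float:
    return q.value if isinstance(q, HypothesisProbability) else float(q)


def _bf_value(bf: float | MinBayesFactorResult) -> float:
    return bf.bf if isinstance(bf, MinBayesFactorResult) else float(bf)


@dataclass(frozen=True)
class SolveResult:
    """Outcome of a three-way solve: the quantity solved for and its inputs."""

    solved_quantity: str  # "posterior", "prior" or "p_value"
    value: float
    method: CalibrationMethod
    inputs: dict
    bf: float


def posterior_from(
    q: float | HypothesisProbability, bf: float | MinBayesFactorResult
) -> HypothesisProbability:
    """Minimum posterior probability of H0 from a prior and a minimum Bayes factor."""
    qv, bfv = _prob_value(q), _bf_value(bf)
    post = prob_from_odds(odds(qv) * bfv)
    return HypothesisProbability(post, Role.POSTERIOR)


def max_prior_from(
    target_posterior: float | HypothesisProbability, bf: float | MinBayesFactorResult
) -> HypothesisProbability:
    """Largest prior whose minimum posterior does not exceed the target."""
    tv, bfv = _prob_value(target_posterior), _bf_value(bf)
    prior = prob_from_odds(odds(tv) / bfv)
    return HypothesisProbability(prior, Role.PRIOR)


def required_bf(
    q: float | HypothesisProbability, target_posterior: float | HypothesisProbability
) -> float:
    """Bayes factor needed to move the prior q to the target posterior.

    Returns posterior odds / prior odds.  Values >= 1 are passed through;
    they signal downstream that no P value below 1/e can achieve the move.
    """
    return odds(_prob_value(target_posterior)) / odds(_prob_value(q))


def max_p(
    q: float | HypothesisProbability,
    target_posterior: float | HypothesisProbability,
    method: CalibrationMethod | Method = Method.SBB,
) -> PValue:
    """Maximum two-sided P value compatible with moving prior q to the target posterior."""
    bf_needed = required_bf(q, target_posterior)
    if bf_needed >= 1.0:
        raise NoSolutionError(
            f"target posterior {_prob_value(target_posterior)} is not below the prior "
            f"{_prob_value(q)}; the required Bayes factor {bf_needed:.6g} is >= 1"
        )
    return inverse_p_from_bf(method, bf_needed)


def solve(
    *,
    prior: float | None = None,
    p: float | None = None,
    posterior: float | None = None,
    method: CalibrationMethod | Method = Method.SBB,
) -> SolveResult:
    """Solve for whichever of prior, P value and posterior is omitted.

    Exactly two of the three keyword arguments must be given.
    """
    given = {k: v for k, v in (("prior", prior), ("p", p), ("posterior", posterior)) if v is not None}
    if len(given) != 2:
        raise ValueError(f"exactly two of prior/p/posterior must be given, got {sorted(given)}")
    m = CalibrationMethod(method) if isinstance(method, Method) else method
    if p is not None:
        bf = min_bf(m, PValue(p)).bf
        if posterior is None:
            value = posterior_from(prior, bf).value
            return SolveResult("posterior", value, m, given, bf)
        value = max_prior_from(posterior, bf).value
        return SolveResult("prior", value, m, given, bf)
    pv = max_p(prior, posterior, m)
    bf = required_bf(prior, posterior)
    return SolveResult("p_value", pv.value, m, given, bf)


_TABLE1_METHODS: list[tuple[str, Method]] = [
    ("Edwards, Lindman, and Savage (1963)", Method.ELS),
    ("Berger and Sellke (1987, Scenario 1)", Method.BS_SYMMETRIC),
    ("Sellke, Bayarri, and Berger (2001)", Method.SBB),
    ("Berger and Sellke (1987, Scenario 2)", Method.BS_UNIMODAL),
    ("Berger and Sellke (1987, Scenario 3)", Method.BS_NORMAL),
]


def percent(x: float, decimals: int = 1) -> float:
    """100*x rounded half-away-from-zero to the given number of decimals."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(100.0 * x))).quantize(q, rounding=ROUND_HALF_UP))


def table1(
    p_values: tuple[float, ...] = (0.05, 0.01, 0.001),
    q: float = 0.5,
    rounded: bool = True,
) -> pd.DataFrame:
    """Minimum posterior probabilities of H0 per calibration and P value.

    Rows are the five calibrations, columns the P values; cells are percent
    (one-decimal rounded by default) at the given prior probability.
    """
    rows = {}
    for label, tag in _TABLE1_METHODS:
        cells = []
        for pv in p_values:
            post = posterior_from(q, min_bf(tag, PValue(pv))).value
            cells.append(percent(post) if rounded else 100.0 * post)
        rows[label] = cells
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[str(pv) for pv in p_values])
    df.index.name = "Method"
    return df
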