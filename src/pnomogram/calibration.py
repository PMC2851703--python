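"""Minimum Bayes factor calibrations of P values against a simple null.

A two-sided P value (or the z- or chi-squared statistic behind it) is
transformed into a *lower bound* on the Bayes factor BF = f(data | H0) /
f(data | H1), minimized over a family of prior densities for the effect
under H1.  Five calibrations are provided:

``ELS``
    point-mass prior at the maximum-likelihood estimate: BF = exp(-z^2/2),
    with z the *one-tailed* normal quantile of the P value.
``BS_SYMMETRIC``
    symmetric two-point priors around the null: BF = phi(z) / max_mu
    0.5*[phi(z-mu) + phi(z+mu)], two-tailed z.
``BS_UNIMODAL``
    unimodal symmetric priors; the least favorable member is uniform on
    [-K, K]: BF = phi(z) / max_K [Phi(K-z) - Phi(-K-z)] / (2K).
``BS_NORMAL``
    normal priors centered at the null: BF = sqrt(e) * z * exp(-z^2/2)
    for z >= 1, and 1 below.
``SBB``
    decreasing beta densities for the P value itself: BF = -e * p * ln(p)
    for p < 1/e, and 1 above.
``CHISQ``
    chi-squared statistics with nu degrees of freedom:
    BF = (x/nu)^(nu/2) * exp(-(x-nu)/2) for x >= nu, and 1 below.  This
    bound coincides with BS_NORMAL at nu = 1, with SBB at nu = 2, and
    tends to ELS as nu -> infinity.

All bounds are capped at 1: a bound of exactly 1 means lack of evidence
against the null hypothesis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from scipy import optimize, special, stats

from .errors import ConvergenceError, NoSolutionError

__all__ = [
    "Tails",
    "PValue",
    "ZStatistic",
    "ChiSquareStatistic",
    "Method",
    "CalibrationMethod",
    "MinBayesFactorResult",
    "z_from_p",
    "p_from_z",
    "min_bf_els",
    "min_bf_bs_symmetric",
    "min_bf_bs_unimodal",
    "min_bf_bs_normal",
    "min_bf_sbb",
    "min_bf_chisq",
    "min_bf",
    "inverse_p_from_bf",
]

_E = math.e
_P_CUTOFF = 1.0 / math.e  # SBB bound is unity for larger P values


class Tails(str, Enum):
    ONE = "one"
    TWO = "two"


@dataclass(frozen=True)
class PValue:
    """An observed P value; the tail convention is recorded, never inferred."""

    value: float
    tails: Tails = Tails.TWO

    def __post_init__(self) -> None:
        if not 0.0 < self.value <= 1.0:
            raise ValueError(f"P value must lie in (0, 1], got {self.value}")
        object.__setattr__(self, "tails", Tails(self.tails))


@dataclass(frozen=True)
class ZStatistic:
    """Absolute value of a standard-normal test statistic."""

    value: float

    def __post_init__(self) -> None:
        if self.value < 0.0 or not math.isfinite(self.value):
            raise ValueError(f"z statistic must be finite and >= 0, got {self.value}")


@dataclass(frozen=True)
class ChiSquareStatistic:
    """A chi-squared test statistic with its degrees of freedom."""

    value: float
    df: float

    def __post_init__(self) -> None:
        if self.value < 0.0:
            raise ValueError(f"chi-squared statistic must be >= 0, got {self.value}")
        if self.df <= 0.0:
            raise ValueError(f"degrees of freedom must be > 0, got {self.df}")


class Method(str, Enum):
    """Tags for the five calibration families."""

    ELS = "els"
    BS_SYMMETRIC = "bs-symmetric"
    BS_UNIMODAL = "bs-unimodal"
    BS_NORMAL = "bs-normal"
    SBB = "sbb"
    CHISQ = "chisq"


@dataclass(frozen=True)
class CalibrationMethod:
    """A calibration tag plus, for the chi-squared bound, its degrees of freedom."""

    tag: Method
    df: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "tag", Method(self.tag))
        if self.tag is Method.CHISQ:
            if self.df is None or self.df <= 0:
                raise ValueError("the chi-squared calibration requires df > 0")
        elif self.df is not None:
            raise ValueError(f"df is only meaningful for the chi-squared calibration, not {self.tag.value}")


@dataclass(frozen=True)
class MinBayesFactorResult:
    """A calibrated lower bound on the Bayes factor, in (0, 1]."""

    bf: float
    method: CalibrationMethod
    input_scale: str  # "p", "z" or "chisq"

    def __post_init__(self) -> None:
        if not 0.0 < self.bf <= 1.0:
            raise ValueError(f"minimum Bayes factor must lie in (0, 1], got {self.bf}")


def z_from_p(p: PValue) -> ZStatistic:
    """Standard-normal quantile of a P value.

    One-tailed: upper quantile at p.  Two-tailed: upper quantile at p/2.
    """
    if not 0.0 < p.value < 1.0:
        raise ValueError(f"quantile conversion requires 0 < p < 1, got {p.value}")
    tail_prob = p.value if p.tails is Tails.ONE else p.value / 2.0
    if tail_prob > 0.5:
        raise ValueError(
            f"one-tailed P value {p.value} exceeds 0.5: the z statistic would be negative"
        )
    return ZStatistic(float(stats.norm.isf(tail_prob)))


def p_from_z(z: ZStatistic, tails: Tails = Tails.TWO) -> PValue:
    """P value of an absolute z statistic under the given tail convention."""
    tails = Tails(tails)
    sf = float(stats.norm.sf(z.value))
    value = sf if tails is Tails.ONE else 2.0 * sf
    return PValue(min(value, 1.0), tails)


def _as_result(bf: float, tag: Method, scale: str, df: float | None = None) -> MinBayesFactorResult:
    return MinBayesFactorResult(min(float(bf), 1.0), CalibrationMethod(tag, df), scale)


def min_bf_els(z: ZStatistic) -> MinBayesFactorResult:
    """Point-mass (maximum-likelihood) bound: BF = exp(-z^2/2)."""
    return _as_result(math.exp(-z.value**2 / 2.0), Method.ELS, "z")


def _maximize_scalar(objective, lo: float, hi: float):
    res = optimize.minimize_scalar(
        lambda t: -objective(t),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10, "maxiter": 2000},
    )
    if not res.success:
        raise ConvergenceError(f"marginal-density maximization failed: {res.message}")
    return res.x, -res.fun


def min_bf_bs_symmetric(z: ZStatistic) -> MinBayesFactorResult:
    """Symmetric two-point-prior bound.

    The least favorable prior puts mass 1/2 at +/-mu; the bound is
    phi(z) over the maximized mixture density 0.5*[phi(z-mu) + phi(z+mu)].
    """
    zv = z.value
    phi_z = stats.norm.pdf(zv)

    def marginal(mu: float) -> float:
        return 0.5 * (stats.norm.pdf(zv - mu) + stats.norm.pdf(zv + mu))

    _, best = _maximize_scalar(marginal, 1e-8, max(20.0, 4.0 * zv))
    best = max(best, phi_z)  # mu = 0 recovers the null density
    return _as_result(phi_z / best, Method.BS_SYMMETRIC, "z")


def min_bf_bs_unimodal(z: ZStatistic) -> MinBayesFactorResult:
    """Unimodal symmetric-prior bound; least favorable member uniform on [-K, K]."""
    zv = z.value
    phi_z = stats.norm.pdf(zv)

    def marginal(k: float) -> float:
        return (stats.norm.cdf(k - zv) - stats.norm.cdf(-k - zv)) / (2.0 * k)

    _, best = _maximize_scalar(marginal, 1e-8, max(20.0, 4.0 * zv))
    best = max(best, phi_z)  # K -> 0 limit is phi(z)
    return _as_result(phi_z / best, Method.BS_UNIMODAL, "z")


def min_bf_bs_normal(z: ZStatistic) -> MinBayesFactorResult:
    """Normal-prior bound: BF = sqrt(e)*z*exp(-z^2/2) for z >= 1, else 1.

    Below z = 1 the unconstrained minimizing prior variance would be
    negative, so the bound is capped at 1; the cap is continuous because
    sqrt(e)*exp(-1/2) = 1.
    """
    zv = z.value
    if zv < 1.0:
        return _as_result(1.0, Method.BS_NORMAL, "z")
    return _as_result(math.sqrt(_E) * zv * math.exp(-zv**2 / 2.0), Method.BS_NORMAL, "z")


def min_bf_sbb(p: PValue) -> MinBayesFactorResult:
    """Decreasing-density bound on the P value scale: BF = -e*p*ln(p) for p < 1/e."""
    pv = p.value
    if pv >= _P_CUTOFF:
        return _as_result(1.0, Method.SBB, "p")
    return _as_result(-_E * pv * math.log(pv), Method.SBB, "p")


def min_bf_chisq(s: ChiSquareStatistic) -> MinBayesFactorResult:
    """Chi-squared-statistic bound: BF = (x/nu)^(nu/2) * exp(-(x-nu)/2) for x >= nu."""
    x, nu = s.value, s.df
    if x < nu:
        return _as_result(1.0, Method.CHISQ, "chisq", df=nu)
    # log-space evaluation keeps large nu (the ELS limit) stable
    log_bf = 0.5 * nu * math.log(x / nu) - 0.5 * (x - nu)
    return _as_result(math.exp(log_bf), Method.CHISQ, "chisq", df=nu)


_Z_BASED = {
    Method.ELS: min_bf_els,
    Method.BS_SYMMETRIC: min_bf_bs_symmetric,
    Method.BS_UNIMODAL: min_bf_bs_unimodal,
    Method.BS_NORMAL: min_bf_bs_normal,
}


def _effective_z(p: PValue, tag: Method) -> ZStatistic:
    # ELS uses the one-tailed quantile of the P value; the BS bounds use the
    # two-tailed quantile (a one-tailed p already encodes the same z).  A P
    # value whose quantile would be negative carries no evidence: z = 0.
    if tag is Method.ELS:
        if p.value >= 0.5:
            return ZStatistic(0.0)
        return z_from_p(PValue(p.value, Tails.ONE))
    return z_from_p(p)


def min_bf(
    method: CalibrationMethod | Method,
    evidence: PValue | ZStatistic | ChiSquareStatistic,
) -> MinBayesFactorResult:
    """Dispatch a calibration over any evidence scale it supports.

    The z-based bounds accept a ``ZStatistic`` directly or convert a
    ``PValue`` (ELS through the one-tailed quantile, the BS bounds through
    the two-tailed quantile).  SBB accepts a ``PValue`` or converts a z to
    a two-sided P value.  The chi-squared bound requires a
    ``ChiSquareStatistic`` or converts a ``PValue`` through the upper
    chi-squared quantile at the method's df.
    """
    if isinstance(method, Method):
        if method is Method.CHISQ and isinstance(evidence, ChiSquareStatistic):
            method = CalibrationMethod(method, evidence.df)
        else:
            method = CalibrationMethod(method)  # bare CHISQ without a statistic fails: it needs df
    tag = method.tag

    if tag is Method.CHISQ:
        if isinstance(evidence, ChiSquareStatistic):
            if method.df != evidence.df:
                raise ValueError(
                    f"method df={method.df} disagrees with statistic df={evidence.df}"
                )
            return min_bf_chisq(evidence)
        if isinstance(evidence, PValue):
            x = float(stats.chi2.isf(evidence.value, method.df))
            return min_bf_chisq(ChiSquareStatistic(x, method.df))
        raise TypeError("the chi-squared calibration needs a ChiSquareStatistic or PValue")

    if isinstance(evidence, ChiSquareStatistic):
        raise TypeError(f"the {tag.value} calibration does not accept a chi-squared statistic")

    if tag is Method.SBB:
        if isinstance(evidence, ZStatistic):
            evidence = p_from_z(evidence, Tails.TWO)
        return min_bf_sbb(evidence)

    if isinstance(evidence, PValue):
        evidence = _effective_z(evidence, tag)
    return _Z_BASED[tag](evidence)


def _p_from_effective_z(z: float, tag: Method) -> float:
    """Two-sided P value whose method-specific effective z equals ``z``."""
    if tag is Method.ELS:
        return float(stats.norm.sf(z))
    return float(2.0 * stats.norm.sf(z))


def inverse_p_from_bf(
    method: CalibrationMethod | Method, bf_target: float
) -> PValue:
    """The unique two-sided P value whose calibrated minimum Bayes factor equals ``bf_target``.

    Each calibration is strictly monotone in p on (0, 1/e) once the tail
    convention is fixed, so the inverse exists.  SBB is inverted in closed
    form through the lower branch of the Lambert W function; the z-based
    bounds by bracketed root finding on the z scale, and the chi-squared
    bound on the statistic scale.
    """
    if isinstance(method, Method):
        method = CalibrationMethod(method)
    if bf_target <= 0.0:
        raise ValueError(f"Bayes factor target must be positive, got {bf_target}")
    if bf_target >= 1.0:
        raise NoSolutionError(
            "Bayes factor target >= 1: no P value below 1/e is required"
        )
    tag = method.tag

    if tag is Method.SBB:
        # -e p ln p = b  <=>  ln(p) e^{ln p} = -b/e  <=>  ln p = W_{-1}(-b/e)
        w = special.lambertw(-bf_target / _E, k=-1)
        return PValue(float(math.exp(w.real)), Tails.TWO)

    if tag is Method.CHISQ:
        nu = method.df

        def f(x: float) -> float:
            return math.log(min_bf_chisq(ChiSquareStatistic(x, nu)).bf) - math.log(bf_target)

        hi = nu + 10.0
        while f(hi) > 0.0:
            hi *= 2.0
            if hi > 1e8:
                raise ConvergenceError("failed to bracket the chi-squared inverse")
        x = optimize.brentq(f, nu, hi, xtol=1e-13, rtol=8.9e-16)
        return PValue(float(stats.chi2.sf(x, nu)), Tails.TWO)

    calib = _Z_BASED[tag]
    lo = 1.0 if tag is Method.BS_NORMAL else 1e-8

    def g(z: float) -> float:
        return math.log(calib(ZStatistic(z)).bf) - math.log(bf_target)

    hi = 10.0
    while g(hi) > 0.0:
        hi += 5.0
        if hi > 200.0:
            raise ConvergenceError("failed to bracket the z-scale inverse")
    if g(lo) < 0.0:
        raise NoSolutionError(
            f"Bayes factor target {bf_target} is not attainable under {tag.value}"
        )
    z = optimize.brentq(g, lo, hi, xtol=1e-13, rtol=8.9e-16)
    return PValue(_p_from_effective_z(z, tag), Tails.TWO)
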