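"""Nonparametric species-richness estimation from abundance data.

Implements the classical Chao1 lower bound, the improved iChao1 estimator
(which adds information from tripletons and quadrupletons), analytic
rarefaction and extrapolation of species richness (Hill number of order
q = 0), and two kinds of confidence intervals: the standard log-transformed
interval for Chao-type estimators and a coverage-based bootstrap.

All estimators consume a :class:`FrequencyCounts` object — the sufficient
statistic (S_obs, n, f_1, f_2, ...) where f_k is the number of species
observed exactly k times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm

from .seeding import rng_from

__all__ = [
    "FrequencyCounts",
    "RichnessEstimate",
    "frequency_counts",
    "chao1",
    "chao1_variance",
    "ichao1",
    "rarefaction_extrapolation",
    "chao1_log_ci",
    "bootstrap_ci",
]


@dataclass(frozen=True)
class FrequencyCounts:
    """Abundance frequency counts: the estimators' sufficient statistic.

    Attributes
    ----------
    s_obs : observed number of species.
    n : total number of individuals (specimens/records).
    f : mapping k -> f_k, the number of species seen exactly k times.
        Only nonzero entries are stored.
    """

    s_obs: int
    n: int
    f: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(k < 1 or v < 0 for k, v in self.f.items()):
            raise ValueError("frequency counts require k >= 1 and f_k >= 0")
        if sum(self.f.values()) != self.s_obs:
            raise ValueError("sum of f_k must equal S_obs")
        if sum(k * v for k, v in self.f.items()) != self.n:
            raise ValueError("sum of k*f_k must equal n")

    def fk(self, k: int) -> int:
        return self.f.get(k, 0)


@dataclass(frozen=True)
class RichnessEstimate:
    """A point estimate of species richness with an optional confidence interval."""

    method: str
    point: float
    s_obs: int
    n: int
    se: float | None = None
    lcl: float | None = None
    ucl: float | None = None
    level: float = 0.95


def frequency_counts(abundance) -> FrequencyCounts:
    """Build :class:`FrequencyCounts` from per-species counts.

    ``abundance`` may be an object with a ``counts`` mapping (an
    AbundanceVector), a mapping species -> count, or a sequence of counts.
    An empty input yields the valid degenerate object (S_obs = 0, n = 0).
    """
    if hasattr(abundance, "counts"):
        values = list(abundance.counts.values())
    elif isinstance(abundance, Mapping):
        values = list(abundance.values())
    else:
        values = list(abundance)
    arr = np.asarray(values, dtype=np.int64)
    if arr.size and arr.min() < 1:
        raise ValueError("abundance counts must all be >= 1")
    ks, fs = np.unique(arr, return_counts=True)
    f = {int(k): int(v) for k, v in zip(ks, fs)}
    return FrequencyCounts(s_obs=int(arr.size), n=int(arr.sum()), f=f)


def chao1(fc: FrequencyCounts) -> float:
    """Chao1 lower-bound richness estimate.

    S_obs + f1^2/(2 f2) when doubletons exist, otherwise the bias-corrected
    form S_obs + f1 (f1 - 1) / 2.  Always >= S_obs.
    """
    f1, f2 = fc.fk(1), fc.fk(2)
    if f2 > 0:
        return fc.s_obs + f1 * f1 / (2.0 * f2)
    return fc.s_obs + f1 * (f1 - 1) / 2.0


def chao1_variance(fc: FrequencyCounts) -> float:
    """Analytic variance of the Chao1 estimator.

    Uses the standard form for f2 > 0 and the bias-corrected form for
    f2 = 0 (the SpadeR/EstimateS lineage formulas).
    """
    f1, f2 = fc.fk(1), fc.fk(2)
    if f2 > 0:
        r = f1 / f2
        return f2 * (0.5 * r**2 + r**3 + 0.25 * r**4)
    if f1 == 0:
        return 0.0
    est = chao1(fc)
    v = f1 * (f1 - 1) / 2.0 + f1 * (2 * f1 - 1) ** 2 / 4.0
    if est > 0:
        v -= f1**4 / (4.0 * est)
    return max(v, 0.0)


def ichao1(fc: FrequencyCounts) -> float:
    """Improved Chao1 estimate using tripletons (f3) and quadrupletons (f4).

    iChao1 = Chao1 + (f3 / (4 f4)) * max(f1 - f2 f3 / (2 f4), 0), with f4
    replaced by f4 + 1 in both places when no quadrupletons were observed.
    The added term is nonnegative, so iChao1 >= Chao1 >= S_obs.
    """
    base = chao1(fc)
    f1, f2, f3, f4 = fc.fk(1), fc.fk(2), fc.fk(3), fc.fk(4)
    if f3 == 0:
        return base
    f4c = f4 if f4 > 0 else f4 + 1
    return base + (f3 / (4.0 * f4c)) * max(f1 - f2 * f3 / (2.0 * f4c), 0.0)


def _log_comb_ratio(n_minus_k: int, n: int, m: int) -> float:
    """C(n-k, m) / C(n, m) computed in log space (0 when m > n-k)."""
    if m > n_minus_k:
        return 0.0
    num = gammaln(n_minus_k + 1) - gammaln(m + 1) - gammaln(n_minus_k - m + 1)
    den = gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
    return float(math.exp(num - den))


def rarefaction_extrapolation(fc: FrequencyCounts, m: int) -> float:
    """Expected species richness at sample size m (Hill number q = 0).

    Interpolation (m <= n) uses the exact hypergeometric expectation
    S_obs - sum_k f_k C(n-k, m)/C(n, m); extrapolation (m > n) uses the
    Chao1-based asymptotic form, approaching Chao1 as m -> infinity.
    """
    if m < 0:
        raise ValueError("m must be nonnegative")
    n, s_obs = fc.n, fc.s_obs
    if n == 0:
        return 0.0
    if m <= n:
        missing = sum(f_k * _log_comb_ratio(n - k, n, m) for k, f_k in fc.f.items())
        return s_obs - missing
    f1 = fc.fk(1)
    if f1 == 0:
        return float(s_obs)
    f0_hat = chao1(fc) - s_obs
    if f0_hat <= 0:
        return float(s_obs)
    m_star = m - n
    return s_obs + f0_hat * (1.0 - (1.0 - f1 / (n * f0_hat + f1)) ** m_star)


def chao1_log_ci(fc: FrequencyCounts, level: float = 0.95) -> tuple[float, float]:
    """Log-transformed confidence interval for the Chao1 estimate.

    With T = Chao1 - S_obs and analytic variance V, the interval is
    (S_obs + T/R, S_obs + T*R) with R = exp(z sqrt(ln(1 + V/T^2))).
    Degenerate when T = 0: both bounds equal S_obs.  The lower bound can
    never fall below S_obs.
    """
    point = chao1(fc)
    t = point - fc.s_obs
    if t <= 0:
        return (float(fc.s_obs), float(fc.s_obs))
    v = chao1_variance(fc)
    z = norm.ppf(0.5 + level / 2.0)
    r = math.exp(z * math.sqrt(math.log(1.0 + v / t**2)))
    return (fc.s_obs + t / r, fc.s_obs + t * r)


_ESTIMATOR_FUNCS: dict[str, Callable[[FrequencyCounts], float]] = {
    "chao1": chao1,
    "ichao1": ichao1,
}


def _resolve_estimator(estimator, m: int | None) -> Callable[[FrequencyCounts], float]:
    if callable(estimator):
        return estimator
    name = str(estimator).lower()
    if name in _ESTIMATOR_FUNCS:
        return _ESTIMATOR_FUNCS[name]
    if name in ("rarefaction", "rarefaction_extrapolation"):
        if m is None:
            raise ValueError("rarefaction estimator requires m")
        return lambda fc: rarefaction_extrapolation(fc, m)
    raise ValueError(f"unknown estimator {estimator!r}")


def bootstrap_ci(
    abundance,
    estimator="chao1",
    B: int = 200,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
    m: int | None = None,
) -> tuple[float, float, float]:
    """Coverage-based bootstrap confidence interval for a richness estimator.

    The bootstrap assemblage assigns each detected species a probability
    proportional to its relative frequency, rescaled so that they sum to the
    estimated sample coverage C_hat = 1 - (f1/n) * (n-1) f1 / ((n-1) f1 + 2 f2);
    f0_hat = ceil(Chao1 - S_obs) undetected species share the remaining
    probability (1 - C_hat) equally.  B multinomial resamples of size n are
    drawn, the estimator applied to each, and the interval is the normal
    interval point +/- z * SD(bootstrap estimates), truncated below at S_obs.

    Returns (lcl, ucl, se).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    fc = frequency_counts(abundance)
    if fc.n < 1:
        raise ValueError("bootstrap requires a nonempty assemblage")
    func = _resolve_estimator(estimator, m)
    point = func(fc)

    if hasattr(abundance, "counts"):
        counts = np.asarray(list(abundance.counts.values()), dtype=float)
    elif isinstance(abundance, Mapping):
        counts = np.asarray(list(abundance.values()), dtype=float)
    else:
        counts = np.asarray(list(abundance), dtype=float)

    n = fc.n
    f1, f2 = fc.fk(1), fc.fk(2)
    if f1 > 0:
        c_hat = 1.0 - (f1 / n) * ((n - 1) * f1 / ((n - 1) * f1 + 2.0 * f2))
    else:
        c_hat = 1.0
    f0_hat = int(math.ceil(max(chao1(fc) - fc.s_obs, 0.0)))
    probs = counts / counts.sum() * c_hat
    if f0_hat > 0 and c_hat < 1.0:
        probs = np.concatenate([probs, np.full(f0_hat, (1.0 - c_hat) / f0_hat)])
    probs = probs / probs.sum()

    rng = rng_from(seed)
    estimates = np.empty(B)
    for b in range(B):
        resample = rng.multinomial(n, probs)
        resample = resample[resample > 0]
        estimates[b] = func(frequency_counts(resample))
    se = float(estimates.std(ddof=1))
    z = norm.ppf(0.5 + level / 2.0)
    lcl = max(point - z * se, float(fc.s_obs))
    ucl = point + z * se
    return (lcl, ucl, se)
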