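"""Abundance assemblages and literature-curve augmentation.

Cleaned occurrence records are tallied into per-region abundance vectors
(species -> specimen count) at three levels: country, continent, and
GLOBAL.  Checklist species with no occurrence records are then added by
drawing a plausible specimen count from a power-law frequency curve fitted
to literature sample sizes — the number of species described from x
specimens falls off roughly as a power of x, so most added species enter
as singletons or doubletons, exactly the rare tail the Chao-type
estimators correct for.

The curve has the two-parameter form

    y(x) = a * x^(1 - ln b)

with a the frequency of size-1 species and 1 - ln(b) < 0 a decaying
exponent.  Counts are drawn from the curve normalised over {1..cap}, where
cap is the region's maximum empirical per-species count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import math

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .seeding import rng_from

__all__ = [
    "GLOBAL",
    "EMPIRICAL",
    "CURVE_SAMPLED",
    "AbundanceVector",
    "LiteratureCurve",
    "build_abundance",
    "size_frequencies",
    "fit_literature_curve",
    "curve_pmf",
    "sample_literature_count",
    "augment_assemblage",
]

GLOBAL = "GLOBAL"
EMPIRICAL = "EMPIRICAL"
CURVE_SAMPLED = "CURVE_SAMPLED"

#: Cap on sampled counts when a region has no empirical counts at all.
DEFAULT_CAP = 100


@dataclass
class AbundanceVector:
    """Per-region species abundances with per-species provenance tags."""

    region: str
    counts: dict[str, int] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("all abundance counts must be >= 1")

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def s_obs(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region,
                "species": list(self.counts),
                "count": list(self.counts.values()),
                "provenance": [self.provenance.get(s, EMPIRICAL) for s in self.counts],
            }
        )


@dataclass(frozen=True)
class LiteratureCurve:
    """Fitted power-law frequency curve y(x) = a * x^(1 - ln b).

    ``a`` is the fitted frequency of single-specimen species and
    ``1 - ln(b)`` the (negative) decay exponent.  ``residual_standard_error``
    uses denominator N - 2.
    """

    a: float
    b: float
    residual_standard_error: float = 0.0
    cap: int | None = None

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("curve parameters must be positive")
        if 1.0 - math.log(self.b) >= 0:
            raise ValueError("curve must decay: requires 1 - ln(b) < 0")

    @property
    def exponent(self) -> float:
        """The decay exponent 1 - ln(b) (negative for a valid curve)."""
        return 1.0 - math.log(self.b)

    def __call__(self, x) -> np.ndarray:
        return self.a * np.asarray(x, dtype=float) ** self.exponent


def build_abundance(
    records,
    region: str,
    region_mapping: Mapping[str, str] | None = None,
) -> AbundanceVector:
    """Tally cleaned occurrence records into an abundance vector for a region.

    ``region`` is a country code, a continent name (requires
    ``region_mapping``: country code -> continent), or ``GLOBAL``.  Records
    without a species key or country code are skipped.
    """
    region_mapping = region_mapping or {}
    if region != GLOBAL and region not in set(region_mapping.values()) and region_mapping:
        known_countries = set(region_mapping)
        if region not in known_countries:
            raise ValueError(f"unknown region label {region!r}")
    counts: dict[str, int] = {}
    for record in records:
        species = getattr(record, "species_key", None)
        country = getattr(record, "country_code", None)
        if not species or not country:
            continue
        if region == GLOBAL:
            member = True
        elif region_mapping and region in set(region_mapping.values()):
            member = region_mapping.get(country) == region
        else:
            member = country == region
        if member:
            counts[species] = counts.get(species, 0) + 1
    return AbundanceVector(
        region=region, counts=counts, provenance={s: EMPIRICAL for s in counts}
    )


def size_frequencies(sizes: Iterable[int]) -> pd.DataFrame:
    """Tabulate raw per-species sample sizes into a (x, y) frequency table.

    x is a sample size, y the number of species with that size; sizes with
    zero frequency are omitted.
    """
    arr = np.asarray(list(sizes), dtype=np.int64)
    if arr.size and arr.min() < 1:
        raise ValueError("sample sizes must be >= 1")
    xs, ys = np.unique(arr, return_counts=True)
    return pd.DataFrame({"x": xs.astype(int), "y": ys.astype(int)})


def fit_literature_curve(size_frequency: pd.DataFrame) -> LiteratureCurve:
    """Fit y(x) = a * x^(1 - ln b) to a size-frequency table by nonlinear
    least squares on the untransformed frequencies.

    A log-log linear fit provides the initial guess.  Requires at least
    three distinct x values.  The residual standard error is reported with
    denominator N - 2.
    """
    x = np.asarray(size_frequency["x"], dtype=float)
    y = np.asarray(size_frequency["y"], dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("curve fitting requires >= 3 distinct sample sizes")
    if x.min() < 1 or y.min() < 0:
        raise ValueError("require x >= 1 and y >= 0")

    # initial guess from a log-log regression (only strictly positive y)
    pos = y > 0
    slope, intercept = np.polyfit(np.log(x[pos]), np.log(y[pos]), 1)
    a0 = float(np.exp(intercept))
    b0 = float(np.exp(1.0 - slope))
    b0 = max(b0, np.e * 1.01)  # keep the initial curve decaying

    def model(x_, a, b):
        return a * x_ ** (1.0 - np.log(b))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, _ = curve_fit(model, x, y, p0=[max(a0, 1e-6), b0], maxfev=20000)
    a_hat, b_hat = float(popt[0]), float(popt[1])
    resid = y - model(x, a_hat, b_hat)
    dof = max(len(x) - 2, 1)
    rse = float(np.sqrt(np.sum(resid**2) / dof))
    return LiteratureCurve(a=a_hat, b=b_hat, residual_standard_error=rse)


def curve_pmf(curve: LiteratureCurve, cap: int) -> np.ndarray:
    """Probability mass function of sampled counts over support {1..cap}."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    weights = curve(np.arange(1, cap + 1))
    return weights / weights.sum()


def sample_literature_count(
    curve: LiteratureCurve, cap: int, rng: int | np.random.Generator
) -> int:
    """Draw one specimen count from the curve truncated to {1..cap}."""
    rng = rng_from(rng)
    pmf = curve_pmf(curve, cap)
    return int(rng.choice(np.arange(1, cap + 1), p=pmf))


def augment_assemblage(
    empirical: AbundanceVector,
    checklist_species: Iterable[str],
    curve: LiteratureCurve,
    rng: int | np.random.Generator,
    default_cap: int = DEFAULT_CAP,
) -> AbundanceVector:
    """Add curve-sampled counts for checklist species missing from the data.

    Every checklist species absent from the empirical vector receives one
    count drawn from the literature curve capped at the maximum empirical
    per-species count in the region.  Empirical counts are never altered.
    When the empirical vector is empty the cap is undefined; a configured
    default is used and a warning emitted.
    """
    rng = rng_from(rng)
    missing = sorted(set(checklist_species) - set(empirical.counts))
    counts = dict(empirical.counts)
    provenance = dict(empirical.provenance)
    if not missing:
        return AbundanceVector(region=empirical.region, counts=counts, provenance=provenance)
    if empirical.counts:
        cap = max(empirical.counts.values())
    else:
        warnings.warn(
            f"region {empirical.region!r} has no empirical counts; "
            f"using default cap {default_cap}",
            stacklevel=2,
        )
        cap = default_cap
    pmf = curve_pmf(curve, cap)
    draws = rng.choice(np.arange(1, cap + 1), size=len(missing), p=pmf)
    for species, draw in zip(missing, draws):
        counts[species] = int(draw)
        provenance[species] = CURVE_SAMPLED
    return AbundanceVector(region=empirical.region, counts=counts, provenance=provenance)
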