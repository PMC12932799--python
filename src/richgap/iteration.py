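"""Iterated curve-resampling of richness estimates and gap reporting.

Because the specimen counts imputed for zero-occurrence checklist species
are random draws from the literature curve, the whole augmentation +
estimation step is repeated R times (default 100) with fresh draws, and the
point estimate and confidence bounds are summarised by their component-wise
medians across iterations.

Regions whose samples are too small or whose estimates diverge wildly from
the observed richness are excluded before reporting.  The final product is
a taxonomic gap report: estimated richness minus described species,
expressed also as a percentage and as years of taxonomic work at the
current description rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from . import estimators as est
from .assemblage import AbundanceVector, LiteratureCurve, augment_assemblage
from .seeding import child_seeds

__all__ = [
    "IterationSummary",
    "GapReport",
    "run_iterations",
    "exclude_region",
    "gap_report",
    "ci_overlap",
]

SMALL_SAMPLE = "SMALL_SAMPLE"
DIVERGENT = "DIVERGENT"


@dataclass
class IterationSummary:
    """Median point estimate and CI bounds over R augmentation iterations."""

    region: str
    method: str
    R: int
    median_point: float
    median_lcl: float
    median_ucl: float
    per_iteration: list[tuple[float, float, float]]
    n_records: int
    s_obs_empirical: int
    s_checklist_only: int
    n_failed: int = 0


@dataclass
class GapReport:
    """Taxonomic gap derived from a richness CI and the described species count."""

    described: int
    gap_low: float
    gap_high: float
    pct_low: int
    pct_high: int
    rate: float
    years_low: int
    years_high: int

    def to_dict(self) -> dict:
        return {
            "described": self.described,
            "gap_low": self.gap_low,
            "gap_high": self.gap_high,
            "pct_low": self.pct_low,
            "pct_high": self.pct_high,
            "rate": self.rate,
            "years_low": self.years_low,
            "years_high": self.years_high,
        }


def _estimate_with_ci(
    assemblage: AbundanceVector,
    method: str,
    ci: str,
    level: float,
    seed: int,
    bootstrap_B: int,
) -> tuple[float, float, float]:
    fc = est.frequency_counts(assemblage)
    if method == "chao1":
        point = est.chao1(fc)
    elif method == "ichao1":
        point = est.ichao1(fc)
    elif method == "inext":
        # asymptotic richness (Hill number q=0), which equals Chao1
        point = est.chao1(fc)
    else:
        raise ValueError(f"unknown method {method!r}")

    if ci == "none":
        return point, point, point
    if ci == "log":
        # Chao-type log-transformed interval around the chosen point estimate
        t = point - fc.s_obs
        if t <= 0:
            return point, float(fc.s_obs), float(fc.s_obs)
        v = est.chao1_variance(fc)
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        r = math.exp(z * math.sqrt(math.log(1.0 + v / t**2)))
        return point, fc.s_obs + t / r, fc.s_obs + t * r
    if ci == "bootstrap":
        estimator = "chao1" if method == "inext" else method
        lcl, ucl, _ = est.bootstrap_ci(
            assemblage, estimator=estimator, B=bootstrap_B, level=level, seed=seed
        )
        return point, lcl, ucl
    raise ValueError(f"unknown ci method {ci!r}")


def run_iterations(
    empirical: AbundanceVector,
    checklist_species: Iterable[str],
    curve: LiteratureCurve,
    method: str = "ichao1",
    R: int = 100,
    seed: int = 0,
    ci: str = "log",
    level: float = 0.95,
    bootstrap_B: int = 100,
) -> IterationSummary:
    """Repeat augmentation + estimation R times and take component-wise medians.

    Iteration i draws fresh curve-sampled counts using the i-th child seed
    of ``seed``, so the whole run is deterministic for a fixed master seed.
    Iterations in which the estimator raises are recorded as failed and
    excluded from the medians; more than 50% failures is a hard error.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    checklist_species = set(checklist_species)
    missing = checklist_species - set(empirical.counts)
    seeds = child_seeds(seed, 2 * R)
    results: list[tuple[float, float, float]] = []
    n_failed = 0
    for i in range(R):
        try:
            augmented = augment_assemblage(empirical, checklist_species, curve, seeds[i])
            results.append(
                _estimate_with_ci(augmented, method, ci, level, seeds[R + i], bootstrap_B)
            )
        except Exception as exc:  # noqa: BLE001 - failure policy is per-iteration
            n_failed += 1
            warnings.warn(f"iteration {i} failed: {exc}", stacklevel=2)
    if n_failed > R / 2:
        raise RuntimeError(f"{n_failed}/{R} iterations failed")
    points, lcls, ucls = (np.array(col) for col in zip(*results))
    return IterationSummary(
        region=empirical.region,
        method=method,
        R=R,
        median_point=float(np.median(points)),
        median_lcl=float(np.median(lcls)),
        median_ucl=float(np.median(ucls)),
        per_iteration=results,
        n_records=empirical.n,
        s_obs_empirical=empirical.s_obs,
        s_checklist_only=len(missing),
        n_failed=n_failed,
    )


def exclude_region(
    summary: IterationSummary,
    min_records: int = 30,
    fold_threshold: float = 10.0,
) -> tuple[bool, str | None]:
    """Decide whether a region's summary is reliable enough to report.

    Excluded with reason SMALL_SAMPLE when the region has fewer than
    ``min_records`` occurrence records (or no observed species at all), and
    with reason DIVERGENT when the median estimate exceeds the observed
    species richness by more than ``fold_threshold``-fold (an order of
    magnitude by default).
    """
    s_obs_total = summary.s_obs_empirical + summary.s_checklist_only
    if summary.n_records < min_records or s_obs_total == 0:
        return (False, SMALL_SAMPLE)
    if summary.median_point / s_obs_total > fold_threshold:
        return (False, DIVERGENT)
    return (True, None)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def gap_report(
    ci: tuple[float, float],
    described: int,
    rate: float = 117.0,
) -> GapReport:
    """Derive the taxonomic gap from a richness confidence interval.

    gap = CI bound - described species (element-wise, floored at 0);
    pct = round(100 * gap / described); years = round(gap / rate), both
    rounded half away from zero.  ``rate`` is the description rate in
    species per year.
    """
    low, high = ci
    if low > high:
        raise ValueError("CI low must be <= high")
    if described < 1:
        raise ValueError("described must be >= 1")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    gap_low, gap_high = low - described, high - described
    if gap_low < 0 or gap_high < 0:
        warnings.warn("estimated richness below described count; gap floored at 0", stacklevel=2)
        gap_low, gap_high = max(gap_low, 0.0), max(gap_high, 0.0)
    return GapReport(
        described=described,
        gap_low=gap_low,
        gap_high=gap_high,
        pct_low=_round_half_away(100.0 * gap_low / described),
        pct_high=_round_half_away(100.0 * gap_high / described),
        rate=rate,
        years_low=_round_half_away(gap_low / rate),
        years_high=_round_half_away(gap_high / rate),
    )


def ci_overlap(summary_a: IterationSummary, summary_b: IterationSummary) -> bool:
    """True iff the two summaries' median CIs intersect (closed intervals).

    Both summaries must describe the same region; touching endpoints count
    as overlap.
    """
    if summary_a.region != summary_b.region:
        raise ValueError("summaries describe different regions")
    return (
        summary_a.median_lcl <= summary_b.median_ucl
        and summary_b.median_lcl <= summary_a.median_ucl
    )
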