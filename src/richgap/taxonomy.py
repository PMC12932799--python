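"""Synonym deduplication and species-accumulation analyses.

Synonym lists accumulate orthographic variants — alternative spellings of
the same published name that are not distinct nomenclatural acts.  They are
removed by grouping names that share an accepted id and (bracket-stripped)
author-year, computing pairwise optimal-string-alignment distances within
each group, linking pairs within a small edit-distance threshold, and
keeping only the first member of each connected component.

The deduplicated taxonomy then yields accumulation curves — cumulative
counts by description year of names that remain valid, of synonyms, and of
first digitised occurrence records — and an ordinary-least-squares
description rate (species/year) over a recent window.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "TaxonName",
    "AccumulationCurve",
    "normalize_epithet",
    "osa_distance",
    "orthographic_clusters",
    "dedupe_synonyms",
    "accumulation_curves",
    "description_rate",
]

ACCEPTED = "ACCEPTED"
SYNONYM = "SYNONYM"

VALID_NAMES = "VALID_NAMES"
SYNONYMS = "SYNONYMS"
FIRST_OCCURRENCE = "FIRST_OCCURRENCE"


@dataclass(frozen=True)
class TaxonName:
    """One name row in a taxonomy: accepted name or synonym."""

    accepted_id: str
    name: str
    author_year: str
    description_year: int | None = None
    status: str = ACCEPTED
    first_occurrence_year: int | None = None


@dataclass(frozen=True)
class AccumulationCurve:
    """Cumulative count of items by year for one series."""

    series: str
    points: tuple[tuple[int, int], ...]  # sorted (year, cumulative count)


def normalize_epithet(name: str, author_year: str = "") -> tuple[str, str]:
    """Normalise a name and its author-year for variant comparison.

    Digits are stripped from the name and brackets/parentheses from the
    author-year; internal whitespace is collapsed and ends trimmed.  Case is
    preserved here; comparisons downstream are case-insensitive.
    """
    if not name or not name.strip():
        raise ValueError("empty name")
    clean_name = re.sub(r"\d+", "", name)
    clean_name = re.sub(r"\s+", " ", clean_name).strip()
    clean_author = re.sub(r"[()\[\]]", "", author_year or "")
    clean_author = re.sub(r"\s+", " ", clean_author).strip()
    return clean_name, clean_author


def osa_distance(a: str, b: str) -> int:
    """Optimal string alignment (restricted Damerau–Levenshtein) distance.

    Allows substitutions, insertions, deletions, and transposition of
    adjacent characters, with no substring edited more than once.
    """
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return la or lb
    prev2 = None
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        prev2, prev = prev, cur
    return prev[lb]


def orthographic_clusters(
    group: Sequence[TaxonName],
    distance_threshold: int = 2,
) -> list[dict]:
    """Cluster orthographic variants within one (acceptedId, authorYear) group.

    Builds a graph with an edge between two names whose normalised,
    case-folded forms are within ``distance_threshold`` OSA edits, takes
    connected components as clusters, and keeps the first member of each
    component in input order as its representative.

    Returns a list of dicts ``{"representative": TaxonName,
    "members": [TaxonName, ...]}`` ordered by first appearance.
    """
    if not group:
        raise ValueError("group must be nonempty")
    normalized = [normalize_epithet(t.name)[0].lower() for t in group]
    graph = nx.Graph()
    graph.add_nodes_from(range(len(group)))
    for i in range(len(group)):
        for j in range(i + 1, len(group)):
            if osa_distance(normalized[i], normalized[j]) <= distance_threshold:
                graph.add_edge(i, j)
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    )
    return [
        {"representative": group[c[0]], "members": [group[i] for i in c]}
        for c in components
    ]


def dedupe_synonyms(
    taxonomy: Sequence[TaxonName],
    distance_threshold: int = 2,
) -> tuple[list[TaxonName], pd.DataFrame]:
    """Remove orthographic variants from a full taxonomy.

    Synonyms are grouped by (acceptedId, normalised authorYear) and
    clustered within each group; accepted names are never removed.  Returns
    the kept rows in original order and a per-row report DataFrame with the
    cluster id and kept/removed status.
    """
    order = {id(t): i for i, t in enumerate(taxonomy)}
    groups: dict[tuple[str, str], list[TaxonName]] = {}
    for t in taxonomy:
        if t.status == SYNONYM:
            _, author = normalize_epithet(t.name, t.author_year)
            groups.setdefault((t.accepted_id, author), []).append(t)

    kept_ids: set[int] = {id(t) for t in taxonomy if t.status != SYNONYM}
    rows = []
    cluster_counter = 0
    for key in sorted(groups):
        group = groups[key]
        for cluster in orthographic_clusters(group, distance_threshold):
            cluster_id = f"c{cluster_counter}"
            cluster_counter += 1
            rep = cluster["representative"]
            kept_ids.add(id(rep))
            for member in cluster["members"]:
                rows.append(
                    {
                        "acceptedId": member.accepted_id,
                        "name": member.name,
                        "authorYear": member.author_year,
                        "cluster": cluster_id,
                        "kept": member is rep,
                    }
                )
    kept = [t for t in taxonomy if id(t) in kept_ids]
    report = pd.DataFrame(rows, columns=["acceptedId", "name", "authorYear", "cluster", "kept"])
    kept.sort(key=lambda t: order[id(t)])
    return kept, report


def _cumulative(years: Iterable[int]) -> tuple[tuple[int, int], ...]:
    years = sorted(years)
    points: list[tuple[int, int]] = []
    for year in years:
        if points and points[-1][0] == year:
            points[-1] = (year, points[-1][1] + 1)
        else:
            points.append((year, (points[-1][1] if points else 0) + 1))
    return tuple(points)


def accumulation_curves(taxonomy: Sequence[TaxonName]) -> dict[str, AccumulationCurve]:
    """Build the three accumulation curves from a deduplicated taxonomy.

    VALID_NAMES counts accepted names by description year; SYNONYMS counts
    synonyms by their (original) description year — not the year they were
    synonymised; FIRST_OCCURRENCE counts names by the year of their first
    digitised occurrence record, skipping names without one.
    """
    valid = [t.description_year for t in taxonomy if t.status == ACCEPTED and t.description_year]
    syn = [t.description_year for t in taxonomy if t.status == SYNONYM and t.description_year]
    occ = [t.first_occurrence_year for t in taxonomy if t.first_occurrence_year]
    return {
        VALID_NAMES: AccumulationCurve(VALID_NAMES, _cumulative(valid)),
        SYNONYMS: AccumulationCurve(SYNONYMS, _cumulative(syn)),
        FIRST_OCCURRENCE: AccumulationCurve(FIRST_OCCURRENCE, _cumulative(occ)),
    }


def description_rate(curve: AccumulationCurve, start_year: int = 1960) -> float:
    """OLS slope (items/year) of the cumulative curve from ``start_year`` on.

    A constant recent description rate shows up as a near-linear cumulative
    curve; the slope is the number of new names per year.
    """
    pts = [(y, c) for y, c in curve.points if y >= start_year]
    if len(pts) < 2:
        raise ValueError("need >= 2 curve points at or after start_year")
    years = np.array([p[0] for p in pts], dtype=float)
    counts = np.array([p[1] for p in pts], dtype=float)
    slope, _ = np.polyfit(years, counts, 1)
    return float(slope)


def curves_to_frame(curves: dict[str, AccumulationCurve]) -> pd.DataFrame:
    """Flatten accumulation curves to a tidy (series, year, cumulative) table."""
    rows = [
        {"series": c.series, "year": y, "cumulative": n}
        for c in curves.values()
        for y, n in c.points
    ]
    return pd.DataFrame(rows, columns=["series", "year", "cumulative"])
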