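"""Synthetic fixtures with planted ground truth.

Everything the pipeline consumes can be generated here with a known answer
attached: communities with known true richness, occurrence files with
per-record planted defect labels (so the six-rule cleaner has an exact
oracle), taxonomies with planted orthographic-variant clusters, country
checklists with a known zero-occurrence subset, and literature sample-size
tables drawn from a known power law.

Geography is deliberately toy-like: synthetic countries are 10-degree
longitude bands, so the coordinate-to-country resolver needed by the
COUNTRY_MISMATCH rule is a trivial lookup and tests need no polygon data.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cleaning import (
    ABSENCE,
    BAD_BASIS,
    BAD_LICENSE,
    COUNTRY_MISMATCH,
    INVALID_BINOMIAL,
    OFF_CHECKLIST,
    OccurrenceRecord,
)
from .seeding import child_seeds, rng_from
from .taxonomy import osa_distance

__all__ = [
    "SyntheticCommunity",
    "ContaminationSpec",
    "generate_community",
    "band_resolver",
    "sample_occurrences",
    "generate_taxonomy",
    "generate_checklist",
    "generate_literature_sizes",
    "simulate_to_dir",
]

_GENERA = (
    "Apis", "Bombus", "Lasioglossum", "Andrena", "Megachile", "Osmia",
    "Halictus", "Xylocopa", "Colletes", "Hylaeus", "Nomada", "Anthophora",
    "Ceratina", "Euglossa", "Melipona", "Perdita", "Exoneura", "Amegilla",
)

_LETTERS = string.ascii_lowercase


def _random_epithet(rng: np.random.Generator, length: int | None = None) -> str:
    n = int(length or rng.integers(6, 11))
    return "".join(rng.choice(list(_LETTERS), size=n))


def _species_names(rng: np.random.Generator, n: int) -> list[str]:
    names: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        name = f"{_GENERA[int(rng.integers(len(_GENERA)))]} {_random_epithet(rng)}"
        if name not in names:
            names.add(name)
            out.append(name)
    return out


@dataclass
class SyntheticCommunity:
    """A community with known true richness and per-species region labels."""

    true_richness: int
    species: list[str]
    relative_abundances: np.ndarray
    region_labels: dict[str, list[str]]  # species -> list of country codes
    regions: list[str] = field(default_factory=list)
    continents: dict[str, str] = field(default_factory=dict)  # country -> continent

    def __post_init__(self) -> None:
        if len(self.species) != self.true_richness:
            raise ValueError("species list length must equal true_richness")
        if abs(float(self.relative_abundances.sum()) - 1.0) > 1e-9:
            raise ValueError("relative abundances must sum to 1")
        if any(not labels for labels in self.region_labels.values()):
            raise ValueError("every species needs >= 1 region label")


@dataclass(frozen=True)
class ContaminationSpec:
    """Per-rule planting probabilities for dirty occurrence records."""

    rate_invalid_binomial: float = 0.0
    rate_bad_basis: float = 0.0
    rate_country_mismatch: float = 0.0
    rate_absence: float = 0.0
    rate_bad_license: float = 0.0
    rate_off_checklist: float = 0.0

    def __post_init__(self) -> None:
        for name, rate in self.as_dict().items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {
            INVALID_BINOMIAL: self.rate_invalid_binomial,
            BAD_BASIS: self.rate_bad_basis,
            COUNTRY_MISMATCH: self.rate_country_mismatch,
            ABSENCE: self.rate_absence,
            BAD_LICENSE: self.rate_bad_license,
            OFF_CHECKLIST: self.rate_off_checklist,
        }


def _region_codes(n: int) -> list[str]:
    codes = []
    for i in range(n):
        codes.append(chr(ord("A") + i // 26) + chr(ord("A") + i % 26))
    return codes


def generate_community(
    s_true: int,
    shape: tuple = ("lognormal", 0.0, 1.5),
    seed: int = 0,
    n_regions: int = 6,
) -> SyntheticCommunity:
    """Generate a community of ``s_true`` species with known abundances.

    ``shape`` is ``("lognormal", meanlog, sdlog)`` for lognormal relative
    abundances (the default, meanlog 0 / sdlog 1.5, yields assemblages rich
    in singletons and doubletons under realistic sample sizes) or
    ``("powerlaw", exponent)`` for a rank-abundance power law
    p_r proportional to r^(-exponent).
    """
    if s_true < 1:
        raise ValueError("s_true must be >= 1")
    if n_regions < 2:
        raise ValueError("need >= 2 synthetic regions")
    rng = rng_from(seed)
    kind = shape[0]
    if kind == "lognormal":
        _, meanlog, sdlog = shape
        if sdlog < 0:
            raise ValueError("sdlog must be >= 0")
        weights = rng.lognormal(meanlog, sdlog, s_true)
    elif kind == "powerlaw":
        _, exponent = shape
        if exponent <= 0:
            raise ValueError("power-law exponent must be > 0")
        weights = np.arange(1, s_true + 1, dtype=float) ** (-float(exponent))
    else:
        raise ValueError(f"unknown abundance shape {kind!r}")
    abundances = weights / weights.sum()

    species = _species_names(rng, s_true)
    regions = _region_codes(n_regions)
    labels: dict[str, list[str]] = {}
    for sp in species:
        k = int(rng.integers(1, min(3, n_regions) + 1))
        chosen = rng.choice(regions, size=k, replace=False)
        labels[sp] = sorted(str(c) for c in chosen)
    half = (n_regions + 1) // 2
    continents = {
        c: ("NORTHLAND" if i < half else "SOUTHLAND") for i, c in enumerate(regions)
    }
    return SyntheticCommunity(
        true_richness=s_true,
        species=species,
        relative_abundances=abundances,
        region_labels=labels,
        regions=regions,
        continents=continents,
    )


def band_resolver(regions: list[str]):
    """Coordinate -> country resolver for 10-degree longitude-band countries.

    Country i occupies longitudes [-180 + 10 i, -180 + 10 (i + 1)).
    Returns a callable (lat, lon) -> code or None outside all bands.
    """
    bands = {code: (-180.0 + 10.0 * i, -180.0 + 10.0 * (i + 1)) for i, code in enumerate(regions)}

    def resolve(lat: float, lon: float) -> str | None:
        for code, (lo, hi) in bands.items():
            if lo <= lon < hi:
                return code
        return None

    resolve.bands = bands  # type: ignore[attr-defined]
    return resolve


def _band_lon(rng: np.random.Generator, regions: list[str], code: str) -> float:
    i = regions.index(code)
    return float(-180.0 + 10.0 * i + rng.uniform(0.5, 9.5))


def sample_occurrences(
    community: SyntheticCommunity,
    n: int,
    contamination: ContaminationSpec = ContaminationSpec(),
    seed: int = 0,
    exclude_species: set[str] | None = None,
) -> tuple[list[OccurrenceRecord], list[set[str]]]:
    """Draw ``n`` occurrence records, planting defects with known labels.

    Species are drawn from the community's relative abundances (optionally
    excluding a zero-occurrence subset); each record starts clean by
    construction — valid binomial, accepted basis/license/status, and
    coordinates inside its stated country's band — then each defect is
    planted independently with its configured rate.  Union semantics: a
    record may carry several defects.  The one incompatible pair is
    INVALID_BINOMIAL + OFF_CHECKLIST (an invalid name has no species key to
    test against the checklist), resolved in favour of INVALID_BINOMIAL.

    Returns (records, per-record planted defect sets).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if community.true_richness == 0 or not community.species:
        raise ValueError("empty community")
    rng = rng_from(seed)
    probs = community.relative_abundances.copy()
    if exclude_species:
        mask = np.array([sp not in exclude_species for sp in community.species])
        if not mask.any():
            raise ValueError("exclude_species removes every species")
        probs = probs * mask
        probs = probs / probs.sum()
    regions = community.regions
    rates = contamination.as_dict()

    records: list[OccurrenceRecord] = []
    truths: list[set[str]] = []
    species_idx = rng.choice(len(community.species), size=n, p=probs)
    for i in range(n):
        sp = community.species[int(species_idx[i])]
        country = str(rng.choice(community.region_labels[sp]))
        lon = _band_lon(rng, regions, country)
        lat = float(rng.uniform(-60.0, 60.0))
        record = OccurrenceRecord(
            scientific_name=sp,
            decimal_latitude=lat,
            decimal_longitude=lon,
            country_code=country,
            basis_of_record="PRESERVED_SPECIMEN",
            occurrence_status="present",
            license="CC0",
            year=int(rng.integers(1950, 2024)),
            species_key=sp,
        )
        planted = {rule for rule, rate in rates.items() if rate > 0 and rng.random() < rate}
        if INVALID_BINOMIAL in planted:
            planted.discard(OFF_CHECKLIST)

        if OFF_CHECKLIST in planted:
            # a well-formed binomial that is on no checklist
            phantom = f"Phantomus {_random_epithet(rng, 8)}"
            record.scientific_name = phantom
            record.species_key = phantom
        if INVALID_BINOMIAL in planted:
            record.scientific_name = sp.split()[0]
            record.species_key = None
        if BAD_BASIS in planted:
            record.basis_of_record = "FOSSIL_SPECIMEN"
        if COUNTRY_MISMATCH in planted:
            others = [c for c in regions if c != country]
            record.decimal_longitude = _band_lon(rng, regions, str(rng.choice(others)))
        if ABSENCE in planted:
            record.occurrence_status = "absent"
        if BAD_LICENSE in planted:
            record.license = "ALL_RIGHTS_RESERVED"

        records.append(record)
        truths.append(planted)
    return records, truths


def generate_checklist(
    community: SyntheticCommunity,
    zero_occurrence_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, set[str]]:
    """Build the species-by-country checklist and pick a zero-occurrence subset.

    The checklist contains every (species, country) pair in the community.
    A fraction of species is marked zero-occurrence; pass that set as
    ``exclude_species`` to :func:`sample_occurrences` to guarantee they
    never appear in the occurrence file.
    """
    if not 0.0 <= zero_occurrence_fraction <= 1.0:
        raise ValueError("zero_occurrence_fraction must be in [0, 1]")
    rng = rng_from(seed)
    rows = [
        {"species": sp, "countryCode": c}
        for sp in community.species
        for c in community.region_labels[sp]
    ]
    n_zero = int(round(zero_occurrence_fraction * community.true_richness))
    zero = set(rng.choice(community.species, size=n_zero, replace=False)) if n_zero else set()
    return pd.DataFrame(rows, columns=["species", "countryCode"]), {str(s) for s in zero}


def _mutate_epithet(
    rng: np.random.Generator,
    epithet: str,
    n_edits: int,
    avoid: tuple[str, ...] = (),
) -> str:
    """Apply 1-2 single-character edits (sub/ins/del/adjacent swap).

    Because optimal-string-alignment distance violates the triangle
    inequality, two sequential edits occasionally land farther than 2 OSA
    edits from the parent; the result is therefore checked and redrawn so
    the planted variant is guaranteed within the clustering threshold and
    distinct from every epithet in ``avoid``.
    """
    for _ in range(100):
        s = list(epithet)
        for _ in range(n_edits):
            op = rng.integers(4)
            pos = int(rng.integers(len(s)))
            if op == 0:  # substitute
                s[pos] = _LETTERS[(ord(s[pos]) - 97 + 1 + int(rng.integers(24))) % 26]
            elif op == 1:  # insert
                s.insert(pos, str(rng.choice(list(_LETTERS))))
            elif op == 2 and len(s) > 4:  # delete
                s.pop(pos)
            elif len(s) > 1:  # swap adjacent
                pos = min(pos, len(s) - 2)
                if s[pos] != s[pos + 1]:
                    s[pos], s[pos + 1] = s[pos + 1], s[pos]
                else:
                    s[pos] = _LETTERS[(ord(s[pos]) - 97 + 1) % 26]
        out = "".join(s)
        if 1 <= osa_distance(out, epithet) <= 2 and all(
            osa_distance(out, e) > 2 for e in avoid
        ):
            return out
    # deterministic fallback: single substitution is always distance 1
    s = list(epithet)
    s[0] = _LETTERS[(ord(s[0]) - 97 + 1) % 26]
    return "".join(s)


def generate_taxonomy(
    n_accepted: int,
    synonyms_per_species: float = 1.0,
    variant_rate: float = 0.0,
    year_range: tuple[int, int] = (1758, 2023),
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a taxonomy with planted orthographic variants.

    Each accepted name receives a Poisson(``synonyms_per_species``) number
    of base synonyms; each base synonym spawns an orthographic variant with
    probability ``variant_rate``.  A variant differs from its parent by at
    most two single-character edits and shares the parent's acceptedId and
    authorYear, so deduplication at edit-distance threshold 2 should merge
    exactly the planted pairs.  Base-synonym epithets within a species are
    kept at OSA distance > 6 from each other so distinct planted clusters
    can never collide.

    The returned table carries a ``trueCluster`` ground-truth column.
    """
    if n_accepted < 1:
        raise ValueError("n_accepted must be >= 1")
    if not 0.0 <= variant_rate <= 1.0:
        raise ValueError("variant_rate must be in [0, 1]")
    if synonyms_per_species < 0:
        raise ValueError("synonyms_per_species must be >= 0")
    y0, y1 = year_range
    if y0 > y1:
        raise ValueError("year_range start must be <= end")
    rng = rng_from(seed)
    authors = ("Smith", "Cockerell", "Friese", "Latreille", "Michener")

    rows = []
    cluster_counter = 0
    names = _species_names(rng, n_accepted)
    for i, name in enumerate(names):
        accepted_id = f"a{i:04d}"
        genus = name.split()[0]
        author = f"{rng.choice(authors)}, {int(rng.integers(y0, y1 + 1))}"
        rows.append(
            {
                "acceptedId": accepted_id,
                "name": name,
                "authorYear": author,
                "descriptionYear": int(author.split(", ")[1]),
                "status": "accepted",
                "trueCluster": f"acc{i:04d}",
            }
        )
        # the species' synonyms share one author-year so that groups can
        # contain several distinct planted clusters
        syn_author = f"{rng.choice(authors)}, {int(rng.integers(y0, y1 + 1))}"
        used_epithets = [name.split()[1]]
        for _ in range(int(rng.poisson(synonyms_per_species))):
            while True:
                epithet = _random_epithet(rng, int(rng.integers(8, 12)))
                if all(osa_distance(epithet, e) > 6 for e in used_epithets):
                    used_epithets.append(epithet)
                    break
            cluster = f"syn{cluster_counter:05d}"
            cluster_counter += 1
            rows.append(
                {
                    "acceptedId": accepted_id,
                    "name": f"{genus} {epithet}",
                    "authorYear": syn_author,
                    "descriptionYear": int(syn_author.split(", ")[1]),
                    "status": "synonym",
                    "trueCluster": cluster,
                }
            )
            if rng.random() < variant_rate:
                others = tuple(e for e in used_epithets if e != epithet)
                variant = _mutate_epithet(rng, epithet, int(rng.integers(1, 3)), avoid=others)
                rows.append(
                    {
                        "acceptedId": accepted_id,
                        "name": f"{genus} {variant}",
                        "authorYear": syn_author,
                        "descriptionYear": int(syn_author.split(", ")[1]),
                        "status": "synonym",
                        "trueCluster": cluster,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["acceptedId", "name", "authorYear", "descriptionYear", "status", "trueCluster"],
    )


def generate_literature_sizes(
    exponent: float,
    n_species: int,
    cap: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-species literature sample sizes from a truncated power law.

    Size x in {1..cap} is drawn with probability proportional to
    x^(-exponent).  Exponents > 1 keep the distribution singleton-dominated
    as the cap grows.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if exponent <= 0:
        raise ValueError("exponent must be > 0")
    rng = rng_from(seed)
    support = np.arange(1, cap + 1, dtype=float)
    pmf = support ** (-float(exponent))
    pmf = pmf / pmf.sum()
    sizes = rng.choice(np.arange(1, cap + 1), size=n_species, p=pmf)
    return pd.DataFrame(
        {"species": [f"Litsp sp{i:05d}" for i in range(n_species)], "nSpecimens": sizes.astype(int)}
    )


def simulate_to_dir(
    out_dir,
    s_true: int = 200,
    n: int = 2000,
    contamination: ContaminationSpec = ContaminationSpec(),
    zero_occurrence_fraction: float = 0.1,
    seed: int = 0,
) -> dict:
    """Write a complete fixture set (CSVs + ground-truth JSON sidecar).

    Generates a community, checklist (with zero-occurrence species),
    occurrence file with planted defects, taxonomy, and literature sizes,
    each from an independent child seed of ``seed``.
    """
    from .cleaning import write_occurrences

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = child_seeds(seed, 5)
    community = generate_community(s_true, seed=seeds[0])
    checklist, zero = generate_checklist(community, zero_occurrence_fraction, seed=seeds[1])
    records, truths = sample_occurrences(
        community, n, contamination, seed=seeds[2], exclude_species=zero
    )
    taxonomy = generate_taxonomy(s_true, 1.0, 0.3, seed=seeds[3])
    literature = generate_literature_sizes(1.37, max(s_true, 500), 100, seed=seeds[4])

    write_occurrences(records, out / "occurrences.csv")
    checklist.to_csv(out / "checklist.csv", index=False)
    taxonomy.to_csv(out / "taxonomy.csv", index=False)
    literature.to_csv(out / "literature_sizes.csv", index=False)
    truth = {
        "true_richness": community.true_richness,
        "regions": community.regions,
        "continents": community.continents,
        "zero_occurrence_species": sorted(zero),
        "planted_defects": [sorted(t) for t in truths],
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return truth
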