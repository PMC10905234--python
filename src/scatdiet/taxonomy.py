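"""Prey taxonomy assignment from best-hit records.

An OTU whose best hit has percent identity >= 96 is assigned to that
species, provided the species occurs on the regional checklist; a >= 96%
hit to a species not confirmed for the region is escalated to genus.
Hits below 96% are placed at a higher rank by configurable identity bands
(default: >=92 genus, >=85 family, else order).  Tree-based placement of
low-identity hits is deliberately out of scope; the bands are an offline,
reproducible stand-in and are exposed so users can match their own
reference system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .io import Checklist, HitRecord, TraitRecord

__all__ = [
    "IdentityBands",
    "TaxonAssignment",
    "CategoryAssignment",
    "TROPHIC_BINS",
    "assign_taxonomy",
    "assign_all",
    "collapse_entities",
    "categorize_prey",
]

RANKS = ("species", "genus", "family", "order")

#: Trophic-level bins (closed on both printed endpoints, one-decimal grid).
#: Bins at or below 3.0 are planktivores, above are carnivores.
TROPHIC_BINS = (
    ("2.0-2.5", 2.0, 2.5),
    ("2.6-3.0", 2.6, 3.0),
    ("3.1-3.5", 3.1, 3.5),
    ("3.6-4.0", 3.6, 4.0),
    ("4.1-4.5", 4.1, 4.5),
)


@dataclass(frozen=True)
class IdentityBands:
    """Percent-identity thresholds for rank assignment."""

    species: float = 96.0
    genus: float = 92.0
    family: float = 85.0


@dataclass(frozen=True)
class TaxonAssignment:
    otu_id: str
    assigned_name: str
    assigned_rank: str  # one of RANKS
    percent_identity: float
    checklist_confirmed: bool

    def __post_init__(self) -> None:
        if self.assigned_rank not in RANKS:
            raise ValueError(f"invalid rank {self.assigned_rank!r}")
        if self.assigned_rank == "species" and not (
            self.percent_identity >= 96.0 and self.checklist_confirmed
        ):
            raise ValueError(
                f"OTU {self.otu_id!r}: species-level assignment requires "
                "identity >= 96 and checklist confirmation"
            )


@dataclass(frozen=True)
class CategoryAssignment:
    item: str
    habitat_class: str
    trophic_bin: str
    guild: str  # planktivore | carnivore


def _name_at_rank(hit: HitRecord, rank: str) -> str:
    name = hit.lineage.get(rank, "")
    if name:
        return name
    if rank == "species" and hit.best_hit_taxon and " " in hit.best_hit_taxon:
        return hit.best_hit_taxon
    if rank == "genus" and hit.best_hit_taxon and " " in hit.best_hit_taxon:
        return hit.best_hit_taxon.split()[0]
    return ""


def assign_taxonomy(
    hit: HitRecord,
    checklist: Checklist,
    bands: IdentityBands = IdentityBands(),
) -> TaxonAssignment:
    """Assign a final taxonomic identity to one OTU from its best hit.

    If the lineage lacks a name at the target rank the assignment falls
    back to the next available higher rank (with a warning).
    """
    ident = hit.percent_identity
    species_name = _name_at_rank(hit, "species")
    if ident >= bands.species and species_name and species_name in checklist:
        return TaxonAssignment(hit.otu_id, species_name, "species", ident, True)

    if ident >= bands.species:
        target = "genus"  # high identity but species unconfirmed regionally
    elif ident >= bands.genus:
        target = "genus"
    elif ident >= bands.family:
        target = "family"
    else:
        target = "order"

    start = RANKS.index(target)
    for rank in RANKS[start:]:
        name = _name_at_rank(hit, rank)
        if name:
            if rank != target:
                warnings.warn(
                    f"OTU {hit.otu_id}: no lineage name at rank {target!r}; "
                    f"assigned at {rank!r} instead",
                    stacklevel=2,
                )
            return TaxonAssignment(hit.otu_id, name, rank, ident, False)
    raise ValueError(f"OTU {hit.otu_id!r}: lineage has no usable rank at or above {target!r}")


def assign_all(hits, checklist, bands: IdentityBands = IdentityBands()) -> list[TaxonAssignment]:
    return [assign_taxonomy(h, checklist, bands) for h in hits]


def collapse_entities(assignments) -> tuple[pd.DataFrame, dict[str, int]]:
    """Group OTUs sharing (assigned name, rank) into unique taxonomic entities.

    Returns the entity table (entity, rank, member OTUs, n_otus) and the
    per-rank tally of *assignments* (how many OTUs resolved at each rank).
    """
    rows: dict[tuple[str, str], list[str]] = {}
    tally = {r: 0 for r in RANKS}
    for a in assignments:
        tally[a.assigned_rank] += 1
        rows.setdefault((a.assigned_name, a.assigned_rank), []).append(a.otu_id)
    table = pd.DataFrame(
        [
            {"entity": name, "rank": rank, "otu_ids": ";".join(otus), "n_otus": len(otus)}
            for (name, rank), otus in sorted(rows.items())
        ],
        columns=["entity", "rank", "otu_ids", "n_otus"],
    )
    return table, tally


def trophic_bin(level: float) -> str:
    """Bin a trophic level into the five half-unit categories.

    The printed bins leave one-decimal gaps (e.g. 2.5-2.6); a value in a
    gap goes to the nearest bin edge, ties rounding up.
    """
    v = round(level * 100)  # integer hundredths avoid float-noise at ties
    best, best_dist = None, None
    for label, lo, hi in TROPHIC_BINS:
        lo_i, hi_i = round(lo * 100), round(hi * 100)
        if lo_i <= v <= hi_i:
            return label
        dist = min(abs(v - lo_i), abs(v - hi_i))
        if best_dist is None or dist <= best_dist:  # ties go to the upper bin
            best, best_dist = label, dist
    return best


def categorize_prey(item: str, trait: TraitRecord | None) -> CategoryAssignment:
    """Attach habitat and trophic category to a prey item.

    A missing trait record yields an 'uncategorized' flag; such items are
    excluded from category-level summaries but kept in item-level ones.
    """
    if trait is None:
        return CategoryAssignment(item, "uncategorized", "uncategorized", "uncategorized")
    tbin = trophic_bin(trait.trophic_level)
    guild = "planktivore" if tbin in ("2.0-2.5", "2.6-3.0") else "carnivore"
    return CategoryAssignment(item, trait.habitat_class, tbin, guild)
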