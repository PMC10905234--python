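"""Readers and writers for the pipeline's external table formats.

The on-disk OTU table follows the common VSEARCH/QIIME dialect (OTUs as
rows, samples as columns); in memory the orientation is samples x OTUs so
that sample-major statistics are natural.  All text I/O is UTF-8 and uses
"." as the decimal separator regardless of locale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ReadCountTable",
    "HitRecord",
    "TraitRecord",
    "HABITAT_CLASSES",
    "ASSAYS",
    "read_otu_table",
    "write_otu_table",
    "read_hits",
    "write_hits",
    "read_traits",
    "write_traits",
    "read_checklist",
    "write_checklist",
    "write_stat_result",
]

#: Closed set of prey habitat classes (depth-zone / benthic categories).
HABITAT_CLASSES = (
    "epipelagic",        # 0-200 m open water
    "mesopelagic",       # 200-1000 m
    "bathypelagic",      # 1000-3000 m
    "rocky_bottom",      # benthic, 0-200 m
    "rocky_bottom_deep", # benthic, >200 m
)

#: Valid assay labels for a sample (blocking-primer PCR, plain PCR, or
#: already pooled replicates).
ASSAYS = ("blocking", "no_blocking", "pooled")

#: Lineage ranks carried by a hit record, most specific first.
LINEAGE_RANKS = ("species", "genus", "family", "order", "class")


class FormatError(ValueError):
    """Malformed input file; the message names the offending location."""


@dataclass
class ReadCountTable:
    """Samples x OTUs integer read counts plus per-sample metadata.

    Attributes
    ----------
    counts : pd.DataFrame
        Non-negative integer matrix, index = sample ids, columns = OTU ids.
    meta : pd.DataFrame
        Indexed by sample id, columns ``rookery`` (str, empty for
        controls), ``is_negative_control`` (bool), ``assay`` (one of
        :data:`ASSAYS`) and optionally ``scat_id`` linking the two assay
        replicates of one scat.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- convenience views -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def negative_controls(self) -> list[str]:
        return list(self.meta.index[self.meta["is_negative_control"]])

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def subset_samples(self, sample_ids) -> "ReadCountTable":
        ids = list(sample_ids)
        return ReadCountTable(self.counts.loc[ids].copy(), self.meta.loc[ids].copy())

    def drop_otus(self, otu_ids) -> "ReadCountTable":
        drop = set(otu_ids)
        keep = [o for o in self.counts.columns if o not in drop]
        return ReadCountTable(self.counts[keep].copy(), self.meta.copy())

    def copy(self) -> "ReadCountTable":
        return ReadCountTable(self.counts.copy(), self.meta.copy())

    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise FormatError("duplicate sample ids in count table")
        if c.columns.has_duplicates:
            raise FormatError("duplicate OTU ids in count table")
        if c.size and not np.issubdtype(c.to_numpy().dtype, np.integer):
            raise FormatError("counts must be integers")
        if c.size and (c.to_numpy() < 0).any():
            bad = np.argwhere(c.to_numpy() < 0)[0]
            raise FormatError(
                f"negative count at sample {c.index[bad[0]]!r}, OTU {c.columns[bad[1]]!r}"
            )
        missing = set(c.index) - set(self.meta.index)
        if missing:
            raise FormatError(f"samples missing from metadata: {sorted(missing)}")
        self.meta = self.meta.loc[c.index]
        bad_assay = set(self.meta["assay"]) - set(ASSAYS)
        if bad_assay:
            raise FormatError(f"unknown assay labels {sorted(bad_assay)}; allowed: {ASSAYS}")
        neg = self.meta["is_negative_control"].astype(bool)
        rook = self.meta["rookery"].fillna("").astype(str)
        if (neg & (rook != "")).any():
            bad = self.meta.index[neg & (rook != "")][0]
            raise FormatError(f"negative control {bad!r} carries a rookery label")


@dataclass(frozen=True)
class HitRecord:
    """Best database hit for one OTU (BLAST-tabular style plus lineage)."""

    otu_id: str
    best_hit_taxon: str
    percent_identity: float
    e_value: float
    lineage: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise FormatError(
                f"OTU {self.otu_id!r}: percent_identity {self.percent_identity} outside [0, 100]"
            )
        if self.e_value < 0:
            raise FormatError(f"OTU {self.otu_id!r}: negative e-value")
        # lineage must have no gaps below its lowest named rank
        names = [self.lineage.get(r, "") for r in LINEAGE_RANKS]
        seen_named = False
        for name in reversed(names):  # class -> species
            if name:
                seen_named = True
            elif seen_named:
                # gap below a named rank is only allowed at the *most*
                # specific end (e.g. species empty for a genus-level hit)
                break
        # walk from species upward: once a rank is named, all higher must be
        low = 0
        while low < len(names) and not names[low]:
            low += 1
        for i in range(low, len(names)):
            if not names[i]:
                raise FormatError(
                    f"OTU {self.otu_id!r}: lineage gap at rank {LINEAGE_RANKS[i]!r}"
                )


@dataclass(frozen=True)
class TraitRecord:
    """Habitat class and trophic level for one prey taxon."""

    taxon: str
    habitat_class: str
    trophic_level: float

    def __post_init__(self) -> None:
        if self.habitat_class not in HABITAT_CLASSES:
            raise FormatError(
                f"taxon {self.taxon!r}: unknown habitat {self.habitat_class!r}; "
                f"allowed values: {', '.join(HABITAT_CLASSES)}"
            )
        if not 2.0 <= self.trophic_level <= 5.0:
            raise FormatError(
                f"taxon {self.taxon!r}: trophic level {self.trophic_level} outside [2.0, 5.0]"
            )


# ---------------------------------------------------------------------------
# OTU table
# ---------------------------------------------------------------------------

def read_otu_table(path, metadata_path) -> ReadCountTable:
    """Read a TSV OTU table (OTU rows, sample columns) plus sample metadata.

    Raises :class:`FormatError` naming the offending cell on any
    non-integer or negative count, and on samples absent from metadata.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.columns[0] != "otu_id":
        raise FormatError(f"{path}: first column must be 'otu_id', got {raw.columns[0]!r}")
    raw = raw.set_index("otu_id")
    mat = np.empty(raw.shape, dtype=np.int64)
    for j, col in enumerate(raw.columns):
        for i, val in enumerate(raw[col]):
            try:
                iv = int(val)
            except ValueError:
                raise FormatError(
                    f"{path}: non-integer count {val!r} at OTU {raw.index[i]!r}, sample {col!r}"
                ) from None
            if iv < 0:
                raise FormatError(
                    f"{path}: negative count {val!r} at OTU {raw.index[i]!r}, sample {col!r}"
                )
            mat[i, j] = iv
    counts = pd.DataFrame(
        mat.T, index=pd.Index(list(raw.columns), name="sample_id"),
        columns=pd.Index(list(raw.index), name=None),
    )
    meta = read_sample_metadata(metadata_path)
    return ReadCountTable(counts, meta)


def read_sample_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "rookery", "is_negative_control", "assay"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"{path}: metadata missing columns {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    meta = meta.set_index("sample_id")
    if not set(meta["is_negative_control"]) <= {"0", "1"}:
        raise FormatError(f"{path}: is_negative_control must be 0/1")
    meta["is_negative_control"] = meta["is_negative_control"] == "1"
    return meta


def write_otu_table(table: ReadCountTable, path, metadata_path) -> None:
    out = table.counts.T.rename_axis("otu_id")
    out.to_csv(path, sep="\t")
    meta = table.meta.copy()
    meta["is_negative_control"] = meta["is_negative_control"].astype(int)
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path, sep="\t")


# ---------------------------------------------------------------------------
# Hits
# ---------------------------------------------------------------------------

_HIT_COLUMNS = ["otu_id", "taxon", "percent_identity", "e_value", *LINEAGE_RANKS]


def read_hits(path) -> list[HitRecord]:
    """Read best-hit records (tab-separated, one row per OTU).

    Columns: otu_id, taxon, percent_identity, e_value, then lineage ranks
    species..class.  OTUs absent from the file are "no hit" by convention.
    """
    records: list[HitRecord] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected >=4 tab-separated fields")
            otu_id, taxon = parts[0], parts[1]
            if otu_id in seen:
                raise FormatError(f"{path}:{ln}: duplicate otu_id {otu_id!r}")
            seen.add(otu_id)
            try:
                ident = float(parts[2])
                evalue = float(parts[3])
            except ValueError:
                raise FormatError(f"{path}:{ln}: non-numeric identity/e-value") from None
            ranks = parts[4:4 + len(LINEAGE_RANKS)]
            ranks += [""] * (len(LINEAGE_RANKS) - len(ranks))
            lineage = {r: v for r, v in zip(LINEAGE_RANKS, ranks) if v}
            records.append(HitRecord(otu_id, taxon, ident, evalue, lineage))
    return records


def write_hits(hits, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for h in hits:
            row = [h.otu_id, h.best_hit_taxon, repr(h.percent_identity), repr(h.e_value)]
            row += [h.lineage.get(r, "") for r in LINEAGE_RANKS]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Traits and checklist
# ---------------------------------------------------------------------------

def read_traits(path) -> dict[str, TraitRecord]:
    """Read a CSV trait table: taxon,habitat_class,trophic_level."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"taxon", "habitat_class", "trophic_level"}
    if missing := required - set(df.columns):
        raise FormatError(f"{path}: trait table missing columns {sorted(missing)}")
    traits: dict[str, TraitRecord] = {}
    for _, row in df.iterrows():
        rec = TraitRecord(row["taxon"], row["habitat_class"], float(row["trophic_level"]))
        traits[rec.taxon] = rec
    return traits


def write_traits(traits: dict[str, TraitRecord], path) -> None:
    rows = [
        {"taxon": t.taxon, "habitat_class": t.habitat_class, "trophic_level": t.trophic_level}
        for t in traits.values()
    ]
    pd.DataFrame(rows, columns=["taxon", "habitat_class", "trophic_level"]).to_csv(
        path, index=False
    )


class Checklist:
    """Case-insensitive set of taxon names confirmed present in the region."""

    def __init__(self, names) -> None:
        self._names = {str(n).strip() for n in names if str(n).strip()}
        self._folded = {n.casefold() for n in self._names}

    def __contains__(self, name: str) -> bool:
        return str(name).strip().casefold() in self._folded

    def __len__(self) -> int:
        return len(self._folded)

    def __iter__(self):
        return iter(sorted(self._names))


def read_checklist(path) -> Checklist:
    with open(path, encoding="utf-8") as fh:
        return Checklist(line.strip() for line in fh)


def write_checklist(checklist, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(checklist):
            fh.write(name + "\n")


# ---------------------------------------------------------------------------
# Statistic results
# ---------------------------------------------------------------------------

def write_stat_result(result, path) -> None:
    """Serialize a statistic result object (dataclass or dict) to JSON."""
    if hasattr(result, "to_dict"):
        payload = result.to_dict()
    elif hasattr(result, "__dataclass_fields__"):
        from dataclasses import asdict

        payload = asdict(result)
    else:
        payload = dict(result)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="list")
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"cannot serialize {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n", encoding="utf-8")
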