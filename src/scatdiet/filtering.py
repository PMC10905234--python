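"""Decontamination cascade for scat-metabarcoding OTU tables.

Raw tables from diet metabarcoding mix true prey reads with predator
(host) reads, laboratory contaminants, and reads mis-assigned between
samples by tag switching.  The cascade applies, in order:

1. pool the two PCR assay replicates (blocking / no-blocking primer) of
   each scat by summing counts;
2. nullify cells whose within-sample relative abundance falls below a
   tag-switch floor derived from the maximum relative abundance of
   predator OTUs in the negative controls;
3. drop whole OTUs with no database hit, identity below 70%, predator
   (otariid) identity, or an obvious non-marine contaminant identity;
4. negative-control and contaminant-proportion filters: nullify cells
   with counts less than or equal to the same OTU's maximum in the
   controls, then nullify OTUs below each sample's obvious-contaminant
   read proportion;
5. nullify cells below 1% of their sample's reads and drop dataset-wide
   singletons;
6. drop samples with fewer than two prey reads, then samples in the
   lowest quartile of prey reads; negative controls are dropped here.

Every per-sample rule nullifies cells; only OTU-level rules remove
columns.  All-zero columns are dropped at the end.  Each step is monotone
(never increases a count, never adds rows or columns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import HitRecord, ReadCountTable

__all__ = [
    "FilterConfig",
    "FilterReport",
    "pool_assays",
    "compute_tag_switch_floor",
    "nullify_below_floor",
    "screen_otus",
    "control_based_filters",
    "minor_otu_filter",
    "exclude_samples",
    "run_filter_cascade",
    "subset_inferential",
]

#: Default taxa treated as the predator (host) signal.
DEFAULT_PREDATOR_TAXA = (
    "Zalophus wollebaeki",
    "Zalophus californianus",
    "Zalophus",
    "Otariidae",
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and switches of the decontamination cascade.

    ``tag_switch_floor`` and ``quartile_cutoff`` are normally derived from
    the data (controls / retained read totals); supplying them freezes the
    derived values, e.g. to re-apply an identical cascade.
    """

    tag_switch_floor: float | None = None   # derived from controls if None
    min_identity: float = 70.0              # percent identity floor for OTUs
    blacklist: tuple[str, ...] = ()         # obvious non-marine contaminant taxa
    predator_taxa: tuple[str, ...] = DEFAULT_PREDATOR_TAXA
    per_sample_min_fraction: float = 0.01   # minor-OTU within-sample floor
    drop_singletons: bool = True
    min_sample_reads_absolute: int = 2      # "zero or one prey reads" excluded
    lowest_quartile_exclusion: bool = True
    quartile_cutoff: float | None = None    # derived if None
    inferential_min_reads: int = 100
    # interpretation switches for the negative-control filter
    use_control_filters: bool = True        # negative-control cell comparison
    control_stat: str = "max"               # max | sum across controls
    control_scope: str = "cell"             # cell | column
    singleton_definition: str = "reads"     # reads | samples

    def __post_init__(self) -> None:
        if self.tag_switch_floor is not None and not 0 <= self.tag_switch_floor <= 1:
            raise ValueError("tag_switch_floor must be in [0, 1]")
        for name in ("min_identity", "per_sample_min_fraction", "min_sample_reads_absolute",
                     "inferential_min_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.control_stat not in ("max", "sum"):
            raise ValueError("control_stat must be 'max' or 'sum'")
        if self.control_scope not in ("cell", "column"):
            raise ValueError("control_scope must be 'cell' or 'column'")
        if self.singleton_definition not in ("reads", "samples"):
            raise ValueError("singleton_definition must be 'reads' or 'samples'")


@dataclass
class FilterReport:
    """Per-step provenance of the cascade: what was removed and why."""

    steps: list[dict] = field(default_factory=list)
    tag_switch_floor: float | None = None
    quartile_cutoff: float | None = None
    excluded_samples: list[str] = field(default_factory=list)
    otu_removals: dict[str, str] = field(default_factory=dict)  # otu_id -> reason

    def log(self, step: str, **info) -> None:
        self.steps.append({"step": step, **info})

    def to_dict(self) -> dict:
        return {
            "steps": self.steps,
            "tag_switch_floor": self.tag_switch_floor,
            "quartile_cutoff": self.quartile_cutoff,
            "excluded_samples": self.excluded_samples,
            "otu_removals": self.otu_removals,
        }


# ---------------------------------------------------------------------------
# individual steps
# ---------------------------------------------------------------------------

def pool_assays(table: ReadCountTable) -> ReadCountTable:
    """Sum the assay replicates of each scat into one pooled sample.

    Replicates are linked by the metadata column ``scat_id``; when absent,
    a trailing ``.<assay>`` token on the sample id is stripped to recover
    the scat id.  Samples already labelled ``pooled`` pass through.
    """
    meta = table.meta
    if "scat_id" in meta.columns:
        scat = meta["scat_id"].astype(str)
        scat = scat.where(scat != "", meta.index.to_series())
    else:
        def strip(sid: str, assay: str) -> str:
            suffix = "." + assay
            return sid[: -len(suffix)] if assay != "pooled" and sid.endswith(suffix) else sid
        scat = pd.Series(
            [strip(s, a) for s, a in zip(meta.index, meta["assay"])], index=meta.index
        )
    counts = table.counts.groupby(scat, sort=False).sum()
    rows = []
    for sid in counts.index:
        members = meta.loc[scat[scat == sid].index]
        rows.append(
            {
                "rookery": members["rookery"].iloc[0],
                "is_negative_control": bool(members["is_negative_control"].iloc[0]),
                "assay": "pooled",
            }
        )
    new_meta = pd.DataFrame(rows, index=counts.index)
    new_meta.index.name = meta.index.name
    return ReadCountTable(counts, new_meta)


def compute_tag_switch_floor(table: ReadCountTable, predator_otus) -> float:
    """Tag-switch floor: max relative abundance of predator OTUs in controls.

    Returns 0 when the controls contain no predator reads.  Raises when
    the table has no negative controls; supply an explicit floor instead.
    """
    controls = table.negative_controls
    if not controls:
        raise ValueError(
            "table has no negative controls; pass an explicit tag_switch_floor"
        )
    predator = [o for o in predator_otus if o in table.counts.columns]
    best = 0.0
    for sid in controls:
        total = table.counts.loc[sid].sum()
        if total == 0:
            continue
        pred = table.counts.loc[sid, predator].sum() if predator else 0
        best = max(best, pred / total)
    return float(best)


def nullify_below_floor(table: ReadCountTable, floor: float) -> ReadCountTable:
    """Zero every cell whose relative abundance within its sample is < floor.

    Sample totals are computed before any nullification; the comparison is
    strict, so a cell exactly at the floor survives.
    """
    if not 0 <= floor <= 1:
        raise ValueError("floor must be in [0, 1]")
    if floor == 0:
        return table.copy()
    counts = table.counts.to_numpy(dtype=np.int64, copy=True)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.divide(counts, totals, out=np.zeros_like(counts, dtype=float), where=totals > 0)
    counts[rel < floor] = 0
    return ReadCountTable(
        pd.DataFrame(counts, index=table.counts.index, columns=table.counts.columns),
        table.meta.copy(),
    )


def _hit_taxa(hit: HitRecord) -> set[str]:
    taxa = {hit.best_hit_taxon}
    taxa.update(v for v in hit.lineage.values() if v)
    if " " in hit.best_hit_taxon:
        taxa.add(hit.best_hit_taxon.split()[0])
    return taxa


def screen_otus(
    table: ReadCountTable,
    hits,
    config: FilterConfig,
    *,
    apply_blacklist: bool = True,
) -> tuple[ReadCountTable, dict[str, str]]:
    """Drop OTU columns failing identity- or identity-class rules.

    Removal reasons: ``no_hit`` (absent from the hit file), ``low_identity``
    (< ``min_identity``), ``predator`` (otariid match at any lineage rank),
    ``contaminant`` (blacklisted taxon; skipped if *apply_blacklist* is
    false so the contaminant proportions can be used downstream first).
    """
    by_otu = {h.otu_id: h for h in hits}
    predator = {t.casefold() for t in config.predator_taxa}
    blacklist = {t.casefold() for t in config.blacklist}
    removals: dict[str, str] = {}
    for otu in table.counts.columns:
        hit = by_otu.get(otu)
        if hit is None:
            removals[otu] = "no_hit"
            continue
        if hit.percent_identity < config.min_identity:
            removals[otu] = "low_identity"
            continue
        taxa = {t.casefold() for t in _hit_taxa(hit)}
        if taxa & predator:
            removals[otu] = "predator"
        elif apply_blacklist and taxa & blacklist:
            removals[otu] = "contaminant"
    return table.drop_otus(removals), removals


def control_based_filters(
    table: ReadCountTable,
    obvious_contaminant_otus,
    config: FilterConfig = FilterConfig(),
) -> ReadCountTable:
    """Negative-control and contaminant-proportion filtering.

    Step 1: a cell is nullified when its count is less than or equal to
    the same OTU's maximum (or sum, per config) across the negative
    controls.  Step 2: per sample, the proportion ``c`` of reads from the
    obvious contaminant OTUs sets a sample-specific floor; any OTU whose
    within-sample relative abundance is strictly below ``c`` is nullified.
    The contaminant columns are then dropped.
    """
    counts = table.counts.to_numpy(dtype=np.int64, copy=True)
    cols = list(table.counts.columns)
    controls = table.negative_controls
    is_control = table.meta["is_negative_control"].to_numpy(dtype=bool)

    if controls and config.use_control_filters:
        ctrl = table.counts.loc[controls].to_numpy()
        thresh = ctrl.sum(axis=0) if config.control_stat == "sum" else ctrl.max(axis=0)
        if config.control_scope == "column":
            counts[:, (counts[~is_control].max(axis=0) <= thresh) & (thresh > 0)] = 0
        else:
            mask = (counts <= thresh[None, :]) & (thresh[None, :] > 0)
            mask[is_control] = False
            counts[mask] = 0

    contaminant_idx = [i for i, c in enumerate(cols) if c in set(obvious_contaminant_otus)]
    if contaminant_idx:
        totals = counts.sum(axis=1)
        contam = counts[:, contaminant_idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.divide(contam, totals, out=np.zeros(len(totals)), where=totals > 0)
        rel = np.divide(
            counts, totals[:, None], out=np.zeros_like(counts, dtype=float),
            where=totals[:, None] > 0,
        )
        mask = rel < c[:, None]
        mask[is_control] = False
        counts[mask] = 0

    out = pd.DataFrame(counts, index=table.counts.index, columns=cols)
    result = ReadCountTable(out, table.meta.copy())
    if contaminant_idx:
        result = result.drop_otus([cols[i] for i in contaminant_idx])
    return result


def minor_otu_filter(table: ReadCountTable, config: FilterConfig = FilterConfig()) -> ReadCountTable:
    """Nullify cells below the per-sample fraction; drop dataset singletons.

    Fractions are relative to the sample total before nullification; the
    comparison is strict.  A singleton is an OTU with a single read across
    the whole dataset (or present in one sample only, per config).
    """
    counts = table.counts.to_numpy(dtype=np.int64, copy=True)
    totals = counts.sum(axis=1, keepdims=True)
    if config.per_sample_min_fraction > 0:
        rel = np.divide(
            counts, totals, out=np.zeros_like(counts, dtype=float), where=totals > 0
        )
        counts[rel < config.per_sample_min_fraction] = 0
    out = ReadCountTable(
        pd.DataFrame(counts, index=table.counts.index, columns=table.counts.columns),
        table.meta.copy(),
    )
    if config.drop_singletons:
        if config.singleton_definition == "reads":
            single = out.counts.columns[out.counts.sum(axis=0) == 1]
        else:
            single = out.counts.columns[(out.counts > 0).sum(axis=0) == 1]
        out = out.drop_otus(single)
    return out


def exclude_samples(
    table: ReadCountTable, config: FilterConfig = FilterConfig()
) -> tuple[ReadCountTable, list[str], float | None]:
    """Drop low-read samples and the lowest quartile of prey-read totals.

    Negative controls are always dropped here.  Samples with totals below
    ``min_sample_reads_absolute`` go first; the 25th percentile (linear
    interpolation) of the remaining totals is then the cutoff, and samples
    strictly below it are dropped (a sample exactly at the cutoff stays).
    With fewer than four samples the quartile step is skipped.
    """
    excluded = list(table.negative_controls)
    work = table.subset_samples(
        [s for s in table.sample_ids if s not in set(excluded)]
    )
    totals = work.sample_totals()
    low = list(totals.index[totals < config.min_sample_reads_absolute])
    excluded += low
    work = work.subset_samples([s for s in work.sample_ids if s not in set(low)])

    cutoff: float | None = config.quartile_cutoff
    if config.lowest_quartile_exclusion:
        totals = work.sample_totals()
        if cutoff is None:
            if len(totals) < 4:
                warnings.warn("fewer than 4 samples; quartile exclusion skipped", stacklevel=2)
            else:
                cutoff = float(np.percentile(totals.to_numpy(), 25, method="linear"))
        if cutoff is not None:
            below = list(totals.index[totals < cutoff])
            excluded += below
            work = work.subset_samples([s for s in work.sample_ids if s not in set(below)])
    return work, excluded, cutoff


def subset_inferential(table: ReadCountTable, min_reads: int = 100) -> ReadCountTable:
    """Keep samples with at least *min_reads* prey reads (inclusive)."""
    totals = table.sample_totals()
    return table.subset_samples(list(totals.index[totals >= min_reads]))


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

def _drop_empty_otus(table: ReadCountTable) -> tuple[ReadCountTable, list[str]]:
    empty = list(table.counts.columns[table.counts.sum(axis=0) == 0])
    return table.drop_otus(empty), empty


def run_filter_cascade(
    table: ReadCountTable, hits, config: FilterConfig = FilterConfig()
) -> tuple[ReadCountTable, FilterReport]:
    """Apply the full decontamination cascade; return table and report.

    The report records every derived threshold; re-running the cascade on
    its own output with those thresholds frozen into the config leaves the
    table unchanged.
    """
    report = FilterReport()
    by_otu = {h.otu_id: h for h in hits}

    work = pool_assays(table)
    report.log("pool_assays", samples_in=len(table.sample_ids), samples_out=len(work.sample_ids))

    predator_taxa = {t.casefold() for t in config.predator_taxa}
    predator_otus = [
        o for o in work.counts.columns
        if o in by_otu and {t.casefold() for t in _hit_taxa(by_otu[o])} & predator_taxa
    ]
    if config.tag_switch_floor is not None:
        floor = config.tag_switch_floor
    elif work.negative_controls:
        floor = compute_tag_switch_floor(work, predator_otus)
    else:
        floor = 0.0
        report.log("tag_switch_floor", warning="no negative controls; floor defaulted to 0")
    report.tag_switch_floor = floor
    before = int((work.counts.to_numpy() > 0).sum())
    work = nullify_below_floor(work, floor)
    report.log(
        "nullify_below_floor", floor=floor,
        cells_nullified=before - int((work.counts.to_numpy() > 0).sum()),
    )

    blacklist = {t.casefold() for t in config.blacklist}
    contaminant_otus = [
        o for o in work.counts.columns
        if o in by_otu and {t.casefold() for t in _hit_taxa(by_otu[o])} & blacklist
    ]
    # blacklist columns are kept through screening so their read proportions
    # can drive the sample-specific contaminant floor, then dropped there
    work, removals = screen_otus(work, hits, config, apply_blacklist=False)
    for otu in contaminant_otus:
        removals.setdefault(otu, "contaminant")
    report.otu_removals.update(removals)
    report.log(
        "screen_otus",
        removed={r: sum(1 for v in removals.values() if v == r)
                 for r in ("no_hit", "low_identity", "predator", "contaminant")},
    )

    work = control_based_filters(work, contaminant_otus, config)
    report.log("control_based_filters", n_controls=len(work.negative_controls),
               n_contaminant_otus=len(contaminant_otus))

    work = minor_otu_filter(work, config)
    report.log("minor_otu_filter", per_sample_min_fraction=config.per_sample_min_fraction)

    work, excluded, cutoff = exclude_samples(work, config)
    report.quartile_cutoff = cutoff
    report.excluded_samples = excluded
    report.log("exclude_samples", excluded=len(excluded), quartile_cutoff=cutoff)

    work, empty = _drop_empty_otus(work)
    for otu in empty:
        report.otu_removals.setdefault(otu, "all_zero_after_filtering")
    report.log("drop_empty_otus", removed=len(empty),
               otus_out=len(work.otu_ids), samples_out=len(work.sample_ids))
    return work, report


def frozen_config(config: FilterConfig, report: FilterReport) -> FilterConfig:
    """Config with the report's derived thresholds baked in (for re-runs)."""
    return replace(
        config,
        tag_switch_floor=report.tag_switch_floor,
        quartile_cutoff=report.quartile_cutoff,
    )
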