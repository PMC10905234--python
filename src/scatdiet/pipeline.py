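"""End-to-end orchestration: simulate/load -> filter -> assign -> summarize
-> compare, with a machine-readable provenance record.

The provenance JSON captures the verbatim run configuration, the seed,
every derived threshold and the per-stage sample/OTU accounting, so a run
can be re-executed identically from the record alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from . import stats as cstats
from .diet import poo_summary, read_share_summary, richness_summary, to_occurrence
from .filtering import FilterConfig, run_filter_cascade, subset_inferential
from .taxonomy import IdentityBands, assign_all, categorize_prey, collapse_entities

__all__ = ["RunConfig", "run_pipeline"]

ALL_STATS = ("permanova", "permdisp", "nmds", "schoener", "indval")


@dataclass
class RunConfig:
    otu_table: str
    metadata: str
    hits: str
    traits: str
    checklist: str
    out_dir: str
    filter: FilterConfig = field(default_factory=FilterConfig)
    bands: IdentityBands = field(default_factory=IdentityBands)
    statistics: tuple[str, ...] = ALL_STATS
    n_perm: int = 9999
    seed: int | None = None
    inferential_subset: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.statistics) - set(ALL_STATS)
        if unknown:
            raise ValueError(f"unknown statistics {sorted(unknown)}; allowed: {ALL_STATS}")
        needs_seed = set(self.statistics) & {"permanova", "permdisp", "nmds", "indval"}
        if needs_seed and self.seed is None:
            raise ValueError("seed is required when permutation statistics are requested")


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; write outputs under ``config.out_dir``.

    Returns the provenance record (also written as provenance.json).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: dict = {
        "config": {
            **{k: v for k, v in asdict(config).items() if k not in ("filter", "bands")},
            "filter": asdict(config.filter),
            "bands": asdict(config.bands),
        },
        "stages": {},
    }

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"[{stage}] {exc}") from exc

    # ---- load ------------------------------------------------------------
    try:
        table = sio.read_otu_table(config.otu_table, config.metadata)
        hits = sio.read_hits(config.hits)
        traits = sio.read_traits(config.traits)
        checklist = sio.read_checklist(config.checklist)
    except Exception as exc:  # noqa: BLE001
        fail("load", exc)
    provenance["stages"]["load"] = {
        "samples": len(table.sample_ids),
        "otus": len(table.otu_ids),
        "hits": len(hits),
    }

    # ---- filter ----------------------------------------------------------
    try:
        filtered, report = run_filter_cascade(table, hits, config.filter)
    except Exception as exc:  # noqa: BLE001
        fail("filter", exc)
    sio.write_otu_table(filtered, out / "filtered_otu_table.tsv", out / "filtered_metadata.tsv")
    sio.write_stat_result(report.to_dict(), out / "filter_report.json")
    provenance["stages"]["filter"] = {
        "samples_retained": len(filtered.sample_ids),
        "otus_retained": len(filtered.otu_ids),
        "tag_switch_floor": report.tag_switch_floor,
        "quartile_cutoff": report.quartile_cutoff,
    }

    # ---- assign ----------------------------------------------------------
    try:
        retained = set(filtered.otu_ids)
        assignments = assign_all(
            [h for h in hits if h.otu_id in retained], checklist, config.bands
        )
        entities, tally = collapse_entities(assignments)
    except Exception as exc:  # noqa: BLE001
        fail("assign", exc)
    entities.to_csv(out / "entities.csv", index=False)
    name_of = {a.otu_id: a.assigned_name for a in assignments}
    categories = [
        categorize_prey(a.otu_id, traits.get(a.assigned_name)) for a in assignments
    ]
    provenance["stages"]["assign"] = {"entities": len(entities), "rank_tally": tally}

    # ---- summarize -------------------------------------------------------
    try:
        occurrence = to_occurrence(filtered)
        shares = read_share_summary(filtered.counts)
        richness = richness_summary(occurrence)
        poo_items = poo_summary(occurrence, "items")
        poo_habitat = poo_summary(occurrence, "habitat", categories)
        poo_trophic = poo_summary(occurrence, "trophic_bin", categories)
    except Exception as exc:  # noqa: BLE001
        fail("summarize", exc)
    shares.rename("read_share_pct").to_csv(out / "read_shares.csv")
    richness.to_csv(out / "richness.csv")
    for label, profiles in (
        ("items", poo_items), ("habitat", poo_habitat), ("trophic", poo_trophic)
    ):
        pd.DataFrame({rk: p.poo for rk, p in profiles.items()}).fillna(0.0).to_csv(
            out / f"poo_{label}.csv"
        )
    provenance["stages"]["summarize"] = {
        "items": len(occurrence.items),
        "rookeries": occurrence.rookeries(),
    }

    # ---- compare ---------------------------------------------------------
    stats_out: dict = {}
    try:
        inferential = (
            subset_inferential(filtered, config.filter.inferential_min_reads)
            if config.inferential_subset
            else filtered
        )
        occ_inf = to_occurrence(inferential)
        rng = np.random.default_rng(config.seed)

        def next_seed() -> int:
            return int(rng.integers(2**31))

        if set(config.statistics) & {"permanova", "permdisp", "nmds"}:
            dm = cstats.jaccard_distances(occ_inf)
            labels = occ_inf.rookery.to_numpy()
            reads = inferential.sample_totals().to_numpy()
        if "permanova" in config.statistics:
            res = cstats.permanova(
                dm, [("rookery", labels), ("reads", reads)],
                n_perm=config.n_perm, seed=next_seed(),
            )
            sio.write_stat_result(res, out / "permanova.json")
            pw = cstats.pairwise_permanova(dm, labels, n_perm=config.n_perm, seed=next_seed())
            pw.to_csv(out / "pairwise_permanova.csv", index=False)
            stats_out["permanova"] = {
                "F": float(res.terms.loc["rookery", "F"]),
                "R2": float(res.terms.loc["rookery", "R2"]),
                "p": float(res.terms.loc["rookery", "p"]),
            }
        if "permdisp" in config.statistics:
            res = cstats.permdisp(dm, labels, n_perm=config.n_perm, seed=next_seed())
            sio.write_stat_result(res, out / "permdisp.json")
            stats_out["permdisp"] = {"F": res.f_statistic, "p": res.p_value}
        if "nmds" in config.statistics:
            res = cstats.nmds(dm, k=3, seed=next_seed())
            np.savetxt(out / "nmds_coordinates.csv", res.coordinates, delimiter=",")
            stats_out["nmds"] = {"stress": res.stress, "k": res.k}
        if "schoener" in config.statistics:
            profiles = poo_summary(occ_inf, "items")
            rows = []
            rks = list(profiles)
            for i in range(len(rks)):
                for j in range(i + 1, len(rks)):
                    ov = cstats.schoener_overlap(profiles[rks[i]], profiles[rks[j]])
                    rows.append({"rookery_a": ov.rookery_a, "rookery_b": ov.rookery_b,
                                 "schoener_d": ov.schoener_d})
            pd.DataFrame(rows).to_csv(out / "schoener.csv", index=False)
            stats_out["schoener"] = rows
        if "indval" in config.statistics:
            res = cstats.indval(occ_inf, n_perm=config.n_perm, seed=next_seed())
            res.table.to_csv(out / "indval.csv")
            best = res.table.sort_values("indval", ascending=False).head(1)
            stats_out["indval_top"] = best.reset_index().to_dict(orient="records")
    except Exception as exc:  # noqa: BLE001
        fail("compare", exc)
    provenance["stages"]["compare"] = {
        "inferential_samples": len(occ_inf.data),
        "results": stats_out,
    }

    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=2, default=str) + "\n", encoding="utf-8"
    )
    return provenance
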