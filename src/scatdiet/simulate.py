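"""Synthetic scat-metabarcoding experiments with known ground truth.

The generator emulates the structure of a multi-rookery pinniped diet
study: each scat is amplified in two PCR assays (with and without a
predator-blocking primer, the former leaving a larger prey read share),
read counts are multinomial over the predator OTU, the scat's true prey
items and laboratory contaminant OTUs, a small fraction of every OTU's
reads leaks uniformly into other samples (tag switching), and negative
controls carry contaminant reads plus a trace of predator reads.  Prey
compositions are rookery-structured: each rookery has a Dirichlet-drawn
frequency vector over its prey pool, and each scat contains a
zero-truncated-Poisson number of items drawn from that vector.

All randomness flows from a single seed, split into independent streams
per component so that, e.g., adding negative controls does not perturb
the sample draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import HABITAT_CLASSES, Checklist, HitRecord, ReadCountTable, TraitRecord

__all__ = ["SimConfig", "GroundTruth", "simulate_experiment", "simulate_group_shift"]

ROOKERY_NAMES = ("Malecon", "Punta_Pitt", "Santa_Fe", "Floreana", "Espanola")

#: Non-marine taxa used for planted obvious contaminants.
CONTAMINANT_TAXA = (
    ("Homo sapiens", "Homo", "Hominidae", "Primates", "Mammalia"),
    ("Sus scrofa", "Sus", "Suidae", "Artiodactyla", "Mammalia"),
    ("Gallus gallus", "Gallus", "Phasianidae", "Galliformes", "Aves"),
    ("Bos taurus", "Bos", "Bovidae", "Artiodactyla", "Mammalia"),
    ("Rattus rattus", "Rattus", "Muridae", "Rodentia", "Mammalia"),
    ("Canis familiaris", "Canis", "Canidae", "Carnivora", "Mammalia"),
)

PREDATOR_OTU = "OTU_predator"
PREDATOR_TAXON = "Zalophus wollebaeki"


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped defaults: five rookeries, two assays per scat.

    ``samples_per_rookery`` mirrors the number of scats extracted per
    rookery in a field campaign of this design; read depths are
    log-uniform over ``reads_per_sample_range`` (right-skewed totals);
    ``predator_read_fraction`` must not be larger in the blocking assay
    than in the no-blocking assay.
    """

    n_rookeries: int = 5
    samples_per_rookery: tuple[int, ...] = (60, 32, 30, 30, 30)
    n_negative_controls: int = 8
    global_prey_pool: int = 90
    prey_pool_size: int = 45            # per-rookery subset of the global pool
    dirichlet_concentration: float = 0.4
    mean_items_per_sample: float = 2.7
    reads_per_sample_range: tuple[int, int] = (100, 30000)
    predator_read_fraction: dict = field(
        default_factory=lambda: {"blocking": 0.70, "no_blocking": 0.95}
    )
    tag_switch_rate: float = 0.001
    n_contaminant_otus: int = 6
    contaminant_read_fraction: float = 0.02
    control_predator_fraction: float = 0.0005
    n_low_identity_otus: int = 3
    n_no_hit_otus: int = 2
    frac_species_confirmed: float = 0.59   # identity >= 96, on checklist
    frac_species_unconfirmed: float = 0.22 # identity >= 96, not on checklist
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.samples_per_rookery) != self.n_rookeries:
            raise ValueError("samples_per_rookery length must equal n_rookeries")
        for name in ("tag_switch_rate", "contaminant_read_fraction",
                     "control_predator_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        pf = self.predator_read_fraction
        if not 0 <= pf["blocking"] <= pf["no_blocking"] <= 1:
            raise ValueError(
                "predator_read_fraction must satisfy 0 <= blocking <= no_blocking <= 1"
            )
        if self.mean_items_per_sample > self.prey_pool_size:
            raise ValueError("mean_items_per_sample exceeds the per-rookery prey pool")
        if self.prey_pool_size > self.global_prey_pool:
            raise ValueError("prey_pool_size exceeds the global prey pool")


@dataclass
class GroundTruth:
    """What the generator actually put into the tables.

    ``occurrence`` records realized occurrences (items that received at
    least one read in a scat's pooled assays, before tag switching): an
    intended item that drew zero reads is not recoverable by any filter
    and is therefore not part of the recoverable truth.
    """

    occurrence: pd.DataFrame            # scats x prey OTUs, binary
    rookery: pd.Series                  # per scat
    predator_otus: set[str]
    contaminant_otus: set[str]          # obvious (non-marine) contaminants
    junk_otus: set[str]                 # planted low-identity / no-hit OTUs
    rookery_frequencies: dict[str, pd.Series]


def _zt_poisson_rate(mean: float) -> float:
    """Rate lambda with zero-truncated-Poisson mean lambda/(1-exp(-lambda))."""
    if mean <= 1.0:
        raise ValueError("zero-truncated Poisson mean must exceed 1")
    lam = mean
    for _ in range(100):
        lam = mean * (1.0 - np.exp(-lam))
    return lam


def _sample_zt_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    out = np.zeros(size, dtype=np.int64)
    todo = np.arange(size)
    while todo.size:
        draw = rng.poisson(lam, size=todo.size)
        ok = draw > 0
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _prey_names(n: int) -> list[tuple[str, ...]]:
    """Synthetic marine lineages: species, genus, family, order, class."""
    lineages = []
    for i in range(n):
        genus = f"Pseudogenus{i:03d}"
        lineages.append(
            (
                f"{genus} speciosus",
                genus,
                f"Family{i // 3:02d}idae",
                f"Order{i // 9:02d}iformes",
                "Actinopterygii",
            )
        )
    return lineages


def simulate_experiment(config: SimConfig):
    """Generate (table, ground_truth, hits, traits, checklist).

    The emitted hit file covers prey OTUs (identities spanning the
    species/genus/family/order assignment bands), the predator OTU,
    obvious non-marine contaminants, planted low-identity (< 70%) OTUs
    and planted no-hit OTUs, so every branch of the screening rules is
    exercised by default.
    """
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(6)
    rng_pool, rng_samples, rng_controls, rng_switch, rng_hits, _ = (
        np.random.default_rng(s) for s in streams
    )

    n_prey = config.global_prey_pool
    prey_otus = [f"OTU_{i:03d}" for i in range(1, n_prey + 1)]
    lineages = _prey_names(n_prey)

    contaminant_otus = [f"OTU_C{i:02d}" for i in range(config.n_contaminant_otus)]
    low_id_otus = [f"OTU_L{i:02d}" for i in range(config.n_low_identity_otus)]
    no_hit_otus = [f"OTU_N{i:02d}" for i in range(config.n_no_hit_otus)]
    junk = low_id_otus + no_hit_otus
    all_otus = [PREDATOR_OTU] + prey_otus + contaminant_otus + junk

    # rookery prey pools and frequency vectors
    rookeries = ROOKERY_NAMES[: config.n_rookeries] if config.n_rookeries <= len(
        ROOKERY_NAMES
    ) else tuple(f"Rookery_{i}" for i in range(config.n_rookeries))
    freq: dict[str, pd.Series] = {}
    pools: dict[str, np.ndarray] = {}
    for rk in rookeries:
        pool = rng_pool.choice(n_prey, size=config.prey_pool_size, replace=False)
        w = rng_pool.dirichlet(np.full(config.prey_pool_size, config.dirichlet_concentration))
        pools[rk] = pool
        freq[rk] = pd.Series(w, index=[prey_otus[i] for i in pool])

    lam = _zt_poisson_rate(config.mean_items_per_sample)
    lo, hi = config.reads_per_sample_range

    scat_ids: list[str] = []
    scat_rookery: list[str] = []
    sample_rows: list[np.ndarray] = []
    sample_meta: list[dict] = []
    occ = []

    otu_index = {o: i for i, o in enumerate(all_otus)}
    contam_frac = config.contaminant_read_fraction

    for rk, n_scats in zip(rookeries, config.samples_per_rookery):
        pool = pools[rk]
        w = freq[rk].to_numpy()
        k_items = _sample_zt_poisson(rng_samples, lam, n_scats)
        for s in range(n_scats):
            scat = f"{rk}_S{s:03d}"
            k = min(int(k_items[s]), config.prey_pool_size)
            chosen = rng_samples.choice(pool, size=k, replace=False, p=w)
            item_props = rng_samples.dirichlet(np.ones(k))
            pooled_prey = np.zeros(len(all_otus), dtype=np.int64)
            for assay in ("blocking", "no_blocking"):
                depth = int(np.exp(rng_samples.uniform(np.log(lo), np.log(hi))))
                p_pred = config.predator_read_fraction[assay]
                p_prey = max(0.0, 1.0 - p_pred - contam_frac)
                probs = np.zeros(len(all_otus))
                probs[otu_index[PREDATOR_OTU]] = p_pred
                for otu_i, prop in zip(chosen, item_props):
                    probs[otu_index[prey_otus[otu_i]]] = p_prey * prop
                if contam_frac > 0:
                    share = contam_frac / len(contaminant_otus + junk)
                    for o in contaminant_otus + junk:
                        probs[otu_index[o]] = share
                probs /= probs.sum()
                reads = rng_samples.multinomial(depth, probs)
                pooled_prey += reads
                sample_rows.append(reads)
                sample_meta.append(
                    {
                        "sample_id": f"{scat}.{assay}",
                        "rookery": rk,
                        "is_negative_control": False,
                        "assay": assay,
                        "scat_id": scat,
                    }
                )
            scat_ids.append(scat)
            scat_rookery.append(rk)
            row = np.zeros(n_prey, dtype=np.int64)
            for otu_i in chosen:
                if pooled_prey[otu_index[prey_otus[otu_i]]] > 0:
                    row[otu_i] = 1
            occ.append(row)

    # negative controls: contaminant reads plus a trace of predator reads
    for c in range(config.n_negative_controls):
        cid = f"NC_{c:02d}"
        if contam_frac == 0 and config.control_predator_fraction == 0:
            reads = np.zeros(len(all_otus), dtype=np.int64)
        else:
            depth = int(np.exp(rng_controls.uniform(np.log(2000), np.log(20000))))
            probs = np.zeros(len(all_otus))
            p_pred = rng_controls.uniform(0, config.control_predator_fraction)
            probs[otu_index[PREDATOR_OTU]] = p_pred
            targets = contaminant_otus if contaminant_otus else junk
            if targets and contam_frac > 0:
                for o in targets:
                    probs[otu_index[o]] = (1.0 - p_pred) / len(targets)
            if probs.sum() == 0:
                reads = np.zeros(len(all_otus), dtype=np.int64)
            else:
                probs /= probs.sum()
                reads = rng_controls.multinomial(depth, probs)
        sample_rows.append(reads)
        sample_meta.append(
            {
                "sample_id": cid,
                "rookery": "",
                "is_negative_control": True,
                "assay": "pooled",
                "scat_id": cid,
            }
        )

    counts = np.stack(sample_rows)

    # tag switching: each read leaks to a uniform random other sample with
    # probability tag_switch_rate; per-OTU totals are conserved
    if config.tag_switch_rate > 0:
        n_samples = counts.shape[0]
        for j in range(counts.shape[1]):
            col = counts[:, j]
            leaks = rng_switch.binomial(col, config.tag_switch_rate)
            if leaks.sum() == 0:
                continue
            col -= leaks
            for src in np.flatnonzero(leaks):
                dest = rng_switch.integers(0, n_samples - 1, size=leaks[src])
                dest[dest >= src] += 1
                np.add.at(col, dest, 1)
            counts[:, j] = col

    meta = pd.DataFrame(sample_meta).set_index("sample_id")
    table = ReadCountTable(
        pd.DataFrame(counts, index=meta.index, columns=all_otus), meta
    )

    # hits, traits, checklist ------------------------------------------------
    hits: list[HitRecord] = []
    checklist_names: list[str] = []
    traits: dict[str, TraitRecord] = {}
    n_conf = int(round(config.frac_species_confirmed * n_prey))
    n_unconf = int(round(config.frac_species_unconfirmed * n_prey))
    shuffled = rng_hits.permutation(n_prey)
    band = {}
    for pos, i in enumerate(shuffled):
        if pos < n_conf:
            band[i] = "species"
        elif pos < n_conf + n_unconf:
            band[i] = "species_unconfirmed"
        else:
            band[i] = ("genus", "family", "order")[pos % 3]
    for i, otu in enumerate(prey_otus):
        sp, genus, *_ = lineages[i]
        kind = band[i]
        if kind == "species":
            ident = rng_hits.uniform(96.0, 100.0)
            checklist_names.append(sp)
        elif kind == "species_unconfirmed":
            ident = rng_hits.uniform(96.0, 100.0)
        elif kind == "genus":
            ident = rng_hits.uniform(92.0, 95.9)
        elif kind == "family":
            ident = rng_hits.uniform(85.0, 91.9)
        else:
            ident = rng_hits.uniform(70.0, 84.9)
        hits.append(
            HitRecord(otu, sp, round(float(ident), 1), 1e-60,
                      dict(zip(("species", "genus", "family", "order", "class"),
                               lineages[i]))),
        )
        habitat = HABITAT_CLASSES[rng_hits.integers(len(HABITAT_CLASSES))]
        trophic = round(float(rng_hits.uniform(2.0, 4.5)), 1)
        for taxon in {sp, genus}:
            traits[taxon] = TraitRecord(taxon, habitat, trophic)
    hits.append(
        HitRecord(PREDATOR_OTU, PREDATOR_TAXON, 99.6, 1e-80,
                  {"species": PREDATOR_TAXON, "genus": "Zalophus",
                   "family": "Otariidae", "order": "Carnivora", "class": "Mammalia"})
    )
    for otu, lineage in zip(contaminant_otus, CONTAMINANT_TAXA):
        hits.append(
            HitRecord(otu, lineage[0], round(float(rng_hits.uniform(97, 100)), 1), 1e-70,
                      dict(zip(("species", "genus", "family", "order", "class"), lineage)))
        )
    for otu in low_id_otus:
        hits.append(HitRecord(otu, "Incertae sedis", round(float(rng_hits.uniform(40, 69.9)), 1),
                              1e-5, {"class": "Actinopterygii"}))
    # no-hit OTUs are simply absent from the hit list

    checklist_names.append("Octopus oculifer")  # regional name not in the prey pool
    checklist = Checklist(checklist_names)

    truth = GroundTruth(
        occurrence=pd.DataFrame(np.stack(occ) if occ else np.zeros((0, n_prey), int),
                                index=scat_ids, columns=prey_otus),
        rookery=pd.Series(scat_rookery, index=scat_ids),
        predator_otus={PREDATOR_OTU},
        contaminant_otus=set(contaminant_otus),
        junk_otus=set(junk),
        rookery_frequencies=freq,
    )
    return table, truth, hits, traits, checklist


def simulate_group_shift(
    n_groups: int = 4,
    samples_per_group: int = 10,
    n_items: int = 30,
    mean_items_per_sample: float = 2.7,
    effect_size: float = 0.0,
    dirichlet_concentration: float = 0.7,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Binary occurrence matrix with a controllable between-group signal.

    All groups share one item-frequency vector; the last group's vector is
    mixed with an independent draw in proportion *effect_size*, so
    ``effect_size = 0`` yields exchangeable groups (a null dataset) and
    large values yield a strong compositional shift.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    rng = np.random.default_rng(seed)
    base = rng.dirichlet(np.full(n_items, dirichlet_concentration))
    alt = rng.dirichlet(np.full(n_items, dirichlet_concentration))
    shifted = (1 - min(effect_size, 1.0)) * base + min(effect_size, 1.0) * alt
    shifted /= shifted.sum()
    lam = _zt_poisson_rate(mean_items_per_sample)

    rows = []
    labels = []
    for gi in range(n_groups):
        w = shifted if gi == n_groups - 1 else base
        ks = _sample_zt_poisson(rng, lam, samples_per_group)
        for k in ks:
            k = min(int(k), n_items)
            chosen = rng.choice(n_items, size=k, replace=False, p=w)
            row = np.zeros(n_items, dtype=int)
            row[chosen] = 1
            rows.append(row)
            labels.append(f"G{gi}")
    data = pd.DataFrame(
        np.stack(rows),
        index=[f"s{i:03d}" for i in range(len(rows))],
        columns=[f"item_{j:02d}" for j in range(n_items)],
    )
    return data, np.asarray(labels)
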