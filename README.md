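# scatdiet

Diet analysis from scat DNA-metabarcoding for pinniped colony studies —
built around the Galapagos sea lion (*Zalophus wollebaeki*) rookery
system, but applicable to any multi-colony predator diet survey that
produces an OTU × sample read-count table.

Metabarcoding a predator's scats yields a noisy mixture: predator (host)
reads dominate, laboratory contaminants and tag-switching mis-assignments
plant false prey occurrences, and sequencing depth varies by orders of
magnitude between samples. `scatdiet` takes the table that comes out of a
standard clustering workflow (VSEARCH-style OTUs at 97% similarity, with
BLAST best hits) and carries it to defensible ecological conclusions:

1. **Decontamination cascade** (`scatdiet.filtering`) — pool the
   blocking/no-blocking PCR assay replicates of each scat; nullify cells
   below a tag-switch floor derived from the maximum relative abundance
   of predator OTUs in the negative controls; drop no-hit, low-identity
   (< 70%), predator and non-marine contaminant OTUs; apply
   negative-control and per-sample contaminant-proportion filters; drop
   sub-1% cells and dataset singletons; exclude samples with < 2 prey
   reads and the lowest quartile of prey-read totals.
2. **Taxonomy** (`scatdiet.taxonomy`) — species assignment for hits with
   identity ≥ 96% confirmed against a regional checklist, identity bands
   (≥ 92 genus, ≥ 85 family, else order) below that; OTUs collapse into
   unique taxonomic entities; prey get habitat classes and half-unit
   trophic-level bins.
3. **Diet summaries** (`scatdiet.diet`) — presence/absence occurrence
   matrix; frequency of occurrence FOO_i and percent of occurrence
   POO_i = 100·FOO_i/Σ_j FOO_j per rookery (items, habitats, trophic
   bins); richness; exact sample-based and read-based rarefaction with
   hypergeometric variances: E[S_n] = Σ_i [1 − C(N−f_i, n)/C(N, n)].
4. **Community statistics** (`scatdiet.stats`) — Jaccard distances;
   PERMANOVA with sequential (type-I) sums of squares on the
   Gower-centered distance matrix (pseudo-F, R², whole-row permutation
   p); pairwise PERMANOVA with Holm correction; PERMDISP (distances to
   group centroids in a PCoA embedding keeping negative-eigenvalue axes,
   z = √(d₊² − d₋²)); non-metric MDS minimizing Kruskal stress-1 with
   isotonic (PAVA) fits; Schoener overlap D = 1 − ½Σ|p_x − p_y|; IndVal
   = √(A·B) over site-group combinations; Spearman/Kruskal–Wallis/paired
   Wilcoxon wrappers and Holm adjustment.
5. **Synthetic experiments** (`scatdiet.simulate`) — a generator that
   emulates the study design (five rookeries, two assays per scat,
   Dirichlet rookery diets, zero-truncated-Poisson items per scat,
   planted contaminants, tag-switch leakage, negative controls) with
   known ground truth, so every filter branch and statistic is testable
   without sequencing data.

## Worked example

```python
from scatdiet.simulate import SimConfig, simulate_experiment, CONTAMINANT_TAXA
from scatdiet.filtering import FilterConfig, run_filter_cascade, subset_inferential
from scatdiet.diet import to_occurrence, richness_summary
from scatdiet.stats import jaccard_distances, permanova

table, truth, hits, traits, checklist = simulate_experiment(SimConfig(seed=1))
cfg = FilterConfig(blacklist=tuple(t[0] for t in CONTAMINANT_TAXA))
filtered, report = run_filter_cascade(table, hits, cfg)
print(len(filtered.sample_ids), round(report.tag_switch_floor, 6))
# 136 0.001256

occ = to_occurrence(subset_inferential(filtered))
print(richness_summary(occ)["mean_per_sample"].round(2).to_dict())
# {'Malecon': 2.88, 'Punta_Pitt': 2.38, 'Santa_Fe': 3.21, 'Floreana': 2.33, 'Espanola': 3.0}

res = permanova(jaccard_distances(occ),
                [("rookery", occ.rookery.to_numpy())], n_perm=999, seed=1)
print(res.terms.round(3))
#          df    SS      F     R2      p
# term
# rookery   4  8.35  4.952  0.131  0.001
```

182 simulated scats enter; the cascade retains 136 with a tag-switch
floor of ≈ 0.13% derived from the controls. On the inferential subset
the rookery factor explains ~13% of the Jaccard-distance variation and
is highly significant — the generator plants rookery-structured diets,
and the pipeline recovers them.

The same stages are scriptable:

```bash
scatdiet simulate --seed 1 --out sim/
scatdiet filter --otu-table sim/otu_table.tsv --meta sim/metadata.tsv \
    --hits sim/hits.tsv --out filt/
scatdiet assign --hits sim/hits.tsv --checklist sim/checklist.txt \
    --out assignments.csv
```

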