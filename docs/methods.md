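# Methods

This note documents the statistical procedures, the defaults and the
design choices behind `scatdiet`, and states what the synthetic-data
tests do and do not demonstrate about real sequencing data.

## The decontamination cascade

The cascade turns a raw OTU × sample read-count table — predator reads,
prey reads, contaminants and cross-sample leakage mixed together — into
a prey occurrence matrix. Steps run in a fixed order; every per-sample
rule *nullifies* cells (sets them to zero) while OTU-level rules remove
whole columns, and columns left all-zero are dropped at the end. Each
step is monotone: no count ever increases, no row or column is added.

1. **Assay pooling.** The blocking-primer and plain PCR replicates of a
   scat are summed before any threshold is applied, so thresholds see
   the scat's full read support. (Whether the tag-switch floor should
   precede pooling is not determinable from the source material; applied
   after pooling here, and the step order is fixed in code so a variant
   cascade can be composed from the step functions.)
2. **Tag-switch floor.** Index hopping moves a small fraction of reads
   between samples. Since negative controls contain no genuine predator
   DNA, the maximum relative abundance of predator OTUs across controls
   estimates the leakage ceiling; cells below that relative abundance
   (strict `<`) are nullified. Controls without predator reads give a
   floor of 0. A cascade run on a table without controls (e.g. its own
   output) uses floor 0 with a logged warning; `compute_tag_switch_floor`
   itself refuses such tables so interactive misuse fails loudly.
3. **OTU screening.** Removed outright: OTUs with no database hit,
   identity < 70%, otariid (predator) matches at any lineage rank, and
   blacklisted non-marine taxa. The comparison `identity < 70` is
   strict: 70.0 survives.
4. **Control-based filters.** (a) A cell is nullified when its count is
   less than *or equal to* the same OTU's maximum across negative
   controls — a per-cell reading of the "equal or fewer reads than the
   controls" rule; the aggregation (`max`/`sum`) and scope
   (`cell`/`column`) are config switches, per-cell max being the
   conservative default. (b) Per sample, the proportion *c* of reads
   from blacklisted contaminant OTUs sets a sample-specific floor: any
   OTU with within-sample relative abundance < *c* is nullified, and the
   contaminant columns are then dropped. To make (b) computable, the
   cascade defers blacklist-column removal from step 3 to step 4; a
   standalone `screen_otus` call still removes them.
5. **Minor OTUs.** Cells under 1% of their sample total (strict, totals
   taken before nullification) are nullified; then dataset singletons —
   OTUs with one read in the whole dataset (alternative definition
   "present in one sample" behind a switch) — are removed.
6. **Sample exclusion.** Negative controls are dropped; samples with
   fewer than 2 prey reads are dropped; the 25th percentile (linear
   interpolation) of the remaining totals is the quartile cutoff and
   samples strictly below it are dropped — a sample exactly at the
   cutoff stays. With fewer than four samples the quartile step is
   skipped with a warning.

**Idempotence.** Re-running the cascade must not remove anything
further. Two thresholds are data-derived (the tag-switch floor and the
quartile cutoff) and would be re-derived differently on the filtered
output — the floor needs the dropped controls, and the quartile of the
retained totals is higher than the original cutoff. The `FilterReport`
therefore records both derived values, and `frozen_config()` bakes them
into a config for exact re-application; the idempotence tests use this.

The inferential subset keeps samples with ≥ 100 prey reads (inclusive);
it is a separate operation, not a cascade step, because descriptive
summaries use the full filtered table.

## Taxonomy assignment

Hits with identity ≥ 96% are assigned to the best-hit species *if* the
species is on the regional checklist (case-insensitive binomial match;
synonyms are out of scope); an unconfirmed species escalates to genus.
Below 96%, configurable identity bands assign genus (≥ 92), family
(≥ 85) or order. The bands replace interactive tree-based placement of
low-identity hits: they are reproducible offline, but rank labels for
low-identity OTUs can differ from what a phylogenetic placement would
give — this is a documented divergence, not an approximation claim.
Trophic levels are binned into five half-unit categories closed at both
printed endpoints (2.0–2.5 … 4.1–4.5); values in the one-decimal gaps
between bins (e.g. 2.55) go to the nearest bin, ties upward, because
the printed bins clearly intend a partition of one-decimal levels.
Guild is planktivore for bins at or below 3.0, carnivore above.

## Diet summaries

FOO_i is the fraction of a rookery's samples containing item *i*; POO
rescales the FOO vector to sum to 100% per rookery. Category POO treats
a sample as containing a habitat/trophic category when it contains any
item of that category; uncategorized items (no trait record) are
excluded from category summaries but kept in item summaries.

Sample-based rarefaction is exact under drawing *n* of *N* samples
without replacement: E[S_n] = Σ_i [1 − C(N−f_i, n)/C(N, n)]. The
variance uses the exact joint-absence probabilities
P(i and j both absent) = C(N−|A_i ∪ A_j|, n)/C(N, n) computed from the
observed joint incidences, so it matches exhaustive subset enumeration
to machine precision (tested). The 95% CI is E ± 1.96·sd — a normal
approximation chosen because the study-style outputs report symmetric
intervals. Read-based rarefaction applies the same hypergeometric logic
to rookery-pooled per-OTU read counts and reports the smallest depth at
which the estimate's coefficient of variation reaches 0.05 (the
"curve has stabilized" criterion).

## Community statistics

All permutation tests use p = (1 + b)/(1 + m), which cannot return 0.

**PERMANOVA.** The distance matrix is Gower-centered
(G = −½·J·D²·J). Terms enter in user order; each term's sum of squares
is tr[(H_j − H_{j−1})·G] with H_j the hat matrix of the cumulative
design (factors dummy-coded, covariates centered), giving sequential
type-I decomposition: ΣSS_terms + SS_residual = SS_total exactly, and
with Euclidean distances on raw data the single-factor case reduces to
classical one-way ANOVA (tested against the closed form). Significance
permutes whole rows/columns of G; per-permutation statistics reuse the
fixed projection matrices, so the 500-replicate type-I calibration runs
in seconds. A rank-deficient added term raises, naming the term.

**PERMDISP.** The centered matrix is eigendecomposed keeping both
positive- and negative-eigenvalue axes (Jaccard distances are not
Euclidean-embeddable in general); the dispersion of sample *i* is
z_i = √(d₊² − d₋²) to its group centroid, negative radicands clamped to
zero with a diagnostic count. A one-way ANOVA F on z is tested by
permuting group labels; pairwise comparisons use Tukey HSD on z, then
Holm. On Euclidean inputs z equals the direct point-to-centroid
distance and the F statistic matches scikit-bio's centroid-based
implementation (both tested).

**NMDS.** Kruskal stress-1,
√(Σ(d̂−θ)²/Σd̂²), minimized by nonmetric SMACOF: isotonic
(pool-adjacent-violators) disparities θ with the primary approach to
ties (within tied dissimilarities, configuration distances are
pre-sorted so the monotone fit constrains them least), disparities
rescaled to the configuration's norm, Guttman-transform updates.
Defaults: 20 starts (one principal-coordinate initialization plus
random starts), 300 iterations, convergence at |Δstress| < 1e-7. On
distances generated from a true k-dimensional configuration the PCoA
start recovers stress < 1e-3 immediately (tested); on sparse binary
data the stress tail converges slowly and a non-converged best-so-far
result is returned with a warning rather than an error.

**Schoener overlap.** D = 1 − ½Σ|p_x − p_y| over the union of items,
with POO vectors renormalized to proportions. POO-based proportions are
the default input (FOO-based profiles can be passed explicitly — the
two differ only by the per-rookery rescaling, which cancels for items
but matters when profiles were built over different item sets).

**IndVal.** For each item and each union C of 1..K−1 site groups:
specificity A = x̄_C/(x̄_C + Σ_{g∉C} x̄_g) with x̄_C the unweighted mean
of the per-group mean occurrences in C (so group sizes do not bias A),
fidelity B = occupied sites in C / sites in C, IndVal = √(A·B). The
best combination per item is reported; significance permutes site
labels with each item's max-over-combinations IndVal as the statistic.
Group-size-weighted A variants exist in the literature; the unweighted
form is the deliberate default here and is flagged in the API docs.

**Univariate tests.** Spearman's rho uses midranks; its p-value is
exact by enumeration for n ≤ 8 without ties (matching exact-table
values such as p = 0.45 for rho = 0.5 at n = 5) and the t-approximation
with ties or larger n (reproducing the conventional tie-handling of
standard implementations). Kruskal–Wallis (tie-corrected, χ² p) and the
paired Wilcoxon (zeros dropped, exact for n ≤ 25 without ties) wrap
scipy. Holm adjustment is the step-down rule with monotonicity
enforcement, implemented directly.

## The synthetic generator

Defaults describe a five-rookery field campaign: 60/32/30/30/30 scats
per rookery, each amplified in two assays; predator read fractions 0.70
(blocking) and 0.95 (no blocking), so blocking assays carry more prey
reads; per-assay depths log-uniform on [100, 30000] (right-skewed totals
with a geometric mean near 1700, matching the order of magnitude of
typical MiSeq diet libraries); per-scat item counts zero-truncated
Poisson with mean 2.7 (the sparsest simple model matching a mean ≈ 2.7
with median 2); rookery diets are Dirichlet(0.4) over 45-taxon subsets
of a 90-taxon pool; 2% contaminant reads over six non-marine taxa;
tag-switch rate 0.001 per read (uniform misassignment across samples,
conserving per-OTU totals); eight negative controls with contaminant
reads and a predator fraction up to 5·10⁻⁴ — which makes the derived
tag-switch floor land near the 10⁻³ order. Planted low-identity and
no-hit OTUs exercise every screening branch. All randomness derives
from one seed through independent spawned streams, so adding controls
does not perturb sample draws.

Ground truth records *realized* occurrences — items that received at
least one read in the scat's pooled assays before tag switching. An
intended item that drew zero reads is invisible to any downstream
method, so recovery is defined against what was sequenced, not what was
intended.

What the generator does **not** emulate: sequence-level errors,
chimeras, PCR amplification bias beyond the two assay fractions,
phylogenetically structured misassignment, or correlated contamination
between samples processed in the same batch. Passing the recovery tests
therefore shows the cascade implements its rules correctly and
un-mixes this noise model; it does not certify performance against
every real-world contamination mode.

`simulate_group_shift` produces binary matrices with a controllable
compositional shift in one group (effect 0 ⇒ exchangeable groups). It
backs two calibration checks: the PERMANOVA type-I error over 500 null
datasets at 199 permutations must lie within two Monte-Carlo standard
errors of 5%, and a fully shifted group in a well-powered two-group
design (25 samples/group, ~4 items/sample) must reach p ≤ 0.001 in at
least 95% of replicates. Replicate counts and permutation numbers were
sized to give informative Monte-Carlo error at desk-scale cost.

## Numerical choices and degenerate inputs

- Binomial-coefficient ratios in rarefaction run through log-gamma.
- Jaccard is undefined for an all-zero sample; such rows raise with the
  sample named (they cannot occur after the cascade, which drops
  sub-2-read samples).
- PERMANOVA with zero residual SS (all within-group distances zero)
  yields an effectively infinite F; permutation p remains valid.
- PERMDISP clamps negative radicands (strong non-Euclidean distortion)
  to zero and counts them in the result.
- All text I/O is UTF-8 with "." decimals; files store OTUs as rows
  (upstream-tool convention), memory is samples × OTUs.

## Known limitations

- Published inferential values tied to the study's deposited per-sample
  matrix (its PERMANOVA F, PERMDISP F, Schoener and IndVal tables) are
  not recomputable without that dataset; the package validates those
  estimators against closed forms, exhaustive enumeration and an
  independent implementation instead.
- The identity-band taxonomy is a stand-in for tree-based placement of
  sub-96% hits; rank labels for such OTUs are band-dependent.
- Checklist matching ignores synonymy and authorship; names must match
  at the binomial level.
- The PERMDISP permutation test shuffles dispersion values among groups
  (label permutation); bias-adjusted variants are not implemented.
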