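"""Descriptive diet statistics: occurrence, POO, richness, rarefaction.

Occurrence data are binary (a prey item was or was not detected in a
scat); frequencies of occurrence (FOO) are per-rookery detection
fractions, and the percent of occurrence (POO) rescales the FOOs so the
items of a rookery sum to 100%.  Rarefaction is computed exactly under
sampling without replacement: sample-based (incidence) rarefaction for
richness standardized to a common number of scats, and read-based
(individual) rarefaction on rookery-pooled read counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import ReadCountTable
from .taxonomy import CategoryAssignment

__all__ = [
    "OccurrenceMatrix",
    "DietProfile",
    "RarefactionEstimate",
    "to_occurrence",
    "read_share_summary",
    "poo_summary",
    "richness_summary",
    "rarefy_samples",
    "rarefy_reads",
]


@dataclass
class OccurrenceMatrix:
    """Binary samples x prey-items matrix with per-sample rookery labels."""

    data: pd.DataFrame          # 0/1 ints, index = sample ids
    rookery: pd.Series          # aligned with data.index

    def __post_init__(self) -> None:
        vals = set(np.unique(self.data.to_numpy())) if self.data.size else set()
        if not vals <= {0, 1}:
            raise ValueError("occurrence matrix must be binary")
        self.rookery = self.rookery.loc[self.data.index]

    @property
    def items(self) -> list[str]:
        return list(self.data.columns)

    def rookeries(self) -> list[str]:
        return list(pd.unique(self.rookery))

    def subset_rookery(self, rookery: str) -> pd.DataFrame:
        return self.data.loc[self.rookery == rookery]


@dataclass
class DietProfile:
    """Per-rookery FOO (proportion) and POO (%) vectors over items."""

    rookery: str
    foo: pd.Series
    poo: pd.Series

    def proportions(self) -> pd.Series:
        """POO renormalized to proportions summing to 1."""
        total = self.poo.sum()
        if total == 0:
            return self.poo * 0.0
        return self.poo / total


@dataclass(frozen=True)
class RarefactionEstimate:
    n: int
    expected_richness: float
    variance: float
    ci_low: float
    ci_high: float


def to_occurrence(table: ReadCountTable) -> OccurrenceMatrix:
    """Binarize a filtered read-count table; all-zero items are dropped."""
    binary = (table.counts > 0).astype(int)
    binary = binary.loc[:, binary.sum(axis=0) > 0]
    return OccurrenceMatrix(binary, table.meta["rookery"].astype(str))


def read_share_summary(counts: pd.DataFrame) -> pd.Series:
    """Percent of total reads contributed by each OTU/item, descending."""
    per_item = counts.sum(axis=0)
    total = per_item.sum()
    if total == 0:
        return per_item.astype(float)
    return (100.0 * per_item / total).sort_values(ascending=False)


def _category_map(categories, field: str) -> dict[str, str]:
    out = {}
    for c in categories:
        if isinstance(c, CategoryAssignment):
            out[c.item] = getattr(c, field)
        else:  # plain mapping item -> label
            out.update(c)
    return out


def poo_summary(
    matrix: OccurrenceMatrix,
    grouping: str = "items",
    categories=None,
) -> dict[str, DietProfile]:
    """FOO/POO per rookery, over items or over habitat/trophic categories.

    FOO_i = fraction of the rookery's samples containing item i;
    POO_i = 100 * FOO_i / sum_j FOO_j.  For category groupings, a sample
    "contains" a category when it contains any item of that category;
    uncategorized items are excluded from category summaries.
    """
    if grouping not in ("items", "habitat", "trophic_bin"):
        raise ValueError(f"unknown grouping {grouping!r}")
    data = matrix.data
    if grouping != "items":
        if categories is None:
            raise ValueError("categories required for category groupings")
        field = "habitat_class" if grouping == "habitat" else "trophic_bin"
        cmap = _category_map(categories, field)
        keep = [i for i in data.columns if cmap.get(i, "uncategorized") != "uncategorized"]
        grouped = (
            data[keep].T.groupby(lambda i: cmap[i]).max().T if keep
            else pd.DataFrame(index=data.index)
        )
        data = (grouped > 0).astype(int)

    profiles: dict[str, DietProfile] = {}
    for rook in matrix.rookeries():
        sub = data.loc[matrix.rookery == rook]
        if len(sub) == 0:
            warnings.warn(f"rookery {rook!r} has no samples; skipped", stacklevel=2)
            continue
        foo = sub.mean(axis=0)
        total = foo.sum()
        poo = 100.0 * foo / total if total > 0 else foo * 0.0
        profiles[rook] = DietProfile(rook, foo, poo)
    return profiles


def richness_summary(matrix: OccurrenceMatrix) -> pd.DataFrame:
    """Per-rookery richness and per-sample richness statistics.

    Columns: n_samples, richness (distinct items in the rookery), mean,
    median, min and max of per-sample item counts.
    """
    rows = []
    for rook in matrix.rookeries():
        sub = matrix.subset_rookery(rook)
        per_sample = sub.sum(axis=1)
        rows.append(
            {
                "rookery": rook,
                "n_samples": len(sub),
                "richness": int((sub.sum(axis=0) > 0).sum()),
                "mean_per_sample": float(per_sample.mean()),
                "median_per_sample": float(per_sample.median()),
                "min_per_sample": int(per_sample.min()),
                "max_per_sample": int(per_sample.max()),
            }
        )
    return pd.DataFrame(rows).set_index("rookery")


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefy_samples(matrix: pd.DataFrame | OccurrenceMatrix, n: int) -> RarefactionEstimate:
    """Sample-based (incidence) rarefaction on a binary matrix.

    E[S_n] = sum_i (1 - C(N - f_i, n) / C(N, n)) with f_i the number of
    samples containing item i.  The variance is exact under sampling of n
    of the N samples without replacement, using the observed joint
    incidences; the 95% CI is the normal approximation E +- 1.96 * sd.
    """
    data = matrix.data if isinstance(matrix, OccurrenceMatrix) else matrix
    x = (data.to_numpy() > 0).astype(int)
    N = x.shape[0]
    if not 1 <= n <= N:
        raise ValueError(f"subsample size {n} outside [1, {N}]")
    f = x.sum(axis=0)
    f = f[f > 0]
    x = x[:, (x.sum(axis=0) > 0)]
    denom = _log_comb(N, n)

    def absent_prob(missing):
        """P(an item contained in N - missing samples is absent), vectorized."""
        missing = np.asarray(missing, dtype=float)
        ok = (N - missing) >= n
        out = np.zeros_like(missing, dtype=float)
        out[ok] = np.exp(_log_comb(N - missing[ok], n) - denom)
        return out

    q = absent_prob(f)                      # per-item absence probabilities
    expected = float(np.sum(1.0 - q))

    # covariance needs P(both absent) = C(N - |A_i u A_j|, n) / C(N, n)
    joint = x.T @ x                         # f_ij on the diagonal-off entries
    union = f[:, None] + f[None, :] - joint
    qq = absent_prob(union)
    cov = qq - q[:, None] * q[None, :]
    var = float(np.sum(cov) - np.trace(cov) + np.sum(q * (1.0 - q)))
    var = max(var, 0.0)
    sd = np.sqrt(var)
    return RarefactionEstimate(n, expected, var, expected - 1.96 * sd, expected + 1.96 * sd)


def rarefy_reads(
    counts,
    grid=None,
    cv_threshold: float = 0.05,
) -> tuple[pd.DataFrame, float | None]:
    """Individual-based (read) rarefaction on pooled per-OTU read counts.

    E[S at m reads] uses the hypergeometric expectation on the pooled
    counts; the variance is the classical exact formula under subsampling
    without replacement.  Also reported: the smallest grid depth at which
    the coefficient of variation of the estimate drops to *cv_threshold*
    (the depth where the curve stabilizes), or None if never reached.
    """
    xs = np.asarray(counts, dtype=np.int64)
    xs = xs[xs > 0]
    total = int(xs.sum())
    if grid is None:
        grid = np.unique(np.linspace(1, total, 50, dtype=np.int64))
    grid = np.asarray(grid, dtype=np.int64)
    if (grid > total).any():
        warnings.warn("grid depths beyond total reads truncated", stacklevel=2)
        grid = grid[grid <= total]

    rows = []
    stable_depth = None
    for m in grid:
        denom = _log_comb(total, m)
        ok = (total - xs) >= m
        q = np.zeros(len(xs))
        q[ok] = np.exp(_log_comb(total - xs[ok], m) - denom)
        e = float(np.sum(1.0 - q))
        union = xs[:, None] + xs[None, :]
        ok2 = (total - union) >= m
        qq = np.zeros_like(union, dtype=float)
        qq[ok2] = np.exp(_log_comb((total - union)[ok2], m) - denom)
        cov = qq - q[:, None] * q[None, :]
        var = float(np.sum(cov) - np.trace(cov) + np.sum(q * (1.0 - q)))
        var = max(var, 0.0)
        cv = np.sqrt(var) / e if e > 0 else np.inf
        if stable_depth is None and cv <= cv_threshold:
            stable_depth = int(m)
        rows.append({"reads": int(m), "expected_otus": e, "variance": var, "cv": cv})
    return pd.DataFrame(rows), stable_depth
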