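"""Distance-based community statistics for diet occurrence data.

Implements, from first principles, the inferential toolkit used to
compare diets among groups of samples: Jaccard distances, PERMANOVA with
sequential (type-I) sums of squares on a Gower-centered distance matrix,
pairwise PERMANOVA with Holm correction, PERMDISP (homogeneity of
multivariate dispersions via distances to group centroids in a
principal-coordinate embedding keeping negative-eigenvalue axes),
non-metric multidimensional scaling minimizing Kruskal stress-1, the
Schoener diet-overlap index, indicator value (IndVal) analysis over
site-group combinations, and thin wrappers for the univariate rank tests
(Spearman, Kruskal-Wallis, paired Wilcoxon) plus Holm adjustment.

Permutation p-values use the (1 + b) / (1 + m) convention so a
permutation test can never report p = 0.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix
from sklearn.isotonic import IsotonicRegression

from .diet import DietProfile, OccurrenceMatrix

__all__ = [
    "PermanovaResult",
    "PermdispResult",
    "NmdsResult",
    "IndvalResult",
    "OverlapResult",
    "jaccard_distances",
    "permanova",
    "pairwise_permanova",
    "permdisp",
    "nmds",
    "schoener_overlap",
    "indval",
    "rank_correlation",
    "group_rank_test",
    "paired_rank_test",
    "holm_adjust",
]


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def jaccard_distances(matrix: OccurrenceMatrix | pd.DataFrame) -> DistanceMatrix:
    """Jaccard distances between samples of a binary matrix.

    d(x, y) = 1 - |x & y| / |x | y| over item sets; an all-zero sample has
    no defined distance and raises.
    """
    data = matrix.data if isinstance(matrix, OccurrenceMatrix) else matrix
    x = (data.to_numpy() > 0).astype(np.int64)
    empty = np.flatnonzero(x.sum(axis=1) == 0)
    if empty.size:
        raise ValueError(f"sample {data.index[empty[0]]!r} has no items; Jaccard undefined")
    inter = x @ x.T
    sizes = x.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    d = 1.0 - inter / union
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=[str(i) for i in data.index])


def _gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix from a distance matrix."""
    a = -0.5 * d ** 2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    terms: pd.DataFrame          # index: term; columns: df, SS, F, R2, p
    residual_df: int
    residual_ss: float
    total_ss: float
    n_permutations: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "terms": self.terms.reset_index().to_dict(orient="records"),
            "residual_df": self.residual_df,
            "residual_ss": self.residual_ss,
            "total_ss": self.total_ss,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def _design_columns(values, name: str) -> np.ndarray:
    values = np.asarray(values)
    if values.dtype.kind in "OUSb":  # categorical factor -> treatment dummies
        levels = pd.unique(values)
        if len(levels) < 2:
            raise ValueError(f"term {name!r} has a single level")
        return np.column_stack([(values == lv).astype(float) for lv in levels[1:]])
    col = values.astype(float)
    return (col - col.mean())[:, None]


def permanova(
    dist: DistanceMatrix,
    terms,
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermanovaResult:
    """PERMANOVA with sequential (type-I) sums of squares.

    *terms* is an ordered mapping / list of (name, values) pairs; string
    values are treated as factors (dummy coded), numeric values as
    covariates.  The distance matrix is Gower-centered; each term's SS is
    the trace of its incremental projection applied to the centered
    matrix, and significance comes from whole-row permutation of the
    distance matrix.
    """
    d = dist.data if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)
    n = d.shape[0]
    if isinstance(terms, dict):
        terms = list(terms.items())
    g = _gower_center(d)
    total_ss = float(np.trace(g))

    x = np.ones((n, 1))
    hats = [x @ np.linalg.pinv(x)]
    ranks = [1]
    names = []
    for name, values in terms:
        if len(values) != n:
            raise ValueError(f"term {name!r} length {len(values)} != {n} samples")
        x = np.hstack([x, _design_columns(values, name)])
        rank = np.linalg.matrix_rank(x)
        if rank == ranks[-1]:
            raise ValueError(f"term {name!r} is collinear with preceding terms")
        hats.append(x @ np.linalg.pinv(x))
        ranks.append(rank)
        names.append(name)

    delta = [hats[i + 1] - hats[i] for i in range(len(names))]
    dfs = [ranks[i + 1] - ranks[i] for i in range(len(names))]
    resid_proj = np.eye(n) - hats[-1]
    df_res = n - ranks[-1]

    def f_stats(gm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ss = np.array([float(np.sum(dh * gm.T)) for dh in delta])
        ss_res = float(np.sum(resid_proj * gm.T))
        f = (ss / dfs) / (ss_res / df_res)
        return ss, f

    ss_obs, f_obs = f_stats(g)
    ss_res = total_ss - ss_obs.sum()

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(names))
    for _ in range(n_perm):
        p = rng.permutation(n)
        _, f_p = f_stats(g[np.ix_(p, p)])
        exceed += f_p >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    table = pd.DataFrame(
        {
            "df": dfs,
            "SS": ss_obs,
            "F": f_obs,
            "R2": ss_obs / total_ss,
            "p": pvals,
        },
        index=pd.Index(names, name="term"),
    )
    return PermanovaResult(table, df_res, ss_res, total_ss, n_perm, seed)


def pairwise_permanova(
    dist: DistanceMatrix,
    groups,
    n_perm: int = 9999,
    seed: int | None = None,
) -> pd.DataFrame:
    """One PERMANOVA per pair of groups, with Holm-adjusted p-values."""
    groups = np.asarray(groups)
    d = dist.data if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in itertools.combinations(levels, 2):
        idx = np.flatnonzero((groups == a) | (groups == b))
        if (groups == a).sum() < 2 or (groups == b).sum() < 2:
            warnings.warn(f"pair ({a}, {b}) skipped: a group has < 2 samples", stacklevel=2)
            continue
        sub = d[np.ix_(idx, idx)]
        res = permanova(
            DistanceMatrix(sub), [("group", groups[idx])],
            n_perm=n_perm, seed=int(rng.integers(2**31)),
        )
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "F": res.terms.loc["group", "F"],
                "R2": res.terms.loc["group", "R2"],
                "p": res.terms.loc["group", "p"],
            }
        )
    table = pd.DataFrame(rows)
    table["p_holm"] = holm_adjust(table["p"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# PERMDISP
# ---------------------------------------------------------------------------

@dataclass
class PermdispResult:
    distances: pd.Series         # per-sample distance to group centroid
    group_means: pd.Series
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    pairwise: pd.DataFrame       # Tukey HSD p, Holm-adjusted
    n_permutations: int
    seed: int | None
    n_clamped: int = 0           # negative radicands clamped to zero

    def to_dict(self) -> dict:
        return {
            "f_statistic": self.f_statistic,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "p_value": self.p_value,
            "group_means": self.group_means.to_dict(),
            "pairwise": self.pairwise.to_dict(orient="records"),
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "n_clamped": self.n_clamped,
        }


def _pcoa_axes(d: np.ndarray, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate axes split into real and imaginary parts.

    Returns (pos, neg): coordinates on positive-eigenvalue axes and on
    negative-eigenvalue axes (scaled by sqrt(|eigenvalue|)).
    """
    g = _gower_center(d)
    vals, vecs = np.linalg.eigh((g + g.T) / 2)
    scale = max(abs(vals).max(), 1.0)
    pos = vals > tol * scale
    neg = vals < -tol * scale
    return vecs[:, pos] * np.sqrt(vals[pos]), vecs[:, neg] * np.sqrt(-vals[neg])


def dispersion_distances(dist: DistanceMatrix, groups) -> tuple[np.ndarray, int]:
    """Distance of each sample to its group centroid in PCoA space.

    Both positive- and negative-eigenvalue axes are kept; the squared
    distance is the positive-space part minus the negative-space part and
    negative radicands are clamped to zero (their count is returned).
    """
    d = dist.data if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)
    groups = np.asarray(groups)
    pos, neg = _pcoa_axes(d)
    z = np.zeros(len(groups))
    clamped = 0
    for lv in pd.unique(groups):
        idx = groups == lv
        dp2 = ((pos[idx] - pos[idx].mean(axis=0)) ** 2).sum(axis=1)
        dn2 = ((neg[idx] - neg[idx].mean(axis=0)) ** 2).sum(axis=1) if neg.size else 0.0
        r = dp2 - dn2
        clamped += int(np.sum(r < 0))
        z[idx] = np.sqrt(np.clip(r, 0.0, None))
    return z, clamped


def permdisp(
    dist: DistanceMatrix,
    groups,
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermdispResult:
    """Homogeneity of multivariate dispersions (group-centroid variant).

    One-way ANOVA F on the distances to group centroids, with the
    permutation p obtained by shuffling group labels over those distances;
    pairwise comparisons via Tukey HSD with Holm adjustment.
    """
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) < 2 or any((groups == lv).sum() < 2 for lv in levels):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    z, clamped = dispersion_distances(dist, groups)

    def anova_f(labels: np.ndarray) -> float:
        grand = z.mean()
        ssb = sum((labels == lv).sum() * (z[labels == lv].mean() - grand) ** 2 for lv in levels)
        ssw = sum(((z[labels == lv] - z[labels == lv].mean()) ** 2).sum() for lv in levels)
        dfb, dfw = len(levels) - 1, len(z) - len(levels)
        if ssw == 0:
            return np.inf if ssb > 0 else 0.0
        return (ssb / dfb) / (ssw / dfw)

    f_obs = anova_f(groups)
    rng = np.random.default_rng(seed)
    exceed = sum(anova_f(rng.permutation(groups)) >= f_obs for _ in range(n_perm))
    p = (1.0 + exceed) / (1.0 + n_perm)

    samples_by_level = [z[groups == lv] for lv in levels]
    tukey = sps.tukey_hsd(*samples_by_level)
    pairs = list(itertools.combinations(range(len(levels)), 2))
    raw = [float(tukey.pvalue[i, j]) for i, j in pairs]
    adj = holm_adjust(raw)
    pairwise = pd.DataFrame(
        {
            "group_a": [levels[i] for i, _ in pairs],
            "group_b": [levels[j] for _, j in pairs],
            "p_tukey": raw,
            "p_holm": adj,
        }
    )
    ids = dist.ids if isinstance(dist, DistanceMatrix) else list(range(len(z)))
    return PermdispResult(
        distances=pd.Series(z, index=list(ids)),
        group_means=pd.Series({lv: z[groups == lv].mean() for lv in levels}),
        f_statistic=f_obs,
        df_between=len(levels) - 1,
        df_within=len(z) - len(levels),
        p_value=p,
        pairwise=pairwise,
        n_permutations=n_perm,
        seed=seed,
        n_clamped=clamped,
    )


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass
class NmdsResult:
    coordinates: np.ndarray
    stress: float                # Kruskal stress-1
    k: int
    n_starts: int
    best_start: int
    converged: bool
    seed: int | None


def _isotonic_disparities(delta: np.ndarray, dhat: np.ndarray) -> np.ndarray:
    """Monotone (primary-ties) fit of configuration distances to delta."""
    order = np.lexsort((dhat, delta))
    iso = IsotonicRegression()
    fitted = iso.fit_transform(np.arange(len(dhat)), dhat[order])
    out = np.empty_like(dhat)
    out[order] = fitted
    return out


def _stress1(dhat: np.ndarray, disp: np.ndarray) -> float:
    denom = np.sum(dhat ** 2)
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((dhat - disp) ** 2) / denom))


def _condensed(x: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist

    return pdist(x)


def _smacof_nonmetric(
    delta: np.ndarray, x0: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, bool]:
    n = x0.shape[0]
    iu = np.triu_indices(n, 1)
    x = x0.copy()
    last = np.inf
    stress = np.inf
    for _ in range(max_iter):
        dhat = _condensed(x)
        disp = _isotonic_disparities(delta, dhat)
        # keep the configuration scale fixed across iterations
        s = np.sum(disp ** 2)
        if s > 0:
            disp = disp * np.sqrt(np.sum(dhat ** 2) / s)
        stress = _stress1(dhat, disp)
        if abs(last - stress) < tol:
            return x, stress, True
        last = stress
        # Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dhat > 0, disp / dhat, 0.0)
        b = np.zeros((n, n))
        b[iu] = -ratio
        b += b.T
        np.fill_diagonal(b, -b.sum(axis=1))
        x = b @ x / n
    return x, stress, False


def nmds(
    dist: DistanceMatrix,
    k: int = 3,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int | None = None,
) -> NmdsResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Runs one metric (principal-coordinate) initialization plus
    ``n_starts - 1`` random starts and returns the best final
    configuration.  Ties in the dissimilarities are handled by the
    primary (weak monotonicity) approach.
    """
    d = dist.data if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)
    n = d.shape[0]
    if k < 1 or n_starts < 1:
        raise ValueError("k and n_starts must be >= 1")
    delta = d[np.triu_indices(n, 1)]
    rng = np.random.default_rng(seed)

    pos, neg = _pcoa_axes(d)
    init = np.zeros((n, k))
    take = min(k, pos.shape[1])
    init[:, :take] = pos[:, np.argsort(-(pos ** 2).sum(axis=0))[:take]]
    if take < k:
        init[:, take:] = rng.normal(scale=1e-4, size=(n, k - take))

    best = None
    for start in range(n_starts):
        x0 = init if start == 0 else rng.normal(size=(n, k)) * delta.std()
        x, stress, converged = _smacof_nonmetric(delta, x0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (x, stress, converged, start)
    x, stress, converged, start = best
    if not converged:
        warnings.warn("NMDS did not converge; returning best configuration so far",
                      stacklevel=2)
    return NmdsResult(x, stress, k, n_starts, start, converged, seed)


# ---------------------------------------------------------------------------
# Schoener overlap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapResult:
    rookery_a: str
    rookery_b: str
    schoener_d: float


def schoener_overlap(profile_x: DietProfile, profile_y: DietProfile) -> OverlapResult:
    """Schoener diet overlap D = 1 - 0.5 * sum |p_x - p_y|.

    Profiles are aligned on the union of their items and renormalized to
    proportions; D is 1 for identical diets and 0 for disjoint ones.
    """
    px = profile_x.proportions()
    py = profile_y.proportions()
    items = px.index.union(py.index)
    px = px.reindex(items, fill_value=0.0)
    py = py.reindex(items, fill_value=0.0)
    d = 1.0 - 0.5 * float(np.abs(px - py).sum())
    return OverlapResult(profile_x.rookery, profile_y.rookery, d)


# ---------------------------------------------------------------------------
# IndVal
# ---------------------------------------------------------------------------

@dataclass
class IndvalResult:
    table: pd.DataFrame          # per item: combination, A, B, indval, p
    n_permutations: int
    seed: int | None
    allow_combinations: bool = True


def _indval_components(
    x: np.ndarray, groups: np.ndarray, levels: list, combos: list[tuple[int, ...]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A, B and IndVal for every (combination, item) pair.

    A (specificity) uses unweighted group means so the statistic does not
    depend on group sizes; B (fidelity) is the occupancy fraction within
    the combination's sites.
    """
    k = len(levels)
    means = np.stack([x[groups == lv].mean(axis=0) for lv in levels])       # k x P
    occ = np.stack([(x[groups == lv] > 0).sum(axis=0) for lv in levels])    # k x P
    sizes = np.array([(groups == lv).sum() for lv in levels])

    n_c = len(combos)
    a = np.zeros((n_c, x.shape[1]))
    b = np.zeros((n_c, x.shape[1]))
    for ci, combo in enumerate(combos):
        inside = np.zeros(k, dtype=bool)
        inside[list(combo)] = True
        mean_in = means[inside].mean(axis=0)
        sum_out = means[~inside].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            a[ci] = np.where(mean_in + sum_out > 0, mean_in / (mean_in + sum_out), 0.0)
        b[ci] = occ[inside].sum(axis=0) / sizes[inside].sum()
    return a, b, np.sqrt(a * b)


def indval(
    matrix: OccurrenceMatrix | pd.DataFrame,
    groups=None,
    allow_combinations: bool = True,
    n_perm: int = 9999,
    seed: int | None = None,
) -> IndvalResult:
    """Indicator value analysis over site groups and their combinations.

    For each item, every union of 1..K-1 groups is scored by
    IndVal = sqrt(A * B); the best combination is reported and its
    significance assessed by permuting site labels (the permutation
    statistic is each item's best IndVal over combinations).
    """
    if isinstance(matrix, OccurrenceMatrix):
        data = matrix.data
        groups = matrix.rookery.to_numpy() if groups is None else np.asarray(groups)
    else:
        data = matrix
        groups = np.asarray(groups)
    x = (data.to_numpy() > 0).astype(float)
    present = x.sum(axis=0) > 0
    if not present.all():
        skipped = [c for c, keep in zip(data.columns, present) if not keep]
        warnings.warn(f"items absent everywhere skipped: {skipped}", stacklevel=2)
    x = x[:, present]
    items = [c for c, keep in zip(data.columns, present) if keep]

    levels = list(pd.unique(groups))
    k = len(levels)
    if k < 2:
        raise ValueError("need >= 2 groups")
    max_size = k - 1 if allow_combinations else 1
    combos = [
        c for r in range(1, max_size + 1) for c in itertools.combinations(range(k), r)
    ]

    a, b, iv = _indval_components(x, groups, levels, combos)
    best_idx = iv.argmax(axis=0)
    obs = iv.max(axis=0)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(items))
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        _, _, ivp = _indval_components(x, perm, levels, combos)
        exceed += ivp.max(axis=0) >= obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for j, item in enumerate(items):
        combo = combos[best_idx[j]]
        rows.append(
            {
                "item": item,
                "combination": "+".join(str(levels[i]) for i in combo),
                "A": a[best_idx[j], j],
                "B": b[best_idx[j], j],
                "indval": obs[j],
                "p": pvals[j],
            }
        )
    table = pd.DataFrame(rows).set_index("item")
    return IndvalResult(table, n_perm, seed, allow_combinations)


# ---------------------------------------------------------------------------
# univariate rank tests
# ---------------------------------------------------------------------------

def rank_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    The p-value is exact (enumeration over all orderings) for n <= 8 when
    neither vector has ties, and the t-approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if n <= 8 and not ties:
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        return rho, count / total
    t = rho * np.sqrt((n - 2) / max(1.0 - rho ** 2, 1e-300))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return rho, float(min(p, 1.0))


def group_rank_test(values, groups) -> tuple[float, int, float]:
    """Kruskal-Wallis rank-sum test; returns (H, df, p)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    if np.ptp(values) == 0:
        raise ValueError("statistic undefined when all values are identical")
    samples = [values[groups == lv] for lv in levels]
    h, p = sps.kruskal(*samples)
    return float(h), len(levels) - 1, float(p)


def paired_rank_test(a, b) -> float:
    """Two-sided paired Wilcoxon signed-rank p; zero differences dropped."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired vectors must have equal length")
    diffs = a - b
    diffs = diffs[diffs != 0]
    if len(diffs) == 0:
        raise ValueError("all paired differences are zero")
    n = len(diffs)
    method = "exact" if n <= 25 and len(np.unique(np.abs(diffs))) == n else "approx"
    res = sps.wilcoxon(diffs, alternative="two-sided", method=method)
    return float(res.pvalue)


def holm_adjust(pvalues) -> np.ndarray:
    """Step-down Holm adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj
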