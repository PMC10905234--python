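import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from scatdiet.diet import DietProfile, OccurrenceMatrix
from scatdiet.stats import (
    dispersion_distances,
    group_rank_test,
    holm_adjust,
    indval,
    jaccard_distances,
    nmds,
    paired_rank_test,
    pairwise_permanova,
    permanova,
    permdisp,
    rank_correlation,
    schoener_overlap,
)


def occ(rows, items=None, rookery=None):
    rows = np.asarray(rows, dtype=int)
    items = items or [f"i{j}" for j in range(rows.shape[1])]
    data = pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))], columns=items)
    rook = rookery or ["R1"] * len(rows)
    return OccurrenceMatrix(data, pd.Series(rook, index=data.index))


class TestJaccard:
    def test_identical_disjoint_partial(self):
        m = occ([[1, 1, 0], [1, 1, 0], [0, 0, 1], [1, 0, 1]])
        d = jaccard_distances(m)
        assert d["s0", "s1"] == 0.0
        assert d["s0", "s2"] == 1.0
        # {A,B} vs {B,C}: 1 - 1/3
        m2 = occ([[1, 1, 0], [0, 1, 1]])
        assert jaccard_distances(m2)["s0", "s1"] == pytest.approx(2 / 3)

    def test_all_zero_row_raises(self):
        with pytest.raises(ValueError, match="s1"):
            jaccard_distances(occ([[1, 0], [0, 0]]))

    @pytest.mark.parametrize("seed", range(5))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        x = (rng.random((12, 8)) < 0.5).astype(int)
        x[x.sum(axis=1) == 0, 0] = 1
        d = jaccard_distances(occ(x)).data
        for i, j, k in itertools.combinations(range(12), 3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12

    def test_matches_scipy(self):
        rng = np.random.default_rng(9)
        x = (rng.random((10, 6)) < 0.5).astype(int)
        x[x.sum(axis=1) == 0, 0] = 1
        mine = jaccard_distances(occ(x)).condensed_form()
        assert np.allclose(mine, pdist(x, metric="jaccard"))


def brute_force_permanova(d, groups):
    """Textbook one-way pseudo-F from sums of squared distances."""
    groups = np.asarray(groups)
    n = len(groups)
    levels = np.unique(groups)
    ss_total = (d[np.triu_indices(n, 1)] ** 2).sum() / n
    ss_within = 0.0
    for lv in levels:
        idx = np.flatnonzero(groups == lv)
        sub = d[np.ix_(idx, idx)]
        ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    ss_among = ss_total - ss_within
    df_a, df_w = len(levels) - 1, n - len(levels)
    return ss_among, ss_within, (ss_among / df_a) / (ss_within / df_w)


class TestPermanova:
    def test_toy_against_exhaustive_enumeration(self):
        # 2 groups of 2: within-group distance 0.2, between-group 1
        d = np.full((4, 4), 1.0)
        d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.2
        np.fill_diagonal(d, 0.0)
        groups = np.array(["a", "a", "b", "b"])
        res = permanova(DistanceMatrix(d), [("g", groups)], n_perm=9999, seed=1)
        ss_a, ss_w, f = brute_force_permanova(d, groups)
        assert res.terms.loc["g", "SS"] == pytest.approx(ss_a)
        assert res.residual_ss == pytest.approx(ss_w)
        assert res.terms.loc["g", "F"] == pytest.approx(f)
        # exhaustive p over all 4! relabelings
        fs = []
        for perm in itertools.permutations(range(4)):
            fs.append(brute_force_permanova(d, groups[list(perm)])[2])
        exact_p = np.mean(np.asarray(fs) >= f - 1e-12)
        assert res.terms.loc["g", "p"] == pytest.approx(exact_p, abs=0.02)

    @pytest.mark.parametrize("seed", range(3))
    def test_f_matches_brute_force_on_random_toys(self, seed):
        rng = np.random.default_rng(seed)
        x = (rng.random((8, 6)) < 0.5).astype(int)
        x[x.sum(axis=1) == 0, 0] = 1
        groups = np.array(["a"] * 4 + ["b"] * 4)
        d = jaccard_distances(occ(x)).data
        res = permanova(DistanceMatrix(d), [("g", groups)], n_perm=99, seed=seed)
        ss_a, ss_w, f = brute_force_permanova(d, groups)
        assert res.terms.loc["g", "F"] == pytest.approx(f)
        assert res.terms.loc["g", "SS"] == pytest.approx(ss_a)

    def test_matches_scikit_bio(self):
        rng = np.random.default_rng(11)
        x = (rng.random((20, 10)) < 0.4).astype(int)
        x[x.sum(axis=1) == 0, 0] = 1
        groups = np.array(["a", "b", "c", "d"]).repeat(5)
        dm = jaccard_distances(occ(x))
        res = permanova(dm, [("g", groups)], n_perm=999, seed=0)
        import skbio.stats.distance as sksd

        ref = sksd.permanova(dm, grouping=groups, permutations=999)
        assert res.terms.loc["g", "F"] == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_euclidean_single_factor_equals_classical_anova(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=12)
        groups = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        d = np.abs(y[:, None] - y[None, :])
        res = permanova(DistanceMatrix(d), [("g", groups)], n_perm=9, seed=0)
        grand = y.mean()
        ss_b = sum(4 * (y[groups == lv].mean() - grand) ** 2 for lv in "abc")
        ss_w = sum(((y[groups == lv] - y[groups == lv].mean()) ** 2).sum() for lv in "abc")
        assert res.terms.loc["g", "SS"] == pytest.approx(ss_b)
        assert res.residual_ss == pytest.approx(ss_w)

    def test_sequential_decomposition_adds_up(self):
        rng = np.random.default_rng(3)
        x = (rng.random((18, 9)) < 0.4).astype(int)
        x[x.sum(axis=1) == 0, 0] = 1
        groups = np.array(["a", "b", "c"]).repeat(6)
        covar = rng.normal(size=18)
        res = permanova(jaccard_distances(occ(x)),
                        [("g", groups), ("cov", covar)], n_perm=99, seed=0)
        assert res.terms["SS"].sum() + res.residual_ss == pytest.approx(res.total_ss)
        assert res.terms["df"].sum() + res.residual_df == len(x) - 1
        assert np.allclose(res.terms["R2"], res.terms["SS"] / res.total_ss)

    def test_collinear_term_raises(self):
        d = np.abs(np.arange(6)[:, None] - np.arange(6)[None, :]).astype(float)
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        with pytest.raises(ValueError, match="dup"):
            permanova(DistanceMatrix(d), [("g", groups), ("dup", groups.copy())],
                      n_perm=9, seed=0)

    def test_statistic_invariant_to_consistent_relabeling(self):
        rng = np.random.default_rng(4)
        x = (rng.random((10, 6)) < 0.5).astype(int)
        x[x.sum(axis=1) == 0, 0] = 1
        groups = np.array(["a"] * 5 + ["b"] * 5)
        d = jaccard_distances(occ(x)).data
        f1 = permanova(DistanceMatrix(d), [("g", groups)], n_perm=9, seed=0)
        perm = rng.permutation(10)
        f2 = permanova(DistanceMatrix(d[np.ix_(perm, perm)]),
                       [("g", groups[perm])], n_perm=9, seed=0)
        assert f1.terms.loc["g", "F"] == pytest.approx(f2.terms.loc["g", "F"])


class TestPairwisePermanova:
    def test_identical_groups_nonsignificant(self):
        x = np.tile([[1, 1, 0], [0, 1, 1], [1, 0, 1]], (2, 1))
        groups = ["a"] * 3 + ["b"] * 3
        table = pairwise_permanova(jaccard_distances(occ(x)), groups,
                                   n_perm=199, seed=0)
        assert table["p"].iloc[0] > 0.5

    def test_three_groups_three_pairs_with_holm(self):
        rng = np.random.default_rng(5)
        x = (rng.random((12, 6)) < 0.5).astype(int)
        x[x.sum(axis=1) == 0, 0] = 1
        groups = np.array(["a", "b", "c"]).repeat(4)
        table = pairwise_permanova(jaccard_distances(occ(x)), groups,
                                   n_perm=99, seed=0)
        assert len(table) == 3
        assert np.allclose(table["p_holm"], holm_adjust(table["p"].to_numpy()))


class TestPermdisp:
    def test_euclidean_line_toy(self):
        # group1 {0,2}, group2 {0,6} on a line -> z = (1,1,3,3)
        pts = np.array([0.0, 2.0, 0.0, 6.0])
        d = np.abs(pts[:, None] - pts[None, :])
        groups = np.array(["g1", "g1", "g2", "g2"])
        z, clamped = dispersion_distances(DistanceMatrix(d), groups)
        assert np.allclose(sorted(z), [1, 1, 3, 3])
        assert clamped == 0

    def test_z_equals_direct_point_to_centroid_distance(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(12, 3))
        groups = np.array(["a", "b", "c"]).repeat(4)
        d = squareform(pdist(pts))
        z, _ = dispersion_distances(DistanceMatrix(d), groups)
        direct = np.zeros(12)
        for lv in "abc":
            idx = groups == lv
            direct[idx] = np.linalg.norm(pts[idx] - pts[idx].mean(axis=0), axis=1)
        assert np.allclose(z, direct)

    def test_mirrored_groups_have_equal_dispersion(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [5, 5], [6, 5], [5, 6]], float)
        d = squareform(pdist(pts))
        groups = np.array(["a"] * 3 + ["b"] * 3)
        res = permdisp(DistanceMatrix(d), groups, n_perm=499, seed=0)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.5

    def test_matches_scikit_bio(self):
        # Euclidean distances: no negative PCoA eigenvalues, so the
        # reference (which drops them) and this implementation (which
        # keeps them) agree exactly
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(20, 4))
        dm = DistanceMatrix(squareform(pdist(pts)),
                            ids=[f"s{i}" for i in range(20)])
        groups = np.array(["a", "b", "c", "d"]).repeat(5)
        res = permdisp(dm, groups, n_perm=99, seed=0)
        import skbio.stats.distance as sksd

        ref = sksd.permdisp(dm, grouping=groups, permutations=99, test="centroid")
        assert res.f_statistic == pytest.approx(ref["test statistic"], rel=1e-6)

    def test_requires_two_groups_of_two(self):
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError):
            permdisp(DistanceMatrix(d), ["a", "a", "b"], n_perm=9, seed=0)


class TestNmds:
    def test_perfect_embedding_recovered(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(20, 3))
        d = squareform(pdist(pts))
        res = nmds(DistanceMatrix(d), k=3, n_starts=4, seed=0)
        assert res.stress < 1e-3

    def test_stress_not_increasing_in_k(self):
        rng = np.random.default_rng(9)
        x = (rng.random((15, 10)) < 0.4).astype(int)
        x[x.sum(axis=1) == 0, 0] = 1
        dm = jaccard_distances(occ(x))
        s2 = nmds(dm, k=2, n_starts=8, seed=0).stress
        s3 = nmds(dm, k=3, n_starts=8, seed=0).stress
        assert s3 <= s2 + 1e-6

    def test_invalid_args(self):
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError):
            nmds(DistanceMatrix(d), k=0)


class TestSchoener:
    def prof(self, name, poo):
        s = pd.Series(poo)
        return DietProfile(name, s / 100, s)

    def test_identical_profiles(self):
        p = self.prof("a", {"x": 60.0, "y": 40.0})
        q = self.prof("b", {"x": 60.0, "y": 40.0})
        assert schoener_overlap(p, q).schoener_d == pytest.approx(1.0)

    def test_disjoint_profiles(self):
        p = self.prof("a", {"x": 100.0})
        q = self.prof("b", {"y": 100.0})
        assert schoener_overlap(p, q).schoener_d == pytest.approx(0.0)

    def test_symmetry_and_l1_identity(self):
        rng = np.random.default_rng(10)
        pa = rng.dirichlet(np.ones(6)) * 100
        pb = rng.dirichlet(np.ones(6)) * 100
        items = [f"i{j}" for j in range(6)]
        p = self.prof("a", dict(zip(items, pa)))
        q = self.prof("b", dict(zip(items, pb)))
        d1 = schoener_overlap(p, q).schoener_d
        d2 = schoener_overlap(q, p).schoener_d
        assert d1 == pytest.approx(d2)
        assert d1 == pytest.approx(1 - 0.5 * np.abs(pa / 100 - pb / 100).sum())


class TestIndval:
    def test_perfect_indicator(self):
        rows = [[1], [1], [1], [1], [0], [0], [0], [0]]
        m = occ(rows, ["sp"], ["a"] * 4 + ["b"] * 4)
        res = indval(m, n_perm=199, seed=0)
        row = res.table.loc["sp"]
        assert row["indval"] == pytest.approx(1.0)
        assert row["combination"] == "a"

    def test_hand_arithmetic_A1_B075(self):
        # item only in group 1, present in 3 of its 4 sites
        rows = [[1], [1], [1], [0], [0], [0], [0], [0]]
        m = occ(rows, ["sp"], ["a"] * 4 + ["b"] * 4)
        row = indval(m, n_perm=99, seed=0).table.loc["sp"]
        assert row["A"] == pytest.approx(1.0)
        assert row["B"] == pytest.approx(0.75)
        assert row["indval"] == pytest.approx(math.sqrt(0.75))

    def test_invariant_to_duplicating_sites(self):
        rng = np.random.default_rng(12)
        x = (rng.random((9, 4)) < 0.5).astype(int)
        x[x.sum(axis=1) == 0, 0] = 1
        groups = ["a", "b", "c"] * 3
        r1 = indval(occ(x, rookery=groups), n_perm=9, seed=0).table
        x2 = np.vstack([x, x])
        r2 = indval(occ(x2, rookery=groups * 2), n_perm=9, seed=0).table
        assert np.allclose(r1["indval"], r2["indval"])

    def test_combinations_cover_unions(self):
        # item in all sites of groups a and b, never in c
        rows = [[1], [1], [1], [1], [0], [0]]
        m = occ(rows, ["sp"], ["a", "a", "b", "b", "c", "c"])
        row = indval(m, n_perm=99, seed=0).table.loc["sp"]
        assert set(row["combination"].split("+")) == {"a", "b"}
        assert row["indval"] == pytest.approx(1.0)
        single = indval(m, allow_combinations=False, n_perm=99, seed=0).table.loc["sp"]
        assert single["indval"] < 1.0


class TestRankTests:
    def test_spearman_perfect_monotone(self):
        rho, _ = rank_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_spearman_exact_p_matches_enumeration(self):
        x = [30, 23, 22, 41, 36]
        y = [872, 499, 289, 731, 434]
        rho, p = rank_correlation(x, y)
        assert rho == pytest.approx(0.50)
        assert p == pytest.approx(0.45, abs=1e-10)

    def test_spearman_with_ties_uses_midranks(self):
        rho, p = rank_correlation([24, 20, 20, 36, 29], [872, 499, 289, 731, 434])
        assert rho == pytest.approx(0.41, abs=0.005)
        assert p == pytest.approx(0.493, abs=0.005)

    def test_spearman_constant_vector_raises(self):
        with pytest.raises(ValueError):
            rank_correlation([1, 1, 1], [1, 2, 3])

    def test_kruskal_wallis_separated_ranks(self):
        # fully separated two groups of 3: H = 3.857
        h, df, p = group_rank_test([1, 2, 3, 10, 11, 12], ["a"] * 3 + ["b"] * 3)
        assert h == pytest.approx(3.857, abs=2e-3)
        assert df == 1
        # exact p by enumerating all C(6,3)=20 rank splits
        from itertools import combinations

        ranks = np.arange(1, 7)
        hs = []
        for comb in combinations(range(6), 3):
            g = np.zeros(6, bool)
            g[list(comb)] = True
            r1, r2 = ranks[g], ranks[~g]
            hh = 12 / (6 * 7) * (3 * (r1.mean() - 3.5) ** 2 + 3 * (r2.mean() - 3.5) ** 2)
            hs.append(hh)
        exact_p = np.mean(np.asarray(hs) >= h - 1e-9)
        assert exact_p == pytest.approx(0.1, abs=1e-9)

    def test_kruskal_identical_values_raise(self):
        with pytest.raises(ValueError):
            group_rank_test([5, 5, 5, 5], ["a", "a", "b", "b"])

    def test_wilcoxon_exact_small_n(self):
        # six strictly positive differences: p = 2/64
        p = paired_rank_test([2, 4, 6, 8, 10, 12], [1, 2, 3, 4, 5, 6])
        assert p == pytest.approx(2 / 64)

    def test_wilcoxon_single_nonzero_pair(self):
        p = paired_rank_test([1, 1, 2], [1, 1, 1])
        assert p == pytest.approx(1.0)

    def test_wilcoxon_all_zero_raises(self):
        with pytest.raises(ValueError):
            paired_rank_test([1, 2], [1, 2])


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.2])[0] == pytest.approx(0.2)

    def test_hand_computed_stepdown(self):
        assert np.allclose(holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06])

    @pytest.mark.parametrize("seed", range(3))
    def test_adjusted_bounds_and_monotone(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(7)
        adj = holm_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
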