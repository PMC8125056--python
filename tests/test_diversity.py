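import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from otunet import io
from otunet.containers import OtuTable, SampleMetadata
from otunet.diversity import (
    bray_curtis,
    chao1,
    diet_distance_matrix,
    faith_pd,
    host_patristic_distance_matrix,
    mantel,
    patristic_distances,
    pcoa,
    permanova,
    permutation_t_test,
    shannon,
    upgma,
)


def _dm(matrix, ids=None):
    matrix = np.asarray(matrix, dtype=float)
    return DistanceMatrix(matrix, ids=ids or [f"S{i}" for i in range(matrix.shape[0])])


class TestChao1:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([5, 3, 2], 3.0),  # no singletons: estimate equals observed richness
            ([5, 3, 1, 1, 2], 5.5),  # 5 + 2*1/(2*(1+1))
            ([1, 1, 1, 1], 10.0),  # 4 + 4*3/(2*1)
        ],
    )
    def test_bias_corrected_values(self, counts, expected):
        assert chao1(counts) == pytest.approx(expected)

    def test_classic_variant_flag(self):
        # S=3, F1=1, F2=1: classic 3 + 1/(2*1) = 3.5
        assert chao1([1, 2, 5], bias_corrected=False) == pytest.approx(3.5)

    def test_fractional_counts_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            chao1([0.5, 1.5])

    def test_at_least_observed_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = rng.poisson(1.0, size=30)
            if counts.sum() == 0:
                continue
            assert chao1(counts) >= (counts > 0).sum() - 1e-12


class TestShannon:
    def test_uniform_is_log_richness(self):
        assert shannon([1, 1, 1, 1]) == pytest.approx(math.log(4))

    def test_single_taxon_zero(self):
        assert shannon([7]) == 0.0

    def test_base2_example(self):
        assert shannon([0.75, 0.25], base=2) == pytest.approx(0.8112781244591328)

    def test_bounded_by_log_richness(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            counts = rng.integers(0, 20, size=12)
            if (counts > 0).sum() == 0:
                continue
            assert shannon(counts) <= math.log((counts > 0).sum()) + 1e-12

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            shannon([0, 0])


class TestFaithPD:
    def test_star_tree(self):
        tree = io.read_newick("(A:1,B:1,C:1,D:1,E:1);")
        assert faith_pd({"A", "B", "C"}, tree) == pytest.approx(3.0)

    def test_all_leaves_give_total_branch_length(self):
        tree = io.read_newick("((A:1,B:2):0.5,(C:3,D:1):0.25);")
        total = sum(n.length for n in tree.traverse(include_self=False))
        assert faith_pd({"A", "B", "C", "D"}, tree) == pytest.approx(total)

    def test_rooted_path_enumeration(self):
        tree = io.read_newick("((A:1,B:1):1,C:2);")
        assert faith_pd({"A", "B"}, tree) == pytest.approx(3.0)

    def test_monotone_under_added_leaf(self):
        tree = io.read_newick("((A:1,B:1):1,(C:2,D:0.5):1);")
        observed = {"A"}
        values = []
        for leaf in ["B", "C", "D"]:
            values.append(faith_pd(observed, tree))
            observed.add(leaf)
        values.append(faith_pd(observed, tree))
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_unmatched_ids_dropped_not_fatal(self):
        tree = io.read_newick("((A:1,B:1):1,C:2);")
        assert faith_pd({"A", "B", "nope"}, tree) == pytest.approx(3.0)

    def test_empty_set_errors(self):
        tree = io.read_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            faith_pd(set(), tree)


class TestBrayCurtis:
    def test_identical_rows_zero_disjoint_one(self):
        t = OtuTable(pd.DataFrame([[3, 1, 0], [3, 1, 0], [0, 0, 9]], index=list("abc"), columns=["x", "y", "z"]))
        d = bray_curtis(t)
        assert d["a", "b"] == pytest.approx(0.0)
        assert d["a", "c"] == pytest.approx(1.0)

    def test_hand_example(self):
        t = OtuTable(pd.DataFrame([[2, 2], [1, 3]], index=["a", "b"], columns=["x", "y"]))
        assert bray_curtis(t)["a", "b"] == pytest.approx(0.25)

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 30, size=(5, 9))
        counts[:, 0] += 1
        t1 = OtuTable(pd.DataFrame(counts, index=[f"s{i}" for i in range(5)], columns=[f"o{j}" for j in range(9)]))
        order = rng.permutation(9)
        t2 = OtuTable(t1.data.iloc[:, order])
        np.testing.assert_allclose(bray_curtis(t1).data, bray_curtis(t2).data)

    def test_matches_hand_formula_on_random_tables(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(0, 40, size=(6, 11)) * rng.integers(0, 2, size=(6, 11))
        counts[:, 0] += 1
        t = OtuTable(pd.DataFrame(counts, index=[f"s{i}" for i in range(6)], columns=[f"o{j}" for j in range(11)]))
        d = bray_curtis(t)
        for i, j in itertools.combinations(range(6), 2):
            x, y = counts[i].astype(float), counts[j].astype(float)
            expected = np.abs(x - y).sum() / (x + y).sum()
            assert d[f"s{i}", f"s{j}"] == pytest.approx(expected, abs=1e-12)

    def test_all_zero_row_errors(self):
        t = OtuTable(pd.DataFrame([[1, 1], [0, 0]], index=["a", "b"], columns=["x", "y"]))
        with pytest.raises(ValueError, match="b"):
            bray_curtis(t)


class TestPcoa:
    def test_three_collinear_points(self):
        d = _dm([[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        res = pcoa(d)
        positive = res.eigenvalues[res.eigenvalues > 1e-10]
        assert positive.size == 1
        assert res.proportion_explained[0] == pytest.approx(1.0)
        coords = np.sort(res.coordinates.iloc[:, 0].to_numpy())
        np.testing.assert_allclose(coords, [-1, 0, 1], atol=1e-9)

    def test_zero_matrix_all_zero_eigenvalues(self):
        res = pcoa(_dm(np.zeros((4, 4))))
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)
        assert res.coordinates.shape[1] == 0

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(11)
        points = rng.normal(size=(10, 2))
        d = _dm(squareform(pdist(points)))
        res = pcoa(d)
        recovered = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(recovered, d.data, atol=1e-9)

    def test_axis_proportions_descending(self):
        rng = np.random.default_rng(12)
        points = rng.normal(size=(8, 4))
        res = pcoa(_dm(squareform(pdist(points))))
        assert np.all(np.diff(res.proportion_explained) <= 1e-12)


class TestPermanova:
    def test_two_tight_separated_clusters_min_p(self):
        # 2 groups of 12: the chance a permutation recreates the exact split
        # (and ties the observed F) is 2/C(24,12) ~ 1e-6, so the minimum
        # attainable p is reached
        d = np.full((24, 24), 10.0)
        d[:12, :12] = 0.1
        d[12:, 12:] = 0.1
        np.fill_diagonal(d, 0.0)
        res = permanova(_dm(d), ["g1"] * 12 + ["g2"] * 12, n_permutations=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.r_squared > 0.99

    def test_exhaustive_enumerates_distinct_arrangements(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 2))
        d = _dm(squareform(pdist(pts)))
        res = permanova(d, ["a", "a", "a", "b", "b", "b"], exhaustive=True)
        assert res.n_permutations == 19  # C(6,3) = 20 arrangements incl. identity
        assert res.p_value * 20 == pytest.approx(round(res.p_value * 20))

    def test_montecarlo_converges_to_exhaustive(self):
        rng = np.random.default_rng(4)
        pts = np.concatenate([rng.normal(size=(3, 2)), rng.normal(loc=1.2, size=(3, 2))])
        d = _dm(squareform(pdist(pts)))
        labels = ["a"] * 3 + ["b"] * 3
        exact = permanova(d, labels, exhaustive=True).p_value
        mc = permanova(d, labels, n_permutations=20000, seed=9).p_value
        assert mc == pytest.approx(exact, abs=0.02)

    def test_equidistant_points_hand_decomposition(self):
        # all d = 4: SS_total = 15*16/6 = 40, SS_within = 2*(3*16/3) = 32,
        # so r^2 = 8/40 and F = (8/1)/(32/4) = 1 for every labeling -> p = 1
        d = np.full((6, 6), 4.0)
        np.fill_diagonal(d, 0.0)
        res = permanova(_dm(d), ["a", "a", "a", "b", "b", "b"], n_permutations=99, seed=1)
        assert res.r_squared == pytest.approx(0.2)
        assert res.pseudo_F == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_statistic_matches_reference_implementation(self):
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(17)
        pts = np.concatenate([rng.normal(size=(5, 3)), rng.normal(loc=0.8, size=(6, 3))])
        d = _dm(squareform(pdist(pts)))
        labels = ["a"] * 5 + ["b"] * 6
        ours = permanova(d, labels, n_permutations=99, seed=0)
        ref = skbio_permanova(d, grouping=labels, permutations=99)
        assert ours.pseudo_F == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_seeded_runs_identical(self):
        rng = np.random.default_rng(8)
        d = _dm(squareform(pdist(rng.normal(size=(9, 2)))))
        labels = ["a", "b", "c"] * 3
        r1 = permanova(d, labels, n_permutations=199, seed=42)
        r2 = permanova(d, labels, n_permutations=199, seed=42)
        assert r1.p_value == r2.p_value

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            permanova(_dm(np.zeros((3, 3))), ["a", "a", "a"])


class TestUpgma:
    def test_hand_agglomeration_heights(self):
        d = _dm([[0, 2, 6], [2, 0, 6], [6, 6, 0]], ids=["A", "B", "C"])
        tree = upgma(d)
        depths = {t.name: t.accumulate_to_ancestor(tree) for t in tree.tips()}
        assert depths == pytest.approx({"A": 3.0, "B": 3.0, "C": 3.0})
        ab = tree.lca(["A", "B"])
        assert ab.accumulate_to_ancestor(tree) == pytest.approx(3.0 - 1.0)

    def test_two_samples(self):
        tree = upgma(_dm([[0, 4], [4, 0]], ids=["A", "B"]))
        assert {t.name: t.length for t in tree.tips()} == pytest.approx({"A": 2.0, "B": 2.0})

    def test_equal_distances_tie_rule_deterministic(self):
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        t1 = upgma(_dm(d, ids=list("dcba")))
        t2 = upgma(_dm(d, ids=list("dcba")))
        assert str(t1) == str(t2)
        depths = {t.name: t.accumulate_to_ancestor(t1) for t in t1.tips()}
        assert all(v == pytest.approx(1.0) for v in depths.values())

    def test_ultrametric_on_random_matrices(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            pts = rng.normal(size=(7, 3))
            tree = upgma(_dm(squareform(pdist(pts))))
            depths = [t.accumulate_to_ancestor(tree) for t in tree.tips()]
            assert max(depths) - min(depths) < 1e-12

    def test_matches_scipy_average_linkage_cophenetic(self):
        rng = np.random.default_rng(14)
        pts = rng.normal(size=(8, 3))
        condensed = pdist(pts)
        ids = [f"s{i}" for i in range(8)]
        tree = upgma(_dm(squareform(condensed), ids=ids))
        coph = squareform(cophenet(linkage(condensed, method="average")))
        ours = patristic_distances(tree)
        for i, j in itertools.combinations(range(8), 2):
            assert ours[ids[i], ids[j]] == pytest.approx(coph[i, j], abs=1e-9)

    def test_nan_rejected(self):
        # DistanceMatrix construction itself rejects NaN, so mutate after the fact
        dm = _dm(np.zeros((3, 3)), ids=list("abc"))
        data = dm.data
        data.flags.writeable = True
        data[0, 1] = data[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            upgma(dm)


class TestPatristic:
    def test_two_leaf(self):
        tree = io.read_newick("(A:1,B:2);")
        assert patristic_distances(tree)["A", "B"] == pytest.approx(3.0)

    def test_path_sums(self):
        tree = io.read_newick("((A:1,B:1):1,C:2);")
        d = patristic_distances(tree)
        assert d["A", "B"] == pytest.approx(2.0)
        assert d["A", "C"] == pytest.approx(4.0)

    def test_zero_diagonal(self):
        tree = io.read_newick("((A:1,B:1):1,C:2);")
        d = patristic_distances(tree)
        assert all(d[x, x] == 0 for x in d.ids)


class TestMantel:
    def test_perfect_linear_relation(self):
        rng = np.random.default_rng(21)
        d1 = _dm(squareform(pdist(rng.normal(size=(8, 2)))))
        d2 = DistanceMatrix(2 * d1.data, ids=list(d1.ids))
        res = mantel(d1, d2, n_permutations=999, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_id_mismatch_lists_difference(self):
        d1 = _dm(np.zeros((3, 3)), ids=["a", "b", "c"])
        d2 = _dm(np.zeros((3, 3)), ids=["a", "b", "x"])
        with pytest.raises(ValueError, match="x"):
            mantel(d1, d2)

    def test_exhaustive_matches_montecarlo_limit(self):
        rng = np.random.default_rng(22)
        d1 = _dm(squareform(pdist(rng.normal(size=(5, 2)))))
        d2 = _dm(squareform(pdist(rng.normal(size=(5, 2)))), ids=list(d1.ids))
        exact = mantel(d1, d2, exhaustive=True)
        assert exact.n_permutations == 119  # 5! = 120 relabelings
        mc = mantel(d1, d2, n_permutations=20000, seed=1)
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.02)
        assert mc.r == pytest.approx(exact.r)

    def test_spearman_method_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(23)
        d1 = _dm(squareform(pdist(rng.normal(size=(7, 2)))))
        d2 = DistanceMatrix(d1.data**3, ids=list(d1.ids))  # monotone distortion
        res = mantel(d1, d2, method="spearman", n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_statistic_matches_reference_implementation(self):
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(25)
        d1 = _dm(squareform(pdist(rng.normal(size=(9, 2)))))
        d2 = _dm(squareform(pdist(rng.normal(size=(9, 2)))), ids=list(d1.ids))
        ours = mantel(d1, d2, n_permutations=99, seed=0)
        ref_r, _, _ = skbio_mantel(d1, d2, method="pearson", permutations=0)
        assert ours.r == pytest.approx(ref_r, abs=1e-10)

    def test_alignment_independent_of_id_order(self):
        rng = np.random.default_rng(24)
        d1 = _dm(squareform(pdist(rng.normal(size=(6, 2)))))
        perm = rng.permutation(6)
        reordered = d1.filter([d1.ids[i] for i in perm])
        res1 = mantel(d1, d1, n_permutations=99, seed=3)
        res2 = mantel(d1, reordered, n_permutations=99, seed=3)
        assert res2.r == pytest.approx(res1.r)


class TestPermutationTTest:
    def test_identical_groups_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert permutation_t_test(x, list(x), n_permutations=199, seed=0) == pytest.approx(1.0)

    def test_tiny_case_matches_exhaustive_enumeration(self):
        x, y = [1.0, 2.0, 4.0], [3.0, 6.0, 7.0]
        exact = permutation_t_test(x, y, exhaustive=True)
        assert exact * 20 == pytest.approx(round(exact * 20))  # C(6,3) grid
        mc = permutation_t_test(x, y, n_permutations=20000, seed=5)
        assert mc == pytest.approx(exact, abs=0.02)

    def test_zero_variance_equal_means(self):
        assert permutation_t_test([2.0, 2.0], [2.0, 2.0], n_permutations=99, seed=0) == pytest.approx(1.0)

    def test_groups_too_small_rejected(self):
        with pytest.raises(ValueError):
            permutation_t_test([1.0], [2.0, 3.0])


class TestMetadataDistances:
    def test_diet_distance_zero_within_sqrt2_between(self, small_metadata):
        d = diet_distance_matrix(small_metadata, small_metadata.sample_ids)
        assert d["S0", "S1"] == pytest.approx(0.0)
        assert d["S0", "S3"] == pytest.approx(math.sqrt(2))

    def test_host_patristic_expansion(self, small_metadata):
        tree = io.read_newick("(sp0:1,sp1:2);")
        d = host_patristic_distance_matrix(tree, small_metadata, small_metadata.sample_ids)
        # S0 and S2 share species sp0; S0 vs S1 crosses sp0-sp1
        assert d["S0", "S2"] == pytest.approx(0.0)
        assert d["S0", "S1"] == pytest.approx(3.0)

    def test_missing_species_listed(self, small_metadata):
        tree = io.read_newick("(sp0:1,other:2);")
        with pytest.raises(ValueError, match="sp1"):
            host_patristic_distance_matrix(tree, small_metadata, small_metadata.sample_ids)
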