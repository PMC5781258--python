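import itertools

import numpy as np
import pytest

from coreshift import (DistanceMatrix, OtuTable, pcoa, permanova, rarefy,
                       shannon_index, simulate_tree, weighted_unifrac,
                       within_between_test)


def brute_force_weighted_unifrac(table, tree, normalized=False):
    """Independent per-branch oracle: walk every branch, sum l*|pA-pB|."""
    rel = table.counts / table.counts.sum(axis=0)
    otu_row = {o: i for i, o in enumerate(table.otu_ids)}
    n = table.n_samples
    d = np.zeros((n, n))
    branches = []
    for node in tree.traverse(include_self=False):
        tips = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        rows = [otu_row[t] for t in tips if t in otu_row]
        branches.append((node.length, rel[rows].sum(axis=0)))
    for a, b in itertools.combinations(range(n), 2):
        num = sum(l * abs(p[a] - p[b]) for l, p in branches)
        if normalized:
            den = sum(l * (p[a] + p[b]) for l, p in branches)
            num = num / den if den else 0.0
        d[a, b] = d[b, a] = num
    return d


def _random_table(rng, n_otus, n_samples):
    counts = rng.integers(0, 50, size=(n_otus, n_samples))
    counts[:, counts.sum(axis=0) == 0] += 1
    return OtuTable(counts, [f"O{i}" for i in range(n_otus)],
                    [f"s{j}" for j in range(n_samples)])


class TestRarefy:
    def test_shallow_samples_dropped_and_totals_exact(self):
        rng = np.random.default_rng(0)
        counts = rng.multinomial(1, np.full(10, 0.1), size=0)  # placeholder
        tot = [25_000, 19_000, 10_000]
        counts = np.column_stack([
            np.random.default_rng(i).multinomial(t, np.full(10, 0.1))
            for i, t in enumerate(tot)])
        table = OtuTable(counts, [f"O{i}" for i in range(10)], ["a", "b", "c"])
        out = rarefy(table, 19_000, seed=1)
        assert out.sample_ids == ["a", "b"]
        assert np.all(out.sample_sums() == 19_000)

    def test_sample_at_exact_depth_unchanged(self):
        counts = np.array([[600], [400]])
        table = OtuTable(counts, ["A", "B"], ["s"])
        out = rarefy(table, 1000, seed=0)
        np.testing.assert_array_equal(out.counts, counts)

    def test_expected_counts_are_hypergeometric(self):
        # mean of the without-replacement draw is depth * n_i / N
        counts = np.array([[700], [200], [100]])
        table = OtuTable(counts, ["A", "B", "C"], ["s"])
        depth, reps = 500, 500
        draws = np.array([rarefy(table, depth, seed=s).counts[:, 0]
                          for s in range(reps)])
        expected = depth * counts[:, 0] / counts.sum()
        # hypergeometric variance for the +-3 SE band
        N = counts.sum()
        var = depth * (counts[:, 0] / N) * (1 - counts[:, 0] / N) * (N - depth) / (N - 1)
        se = np.sqrt(var / reps)
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 3 * se + 1e-9)

    def test_all_samples_below_depth_errors(self):
        table = OtuTable(np.array([[5], [5]]), ["A", "B"], ["s"])
        with pytest.raises(ValueError, match="no sample"):
            rarefy(table, 100, seed=0)


class TestShannon:
    def test_uniform_maximum(self):
        assert shannon_index([0.25] * 4, min_frac=0) == pytest.approx(np.log(4))

    def test_single_otu_is_zero(self):
        assert shannon_index([1.0]) == 0.0

    def test_hand_value(self):
        # -(0.5 ln 0.5 + 0.3 ln 0.3 + 0.2 ln 0.2)
        assert shannon_index([0.5, 0.3, 0.2], min_frac=0) == pytest.approx(
            1.02965, abs=1e-4)

    def test_filter_drops_rare_then_renormalizes(self):
        # the 5e-5 OTU is at most min_frac, so H is over the remaining two
        h = shannon_index([0.6, 0.39995, 5e-5], min_frac=1e-4)
        p = np.array([0.6, 0.39995])
        p = p / p.sum()
        assert h == pytest.approx(float(-(p * np.log(p)).sum()))

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            shannon_index([0.0, 0.0])


class TestWeightedUnifrac:
    def test_identical_samples_distance_zero(self):
        tree = simulate_tree(["A", "B", "C"], seed=0)
        counts = np.array([[5, 5], [3, 3], [2, 2]])
        table = OtuTable(counts, ["A", "B", "C"], ["x", "y"])
        dm = weighted_unifrac(table, tree)
        assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_two_tip_opposite_samples(self, tmp_path):
        from coreshift import read_newick
        path = tmp_path / "t.nwk"
        path.write_text("(A:1,B:1):0;\n")
        tree = read_newick(path)
        table = OtuTable(np.array([[10, 0], [0, 10]]), ["A", "B"], ["x", "y"])
        raw = weighted_unifrac(table, tree, normalized=False)
        norm = weighted_unifrac(table, tree, normalized=True)
        assert raw.values[0, 1] == pytest.approx(2.0)
        assert norm.values[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("normalized", [False, True])
    def test_matches_per_branch_oracle_on_random_trees(self, normalized):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n_tips = int(rng.integers(2, 9))
            ids = [f"O{i}" for i in range(n_tips)]
            tree = simulate_tree(ids, seed=int(rng.integers(2**31)))
            table = _random_table(rng, n_tips, 4)
            dm = weighted_unifrac(table, tree, normalized=normalized)
            oracle = brute_force_weighted_unifrac(table, tree, normalized)
            np.testing.assert_allclose(dm.values, oracle, atol=1e-10)

    def test_missing_otu_listed_in_error(self):
        tree = simulate_tree(["A", "B"], seed=0)
        table = OtuTable(np.array([[1], [1], [1]]), ["A", "B", "Z"], ["s"])
        with pytest.raises(ValueError, match="Z"):
            weighted_unifrac(table, tree)

    def test_raw_triangle_inequality_on_synthetic_data(self, default_dataset):
        table, tree, _ = default_dataset
        dm = weighted_unifrac(table, tree)
        d = dm.values
        n = d.shape[0]
        for i, j, k in itertools.combinations(range(n), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestPcoa:
    def test_two_samples_hand_eigendecomposition(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 2.0], [2.0, 0.0]]))
        ord_res = pcoa(dm)
        assert ord_res.coordinates.shape == (2, 1)
        np.testing.assert_allclose(np.abs(ord_res.coordinates[:, 0]), [1, 1])
        assert ord_res.eigenvalues[0] == pytest.approx(2.0)

    def test_collinear_points_recover_line(self):
        vals = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        ord_res = pcoa(DistanceMatrix(["a", "b", "c"], vals))
        x = ord_res.coordinates[:, 0]
        got = np.abs(x - x[0])[1:]
        np.testing.assert_allclose(sorted(got), [1, 2], atol=1e-10)

    def test_euclidean_distances_reproduced(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 3))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        ord_res = pcoa(DistanceMatrix([f"s{i}" for i in range(6)], d))
        back = np.linalg.norm(ord_res.coordinates[:, None]
                              - ord_res.coordinates[None], axis=-1)
        np.testing.assert_allclose(back, d, atol=1e-8)

    def test_matches_skbio_eigenvalues(self):
        import skbio
        from skbio.stats.ordination import pcoa as skbio_pcoa
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(7, 4))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        mine = pcoa(DistanceMatrix([f"s{i}" for i in range(7)], d))
        ref = skbio_pcoa(skbio.DistanceMatrix(d), method="eigh")
        np.testing.assert_allclose(mine.eigenvalues,
                                   ref.eigvals.to_numpy()[:len(mine.eigenvalues)],
                                   atol=1e-8)

    def test_all_zero_matrix_gives_origin(self):
        dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        ord_res = pcoa(dm)
        assert np.allclose(ord_res.coordinates, 0)


def _cluster_dm(rng, centers, per_group):
    pts = np.concatenate([c + 0.05 * rng.normal(size=(per_group, 2))
                          for c in centers])
    d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
    labels = [f"s{i}" for i in range(len(pts))]
    return DistanceMatrix(labels, d), labels


class TestPermanova:
    def test_separated_clusters_f_is_enumeration_maximum(self):
        # 4+4 tight clusters: exhaustive enumeration of all C(8,4) splits
        # confirms F_obs is the maximum; permutations recreating the original
        # split (probability 2*4!4!/8!) reproduce F_obs, so the attainable p
        # is ~0.03, comfortably significant
        from coreshift.diversity import _pseudo_f
        rng = np.random.default_rng(0)
        dm, labels = _cluster_dm(rng, [np.zeros(2), np.full(2, 10.0)], 4)
        grouping = {s: ("g1" if i < 4 else "g2") for i, s in enumerate(labels)}
        f, p = permanova(dm, grouping, n_perm=999, seed=1)
        d2 = dm.values ** 2
        all_f = []
        for combo in itertools.combinations(range(8), 4):
            rest = np.array([i for i in range(8) if i not in combo])
            all_f.append(_pseudo_f(d2, [np.array(combo), rest]))
        assert f == pytest.approx(max(all_f))
        assert p < 0.05
        assert f > 100

    def test_matches_skbio_pseudo_f(self):
        import skbio
        from skbio.stats.distance import permanova as skbio_permanova
        rng = np.random.default_rng(3)
        dm, labels = _cluster_dm(rng, [np.zeros(2), np.ones(2), 2 * np.ones(2)], 4)
        grouping = {s: f"g{i // 4}" for i, s in enumerate(labels)}
        f, _ = permanova(dm, grouping, n_perm=9, seed=0)
        ref = skbio_permanova(skbio.DistanceMatrix(dm.values, ids=labels),
                              [grouping[s] for s in labels], permutations=9)
        assert f == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_single_group_rejected(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            permanova(dm, {"a": "g", "b": "g"})

    def test_null_p_values_are_uniform(self):
        # exchangeable data: p should be uniform on the achievable grid
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(200):
            pts = rng.normal(size=(12, 2))
            d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
            dm = DistanceMatrix([f"s{i}" for i in range(12)], d)
            grouping = {f"s{i}": f"g{i // 6}" for i in range(12)}
            _, p = permanova(dm, grouping, n_perm=99,
                             seed=int(rng.integers(2**31)))
            ps.append(p)
        from scipy import stats
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestWithinBetween:
    def test_displaced_group_is_extreme(self):
        # all between-distances dwarf all within-distances; only assignments
        # recreating one of the two original groups can match |t_obs|, so p
        # sits near 2*5!5!/10! ~ 0.008
        rng = np.random.default_rng(1)
        dm, labels = _cluster_dm(rng, [np.zeros(2), np.full(2, 50.0)], 5)
        t, p = within_between_test(dm, labels[:5], labels[5:], n_perm=999, seed=2)
        assert p < 0.02
        assert t < 0  # within distances smaller than between

    def test_asymmetric_counterpart_differs(self):
        # 2+2 toy: group a tight, group b loose
        vals = np.array([
            [0.0, 1.0, 5.0, 5.0],
            [1.0, 0.0, 5.0, 5.0],
            [5.0, 5.0, 0.0, 9.0],
            [5.0, 5.0, 9.0, 0.0],
        ])
        dm = DistanceMatrix(["a1", "a2", "b1", "b2"], vals)
        t_a, _ = within_between_test(dm, ["a1", "a2"], ["b1", "b2"], 99, seed=0)
        t_b, _ = within_between_test(dm, ["b1", "b2"], ["a1", "a2"], 99, seed=0)
        # hand values: within_a=[1] vs between=[5,5,5,5]; within_b=[9] vs same
        assert t_a < 0 < t_b
        assert t_a != t_b

    def test_overlapping_groups_rejected(self):
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.0]]))
        with pytest.raises(ValueError, match="disjoint"):
            within_between_test(dm, ["a", "b"], ["b", "c"])

    def test_null_type_one_error_near_nominal(self):
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            pts = rng.normal(size=(12, 2))
            d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
            dm = DistanceMatrix([f"s{i}" for i in range(12)], d)
            labels = [f"s{i}" for i in range(12)]
            _, p = within_between_test(dm, labels[:6], labels[6:], n_perm=99,
                                       seed=int(rng.integers(2**31)))
            rejections += p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rejections / n_rep - 0.05) < 3 * se + 0.01
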