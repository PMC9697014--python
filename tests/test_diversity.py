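"""IBS distances, bins, subgroup summaries, PCA, NJ trees, conversions."""

import itertools

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from snpfinger.diversity import (
    DistanceMatrix,
    bin_distances,
    conversion_test,
    distance_matrix,
    ibs_distance,
    nj_tree,
    pca,
    subgroup_distances,
)
from snpfinger.reference import build_reference
from snpfinger.sample_qc import similarity_rate
from snpfinger.simulate import SimulationConfig, simulate_panel

from conftest import build_matrix, random_call_vector, similarity_oracle


def two_cluster_config(seed, F=0.3, n_per=20, n_markers=120):
    return SimulationConfig(
        n_markers=n_markers,
        n_lines={"P1": n_per, "P2": n_per},
        divergence_F={"P1": F, "P2": F},
        maf_range=(0.2, 0.5),
        residual_het=0.0,
        n_replicates=1,
        call_error_rate=0.0,
        missing_rate=0.0,
        seed=seed,
    )


class TestIBSDistance:
    def test_hand_enumeration(self):
        # shares per marker: 2, 1, 1, 2 of 8 alleles -> distance 0.25
        a = build_matrix([["A/A", "A/G", "C/C", "T/T"]]).calls[0]
        b = build_matrix([["A/A", "A/A", "C/T", "T/T"]]).calls[0]
        assert ibs_distance(a, b) == pytest.approx(0.25)

    def test_identical_lines_give_zero(self):
        v = build_matrix([["A/A", "C/C", "G/T"]]).calls[0]
        assert ibs_distance(v, v) == 0.0

    def test_complementary_homozygotes_give_one(self):
        a = build_matrix([["A/A"] * 5], ref_alleles=["A/G"] * 5).calls[0]
        b = build_matrix([["G/G"] * 5], ref_alleles=["A/G"] * 5).calls[0]
        assert ibs_distance(a, b) == 1.0

    def test_complement_of_similarity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = random_call_vector(rng, 15)
            b = random_call_vector(rng, 15)
            if not ((a[:, 0] >= 0) & (b[:, 0] >= 0)).any():
                continue
            assert ibs_distance(a, b) == pytest.approx(1 - similarity_rate(a, b))


class TestDistanceMatrix:
    def test_identical_lines_zero_matrix(self):
        rows = [["A/A", "C/C"]] * 3
        m = build_matrix(rows, lines=[("L1", "R1"), ("L2", "R1"), ("L3", "R1")])
        dm = distance_matrix(m)
        assert np.allclose(dm.values, 0.0)

    def test_matches_double_loop_oracle(self, preset_panel):
        matrix, _ = preset_panel
        sub = matrix.subset(sample_idx=range(10))
        dm = distance_matrix(sub)
        for i, j in itertools.combinations(range(10), 2):
            expected = 1 - similarity_oracle(sub.calls[i], sub.calls[j])
            assert dm.values[i, j] == pytest.approx(expected)

    def test_two_population_panel_between_exceeds_within(self):
        matrix, truth = simulate_panel(two_cluster_config(seed=5))
        dm = distance_matrix(matrix)
        groups = {s.sample_id: s.subgroup for s in matrix.samples}
        table = subgroup_distances(dm, groups)
        pivot = {
            (r.group_a, r.group_b): r.mean_distance for r in table.itertuples()
        }
        assert pivot[("P1", "P2")] > pivot[("P1", "P1")]
        assert pivot[("P1", "P2")] > pivot[("P2", "P2")]

    def test_symmetry_and_range(self, preset_panel):
        matrix, _ = preset_panel
        ref = build_reference(matrix)
        dm = distance_matrix(ref)
        assert np.allclose(dm.values, dm.values.T, equal_nan=True)
        assert np.all(np.diag(dm.values) == 0)
        vals = dm.pair_values()
        assert np.nanmin(vals) >= 0 and np.nanmax(vals) <= 1


class TestBins:
    def test_all_identical_panel_in_zero_bin(self):
        dm = DistanceMatrix(labels=["a", "b", "c"], values=np.zeros((3, 3)))
        bins = bin_distances(dm)
        assert bins.table.iloc[0]["fraction_pct"] == pytest.approx(100.0)
        assert len(bins.zero_pairs) == 3

    def test_hand_counted_fractions(self):
        # 4 lines, distances {0, 0.2, 0.4, 0.4, 0.6, 0.6}
        v = np.array(
            [
                [0.0, 0.0, 0.2, 0.4],
                [0.0, 0.0, 0.4, 0.6],
                [0.2, 0.4, 0.0, 0.6],
                [0.4, 0.6, 0.6, 0.0],
            ]
        )
        dm = DistanceMatrix(labels=list("abcd"), values=v)
        bins = bin_distances(dm, breaks=[0.05, 0.10, 0.30, 0.50])
        fr = bins.table["fraction_pct"].tolist()
        # (0): 1/6; (0.1,0.3]: 1/6; (0.3,0.5]: 2/6; (0.5,1]: 2/6
        assert fr == pytest.approx([100 / 6, 0.0, 100 / 6, 200 / 6, 200 / 6])
        assert bins.zero_pairs == [("a", "b")]
        assert bins.n_pairs_below_guard == 1

    def test_fractions_sum_to_hundred(self, preset_panel):
        matrix, _ = preset_panel
        dm = distance_matrix(build_reference(matrix))
        bins = bin_distances(dm)
        assert bins.table["fraction_pct"].sum() == pytest.approx(100.0)


class TestSubgroupDistances:
    def test_single_pair_mean_is_that_distance(self):
        v = np.array([[0.0, 0.3], [0.3, 0.0]])
        dm = DistanceMatrix(labels=["x", "y"], values=v)
        table = subgroup_distances(dm, {"x": "G1", "y": "G1"})
        assert table.iloc[0]["mean_distance"] == pytest.approx(0.3)

    def test_small_group_within_mean_undefined(self):
        v = np.array([[0.0, 0.3], [0.3, 0.0]])
        dm = DistanceMatrix(labels=["x", "y"], values=v)
        table = subgroup_distances(dm, {"x": "G1", "y": "G2"})
        within = table[(table.group_a == "G1") & (table.group_b == "G1")]
        assert np.isnan(within.iloc[0]["mean_distance"])

    def test_means_match_brute_force(self, preset_panel):
        matrix, _ = preset_panel
        ref = build_reference(matrix)
        dm = distance_matrix(ref)
        groups = {s.line_name: s.subgroup for s in ref.matrix.samples}
        table = subgroup_distances(dm, groups)
        for row in table.itertuples():
            ia = [i for i, l in enumerate(dm.labels) if groups[l] == row.group_a]
            ib = [i for i, l in enumerate(dm.labels) if groups[l] == row.group_b]
            if row.group_a == row.group_b:
                vals = [dm.values[i, j] for i, j in itertools.combinations(ia, 2)]
            else:
                vals = [dm.values[i, j] for i in ia for j in ib]
            if len(vals):
                assert row.mean_distance == pytest.approx(np.nanmean(vals))


class TestPCA:
    def test_duplicated_line_identical_coordinates(self):
        rows = [
            ["A/A", "C/C", "G/G", "T/T"],
            ["A/A", "C/C", "G/G", "T/T"],
            ["A/G", "C/G", "A/G", "A/T"],
        ]
        m = build_matrix(
            rows,
            ref_alleles=["A/G", "C/G", "A/G", "A/T"],
            lines=[("L1", "R1"), ("L2", "R1"), ("L3", "R1")],
        )
        res = pca(m, n_components=2)
        assert np.allclose(
            res.coordinates.iloc[0].values, res.coordinates.iloc[1].values
        )

    def test_pc1_separates_two_clusters(self):
        matrix, _ = simulate_panel(two_cluster_config(seed=6))
        res = pca(matrix, n_components=2)
        pc1 = res.coordinates["PC1"].values
        g = np.array([s.subgroup for s in matrix.samples])
        between = abs(pc1[g == "P1"].mean() - pc1[g == "P2"].mean())
        pooled_sd = np.sqrt(0.5 * (pc1[g == "P1"].var() + pc1[g == "P2"].var()))
        assert between > 2 * pooled_sd

    def test_explained_variance_monotone_and_bounded(self, preset_panel):
        matrix, _ = preset_panel
        res = pca(build_reference(matrix), n_components=5)
        evr = res.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1.0 + 1e-9

    def test_marker_permutation_invariance_up_to_sign(self):
        matrix, _ = simulate_panel(two_cluster_config(seed=8, n_per=10, n_markers=40))
        rng = np.random.default_rng(0)
        perm = rng.permutation(matrix.n_markers)
        res1 = pca(matrix, n_components=2)
        res2 = pca(matrix.subset(marker_idx=perm), n_components=2)
        for c in ("PC1", "PC2"):
            a, b = res1.coordinates[c].values, res2.coordinates[c].values
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_zero_variance_is_error(self):
        rows = [["A/A", "C/C"]] * 3
        m = build_matrix(rows, lines=[("L1", "R1"), ("L2", "R1"), ("L3", "R1")])
        with pytest.raises(ValueError, match="zero variance"):
            pca(m)


def random_additive_tree(rng, n_leaves):
    """Random binary tree with positive branch lengths and its additive
    distance matrix (the oracle for NJ reconstruction)."""
    taxa = [f"T{i}" for i in range(n_leaves)]

    def grow(labels):
        if len(labels) == 1:
            return labels[0]
        k = rng.integers(1, len(labels))
        left, right = labels[:k], labels[k:]
        bl = rng.uniform(0.1, 1.0)
        br = rng.uniform(0.1, 1.0)
        return f"({grow(left)}:{bl:.6f},{grow(right)}:{br:.6f})"

    shuffled = list(rng.permutation(taxa))
    newick = grow(shuffled) + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    ns = tree.taxon_namespace
    D = np.zeros((n_leaves, n_leaves))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i < j:
                d = pdm.distance(ns.get_taxon(a), ns.get_taxon(b))
                D[i, j] = D[j, i] = d
    return taxa, newick, D


def rf_distance(newick_a, newick_b):
    ns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=ns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=ns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return treecompare.symmetric_difference(ta, tb)


class TestNJTree:
    def test_three_taxa_closed_form(self):
        v = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        dm = DistanceMatrix(labels=["a", "b", "c"], values=v)
        tree = nj_tree(dm).tree
        pdm = tree.phylogenetic_distance_matrix()
        ns = tree.taxon_namespace
        for (la, lb), expected in [(("a", "b"), 0.3), (("a", "c"), 0.5), (("b", "c"), 0.6)]:
            d = pdm.distance(ns.get_taxon(la), ns.get_taxon(lb))
            assert d == pytest.approx(expected)

    def test_four_taxon_split_matches_least_squares_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            taxa, newick, D = random_additive_tree(rng, 4)
            dm = DistanceMatrix(labels=taxa, values=D)
            got = nj_tree(dm).newick
            # least-squares over the three unrooted 4-taxon topologies
            topologies = [
                "((T0:1,T1:1):1,(T2:1,T3:1):1);",
                "((T0:1,T2:1):1,(T1:1,T3:1):1);",
                "((T0:1,T3:1):1,(T1:1,T2:1):1);",
            ]
            pairs = list(itertools.combinations(range(4), 2))
            best, best_sse = None, np.inf
            for topo, split in zip(
                topologies, [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
            ):
                # path incidence matrix: 5 edges (4 pendant + internal)
                A = np.zeros((6, 5))
                for r, (i, j) in enumerate(pairs):
                    A[r, i] = A[r, j] = 1
                    same = {i, j} in (set(split[0]), set(split[1]))
                    if not same:
                        A[r, 4] = 1
                y = np.array([D[i, j] for i, j in pairs])
                coef, *_ = np.linalg.lstsq(A, y, rcond=None)
                sse = float(((A @ coef - y) ** 2).sum())
                if sse < best_sse:
                    best, best_sse = topo, sse
            assert rf_distance(got, best) == 0

    def test_additive_matrices_recover_topology(self):
        rng = np.random.default_rng(33)
        for _ in range(15):
            n = int(rng.integers(4, 9))
            taxa, newick, D = random_additive_tree(rng, n)
            got = nj_tree(DistanceMatrix(labels=taxa, values=D)).newick
            assert rf_distance(got, newick) == 0

    def test_matches_independent_nj_implementation(self):
        """Topology agrees with scikit-bio's neighbor joining on a random
        (non-additive) matrix."""
        import io as _io

        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(44)
        n = 7
        M = rng.uniform(0.1, 1.0, size=(n, n))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        labels = [f"T{i}" for i in range(n)]
        ours = nj_tree(DistanceMatrix(labels=labels, values=D)).newick
        theirs = skbio_nj(SkbioDM(D, ids=labels))
        buf = _io.StringIO()
        theirs.write(buf, format="newick")
        assert rf_distance(ours, buf.getvalue()) == 0

    def test_replicate_clusters_form_clades(self):
        cfg = SimulationConfig(
            n_markers=100,
            n_lines={"P1": 5},
            divergence_F={"P1": 0.1},
            residual_het=0.0,
            n_replicates=3,
            call_error_rate=0.005,
            missing_rate=0.01,
            seed=17,
        )
        matrix, _ = simulate_panel(cfg)
        dm = distance_matrix(matrix)
        tree = nj_tree(dm).tree
        tree.encode_bipartitions()
        full = tree.taxon_namespace.all_taxa_bitmask()
        sides = set()
        for e in tree.preorder_edge_iter():
            if e.bipartition is not None:
                sides.add(e.bipartition.leafset_bitmask)
                sides.add(e.bipartition.leafset_bitmask ^ full)
        for line, idx in matrix.line_indices().items():
            mask = 0
            for i in idx:
                t = tree.taxon_namespace.get_taxon(matrix.sample_ids[i])
                mask |= tree.taxon_namespace.taxon_bitmask(t)
            assert mask in sides, f"replicates of {line} not monophyletic"

    def test_degenerate_two_labels(self):
        dm = DistanceMatrix(labels=["a", "b"], values=np.array([[0, 0.4], [0.4, 0]]))
        with pytest.warns(UserWarning, match="degenerate"):
            t = nj_tree(dm)
        assert "a" in t.newick and "b" in t.newick


class TestConversionTest:
    def test_identical_pair_zero_and_flagging(self):
        v = np.array([[0.0, 0.0, 0.45], [0.0, 0.0, 0.45], [0.45, 0.45, 0.0]])
        dm = DistanceMatrix(labels=["parent", "conv", "other"], values=v)
        table = conversion_test([("parent", "conv"), ("parent", "other")], dm)
        assert table.iloc[0]["distance"] == 0.0
        assert not table.iloc[0]["exceeds_threshold"]
        assert table.iloc[1]["exceeds_threshold"]

    def test_missing_line_reported(self):
        dm = DistanceMatrix(labels=["a", "b"], values=np.array([[0, 0.1], [0.1, 0]]))
        table = conversion_test([("a", "zzz")], dm)
        assert table.iloc[0]["status"].startswith("MISSING")
        assert np.isnan(table.iloc[0]["distance"])

    def test_simulated_conversions_near_parent(self, preset_panel):
        matrix, truth = preset_panel
        ref = build_reference(matrix)
        dm = distance_matrix(ref)
        pairs = [
            (row.conversion_of, row.line_name)
            for row in truth.lines.itertuples()
            if row.conversion_of
        ]
        table = conversion_test(pairs, dm)
        panel_mean = np.nanmean(dm.pair_values())
        assert (table["distance"] < 0.15).all()
        assert (table["distance"] < panel_mean / 2).all()
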