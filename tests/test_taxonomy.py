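import numpy as np
import pandas as pd
import pytest

from spectrotype.errors import ParameterError, ValidationError
from spectrotype.library import MainSpectrum
from spectrotype.taxonomy import (
    binary_matrix,
    bootstrap_support,
    compare_topology,
    mean_character_distance,
    missing_truth_clades,
    upgma,
)


def msp(label, bins):
    bins = np.asarray(sorted(bins), dtype=int)
    return MainSpectrum(label, "strain", bins, np.ones(bins.size), np.ones(bins.size), 2)


def brute_force_upgma(dist, labels):
    """Independent oracle: cluster distances recomputed each step as plain
    means over the ORIGINAL pairwise entries (no incremental update)."""
    dist = np.asarray(dist, dtype=float)
    clusters = {i: frozenset([i]) for i in range(len(labels))}
    merges = {}
    next_id = len(labels)
    while len(clusters) > 1:
        best = None
        for i in clusters:
            for j in clusters:
                if i >= j:
                    continue
                d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                tag_i = min(labels[k] for k in clusters[i])
                tag_j = min(labels[k] for k in clusters[j])
                lo, hi = sorted((tag_i, tag_j))
                cand = (d, lo, hi, i, j)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        d, _, _, i, j = best
        members = clusters.pop(i) | clusters.pop(j)
        merges[frozenset(labels[k] for k in members)] = d / 2.0
        clusters[next_id] = members
        next_id += 1
    return merges


def tree_clade_heights(tree):
    out = {}
    stack = [tree]
    while stack:
        node = stack.pop()
        if node.children:
            out[frozenset(node.leaf_names())] = node.height
            stack.extend(node.children)
    return out


class TestBinaryMatrix:
    def test_hand_coding(self):
        m = binary_matrix([msp("A", [5000]), msp("B", [5000, 6000])])
        frame = m.to_frame()
        assert list(frame.columns) == [5000, 6000]
        assert frame.loc["A"].tolist() == [1, 0]
        assert frame.loc["B"].tolist() == [1, 1]

    def test_identical_msps_identical_rows(self):
        m = binary_matrix([msp("A", [4000, 9000]), msp("B", [4000, 9000])])
        assert (m.cells[0] == m.cells[1]).all()

    def test_single_taxon_rejected(self):
        with pytest.raises(ValidationError):
            binary_matrix([msp("A", [5000])])

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            binary_matrix([msp("A", [5000]), msp("A", [6000])])


class TestMeanCharacterDistance:
    def test_hand_hamming(self):
        m = binary_matrix([msp("A", [4000, 6000]), msp("B", [4000, 7000])])
        # characters: 4000, 6000, 7000 -> rows 110 vs 101 differ in 2 of 3
        d = mean_character_distance(m)
        assert d.loc["A", "B"] == pytest.approx(2 / 3)

    def test_identical_rows_zero(self):
        m = binary_matrix([msp("A", [4000]), msp("B", [4000]), msp("C", [5000])])
        d = mean_character_distance(m)
        assert d.loc["A", "B"] == 0.0

    def test_complementary_rows_one(self):
        m = binary_matrix([msp("A", [4000, 5000]), msp("B", [6000, 7000])])
        assert mean_character_distance(m).loc["A", "B"] == 1.0


class TestUPGMA:
    def test_three_taxon_hand_example(self):
        d = pd.DataFrame(
            [[0, 2, 6], [2, 0, 6], [6, 6, 0]], index=list("ABC"), columns=list("ABC"),
            dtype=float,
        )
        tree = upgma(d)
        heights = tree_clade_heights(tree)
        assert heights[frozenset("AB")] == pytest.approx(1.0)
        assert heights[frozenset("ABC")] == pytest.approx(3.0)

    def test_all_equal_distances_ultrametric(self):
        n = 5
        d = np.full((n, n), 4.0)
        np.fill_diagonal(d, 0.0)
        tree = upgma(d, list("ABCDE"))
        depths = []

        def walk(node, acc):
            if not node.children:
                depths.append(acc + node.length)
            for c in node.children:
                walk(c, acc + node.length)

        walk(tree, 0.0)
        assert max(depths) - min(depths) < 1e-6

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            n = int(rng.integers(3, 7))
            labels = [f"T{i}" for i in range(n)]
            x = rng.random((n, n))
            d = (x + x.T) / 2
            np.fill_diagonal(d, 0.0)
            mine = tree_clade_heights(upgma(d, labels))
            oracle = brute_force_upgma(d, labels)
            assert set(mine) == set(oracle)
            for clade, h in oracle.items():
                assert mine[clade] == pytest.approx(h, abs=1e-9)

    def test_matches_scipy_average_linkage_heights(self):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(4)
        x = rng.random((6, 6))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = upgma(d, list("ABCDEF"))
        heights = sorted(tree_clade_heights(tree).values())
        scipy_heights = sorted(average(squareform(d))[:, 2] / 2.0)
        np.testing.assert_allclose(heights, scipy_heights, atol=1e-12)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValidationError):
            upgma(np.array([[0.0, np.nan], [np.nan, 0.0]]), ["A", "B"])
        with pytest.raises(ValidationError):
            upgma(np.array([[0.0, -1.0], [-1.0, 0.0]]), ["A", "B"])
        with pytest.raises(ValidationError):
            upgma(np.array([[0.0, 1.0], [2.0, 0.0]]), ["A", "B"])


class TestBootstrap:
    def test_identical_rows_get_full_support(self):
        msps = [msp("A", [4000, 5000]), msp("B", [4000, 5000]),
                msp("C", [9000, 11000, 13000])]
        tree = bootstrap_support(binary_matrix(msps), n_reps=50, seed=0)
        supports = {
            frozenset(n.leaf_names()): n.support
            for n in _internal_nodes(tree) if n.support is not None
        }
        assert supports[frozenset("AB")] == 100.0

    def test_single_replicate_supports_are_binary(self):
        msps = [msp("A", [4000]), msp("B", [4000, 6000]), msp("C", [9000]),
                msp("D", [9000, 11000])]
        tree = bootstrap_support(binary_matrix(msps), n_reps=1, seed=3)
        for node in _internal_nodes(tree):
            if node.support is not None:
                assert node.support in (0.0, 100.0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(9)
        msps = [msp(f"T{i}", rng.choice(np.arange(4000, 8000, 25), 8, replace=False))
                for i in range(5)]
        t1 = bootstrap_support(binary_matrix(msps), n_reps=100, seed=42)
        t2 = bootstrap_support(binary_matrix(msps), n_reps=100, seed=42)
        s1 = sorted(n.support for n in _internal_nodes(t1) if n.support is not None)
        s2 = sorted(n.support for n in _internal_nodes(t2) if n.support is not None)
        assert s1 == s2

    def test_true_clades_outscore_random_groupings(self):
        # two tight pairs plus noise characters: the true pairs' mean support
        # must exceed the support any other grouping could attain
        rng = np.random.default_rng(14)
        base = {"A1": [4000, 4100, 4200], "A2": [4000, 4100, 4200],
                "B1": [9000, 9100, 9200], "B2": [9000, 9100, 9200]}
        msps = []
        for label, bins in base.items():
            noise = rng.choice(np.arange(6000, 7000, 25), 2, replace=False)
            msps.append(msp(label, list(bins) + list(noise)))
        tree = bootstrap_support(binary_matrix(msps), n_reps=200, seed=7)
        supports = {
            frozenset(n.leaf_names()): n.support
            for n in _internal_nodes(tree) if n.support is not None
        }
        true_pairs = [frozenset({"A1", "A2"}), frozenset({"B1", "B2"})]
        assert all(supports.get(p, 0.0) > 50.0 for p in true_pairs)

    def test_too_few_taxa(self):
        with pytest.raises(ParameterError):
            bootstrap_support(binary_matrix([msp("A", [4000]), msp("B", [5000])]), 10)


def _internal_nodes(tree):
    out = []
    stack = [tree]
    while stack:
        node = stack.pop()
        if node.children:
            out.append(node)
            stack.extend(node.children)
    return out


class TestCompareTopology:
    def test_tree_vs_itself(self):
        d = np.array([[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 3], [6, 6, 3, 0.0]])
        t = upgma(d, list("ABCD"))
        assert compare_topology(t, t)["rf_distance"] == 0

    def test_four_taxon_alternative_topologies(self):
        d1 = np.array([[0, 1, 6, 6], [1, 0, 6, 6], [6, 6, 0, 1], [6, 6, 1, 0.0]])
        d2 = np.array([[0, 6, 1, 6], [6, 0, 6, 1], [1, 6, 0, 6], [6, 1, 6, 0.0]])
        ta = upgma(d1, list("ABCD"))  # ((A,B),(C,D))
        tb = upgma(d2, list("ABCD"))  # ((A,C),(B,D))
        result = compare_topology(ta, tb)
        assert result["rf_distance"] == 2
        assert result["shared_bipartitions"] == 0

    def test_agrees_with_dendropy_rf(self):
        import dendropy

        from spectrotype.spectrum_io import write_newick

        rng = np.random.default_rng(2)
        trees = []
        for _ in range(2):
            x = rng.random((6, 6))
            d = (x + x.T) / 2
            np.fill_diagonal(d, 0.0)
            trees.append(upgma(d, list("ABCDEF")))
        mine = compare_topology(trees[0], trees[1])["rf_distance"]
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=write_newick(trees[0]), schema="newick",
                               taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=write_newick(trees[1]), schema="newick",
                               taxon_namespace=tns)
        oracle = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert mine == oracle

    def test_leaf_mismatch_listed(self):
        t1 = upgma(np.array([[0.0, 2.0], [2.0, 0.0]]), ["A", "B"])
        t2 = upgma(np.array([[0.0, 2.0], [2.0, 0.0]]), ["A", "C"])
        with pytest.raises(ValidationError, match="C"):
            compare_topology(t1, t2)


class TestTaxonomyRecovery:
    def test_low_noise_fingerprints_recover_truth(self):
        from spectrotype.library import build_main_spectrum
        from spectrotype.synthetic_data import NoiseModel, make_taxonomy, simulate_replicates

        low_noise = NoiseModel(mz_jitter_sd=0.1, intensity_cv_technical=0.02,
                               intensity_cv_biological=0.05, noise_sd=0.0)
        templates, truth = make_taxonomy(2, 2, 2, seed=31)
        msps = []
        for i, t in enumerate(templates):
            reps = simulate_replicates(t, noise=low_noise, seed=100 + i)
            msps.append(build_main_spectrum(reps, label=t.strain,
                                            genus=t.genus, species=t.species))
        tree = upgma(mean_character_distance(binary_matrix(msps)))
        assert missing_truth_clades(tree, truth) == 0
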