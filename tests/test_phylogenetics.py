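"""Distances, NJ reconstruction (with independent oracles), bootstrap, monophyly."""

import numpy as np
import pytest

from ervscribe import phylogenetics as ph
from ervscribe import synthetic_data as sd


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGTACGT", "ACGTACGT", 0.0),
            ("ACGT", "ACGA", 0.25),
            ("A-CT", "AGCT", 0.0),  # pairwise deletion: 0 mismatches over 3 sites
        ],
    )
    def test_hand_counts(self, a, b, expected):
        dm = ph.p_distance_matrix({"x": a, "y": b})
        assert dm.matrix[0, 1] == pytest.approx(expected)

    def test_all_gap_pair_flagged_undefined(self):
        dm = ph.p_distance_matrix({"x": "AC--", "y": "--GT"})
        assert np.isnan(dm.matrix[0, 1])
        assert ("x", "y") in dm.undefined_pairs

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(4)
        msa = {f"t{i}": sd.random_sequence(300, rng) for i in range(6)}
        dm = ph.p_distance_matrix(msa)
        off = dm.matrix[~np.eye(6, dtype=bool)]
        assert ((off >= 0) & (off <= 1)).all()


class TestK2P:
    def test_zero_distance_for_identical(self):
        dm = ph.k2p_distance_matrix({"x": "ACGT" * 10, "y": "ACGT" * 10})
        assert dm.matrix[0, 1] == 0.0

    def test_pure_transition_closed_form(self):
        # 10 A->G transitions over 100 sites: P=0.1, Q=0 -> -ln(0.8)/2
        msa = {"x": "A" * 100, "y": "G" * 10 + "A" * 90}
        dm = ph.k2p_distance_matrix(msa)
        assert dm.matrix[0, 1] == pytest.approx(-0.5 * np.log(0.8))

    def test_formula_with_both_classes(self):
        # P=0.3, Q=0.2: log arguments positive, value per formula
        x = "A" * 100
        y = "G" * 30 + "C" * 20 + "A" * 50
        dm = ph.k2p_distance_matrix({"x": x, "y": y})
        expected = -0.5 * np.log(1 - 0.6 - 0.2) - 0.25 * np.log(1 - 0.4)
        assert dm.matrix[0, 1] == pytest.approx(expected)

    def test_saturated_pair_flagged(self):
        # P=0.45, Q=0.2: 1-2P-Q < 0
        y = "G" * 45 + "C" * 20 + "A" * 35
        dm = ph.k2p_distance_matrix({"x": "A" * 100, "y": y})
        assert np.isnan(dm.matrix[0, 1])

    def test_k2p_at_least_p_distance(self):
        rng = np.random.default_rng(5)
        ref = sd.build_ancestral_provirus(seed=60)
        cfg = sd.SimulationConfig(seed=61)
        msa = {
            f"t{i}": sd.evolve_sequence(ref.sequence[:1000], 30.0, cfg, rng)
            for i in range(5)
        }
        p = ph.p_distance_matrix(msa).matrix
        k = ph.k2p_distance_matrix(msa).matrix
        mask = ~np.isnan(k) & ~np.eye(5, dtype=bool)
        assert (k[mask] >= p[mask] - 1e-12).all()


def _random_additive_tree(labels, rng):
    """Independent oracle: random binary topology with positive branch lengths.

    Returns (splits, distances): the set of non-trivial bipartitions
    (canonical: side not containing the first-sorted label) and the
    leaf-to-leaf path-length matrix, both computed by direct recursion with
    no shared code with the NJ implementation.
    """
    nodes = [(lab,) for lab in labels]
    edges = {}  # node (tuple of leaves) -> list of (child, branch length)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = tuple(sorted(a + b))
        edges[parent] = [
            (a, float(rng.uniform(0.05, 1.0))),
            (b, float(rng.uniform(0.05, 1.0))),
        ]
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    # connect the last two subtrees by a single edge
    root_edge = float(rng.uniform(0.05, 1.0))

    def leaf_depths(node, acc):
        if node not in edges:
            return {node[0]: acc}
        out = {}
        for child, w in edges[node]:
            out.update(leaf_depths(child, acc + w))
        return out

    left, right = nodes
    dl, dr = leaf_depths(left, 0.0), leaf_depths(right, 0.0)

    dist = {}
    def within(node):
        if node not in edges:
            return
        (a, wa), (b, wb) = edges[node]
        da, db = leaf_depths(a, wa), leaf_depths(b, wb)
        for la, va in da.items():
            for lb, vb in db.items():
                dist[frozenset((la, lb))] = va + vb
        within(a)
        within(b)

    within(left)
    within(right)
    for la, va in dl.items():
        for lb, vb in dr.items():
            dist[frozenset((la, lb))] = va + vb + root_edge

    ref = min(labels)
    splits = set()
    def collect(node):
        if node not in edges:
            return
        side = set(node)
        if 2 <= len(side) <= len(labels) - 2:
            canonical = frozenset(set(labels) - side) if ref in side else frozenset(side)
            splits.add(canonical)
        for child, _ in edges[node]:
            collect(child)

    collect(left)
    collect(right)
    matrix = np.zeros((len(labels), len(labels)))
    for x, la in enumerate(labels):
        for y, lb in enumerate(labels):
            if x != y:
                matrix[x, y] = dist[frozenset((la, lb))]
    return splits, matrix


class TestNeighborJoining:
    def test_quartet_recovered_with_internal_branch(self):
        m = np.array(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], dtype=float
        )
        tree = ph.neighbor_joining(ph.DistanceMatrix(["A", "B", "C", "D"], m, "p_distance"))
        mono, _ = ph.is_monophyletic(tree, {"A", "B"})
        assert mono
        assert tree.path_distance("A", "B") == pytest.approx(2.0)
        assert tree.path_distance("A", "C") == pytest.approx(3.0)

    def test_three_taxa_closed_form(self):
        m = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = ph.neighbor_joining(ph.DistanceMatrix(["A", "B", "C"], m, "p_distance"))
        # v_A = (dAB + dAC - dBC)/2 = 1, v_B = 2, v_C = 3
        assert tree.path_distance("A", "B") == pytest.approx(3.0)
        assert tree.path_distance("A", "C") == pytest.approx(4.0)
        assert tree.path_distance("B", "C") == pytest.approx(5.0)

    def test_recovers_random_additive_trees_exactly(self):
        rng = np.random.default_rng(12)
        labels = [f"T{i}" for i in range(8)]
        for _ in range(20):
            splits, matrix = _random_additive_tree(labels, rng)
            tree = ph.neighbor_joining(ph.DistanceMatrix(list(labels), matrix, "p_distance"))
            assert set(tree.bipartitions()) == splits
            for x in range(8):
                for y in range(x + 1, 8):
                    assert tree.path_distance(labels[x], labels[y]) == pytest.approx(
                        matrix[x, y], abs=1e-9
                    )

    def test_matches_dendropy_on_simulated_alignment(self):
        dendropy = pytest.importorskip("dendropy")
        import io

        ref = sd.build_ancestral_provirus(seed=70)
        cfg = sd.SimulationConfig(seed=71)
        rng = np.random.default_rng(71)
        msa = {
            f"t{i}": sd.evolve_sequence(ref.sequence[:1500], float(a), cfg, rng)
            for i, a in enumerate(rng.uniform(5, 60, 7))
        }
        dm = ph.p_distance_matrix(msa)
        mine = ph.neighbor_joining(dm)
        header = "s," + ",".join(dm.labels)
        rows = [
            dm.labels[i] + "," + ",".join(str(x) for x in dm.matrix[i])
            for i in range(len(dm.labels))
        ]
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=io.StringIO(header + "\n" + "\n".join(rows) + "\n"), delimiter=","
        )
        ref_taxon = min(dm.labels)
        oracle_splits = set()
        dtree = pdm.nj_tree()
        all_taxa = set(dm.labels)
        for edge in dtree.preorder_edge_iter():
            head = edge.head_node
            leaves = {lf.taxon.label for lf in head.leaf_iter()}
            if 2 <= len(leaves) <= len(all_taxa) - 2:
                canonical = (
                    frozenset(all_taxa - leaves) if ref_taxon in leaves else frozenset(leaves)
                )
                oracle_splits.add(canonical)
        assert set(mine.bipartitions()) == oracle_splits

    def test_undefined_entries_rejected(self):
        m = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError):
            ph.neighbor_joining(ph.DistanceMatrix(["a", "b", "c"], m, "p_distance"))

    def test_newick_is_parseable_and_complete(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(13)
        labels = [f"T{i}" for i in range(6)]
        _, matrix = _random_additive_tree(labels, rng)
        tree = ph.neighbor_joining(ph.DistanceMatrix(labels, matrix, "p_distance"))
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert {lf.taxon.label for lf in parsed.leaf_node_iter()} == set(labels)


@pytest.fixture(scope="module")
def split_msa():
    """Two clades separated by a deep split."""
    ref = sd.build_ancestral_provirus(seed=80)
    cfg = sd.SimulationConfig(seed=81)
    rng = np.random.default_rng(81)
    deep_a = sd.evolve_sequence(ref.sequence[:1200], 120.0, cfg, rng)
    deep_b = sd.evolve_sequence(ref.sequence[:1200], 120.0, cfg, rng)
    msa = {}
    for i in range(4):
        msa[f"a{i}"] = sd.evolve_sequence(deep_a, 10.0, cfg, rng)
        msa[f"b{i}"] = sd.evolve_sequence(deep_b, 10.0, cfg, rng)
    return msa


class TestBootstrap:
    def test_deep_split_strongly_supported(self, split_msa):
        tree = ph.bootstrap_support(split_msa, replicates=100, seed=3)
        mono, support = ph.is_monophyletic(tree, [k for k in split_msa if k.startswith("a")])
        assert mono and support >= 95.0

    def test_single_replicate_supports_are_binary(self, split_msa):
        tree = ph.bootstrap_support(split_msa, replicates=1, seed=3)
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_fixed_seed_reproducible(self, split_msa):
        s1 = ph.bootstrap_support(split_msa, replicates=50, seed=9).supports
        s2 = ph.bootstrap_support(split_msa, replicates=50, seed=9).supports
        assert s1 == s2

    def test_supports_invariant_under_taxon_order(self, split_msa):
        shuffled = dict(reversed(list(split_msa.items())))
        s1 = ph.bootstrap_support(split_msa, replicates=50, seed=9).supports
        s2 = ph.bootstrap_support(shuffled, replicates=50, seed=9).supports
        assert s1 == s2


@pytest.fixture(scope="module")
def quartet():
    m = np.array(
        [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], dtype=float
    )
    return ph.neighbor_joining(
        ph.DistanceMatrix(["H1", "H2", "O1", "O2"], m, "p_distance")
    )


class TestMonophyly:
    def test_true_clade(self, quartet):
        assert ph.is_monophyletic(quartet, {"H1", "H2"})[0]

    def test_split_pair_is_not_clade(self, quartet):
        assert not ph.is_monophyletic(quartet, {"H1", "O1"})[0]

    def test_unknown_taxon_rejected(self, quartet):
        with pytest.raises(KeyError):
            ph.is_monophyletic(quartet, {"H1", "nope"})

    def test_trivial_subset_rejected(self, quartet):
        with pytest.raises(ValueError):
            ph.is_monophyletic(quartet, {"H1"})
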