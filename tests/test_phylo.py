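"""Distance matrices, neighbor joining vs oracles, bootstrap supports."""

import numpy as np
import pytest

from exaptscan import dating, phylo, simulate
from exaptscan.dating import MultipleAlignment


def _additive_matrix_5taxa(rng):
    """Random additive 5-taxon matrix from tree ((A,B),(C,D),E) by path sums.

    Branch lengths are drawn positive; the generating internal
    bipartitions are {A,B} and {C,D} (modulo the E placement).
    """
    L = {k: float(rng.uniform(0.5, 3.0)) for k in
         ("A", "B", "C", "D", "E", "ab", "cd")}
    names = ["A", "B", "C", "D", "E"]
    # unrooted tree: internal node u joins (A, B), v joins (C, D),
    # E hangs off the central node r on the u - r - v path
    side = {"A": "u", "B": "u", "C": "v", "D": "v", "E": "r"}

    def path(x, y):
        d = L[x] + L[y]
        if side[x] == side[y]:
            return d
        if "u" in (side[x], side[y]):
            d += L["ab"]
        if "v" in (side[x], side[y]):
            d += L["cd"]
        return d

    m = np.zeros((5, 5))
    for i, x in enumerate(names):
        for j, y in enumerate(names):
            if i < j:
                m[i, j] = m[j, i] = path(x, y)
    return names, m


class TestDistanceMatrix:
    def test_identical_members_zero(self):
        msa = MultipleAlignment([("a", "ACGT"), ("b", "ACGT"), ("c", "ACGT")])
        dm = phylo.distance_matrix(msa)
        assert np.allclose(dm.matrix, 0.0)

    def test_entries_are_corrected_p_distances(self):
        msa = MultipleAlignment(
            [("a", "AAAAAAAAAA"), ("b", "AAAAAAAAAC"), ("c", "AAAAAAAACC")]
        )
        dm = phylo.distance_matrix(msa, model="JC")
        p, _ = dating.p_distance("AAAAAAAAAA", "AAAAAAAAAC")
        assert dm.matrix[0, 1] == pytest.approx(dating.jc_distance(p))

    def test_saturated_pair_named(self):
        msa = MultipleAlignment(
            [("x", "AAAA"), ("y", "CCCC"), ("z", "AAAA")]
        )
        with pytest.raises(dating.UndefinedDistanceError, match="x.*y"):
            phylo.distance_matrix(msa)

    def test_star_phylogeny_near_equal_distances(self):
        """Equal-age decay from one ancestor gives low dispersion at 5 kb."""
        te = simulate.generate_te_consensus(5000, 0, seed=15)
        members = [
            (f"t{k}", simulate.evolve_copy(te, 0.03, seed=k)[0].sequence)
            for k in range(6)
        ]
        dm = phylo.distance_matrix(MultipleAlignment(members))
        off = dm.matrix[np.triu_indices(6, 1)]
        assert off.std() / off.mean() < 0.2


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        """((A:1,B:2):1,(C:3,D:1)) rebuilt exactly from its path-sum matrix."""
        names = ["A", "B", "C", "D"]
        m = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float
        )
        tree = phylo.neighbor_joining(phylo.DistanceMatrix(names, m))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        # leaf branch lengths recovered exactly
        lengths = {}

        def walk(node):
            for child, L in node.children:
                if not child.children:
                    lengths[child.name] = L
                walk(child)

        walk(tree.root)
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 1.0}

    def test_three_taxa_closed_form(self):
        names = ["a", "b", "c"]
        m = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        tree = phylo.neighbor_joining(phylo.DistanceMatrix(names, m))
        lengths = {c.name: L for c, L in tree.root.children}
        assert lengths["a"] == pytest.approx(0.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_recovers_100_seeded_additive_topologies(self):
        """NJ equals the generating topology for 100 additive 5-taxon matrices."""
        expected = {frozenset({"C", "D"}), frozenset({"C", "D", "E"})}
        rng = np.random.default_rng(17)
        for _ in range(100):
            names, m = _additive_matrix_5taxa(rng)
            tree = phylo.neighbor_joining(phylo.DistanceMatrix(names, m))
            assert tree.bipartitions() == expected

    def test_agrees_with_external_nj_on_random_matrices(self):
        """Cross-check topology against scikit-bio's neighbor joining."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(23)
        for _ in range(10):
            names, m = _additive_matrix_5taxa(rng)
            ours = phylo.neighbor_joining(phylo.DistanceMatrix(names, m))
            theirs = skbio_nj(SkbioDM(m, ids=names))
            their_bps = set()
            for node in theirs.non_tips():
                side = frozenset(t.name for t in node.tips())
                if 2 <= len(side) <= 3:
                    if names[0] in side:
                        side = frozenset(set(names) - side)
                    their_bps.add(side)
            assert ours.bipartitions() == their_bps

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError):
            phylo.DistanceMatrix(["a", "b", "c"], m)


@pytest.fixture(scope="module")
def two_clade_msa():
    rng = np.random.default_rng(31)
    root = simulate._random_seq(rng, 600, 0.5)
    anc_a = simulate.evolve_copy(root, 0.12, seed=1)[0].sequence
    anc_b = simulate.evolve_copy(root, 0.12, seed=2)[0].sequence
    members = [
        (f"a{i}", simulate.evolve_copy(anc_a, 0.02, seed=3 + i)[0].sequence)
        for i in range(3)
    ] + [
        (f"b{i}", simulate.evolve_copy(anc_b, 0.02, seed=13 + i)[0].sequence)
        for i in range(3)
    ]
    return MultipleAlignment(members)


class TestBootstrap:
    def test_strong_split_gets_high_support(self, two_clade_msa):
        tree = phylo.bootstrap(two_clade_msa, n_reps=100, seed=7)
        split = frozenset({"b0", "b1", "b2"})
        assert split in tree.supports
        assert tree.supports[split] >= 95

    def test_single_replicate_supports_are_binary(self, two_clade_msa):
        tree = phylo.bootstrap(two_clade_msa, n_reps=1, seed=3)
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_deterministic_per_seed(self, two_clade_msa):
        t1 = phylo.bootstrap(two_clade_msa, n_reps=50, seed=11)
        t2 = phylo.bootstrap(two_clade_msa, n_reps=50, seed=11)
        assert t1.supports == t2.supports
        assert t1.newick() == t2.newick()

    def test_supports_bounded_and_taxon_order_invariant(self, two_clade_msa):
        t1 = phylo.bootstrap(two_clade_msa, n_reps=60, seed=5)
        assert all(0 <= v <= 100 for v in t1.supports.values())
        shuffled = MultipleAlignment(two_clade_msa.members[::-1])
        t2 = phylo.bootstrap(shuffled, n_reps=60, seed=5)
        # canonicalize both support maps against a fixed reference taxon
        all_names = set(two_clade_msa.names())

        def canon(tree):
            out = {}
            for bp, v in tree.supports.items():
                side = frozenset(all_names - bp) if "a0" in bp else bp
                out[side] = v
            return set(out)

        assert canon(t1) == canon(t2)

    def test_newick_is_parseable(self, two_clade_msa):
        dendropy = pytest.importorskip("dendropy")
        tree = phylo.bootstrap(two_clade_msa, n_reps=20, seed=9)
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert {t.taxon.label for t in parsed.leaf_node_iter()} == set(
            two_clade_msa.names()
        )
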