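import random

import networkx as nx
import numpy as np
import pytest

import barcodegap as bg
from barcodegap.errors import LabelingError, TrivialTreeError

from conftest import random_alignment


def random_additive_tree(rng: random.Random, n: int):
    """Random unrooted binary tree with positive branch lengths, built as a
    networkx graph (independent of the package's tree machinery).

    Returns (graph, leaf names, distance matrix, set of non-trivial
    bipartitions canonicalised away from leaf 'L0')."""
    G = nx.Graph()
    leaves = [f"L{i}" for i in range(n)]
    G.add_edge(leaves[0], leaves[1], length=rng.uniform(0.05, 1.0))
    internal = 0
    for leaf in leaves[2:]:
        u, v = random.Random(rng.random()).choice(list(G.edges()))
        w = G[u][v]["length"]
        G.remove_edge(u, v)
        mid = f"I{internal}"
        internal += 1
        split = rng.uniform(0.2, 0.8) * w
        G.add_edge(u, mid, length=split)
        G.add_edge(mid, v, length=w - split)
        G.add_edge(mid, leaf, length=rng.uniform(0.05, 1.0))
    D = np.zeros((n, n))
    paths = dict(nx.all_pairs_dijkstra_path_length(G, weight="length"))
    for i in range(n):
        for j in range(n):
            D[i, j] = paths[leaves[i]][leaves[j]]
    # bipartitions: removing each internal edge splits the leaves
    bips = set()
    for u, v in G.edges():
        H = G.copy()
        H.remove_edge(u, v)
        side = frozenset(l for l in leaves if nx.has_path(H, leaves[0], l))
        other = frozenset(leaves) - side
        if 2 <= len(other) <= n - 2:
            bips.add(other)
    return G, leaves, D, bips


class TestNJ:
    def test_three_taxa_three_point_lengths(self):
        d = np.array([[0.0, 0.3, 0.4], [0.3, 0.0, 0.5], [0.4, 0.5, 0.0]])
        dm = bg.DistanceMatrix(ids=["a", "b", "c"], d=d)
        tree = bg.nj(dm)
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.3)

    def test_additive_four_taxon_split_and_internal_length(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> split AB|CD, internal branch 1
        d = np.array(
            [
                [0.0, 3.0, 5.0, 6.0],
                [3.0, 0.0, 6.0, 7.0],
                [5.0, 6.0, 0.0, 7.0],
                [6.0, 7.0, 7.0, 0.0],
            ],
            dtype=float,
        )
        dm = bg.DistanceMatrix(ids=list("ABCD"), d=d)
        tree = bg.nj(dm)
        bips = tree.bipartitions()
        assert set(bips) == {frozenset({"C", "D"})}
        internal = bips[frozenset({"C", "D"})]
        assert internal.length == pytest.approx(1.0)
        patristic = tree.distance_matrix()
        assert np.allclose(patristic.submatrix(list("ABCD")).d, d)

    def test_too_few_taxa(self):
        dm = bg.DistanceMatrix(ids=["a", "b"], d=np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(TrivialTreeError):
            bg.nj(dm)

    def test_permutation_equivariance(self):
        rng = random.Random(3)
        _, leaves, D, bips = random_additive_tree(rng, 7)
        dm = bg.DistanceMatrix(ids=leaves, d=D)
        t1 = bg.nj(dm)
        perm = list(range(7))
        random.Random(0).shuffle(perm)
        dmp = bg.DistanceMatrix(
            ids=[leaves[k] for k in perm], d=D[np.ix_(perm, perm)]
        )
        t2 = bg.nj(dmp)

        def canon(tree):
            full = frozenset(leaves)
            out = set()
            for s in tree.bipartitions():
                out.add(min(s, full - s, key=lambda x: sorted(x)))
            return out

        assert canon(t1) == canon(t2)

    def test_matches_scikit_bio_on_random_matrix(self):
        """Independent cross-check: same topology as skbio's classic NJ on
        a noisy (non-additive) matrix."""
        import skbio

        rng = np.random.default_rng(12)
        _, leaves, D, _ = random_additive_tree(random.Random(12), 8)
        D = D + rng.uniform(0, 0.02, D.shape)
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        mine = bg.nj(bg.DistanceMatrix(ids=leaves, d=D), clamp=False)
        ref = skbio.tree.nj(skbio.DistanceMatrix(D, ids=leaves))
        full = frozenset(leaves)

        def canon_sides(sides):
            return {
                min(s, full - s, key=lambda x: sorted(x))
                for s in sides
                if 2 <= len(s) <= len(leaves) - 2
            }

        ref_sides = []
        for node in ref.non_tips(include_self=False):
            ref_sides.append(frozenset(t.name for t in node.tips()))
        assert canon_sides(set(mine.bipartitions())) == canon_sides(set(ref_sides))


class TestBootstrap:
    @staticmethod
    def _two_cluster_alignment(n_fixed=60, L=573, seed=0):
        """Two 4-taxon clusters separated by n_fixed fixed transversions.

        Each specimen carries a distinct number of private substitutions
        (i + 1 for the i-th member) at distinct positions, so pairwise
        distances — and hence the NJ Q-criterion — are free of exact
        ties."""
        rng = random.Random(seed)
        anc = [rng.choice("ACGT") for _ in range(L)]
        other = list(anc)
        flip = {"A": "T", "T": "A", "C": "G", "G": "C"}
        for k in range(n_fixed):
            other[k] = flip[other[k]]
        ids, seqs = [], []
        for grp, base, offset in (("a", anc, 100), ("b", other, 330)):
            for i in range(4):
                s = list(base)
                for k in range(i + 1):
                    pos = offset + 12 * i + k
                    s[pos] = flip[s[pos]]
                ids.append(f"{grp}{i}")
                seqs.append("".join(s))
        return bg.BarcodeAlignment(ids=ids, seqs=seqs)

    def test_saturated_signal_full_support(self):
        aln = self._two_cluster_alignment()
        tree = bg.bootstrap(aln, B=200, seed=1)
        split = frozenset({"b0", "b1", "b2", "b3"})
        bips = tree.bipartitions()
        assert split in bips
        assert bips[split].support == 100.0

    def test_single_replicate_supports_binary(self):
        aln = self._two_cluster_alignment()
        tree = bg.bootstrap(aln, B=1, seed=2)
        for clade in tree.bipartitions().values():
            assert clade.support in (0.0, 100.0)

    def test_same_seed_identical_supports(self):
        aln = self._two_cluster_alignment()
        t1 = bg.bootstrap(aln, B=50, seed=9)
        t2 = bg.bootstrap(aln, B=50, seed=9)
        s1 = {k: v.support for k, v in t1.bipartitions().items()}
        s2 = {k: v.support for k, v in t2.bipartitions().items()}
        assert s1 == s2

    def test_split_support_invariant_to_taxon_order(self):
        """Randomness attaches to column draws, not taxa, so the
        well-separated split's support does not depend on input order.
        (Supports on shallow within-cluster edges can shift: bootstrap
        replicates routinely produce exact Q-criterion ties there, and
        the deterministic lowest-index tie-break then follows input
        order.)"""
        aln = self._two_cluster_alignment()
        perm = list(range(aln.n))[::-1]
        t1 = bg.bootstrap(aln, B=50, seed=4)
        t2 = bg.bootstrap(aln.reorder(perm), B=50, seed=4)
        split = frozenset({"b0", "b1", "b2", "b3"})
        other = frozenset(aln.ids) - split

        def support(tree):
            bips = tree.bipartitions()
            clade = bips.get(split) or bips[other]
            return clade.support

        assert support(t1) == support(t2) == 100.0


class TestMonophyly:
    @staticmethod
    def _dm_from_clusters(pairs):
        # pairs: dict id -> cluster; within 0.01, between 0.2
        ids = list(pairs)
        n = len(ids)
        d = np.full((n, n), 0.2)
        for i in range(n):
            for j in range(n):
                if pairs[ids[i]] == pairs[ids[j]]:
                    d[i, j] = 0.0 if i == j else 0.01
        return bg.DistanceMatrix(ids=ids, d=d)

    def test_clustered_species_monophyletic(self):
        dm = self._dm_from_clusters({"a1": 1, "a2": 1, "b1": 2, "b2": 2})
        tree = bg.nj(dm)
        res = bg.monophyly(tree, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert res["A"].is_monophyletic and res["B"].is_monophyletic
        assert res["A"].clade_size == 2

    def test_interleaved_species_not_monophyletic(self):
        dm = self._dm_from_clusters({"a1": 1, "b1": 1, "a2": 2, "b2": 2})
        tree = bg.nj(dm)
        res = bg.monophyly(tree, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert not res["A"].is_monophyletic
        assert not res["B"].is_monophyletic
        assert res["A"].clade_size > 2

    def test_singleton_by_convention(self):
        dm = self._dm_from_clusters({"a1": 1, "a2": 1, "b1": 2, "c1": 3})
        tree = bg.nj(dm)
        res = bg.monophyly(tree, {"a1": "A", "a2": "A", "b1": "B", "c1": "C"})
        assert res["B"].is_monophyletic and res["B"].clade_size == 1

    def test_label_absent_from_tree(self):
        dm = self._dm_from_clusters({"a1": 1, "a2": 1, "b1": 2})
        tree = bg.nj(dm)
        with pytest.raises(LabelingError):
            bg.monophyly(tree, {"a1": "A", "a2": "A", "b1": "B", "zz": "Z"})

    def test_synthetic_study_matches_bipartition_scan(self, pencilfish, pencilfish_dm):
        """Exhaustive oracle: scan every edge side for an exact species
        match on the full synthetic study."""
        tree = bg.nj(pencilfish_dm)
        species = {r.specimen_id: r.species for r in pencilfish.records}
        res = bg.monophyly(tree, species)
        leafset = set(tree.leaves())
        sides = [set(s) for s in tree.edge_sides()]
        sides += [leafset - s for s in sides]
        for sp in set(species.values()):
            members = {sid for sid, s in species.items() if s == sp}
            expected = len(members) == 1 or members in sides
            assert res[sp].is_monophyletic == expected


class TestNewick:
    def test_newick_parses_with_dendropy(self, tiny_alignment):
        import dendropy

        dm = bg.distance_matrix(tiny_alignment, deletion_mode="pairwise")
        tree = bg.nj(dm)
        t = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {l.taxon.label for l in t.leaf_node_iter()} == set(tiny_alignment.ids)
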