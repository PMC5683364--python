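"""Neighbor joining consistency on additive matrices, p-distances, group
assignment, and bootstrap support."""

import numpy as np
import pytest

from cngckit import phylo
from cngckit.phylo import (DistanceMatrix, PhyloError, assign_groups,
                           bootstrap_support, neighbor_joining, p_distance,
                           p_distance_matrix, tree_splits)
from cngckit.seqio import SequenceRecord


def prot(seq, pid="p"):
    return SequenceRecord(pid, seq, "protein")


class TestPDistance:
    def test_identical_zero(self):
        assert p_distance("ACDE", "ACDE") == 0.0

    def test_quarter(self):
        assert p_distance("AAAA", "AAAT") == 0.25

    def test_gap_columns_excluded(self):
        assert p_distance("AA-A", "AATA") == 0.0
        assert p_distance("CA-A", "AATA") == pytest.approx(1 / 3)

    def test_all_gap_error(self):
        with pytest.raises(PhyloError):
            p_distance("--", "AA")

    def test_matrix_symmetric_zero_diag(self):
        dm = p_distance_matrix([prot("AAAA", "a"), prot("AAAT", "b"),
                                prot("TTTT", "c")])
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0)


def additive_matrix_from_tree(rng, n_leaves):
    """Random caterpillar-free binary tree -> leaf distance matrix + splits."""
    # build by random sequential joins with positive branch lengths
    import itertools

    dist = np.zeros((n_leaves, n_leaves))
    counter = itertools.count(n_leaves)
    active = {i: [i] for i in range(n_leaves)}  # node -> leaves below
    leaf_dist_to_node = {i: {i: 0.0} for i in range(n_leaves)}
    splits = set()
    while len(active) > 1:
        keys = sorted(active)
        i, j = rng.choice(keys, size=2, replace=False)
        bi = float(rng.uniform(0.5, 3.0))
        bj = float(rng.uniform(0.5, 3.0))
        new = next(counter)
        leaves_i, leaves_j = active.pop(int(i)), active.pop(int(j))
        di = {leaf: d + bi for leaf, d in leaf_dist_to_node[int(i)].items()}
        dj = {leaf: d + bj for leaf, d in leaf_dist_to_node[int(j)].items()}
        for a, da in di.items():
            for b, db in dj.items():
                dist[a, b] = dist[b, a] = da + db
        active[new] = leaves_i + leaves_j
        leaf_dist_to_node[new] = {**di, **dj}
        side = frozenset(f"L{k}" for k in active[new])
        if 2 <= len(side) <= n_leaves - 2:
            all_leaves = frozenset(f"L{k}" for k in range(n_leaves))
            splits.add(phylo._canon_split(side, all_leaves))
    labels = [f"L{k}" for k in range(n_leaves)]
    return DistanceMatrix(labels, dist), splits


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        # distances from ((A:1,B:2):1,(C:3,D:4))
        labels = ["A", "B", "C", "D"]
        d = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        assert tree_splits(tree) == {frozenset({"A", "B"})}
        assert tree.newick() == "((A:1,B:2):1,C:3,D:4);"

    def test_three_taxon_closed_form(self):
        labels = ["A", "B", "C"]
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        lengths = {c.name: bl for c, bl in tree.children}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_fewer_than_three_error(self):
        with pytest.raises(PhyloError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.zeros((2, 2))))

    def test_recovers_generating_topology_on_additive(self, rng):
        for _ in range(8):
            dm, true_splits = additive_matrix_from_tree(rng, 8)
            tree = neighbor_joining(dm)
            assert tree_splits(tree) == true_splits

    def test_agrees_with_scikit_bio(self, rng):
        skbio = pytest.importorskip("skbio")
        dm, _ = additive_matrix_from_tree(rng, 7)
        ours = tree_splits(neighbor_joining(dm))
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(dm.d, ids=dm.labels))
        all_leaves = frozenset(dm.labels)
        theirs = set()
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= len(all_leaves) - 2:
                theirs.add(phylo._canon_split(side, all_leaves))
        assert ours == theirs


class TestGroups:
    REFS = [(prot("AAAAAAAAAA", "r1"), "I"), (prot("CCCCCCCCCC", "r2"), "II"),
            (prot("DDDDDDDDDD", "r3"), "III")]

    def test_identical_query_distance_zero(self):
        out = assign_groups([prot("CCCCCCCCCC", "q")], self.REFS)
        assert out[0].group == "II" and out[0].anchor_distance == 0.0

    def test_tie_broken_by_first_label(self):
        # query equidistant to two anchors of the same group: that group,
        # with the lexicographically first anchor reported
        refs = [(prot("AAAA", "r2"), "I"), (prot("CCCC", "r1"), "I")]
        out = assign_groups([prot("AACC", "q")], refs)
        assert out[0].group == "I" and out[0].anchor_id == "r1"

    def test_no_references_error(self):
        with pytest.raises(PhyloError):
            assign_groups([prot("AAAA", "q")], [])

    def test_order_invariance(self):
        queries = [prot("AAAAAAAAAC", "q1"), prot("CCCCCCCCCA", "q2")]
        fwd = assign_groups(queries, self.REFS)
        rev = assign_groups(queries[::-1], self.REFS)
        assert {a.protein_id: a.group for a in fwd} == \
            {a.protein_id: a.group for a in rev}

    def test_simulated_four_group_recovery(self, rng):
        # anchors from 4 divergent ancestors; queries diverge 10% from
        # their own anchor -> at least 95% correct assignment
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        anchors = ["".join(rng.choice(alphabet, 200)) for _ in range(4)]
        refs = [(prot(a, f"anchor{i}"), ["I", "II", "III", "IV-a"][i])
                for i, a in enumerate(anchors)]
        correct = total = 0
        for i, anc in enumerate(anchors):
            for k in range(10):
                seq = list(anc)
                for posn in rng.choice(200, size=20, replace=False):
                    seq[posn] = rng.choice(alphabet)
                out = assign_groups([prot("".join(seq), f"q{i}_{k}")], refs)
                total += 1
                correct += out[0].group == refs[i][1]
        assert correct / total >= 0.95


class TestBootstrap:
    def make_two_clades(self, rng):
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(alphabet, 120))
        b = list(a)
        for posn in rng.choice(120, size=60, replace=False):  # divergence .5
            b[posn] = rng.choice(alphabet)
        seqs = []
        for tag, base in (("a", a), ("b", "".join(b))):
            for k in range(3):
                s = list(base)
                for posn in rng.choice(120, size=2, replace=False):  # ~0.01
                    s[posn] = rng.choice(alphabet)
                seqs.append(prot("".join(s), f"{tag}{k}"))
        return seqs

    def test_clear_split_high_support(self, rng):
        seqs = self.make_two_clades(rng)
        tree, support = bootstrap_support(seqs, replicates=100, seed=5)
        split = phylo._canon_split(frozenset({"a0", "a1", "a2"}),
                                   frozenset(s.id for s in seqs))
        assert support[split] >= 90

    def test_single_replicate_binary_support(self, rng):
        seqs = self.make_two_clades(rng)
        _, support = bootstrap_support(seqs, replicates=1, seed=1)
        assert set(support.values()) <= {0.0, 100.0}

    def test_seed_reproducible(self, rng):
        seqs = self.make_two_clades(rng)
        _, s1 = bootstrap_support(seqs, replicates=20, seed=9)
        _, s2 = bootstrap_support(seqs, replicates=20, seed=9)
        assert s1 == s2
        assert all(0 <= v <= 100 for v in s1.values())
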