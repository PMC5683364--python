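"""Distance-based phylogenetics and family group assignment.

Neighbor joining (Saitou-Nei, Studier-Keppler Q criterion) over p-distances
is the tree builder; the published family structure (Groups I-IV with IV
split into IV-a and IV-b) is assigned by nearest reference anchor. Bootstrap
support resamples alignment columns around NJ.

Tie-breaks are deterministic: the joined pair with minimal Q is chosen by the
smallest (leaf-label) pair on ties; negative NJ branch lengths are clamped to
zero with the deficit transferred to the sister edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import SequenceRecord


class PhyloError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise PhyloError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise PhyloError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise PhyloError("nonzero diagonal")
        if not np.isfinite(self.d).all():
            raise PhyloError("non-finite distances")


@dataclass
class TreeNode:
    """Rooted representation of an (unrooted) NJ tree."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self, supports: dict[frozenset, float] | None = None,
               _all_leaves: frozenset | None = None) -> str:
        if _all_leaves is None:
            _all_leaves = frozenset(self.leaves())
            return ("(" + ",".join(
                c._nwk(bl, supports, _all_leaves)
                for c, bl in self.children) + ");")
        raise RuntimeError  # pragma: no cover

    def _nwk(self, bl: float, supports, all_leaves) -> str:
        if not self.children:
            return f"{self.name}:{bl:.6g}"
        inner = ",".join(c._nwk(b, supports, all_leaves)
                         for c, b in self.children)
        label = ""
        if supports is not None:
            side = frozenset(self.leaves())
            key = _canon_split(side, all_leaves)
            if key in supports:
                label = f"{supports[key]:g}"
        return f"({inner}){label}:{bl:.6g}"


def _canon_split(side: frozenset, all_leaves: frozenset) -> frozenset:
    other = all_leaves - side
    return min(side, other, key=lambda s: (len(s), sorted(s)))


def tree_splits(tree: TreeNode) -> set[frozenset]:
    """Nontrivial bipartitions induced by the tree's internal edges."""
    all_leaves = frozenset(tree.leaves())
    splits: set[frozenset] = set()

    def walk(node: TreeNode) -> frozenset:
        if not node.children:
            return frozenset([node.name])
        below = frozenset()
        for child, _ in node.children:
            below |= walk(child)
        if 2 <= len(below) <= len(all_leaves) - 2:
            splits.add(_canon_split(below, all_leaves))
        return below

    for child, _ in tree.children:
        walk(child)
    return splits


# ---------------------------------------------------------------------------
# p-distances
# ---------------------------------------------------------------------------

def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of mismatched columns; gap columns excluded entirely."""
    if len(seq_a) != len(seq_b):
        raise PhyloError("aligned sequences differ in length")
    compared = mismatch = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x == "-" or y == "-":
            continue
        compared += 1
        if x != y:
            mismatch += 1
    if compared == 0:
        raise PhyloError("zero comparable columns")
    return mismatch / compared


def p_distance_matrix(aligned: list[SequenceRecord]) -> DistanceMatrix:
    labels = [r.id for r in aligned]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(aligned[i].residues,
                                           aligned[j].residues)
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei NJ; returns the tree rooted at the final three-way join."""
    n = len(dm.labels)
    if n < 3:
        raise PhyloError("neighbor joining needs at least 3 taxa")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=dm.labels[i]) for i in range(n)}
    # sort key per working node: smallest leaf label beneath it
    keys: dict[int, str] = {i: dm.labels[i] for i in range(n)}
    d = {(i, j): dm.d[i, j] for i in range(n) for j in range(n) if i != j}
    active = set(range(n))
    next_id = n

    while len(active) > 3:
        r = len(active)
        R = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for i in active:
            for j in active:
                if i >= j:
                    continue
                q = (r - 2) * d[i, j] - R[i] - R[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand < best:
                    best = cand
        _, _, i, j = best
        dij = d[i, j]
        li = 0.5 * dij + (R[i] - R[j]) / (2 * (r - 2))
        lj = dij - li
        # clamp negatives, moving the deficit onto the sister edge
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        nodes[next_id] = new
        keys[next_id] = min(keys[i], keys[j])
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (d[i, k] + d[j, k] - dij)
            d[next_id, k] = d[k, next_id] = max(dk, 0.0)
        active.discard(i)
        active.discard(j)
        active.add(next_id)
        next_id += 1

    a, b, c = sorted(active, key=lambda x: keys[x])
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    return TreeNode(children=[(nodes[a], max(la, 0.0)),
                              (nodes[b], max(lb, 0.0)),
                              (nodes[c], max(lc, 0.0))])


# ---------------------------------------------------------------------------
# Group assignment
# ---------------------------------------------------------------------------

GROUPS = ("I", "II", "III", "IV-a", "IV-b")


@dataclass(frozen=True)
class GroupAssignment:
    protein_id: str
    group: str
    anchor_id: str
    anchor_distance: float


def assign_groups(queries: list[SequenceRecord],
                  references: list[tuple[SequenceRecord, str]]
                  ) -> list[GroupAssignment]:
    """Assign each query the group of its nearest reference by p-distance.

    All sequences must come from one joint alignment (equal lengths). Ties
    are broken by the lexicographically first anchor id.
    """
    if not references:
        raise PhyloError("no reference anchors provided")
    out = []
    for q in queries:
        best = min(((p_distance(q.residues, ref.residues), ref.id, grp)
                    for ref, grp in references),
                   key=lambda t: (t[0], t[1]))
        out.append(GroupAssignment(q.id, best[2], best[1], best[0]))
    return out


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(aligned: list[SequenceRecord], replicates: int,
                      seed: int) -> tuple[TreeNode, dict[frozenset, float]]:
    """Column-resampling bootstrap around NJ on p-distances.

    Returns the full-alignment tree and support percentages (0-100) for each
    of its nontrivial splits.
    """
    if replicates < 1:
        raise PhyloError("replicates must be >= 1")
    tree = neighbor_joining(p_distance_matrix(aligned))
    ref_splits = tree_splits(tree)
    counts = {s: 0 for s in ref_splits}
    rng = np.random.default_rng(seed)
    ncol = len(aligned[0].residues)
    mat = np.array([list(r.residues) for r in aligned])
    for _ in range(replicates):
        idx = rng.integers(0, ncol, size=ncol)
        boot = [SequenceRecord(r.id, "".join(mat[i, idx]), r.alphabet)
                for i, r in enumerate(aligned)]
        rep_splits = tree_splits(neighbor_joining(p_distance_matrix(boot)))
        for s in ref_splits:
            if s in rep_splits:
                counts[s] += 1
    support = {s: 100.0 * c / replicates for s, c in counts.items()}
    return tree, support
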