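"""Locus comparison: pairwise alignment distances, neighbor-joining trees
and reference-group cluster assignment.

Loci are compared by global affine-gap pairwise alignment (match +1,
mismatch -1, gap open -4 charged on the first gap residue, extend -1);
distance is one minus the fractional identity over alignment columns.
The tree is canonical neighbor joining (Saitou-Nei with the Studier-Keppler
update), with negative branch lengths clamped to zero and ties broken
deterministically by taxon order. Cluster labels are assigned by rooting on
a designated outgroup and asking whether a query falls inside the smallest
clade containing all of one reference group and none of the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

import dendropy


@dataclass
class DistanceMatrix:
    ids: list
    matrix: np.ndarray  # symmetric, zero diagonal, non-negative

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        self.matrix = m


@dataclass
class ClusterAssignment:
    locus_id: str
    label: str  # REF_GROUP_A | REF_GROUP_B | OUTSIDE


def _aligner(match: float = 1.0, mismatch: float = -1.0,
             gap_open: float = -4.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def global_align(a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
                 gap_open: float = -4.0, gap_extend: float = -1.0) -> dict:
    """Optimal global affine-gap alignment of two sequences.

    Returns the score, the aligned pair (gapped strings) and the identity
    fraction (matches / alignment columns). Case and T/U spelling are
    normalized before alignment.
    """
    from .seqs import as_dna
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = as_dna(a), as_dna(b)
    al = _aligner(match, mismatch, gap_open, gap_extend)
    best = al.align(a, b)[0]
    ga, gb = str(best[0]), str(best[1])
    matches = sum(x == y and x != "-" for x, y in zip(ga, gb))
    return {
        "score": best.score,
        "aligned": (ga, gb),
        "identity": matches / len(ga),
    }


def distance_matrix(seqs: dict) -> DistanceMatrix:
    """Pairwise 1 - identity over all sequences (id -> sequence mapping)."""
    ids = list(seqs)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sequence ids")
    if len(ids) < 3:
        raise ValueError("need at least 3 sequences")
    n = len(ids)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - global_align(seqs[ids[i]], seqs[ids[j]])["identity"]
            m[i, j] = m[j, i] = d
    return DistanceMatrix(ids, m)


# ---------------------------------------------------------------------------
# neighbor joining


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []  # (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.6f}" for c, bl in self.children)
        return f"({inner})"


def nj_tree(dm: DistanceMatrix) -> str:
    """Unrooted neighbor-joining tree as a newick string.

    Negative branch-length estimates are clamped to zero; agglomeration
    ties break on the (sorted) taxon order, so the output is deterministic.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = {i: _Node(label=dm.ids[i]) for i in range(n)}
    D = {(i, j): float(dm.matrix[i, j]) for i in range(n)
         for j in range(i + 1, n)}

    def d(i, j):
        return D[(i, j) if i < j else (j, i)]

    active = list(range(n))
    next_id = n
    while len(active) > 3:
        r = len(active)
        R = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * d(i, j) - R[i] - R[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d(i, j) + (R[i] - R[j]) / (2 * (r - 2))
        lj = d(i, j) - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        for k in active:
            if k in (i, j):
                continue
            D[(min(k, next_id), max(k, next_id))] = \
                0.5 * (d(i, k) + d(j, k) - d(i, j))
        nodes[next_id] = new
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    a, b, c = active
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    root = _Node(children=[(nodes[a], max(la, 0.0)),
                           (nodes[b], max(lb, 0.0)),
                           (nodes[c], max(lc, 0.0))])
    return root.newick() + ";"


# ---------------------------------------------------------------------------
# cluster assignment


def _rooted_tree(newick: str, outgroup: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    og = tree.find_node_with_taxon_label(outgroup)
    if og is None:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    tree.to_outgroup_position(og, update_bipartitions=True)
    return tree

def clade_leaves(newick: str, taxa: list, outgroup: str) -> set:
    """Leaf labels of the smallest outgroup-rooted clade containing `taxa`."""
    tree = _rooted_tree(newick, outgroup)
    taxon_objs = [tree.taxon_namespace.get_taxon(t) for t in taxa]
    if any(t is None for t in taxon_objs):
        missing = [t for t, o in zip(taxa, taxon_objs) if o is None]
        raise ValueError(f"taxa missing from tree: {missing}")
    mrca = tree.mrca(taxa=taxon_objs)
    return {lf.taxon.label for lf in mrca.leaf_iter()}


def is_monophyletic(newick: str, taxa: list, outgroup: str) -> bool:
    return clade_leaves(newick, taxa, outgroup) == set(taxa)


def assign_cluster(locus_id: str, refs_a: list, refs_b: list, newick: str,
                   outgroup: str) -> ClusterAssignment:
    """Label `locus_id` by membership in the exclusive reference clades.

    A query is REF_GROUP_A when the smallest outgroup-rooted clade
    containing every group-A reference together with the query holds no
    group-B reference (and symmetrically for B); otherwise OUTSIDE. The
    outgroup itself can never satisfy either rule.
    """
    for refs, label in ((refs_a, "REF_GROUP_A"), (refs_b, "REF_GROUP_B")):
        other = refs_b if label == "REF_GROUP_A" else refs_a
        leaves = clade_leaves(newick, list(refs) + [locus_id], outgroup)
        if not leaves & set(other):
            return ClusterAssignment(locus_id, label)
    return ClusterAssignment(locus_id, "OUTSIDE")
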