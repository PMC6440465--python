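"""p-distance matrices, neighbor-joining trees and reference-guided grouping.

Neighbor joining (Saitou & Nei 1987) is exact on additive distance
matrices: it recovers the generating topology and branch lengths.  Ties in
the Q-criterion are broken deterministically (lowest index pair), so the
output is a pure function of the input matrix.  Trees are returned as
dendropy objects and round-trip losslessly through Newick.

Group assignment anchors named groups to reference leaves: every
unlabeled leaf takes the group of its nearest reference by patristic
(path-length) distance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np

from .align import global_align
from .genome_io import SeqRecord


class PhylogenyError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise PhylogenyError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise PhylogenyError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise PhylogenyError("distance matrix diagonal is not zero")


def pdistance_matrix(seqs: list[SeqRecord]) -> DistanceMatrix:
    """Pairwise p-distances: mismatch fraction over gap-free aligned columns."""
    if len(seqs) < 3:
        raise PhylogenyError("need at least 3 sequences")
    n = len(seqs)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        aln = global_align(seqs[i].seq, seqs[j].seq, mode="protein")
        comparable = mismatch = 0
        for a, b in zip(aln.aligned_a, aln.aligned_b):
            if a == "-" or b == "-":
                continue
            comparable += 1
            if a != b:
                mismatch += 1
        if comparable == 0:
            raise PhylogenyError(
                f"no comparable columns between {seqs[i].id} and {seqs[j].id}"
            )
        d[i, j] = d[j, i] = mismatch / comparable
    return DistanceMatrix([s.id for s in seqs], d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Negative branch-length estimates are clamped to zero and counted in
    the tree annotation ``clamped_branches``.
    """
    n = len(dm.labels)
    if n < 3:
        raise PhylogenyError("need at least 3 taxa")
    d = dm.d.copy()
    # each active entry is a (newick fragment, ) subtree string
    nodes: list[str] = [_quote(lbl) for lbl in dm.labels]
    active = list(range(n))
    clamped = 0

    def fmt(sub: str, length: float) -> str:
        nonlocal clamped
        if length < 0:
            clamped += 1
            length = 0.0
        return f"{sub}:{length:.10g}"

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, aj in itertools.combinations(range(m), 2):
            i, j = active[ai], active[aj]
            q = (m - 2) * d[i, j] - r[i] - r[j]
            if best is None or q < best[0] - 1e-12:
                best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        new = len(nodes)
        nodes.append(f"({fmt(nodes[i], li)},{fmt(nodes[j], lj)})")
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new, k] = d[k, new] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        active = [k for k in active if k not in (i, j)] + [new]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    newick = f"({fmt(nodes[i], li)},{fmt(nodes[j], lj)},{fmt(nodes[k], lk)});"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    tree.annotations.add_new("clamped_branches", clamped)
    return tree


def _quote(label: str) -> str:
    return label.replace(" ", "_")


def write_newick(tree: dendropy.Tree, path: str) -> None:
    tree.write(path=path, schema="newick", suppress_rooting=True)


def patristic_distances(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """Path-length distance between every pair of leaves."""
    pdm = tree.phylogenetic_distance_matrix()
    out: dict[tuple[str, str], float] = {}
    taxa = list(tree.taxon_namespace)
    for t1, t2 in itertools.combinations(taxa, 2):
        dist = pdm.patristic_distance(t1, t2)
        out[(t1.label, t2.label)] = dist
        out[(t2.label, t1.label)] = dist
    return out


def assign_groups(
    tree: dendropy.Tree, reference_labels: dict[str, str]
) -> dict[str, str]:
    """Propagate group labels from reference leaves to all leaves.

    Each non-reference leaf takes the group of its nearest reference by
    patristic distance; exact ties resolve to the lexicographically
    smallest group name.  Every group in ``reference_labels`` must have at
    least one reference leaf present in the tree.
    """
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    refs = {lbl: grp for lbl, grp in reference_labels.items() if lbl in leaf_labels}
    missing = set(reference_labels.values()) - set(refs.values())
    if missing:
        raise PhylogenyError(f"groups with no reference leaf in tree: {sorted(missing)}")
    dists = patristic_distances(tree)
    out: dict[str, str] = dict(refs)
    for leaf in sorted(leaf_labels - set(refs)):
        best_d, best_grp = None, None
        for ref, grp in refs.items():
            dist = dists[(leaf, ref)]
            if (
                best_d is None
                or dist < best_d - 1e-12
                or (abs(dist - best_d) <= 1e-12 and grp < best_grp)
            ):
                best_d, best_grp = dist, grp
        out[leaf] = best_grp
    return out
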