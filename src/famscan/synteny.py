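"""Microsynteny: anchor detection and collinear block chaining.

A collinear block is a run of homologous gene pairs (anchors) whose order
is preserved between two genomes — increasing gene rank on both for a
same-orientation block, increasing on one and decreasing on the other for
an inverted block.  Blocks are found per chromosome pair by a
longest-increasing-subsequence dynamic program with a rank-gap
constraint, then extracted greedily in decreasing size; chains shorter
than ``min_block`` anchors are discarded.

Defaults (min_block=5, top_hits=5, max_gap=25) follow the documented
defaults of the standard collinearity scanner this module re-implements
in simplified form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .align import align_score
from .genome_io import GeneModel, SeqRecord

MIN_BLOCK = 5
TOP_HITS = 5
MAX_GAP = 25
#: minimum anchors per spanned gene rank (on both genomes); this density
#: requirement is the block-significance filter — chance chains in
#: shuffled gene orders are sparse, true collinear runs are dense
MIN_DENSITY = 0.5


@dataclass(frozen=True)
class Anchor:
    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int
    score: float


@dataclass(frozen=True)
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    orientation: str  # same | inverted
    anchors: tuple[Anchor, ...]


def gene_ranks(models: list[GeneModel]) -> dict[str, tuple[str, int]]:
    """gene_id -> (chrom, rank) with ranks by start coordinate per chromosome."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    out: dict[str, tuple[str, int]] = {}
    for chrom, genes in by_chrom.items():
        for rank, g in enumerate(sorted(genes, key=lambda m: (m.start, m.gene_id))):
            out[g.gene_id] = (chrom, rank)
    return out


def find_anchors(
    proteome_a: list[SeqRecord],
    proteome_b: list[SeqRecord],
    models_a: list[GeneModel],
    models_b: list[GeneModel],
    top_hits: int = TOP_HITS,
    min_score: float = 100.0,
) -> list[Anchor]:
    """Up to ``top_hits`` best-scoring partners in B for every gene in A.

    Scores are global protein alignment scores; genes without an
    annotation record are skipped with a warning.
    """
    ranks_a = gene_ranks(models_a)
    ranks_b = gene_ranks(models_b)
    anchors: list[Anchor] = []
    for pa in proteome_a:
        if pa.id not in ranks_a:
            warnings.warn(f"unannotated gene skipped: {pa.id}", stacklevel=2)
            continue
        scored = []
        for pb in proteome_b:
            if pb.id not in ranks_b:
                continue
            score = align_score(pa.seq, pb.seq, mode="protein")
            if score >= min_score:
                scored.append((score, pb.id))
        scored.sort(key=lambda t: (-t[0], t[1]))
        for score, gb in scored[:top_hits]:
            ca, ra = ranks_a[pa.id]
            cb, rb = ranks_b[gb]
            anchors.append(Anchor(pa.id, gb, ca, cb, ra, rb, score))
    return anchors


def _chain_one_orientation(
    anchors: list[Anchor], inverted: bool, max_gap: int
) -> list[list[Anchor]]:
    """Greedy extraction of maximal gap-constrained increasing chains.

    Anchors are sorted by rank_a; rank_b must increase (same orientation)
    or decrease (inverted) with successive rank gaps <= max_gap on both
    genomes.  Repeatedly finds the longest chain by DP and removes it.
    """
    sign = -1 if inverted else 1
    pool = sorted(anchors, key=lambda x: (x.rank_a, sign * x.rank_b))
    chains: list[list[Anchor]] = []
    while pool:
        n = len(pool)
        best_len = [1] * n
        prev = [-1] * n
        for i in range(n):
            for j in range(i):
                gap_a = pool[i].rank_a - pool[j].rank_a
                gap_b = sign * (pool[i].rank_b - pool[j].rank_b)
                if 0 < gap_a <= max_gap and 0 < gap_b <= max_gap:
                    if best_len[j] + 1 > best_len[i]:
                        best_len[i] = best_len[j] + 1
                        prev[i] = j
        top = max(range(n), key=lambda i: (best_len[i], -i))
        if best_len[top] < 2:
            break
        chain = []
        k = top
        while k != -1:
            chain.append(pool[k])
            k = prev[k]
        chain.reverse()
        chains.append(chain)
        used = set(id(a) for a in chain)
        pool = [a for a in pool if id(a) not in used]
    return chains


def _dense_enough(chain: list[Anchor], min_density: float) -> bool:
    if len(chain) < 2 or min_density <= 0:
        return True
    span_a = chain[-1].rank_a - chain[0].rank_a + 1
    ranks_b = [a.rank_b for a in chain]
    span_b = max(ranks_b) - min(ranks_b) + 1
    k = len(chain)
    return k / span_a >= min_density and k / span_b >= min_density


def chain_collinear(
    anchors: list[Anchor],
    min_block: int = MIN_BLOCK,
    max_gap: int = MAX_GAP,
    min_density: float = MIN_DENSITY,
) -> list[CollinearBlock]:
    """Chain anchors into collinear blocks per chromosome pair and orientation.

    Chains shorter than ``min_block`` or sparser than ``min_density``
    (anchors per spanned rank, on either genome) are discarded; the
    density requirement plays the role of a block-significance test, so
    chance chains in unrelated gene orders are not reported.
    """
    groups: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.chrom_a, a.chrom_b), []).append(a)
    blocks: list[CollinearBlock] = []
    for (ca, cb), group in sorted(groups.items()):
        for orientation, inverted in (("same", False), ("inverted", True)):
            for chain in _chain_one_orientation(group, inverted, max_gap):
                if len(chain) >= min_block and _dense_enough(chain, min_density):
                    blocks.append(CollinearBlock(ca, cb, orientation, tuple(chain)))
    blocks.sort(key=lambda b: (-len(b.anchors), b.chrom_a, b.chrom_b))
    return blocks


def family_ortho_pairs(
    blocks: list[CollinearBlock],
    members_a: set[str],
    members_b: set[str],
) -> list[tuple[str, str]]:
    """Family-member anchor pairs inside collinear blocks, deduplicated.

    A member may appear in several pairs (one per block partner).
    """
    seen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    for block in blocks:
        for a in block.anchors:
            if a.gene_a in members_a and a.gene_b in members_b:
                pair = (a.gene_a, a.gene_b)
                if pair not in seen:
                    seen.add(pair)
                    out.append(pair)
    return out
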