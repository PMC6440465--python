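"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the genetic code
comes from Biopython, alignments are enumerated exhaustively, and chains
are found by subset enumeration.
"""

from __future__ import annotations

import itertools

from Bio.Seq import Seq

NUCS = "ACGT"


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def is_stop(codon: str) -> bool:
    return translate_codon(codon) == "*"


def ng86_sites_oracle(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts by direct mutant enumeration."""
    aa = translate_codon(codon)
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for nuc in NUCS:
            if nuc == codon[pos]:
                continue
            mut = codon[:pos] + nuc + codon[pos + 1:]
            if is_stop(mut):
                continue
            tot += 1
            syn += translate_codon(mut) == aa
        if tot:
            s += syn / tot
    return s, 3.0 - s


def ng86_pathways_oracle(ca: str, cb: str) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) differences by explicit enumeration."""
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    if not diffs:
        return 0.0, 0.0
    valid, blocked = [], []
    for order in itertools.permutations(diffs):
        cur = ca
        syn = non = 0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if is_stop(nxt) and nxt != cb:
                hit_stop = True
            if translate_codon(cur) == translate_codon(nxt) and not is_stop(nxt):
                syn += 1
            else:
                non += 1
            cur = nxt
        (blocked if hit_stop else valid).append((syn, non))
    use = valid if valid else blocked
    return (sum(x[0] for x in use) / len(use), sum(x[1] for x in use) / len(use))


def enumerate_alignments(a: str, b: str):
    """Every global alignment of a and b as (row_a, row_b) pairs."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def score_alignment_dna(row_a: str, row_b: str) -> float:
    """Affine-gap score matching the package's DNA scheme.

    match +2, mismatch -3; a gap of length k costs 5 + (k-1)*2 (the first
    gap column carries the open score, later columns the extend score).
    """
    score = 0.0
    for i, (x, y) in enumerate(zip(row_a, row_b)):
        if x == "-" or y == "-":
            row = row_a if x == "-" else row_b
            opened = i == 0 or row[i - 1] != "-"
            score -= 5.0 if opened else 2.0
        else:
            score += 2.0 if x == y else -3.0
    return score


def best_alignment_score_dna(a: str, b: str) -> float:
    return max(
        score_alignment_dna(ra, rb) for ra, rb in enumerate_alignments(a, b)
    )


def max_chain_bruteforce(ranks: list[tuple[int, int]], max_gap: int) -> int:
    """Longest strictly-increasing chain (both coordinates) with gap bound."""
    n = len(ranks)
    best = 0
    for mask in range(1, 1 << n):
        sel = [ranks[i] for i in range(n) if mask >> i & 1]
        sel.sort()
        ok = all(
            0 < s2[0] - s1[0] <= max_gap and 0 < s2[1] - s1[1] <= max_gap
            for s1, s2 in zip(sel, sel[1:])
        )
        if ok:
            best = max(best, len(sel))
    return best
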