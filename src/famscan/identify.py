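"""Family identification by similarity prefilter plus domain assembly.

The family is defined by a compact domain of four ordered zinc fingers —
two C2H2 followed by two C2HC — matching the consensus
(F/Y)-X-C-X(2,5)-C-X3-(F/Y)-X5-psi-X2-H-X(3,5)-H (psi = hydrophobic; the
C2HC variant ends in C instead of the final H).  Members usually carry an
N-terminal nuclear localization signal (KKKR or KRKR) and often two
C-terminal motifs (MSATALLQKAA, TRDFLG) whose absence marks one subgroup.

The pipeline replaces a database-search-plus-manual-inspection protocol
with a reproducible rule: similarity prefilter against query proteins,
then require a complete four-finger domain, then de-duplicate isoforms of
the same locus keeping the longest.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .align import global_align
from .genome_io import SeqRecord
from .protparam import ProteinParams, protein_params

HYDROPHOBIC = "AVLIMFWC"

_C2H2 = re.compile(
    rf"[FY].(C).{{2,5}}(C).{{3}}[FY].{{5}}[{HYDROPHOBIC}].{{2}}(H).{{3,5}}(H)"
)
_C2HC = re.compile(
    rf"[FY].(C).{{2,5}}(C).{{3}}[FY].{{5}}[{HYDROPHOBIC}].{{2}}(H).{{3,5}}(C)"
)

NLS_MOTIFS = ("KKKR", "KRKR")
CTERM_MOTIFS = {"MSATALLQKAA": 2, "TRDFLG": 1}  # motif -> max mismatches

MAX_DOMAIN_SPAN = 220


@dataclass(frozen=True)
class ZincFinger:
    kind: str  # "C2H2" | "C2HC"
    start: int  # 0-based half-open protein coords
    end: int
    coordinating: tuple[int, int, int, int]


@dataclass(frozen=True)
class IDDomain:
    zfs: tuple[ZincFinger, ZincFinger, ZincFinger, ZincFinger]
    start: int
    end: int


@dataclass(frozen=True)
class MotifHit:
    motif: str
    position: int
    mismatches: int


@dataclass
class FamilyMember:
    gene_id: str
    protein: SeqRecord
    domain: IDDomain
    nls: MotifHit | None = None
    cterm_motifs: list[MotifHit] = field(default_factory=list)
    params: ProteinParams | None = None


def scan_zinc_fingers(protein: SeqRecord | str) -> list[ZincFinger]:
    """All non-overlapping finger matches, resolved leftmost-first.

    At each scan position the earliest-starting match of either finger
    pattern wins (C2H2 preferred on an exact tie); scanning resumes after
    its end, so candidate matches overlapping an accepted one are dropped.
    """
    seq = protein.seq if isinstance(protein, SeqRecord) else protein
    out: list[ZincFinger] = []
    pos = 0
    while pos < len(seq):
        best: tuple[int, str, re.Match] | None = None
        for kind, pat in (("C2H2", _C2H2), ("C2HC", _C2HC)):
            m = pat.search(seq, pos)
            if m and (best is None or m.start() < best[0]):
                best = (m.start(), kind, m)
        if best is None:
            break
        _, kind, m = best
        out.append(
            ZincFinger(
                kind=kind,
                start=m.start(),
                end=m.end(),
                coordinating=tuple(m.start(g) for g in range(1, 5)),
            )
        )
        pos = m.end()
    return out


def assemble_id_domain(
    zfs: list[ZincFinger], max_domain_span: int = MAX_DOMAIN_SPAN
) -> IDDomain | None:
    """First window of four fingers with kinds C2H2,C2H2,C2HC,C2HC in order.

    The total span (first finger start to last finger end) must not exceed
    ``max_domain_span`` residues; returns None if no window qualifies.
    """
    want = ("C2H2", "C2H2", "C2HC", "C2HC")
    for i in range(len(zfs) - 3):
        quartet = tuple(zfs[i:i + 4])
        if tuple(z.kind for z in quartet) != want:
            continue
        span = quartet[3].end - quartet[0].start
        if span <= max_domain_span:
            return IDDomain(quartet, quartet[0].start, quartet[3].end)
    return None


def find_nls(protein: SeqRecord | str, domain: IDDomain) -> MotifHit | None:
    """Leftmost KKKR/KRKR lying entirely N-terminal of the domain."""
    seq = protein.seq if isinstance(protein, SeqRecord) else protein
    best: MotifHit | None = None
    for motif in NLS_MOTIFS:
        idx = seq.find(motif)
        while idx != -1:
            if idx + len(motif) <= domain.start:
                if best is None or idx < best.position:
                    best = MotifHit(motif, idx, 0)
                break
            idx = seq.find(motif, idx + 1)
    return best


def find_cterm_motifs(
    protein: SeqRecord | str,
    domain: IDDomain,
    max_mismatch: dict[str, int] | None = None,
) -> list[MotifHit]:
    """Best ungapped occurrence of each C-terminal motif after the domain.

    Each motif has its own mismatch budget (default: 2 for MSATALLQKAA,
    1 for TRDFLG); ties go to the leftmost position.
    """
    seq = protein.seq if isinstance(protein, SeqRecord) else protein
    budgets = max_mismatch if max_mismatch is not None else CTERM_MOTIFS
    tail = seq[domain.end:]
    hits: list[MotifHit] = []
    for motif, budget in budgets.items():
        k = len(motif)
        best_mm, best_pos = budget + 1, -1
        for i in range(len(tail) - k + 1):
            mm = sum(1 for a, b in zip(tail[i:i + k], motif) if a != b)
            if mm < best_mm:
                best_mm, best_pos = mm, i
        if best_pos >= 0 and best_mm <= budget:
            hits.append(MotifHit(motif, domain.end + best_pos, best_mm))
    return hits


def locus_of(protein_id: str) -> str:
    """Gene locus of a protein id: a trailing '.<n>' isoform suffix is dropped."""
    stem, dot, suffix = protein_id.rpartition(".")
    if dot and suffix.isdigit():
        return stem
    return protein_id


def annotate_member(protein: SeqRecord) -> FamilyMember | None:
    """Build a FamilyMember if the protein carries a complete domain."""
    domain = assemble_id_domain(scan_zinc_fingers(protein))
    if domain is None:
        return None
    return FamilyMember(
        gene_id=locus_of(protein.id),
        protein=protein,
        domain=domain,
        nls=find_nls(protein, domain),
        cterm_motifs=find_cterm_motifs(protein, domain),
        params=protein_params(protein.seq),
    )


def identify_family(
    proteome: list[SeqRecord],
    queries: list[SeqRecord],
    min_query_identity: float = 0.25,
) -> list[FamilyMember]:
    """Identify family members in an annotated proteome.

    1. prefilter: keep proteins whose best global-alignment identity to any
       query is >= ``min_query_identity`` (loose on purpose — the domain
       test below is the real filter);
    2. require a complete four-finger domain;
    3. de-duplicate by gene locus, keeping the longest isoform.
    """
    if not queries:
        raise ValueError("queries must be non-empty")
    by_locus: dict[str, FamilyMember] = {}
    for prot in proteome:
        best_id = max(
            global_align(prot.seq, q.seq, mode="protein").identity for q in queries
        )
        if best_id < min_query_identity:
            continue
        member = annotate_member(prot)
        if member is None:
            continue
        prev = by_locus.get(member.gene_id)
        if prev is None or len(member.protein) > len(prev.protein):
            by_locus[member.gene_id] = member
    return [by_locus[k] for k in sorted(by_locus)]
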