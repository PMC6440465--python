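"""Global pairwise alignment for proteins and DNA.

Needleman-Wunsch with affine gaps (protein: BLOSUM62, open 10 / extend 0.5;
DNA: match +2 / mismatch -3, open 5 / extend 2), shared by the
identification, duplication, Ka/Ks and synteny stages.  Identity is
computed over alignment columns, by default excluding terminal gap
overhangs (the two sequences being compared often differ in length).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import NUCLEOTIDE_ALPHABET, PROTEIN_ALPHABET

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))


def translate(cds: str) -> str:
    """Translate a CDS (length divisible by 3); stops become '*'."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return "".join(GENETIC_CODE.get(cds[i:i + 3], "X") for i in range(0, len(cds), 3))


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class Alignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise AlignmentError("aligned rows differ in length")


@lru_cache(maxsize=4)
def _aligner(mode: str, score_only: bool = False) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if mode == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
    elif mode == "dna":
        aligner.match_score = 2.0
        aligner.mismatch_score = -3.0
        aligner.open_gap_score = -5.0
        aligner.extend_gap_score = -2.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return aligner


def _check_alphabet(seq: str, mode: str, name: str) -> None:
    allowed = PROTEIN_ALPHABET if mode == "protein" else NUCLEOTIDE_ALPHABET
    bad = set(seq) - allowed
    if bad:
        raise AlignmentError(f"illegal {mode} characters in {name}: {sorted(bad)}")


def align_score(a: str, b: str, mode: str = "protein") -> float:
    """Optimal global alignment score without traceback (fast path)."""
    _check_alphabet(a, mode, "a")
    _check_alphabet(b, mode, "b")
    return float(_aligner(mode).score(a, b))


def global_align(a: str, b: str, mode: str = "protein") -> Alignment:
    """Optimal global alignment; first optimal traceback (deterministic)."""
    _check_alphabet(a, mode, "a")
    _check_alphabet(b, mode, "b")
    if not a or not b:
        raise AlignmentError("empty sequence")
    aln = next(iter(_aligner(mode).align(a, b)))
    row_a, row_b = str(aln[0]), str(aln[1])
    out = Alignment(row_a, row_b, float(aln.score), 0.0)
    return Alignment(row_a, row_b, float(aln.score), identity(out))


def identity(aln: Alignment, convention: str = "exclude_terminal_gaps") -> float:
    """Fraction of identical columns.

    ``all_columns`` divides by the full alignment length; the default
    ``exclude_terminal_gaps`` drops leading/trailing gap overhangs from the
    denominator (internal gaps still count as mismatches).
    """
    a, b = aln.aligned_a, aln.aligned_b
    n = len(a)
    lo, hi = 0, n
    if convention == "exclude_terminal_gaps":
        while lo < n and _is_overhang(a, b, lo, "left"):
            lo += 1
        while hi > lo and _is_overhang(a, b, hi - 1, "right"):
            hi -= 1
    elif convention != "all_columns":
        raise ValueError(f"unknown identity convention {convention!r}")
    denom = hi - lo
    if denom == 0:
        return 0.0
    matches = sum(1 for i in range(lo, hi) if a[i] == b[i] and a[i] != "-")
    return matches / denom


def _is_overhang(a: str, b: str, i: int, side: str) -> bool:
    """True when column i belongs to a terminal gap run of either row."""
    for row in (a, b):
        if row[i] == "-":
            run = row[:i + 1] if side == "left" else row[i:]
            if set(run) == {"-"}:
                return True
    return False


def cds_identity(cds_a: str, cds_b: str, convention: str = "exclude_terminal_gaps") -> float:
    """Identity of the optimal global DNA alignment of two coding sequences."""
    return identity(global_align(cds_a, cds_b, mode="dna"), convention)


def codon_align(protein_aln: Alignment, cds_a: str, cds_b: str) -> tuple[str, str]:
    """Thread CDS pairs through a protein alignment (each gap becomes ``---``).

    Requires ``len(cds) == 3 * len(ungapped protein)`` and exact
    translation agreement on both sides.
    """
    out = []
    for row, cds, name in (
        (protein_aln.aligned_a, cds_a, "a"),
        (protein_aln.aligned_b, cds_b, "b"),
    ):
        prot = row.replace("-", "")
        if len(cds) != 3 * len(prot):
            raise AlignmentError(
                f"cds_{name} length {len(cds)} != 3 x {len(prot)} protein residues"
            )
        tr = translate(cds)
        for i, (p, t) in enumerate(zip(prot, tr)):
            if p != t:
                raise AlignmentError(
                    f"cds_{name} translation mismatch at residue {i}: {t} != {p}"
                )
        pieces = []
        k = 0
        for ch in row:
            if ch == "-":
                pieces.append("---")
            else:
                pieces.append(cds[3 * k:3 * k + 3])
                k += 1
        out.append("".join(pieces))
    return out[0], out[1]


def align_cds_pair(cds_a: str, cds_b: str) -> tuple[str, str]:
    """Protein-guided codon alignment of two coding sequences.

    Trailing stop codons are trimmed before the protein alignment and are
    not part of the returned codon rows.
    """
    a = cds_a[:-3] if cds_a[-3:] in STOP_CODONS else cds_a
    b = cds_b[:-3] if cds_b[-3:] in STOP_CODONS else cds_b
    paln = global_align(translate(a), translate(b), mode="protein")
    return codon_align(paln, a, b)
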