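"""Duplication classification and Nei-Gojobori (1986) Ka/Ks.

Synonymous/nonsynonymous site fractions are counted per codon position
among non-stop single-nucleotide mutants, so sites always sum to 3 per
codon.  Differences between codon pairs are averaged over all minimal
substitution pathways, excluding pathways that pass through a stop codon
(if every pathway is blocked, all pathways are used with stop steps
counted as nonsynonymous).  Proportions are distance-corrected with the
one-parameter Jukes-Cantor map d = -(3/4) ln(1 - (4/3) p).

A Ka/Ks ratio below 1 is read as purifying selection, 1 as neutral and
above 1 as positive selection.  Sliding windows (default 150 bp window,
9 bp step, both multiples of 3) localize these signals along a codon
alignment.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

from .align import GENETIC_CODE, STOP_CODONS, align_cds_pair, cds_identity
from .genome_io import GeneModel

NUCS = "ACGT"

#: same-chromosome separation threshold (bp) in the duplication rules
TANDEM_SEPARATION_BP = 200_000
#: coding-sequence identity threshold for calling a duplicate pair
DUPLICATE_IDENTITY = 0.80


class KaKsError(ValueError):
    pass


@dataclass(frozen=True)
class KaKsResult:
    """NG86 counts and Jukes-Cantor-corrected rates for one codon alignment.

    ``ka``/``ks`` are None when the corresponding proportion is saturated
    (p >= 3/4) or has zero sites; ``ratio`` is None whenever it cannot be
    formed (Ks undefined or zero).
    """

    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float | None
    pn: float | None
    ks: float | None
    ka: float | None
    ratio: float | None
    codons: int

    @property
    def selection(self) -> str:
        """purifying / neutral / positive, or n/a when the ratio is undefined."""
        if self.ratio is None:
            return "n/a"
        if self.ratio < 1.0:
            return "purifying"
        if self.ratio == 1.0:
            return "neutral"
        return "positive"


@dataclass(frozen=True)
class WindowProfile:
    window_size: int
    step: int
    window_starts: tuple[int, ...]
    results: tuple[KaKsResult, ...]


@dataclass(frozen=True)
class DupPair:
    gene_a: str
    gene_b: str
    identity: float
    dup_class: str  # tandem | segmental | unclassified
    chrom_a: str
    chrom_b: str
    genomic_separation: int | None


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon.

    Per position, the synonymous fraction is computed among the non-stop
    single-nucleotide mutants at that position; fractions at the three
    positions sum to 3 exactly.
    """
    aa = GENETIC_CODE.get(codon)
    if aa is None:
        raise KaKsError(f"not a codon: {codon!r}")
    if aa == "*":
        raise KaKsError(f"stop codon has no site counts: {codon}")
    s = 0.0
    for pos in range(3):
        syn = 0
        tot = 0
        for nuc in NUCS:
            if nuc == codon[pos]:
                continue
            mutant = codon[:pos] + nuc + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue
            tot += 1
            if GENETIC_CODE[mutant] == aa:
                syn += 1
        if tot:
            s += syn / tot
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences for one codon pair.

    Enumerates every ordering of the differing positions; pathways through
    stop codons are excluded from the average (all pathways used, with
    stop steps nonsynonymous, if none survives).
    """
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return 0.0, 0.0
    paths: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in itertools.permutations(diffs):
        cur = codon_a
        syn = nonsyn = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if GENETIC_CODE[nxt] == "*" and nxt != codon_b:
                through_stop = True
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt] and GENETIC_CODE[nxt] != "*":
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        (blocked if through_stop else paths).append((syn, nonsyn))
    use = paths if paths else blocked
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC-corrected distance; None at or beyond saturation (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_pair(codon_aln_a: str, codon_aln_b: str) -> KaKsResult:
    """NG86 Ka/Ks for two equal-length gapped codon strings.

    Columns (codons) containing a gap or a stop in either row are skipped.
    """
    if len(codon_aln_a) != len(codon_aln_b):
        raise KaKsError("codon alignments differ in length")
    if len(codon_aln_a) % 3:
        raise KaKsError("codon alignment length not divisible by 3")
    s_a = s_b = n_a = n_b = 0.0
    sd = nd = 0.0
    codons = 0
    for i in range(0, len(codon_aln_a), 3):
        ca, cb = codon_aln_a[i:i + 3], codon_aln_b[i:i + 3]
        if "-" in ca or "-" in cb:
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        if GENETIC_CODE.get(ca) is None or GENETIC_CODE.get(cb) is None:
            continue
        codons += 1
        sa, na = ng86_site_counts(ca)
        sb, nb = ng86_site_counts(cb)
        s_a += sa
        s_b += sb
        n_a += na
        n_b += nb
        dsd, dnd = _pathway_counts(ca, cb)
        sd += dsd
        nd += dnd
    s_sites = 0.5 * (s_a + s_b)
    n_sites = 0.5 * (n_a + n_b)
    ps = sd / s_sites if s_sites > 0 else None
    pn = nd / n_sites if n_sites > 0 else None
    ks = jukes_cantor(ps) if ps is not None else None
    ka = jukes_cantor(pn) if pn is not None else None
    ratio = ka / ks if (ka is not None and ks is not None and ks > 0) else None
    return KaKsResult(
        s_sites=s_sites, n_sites=n_sites, sd=sd, nd=nd,
        ps=ps, pn=pn, ks=ks, ka=ka, ratio=ratio, codons=codons,
    )


def kaks_for_cds_pair(cds_a: str, cds_b: str) -> KaKsResult:
    """Protein-guided codon alignment followed by NG86."""
    row_a, row_b = align_cds_pair(cds_a, cds_b)
    return ng86_pair(row_a, row_b)


def sliding_window(
    codon_aln_a: str,
    codon_aln_b: str,
    window: int = 150,
    step: int = 9,
) -> WindowProfile:
    """Per-window NG86 profile along a codon alignment.

    Windows start at alignment offsets 0, step, 2*step, ... with
    start + window <= alignment length, i.e. floor((L - window)/step) + 1
    windows.  Window and step must be multiples of 3.
    """
    if window % 3 or step % 3:
        raise KaKsError("window and step must be multiples of 3")
    L = len(codon_aln_a)
    if L < window:
        warnings.warn(f"alignment length {L} shorter than window {window}", stacklevel=2)
        return WindowProfile(window, step, (), ())
    starts = tuple(range(0, L - window + 1, step))
    results = tuple(
        ng86_pair(codon_aln_a[s:s + window], codon_aln_b[s:s + window])
        for s in starts
    )
    return WindowProfile(window, step, starts, results)


def _separation(a: GeneModel, b: GeneModel) -> int:
    """bp between the nearest ends of two genes on one chromosome (0 if overlapping)."""
    if a.end <= b.start:
        return b.start - a.end
    if b.end <= a.start:
        return a.start - b.end
    return 0


def classify_duplicates(
    models: dict[str, GeneModel],
    cds: dict[str, str],
    identity_threshold: float = DUPLICATE_IDENTITY,
    tandem_rule: str = "as_printed",
) -> list[DupPair]:
    """All duplicate gene pairs (CDS identity above threshold), classified.

    ``as_printed`` follows the source rules verbatim: same chromosome and
    separated by at least 200 kb -> tandem; different chromosomes ->
    segmental; same chromosome closer than 200 kb -> unclassified.
    ``conventional`` uses the field's usual reading: same chromosome within
    200 kb -> tandem; the distant same-chromosome case is unclassified.
    """
    if tandem_rule not in ("as_printed", "conventional"):
        raise ValueError(f"unknown tandem_rule {tandem_rule!r}")
    pairs: list[DupPair] = []
    ids = sorted(models)
    for ga, gb in itertools.combinations(ids, 2):
        if ga not in cds or gb not in cds:
            raise KaKsError(f"missing CDS for {ga if ga not in cds else gb}")
        ident = cds_identity(cds[ga], cds[gb])
        if ident <= identity_threshold:
            continue
        ma, mb = models[ga], models[gb]
        if ma.chrom != mb.chrom:
            dup_class, sep = "segmental", None
        else:
            sep = _separation(ma, mb)
            far = sep >= TANDEM_SEPARATION_BP
            tandem = far if tandem_rule == "as_printed" else not far
            dup_class = "tandem" if tandem else "unclassified"
        pairs.append(
            DupPair(ga, gb, ident, dup_class, ma.chrom, mb.chrom, sep)
        )
    return pairs
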