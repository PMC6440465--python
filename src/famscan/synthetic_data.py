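"""Synthetic genomes, proteomes, promoters and Ct tables with planted truth.

Every downstream stage (identification, duplication and Ka/Ks, synteny,
promoter scanning, expression) can be exercised without any downloads:
the generator emits standard FASTA/GFF3/TSV files together with a truth
table recording exactly what was planted.

Family proteins are built to satisfy the four-finger domain consensus
(two C2H2 then two C2HC fingers), with an optional N-terminal KKKR/KRKR
nuclear localization signal and group-dependent C-terminal motifs
(MSATALLQKAA, TRDFLG; the "group 4" template omits both).  Decoys carry
at most two fingers or a broken finger (a coordinating Cys mutated to
Ser).  Background/linker residues are drawn from a hydrophilic alphabet
that excludes C, H, F, Y, W and R, so neither accidental fingers nor
accidental NLS motifs can arise — the ground truth is unambiguous.

Duplicate pairs are created by planting synonymous and nonsynonymous
point substitutions whose counts invert the NG86 + Jukes-Cantor map at
the requested Ka and Ks, so the estimator is expected to recover the
targets.  Substitutions never create stop codons, and nonsynonymous ones
avoid the domain and motif spans so a duplicate remains a family member.
"""

from __future__ import annotations

import math
import random
import re
from dataclasses import dataclass, field

import pandas as pd

from .align import GENETIC_CODE, STOP_CODONS, translate
from .cis_elements import CisCatalog, default_catalog, iupac_regex
from .evolution import ng86_site_counts
from .genome_io import GeneModel, SeqRecord, revcomp
from .identify import NLS_MOTIFS

# background alphabets: hydrophilic, free of C/H/F/Y/W (no accidental
# fingers) and of R (no accidental KKKR/KRKR)
LINKER_ALPHABET = "DEGKNQST"
# decoy backgrounds: compositionally broad (so unrelated proteins do not
# cross-score under BLOSUM62) but cysteine-free — every finger pattern
# needs two C's, so no accidental finger can arise in a decoy background
DECOY_ALPHABET = "ADEFGIKLMNPQRSTVWY"
DNA = "ACGT"

_CODONS_FOR = {}
for _c, _aa in GENETIC_CODE.items():
    if _aa != "*":
        _CODONS_FOR.setdefault(_aa, []).append(_c)
for _aa in _CODONS_FOR:
    _CODONS_FOR[_aa].sort()


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the generator (defaults are the test surface)."""

    seed: int = 1
    n_family: int = 20
    n_decoys: int = 20
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 600_000 for i in range(1, 6)}
    )
    #: (type, target_ka, target_ks); duplicates are family members derived
    #: from distinct base members
    dup_pairs: list[tuple[str, float, float]] = field(
        default_factory=lambda: [
            ("tandem", 0.05, 0.25),
            ("tandem", 0.05, 0.25),
            ("segmental", 0.05, 0.25),
            ("segmental", 0.05, 0.25),
        ]
    )
    #: planted collinear blocks for the two-genome bundle
    block_spec: list[tuple[int, str]] = field(
        default_factory=lambda: [(8, "same"), (6, "inverted")]
    )
    #: element name -> copies planted per member promoter
    cis_plan: dict[str, int] = field(
        default_factory=lambda: {"CGTCA-motif": 3, "G-Box": 2}
    )
    #: gene -> sample -> true fold change (calibrator must be 1.0)
    expr_design: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "IDD1": {"control": 1.0, "treated2h": 4.0, "treated8h": 0.5},
            "IDD2": {"control": 1.0, "treated2h": 1.0, "treated8h": 2.0},
        }
    )
    ct_noise_sd: float = 0.2
    nls_prob: float = 0.8
    calibrator: str = "control"
    reference_gene: str = "Tubulin"
    replicates: int = 3

    def __post_init__(self) -> None:
        for _, ka, ks in self.dup_pairs:
            if not (0 <= ka <= 0.7 and 0 <= ks <= 0.7):
                raise SimulationError("target ka/ks outside [0, 0.7]")
        if self.ct_noise_sd < 0:
            raise SimulationError("ct_noise_sd must be >= 0")
        if min(self.n_family, self.n_decoys) < 0:
            raise SimulationError("counts must be >= 0")


@dataclass
class PlantedDup:
    gene_a: str
    gene_b: str
    dup_type: str
    target_ka: float
    target_ks: float


@dataclass
class TruthTable:
    members: list[str] = field(default_factory=list)
    decoys: list[str] = field(default_factory=list)
    groups: dict[str, int] = field(default_factory=dict)
    has_nls: dict[str, bool] = field(default_factory=dict)
    exon_counts: dict[str, int] = field(default_factory=dict)
    dup_pairs: list[PlantedDup] = field(default_factory=list)
    cis_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    block_anchors: list[list[tuple[str, str]]] = field(default_factory=list)
    fold_changes: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass
class GenomeBundle:
    """Everything the generator knows about one synthetic genome."""

    genome: dict[str, SeqRecord]
    models: list[GeneModel]
    proteome: list[SeqRecord]
    cds: dict[str, str]
    queries: list[SeqRecord]
    truth: TruthTable


# ---------------------------------------------------------------------------
# protein construction

def _rand(rng: random.Random, alphabet: str, n: int) -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def _finger(rng: random.Random, kind: str) -> str:
    """One zinc finger satisfying the consensus (C2HC ends in C)."""
    x = lambda n: _rand(rng, LINKER_ALPHABET, n)
    last = "H" if kind == "C2H2" else "C"
    return (
        rng.choice("FY") + x(1) + "C" + x(rng.randint(2, 5)) + "C" + x(3)
        + rng.choice("FY") + x(5) + rng.choice("AVLIM") + x(2)
        + "H" + x(rng.randint(3, 5)) + last
    )


def _domain(rng: random.Random) -> str:
    parts = []
    for kind in ("C2H2", "C2H2", "C2HC", "C2HC"):
        parts.append(_finger(rng, kind))
        parts.append(_rand(rng, LINKER_ALPHABET, rng.randint(6, 12)))
    return "".join(parts[:-1])


@dataclass
class _ProteinPlan:
    seq: str
    has_nls: bool
    group: int
    protected: set[int]  # residue indices that nonsynonymous changes must avoid


def _mutate_background(rng: random.Random, seq: str, mu: float) -> str:
    """Substitute background (hydrophilic-alphabet) positions at rate mu.

    Positions holding consensus-critical characters (F/Y/C/H/W and the
    hydrophobic psi residues — none of which are in the background
    alphabet) are left untouched, so the finger consensus survives.
    """
    out = list(seq)
    for i, ch in enumerate(out):
        if ch in LINKER_ALPHABET and rng.random() < mu:
            out[i] = rng.choice(LINKER_ALPHABET.replace(ch, ""))
    return "".join(out)


@dataclass
class _FamilyScaffold:
    """Shared family architecture members are derived from.

    Gene families are not collections of independent sequences: members
    descend from a common ancestor.  A base scaffold is diversified into
    per-group scaffolds, and members mutate their group scaffold lightly,
    giving realistic within/between-group similarity while the planted
    duplicate pairs stay far more similar than any other pair.
    """

    nterm: str
    nls_pos: int
    domain: str
    cterm: str
    m1_pos: int
    m2_pos: int

    @classmethod
    def build(cls, rng: random.Random) -> "_FamilyScaffold":
        nterm = _rand(rng, LINKER_ALPHABET, 40)
        nls_pos = rng.randint(3, 30)
        dom = _domain(rng)
        cterm = _rand(rng, LINKER_ALPHABET, 120)
        m1 = rng.randint(5, 15)
        m2 = m1 + 11 + rng.randint(8, 20)
        return cls(nterm, nls_pos, dom, cterm, m1, m2)

    def diversify(self, rng: random.Random, mu: float) -> "_FamilyScaffold":
        return _FamilyScaffold(
            _mutate_background(rng, self.nterm, mu),
            self.nls_pos,
            _mutate_background(rng, self.domain, mu),
            _mutate_background(rng, self.cterm, mu),
            self.m1_pos,
            self.m2_pos,
        )


GROUP_MU = 0.22  # background divergence between group scaffolds
MEMBER_MU = 0.08  # background divergence of a member from its group scaffold
QUERY_MU = 0.30  # divergence of query species proteins from the base scaffold


def _member_protein(
    rng: random.Random,
    scaffold: _FamilyScaffold,
    group: int,
    with_nls: bool,
    mu: float = MEMBER_MU,
) -> _ProteinPlan:
    """Family protein: M + N-term (NLS?) + domain + C-term (group motifs).

    ``protected`` marks the domain, NLS and C-terminal motif spans so that
    duplicate evolution cannot knock a member out of the family.
    """
    protected: set[int] = set()
    nterm = _mutate_background(rng, scaffold.nterm, mu)
    if with_nls:
        nls = rng.choice(NLS_MOTIFS)
        nterm = nterm[:scaffold.nls_pos] + nls + nterm[scaffold.nls_pos + 4:]
    dom = _mutate_background(rng, scaffold.domain, mu)
    cterm = _mutate_background(rng, scaffold.cterm, mu)
    motif_spans: list[tuple[int, int]] = []
    if group != 4:
        m1, m2 = "MSATALLQKAA", "TRDFLG"
        p1, p2 = scaffold.m1_pos, scaffold.m2_pos
        cterm = cterm[:p1] + m1 + cterm[p1 + len(m1):]
        cterm = cterm[:p2] + m2 + cterm[p2 + len(m2):]
        motif_spans = [(p1, p1 + len(m1)), (p2, p2 + len(m2))]
    seq = "M" + nterm + dom + cterm
    dom_start = 1 + len(nterm)
    protected.update(range(dom_start, dom_start + len(dom)))
    cterm_start = dom_start + len(dom)
    for s, e in motif_spans:
        protected.update(range(cterm_start + s, cterm_start + e))
    if with_nls:
        protected.update(range(1 + scaffold.nls_pos, 1 + scaffold.nls_pos + 4))
    return _ProteinPlan(seq, with_nls, group, protected)


def _decoy_protein(rng: random.Random) -> str:
    """Non-member: two fingers at most, or a quartet with a broken finger."""
    style = rng.randint(0, 2)
    if style == 0:  # plain background, no fingers
        return "M" + _rand(rng, DECOY_ALPHABET, rng.randint(150, 350))
    if style == 1:  # two fingers only
        mid = _finger(rng, "C2H2") + _rand(rng, LINKER_ALPHABET, 10) + _finger(rng, "C2HC")
    else:  # four fingers, first one broken at a coordinating Cys
        dom = _domain(rng)
        idx = dom.index("C")
        mid = dom[:idx] + "S" + dom[idx + 1:]
    return (
        "M" + _rand(rng, DECOY_ALPHABET, rng.randint(20, 40))
        + mid + _rand(rng, DECOY_ALPHABET, rng.randint(60, 120))
    )


def back_translate(rng: random.Random, protein: str) -> str:
    """Uniform-synonymous-codon back-translation, with a stop appended."""
    codons = [rng.choice(_CODONS_FOR[aa]) for aa in protein]
    codons.append(rng.choice(sorted(STOP_CODONS)))
    return "".join(codons)


# ---------------------------------------------------------------------------
# duplicate evolution

def _inverse_jc(d: float) -> float:
    p = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    if p >= 0.75:
        raise SimulationError(f"target distance {d} at/beyond JC saturation")
    return p


def evolve_duplicate(
    cds: str,
    target_ka: float,
    target_ks: float,
    seed: int,
    protected_codons: set[int] | None = None,
) -> str:
    """Mutate a CDS so NG86 + JC estimates are expected to equal the targets.

    Plants round(N * pN) nonsynonymous and round(S * pS) synonymous point
    substitutions (pN, pS from inverting the Jukes-Cantor map), at
    distinct nucleotide positions, never creating a stop codon.
    Nonsynonymous changes avoid ``protected_codons`` (codon indices).
    """
    if len(cds) % 3:
        raise SimulationError("CDS length not divisible by 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    coding = [i for i, c in enumerate(codons) if c not in STOP_CODONS]
    if any(codons[i] in STOP_CODONS for i in coding[:-1]):
        raise SimulationError("internal stop codon in input CDS")
    protected = protected_codons or set()
    rng = random.Random(seed)

    s_sites = n_sites = 0.0
    for i in coding:
        s, n = ng86_site_counts(codons[i])
        s_sites += s
        n_sites += n
    want_syn = round(s_sites * _inverse_jc(target_ks))
    want_non = round(n_sites * _inverse_jc(target_ka))

    used: set[int] = set()  # nucleotide positions already substituted

    def plant(kind: str, count: int) -> None:
        planted = 0
        attempts = 0
        while planted < count:
            attempts += 1
            if attempts > 200 * max(count, 1) + 1000:
                raise SimulationError(f"could not place {kind} substitutions")
            ci = rng.choice(coding)
            if kind == "non" and ci in protected:
                continue
            pos = rng.randint(0, 2)
            ntpos = 3 * ci + pos
            if ntpos in used:
                continue
            cur = codons[ci]
            options = []
            for nuc in DNA:
                if nuc == cur[pos]:
                    continue
                mut = cur[:pos] + nuc + cur[pos + 1:]
                if mut in STOP_CODONS:
                    continue
                same_aa = GENETIC_CODE[mut] == GENETIC_CODE[cur]
                if (kind == "syn") == same_aa:
                    options.append(mut)
            if not options:
                continue
            codons[ci] = rng.choice(options)
            used.add(ntpos)
            planted += 1

    plant("syn", want_syn)
    plant("non", want_non)
    return "".join(codons)


# ---------------------------------------------------------------------------
# genome assembly

def _random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choices(DNA, k=n))


def _split_exons(rng: random.Random, cds: str, n_exons: int) -> tuple[list[str], list[str]]:
    """Split a CDS into exon pieces with random intron sequences between."""
    L = len(cds)
    cuts = sorted(rng.sample(range(1, L), n_exons - 1)) if n_exons > 1 else []
    pieces = []
    prev = 0
    for c in cuts + [L]:
        pieces.append(cds[prev:c])
        prev = c
    introns = [_random_dna(rng, rng.randint(80, 250)) for _ in range(n_exons - 1)]
    return pieces, introns


def _clean_background(rng: random.Random, seq: str, patterns: list[re.Pattern]) -> str:
    """Rewrite bases until no catalog pattern matches on either strand."""
    s = seq
    for _ in range(50):
        dirty = False
        for pat in patterns:
            for target in (s, revcomp(s)):
                m = pat.search(target)
                if m:
                    dirty = True
                    if target is s:
                        i = m.start() + (m.end() - m.start()) // 2
                    else:
                        i = len(s) - 1 - (m.start() + (m.end() - m.start()) // 2)
                    s = s[:i] + rng.choice(DNA.replace(s[i], "")) + s[i + 1:]
        if not dirty:
            return s
    raise SimulationError("could not clean promoter background")


def _planted_promoter(
    rng: random.Random, length: int, plan: dict[str, int], catalog: CisCatalog
) -> str:
    """Promoter background free of catalog elements, with planted copies.

    The returned promoter satisfies two checked guarantees: the plus-strand
    hit count of every catalog element equals the plan (zero for elements
    not planted), and every hit on either strand lies entirely inside a
    planted site (no junction artifacts).  Minus-strand hits arise only as
    the strand mirrors the planted sites imply (e.g. a planted CGTCA site
    is also a minus-strand TGACG hit; a palindromic G-Box hits both
    strands).
    """
    patterns = [
        re.compile(iupac_regex(p))
        for entry in catalog.entries.values()
        for p in entry.patterns
    ]
    for _ in range(30):
        bg = _clean_background(rng, _random_dna(rng, length), patterns)
        inserts: list[tuple[int, str]] = []
        taken: list[tuple[int, int]] = []
        ok = True
        for element, count in sorted(plan.items()):
            pats = catalog.entries[element].patterns
            for _ in range(count):
                site = _concrete(rng, rng.choice(pats))
                for _try in range(200):
                    pos = rng.randint(10, length - len(site) - 10)
                    if all(pos + len(site) + 6 <= s or pos >= e + 6 for s, e in taken):
                        taken.append((pos, pos + len(site)))
                        inserts.append((pos, site))
                        break
                else:
                    ok = False
        if not ok:
            continue
        prom = list(bg)
        for pos, site in inserts:
            prom[pos:pos + len(site)] = site
        prom_s = "".join(prom)
        if _promoter_is_clean(prom_s, plan, taken, catalog):
            return prom_s
    raise SimulationError("could not plant promoter elements cleanly")


def _promoter_is_clean(
    prom: str,
    plan: dict[str, int],
    planted_intervals: list[tuple[int, int]],
    catalog: CisCatalog,
) -> bool:
    from .cis_elements import scan_promoter

    plus_counts: dict[str, int] = {}
    for hit in scan_promoter(SeqRecord("tmp", prom), catalog):
        if not any(s <= hit.position and hit.position + len(hit.matched) <= e
                   for s, e in planted_intervals):
            return False
        if hit.strand == "+":
            plus_counts[hit.element] = plus_counts.get(hit.element, 0) + 1
    for element in catalog.entries:
        if plus_counts.get(element, 0) != plan.get(element, 0):
            return False
    return True


def _concrete(rng: random.Random, iupac: str) -> str:
    from .cis_elements import IUPAC

    return "".join(rng.choice(IUPAC[ch]) for ch in iupac)


@dataclass
class _Placement:
    chrom: str
    start: int
    strand: str


class _Placer:
    """Sequential non-overlapping gene placement with promoter headroom."""

    def __init__(self, rng: random.Random, chrom_sizes: dict[str, int], gap: int = 4_000):
        self.rng = rng
        self.cursor = {c: 2_000 for c in chrom_sizes}
        self.sizes = dict(chrom_sizes)
        self.order = sorted(chrom_sizes)
        self.gap = gap
        self._rr = 0

    def place(self, glen: int, chrom: str | None = None, min_start: int | None = None) -> _Placement:
        if chrom is None:
            chrom = self.order[self._rr % len(self.order)]
            self._rr += 1
        start = self.cursor[chrom]
        if min_start is not None:
            start = max(start, min_start)
        if start + glen + 2_000 > self.sizes[chrom]:
            raise SimulationError(f"chromosome {chrom} too short for requested genes")
        self.cursor[chrom] = start + glen + self.gap
        strand = self.rng.choice("+-")
        return _Placement(chrom, start, strand)


def _install_gene(
    chrom_buf: dict[str, bytearray],
    gene_id: str,
    cds: str,
    n_exons: int,
    placement: _Placement,
    rng: random.Random,
) -> GeneModel:
    """Write a gene (exons + introns) into the chromosome buffer."""
    pieces, introns = _split_exons(rng, cds, n_exons)
    transcript_genomic = ""
    exon_rel: list[tuple[int, int]] = []
    off = 0
    for i, piece in enumerate(pieces):
        exon_rel.append((off, off + len(piece)))
        transcript_genomic += piece
        off += len(piece)
        if i < len(introns):
            transcript_genomic += introns[i]
            off += len(introns[i])
    glen = len(transcript_genomic)
    if placement.strand == "-":
        transcript_genomic = revcomp(transcript_genomic)
        exon_rel = [(glen - e, glen - s) for s, e in reversed(exon_rel)]
    start = placement.start
    chrom_buf[placement.chrom][start:start + glen] = transcript_genomic.encode()
    exons = [(start + s, start + e) for s, e in exon_rel]
    return GeneModel(
        gene_id=gene_id,
        chrom=placement.chrom,
        strand=placement.strand,
        start=start,
        end=start + glen,
        exons=exons,
        cds=cds,
    )


def _install_promoter(
    chrom_buf: dict[str, bytearray], model: GeneModel, promoter: str
) -> None:
    if model.strand == "+":
        lo = model.start - len(promoter)
        if lo < 0:
            raise SimulationError(f"{model.gene_id}: no room for promoter")
        chrom_buf[model.chrom][lo:model.start] = promoter.encode()
    else:
        hi = model.end + len(promoter)
        if hi > len(chrom_buf[model.chrom]):
            raise SimulationError(f"{model.gene_id}: no room for promoter")
        chrom_buf[model.chrom][model.end:hi] = revcomp(promoter).encode()


def generate_family_genome(
    cfg: SimConfig, catalog: CisCatalog | None = None
) -> GenomeBundle:
    """One synthetic genome with planted family members, decoys, duplicates
    and promoter elements; deterministic given ``cfg.seed``."""
    rng = random.Random(cfg.seed)
    catalog = catalog or default_catalog()
    truth = TruthTable(fold_changes={g: dict(s) for g, s in cfg.expr_design.items()})

    chrom_buf = {c: bytearray(_random_dna(rng, n).encode()) for c, n in cfg.chromosomes.items()}
    placer = _Placer(rng, cfg.chromosomes)

    n_dup = len(cfg.dup_pairs)
    n_base = cfg.n_family - n_dup
    if n_base < n_dup:
        raise SimulationError("n_family too small for the requested duplicate pairs")

    proteome: list[SeqRecord] = []
    cds_map: dict[str, str] = {}
    models: list[GeneModel] = []
    plans: dict[str, _ProteinPlan] = {}

    base_scaffold = _FamilyScaffold.build(rng)
    group_scaffolds = {
        g: base_scaffold.diversify(rng, GROUP_MU) for g in (1, 2, 3, 4)
    }

    # base family members
    for i in range(n_base):
        gid = f"FAM{i + 1:03d}"
        group = (i % 4) + 1
        with_nls = rng.random() < cfg.nls_prob
        plan = _member_protein(rng, group_scaffolds[group], group, with_nls)
        cds = back_translate(rng, plan.seq)
        n_exons = rng.choice((2, 3, 4))
        placement = placer.place(len(cds) + 260 * (n_exons - 1))
        model = _install_gene(chrom_buf, gid, cds, n_exons, placement, rng)
        plans[gid] = plan
        proteome.append(SeqRecord(gid, plan.seq, f"synthetic family member group{group}"))
        cds_map[gid] = cds
        models.append(model)
        truth.members.append(gid)
        truth.groups[gid] = group
        truth.has_nls[gid] = with_nls
        truth.exon_counts[gid] = n_exons

    # duplicate partners (members themselves), derived from distinct bases
    for j, (dup_type, ka, ks) in enumerate(cfg.dup_pairs):
        src = truth.members[j]
        gid = f"FAM{n_base + j + 1:03d}"
        # protein residue index == codon index (CDS is protein + stop)
        protected = set(plans[src].protected)
        new_cds = evolve_duplicate(
            cds_map[src], ka, ks, seed=rng.randrange(2 ** 31), protected_codons=protected
        )
        protein = translate(new_cds[:-3])
        src_model = next(m for m in models if m.gene_id == src)
        n_exons = rng.choice((2, 3, 4))
        glen = len(new_cds) + 260 * (n_exons - 1)
        if dup_type == "tandem":
            placement = placer.place(
                glen, chrom=src_model.chrom, min_start=src_model.end + 210_000
            )
        elif dup_type == "segmental":
            other = [c for c in sorted(cfg.chromosomes) if c != src_model.chrom]
            placement = placer.place(glen, chrom=rng.choice(other))
        else:
            raise SimulationError(f"unknown duplication type {dup_type!r}")
        model = _install_gene(chrom_buf, gid, new_cds, n_exons, placement, rng)
        proteome.append(SeqRecord(gid, protein, f"synthetic duplicate of {src}"))
        cds_map[gid] = new_cds
        models.append(model)
        plans[gid] = _ProteinPlan(protein, plans[src].has_nls, plans[src].group,
                                  set(plans[src].protected))
        truth.members.append(gid)
        truth.groups[gid] = plans[src].group
        truth.has_nls[gid] = plans[src].has_nls
        truth.exon_counts[gid] = n_exons
        truth.dup_pairs.append(PlantedDup(src, gid, dup_type, ka, ks))

    # decoys
    for i in range(cfg.n_decoys):
        gid = f"DEC{i + 1:03d}"
        protein = _decoy_protein(rng)
        cds = back_translate(rng, protein)
        n_exons = rng.choice((2, 3, 4))
        placement = placer.place(len(cds) + 260 * (n_exons - 1))
        model = _install_gene(chrom_buf, gid, cds, n_exons, placement, rng)
        proteome.append(SeqRecord(gid, protein, "synthetic decoy"))
        cds_map[gid] = cds
        models.append(model)
        truth.decoys.append(gid)
        truth.exon_counts[gid] = n_exons

    # promoters with planted elements (members only)
    if cfg.cis_plan:
        for gid in truth.members:
            prom = _planted_promoter(rng, 1_500, cfg.cis_plan, catalog)
            model = next(m for m in models if m.gene_id == gid)
            _install_promoter(chrom_buf, model, prom)
            truth.cis_counts[gid] = dict(cfg.cis_plan)  # plus-strand convention

    genome = {
        c: SeqRecord(c, buf.decode(), "synthetic chromosome")
        for c, buf in chrom_buf.items()
    }
    queries = [
        SeqRecord(
            f"QUERY{k}",
            _member_protein(rng, base_scaffold, k, True, mu=QUERY_MU).seq,
            "synthetic query (diverged species homolog)",
        )
        for k in (1, 4)
    ]
    return GenomeBundle(genome, models, proteome, cds_map, queries, truth)


def generate_genome_pair(cfg: SimConfig) -> tuple[GenomeBundle, GenomeBundle]:
    """Two genomes with planted collinear blocks (for microsynteny tests).

    Each block from ``cfg.block_spec`` occupies its own chromosome pair:
    genome A holds a run of genes (one family member, the rest decoys);
    genome B holds slightly diverged orthologous copies in the same
    (``same``) or reversed (``inverted``) order.  Truth records the
    planted anchor pairs per block, ordered along genome A.
    """
    rng = random.Random(cfg.seed + 7_919)
    catalog = default_catalog()
    truth_a, truth_b = TruthTable(), TruthTable()
    chrom_a: dict[str, int] = {}
    chrom_b: dict[str, int] = {}
    per_gene = 6_000
    for bi, (n_anchors, _orient) in enumerate(cfg.block_spec):
        chrom_a[f"A{bi + 1}"] = per_gene * n_anchors + 10_000
        chrom_b[f"B{bi + 1}"] = per_gene * n_anchors + 10_000

    buf_a = {c: bytearray(_random_dna(rng, n).encode()) for c, n in chrom_a.items()}
    buf_b = {c: bytearray(_random_dna(rng, n).encode()) for c, n in chrom_b.items()}
    placer_a = _Placer(rng, chrom_a)
    placer_b = _Placer(rng, chrom_b)

    prot_a: list[SeqRecord] = []
    prot_b: list[SeqRecord] = []
    cds_a: dict[str, str] = {}
    cds_b: dict[str, str] = {}
    models_a: list[GeneModel] = []
    models_b: list[GeneModel] = []

    scaffold = _FamilyScaffold.build(rng)
    for bi, (n_anchors, orient) in enumerate(cfg.block_spec):
        member_slot = rng.randrange(n_anchors)
        a_entries = []
        for k in range(n_anchors):
            gid_a = f"A{bi + 1}G{k + 1:02d}"
            gid_b = f"B{bi + 1}G{k + 1:02d}"
            if k == member_slot:
                plan = _member_protein(rng, scaffold, (k % 4) + 1, True)
                protein, protected = plan.seq, plan.protected
                desc = "synthetic family member"
                truth_a.members.append(gid_a)
                truth_b.members.append(gid_b)
            else:
                # generic neighbor genes: plain backgrounds, so the only
                # high-scoring partner of each gene is its ortholog
                protein = "M" + _rand(rng, DECOY_ALPHABET, rng.randint(150, 350))
                protected, desc = set(), "synthetic neighbor gene"
                truth_a.decoys.append(gid_a)
                truth_b.decoys.append(gid_b)
            cds = back_translate(rng, protein)
            ortho_cds = evolve_duplicate(
                cds, 0.02, 0.05, seed=rng.randrange(2 ** 31), protected_codons=protected
            )
            a_entries.append((gid_a, gid_b, protein, cds, ortho_cds, desc))

        b_order = a_entries if orient == "same" else list(reversed(a_entries))
        for gid_a, _, protein, cds, _, desc in a_entries:
            placement = placer_a.place(len(cds), chrom=f"A{bi + 1}")
            models_a.append(_install_gene(buf_a, gid_a, cds, 2, placement, rng))
            prot_a.append(SeqRecord(gid_a, protein, desc))
            cds_a[gid_a] = cds
        for _, gid_b, _, _, ortho_cds, desc in b_order:
            placement = placer_b.place(len(ortho_cds), chrom=f"B{bi + 1}")
            models_b.append(_install_gene(buf_b, gid_b, ortho_cds, 2, placement, rng))
            prot_b.append(SeqRecord(gid_b, translate(ortho_cds[:-3]), desc))
            cds_b[gid_b] = ortho_cds
        truth_a.block_anchors.append([(ga, gb) for ga, gb, *_ in a_entries])

    genome_a = {c: SeqRecord(c, b.decode()) for c, b in buf_a.items()}
    genome_b = {c: SeqRecord(c, b.decode()) for c, b in buf_b.items()}
    queries = [
        SeqRecord(
            "QUERY1",
            _member_protein(rng, scaffold, 1, True, mu=QUERY_MU).seq,
            "synthetic query",
        )
    ]
    bundle_a = GenomeBundle(genome_a, models_a, prot_a, cds_a, queries, truth_a)
    bundle_b = GenomeBundle(genome_b, models_b, prot_b, cds_b, queries, truth_b)
    return bundle_a, bundle_b


# ---------------------------------------------------------------------------
# qPCR simulation

def simulate_ct_table(cfg: SimConfig):
    """Replicated Ct measurements matching the planted expression design.

    The reference gene has constant expected Ct across samples; a target's
    expected Ct in a sample is ref + base dCt - log2(true fold change),
    with Gaussian noise of sd ``cfg.ct_noise_sd`` per replicate.
    Returns a long-format pandas DataFrame (sample, gene, replicate, ct).
    """
    import pandas as pd

    if not cfg.expr_design:
        raise SimulationError("expr_design is empty")
    rng = random.Random(cfg.seed + 104_729)
    ref_ct = 20.0
    base_dct = 3.0
    rows = []
    samples = sorted({s for d in cfg.expr_design.values() for s in d})
    for sample in samples:
        for rep in range(1, cfg.replicates + 1):
            rows.append(
                dict(sample=sample, gene=cfg.reference_gene, replicate=rep,
                     ct=ref_ct + rng.gauss(0, cfg.ct_noise_sd))
            )
    for gene, design in sorted(cfg.expr_design.items()):
        for sample, fc in sorted(design.items()):
            if fc <= 0:
                raise SimulationError(f"fold change must be > 0 ({gene}/{sample})")
            mean_ct = ref_ct + base_dct - math.log2(fc)
            for rep in range(1, cfg.replicates + 1):
                rows.append(
                    dict(sample=sample, gene=gene, replicate=rep,
                         ct=mean_ct + rng.gauss(0, cfg.ct_noise_sd))
                )
    return pd.DataFrame(rows)
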