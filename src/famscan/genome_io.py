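"""Sequence and annotation I/O.

FASTA and GFF3 readers/writers, coordinate conventions, exon counting and
strand-aware promoter extraction.

Coordinates are 0-based half-open everywhere inside the package; conversion
to and from GFF3's 1-based inclusive convention happens only at the file
boundary.
"""

from __future__ import annotations

import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}
NUCLEOTIDE_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeIOError(ValueError):
    """Malformed input file or inconsistent annotation."""


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence (protein or nucleotide)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise GenomeIOError("sequence record has empty id")
        if not self.seq:
            raise GenomeIOError(f"sequence record {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """A gene locus: coordinates, exon structure and spliced CDS.

    ``start``/``end`` and exon intervals are 0-based half-open on the
    chromosome.  ``cds`` is the spliced coding sequence in transcription
    order (reverse-complemented for minus-strand genes).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: str = ""
    cds_ok: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GenomeIOError(f"{self.gene_id}: strand must be + or -")
        if self.start > self.end:
            raise GenomeIOError(f"{self.gene_id}: start > end")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise GenomeIOError(f"{self.gene_id}: overlapping exons")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N stays N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into a list of records, order preserved.

    Softmasked (lowercase) residues are uppercased.  Duplicate ids are an
    error, as is an empty file.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise GenomeIOError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SeqRecord(rec.id, str(rec.seq).upper(), desc))
    if not records:
        raise GenomeIOError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    """Write records as multi-FASTA, wrapped at ``width`` columns."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def _fetch(genome: Mapping[str, SeqRecord] | Mapping[str, str], chrom: str) -> str:
    rec = genome[chrom]
    return rec.seq if isinstance(rec, SeqRecord) else rec


def read_gff3(path: str | Path, genome: Mapping[str, SeqRecord] | None = None) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into :class:`GeneModel` objects.

    For genes with several mRNAs the isoform with the longest summed CDS is
    kept as the gene's representative.  If ``genome`` is given, the spliced
    CDS is assembled from it (reverse-complemented for minus-strand genes);
    a CDS whose length is not a multiple of 3 is kept but flagged
    (``cds_ok=False``) with a warning.  Exons or CDS whose Parent cannot be
    resolved are an error.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    known_tx: set[str] = set()
    for feat in db.all_features():
        if feat.featuretype in ("mRNA", "transcript", "gene"):
            known_tx.add(feat.id)
    for feat in db.all_features():
        if feat.featuretype in ("exon", "CDS"):
            parents = feat.attributes.get("Parent", [])
            if not parents or not any(p in known_tx for p in parents):
                raise GenomeIOError(
                    f"orphan {feat.featuretype} at {feat.seqid}:{feat.start}-{feat.end}"
                )

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype=("mRNA", "transcript")))
        candidates = mrnas if mrnas else [gene]
        best: GeneModel | None = None
        best_cds_len = -1
        for tx in candidates:
            exons = [
                (f.start - 1, f.end)
                for f in db.children(tx, featuretype="exon", order_by="start")
            ]
            cds_iv = [
                (f.start - 1, f.end)
                for f in db.children(tx, featuretype="CDS", order_by="start")
            ]
            if not exons:
                exons = list(cds_iv)
            cds_len = sum(e - s for s, e in cds_iv)
            cds = ""
            cds_ok = cds_len % 3 == 0
            if genome is not None and cds_iv:
                chrom_seq = _fetch(genome, gene.seqid)
                cds = "".join(chrom_seq[s:e] for s, e in sorted(cds_iv)).upper()
                if gene.strand == "-":
                    cds = revcomp(cds)
            if not cds_ok:
                warnings.warn(
                    f"{gene.id}: CDS length {cds_len} not divisible by 3",
                    stacklevel=2,
                )
            if cds_len > best_cds_len:
                best_cds_len = cds_len
                best = GeneModel(
                    gene_id=gene.id,
                    chrom=gene.seqid,
                    strand=gene.strand,
                    start=gene.start - 1,
                    end=gene.end,
                    exons=exons,
                    cds=cds,
                    cds_ok=cds_ok,
                )
        if best is not None:
            models.append(best)
    return models


def read_gff3_text(text: str, genome: Mapping[str, SeqRecord] | None = None) -> list[GeneModel]:
    """`read_gff3` on an in-memory GFF3 string (convenience for pipelines)."""
    with tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False) as fh:
        fh.write(text)
        name = fh.name
    try:
        return read_gff3(name, genome=genome)
    finally:
        Path(name).unlink(missing_ok=True)


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Emit gene/mRNA/exon/CDS lines (1-based inclusive) with Parent links."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gid, tid = m.gene_id, f"{m.gene_id}.t1"
            fh.write(
                f"{m.chrom}\tfamscan\tgene\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{m.chrom}\tfamscan\tmRNA\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\tID={tid};Parent={gid}\n"
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.chrom}\tfamscan\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\tParent={tid}\n"
                )
            phase = 0
            cds_exons = m.exons if m.strand == "+" else list(reversed(m.exons))
            for s, e in cds_exons:
                fh.write(
                    f"{m.chrom}\tfamscan\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t{phase}\tParent={tid}\n"
                )
                phase = (3 - ((e - s) - phase) % 3) % 3


def exon_count(model: GeneModel) -> int:
    """Number of exon intervals in the gene's representative isoform."""
    return len(model.exons)


def extract_upstream(
    genome: Mapping[str, SeqRecord] | Mapping[str, str],
    model: GeneModel,
    length: int = 1500,
    include_start: bool = False,
) -> SeqRecord:
    """Promoter: the ``length`` bp immediately 5' of the gene on the coding strand.

    The translation-start codon itself is excluded unless ``include_start``.
    For minus-strand genes the slice lies downstream in chromosome
    coordinates and is reverse-complemented.  Truncated with a warning when
    the gene sits within ``length`` bp of the chromosome edge.
    """
    if model.chrom not in genome:
        raise GenomeIOError(f"chromosome {model.chrom!r} not in genome")
    chrom_seq = _fetch(genome, model.chrom)
    if model.strand == "+":
        hi = model.start + (3 if include_start else 0)
        lo = max(0, hi - (length + (3 if include_start else 0)))
        seq = chrom_seq[lo:hi]
    else:
        lo = model.end - (3 if include_start else 0)
        hi = min(len(chrom_seq), lo + length + (3 if include_start else 0))
        seq = revcomp(chrom_seq[lo:hi])
    want = length + (3 if include_start else 0)
    if len(seq) < want:
        warnings.warn(
            f"{model.gene_id}: promoter truncated to {len(seq)} bp "
            f"(chromosome edge)",
            stacklevel=2,
        )
    return SeqRecord(f"{model.gene_id}_promoter", seq.upper(), f"upstream {len(seq)} bp")


def write_tsv(rows: Iterable[Mapping[str, object]], path: str | Path, columns: list[str]) -> None:
    """Write a header + rows TSV report."""
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")
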