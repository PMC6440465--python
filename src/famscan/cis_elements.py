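"""Promoter cis-acting element scanning.

Scans promoter sequences (by default the 1,500 bp upstream of the
translation start) for a configurable catalog of plant cis-acting
elements on both strands.  Patterns are IUPAC strings; N in the sequence
never matches.  All overlapping occurrences are reported, per strand,
without collapsing reverse-complement equivalences (a CGTCA site is both
a plus-strand CGTCA-motif hit and a minus-strand TGACG-motif hit).

The shipped default catalog carries consensus strings for the elements
commonly reported in plant promoter studies (light, hormone, stress and
meristem classes).  Consensus strings for several elements vary between
database versions; the catalog is data, not code, and can be replaced
wholesale with an export from a motif database.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .genome_io import SeqRecord, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


class CatalogError(ValueError):
    pass


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    patterns: tuple[str, ...]
    function_class: str


@dataclass
class CisCatalog:
    entries: dict[str, CatalogEntry] = field(default_factory=dict)

    def add(self, name: str, patterns: list[str], function_class: str) -> None:
        for p in patterns:
            bad = set(p.upper()) - set(IUPAC)
            if bad:
                raise CatalogError(f"{name}: non-IUPAC characters {sorted(bad)}")
        if not patterns:
            raise CatalogError(f"{name}: no patterns")
        self.entries[name] = CatalogEntry(
            name, tuple(p.upper() for p in patterns), function_class
        )


@dataclass(frozen=True)
class CisHit:
    element: str
    strand: str  # + | -
    position: int  # 0-based offset of the matched substring in the promoter
    matched: str  # forward-strand substring of the promoter


def iupac_regex(pattern: str) -> str:
    """Regex for an IUPAC pattern; degenerate codes expand to character classes.

    N in the *sequence* never matches because expansions never include N.
    """
    parts = []
    for ch in pattern.upper():
        exp = IUPAC[ch]
        parts.append(exp if len(exp) == 1 else f"[{exp}]")
    return "".join(parts)


def load_catalog(path: str | Path) -> CisCatalog:
    """Load a YAML catalog: list of {name, patterns, class} entries."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    cat = CisCatalog()
    for entry in data["elements"]:
        cat.add(entry["name"], list(entry["patterns"]), entry["class"])
    return cat


def default_catalog() -> CisCatalog:
    """The catalog shipped with the package."""
    ref = resources.files("famscan").joinpath("data/cis_catalog.yaml")
    with resources.as_file(ref) as path:
        return load_catalog(path)


def scan_promoter(promoter: SeqRecord, catalog: CisCatalog) -> list[CisHit]:
    """All overlapping catalog matches on both strands of one promoter.

    A minus-strand hit is a match of the pattern against the reverse
    complement; its ``position``/``matched`` refer to the forward-strand
    slice it occupies, so re-slicing the promoter reproduces ``matched``.
    """
    seq = promoter.seq.upper()
    rc = revcomp(seq)
    n = len(seq)
    hits: list[CisHit] = []
    for name, entry in sorted(catalog.entries.items()):
        for pattern in entry.patterns:
            rx = re.compile(f"(?=({iupac_regex(pattern)}))")
            for m in rx.finditer(seq):
                hits.append(CisHit(name, "+", m.start(), m.group(1)))
            for m in rx.finditer(rc):
                start = n - m.start() - len(m.group(1))
                hits.append(CisHit(name, "-", start, seq[start:start + len(m.group(1))]))
    hits.sort(key=lambda h: (h.position, h.element, h.strand))
    return hits


def element_summary(
    hits_by_gene: dict[str, list[CisHit]], catalog: CisCatalog
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene per-element counts and per-gene per-class totals.

    Counts include both strands (each reported hit counts once).  Returns
    (element table, class table); genes with no hits get all-zero rows.
    """
    elements = sorted(catalog.entries)
    classes = sorted({e.function_class for e in catalog.entries.values()})
    elem_rows = {}
    class_rows = {}
    for gene, hits in hits_by_gene.items():
        ecount = dict.fromkeys(elements, 0)
        ccount = dict.fromkeys(classes, 0)
        for h in hits:
            ecount[h.element] += 1
            ccount[catalog.entries[h.element].function_class] += 1
        elem_rows[gene] = ecount
        class_rows[gene] = ccount
    elem = pd.DataFrame.from_dict(elem_rows, orient="index", columns=elements)
    cls = pd.DataFrame.from_dict(class_rows, orient="index", columns=classes)
    return elem.sort_index(), cls.sort_index()
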