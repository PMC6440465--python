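"""Protein physicochemical parameters in the ExPASy/ProtParam convention.

Length, average molecular weight, Bjellqvist isoelectric point (bisection
on the Henderson-Hasselbalch net charge) and Kyte-Doolittle GRAVY.  The pK
sets and mass table are module-level data so an alternative convention can
be substituted.

Unknown residues (X) contribute the mean residue mass, carry no charge and
are excluded from the GRAVY denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

# Average (isotope-weighted) residue masses, Da; free water added once per chain.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524
MEAN_RESIDUE_MASS = sum(RESIDUE_MASS.values()) / len(RESIDUE_MASS)

# Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "E": -3.5, "Q": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Bjellqvist pK set (the one behind the ExPASy ProtParam pI).
PK_SIDE_POSITIVE = {"K": 10.0, "R": 12.0, "H": 5.98}
PK_SIDE_NEGATIVE = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PK_NTERM_DEFAULT = 7.5
PK_NTERM = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}
PK_CTERM_DEFAULT = 3.55
PK_CTERM = {"D": 4.55, "E": 4.75}


class ProtParamError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinParams:
    """Per-protein summary: residue count, MW (kDa), pI and GRAVY."""

    aa_count: int
    mw: float
    pi: float
    gravy: float


def _validate(seq: str, allow_x: bool = True) -> None:
    if not seq:
        raise ProtParamError("empty protein sequence")
    allowed = set(RESIDUE_MASS) | ({"X"} if allow_x else set())
    bad = set(seq) - allowed
    if bad:
        raise ProtParamError(f"illegal residues: {sorted(bad)}")


def molecular_weight(seq: str) -> float:
    """Average molecular weight in kDa (sum of residue masses + one water)."""
    _validate(seq)
    da = WATER_MASS + sum(
        RESIDUE_MASS.get(aa, MEAN_RESIDUE_MASS) for aa in seq
    )
    return da / 1000.0


def net_charge(seq: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at the given pH.

    Positive groups: N-terminus, K, R, H; negative: C-terminus, D, E, C, Y.
    """
    _validate(seq)
    if not 0.0 <= ph <= 14.0:
        raise ProtParamError(f"pH {ph} outside [0, 14]")

    def pos(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pk))

    def neg(pk: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pk - ph))

    charge = pos(PK_NTERM.get(seq[0], PK_NTERM_DEFAULT))
    charge += neg(PK_CTERM.get(seq[-1], PK_CTERM_DEFAULT))
    for aa in seq:
        if aa in PK_SIDE_POSITIVE:
            charge += pos(PK_SIDE_POSITIVE[aa])
        elif aa in PK_SIDE_NEGATIVE:
            charge += neg(PK_SIDE_NEGATIVE[aa])
    return charge


def isoelectric_point(seq: str, tol: float = 1e-4, max_iter: int = 100) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14]."""
    _validate(seq)
    lo, hi = 0.0, 14.0
    c_lo, c_hi = net_charge(seq, lo), net_charge(seq, hi)
    if c_lo < 0 or c_hi > 0:
        raise ProtParamError("net charge has no sign change on [0, 14]")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        c = net_charge(seq, mid)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gravy(seq: str) -> float:
    """Grand average of hydropathy (mean Kyte-Doolittle over known residues)."""
    _validate(seq)
    vals = [KYTE_DOOLITTLE[aa] for aa in seq if aa in KYTE_DOOLITTLE]
    if not vals:
        raise ProtParamError("no standard residues for GRAVY")
    return sum(vals) / len(vals)


def protein_params(seq: str) -> ProteinParams:
    """All four ProtParam summaries for one sequence."""
    return ProteinParams(
        aa_count=len(seq),
        mw=molecular_weight(seq),
        pi=isoelectric_point(seq),
        gravy=gravy(seq),
    )
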