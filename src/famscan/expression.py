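"""Relative qPCR expression by the 2^-ddCt method.

For each sample, dCt = mean Ct(target) - mean Ct(reference); ddCt =
dCt(sample) - dCt(calibrator); relative expression (fold change) =
2^-ddCt.  The spread is propagated from the replicate SD of dCt as the
asymmetric range 2^-(ddCt +/- sd).  Significance of a sample against the
calibrator is a two-sided Welch t-test on the per-replicate dCt values,
starred at P < 0.05 (*) and P < 0.01 (**); no multiple-testing
correction is applied, matching the raw-threshold convention of qPCR
bar plots.

Ct tables are long-format DataFrames with columns
(sample, gene, replicate, ct).  Undetected genes are simply absent from
the table and yield no fold-change row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ("sample", "gene", "replicate", "ct")


class ExpressionError(ValueError):
    pass


@dataclass(frozen=True)
class FoldChange:
    sample: str
    gene: str
    delta_ct: float
    delta_delta_ct: float
    fold: float
    fold_lo: float
    fold_hi: float
    p_value: float | None
    stars: str


def read_ct_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ExpressionError(f"Ct table missing columns: {sorted(missing)}")
    return table


def _validate(table: pd.DataFrame) -> None:
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ExpressionError(f"Ct table missing columns: {sorted(missing)}")
    if ((table.ct <= 0) | (table.ct >= 45)).any():
        raise ExpressionError("Ct values must lie in (0, 45)")
    counts = table.groupby(["sample", "gene"])["replicate"].count()
    if counts.nunique() > 1:
        raise ExpressionError("replicate count differs between (sample, gene) cells")


def _replicate_dct(
    table: pd.DataFrame, target: str, reference: str, sample: str
) -> np.ndarray:
    """Per-replicate dCt values (target - reference, paired by replicate id)."""
    sub = table[table["sample"] == sample]
    tgt = sub[sub.gene == target].set_index("replicate")["ct"]
    ref = sub[sub.gene == reference].set_index("replicate")["ct"]
    if ref.empty:
        raise ExpressionError(f"reference gene {reference!r} missing in sample {sample!r}")
    if tgt.empty:
        raise ExpressionError(f"target gene {target!r} missing in sample {sample!r}")
    if len(tgt) != len(ref):
        raise ExpressionError(f"replicate count mismatch in sample {sample!r}")
    return (tgt - ref.reindex(tgt.index)).to_numpy()


def significance(
    table: pd.DataFrame, target: str, reference: str, sample: str, calibrator: str
) -> tuple[float | None, str]:
    """Welch t-test of per-replicate dCt, sample vs calibrator."""
    d_s = _replicate_dct(table, target, reference, sample)
    d_c = _replicate_dct(table, target, reference, calibrator)
    if len(d_s) < 2 or len(d_c) < 2:
        return None, ""
    if np.ptp(np.concatenate([d_s, d_c])) == 0.0:
        return 1.0, ""  # identical replicate sets: no evidence of difference
    p = float(stats.ttest_ind(d_s, d_c, equal_var=False).pvalue)
    if math.isnan(p):
        return None, ""
    stars = "**" if p < 0.01 else "*" if p < 0.05 else ""
    return p, stars


def delta_delta_ct(
    table: pd.DataFrame,
    target: str,
    reference: str,
    calibrator_sample: str,
    with_significance: bool = True,
) -> list[FoldChange]:
    """2^-ddCt fold changes of one target gene across all samples."""
    _validate(table)
    samples = sorted(table["sample"].unique())
    if calibrator_sample not in samples:
        raise ExpressionError(f"calibrator sample {calibrator_sample!r} not in table")
    dct_cal = _replicate_dct(table, target, reference, calibrator_sample)
    out: list[FoldChange] = []
    for sample in samples:
        dct = _replicate_dct(table, target, reference, sample)
        ddct = float(dct.mean() - dct_cal.mean())
        sd = float(dct.std(ddof=1)) if len(dct) > 1 else 0.0
        p, stars = (None, "")
        if with_significance and sample != calibrator_sample:
            p, stars = significance(table, target, reference, sample, calibrator_sample)
        out.append(
            FoldChange(
                sample=sample,
                gene=target,
                delta_ct=float(dct.mean()),
                delta_delta_ct=ddct,
                fold=2.0 ** -ddct,
                fold_lo=2.0 ** -(ddct + sd),
                fold_hi=2.0 ** -(ddct - sd),
                p_value=p,
                stars=stars,
            )
        )
    return out


def fold_change_table(
    table: pd.DataFrame, reference: str, calibrator_sample: str
) -> pd.DataFrame:
    """ddCt analysis of every non-reference gene in the table."""
    genes = sorted(g for g in table.gene.unique() if g != reference)
    rows = []
    for gene in genes:
        sub = table[(table.gene == gene) | (table.gene == reference)]
        for fc in delta_delta_ct(sub, gene, reference, calibrator_sample):
            rows.append(fc.__dict__)
    return pd.DataFrame(rows)
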