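"""Proteomics set analytics and closed-form assay arithmetic.

Covers the threshold-based comparisons used for vesicle and tissue
proteomes — Venn partitions of identification lists, fold-change ≥ 2 plus
FDR ≤ 0.05 differential filters on log2 abundances — together with the
small closed-form assay computations: 2^−ΔΔCt relative qPCR expression
against the mean of three housekeeping genes, the CD63-bead sEV-secretion
fold change, and the GAPDH-normalised densitometry ratio.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VennCounts",
    "DiffResult",
    "venn_partition",
    "bh_adjust",
    "differential_filter",
    "ddct",
    "bead_fold_change",
    "densitometry_ratio",
]

VennCounts = namedtuple("VennCounts", ["a_only", "b_only", "common"])

DEFAULT_HOUSEKEEPING = ("ACTB", "GAPDH", "B2M")


def venn_partition(set_a, set_b) -> VennCounts:
    """Exact two-set partition counts (A-only, B-only, common)."""
    a, b = set(set_a), set(set_b)
    common = len(a & b)
    return VennCounts(a_only=len(a) - common, b_only=len(b) - common, common=common)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order preserving.

    NaN entries (degenerate tests) are excluded from the number of tests m
    and returned as NaN.  Raises for p outside [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    valid = ~np.isnan(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if valid.sum():
        out[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return out


@dataclass
class DiffResult:
    """Per-protein differential table plus the direction counts.

    ``table`` columns: log2fc, fold_change (linear, B over A), p_value,
    p_adjusted, significant.  ``n_up_in_a`` / ``n_up_in_b`` count
    significant proteins by direction.
    """

    table: pd.DataFrame
    n_up_in_a: int
    n_up_in_b: int


def differential_filter(
    table: pd.DataFrame,
    groups: pd.Series,
    group_a: str = "A",
    group_b: str = "B",
    fc_min: float = 2.0,
    fdr_max: float = 0.05,
    assume_log2: bool = False,
) -> DiffResult:
    """Two-group differential filter: |fold change| ≥ fc_min and FDR ≤ fdr_max.

    Abundances are log2-transformed (unless ``assume_log2``), group means
    are taken on the log2 scale and back-transformed, so the reported fold
    change is the geometric-mean ratio B/A.  Per-protein Welch t-tests on
    log2 values feed a Benjamini–Hochberg adjustment; proteins with zero
    variance in both groups are flagged degenerate (NaN p) and excluded
    from the number of tests.
    """
    cols_a = groups.index[groups == group_a]
    cols_b = groups.index[groups == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    a = table[cols_a].to_numpy(float)
    b = table[cols_b].to_numpy(float)
    if not assume_log2:
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("abundances must be positive for log2 transform")
        a, b = np.log2(a), np.log2(b)

    log2fc = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant proteins trip scipy's precision-loss warning; they are
        # flagged degenerate below
        warnings.simplefilter("ignore", RuntimeWarning)
        pvals = stats.ttest_ind(b, a, axis=1, equal_var=False).pvalue
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    pvals = np.where(degenerate, np.nan, pvals)
    padj = bh_adjust(pvals)

    fc = 2.0**log2fc
    sig = ((fc >= fc_min) | (fc <= 1.0 / fc_min)) & (padj <= fdr_max)
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "fold_change": fc,
            "p_value": pvals,
            "p_adjusted": padj,
            "significant": sig,
        },
        index=table.index,
    )
    return DiffResult(
        table=out,
        n_up_in_a=int((sig & (log2fc < 0)).sum()),
        n_up_in_b=int((sig & (log2fc > 0)).sum()),
    )


def ddct(
    ct: pd.DataFrame,
    target: str,
    group: str,
    calibrator: str,
    housekeeping: tuple[str, ...] = DEFAULT_HOUSEKEEPING,
) -> float:
    """Relative expression by the 2^−ΔΔCt method.

    ``ct`` is a long table with columns ``sample, gene, ct, group``.  Per
    sample, ΔCt = Ct_target − mean(Ct of the housekeeping genes); ΔΔCt is
    the group-mean ΔCt minus the calibrator-mean ΔCt, and the result is
    2^−ΔΔCt.  A per-sample additive Ct offset shared by target and
    housekeeping genes cancels exactly.
    """
    for col in ("sample", "gene", "ct", "group"):
        if col not in ct.columns:
            raise ValueError(f"Ct table missing column '{col}'")
    if np.any(ct["ct"].to_numpy(float) <= 0):
        raise ValueError("Ct values must be positive")

    def delta_cts(label: str) -> np.ndarray:
        sub = ct[ct["group"] == label]
        if sub.empty:
            raise ValueError(f"no samples in group '{label}'")
        vals = []
        for sample, g in sub.groupby("sample"):
            genes = g.set_index("gene")["ct"]
            if target not in genes.index:
                raise ValueError(f"sample {sample} missing target gene {target}")
            missing = [h for h in housekeeping if h not in genes.index]
            if missing:
                raise ValueError(f"sample {sample} missing housekeeping genes {missing}")
            vals.append(genes[target] - np.mean([genes[h] for h in housekeeping]))
        return np.asarray(vals, dtype=float)

    ddct_val = delta_cts(group).mean() - delta_cts(calibrator).mean()
    return float(2.0**(-ddct_val))


def bead_fold_change(
    treatment: tuple[float, float, float],
    control: tuple[float, float, float],
) -> float:
    """sEV-secretion fold change from the CD63-bead capture assay.

    Each condition is (fluorescence AU, percent positive beads, viable
    cells); the per-condition signal is fluorescence × percent positive /
    viable cells, and the fold change is treatment over control.
    """

    def au(fluor, pct, cells):
        if cells <= 0:
            raise ValueError("viable cell count must be positive")
        return fluor * pct / cells

    denom = au(*control)
    if denom == 0:
        raise ValueError("control signal is zero: fold change undefined")
    return float(au(*treatment) / denom)


def densitometry_ratio(
    band_plaque: float,
    loading_plaque: float,
    band_intact: float,
    loading_intact: float,
) -> float:
    """Western-blot fold change, plaque over intact, normalised to the
    loading control (GAPDH) in each sample."""
    for name, v in (
        ("band_plaque", band_plaque),
        ("loading_plaque", loading_plaque),
        ("band_intact", band_intact),
        ("loading_intact", loading_intact),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    return float((band_plaque / loading_plaque) / (band_intact / loading_intact))
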