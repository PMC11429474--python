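"""CNVR copy-number dose effects on gene expression (cis/trans eQTL).

Each (CNVR, gene) pair is tested with a per-pair linear model of
log2(expression + 1) on the region copy number — the additive model of
standard eQTL mappers.  Pairs are labeled cis when the gene's TSS lies
within a distance window of the CNVR on the same chromosome, trans
otherwise, and Benjamini-Hochberg FDR is applied separately within the
cis and trans families.  A significant positive slope at a locus where
one breed carries more copies is a dose effect: expression scales with
genomic copy number.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cnvr import CnvrCatalog

logger = logging.getLogger(__name__)

EQTL_COLS = ["cnvr_id", "gene_id", "relation", "slope", "tstat", "p", "fdr",
             "direction"]


def _relation(region, gene, cis_window_bp: int) -> str:
    if region["chrom"] != gene["chrom"]:
        return "trans"
    tss = int(gene["tss"])
    if tss < region["start"]:
        dist = region["start"] - tss
    elif tss >= region["end"]:
        dist = tss - region["end"] + 1
    else:
        dist = 0
    return "cis" if dist <= cis_window_bp else "trans"


def associate(
    catalog: CnvrCatalog,
    expr: pd.DataFrame,
    gene_pos: pd.DataFrame,
    breed_l: str,
    breed_m: str,
    cnvr_ids: list[str] | None = None,
    cis_window_bp: int = 1_000_000,
    log2_transform: bool = True,
) -> pd.DataFrame:
    """Per-pair linear regression of log2(expression + 1) on copy number.

    ``gene_pos`` needs gene_id, chrom, tss.  Pairs whose copy number has
    zero variance across the shared samples are skipped with a log notice.
    ``direction`` is the predicted expression change in breed M relative
    to breed L: sign(slope x (mean CN_M - mean CN_L)).  The pseudo-count
    log2 transform stabilizes the fit at FPKM scale; ``log2_transform=False``
    regresses raw expression instead.
    """
    shared = [s for s in expr.columns if s in catalog.cn.columns]
    if len(shared) < 4:
        raise ValueError("need at least 4 samples shared between CN and expression")
    samples_l = [s for s in shared if catalog.breeds[s] == breed_l]
    samples_m = [s for s in shared if catalog.breeds[s] == breed_m]
    regions = catalog.regions.set_index("cnvr_id")
    if cnvr_ids is None:
        cnvr_ids = list(regions.index)
    genes = gene_pos.set_index("gene_id")
    log_expr = np.log2(expr[shared] + 1.0) if log2_transform else expr[shared]

    rows = []
    for rid in cnvr_ids:
        region = regions.loc[rid]
        cn = catalog.cn.loc[rid, shared].to_numpy(dtype=float)
        if np.var(cn) == 0.0:
            logger.info("skipping %s: zero copy-number variance", rid)
            continue
        delta = (
            catalog.cn.loc[rid, samples_m].mean()
            - catalog.cn.loc[rid, samples_l].mean()
        )
        for gid in expr.index:
            y = log_expr.loc[gid].to_numpy(dtype=float)
            fit = stats.linregress(cn, y)
            rel = _relation(region, genes.loc[gid], cis_window_bp)
            direction = "up" if fit.slope * delta > 0 else "down"
            rows.append(
                (rid, gid, rel, float(fit.slope),
                 float(fit.slope / fit.stderr) if fit.stderr > 0 else np.inf,
                 float(fit.pvalue), np.nan, direction)
            )
    records = pd.DataFrame(rows, columns=EQTL_COLS)
    for rel in ("cis", "trans"):
        mask = records["relation"] == rel
        if mask.any():
            records.loc[mask, "fdr"] = multipletests(
                records.loc[mask, "p"], method="fdr_bh"
            )[1]
    return records


def direction_summary(
    records: pd.DataFrame, threshold_fdr: float = 0.05
) -> pd.DataFrame:
    """Counts of up/down-regulated significant genes per cis/trans family."""
    sig = records[records["fdr"] < threshold_fdr]
    out = (
        sig.groupby(["relation", "direction"], observed=False)["gene_id"]
        .nunique()
        .unstack(fill_value=0)
    )
    return out.reindex(
        index=["cis", "trans"], columns=["up", "down"], fill_value=0
    ).fillna(0).astype(int)


def dose_concordance(
    catalog: CnvrCatalog, expr: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Spearman rank correlation of per-sample CN with expression, per pair.

    A pair is dose-consistent when the correlation is positive with
    p < 0.05.  Constant copy number leaves the correlation undefined
    (NaN, flagged).
    """
    shared = [s for s in expr.columns if s in catalog.cn.columns]
    rows = []
    for rid, gid in pairs:
        cn = catalog.cn.loc[rid, shared].to_numpy(dtype=float)
        y = expr.loc[gid, shared].to_numpy(dtype=float)
        if np.var(cn) == 0.0:
            rows.append((rid, gid, np.nan, np.nan, False, False))
            continue
        rho, p = stats.spearmanr(cn, y)
        rows.append((rid, gid, float(rho), float(p), rho > 0 and p < 0.05, True))
    return pd.DataFrame(
        rows,
        columns=["cnvr_id", "gene_id", "rho", "p", "dose_consistent", "defined"],
    )


def de_filter(
    de_table: pd.DataFrame, lfc_min: float = 2.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Differential-expression threshold rule over an external DE table.

    Keeps genes with |log2 fold change| > ``lfc_min`` and adjusted
    p < ``alpha``; log2 fold change is oriented LW:MZ, so positive values
    mean higher expression in LW.  Adds a ``direction`` column from the
    sign.
    """
    if not np.isfinite(de_table["log2fc"]).all():
        raise ValueError("log2 fold changes must be finite (apply a pseudo-count)")
    kept = de_table[
        (de_table["log2fc"].abs() > lfc_min) & (de_table["padj"] < alpha)
    ].copy()
    kept["direction"] = np.where(kept["log2fc"] > 0, "up_in_LW", "up_in_MZ")
    return kept
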