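"""qPCR copy-number estimation and concordance with the read-depth caller.

Relative quantification: with a reference gene of conserved copy number
and a calibrator sample of known diploid state, ddCt = dCt_sample -
dCt_calibrator and CN = 2 * 2^(-ddCt).  Replicates are averaged on the Ct
scale before exponentiation.  Standard curves (Ct vs log10 dilution) give
the amplification efficiency of each primer pair, 10^(-1/slope) - 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .depth import classify_window


@dataclass
class QpcrTable:
    """Raw Ct table: sample_id, locus_id, replicate, ct_target, ct_reference.

    ``calibrator`` names the sample of known CN = 2 used as the ddCt anchor.
    """

    data: pd.DataFrame
    calibrator: str

    def __post_init__(self) -> None:
        ct = self.data[["ct_target", "ct_reference"]].to_numpy()
        if ((ct <= 0) | (ct >= 45)).any():
            raise ValueError("Ct values must lie in (0, 45)")


@dataclass
class StandardCurve:
    locus_id: str
    slope: float
    intercept: float
    r_squared: float
    efficiency: float  # fraction: 1.0 == perfect per-cycle doubling
    valid: bool


def fit_standard_curve(
    log10_dilution, ct, locus_id: str = ""
) -> StandardCurve:
    """OLS of Ct on log10(dilution); needs >= 3 dilution points.

    A non-negative slope marks the curve invalid (efficiency undefined,
    reported as NaN).
    """
    x = np.asarray(log10_dilution, dtype=float)
    y = np.asarray(ct, dtype=float)
    if x.size < 3:
        raise ValueError("a standard curve needs at least 3 dilution points")
    fit = stats.linregress(x, y)
    valid = fit.slope < 0
    eff = 10.0 ** (-1.0 / fit.slope) - 1.0 if valid else float("nan")
    return StandardCurve(
        locus_id=locus_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        efficiency=eff,
        valid=valid,
    )


def estimate_cn(table: QpcrTable) -> pd.DataFrame:
    """Per (sample, locus) copy number by the ddCt scheme.

    dCt = Ct_target - Ct_reference per replicate, averaged per (sample,
    locus); ddCt = dCt - dCt_calibrator(locus); CN = 2 * 2^(-ddCt).
    """
    df = table.data.copy()
    df["dct"] = df["ct_target"] - df["ct_reference"]
    mean_dct = (
        df.groupby(["sample_id", "locus_id"], sort=False)["dct"]
        .mean()
        .reset_index()
    )
    cal = mean_dct[mean_dct["sample_id"] == table.calibrator].set_index(
        "locus_id"
    )["dct"]
    missing = set(mean_dct["locus_id"]) - set(cal.index)
    if missing:
        raise ValueError(
            f"calibrator {table.calibrator!r} missing for loci {sorted(missing)}"
        )
    out = mean_dct[mean_dct["sample_id"] != table.calibrator].copy()
    ddct = out["dct"].to_numpy() - cal.loc[out["locus_id"]].to_numpy()
    out["cn"] = 2.0 * 2.0 ** (-ddct)
    return out[["sample_id", "locus_id", "cn"]].reset_index(drop=True)


def concordance(
    qpcr_cn: pd.DataFrame, caller_cn: pd.DataFrame
) -> tuple[float, pd.DataFrame]:
    """Agreement of loss/normal/gain categories between qPCR and the caller.

    Both inputs carry sample_id, locus_id, cn; keys are intersected.
    Returns (agreement fraction, confusion table qPCR-state x caller-state).
    """
    merged = qpcr_cn.merge(
        caller_cn, on=["sample_id", "locus_id"], suffixes=("_qpcr", "_caller")
    )
    if merged.empty:
        raise ValueError("no shared (sample, locus) keys between qPCR and caller")
    states_q = [classify_window(v).value for v in merged["cn_qpcr"]]
    states_c = [classify_window(v).value for v in merged["cn_caller"]]
    order = ["loss", "normal", "gain"]
    confusion = (
        pd.crosstab(
            pd.Categorical(states_q, categories=order),
            pd.Categorical(states_c, categories=order),
            dropna=False,
        )
        .rename_axis(index="qpcr", columns="caller")
    )
    agree = float(np.mean(np.array(states_q) == np.array(states_c)))
    return agree, confusion
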