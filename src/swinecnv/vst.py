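"""V_ST: variance-based copy-number differentiation between two breeds.

For a CNVR with copy numbers split into breeds L and M,

    V_ST = (V_total - (V_L * N_L + V_M * N_M) / N_total) / V_total

where all variances are population variances (divisor n).  With that
convention the size-weighted within-breed variance never exceeds the
total variance (law of total variance), so V_ST lies in [0, 1]: 0 when
the breeds share one distribution of copy numbers, 1 when copy numbers
are constant within each breed but differ between them.  The statistic
is the copy-number analogue of F_ST.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cnvr import CnvrCatalog


@dataclass
class VstRecord:
    cnvr_id: str
    v_total: float
    v_within: float
    vst: float
    defined: bool


def compute_vst(values_l, values_m, cnvr_id: str = "") -> VstRecord:
    """V_ST for one CNVR from the two breeds' copy numbers.

    Each breed needs at least 2 samples.  If the total variance is zero
    the statistic is undefined; the record is flagged and vst reported
    as 0.
    """
    a = np.asarray(values_l, dtype=float)
    b = np.asarray(values_m, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each breed needs at least 2 samples for V_ST")
    v_total = float(np.var(np.concatenate([a, b])))
    v_within = float(
        (np.var(a) * a.size + np.var(b) * b.size) / (a.size + b.size)
    )
    if v_total == 0.0:
        return VstRecord(cnvr_id, 0.0, 0.0, 0.0, defined=False)
    vst = (v_total - v_within) / v_total
    # clamp fp dust at the ends; the decomposition bounds vst to [0, 1]
    vst = min(1.0, max(0.0, vst))
    return VstRecord(cnvr_id, v_total, v_within, vst, defined=True)


def compute_vst_table(
    catalog: CnvrCatalog, breed_l: str, breed_m: str
) -> pd.DataFrame:
    """Per-CNVR V_ST records for a catalog, with genomic coordinates."""
    samples_l = [s for s, b in catalog.breeds.items() if b == breed_l]
    samples_m = [s for s, b in catalog.breeds.items() if b == breed_m]
    rows = []
    for _, r in catalog.regions.iterrows():
        rid = r["cnvr_id"]
        rec = compute_vst(
            catalog.cn.loc[rid, samples_l],
            catalog.cn.loc[rid, samples_m],
            cnvr_id=rid,
        )
        rows.append(
            {
                "cnvr_id": rid, "chrom": r["chrom"], "start": r["start"],
                "end": r["end"], "v_total": rec.v_total,
                "v_within": rec.v_within, "vst": rec.vst,
                "defined": rec.defined,
            }
        )
    return pd.DataFrame(
        rows, columns=["cnvr_id", "chrom", "start", "end", "v_total",
                       "v_within", "vst", "defined"]
    )


def select_top_quantile(records: pd.DataFrame, q: float = 0.01) -> list[str]:
    """IDs of the floor(q * N) records with the largest V_ST.

    N is the number of records supplied; undefined (zero-variance) records
    are excluded from the ranking.  Ties at the cutoff break by genomic
    order (chrom, start).  k = 0 returns an empty list with a warning.
    """
    if records.empty:
        raise ValueError("no V_ST records to rank")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    k = math.floor(q * len(records))
    if k == 0:
        warnings.warn(
            f"top-{q:g} of {len(records)} records is empty", stacklevel=2
        )
        return []
    ranked = records[records["defined"]].sort_values(
        ["vst", "chrom", "start"], ascending=[False, True, True]
    )
    return list(ranked["cnvr_id"].head(k))


def filter_differential(
    candidates: list[str],
    catalog: CnvrCatalog,
    breed_l: str,
    breed_m: str,
    min_delta: float = 0.5,
) -> list[str]:
    """Keep candidates with |mean CN(L) - mean CN(M)| >= min_delta.

    An automated stand-in for manual genome-browser screening of the
    top-quantile candidates: only regions with a substantial between-breed
    mean copy-number difference survive.
    """
    samples_l = [s for s, b in catalog.breeds.items() if b == breed_l]
    samples_m = [s for s, b in catalog.breeds.items() if b == breed_m]
    kept = []
    for rid in candidates:
        delta = abs(
            catalog.cn.loc[rid, samples_l].mean()
            - catalog.cn.loc[rid, samples_m].mean()
        )
        if delta >= min_delta:
            kept.append(rid)
    return kept
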