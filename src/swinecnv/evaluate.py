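"""Parameter-recovery evaluation of the pipeline on synthetic data.

Given a simulation's ground truth, these helpers score how well each
analysis stage recovers what was planted: segment-level CNV recovery,
V_ST ranking of breed-differential loci, statistical power for dose
genes, and the type-I error of the eQTL association under the null.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cnvr import CnvrCatalog, build_cnvrs
from .depth import build_cn_matrix, segment_all
from .eqtl import associate
from .simulate import GroundTruth, SimulationConfig, simulate_depth
from .vst import compute_vst_table


def segment_recovery(
    truth: GroundTruth, segments: pd.DataFrame, min_length_bp: int = 3000
) -> tuple[float, int]:
    """Fraction of planted per-sample CNVs recovered with correct direction.

    A (sample, locus) event — truth CN != 2 at a locus of at least
    ``min_length_bp`` — counts as recovered when one of that sample's
    called segments of the matching state (gain for CN > 2, loss for
    CN < 2) overlaps the locus.  Returns (fraction, number of events).
    """
    events = 0
    recovered = 0
    by_sample = dict(tuple(segments.groupby("sample_id", sort=False)))
    for _, locus in truth.loci.iterrows():
        if locus["end"] - locus["start"] < min_length_bp:
            continue
        for s in truth.cn.columns:
            cn = truth.cn.at[locus["locus_id"], s]
            if cn == 2:
                continue
            events += 1
            want_state = "gain" if cn > 2 else "loss"
            segs = by_sample.get(s)
            if segs is None:
                continue
            hit = segs[
                (segs["chrom"] == locus["chrom"])
                & (segs["start"] < locus["end"])
                & (segs["end"] > locus["start"])
                & (segs["state"] == want_state)
            ]
            recovered += int(len(hit) > 0)
    if events == 0:
        raise ValueError("no planted CNV events at or above min_length_bp")
    return recovered / events, events


def _call_catalog(config: SimulationConfig):
    tracks, truth = simulate_depth(config)
    matrix = build_cn_matrix(tracks)
    segments = segment_all(matrix)
    catalog = build_cnvrs(segments, matrix)
    return truth, matrix, segments, catalog


def differential_loci_top_ranked(
    truth: GroundTruth, catalog: CnvrCatalog, breed_l: str, breed_m: str
) -> bool:
    """True when the top-k V_ST regions all overlap planted differential loci
    (k = number of differential loci)."""
    diff = truth.loci[truth.loci["kind"] == "differential"]
    k = len(diff)
    if k == 0:
        raise ValueError("no differential loci planted")
    records = compute_vst_table(catalog, breed_l, breed_m)
    ranked = records[records["defined"]].sort_values(
        ["vst", "chrom", "start"], ascending=[False, True, True]
    )
    top = ranked.head(k)
    for _, r in top.iterrows():
        ov = diff[
            (diff["chrom"] == r["chrom"])
            & (diff["start"] < r["end"])
            & (diff["end"] > r["start"])
        ]
        if ov.empty:
            return False
    return True


def vst_rank_success_rate(
    base_config: SimulationConfig,
    n_seeds: int = 100,
    breed_l: str = "LW",
    breed_m: str = "MZ",
) -> tuple[float, int]:
    """Across reruns with seeds base_seed..base_seed+n_seeds-1, the rate at
    which planted breed-differential loci occupy the top V_ST ranks."""
    wins = 0
    for i in range(n_seeds):
        cfg = dataclasses.replace(base_config, seed=base_config.seed + i)
        truth, _, _, catalog = _call_catalog(cfg)
        wins += int(differential_loci_top_ranked(truth, catalog, breed_l, breed_m))
    return wins / n_seeds, n_seeds


def dose_gene_power(
    truth: GroundTruth,
    catalog: CnvrCatalog,
    expr: pd.DataFrame,
    genes: pd.DataFrame,
    breed_l: str = "LW",
    breed_m: str = "MZ",
    alpha: float = 0.05,
    gamma: float = 1.0,
    cis_window_bp: int = 1_000_000,
) -> tuple[float, int]:
    """Power to recover planted dose genes as significant cis eQTLs.

    A dose gene is recovered when a catalog region overlapping its planted
    locus gives a cis association at BH-FDR < ``alpha`` with the slope
    sign matching the planted exponent.  Returns (power, n dose genes).
    """
    if truth.dose_pairs is None or truth.dose_pairs.empty:
        raise ValueError("no dose genes planted")
    loci = truth.loci.set_index("locus_id")
    regions = catalog.regions
    locus_cnvrs: dict[str, set[str]] = {}
    for lid in truth.dose_pairs["locus_id"].unique():
        locus = loci.loc[lid]
        ov = regions[
            (regions["chrom"] == locus["chrom"])
            & (regions["start"] < locus["end"])
            & (regions["end"] > locus["start"])
        ]
        locus_cnvrs[lid] = set(ov["cnvr_id"])
    test_ids = sorted(set().union(*locus_cnvrs.values()))
    records = associate(
        catalog, expr, genes, breed_l, breed_m, cnvr_ids=test_ids,
        cis_window_bp=cis_window_bp,
    )
    want_sign = np.sign(gamma)
    hits = 0
    for _, pair in truth.dose_pairs.iterrows():
        rec = records[
            (records["gene_id"] == pair["gene_id"])
            & (records["cnvr_id"].isin(locus_cnvrs[pair["locus_id"]]))
            & (records["relation"] == "cis")
            & (records["fdr"] < alpha)
            & (np.sign(records["slope"]) == want_sign)
        ]
        hits += int(len(rec) > 0)
    n = len(truth.dose_pairs)
    return hits / n, n


def eqtl_null_type1_rate(
    n_pairs: int = 1000, seed: int = 0, alpha: float = 0.05
) -> tuple[float, int]:
    """Empirical type-I error of the per-pair test on null data.

    One variable-copy-number region, ``n_pairs`` genes whose expression is
    independent of it; returns the fraction of pairs with p < ``alpha``.
    """
    rng = np.random.default_rng([seed, 97])
    samples = [f"LW_{i:02d}" for i in range(12)] + [
        f"MZ_{i:02d}" for i in range(11)
    ]
    breeds = {s: s.split("_")[0] for s in samples}
    cn_values = rng.integers(1, 5, size=len(samples)).astype(float)
    regions = pd.DataFrame(
        [{"cnvr_id": "null_r", "chrom": "chr1", "start": 0, "end": 10_000,
          "length": 10_000, "type": "gain", "n_carriers": len(samples),
          "carriers_LW": 12, "carriers_MZ": 11}]
    )
    catalog = CnvrCatalog(
        regions=regions,
        cn=pd.DataFrame([cn_values], index=["null_r"], columns=samples),
        breeds=breeds,
        genome_size=10_000_000,
    )
    expr = pd.DataFrame(
        2.0 ** rng.normal(4.0, 1.0, size=(n_pairs, len(samples))),
        index=[f"G{i:04d}" for i in range(n_pairs)],
        columns=samples,
    )
    gene_pos = pd.DataFrame(
        {"gene_id": expr.index, "chrom": "chr2",
         "tss": np.arange(n_pairs) * 1000}
    )
    records = associate(catalog, expr, gene_pos, "LW", "MZ")
    return float((records["p"] < alpha).mean()), len(records)
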