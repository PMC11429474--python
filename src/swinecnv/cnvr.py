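"""Population CNVR construction, typing, and genomic-feature annotation.

Per-sample CNV segments are merged across samples by interval union
(>= 1 bp overlap): any set of transitively overlapping segments becomes
one population copy-number-variable region (CNVR).  A CNVR is typed
gain / loss / both from the states of its carrier segments, and every
sample (carrier or not) gets a region copy number, the mean CN of its
windows inside the region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .depth import CopyNumberMatrix

FEATURE_PRIORITY = [
    "promoter",
    "5'UTR",
    "3'UTR",
    "exon",
    "intron",
    "downstream",
    "distal_intergenic",
]


@dataclass
class CnvrCatalog:
    """Population CNVR catalog.

    regions: cnvr_id, chrom, start, end, length, type, n_carriers, plus one
    carriers_<breed> column per breed.  cn: regions x samples mean copy
    numbers.  span / coverage summarize the genome fraction affected.
    """

    regions: pd.DataFrame
    cn: pd.DataFrame
    breeds: dict[str, str]
    genome_size: int

    @property
    def span(self) -> int:
        return int(self.regions["length"].sum())

    @property
    def coverage(self) -> float:
        return self.span / self.genome_size

    def __len__(self) -> int:
        return len(self.regions)


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals; >= 1 bp overlap merges (touching does not)."""
    merged: list[list[int]] = []
    for s, e in sorted(iv):
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def build_cnvrs(
    segments: pd.DataFrame,
    matrix: CopyNumberMatrix,
    min_carriers: int = 1,
) -> CnvrCatalog:
    """Merge per-sample segments into a population CNVR catalog.

    Region type: gain if every carrier segment is a gain, loss if every one
    is a loss, both otherwise.  Regions carried by fewer than
    ``min_carriers`` samples are dropped.  Rebuilding from a catalog's own
    intervals is a no-op (merging is idempotent).
    """
    breeds = matrix.breeds
    breed_names = sorted(set(breeds.values()))
    win = matrix.windows
    win_by_chrom = {
        c: (g["start"].to_numpy(), g["end"].to_numpy(), g.index.to_numpy())
        for c, g in win.groupby("chrom", sort=False)
    }

    rows = []
    cn_rows = []
    region_no = 0
    for chrom in win["chrom"].unique():
        seg_c = segments[segments["chrom"] == chrom]
        if seg_c.empty:
            continue
        merged = _merge_intervals(list(zip(seg_c["start"], seg_c["end"])))
        starts, ends, w_idx = win_by_chrom[chrom]
        for s, e in merged:
            inside = seg_c[(seg_c["start"] < e) & (seg_c["end"] > s)]
            carriers = inside["sample_id"].unique()
            if len(carriers) < min_carriers:
                continue
            states = set(inside["state"])
            rtype = states.pop() if len(states) == 1 else "both"
            region_no += 1
            row = {
                "cnvr_id": f"cnvr_{region_no:05d}",
                "chrom": chrom,
                "start": int(s),
                "end": int(e),
                "length": int(e - s),
                "type": rtype,
                "n_carriers": len(carriers),
            }
            carrier_breeds = pd.Series(
                [breeds[x] for x in carriers]
            ).value_counts()
            for b in breed_names:
                row[f"carriers_{b}"] = int(carrier_breeds.get(b, 0))
            rows.append(row)
            sel = w_idx[(starts < e) & (ends > s)]
            cn_rows.append(matrix.cn.loc[sel].mean(axis=0))

    breed_cols = [f"carriers_{b}" for b in breed_names]
    if rows:
        regions = pd.DataFrame(rows)
        cn = pd.DataFrame(cn_rows)
        cn.index = regions["cnvr_id"].to_numpy()
    else:
        regions = pd.DataFrame(
            columns=["cnvr_id", "chrom", "start", "end", "length", "type",
                     "n_carriers", *breed_cols]
        )
        cn = pd.DataFrame(columns=matrix.samples)
    return CnvrCatalog(
        regions=regions, cn=cn, breeds=breeds, genome_size=matrix.genome_size()
    )


def venn_partition(
    catalog: CnvrCatalog, breed_a: str, breed_b: str
) -> tuple[int, int, int]:
    """(shared, A-specific, B-specific) CNVR counts between two breeds.

    A CNVR is breed-specific iff all its carriers belong to one breed;
    shared otherwise.
    """
    for b in (breed_a, breed_b):
        if b not in set(catalog.breeds.values()):
            raise ValueError(f"unknown breed {b!r}")
    a = catalog.regions[f"carriers_{breed_a}"] > 0
    b = catalog.regions[f"carriers_{breed_b}"] > 0
    return int((a & b).sum()), int((a & ~b).sum()), int((b & ~a).sum())


def venn_from_counts(n_a: int, n_b: int, n_merged: int) -> dict[str, int]:
    """Inclusion-exclusion on published per-breed and merged CNVR counts."""
    return {
        "shared": n_a + n_b - n_merged,
        "a_specific": n_merged - n_b,
        "b_specific": n_merged - n_a,
    }


def length_frequency_stats(
    catalog: CnvrCatalog,
    length_bins_kb: tuple[float, ...] = (1.5, 3.0, 6.0, 12.0),
    freq_bins: tuple[int, ...] = (1, 5, 10, 15),
) -> tuple[pd.DataFrame, pd.Series]:
    """Length histogram per CNVR type and carrier-frequency histogram.

    Default length bins: <1.5, 1.5-3, 3-6, 6-12, >12 kb; default occupancy
    bins: 1, 2-5, 6-10, 11-15, >15 samples.
    """
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    edges = [0.0, *length_bins_kb, float("inf")]
    labels = (
        [f"<{length_bins_kb[0]:g}kb"]
        + [f"{a:g}-{b:g}kb" for a, b in zip(length_bins_kb, length_bins_kb[1:])]
        + [f">{length_bins_kb[-1]:g}kb"]
    )
    kb = catalog.regions["length"] / 1000.0
    binned = pd.cut(kb, bins=edges, labels=labels, right=True)
    length_hist = (
        pd.crosstab(binned, catalog.regions["type"], dropna=False)
        .reindex(labels)
        .fillna(0)
        .astype(int)
    )
    for t in ("gain", "loss", "both"):
        if t not in length_hist.columns:
            length_hist[t] = 0
    length_hist = length_hist[["gain", "loss", "both"]]

    f_edges = [0, *freq_bins, np.inf]
    f_labels = (
        [f"{freq_bins[0]}"]
        + [f"{a + 1}-{b}" for a, b in zip(freq_bins, freq_bins[1:])]
        + [f">{freq_bins[-1]}"]
    )
    freq_hist = (
        pd.cut(catalog.regions["n_carriers"], bins=f_edges, labels=f_labels)
        .value_counts()
        .reindex(f_labels)
        .fillna(0)
        .astype(int)
    )
    return length_hist, freq_hist


def _classify_midpoint(
    m: int, gene: pd.Series, promoter_bp: int, downstream_bp: int
) -> str | None:
    strand = gene["strand"]
    if strand not in ("+", "-"):
        raise ValueError(f"gene {gene['gene_id']} has no strand")
    start, end = int(gene["start"]), int(gene["end"])
    tss = start if strand == "+" else end
    if tss - promoter_bp <= m < tss + promoter_bp:
        return "promoter"
    if start <= m < end:
        ex_s = [int(x) for x in str(gene["exon_starts"]).split(",")]
        ex_e = [int(x) for x in str(gene["exon_ends"]).split(",")]
        in_exon = any(s <= m < e for s, e in zip(ex_s, ex_e))
        if in_exon:
            cds_s, cds_e = int(gene["cds_start"]), int(gene["cds_end"])
            if cds_s <= m < cds_e:
                return "exon"
            before_cds = m < cds_s
            if (before_cds and strand == "+") or (not before_cds and strand == "-"):
                return "5'UTR"
            return "3'UTR"
        return "intron"
    if strand == "+" and end <= m < end + downstream_bp:
        return "downstream"
    if strand == "-" and start - downstream_bp <= m < start:
        return "downstream"
    return None


def annotate_position(
    catalog: CnvrCatalog,
    gene_models: pd.DataFrame,
    promoter_bp: int = 3000,
    downstream_bp: int = 3000,
) -> tuple[pd.Series, pd.Series]:
    """Label each CNVR by the genomic feature at its midpoint.

    Priority promoter > 5'UTR > 3'UTR > exon > intron > downstream >
    distal intergenic; the promoter is TSS +/- ``promoter_bp`` (strand
    aware).  Returns (per-CNVR label Series indexed by cnvr_id,
    percentage Series over labels, summing to 100).
    """
    if gene_models["strand"].isna().any():
        raise ValueError("gene models must carry strand")
    trees: dict[str, IntervalTree] = {}
    margin = max(promoter_bp, downstream_bp)
    for i, g in gene_models.iterrows():
        trees.setdefault(g["chrom"], IntervalTree()).addi(
            int(g["start"]) - margin, int(g["end"]) + margin, i
        )
    rank = {f: r for r, f in enumerate(FEATURE_PRIORITY)}
    labels = {}
    for _, r in catalog.regions.iterrows():
        m = (int(r["start"]) + int(r["end"])) // 2
        best = "distal_intergenic"
        tree = trees.get(r["chrom"])
        if tree is not None:
            for hit in tree.at(m):
                lab = _classify_midpoint(
                    m, gene_models.loc[hit.data], promoter_bp, downstream_bp
                )
                if lab is not None and rank[lab] < rank[best]:
                    best = lab
        labels[r["cnvr_id"]] = best
    label_s = pd.Series(labels, name="feature")
    pct = (
        label_s.value_counts().reindex(FEATURE_PRIORITY).fillna(0)
        / len(label_s) * 100.0
    )
    return label_s, pct
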