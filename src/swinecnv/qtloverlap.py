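"""Overlap of differential CNVRs with a QTL interval database.

Every QTL overlapping at least one differential CNVR by >= 1 bp is
counted once, grouped by the QTL database's five top-level trait
categories (Exterior, Health, Meat, Production, Reproduction).  Fatness
traits — a subset of Meat identified by trait-name keywords — are
reported as a proportion of all overlapped QTLs and of the Meat QTLs,
the accounting used to ask whether back-fat-relevant QTLs are enriched
under copy-number-differentiated regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from intervaltree import IntervalTree

CATEGORIES = ("Exterior", "Health", "Meat", "Production", "Reproduction")
DEFAULT_FATNESS_KEYWORDS = ("fat", "backfat", "fatness")


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals (spreadsheet-style percentages)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class OverlapReport:
    """Trait-category accounting of QTLs overlapped by CNVRs."""

    total: int
    per_category: dict[str, int]
    fatness: int

    def __post_init__(self) -> None:
        unknown = set(self.per_category) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown QTL categories: {sorted(unknown)}")
        if sum(self.per_category.values()) != self.total:
            raise ValueError("per-category counts must sum to total")

    @property
    def fatness_pct_of_total(self) -> float | None:
        if self.total == 0:
            return None
        return round2(100.0 * self.fatness / self.total)

    @property
    def fatness_pct_of_meat(self) -> float | None:
        meat = self.per_category.get("Meat", 0)
        if meat == 0:
            return None
        return round2(100.0 * self.fatness / meat)


def overlap_qtls(
    cnvr_regions: pd.DataFrame,
    qtl: pd.DataFrame,
    fatness_keywords: tuple[str, ...] = DEFAULT_FATNESS_KEYWORDS,
) -> OverlapReport:
    """Count QTLs overlapped (>= 1 bp) by at least one CNVR, once each.

    ``cnvr_regions`` needs chrom, start, end (duplicated regions are
    harmless: a QTL is still counted once); ``qtl`` needs chrom, start,
    end, category, trait_name.  Unknown categories are an error.
    """
    bad = set(qtl["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown QTL categories: {sorted(bad)}")
    trees: dict[str, IntervalTree] = {}
    for _, r in cnvr_regions.iterrows():
        if r["end"] > r["start"]:
            trees.setdefault(r["chrom"], IntervalTree()).addi(
                int(r["start"]), int(r["end"])
            )
    per_category = dict.fromkeys(CATEGORIES, 0)
    fatness = 0
    total = 0
    for _, q in qtl.iterrows():
        tree = trees.get(q["chrom"])
        if tree is None or not tree.overlap(int(q["start"]), int(q["end"])):
            continue
        total += 1
        per_category[q["category"]] += 1
        name = str(q["trait_name"]).lower()
        if q["category"] == "Meat" and any(k in name for k in fatness_keywords):
            fatness += 1
    return OverlapReport(total=total, per_category=per_category, fatness=fatness)


def database_report(
    qtl: pd.DataFrame,
    fatness_keywords: tuple[str, ...] = DEFAULT_FATNESS_KEYWORDS,
) -> OverlapReport:
    """Whole-database accounting (the baseline row of the comparison)."""
    bad = set(qtl["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown QTL categories: {sorted(bad)}")
    per_category = dict.fromkeys(CATEGORIES, 0)
    fatness = 0
    for _, q in qtl.iterrows():
        per_category[q["category"]] += 1
        name = str(q["trait_name"]).lower()
        if q["category"] == "Meat" and any(k in name for k in fatness_keywords):
            fatness += 1
    return OverlapReport(
        total=len(qtl), per_category=per_category, fatness=fatness
    )


def proportion_table(
    report: OverlapReport, baseline: OverlapReport
) -> pd.DataFrame:
    """Two-row comparison: CNVR-overlapped QTLs vs the whole database.

    Percentages are half-up rounded to 2 decimals; zero denominators give
    NaN cells.
    """
    rows = []
    for name, rep in (("eQTL_CNVR", report), ("Total_QTLs", baseline)):
        row = {"group": name, "total": rep.total}
        row.update({c: rep.per_category.get(c, 0) for c in CATEGORIES})
        row["fatness"] = rep.fatness
        pt = rep.fatness_pct_of_total
        pm = rep.fatness_pct_of_meat
        row["fatness_pct_of_total"] = float("nan") if pt is None else pt
        row["fatness_pct_of_meat"] = float("nan") if pm is None else pm
        rows.append(row)
    return pd.DataFrame(rows)
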