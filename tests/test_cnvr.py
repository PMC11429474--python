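"""CNVR merging, typing, Venn partition, and genomic-feature annotation."""

import numpy as np
import pandas as pd
import pytest

import swinecnv as sc
from swinecnv.cnvr import _merge_intervals


def _matrix(n_windows=300, samples=("s1", "s2"), breeds=("LW", "MZ")):
    win = pd.DataFrame(
        {"chrom": "chr1", "start": np.arange(n_windows) * 1000,
         "end": (np.arange(n_windows) + 1) * 1000}
    )
    cn = pd.DataFrame({s: np.full(n_windows, 2.0) for s in samples})
    return sc.CopyNumberMatrix(win, cn, dict(zip(samples, breeds)))


def _seg(sample, start, end, state, cn=3.0):
    return {"sample_id": sample, "chrom": "chr1", "start": start, "end": end,
            "state": state, "cn": cn, "n_windows": (end - start) // 1000}


class TestBuildCnvrs:
    def test_single_gain_segment(self):
        segs = pd.DataFrame([_seg("s1", 5000, 9000, "gain")])
        cat = sc.build_cnvrs(segs, _matrix())
        assert len(cat) == 1
        r = cat.regions.iloc[0]
        assert (r["start"], r["end"], r["type"], r["n_carriers"]) == (
            5000, 9000, "gain", 1)

    def test_overlapping_gain_and_loss_types_both(self):
        segs = pd.DataFrame(
            [_seg("s1", 5000, 9000, "gain"), _seg("s2", 7000, 12000, "loss", 1.0)]
        )
        cat = sc.build_cnvrs(segs, _matrix())
        assert len(cat) == 1
        assert cat.regions.iloc[0]["type"] == "both"
        assert cat.regions.iloc[0]["n_carriers"] == 2

    def test_disjoint_segments_stay_separate(self):
        segs = pd.DataFrame(
            [_seg("s1", 5000, 9000, "gain"), _seg("s2", 20000, 24000, "gain")]
        )
        cat = sc.build_cnvrs(segs, _matrix())
        assert len(cat) == 2

    def test_touching_intervals_do_not_merge(self):
        # half-open: [5000,9000) and [9000,12000) share 0 bp
        assert _merge_intervals([(5000, 9000), (9000, 12000)]) == [
            (5000, 9000), (9000, 12000)]

    def test_min_carriers_filter(self):
        segs = pd.DataFrame([_seg("s1", 5000, 9000, "gain")])
        cat = sc.build_cnvrs(segs, _matrix(), min_carriers=2)
        assert len(cat) == 0

    def test_idempotent_on_own_intervals(self, small_run):
        cat = small_run["catalog"]
        as_segments = cat.regions.rename(columns={"type": "state"}).assign(
            sample_id=small_run["matrix"].samples[0], cn=2.0, n_windows=1
        ).replace({"state": {"both": "gain"}})
        rebuilt = sc.build_cnvrs(as_segments, small_run["matrix"])
        got = list(zip(rebuilt.regions["chrom"], rebuilt.regions["start"],
                       rebuilt.regions["end"]))
        want = list(zip(cat.regions["chrom"], cat.regions["start"],
                        cat.regions["end"]))
        assert got == want

    def test_type_counts_sum_to_catalog_size(self, small_run):
        cat = small_run["catalog"]
        assert cat.regions["type"].value_counts().sum() == len(cat)

    def test_region_cn_is_sample_window_mean(self):
        m = _matrix()
        m.cn.loc[5:8, "s1"] = 4.0  # windows 5000..9000
        segs = pd.DataFrame([_seg("s1", 5000, 9000, "gain")])
        cat = sc.build_cnvrs(segs, m)
        assert cat.cn.iloc[0]["s1"] == pytest.approx(4.0)
        assert cat.cn.iloc[0]["s2"] == pytest.approx(2.0)


class TestVenn:
    def test_inclusion_exclusion_identity(self, small_run):
        cat = small_run["catalog"]
        shared, a_spec, b_spec = sc.venn_partition(cat, "LW", "MZ")
        n_a = int((cat.regions["carriers_LW"] > 0).sum())
        n_b = int((cat.regions["carriers_MZ"] > 0).sum())
        assert shared == n_a + n_b - len(cat)
        assert shared + a_spec + b_spec == len(cat)

    def test_published_count_arithmetic(self):
        venn = sc.venn_from_counts(10403, 10800, 11097)
        assert venn == {"shared": 10106, "a_specific": 297, "b_specific": 694}

    def test_single_breed_catalog_all_specific(self):
        segs = pd.DataFrame([_seg("s1", 5000, 9000, "gain"),
                             _seg("s1", 20000, 24000, "loss", 1.0)])
        m = _matrix(samples=("s1", "s2"), breeds=("LW", "MZ"))
        cat = sc.build_cnvrs(segs, m)
        shared, a_spec, b_spec = sc.venn_partition(cat, "LW", "MZ")
        assert (shared, a_spec, b_spec) == (0, 2, 0)

    def test_unknown_breed_rejected(self, small_run):
        with pytest.raises(ValueError, match="unknown breed"):
            sc.venn_partition(small_run["catalog"], "LW", "Duroc")


class TestLengthFrequencyStats:
    def test_single_2kb_cnvr_in_middle_bin(self):
        segs = pd.DataFrame([_seg("s1", 5000, 7000, "gain")])
        cat = sc.build_cnvrs(segs, _matrix())
        length_hist, freq_hist = sc.length_frequency_stats(cat)
        assert length_hist.loc["1.5-3kb", "gain"] == 1
        assert length_hist.to_numpy().sum() == 1
        assert freq_hist["1"] == 1

    def test_lengths_1_2_4kb_one_per_bin(self):
        segs = pd.DataFrame(
            [_seg("s1", 5000, 6000, "gain"), _seg("s1", 20000, 22000, "gain"),
             _seg("s1", 40000, 44000, "gain")]
        )
        cat = sc.build_cnvrs(segs, _matrix())
        length_hist, _ = sc.length_frequency_stats(cat)
        assert list(length_hist["gain"][:3]) == [1, 1, 1]

    def test_empty_type_stratum_is_zero(self):
        segs = pd.DataFrame([_seg("s1", 5000, 7000, "gain")])
        cat = sc.build_cnvrs(segs, _matrix())
        length_hist, _ = sc.length_frequency_stats(cat)
        assert (length_hist["loss"] == 0).all()

    def test_empty_catalog_rejected(self):
        cat = sc.build_cnvrs(pd.DataFrame(columns=list(_seg("s", 0, 1000, "gain"))),
                             _matrix())
        with pytest.raises(ValueError):
            sc.length_frequency_stats(cat)


def _gene(gene_id="g1", chrom="chr1", start=100_000, end=130_000, strand="+"):
    length = end - start
    return {
        "gene_id": gene_id, "chrom": chrom, "start": start, "end": end,
        "strand": strand, "cds_start": start + length // 10,
        "cds_end": end - length // 10,
        "exon_starts": f"{start},{start + length // 2}",
        "exon_ends": f"{start + length // 4},{end}",
        "tss": start if strand == "+" else end,
    }


def _catalog_at(midpoints):
    segs = pd.DataFrame(
        [_seg("s1", m - 1000, m + 1000, "gain") for m in midpoints]
    )
    return sc.build_cnvrs(segs, _matrix(n_windows=1000))


class TestAnnotatePosition:
    def test_upstream_of_tss_is_promoter(self):
        genes = pd.DataFrame([_gene()])
        cat = _catalog_at([99_000])  # 1 kb upstream of + strand TSS
        labels, pct = sc.annotate_position(cat, genes)
        assert labels.iloc[0] == "promoter"
        assert pct.sum() == pytest.approx(100.0)

    def test_midpoint_in_cds_exon(self):
        genes = pd.DataFrame([_gene()])
        cat = _catalog_at([106_000])  # inside first exon, in CDS, > 3 kb from TSS
        labels, _ = sc.annotate_position(cat, genes)
        assert labels.iloc[0] == "exon"

    def test_intron_between_exons(self):
        genes = pd.DataFrame([_gene()])
        cat = _catalog_at([110_000])  # between exon1 end (107500) and exon2 (115000)
        labels, _ = sc.annotate_position(cat, genes)
        assert labels.iloc[0] == "intron"

    def test_far_from_any_gene_is_distal(self):
        genes = pd.DataFrame([_gene()])
        cat = _catalog_at([600_000])
        labels, _ = sc.annotate_position(cat, genes)
        assert labels.iloc[0] == "distal_intergenic"

    def test_downstream_window(self):
        genes = pd.DataFrame([_gene()])
        cat = _catalog_at([132_000])  # 2 kb past the + strand 3' end
        labels, _ = sc.annotate_position(cat, genes)
        assert labels.iloc[0] == "downstream"

    def test_minus_strand_promoter_at_gene_end(self):
        genes = pd.DataFrame([_gene(strand="-")])
        cat = _catalog_at([131_000])  # 1 kb past end = upstream of - strand TSS
        labels, _ = sc.annotate_position(cat, genes)
        assert labels.iloc[0] == "promoter"

    def test_missing_strand_rejected(self):
        g = _gene()
        g["strand"] = None
        with pytest.raises(ValueError, match="strand"):
            sc.annotate_position(_catalog_at([99_000]), pd.DataFrame([g]))

    def test_proportions_sum_to_100(self, small_run):
        cfg = small_run["cfg"]
        _, genes = sc.simulate_expression(small_run["truth"], cfg)
        _, pct = sc.annotate_position(small_run["catalog"], genes)
        assert pct.sum() == pytest.approx(100.0)
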