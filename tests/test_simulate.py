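"""The synthetic generator must have the structure the analysis assumes:
depth expectation linear in copy number, multiplicative expression dose
response, weighted QTL categories, and Ct values consistent with planted
copy numbers — all byte-reproducible under a fixed seed."""

import dataclasses
import io

import numpy as np
import pandas as pd
import pytest

import swinecnv as sc
from swinecnv import _io
from swinecnv.simulate import CT_NONDETECT


def _cfg(**kw):
    base = dict(seed=5, n_chrom=1, chrom_length_bp=2_000_000, n_cnv_loci=6,
                n_genes=40, n_qtl=40)
    base.update(kw)
    return sc.SimulationConfig(**base)


class TestSimulateDepth:
    def test_no_cnv_mean_depth(self):
        cfg = _cfg(n_cnv_loci=0)
        tracks, truth = sc.simulate_depth(cfg)
        assert truth.loci.empty
        depth = tracks[0].windows["depth"].to_numpy()
        n_reads = cfg.mean_depth * cfg.window_bp / cfg.read_length_bp
        se = (
            np.sqrt(cfg.depth_dispersion * n_reads)
            * cfg.read_length_bp / cfg.window_bp
            / np.sqrt(depth.size)
        )
        assert abs(depth.mean() - cfg.mean_depth) < 3 * se

    def test_homozygous_deletion_gives_zero_depth(self):
        profiles = [{"LW": {0: 1.0}, "MZ": {0: 1.0}}]
        cfg = _cfg(n_cnv_loci=1, breed_cn_profiles=profiles)
        tracks, truth = sc.simulate_depth(cfg)
        locus = truth.loci.iloc[0]
        for t in tracks:
            w = t.windows
            inside = (w["start"] >= locus["start"]) & (w["end"] <= locus["end"])
            assert (w.loc[inside, "depth"] == 0).all()

    def test_depth_ratio_between_breeds_tracks_cn(self):
        # LW fixed CN 2, MZ fixed CN 4 at one locus: depth ratio MZ/LW ~ 2
        profiles = [{"LW": {2: 1.0}, "MZ": {4: 1.0}}]
        cfg = _cfg(seed=7, n_cnv_loci=1, breed_cn_profiles=profiles)
        tracks, truth = sc.simulate_depth(cfg)
        locus = truth.loci.iloc[0]
        means = {"LW": [], "MZ": []}
        for t in tracks:
            w = t.windows
            inside = (w["start"] >= locus["start"]) & (w["end"] <= locus["end"])
            means[t.breed].append(w.loc[inside, "depth"].mean())
        ratio = np.mean(means["MZ"]) / np.mean(means["LW"])
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_depth_expectation_linear_in_cn(self):
        """Regression of mean locus depth on planted CN recovers slope d/2."""
        cfg = _cfg(seed=3, n_cnv_loci=10)
        tracks, truth = sc.simulate_depth(cfg)
        xs, ys = [], []
        for t in tracks:
            w = t.windows
            for _, locus in truth.loci.iterrows():
                inside = (w["start"] >= locus["start"]) & (w["end"] <= locus["end"])
                xs.append(truth.cn.at[locus["locus_id"], t.sample_id])
                ys.append(w.loc[inside, "depth"].mean())
        slope = np.polyfit(xs, ys, 1)[0]
        assert slope == pytest.approx(cfg.mean_depth / 2, rel=0.05)

    def test_fixed_seed_byte_identical(self):
        cfg = _cfg()
        out = []
        for _ in range(2):
            tracks, _ = sc.simulate_depth(cfg)
            buf = io.StringIO()
            tracks[0].windows.to_csv(buf, sep="\t", index=False)
            out.append(buf.getvalue())
        assert out[0] == out[1]

    def test_rejects_unresolvable_cnv_length(self):
        with pytest.raises(ValueError, match="unresolvable"):
            _cfg(cnv_length_range_bp=(500, 2000)).validate()

    def test_rejects_bad_window(self):
        with pytest.raises(ValueError, match="divide"):
            _cfg(chrom_length_bp=1_000_500).validate()

    def test_rejects_bad_profile_probabilities(self):
        profiles = [{"LW": {2: 0.6, 4: 0.6}, "MZ": {2: 1.0}}]
        with pytest.raises(ValueError, match="sum to 1"):
            _cfg(n_cnv_loci=1, breed_cn_profiles=profiles).validate()

    def test_breed_cn_histogram_converges_to_profile(self):
        dist = {1: 0.25, 2: 0.5, 3: 0.25}
        profiles = [{"LW": dict(dist), "MZ": dict(dist)}]
        cfg = _cfg(n_cnv_loci=1, breed_cn_profiles=profiles,
                   breeds=(("LW", 300), ("MZ", 300)))
        _, truth = sc.simulate_depth(cfg)
        freqs = truth.cn.iloc[0].value_counts(normalize=True)
        for cn, p in dist.items():
            assert freqs[cn] == pytest.approx(p, abs=0.06)


class TestSimulateExpression:
    def test_noiseless_dose_ratio_is_exact(self):
        profiles = [{"LW": {2: 1.0}, "MZ": {4: 1.0}}]
        cfg = _cfg(n_cnv_loci=1, breed_cn_profiles=profiles,
                   expr_noise_sd=0.0, frac_dose_genes=0.1)
        _, truth = sc.simulate_depth(cfg)
        expr, _ = sc.simulate_expression(truth, cfg)
        lw = [s for s, b in truth.breeds.items() if b == "LW"]
        mz = [s for s, b in truth.breeds.items() if b == "MZ"]
        for gid in truth.dose_pairs["gene_id"]:
            ratio = expr.loc[gid, mz].mean() / expr.loc[gid, lw].mean()
            assert ratio == pytest.approx(2.0, rel=1e-12)

    def test_gamma_zero_decouples_expression_from_cn(self):
        profiles = [{"LW": {2: 1.0}, "MZ": {4: 1.0}}]
        cfg = _cfg(n_cnv_loci=1, breed_cn_profiles=profiles,
                   dose_exponent=0.0, expr_noise_sd=0.0)
        _, truth = sc.simulate_depth(cfg)
        expr, _ = sc.simulate_expression(truth, cfg)
        for gid in truth.dose_pairs["gene_id"]:
            assert expr.loc[gid].nunique() == 1

    def test_group_log2_ratio_within_3se(self):
        profiles = [{"LW": {2: 1.0}, "MZ": {4: 1.0}}]
        cfg = _cfg(n_cnv_loci=1, breed_cn_profiles=profiles,
                   breeds=(("LW", 12), ("MZ", 12)), expr_noise_sd=0.1)
        _, truth = sc.simulate_depth(cfg)
        expr, _ = sc.simulate_expression(truth, cfg)
        lw = [s for s, b in truth.breeds.items() if b == "LW"]
        mz = [s for s, b in truth.breeds.items() if b == "MZ"]
        se = 0.1 * np.sqrt(2 / 12)
        for gid in truth.dose_pairs["gene_id"]:
            log2_ratio = (
                np.log2(expr.loc[gid, mz]).mean()
                - np.log2(expr.loc[gid, lw]).mean()
            )
            assert abs(log2_ratio - 1.0) < 3 * se

    def test_dose_gene_tss_within_cis_window(self):
        cfg = _cfg()
        _, truth = sc.simulate_depth(cfg)
        _, genes = sc.simulate_expression(truth, cfg)
        gpos = genes.set_index("gene_id")
        loci = truth.loci.set_index("locus_id")
        for _, pair in truth.dose_pairs.iterrows():
            g = gpos.loc[pair["gene_id"]]
            locus = loci.loc[pair["locus_id"]]
            assert g["chrom"] == locus["chrom"]
            dist = max(locus["start"] - g["tss"], g["tss"] - locus["end"], 0)
            assert dist <= cfg.cis_window_bp


class TestSimulateQtl:
    def test_single_category_weights(self):
        cfg = _cfg(qtl_trait_categories=(("Meat", 1.0),))
        qtl = sc.simulate_qtl_db(cfg)
        assert (qtl["category"] == "Meat").all()

    def test_empty_table(self):
        assert sc.simulate_qtl_db(_cfg(n_qtl=0)).empty

    def test_deterministic_under_seed(self):
        a = sc.simulate_qtl_db(_cfg())
        b = sc.simulate_qtl_db(_cfg())
        pd.testing.assert_frame_equal(a, b)

    def test_intervals_inside_genome(self):
        cfg = _cfg()
        qtl = sc.simulate_qtl_db(cfg)
        assert (qtl["start"] >= 0).all()
        assert (qtl["end"] <= cfg.chrom_length_bp).all()
        assert (qtl["end"] > qtl["start"]).all()


class TestSimulateQpcr:
    def test_zero_noise_recovers_planted_cn(self):
        cfg = _cfg(qpcr_ct_sd=0.0)
        _, truth = sc.simulate_depth(cfg)
        table = sc.simulate_qpcr(truth, cfg)
        est = sc.estimate_cn(table)
        merged = est.merge(truth.qpcr_cn, on=["sample_id", "locus_id"],
                           suffixes=("_est", "_true"))
        nonzero = merged[merged["cn_true"] > 0]
        assert np.allclose(nonzero["cn_est"], nonzero["cn_true"], rtol=1e-9)
        # homozygous deletions hit the non-detect Ct and come back near zero
        zero = merged[merged["cn_true"] == 0]
        assert (zero["cn_est"] < 0.01).all()

    def test_noisy_recovery_within_5pct(self):
        profiles = [{"LW": {3: 1.0}, "MZ": {3: 1.0}}]
        cfg = _cfg(n_cnv_loci=1, breed_cn_profiles=profiles,
                   n_qpcr_loci=1, qpcr_replicates=8, qpcr_ct_sd=0.05)
        _, truth = sc.simulate_depth(cfg)
        est = sc.estimate_cn(sc.simulate_qpcr(truth, cfg))
        assert est["cn"].mean() == pytest.approx(3.0, rel=0.05)

    def test_ct_values_in_valid_range(self):
        cfg = _cfg()
        _, truth = sc.simulate_depth(cfg)
        table = sc.simulate_qpcr(truth, cfg)
        assert table.data["ct_target"].between(0, CT_NONDETECT, inclusive="both").all()
        assert (table.data["sample_id"] == table.calibrator).any()


def test_io_round_trips(tmp_path, small_run):
    track = small_run["tracks"][0]
    p = tmp_path / "t.bedgraph"
    _io.write_bedgraph(track.windows, p)
    back = _io.read_bedgraph(p)
    pd.testing.assert_frame_equal(
        back, track.windows[["chrom", "start", "end", "depth"]],
        check_dtype=False,
    )
    breeds = small_run["truth"].breeds
    mp = tmp_path / "m.tsv"
    _io.write_manifest(breeds, mp)
    assert _io.read_manifest(mp) == breeds
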