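"""End-to-end orchestration: simulate/load -> call -> CNVR -> V_ST -> eQTL
-> QTL overlap -> qPCR validation, with a config file and a run manifest.

Every output is a TSV (intervals BED-style, 0-based half-open) written
under one output directory, and every file is re-derivable from the
config + seed alone: the manifest records versions and parameters but no
wall-clock state, so a rerun is byte-identical.
"""

from __future__ import annotations

import dataclasses
import glob
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__, _io
from .cnvr import build_cnvrs, length_frequency_stats, venn_partition
from .depth import CopyNumberMatrix, DepthTrack, build_cn_matrix, segment_all
from .eqtl import associate, direction_summary, dose_concordance
from .qpcr import QpcrTable, concordance, estimate_cn
from .qtloverlap import (DEFAULT_FATNESS_KEYWORDS, database_report,
                         overlap_qtls, proportion_table)
from .simulate import (SimulationConfig, simulate_depth, simulate_expression,
                       simulate_qpcr, simulate_qtl_db)
from .vst import compute_vst_table, filter_differential, select_top_quantile

logger = logging.getLogger("swinecnv.pipeline")


@dataclass
class PipelineConfig:
    """Stage parameters and I/O locations for one pipeline run.

    With ``input_dir`` unset the pipeline simulates its own inputs from
    ``simulation`` (seeded); otherwise it reads bedGraph tracks,
    manifest.tsv and the optional expression / gene / QTL / qPCR tables
    from that directory, skipping stages whose inputs are absent.
    """

    seed: int = 0
    input_dir: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    gap_windows: int = 1
    min_windows: int = 2
    min_carriers: int = 1
    top_quantile: float = 0.01
    min_delta: float = 0.5
    cis_window_bp: int = 1_000_000
    fdr_alpha: float = 0.05
    fatness_keywords: tuple[str, ...] = DEFAULT_FATNESS_KEYWORDS
    qpcr_calibrator: str = "CALIBRATOR"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)

    def __post_init__(self) -> None:
        # one seed drives everything, including the simulator
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)
        self.fatness_keywords = tuple(self.fatness_keywords)


def _write(df: pd.DataFrame, outdir: str, name: str, **kw) -> str:
    path = os.path.join(outdir, name)
    df.to_csv(path, sep="\t", index=kw.pop("index", False), **kw)
    return path


def _load_inputs(config: PipelineConfig):
    d = config.input_dir
    breeds = _io.read_manifest(os.path.join(d, "manifest.tsv"))
    tracks = []
    for path in sorted(glob.glob(os.path.join(d, "*.bedgraph"))):
        sid = os.path.splitext(os.path.basename(path))[0]
        tracks.append(
            DepthTrack(sid, breeds[sid], _io.read_bedgraph(path))
        )
    if not tracks:
        raise FileNotFoundError(f"no *.bedgraph tracks in {d}")

    def opt(name, reader):
        p = os.path.join(d, name)
        return reader(p) if os.path.exists(p) else None

    expr = opt("expression.tsv", _io.read_expression)
    genes = opt("genes.tsv", _io.read_gene_models)
    qtl = opt("qtl.tsv", _io.read_qtl_table)
    qpcr_df = opt("qpcr.tsv", lambda p: pd.read_csv(p, sep="\t"))
    qpcr = (
        QpcrTable(qpcr_df, config.qpcr_calibrator)
        if qpcr_df is not None
        else None
    )
    return tracks, expr, genes, qtl, qpcr, None


def _simulate_inputs(config: PipelineConfig, outdir: str):
    sim = config.simulation
    tracks, truth = simulate_depth(sim)
    expr, genes = simulate_expression(truth, sim)
    qtl = simulate_qtl_db(sim)
    qpcr = simulate_qpcr(truth, sim)

    indir = os.path.join(outdir, "inputs")
    os.makedirs(indir, exist_ok=True)
    for t in tracks:
        _io.write_bedgraph(t.windows, os.path.join(indir, f"{t.sample_id}.bedgraph"))
    _io.write_manifest(truth.breeds, os.path.join(indir, "manifest.tsv"))
    _io.write_expression(expr, os.path.join(indir, "expression.tsv"))
    _io.write_gene_models(genes, os.path.join(indir, "genes.tsv"))
    _io.write_qtl_table(qtl, os.path.join(indir, "qtl.tsv"))
    qpcr.data.to_csv(os.path.join(indir, "qpcr.tsv"), sep="\t", index=False)
    sizes = {f"chr{c + 1}": sim.chrom_length_bp for c in range(sim.n_chrom)}
    _io.write_chrom_sizes(sizes, os.path.join(indir, "chrom.sizes"))
    # ground-truth sidecars, for parameter-recovery checks on the run
    truth.loci.to_csv(os.path.join(indir, "truth_loci.tsv"), sep="\t", index=False)
    truth.cn.to_csv(os.path.join(indir, "truth_cn.tsv"), sep="\t",
                    index_label="locus_id")
    truth.dose_pairs.to_csv(os.path.join(indir, "truth_dose.tsv"), sep="\t",
                            index=False)
    truth.qpcr_cn.to_csv(os.path.join(indir, "truth_qpcr.tsv"), sep="\t",
                         index=False)
    return tracks, expr, genes, qtl, qpcr, truth


def region_mean_cn(matrix: CopyNumberMatrix, chrom: str, start: int,
                   end: int) -> pd.Series:
    """Per-sample mean copy number over the windows of one interval."""
    w = matrix.windows
    sel = (w["chrom"] == chrom) & (w["start"] < end) & (w["end"] > start)
    return matrix.cn.loc[sel.to_numpy()].mean(axis=0)


def run_pipeline(config: PipelineConfig, outdir: str) -> dict:
    """Execute every stage; returns a summary dict (also written as TSVs).

    A stage failure aborts the run with the failing stage named.
    """
    os.makedirs(outdir, exist_ok=True)
    summary: dict = {"seed": config.seed, "skipped": []}
    stage = "inputs"
    try:
        if config.input_dir is None:
            tracks, expr, genes, qtl, qpcr, truth = _simulate_inputs(config, outdir)
        else:
            tracks, expr, genes, qtl, qpcr, truth = _load_inputs(config)
        logger.info("stage inputs: %d depth tracks", len(tracks))

        stage = "callcn"
        matrix = build_cn_matrix(tracks)
        segments = segment_all(
            matrix, gap_windows=config.gap_windows,
            min_windows=config.min_windows,
        )
        _write(segments, outdir, "segments.tsv")
        logger.info("stage callcn: %d per-sample segments", len(segments))

        stage = "cnvr"
        catalog = build_cnvrs(segments, matrix, min_carriers=config.min_carriers)
        _write(catalog.regions, outdir, "cnvr_catalog.tsv")
        _write(catalog.cn, outdir, "cnvr_cn.tsv", index=True)
        summary["n_cnvr"] = len(catalog)
        breed_names = sorted(set(matrix.breeds.values()))
        table1 = _table1(segments, matrix, config, breed_names, catalog)
        _write(table1, outdir, "table1_catalog_summary.tsv")
        if len(catalog):
            length_hist, freq_hist = length_frequency_stats(catalog)
            _write(length_hist, outdir, "length_histogram.tsv", index=True)
            _write(freq_hist.rename("n_cnvr").to_frame(), outdir,
                   "frequency_histogram.tsv", index=True)
        breed_l, breed_m = breed_names[0], breed_names[1]
        shared, a_spec, b_spec = venn_partition(catalog, breed_l, breed_m)
        venn = pd.DataFrame(
            [{"shared": shared, f"{breed_l}_specific": a_spec,
              f"{breed_m}_specific": b_spec}]
        )
        _write(venn, outdir, "venn.tsv")
        summary["venn"] = venn.iloc[0].to_dict()
        logger.info("stage cnvr: %d CNVRs (%d shared)", len(catalog), shared)

        stage = "vst"
        records = compute_vst_table(catalog, breed_l, breed_m)
        _write(records, outdir, "vst.tsv")
        candidates = select_top_quantile(records, q=config.top_quantile)
        differential = filter_differential(
            candidates, catalog, breed_l, breed_m, min_delta=config.min_delta
        )
        _write(pd.DataFrame({"cnvr_id": differential}), outdir,
               "differential_cnvrs.tsv")
        summary["n_candidates"] = len(candidates)
        summary["n_differential"] = len(differential)
        logger.info("stage vst: %d candidates -> %d differential",
                    len(candidates), len(differential))

        stage = "eqtl"
        if expr is not None and genes is not None and differential:
            eqtl = associate(
                catalog, expr, genes, breed_l, breed_m,
                cnvr_ids=differential, cis_window_bp=config.cis_window_bp,
            )
            _write(eqtl, outdir, "eqtl.tsv")
            summ = direction_summary(eqtl, threshold_fdr=config.fdr_alpha)
            _write(summ, outdir, "eqtl_direction_summary.tsv", index=True)
            sig_cis = eqtl[(eqtl["relation"] == "cis")
                           & (eqtl["fdr"] < config.fdr_alpha)]
            pairs = list(zip(sig_cis["cnvr_id"], sig_cis["gene_id"]))
            dose = dose_concordance(catalog, expr, pairs)
            _write(dose, outdir, "dose_concordance.tsv")
            summary["eqtl_significant"] = summ.to_dict()
            logger.info("stage eqtl: %d significant cis pairs", len(sig_cis))
        else:
            summary["skipped"].append("eqtl")
            logger.info("stage eqtl: skipped (no expression input)")

        stage = "qtl_overlap"
        if qtl is not None and len(qtl) and differential:
            diff_regions = catalog.regions[
                catalog.regions["cnvr_id"].isin(differential)
            ]
            report = overlap_qtls(diff_regions, qtl, config.fatness_keywords)
            baseline = database_report(qtl, config.fatness_keywords)
            table2 = proportion_table(report, baseline)
            _write(table2, outdir, "table2_qtl_overlap.tsv")
            summary["qtl_overlap_total"] = report.total
            logger.info("stage qtl_overlap: %d QTLs overlapped", report.total)
        else:
            summary["skipped"].append("qtl_overlap")
            logger.info("stage qtl_overlap: skipped")

        stage = "qpcr"
        if qpcr is not None:
            qpcr_cn = estimate_cn(qpcr)
            caller_rows = []
            region_cache: dict[str, pd.Series] = {}
            loci_coords = None
            if truth is not None:
                loci_coords = truth.loci.set_index("locus_id")
            for lid in qpcr_cn["locus_id"].unique():
                if loci_coords is not None and lid in loci_coords.index:
                    loc = loci_coords.loc[lid]
                    region_cache[lid] = region_mean_cn(
                        matrix, loc["chrom"], int(loc["start"]), int(loc["end"])
                    )
            for _, r in qpcr_cn.iterrows():
                mean_cn = region_cache.get(r["locus_id"])
                if mean_cn is not None and r["sample_id"] in mean_cn.index:
                    caller_rows.append(
                        {"sample_id": r["sample_id"], "locus_id": r["locus_id"],
                         "cn": float(mean_cn[r["sample_id"]])}
                    )
            _write(qpcr_cn, outdir, "qpcr_cn.tsv")
            if caller_rows:
                caller_cn = pd.DataFrame(caller_rows)
                agree, confusion = concordance(qpcr_cn, caller_cn)
                _write(confusion, outdir, "qpcr_confusion.tsv", index=True)
                summary["qpcr_concordance"] = agree
                logger.info("stage qpcr: concordance %.3f", agree)
        else:
            summary["skipped"].append("qpcr")
            logger.info("stage qpcr: skipped")
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "swinecnv_version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items()
            if k != "simulation"
        },
        "simulation": dataclasses.asdict(config.simulation),
        "summary": {k: v for k, v in summary.items() if k != "skipped"},
        "skipped_stages": summary["skipped"],
    }
    with open(os.path.join(outdir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return summary


def _table1(segments, matrix, config, breed_names, merged_catalog):
    """Per-breed (by restriction) and merged catalog summary table."""
    rows = []
    for b in breed_names:
        samples = [s for s, br in matrix.breeds.items() if br == b]
        sub = segments[segments["sample_id"].isin(samples)]
        cat = build_cnvrs(sub, matrix, min_carriers=config.min_carriers)
        rows.append(_table1_row(b, len(samples), cat))
    rows.append(
        _table1_row("Merged", len(matrix.samples), merged_catalog)
    )
    return pd.DataFrame(rows)


def _table1_row(name, n_samples, cat):
    counts = cat.regions["type"].value_counts() if len(cat) else {}
    return {
        "breed": name,
        "n_samples": n_samples,
        "n_cnvr": len(cat),
        "n_gain": int(counts.get("gain", 0)),
        "n_loss": int(counts.get("loss", 0)),
        "n_both": int(counts.get("both", 0)),
        "length_bp": cat.span,
        "coverage_pct": round(100.0 * cat.coverage, 2),
    }
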