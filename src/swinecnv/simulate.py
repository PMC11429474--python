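"""Synthetic whole-genome depth, expression, QTL and qPCR data.

The generator emulates the statistical structure the downstream analysis
assumes: overdispersed ~12.89x windowed read-depth tracks over a toy
genome, breed-structured integer copy numbers at planted CNV loci,
gene expression with a multiplicative copy-number dose response at
designated cis genes, a trait-annotated QTL interval database, and qPCR
Ct tables consistent with the planted copy numbers.  Everything is
deterministic given the config seed: each stage draws from its own
`numpy` Generator spawned from (seed, stage-tag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .depth import DepthTrack
from .qpcr import QpcrTable

# rng stream tags, one per stage so call order cannot perturb results
_DEPTH, _EXPR, _QTL, _QPCR = 1, 2, 3, 4

#: Non-detect cycle threshold assigned to homozygous-deletion targets.
CT_NONDETECT = 40.0

QTL_TRAIT_POOLS = {
    "Exterior": ["coat color", "ear size", "teat number"],
    "Health": ["immune capacity", "hematocrit", "disease susceptibility"],
    "Meat": ["loin muscle area", "meat color", "drip loss", "muscle pH",
             "tenderness score"],
    "Production": ["average daily gain", "feed conversion ratio"],
    "Reproduction": ["litter size", "age at puberty"],
}
#: Fatness trait names (all match the default fatness keyword set).
QTL_FATNESS_POOL = ["backfat thickness", "fat androstenone level",
                    "fatness index", "intramuscular fat content"]


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults mirror the real design: two breeds (12 Large White, 11
    Minzhu = 23 samples), mean depth 12.89x, a 2 x 10 Mb toy genome in
    1 kb windows (> 10^4 windows, enough for stable quantiles).
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length_bp: int = 10_000_000
    window_bp: int = 1000
    breeds: tuple[tuple[str, int], ...] = (("LW", 12), ("MZ", 11))
    mean_depth: float = 12.89
    read_length_bp: int = 150
    depth_dispersion: float = 1.5  # variance/mean of read counts; 1.0 = Poisson
    n_cnv_loci: int = 40
    cnv_length_range_bp: tuple[int, int] = (3000, 20000)
    frac_differential: float = 0.25  # loci fixed CN 2 in one breed, CN 4 or 0 in the other
    breed_cn_profiles: list[dict[str, dict[int, float]]] | None = None
    n_genes: int = 200
    frac_dose_genes: float = 0.1
    dose_exponent: float = 1.0  # gamma in expression = base * (CN/2)^gamma
    expr_noise_sd: float = 0.1  # SD of log2-expression noise
    cis_window_bp: int = 1_000_000
    n_qtl: int = 200
    qtl_trait_categories: tuple[tuple[str, float], ...] = (
        ("Exterior", 0.077), ("Health", 0.207), ("Meat", 0.529),
        ("Production", 0.090), ("Reproduction", 0.097),
    )
    qtl_fatness_frac_of_meat: float = 0.19
    qtl_length_range_bp: tuple[int, int] = (5_000, 200_000)
    n_qpcr_loci: int = 4
    qpcr_replicates: int = 3
    qpcr_ct_sd: float = 0.1

    def validate(self) -> None:
        if min(self.n_chrom, self.chrom_length_bp, self.window_bp,
               self.n_genes) <= 0:
            raise ValueError("counts must be positive")
        if self.chrom_length_bp % self.window_bp != 0:
            raise ValueError("window_bp must divide chrom_length_bp")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.depth_dispersion < 1.0:
            raise ValueError("depth_dispersion is a variance/mean ratio, >= 1")
        if self.cnv_length_range_bp[0] < self.window_bp:
            raise ValueError(
                "cnv_length_range_bp below window_bp: such CNVs are "
                "unresolvable at this window size"
            )
        if self.breed_cn_profiles is not None:
            names = {b for b, _ in self.breeds}
            for prof in self.breed_cn_profiles:
                for breed, dist in prof.items():
                    if breed not in names:
                        raise ValueError(f"unknown breed {breed!r} in profile")
                    if not math.isclose(sum(dist.values()), 1.0, abs_tol=1e-9):
                        raise ValueError("CN probabilities must sum to 1")
                    if any(c < 0 or c > 6 for c in dist):
                        raise ValueError("CN support must lie in 0..6")

    @property
    def sample_ids(self) -> list[str]:
        out = []
        for breed, n in self.breeds:
            out.extend(f"{breed}_{i + 1:02d}" for i in range(n))
        return out

    @property
    def breed_map(self) -> dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.sample_ids}

    def _rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, tag])


@dataclass
class GroundTruth:
    """Planted state of a simulation, for parameter-recovery tests.

    loci: locus_id, chrom, start, end, kind (differential / shared).
    cn:   loci x samples integer copy numbers.
    Later stages fill genes / dose_pairs / qtl / qpcr_cn.
    """

    loci: pd.DataFrame
    cn: pd.DataFrame
    breeds: dict[str, str]
    genes: pd.DataFrame | None = None
    dose_pairs: pd.DataFrame | None = None
    qtl: pd.DataFrame | None = None
    qpcr_cn: pd.DataFrame | None = None


def default_cn_profiles(
    config: SimulationConfig, rng: np.random.Generator
) -> list[dict[str, dict[int, float]]]:
    """Per-locus breed->CN-distribution maps.

    The first round(frac_differential * n) loci are differential: fixed
    CN 2 in the first breed and fixed CN 4 (alternating with CN 0) in the
    second — a between-breed mean difference of 2 copies.  Remaining loci
    are shared polymorphic: the same distribution in every breed, drawn
    from loss-leaning / gain-leaning / mixed templates.
    """
    names = [b for b, _ in config.breeds]
    shared_templates = [
        {1: 0.3, 2: 0.4, 3: 0.3},
        {0: 0.2, 1: 0.5, 2: 0.3},
        {2: 0.5, 3: 0.3, 4: 0.2},
        {1: 0.5, 2: 0.5},
        {2: 0.5, 4: 0.5},
    ]
    n_diff = round(config.frac_differential * config.n_cnv_loci)
    if len(names) < 2:
        n_diff = 0
    profiles: list[dict[str, dict[int, float]]] = []
    for i in range(config.n_cnv_loci):
        if i < n_diff:
            alt_cn = 4 if i % 2 == 0 else 0
            prof = {names[0]: {2: 1.0}, names[1]: {alt_cn: 1.0}}
            for other in names[2:]:
                prof[other] = {2: 1.0}
        else:
            tmpl = shared_templates[int(rng.integers(len(shared_templates)))]
            prof = {b: dict(tmpl) for b in names}
        profiles.append(prof)
    return profiles


def _make_windows(config: SimulationConfig) -> pd.DataFrame:
    frames = []
    n_win = config.chrom_length_bp // config.window_bp
    for c in range(config.n_chrom):
        starts = np.arange(n_win, dtype=np.int64) * config.window_bp
        frames.append(
            pd.DataFrame(
                {
                    "chrom": f"chr{c + 1}",
                    "start": starts,
                    "end": starts + config.window_bp,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _place_loci(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Place non-overlapping window-aligned CNV loci uniformly on the genome."""
    lo = max(1, -(-config.cnv_length_range_bp[0] // config.window_bp))
    hi = config.cnv_length_range_bp[1] // config.window_bp
    if hi < lo:
        raise ValueError("cnv_length_range_bp narrower than one window")
    n_win = config.chrom_length_bp // config.window_bp
    occupied: dict[str, list[tuple[int, int]]] = {}
    rows = []
    attempts = 0
    while len(rows) < config.n_cnv_loci:
        attempts += 1
        if attempts > 1000 * config.n_cnv_loci:
            raise RuntimeError("could not place CNV loci without overlap; "
                               "genome too small for n_cnv_loci")
        chrom = f"chr{int(rng.integers(config.n_chrom)) + 1}"
        length_w = int(rng.integers(lo, hi + 1))
        if length_w > n_win:
            continue
        start_w = int(rng.integers(n_win - length_w + 1))
        # keep a 2-window buffer so adjacent loci never merge by accident
        span = (start_w - 2, start_w + length_w + 2)
        if any(a < span[1] and span[0] < b for a, b in occupied.get(chrom, [])):
            continue
        occupied.setdefault(chrom, []).append(span)
        rows.append(
            {
                "locus_id": f"locus_{len(rows) + 1:03d}",
                "chrom": chrom,
                "start": start_w * config.window_bp,
                "end": (start_w + length_w) * config.window_bp,
            }
        )
    loci = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    loci["locus_id"] = [f"locus_{i + 1:03d}" for i in range(len(loci))]
    return loci


def _overdispersed_counts(
    rng: np.random.Generator, mu: np.ndarray, phi: float
) -> np.ndarray:
    """Counts with mean mu and variance phi * mu (phi = 1 is Poisson).

    Implemented as negative binomial with size r = mu / (phi - 1), the
    parametrization in which the dispersion factor is constant across
    expectation levels.
    """
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if phi <= 1.0:
        out[pos] = rng.poisson(mu[pos])
    else:
        r = mu[pos] / (phi - 1.0)
        out[pos] = rng.negative_binomial(r, r / (r + mu[pos]))
    return out


def simulate_depth(config: SimulationConfig) -> tuple[list[DepthTrack], GroundTruth]:
    """Windowed raw-depth tracks with planted breed-structured CNVs.

    Depth in window w of sample s is negative-binomial with expectation
    mean_depth * CN_sw / 2, where CN_sw = 2 outside planted loci and is
    drawn from the locus's breed profile inside them.
    """
    config.validate()
    rng = config._rng(_DEPTH)
    windows = _make_windows(config)

    if config.n_cnv_loci > 0:
        loci = _place_loci(config, rng)
        profiles = config.breed_cn_profiles
        if profiles is None:
            profiles = default_cn_profiles(config, rng)
        if len(profiles) != len(loci):
            raise ValueError("breed_cn_profiles length must equal n_cnv_loci")
        n_diff = sum(
            1 for p in profiles
            if len({tuple(sorted(d.items())) for d in p.values()}) > 1
        )
    else:
        loci = pd.DataFrame(columns=["locus_id", "chrom", "start", "end"])
        profiles = []
        n_diff = 0

    samples = config.sample_ids
    breed_map = config.breed_map

    # integer truth CN, loci x samples
    cn_rows = {}
    kinds = []
    for i, (_, locus) in enumerate(loci.iterrows()):
        prof = profiles[i]
        row = np.empty(len(samples), dtype=np.int64)
        for j, s in enumerate(samples):
            dist = prof[breed_map[s]]
            cns = np.array(sorted(dist))
            probs = np.array([dist[c] for c in cns], dtype=float)
            row[j] = int(rng.choice(cns, p=probs / probs.sum()))
        cn_rows[locus["locus_id"]] = row
        uniq = {tuple(sorted(d.items())) for d in prof.values()}
        kinds.append("differential" if len(uniq) > 1 else "shared")
    loci = loci.assign(kind=kinds) if len(loci) else loci.assign(kind=[])
    truth_cn = pd.DataFrame.from_dict(cn_rows, orient="index", columns=samples)

    # window membership of each locus, precomputed once
    win_chrom = windows["chrom"].to_numpy()
    win_start = windows["start"].to_numpy()
    win_end = windows["end"].to_numpy()
    locus_windows = {
        locus["locus_id"]: np.flatnonzero(
            (win_chrom == locus["chrom"])
            & (win_start < locus["end"])
            & (win_end > locus["start"])
        )
        for _, locus in loci.iterrows()
    }

    # simulate read counts per window, then report coverage-scale depth:
    # a 1 kb window at 12.89x holds ~86 reads of 150 bp, so the relative
    # count noise matches what windowed WGS depth actually shows
    reads_per_window = (
        config.mean_depth * config.window_bp / config.read_length_bp
    )
    bp_per_read = config.read_length_bp / config.window_bp
    tracks = []
    for j, s in enumerate(samples):
        cn_vec = np.full(len(windows), 2.0)
        for lid, idx in locus_windows.items():
            cn_vec[idx] = truth_cn.at[lid, s]
        mu = reads_per_window * cn_vec / 2.0
        counts = _overdispersed_counts(rng, mu, config.depth_dispersion)
        depth = counts * bp_per_read
        tracks.append(
            DepthTrack(
                sample_id=s,
                breed=breed_map[s],
                windows=windows.assign(depth=depth),
            )
        )

    truth = GroundTruth(loci=loci, cn=truth_cn, breeds=breed_map)
    return tracks, truth


def simulate_expression(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM-like expression with a multiplicative dose response.

    A fraction of genes are planted as cis dose genes: their TSS lies
    within the cis window of a planted CNV locus, and their expression is
    base * (CN/2)^gamma * 2^eps with eps ~ N(0, expr_noise_sd).  Non-dose
    genes are independent of copy number.  Updates ``truth.genes`` and
    ``truth.dose_pairs`` and returns (expression matrix, gene models).
    """
    rng = config._rng(_EXPR)
    samples = list(truth.cn.columns) if len(truth.cn) else config.sample_ids
    genome = {f"chr{c + 1}": config.chrom_length_bp for c in range(config.n_chrom)}

    n_dose = round(config.frac_dose_genes * config.n_genes)
    # dose genes need copy-number variation across samples to be detectable
    variable = [
        lid for lid in truth.cn.index if truth.cn.loc[lid].nunique() > 1
    ]
    if not variable:
        n_dose = 0

    gene_rows = []
    dose_rows = []
    expr = np.empty((config.n_genes, len(samples)))
    base = 2.0 ** rng.normal(4.0, 1.0, size=config.n_genes)
    for g in range(config.n_genes):
        gid = f"G{g + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(2_000, 50_000))
        if g < n_dose:
            lid = variable[g % len(variable)]
            locus = truth.loci.set_index("locus_id").loc[lid]
            chrom = locus["chrom"]
            mid = (int(locus["start"]) + int(locus["end"])) // 2
            offset = int(rng.integers(-config.cis_window_bp // 4,
                                      config.cis_window_bp // 4 + 1))
            tss = int(np.clip(mid + offset, 0, genome[chrom] - length - 1))
        else:
            chrom = f"chr{int(rng.integers(config.n_chrom)) + 1}"
            tss = int(rng.integers(0, genome[chrom] - length))
        if strand == "+":
            start, end = tss, tss + length
        else:
            start, end = tss - length, tss
            if start < 0:
                start, end = 0, length
                tss = end
        # simple 3-exon structure; CDS excludes the terminal eighths (UTRs)
        e1 = start + max(1, length // 8)
        e2 = start + length // 2
        e3 = start + 5 * length // 8
        exon_starts = f"{start},{e2},{end - max(1, length // 8)}"
        exon_ends = f"{e1},{e3},{end}"
        cds_start = start + max(1, length // 16)
        cds_end = end - max(1, length // 16)
        gene_rows.append(
            {
                "gene_id": gid, "chrom": chrom, "start": start, "end": end,
                "strand": strand, "cds_start": cds_start, "cds_end": cds_end,
                "exon_starts": exon_starts, "exon_ends": exon_ends, "tss": tss,
            }
        )

        noise = 2.0 ** rng.normal(0.0, config.expr_noise_sd, size=len(samples))
        if g < n_dose:
            cn = truth.cn.loc[lid, samples].to_numpy(dtype=float)
            expr[g] = base[g] * (cn / 2.0) ** config.dose_exponent * noise
            dose_rows.append(
                {"gene_id": gid, "locus_id": lid, "gamma": config.dose_exponent}
            )
        else:
            expr[g] = base[g] * noise

    genes = pd.DataFrame(gene_rows)
    expr_df = pd.DataFrame(expr, index=genes["gene_id"], columns=samples)
    truth.genes = genes
    truth.dose_pairs = pd.DataFrame(
        dose_rows, columns=["gene_id", "locus_id", "gamma"]
    )
    return expr_df, genes


def simulate_qtl_db(config: SimulationConfig) -> pd.DataFrame:
    """A QTL interval database with weighted trait categories.

    Intervals are uniform over the toy genome; trait names within the
    Meat category are fatness-related with probability
    ``qtl_fatness_frac_of_meat``.
    """
    config.validate()
    rng = config._rng(_QTL)
    cats = [c for c, _ in config.qtl_trait_categories]
    w = np.array([w for _, w in config.qtl_trait_categories], dtype=float)
    if config.n_qtl == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "category",
                                     "trait_name"])
    w = w / w.sum()
    rows = []
    lo, hi = config.qtl_length_range_bp
    for _ in range(config.n_qtl):
        chrom = f"chr{int(rng.integers(config.n_chrom)) + 1}"
        length = int(rng.integers(lo, hi + 1))
        length = min(length, config.chrom_length_bp - 1)
        start = int(rng.integers(0, config.chrom_length_bp - length))
        cat = cats[int(rng.choice(len(cats), p=w))]
        if cat == "Meat" and rng.random() < config.qtl_fatness_frac_of_meat:
            name = QTL_FATNESS_POOL[int(rng.integers(len(QTL_FATNESS_POOL)))]
        else:
            pool = QTL_TRAIT_POOLS[cat]
            name = pool[int(rng.integers(len(pool)))]
        rows.append({"chrom": chrom, "start": start, "end": start + length,
                     "category": cat, "trait_name": name})
    return pd.DataFrame(rows)


def simulate_qpcr(truth: GroundTruth, config: SimulationConfig) -> QpcrTable:
    """Ct tables consistent with the planted copy numbers.

    Ct_target - Ct_reference = -log2(CN/2) + per-locus calibrator offset
    + Gaussian noise; the reference gene behaves as a constant CN = 2.
    A dedicated calibrator sample with CN = 2 at every assayed locus is
    appended, since relative quantification needs a known anchor.
    Homozygous-deletion targets get a non-detect Ct of 40.
    """
    rng = config._rng(_QPCR)
    # favor loci whose CN never hits 0, as real validation assays would
    candidates = sorted(
        truth.cn.index, key=lambda lid: (truth.cn.loc[lid].min() == 0,)
    )
    loci = candidates[: config.n_qpcr_loci]
    samples = list(truth.cn.columns)
    calibrator = "CALIBRATOR"
    offsets = {lid: float(rng.normal(0.0, 0.5)) for lid in loci}

    rows = []
    qpcr_truth = []
    for lid in loci:
        for s in samples + [calibrator]:
            cn = 2 if s == calibrator else int(truth.cn.at[lid, s])
            qpcr_truth.append({"sample_id": s, "locus_id": lid, "cn": cn})
            for rep in range(config.qpcr_replicates):
                ct_ref = 20.0 + float(rng.normal(0.0, config.qpcr_ct_sd))
                if cn == 0:
                    ct_tgt = CT_NONDETECT
                else:
                    ct_tgt = (
                        20.0 + offsets[lid] - math.log2(cn / 2.0)
                        + float(rng.normal(0.0, config.qpcr_ct_sd))
                    )
                rows.append(
                    {"sample_id": s, "locus_id": lid, "replicate": rep + 1,
                     "ct_target": ct_tgt, "ct_reference": ct_ref}
                )
    truth.qpcr_cn = pd.DataFrame(qpcr_truth)
    return QpcrTable(
        data=pd.DataFrame(
            rows, columns=["sample_id", "locus_id", "replicate", "ct_target",
                           "ct_reference"]
        ),
        calibrator=calibrator,
    )
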