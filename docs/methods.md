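# Methods

`swinecnv` implements a read-depth copy-number-variation (CNV) pipeline for
two-breed comparisons in pigs — the setting is a European lean breed (Large
White, LW) against a Chinese indigenous fatty breed (Minzhu, MZ), where
copy-number differences are candidate drivers of back-fat deposition — plus
a seeded synthetic-data generator that makes every stage testable at desk
scale.

## Copy-number model

Sequencing coverage in a genomic window scales linearly with the local copy
count. For each sample, windowed raw depth is rescaled to diploid copy
numbers as

    CN_w = 2 * depth_w / median(depth),

anchoring the genome-wide median at CN = 2. The median rather than the mean
is used because the CNVs themselves would bias a mean anchor; the estimator
is scale-invariant, so read-count units versus coverage units do not matter.
No GC or mappability correction is applied — the synthetic data do not
simulate those biases, and correcting for an absent bias would only add
variance.

Windows are classified loss (CN < 1.5), normal (1.5 ≤ CN ≤ 2.5) or gain
(CN > 2.5). The boundary values are deliberately assigned to "normal" so the
three states partition [0, ∞) deterministically.

**Segmentation.** Per sample, maximal runs of same-state non-normal windows
are merged into CNV segments, tolerating up to `gap_windows` (default 1)
interior normal windows; a window of the opposite state always ends a run.
Segments with fewer than `min_windows` (default 2) non-normal windows are
discarded. Segment CN is the mean over the whole span, bridged windows
included. Both knobs trade sensitivity against false calls: at the default
noise level a single misclassified window is common (a few percent of
windows), two consecutive ones are rare.

The default window is 1 kb, matching the conventional ≥ 1 kb definition of a
CNV: with `min_windows = 2` the smallest callable event is 2 kb.

## Population CNVRs

Per-sample segments are merged across samples by interval union: segments
overlapping by ≥ 1 bp (half-open coordinates; touching intervals do not
overlap) coalesce into one copy-number-variable region (CNVR). A CNVR is
typed `gain` when every carrier segment is a gain, `loss` when every one is
a loss, and `both` otherwise — union typing is why a merged two-breed
catalog can hold more `both` regions than either single-breed catalog.
Every sample, carrier or not, gets a region copy number (mean CN of its
windows inside the region); carrier counts are kept per breed.

Breed sharing is defined by carriers: a CNVR is breed-specific iff all its
carriers belong to one breed. Counting per-breed CNVRs as regions of the
merged catalog with at least one carrier of that breed makes the Venn
arithmetic exact by inclusion–exclusion: shared = n_A + n_B − n_merged.
(Rebuilding per-breed catalogs by re-merging only that breed's segments can
split a region whose parts are bridged by the other breed, so the identity
is only approximate under that construction; the merged-universe counting
is used wherever exactness matters.)

**Feature annotation.** Each CNVR is labeled by the genomic feature at its
midpoint with priority promoter > 5'UTR > 3'UTR > exon > intron >
downstream > distal intergenic. The promoter is TSS ± 3 kb (strand-aware)
and downstream extends 3 kb past the 3' end, mirroring the defaults of the
standard peak-annotation tools. The midpoint rule gives exactly one label
per region, so feature proportions sum to 100%.

## V_ST

For each CNVR the between-breed differentiation statistic is

    V_ST = (V_total − (V_L·N_L + V_M·N_M) / N_total) / V_total,

the copy-number analogue of F_ST. All variances are population variances
(divisor n). That choice is what guarantees 0 ≤ V_ST ≤ 1 by the law of
total variance; with sample variances (divisor n − 1) the statistic can go
slightly negative. Zero total variance leaves V_ST undefined; such records
are flagged and excluded from ranking rather than treated as rank-0
candidates.

Candidate differential CNVRs are the top quantile: k = floor(q·N) records
with the largest V_ST (default q = 0.01; N is the full record count, ties
at the cutoff break by genomic order). A catalog of 11,097 regions thus
yields exactly 110 candidates. Candidates are then screened by an automated
between-breed contrast: keep regions with |mean CN(L) − mean CN(M)| ≥
`min_delta` (default 0.5, a quarter of a copy-number step per breed). This
replaces manual genome-browser inspection with a reproducible rule.

## eQTL dose effects

Each (CNVR, gene) pair is tested by simple linear regression of
log2(expression + 1) on region copy number — the additive model of the
standard matrix eQTL mappers. The pseudo-count log transform stabilizes the
fit at FPKM scale; a raw-scale fit is available (`log2_transform=False`)
for settings where expression is exactly proportional to copy number. Pairs
are cis when the gene TSS lies within 1 Mb of the region boundary on the
same chromosome (the convention of the cited mappers; the distance is
configurable), trans otherwise. Benjamini–Hochberg FDR is applied
separately within the cis and trans families, since the two analyses ask
different questions and have very different family sizes. Direction is the
predicted expression change in MZ relative to LW:
sign(slope × (mean CN_MZ − mean CN_LW)).

Dose concordance per pair is the Spearman rank correlation between
per-sample CN and expression; a pair is dose-consistent when ρ > 0 with
p < 0.05. The DE helper applies only the threshold rule
(|log2FC| > 2, adjusted p < 0.05, log2FC oriented LW:MZ) to an externally
produced differential-expression table; the DE model itself is out of scope.

## QTL overlap accounting

A QTL counts once if it overlaps any differential CNVR by ≥ 1 bp
(interval-tree lookup; a quadratic scan serves as the test oracle). Counts
are grouped by the QTL database's five top-level categories; fatness traits
are identified inside Meat by trait-name keywords (default
{"fat", "backfat", "fatness"}, case-insensitive), since the live trait
ontology is external. Percentages (fatness of total, fatness of Meat) use
half-up rounding to 2 decimals.

## qPCR validation

Relative quantification follows the ΔΔCt scheme with a reference gene of
conserved copy number and a calibrator sample of known diploid state:
ΔCt = Ct_target − Ct_reference per replicate, replicates averaged on the Ct
scale, ΔΔCt = ΔCt − ΔCt_calibrator, and CN = 2·2^(−ΔΔCt). A plain 2^(−ΔCt)
readout cannot return an absolute copy number without an anchor, so the
calibrator convention is adopted and documented. Standard curves are OLS of
Ct on log10 dilution with efficiency 10^(−1/slope) − 1; a non-negative
slope marks a curve invalid. Concordance with the read-depth caller
classifies both estimates through the same loss/normal/gain thresholds and
reports the agreement fraction and confusion table.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes:

- **Cohort and depth**: two breeds of 12 (LW) and 11 (MZ) samples at mean
  depth 12.89×, the real design's sizes and mean coverage. The toy genome is
  2 chromosomes × 10 Mb in 1 kb windows — over 2·10⁴ windows, enough for
  stable medians and quantiles at desk scale.
- **Depth noise**: read counts per window are negative binomial with
  variance/mean ratio `depth_dispersion` (default 1.5; 1.0 is Poisson),
  since real WGS depth is overdispersed. Counts use a realistic scale — a
  1 kb window at 12.89× holds ~86 reads of 150 bp — and are reported as
  coverage, so the relative window noise (~13%) matches what windowed WGS
  depth actually shows. Expected depth is mean_depth × CN/2; homozygous
  deletions give exactly zero.
- **Planted CNVs**: 40 non-overlapping window-aligned loci of 3–20 kb. By
  default a quarter are breed-differential (fixed CN 2 in LW vs fixed CN 4
  or CN 0 in MZ — a between-breed mean difference of two copies); the rest
  are shared polymorphic with identical CN distributions in both breeds,
  serving as differentiation nulls.
- **Expression**: 200 genes; 10% are dose genes whose TSS is placed within
  the cis window of a copy-number-variable locus and whose expression is
  base·(CN/2)^γ·2^ε with γ = 1 and ε ~ N(0, 0.1) on the log2 scale.
  Non-dose genes are independent of copy number.
- **QTL database**: 200 intervals with category weights matching the real
  database's proportions (Meat ≈ 53%, etc.) and ~19% of Meat traits
  fatness-named, so the baseline accounting resembles the real one.
- **qPCR**: 4 assayed loci (preferring loci without homozygous deletions,
  as real validation assays would), 3 replicates, Ct noise SD 0.1, a
  per-locus primer offset, and an appended calibrator sample with CN = 2 at
  every assayed locus. Homozygous-deletion targets get a non-detect Ct of
  40, so zero copies read back as near-zero rather than exactly zero.

Each stage draws from its own generator stream spawned from (seed, stage
tag), so outputs are byte-identical under a fixed seed regardless of call
order.

**What the generator does not emulate**: read alignment artifacts,
mappability and GC bias, sex chromosomes, linkage between loci, population
structure within a breed, library-size differences between RNA samples, and
qPCR efficiency below 100%. Passing recovery tests therefore demonstrate
the statistical machinery is correct under the stated noise model, not that
the caller is robust to alignment-level artifacts of real data.

## Numerical choices and degenerate inputs

- Population variances (ddof = 0) throughout V_ST; results clamped to
  [0, 1] only against floating-point dust (the decomposition already bounds
  them).
- V_ST matches a pure-python brute-force evaluation to < 1e-12 over 10⁴
  random partitions (tested).
- Normalization requires ≥ 100 windows and a positive median; an all-zero
  track is an error, not CN 0 everywhere.
- Zero-variance copy numbers: V_ST records flagged undefined; eQTL pairs
  skipped with a log notice; dose concordance NaN with a flag.
- Rounding of report percentages is decimal half-up, not banker's.
- The top-quantile rule warns and returns empty when floor(q·N) = 0.

## Evaluation scale

The bundled evaluation (`swinecnv.evaluate`, exercised by the test suite
and `scripts/acceptance.py`) runs the full study-scale simulation once
(2 × 10 Mb, 23 samples) for segment recovery, dose-gene power and qPCR
closure, and a 100-seed rerun on a reduced 1 × 2 Mb genome for the V_ST
ranking success rate — the reduced genome keeps 100 full
simulate-call-rank cycles fast while preserving the n = 12/11 breed
design that drives the statistic.

## Known limitations

- The |ΔCN| screening step is a reproducible surrogate for manual browser
  inspection, not a reimplementation of it.
- Carrier-based breed specificity is not identical to per-breed re-calling.
- The eQTL model fits no covariates (no kinship, batch, or library-size
  terms) and is intended for the synthetic design, where none exist.
- qPCR efficiency is assumed perfect in copy-number estimation; standard
  curves report, but do not correct for, sub-100% efficiency.
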