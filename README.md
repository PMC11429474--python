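# swinecnv

Read-depth copy-number-variation (CNV) analysis for breed comparisons in
pigs: from windowed sequencing depth to population CNVRs, between-breed
V_ST differentiation, copy-number dose effects on gene expression
(cis/trans eQTL), QTL trait-category overlap, and qPCR validation of the
calls.

## The problem

Back fat thickness separates European lean breeds (Large White, LW) from
Chinese indigenous fatty breeds (Minzhu, MZ), and copy-number differences
between the breeds are candidate drivers of that trait. Given whole-genome
sequencing depth for samples of both breeds plus back-fat expression data,
the analysis asks: which genomic regions differ in copy number between the
breeds, and do those regions change the expression of nearby (cis) or
distant (trans) genes in a copy-dose fashion?

The package is aimed at quantitative geneticists who want each stage as a
tested, seedable library function rather than a chain of external callers,
and it ships a synthetic-data generator so the entire pipeline runs and is
validated without any sequencing downloads.

## Pipeline

1. **Copy number** — windowed depth is rescaled per sample so the
   genome-wide median maps to CN = 2 (`CN_w = 2 · depth_w / median`);
   windows are classified loss (CN < 1.5), normal (1.5–2.5) or gain
   (> 2.5) and merged into per-sample segments.
2. **CNVRs** — segments from all samples are union-merged (≥ 1 bp overlap)
   into population regions typed gain / loss / both, with per-breed
   carrier counts, length/frequency histograms and genomic-feature
   annotation (promoter, UTR, exon, intron, downstream, distal intergenic).
3. **V_ST** — per CNVR,
   `V_ST = (V_total − (V_L·N_L + V_M·N_M)/N_total) / V_total`
   with population variances, so V_ST ∈ [0, 1] like F_ST. The top quantile
   (floor(q·N), default 1%) gives candidates; an automated
   |mean CN(LW) − mean CN(MZ)| ≥ 0.5 screen gives the final differential
   set.
4. **eQTL dose effects** — per (CNVR, gene) linear regression of
   log2(expression + 1) on copy number; cis within 1 Mb of the region on
   the same chromosome; Benjamini–Hochberg FDR within the cis and trans
   families separately; Spearman dose-concordance per pair.
5. **QTL overlap** — QTLs overlapping the differential CNVRs counted once
   each, by trait category, with fatness percentages of the total and of
   the Meat category.
6. **qPCR** — ΔΔCt copy-number estimation with a CN = 2 calibrator
   (`CN = 2·2^(−ΔΔCt)`), standard-curve efficiencies, and loss/normal/gain
   concordance with the read-depth caller.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

Run the full synthetic study (2 × 10 Mb genome, 12 LW + 11 MZ samples at
~12.89× depth, 40 planted CNV loci of which 10 are breed-differential):

```bash
swinecnv report --seed 1 --outdir run1
```

or equivalently from Python:

```python
import swinecnv as sc
summary = sc.run_pipeline(sc.PipelineConfig(seed=1), "run1")
```

`run1/table1_catalog_summary.tsv` summarizes the catalog per breed (by
restriction) and merged:

```
breed   n_samples  n_cnvr  n_gain  n_loss  n_both  length_bp  coverage_pct
LW      12         774     540     208     26      2368000    11.84
MZ      11         692     447     221     24      2242000    11.21
Merged  23         1313    868     350     95      4043000    20.21
```

The merged catalog holds 1,313 CNVRs: the ~300 regions backed by planted
loci plus small noise regions, which is what the V_ST ranking must (and
does) separate. The three strongest records in `run1/vst.tsv`:

```
cnvr_id     chrom  start    end      v_total  v_within  vst       defined
cnvr_00122  chr1   1800000  1820000  0.914843 0.001779  0.998056  True
cnvr_00418  chr1   6347000  6368000  0.745665 0.002261  0.996968  True
cnvr_00372  chr1   5662000  5673000  0.843798 0.003247  0.996151  True
```

all of which coincide with planted differential loci (near-zero
within-breed variance, large between-breed contrast). The run recovers 13
top-1% candidates of which exactly the 10 planted differential loci
survive the |ΔCN| ≥ 0.5 screen, finds cis dose genes at those regions
(`run1/eqtl.tsv`), overlaps them with the simulated QTL database
(`run1/table2_qtl_overlap.tsv`), and reports qPCR-vs-caller concordance
1.0 at the four assayed loci. Reruns with the same seed are byte-identical;
`run1/run_manifest.json` records the version, seed and every parameter.

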