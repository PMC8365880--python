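# enhancerscape

Tumor-versus-normal enhancer-landscape analysis from ChIP-seq peaks and
signal tracks: typical/super enhancer calling, variant enhancer loci,
differential expression, multi-omic set integration and known-motif
enrichment — with a synthetic-data generator that plants ground truth so
the whole pipeline is verifiable offline.

## What it does

Cancer tissues rewire their cis-regulatory landscape: enhancers marked
by H3K27ac (with H3K4me1) are gained near oncogenes and lost near
tissue-identity genes. Given peak calls and signal tracks for the two
marks in tumor and normal tissue, plus RNA-seq counts, this package:

1. builds the **active enhancer catalog** per condition — H3K27ac peaks
   supported by H3K4me1, distal to every TSS (boundary ≥ 1.5 kb or
   center ≥ 3 kb), stitched when closer than 12.5 kb;
2. calls **super enhancers**: enhancers ranked by total H3K27ac signal;
   on the [0,1]²-scaled rank curve the cutoff is the slope-1 tangent
   point (argmin of y − x), and loci above it are super;
3. calls **VELs** (variant enhancer loci) on the tumor/normal union
   catalog by pooled H3K27ac fold change — gain at FC ≥ 2, lost at
   FC ≤ 0.5 — and **VSELs**, the same logic restricted to super loci;
4. calls **DEGs** from FPKM (|log2FC| ≥ 1 and p < 0.05, Welch test on
   log2(FPKM+1));
5. **integrates**: nearest-TSS proximal genes for VELs, gain-VEL genes ∩
   up DEGs (and lost ∩ down), three-way TF-target intersections, and the
   coordinated gene set (TF targets ∩ up DEGs ∩ gain-VEL genes) with its
   top-10 ranking;
6. runs **known-motif enrichment** of gain-VEL sequences against a
   shuffled background (PWM log-odds scanning, both strands, one-sided
   Fisher test per motif) — the canonical AP-1/TPA-response element
   TGACTCA is the planted positive in the synthetic data;
7. computes **QC**: Spearman correlation of 2 kb-binned tracks and
   peak-centered metagene profiles (±3 kb).

The synthetic generator (`enhancerscape.synthetic`) emulates the whole
study — NB-noise ChIP tracks with planted typical/super/gain/lost loci,
RNA counts with planted DEGs wired to VEL-proximal genes, enhancer
sequences with planted motifs — and records the truth, so recovery and
null-calibration tests quantify every stage. See `docs/methods.md` for
the model and its assumptions.

## Worked example

The numbered scripts under `analysis/` run the full study on simulated
data (inputs land in `scratch/sim/`, tables in `results/`):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_call_enhancers.py
python analysis/03_differential.py
python analysis/04_integration.py
python analysis/05_motif_enrichment.py --seed 1
python analysis/06_qc_profiles.py
```

Output from seed 1 (abridged):

```
simulated 292 enhancer loci on 2 x 6 Mb (seed 1):
  typical stable 200 | typical gain 40 | typical lost 40
  super gain 4 | super lost 4 | super stable 4
300 genes (44 planted up, 44 planted down); 12 ChIP tracks; 34 AP-1 sites planted

normal: 327 active peaks -> 327 distal -> 292 stitched enhancers, 12 super
tumor:  327 active peaks -> 327 distal -> 292 stitched enhancers,  9 super

VELs: 44 gain, 44 lost (fold change >= 2 / <= 0.5 on pooled H3K27ac RPKM)
VSELs: 5 gain, 4 lost
DEGs: 43 up, 43 down of 300 genes
gain VELs with up DEGs: 43; lost VELs with down DEGs: 43
genes targeted by all 3 TFs: 74
coordinated genes (TF targets ∩ up DEGs ∩ gain-VEL genes): 43

motif ranking: MA_AP1 rank 1 (35/44 fg vs 5/44 bg hits, p = 4.3e-11)
metagene over 327 peaks: center 1.99 vs edge 0.05 reads/bp (ratio 37.7)
```

Reading: of the 88 planted variant loci all 88 are recovered with the
correct direction; 43 of the 44 planted DEGs survive testing at the
planted effect size, and the same 43 come back through the
VEL→proximal-gene→DEG→TF-target intersection chain; the planted AP-1
motif outranks all decoys. The `tumor: 9 super` line is the directional
truth: 4 gain + 4 stable supers are super in tumor (lost supers are
super in normal only), plus one strongly gained typical locus that
crosses the tangent cutoff.

Equivalently, `enhancerscape.pipeline.run_all(PipelineConfig(seed=1),
outdir)` runs everything in one call and writes a manifest with every
parameter and an output checksum; two runs with the same seed are
byte-identical.

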