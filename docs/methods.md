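# Methods

This package implements a tumor-versus-normal enhancer-landscape
analysis — active-enhancer cataloguing from H3K27ac/H3K4me1 peaks,
ROSE-style super-enhancer calling, variant enhancer loci (VELs and
VSELs), differential expression, proximal-gene/TF-target integration and
known-motif enrichment — together with a synthetic-data generator that
plants ground truth so every stage can be validated end to end without
any external dataset.

## Enhancer catalog

Peak calling and alignment are upstream of this package: inputs are
peak intervals (BED/broadPeak) and signal tracks (bedGraph, reads/bp),
0-based half-open throughout. Per condition:

1. **Active-enhancer filter.** An H3K27ac peak enters the catalog when
   it overlaps an H3K4me1 peak by at least 1 bp (active = both marks).
   The overlap fraction is configurable; no published fraction exists
   for this rule, so ≥1 bp is the default.
2. **Distal filter.** A peak is distal when, for *every* TSS, the
   boundary distance is ≥ 1.5 kb **or** the center distance is ≥ 3 kb.
   Both distances and the or/and combination are parameters
   (`DistalFilterRules`); the disjunction is the default reading. The
   coarser 2 kb active-enhancer distance is a separate knob. Distance
   to a TSS inside the peak is 0.
3. **Stitching.** Sorted peaks with inter-peak gap strictly less than
   12.5 kb merge into one enhancer (single linkage); a gap of exactly
   12.5 kb splits ("shorter than" is read strictly).
4. **Quantification.** raw = Σ value × overlap over the stitched span;
   RPKM = raw / (length_kb × library_size/10⁶). Replicate tracks are
   pooled (values and library sizes summed) before quantification.

### Super-enhancer cutoff

Enhancers are ranked ascending by total H3K27ac signal and both axes
scaled to [0,1]. The cutoff is the point where a line of slope 1 is
tangent to the curve. For a convex curve this is exactly where the gap
below the unit diagonal, y − x, is most negative, so the cutoff index is
`argmin(y − x)`; enhancers with signal strictly above the cutoff signal
are super. On y = x³ this reproduces the closed-form tangent point
x = 3^(−1/2) ≈ 0.577.

The obvious local alternative — scan finite-difference slopes left to
right and stop at the first value above 1 — is *not* used: on rank
curves with counting noise, order-statistic gaps in the flat left tail
(and the one-sided estimate at rank 0) exceed slope 1 sporadically,
which collapses the typical/super split (in one synthetic run it
classified 291 of 292 enhancers as super). The diagonal-gap form is the
same tangent construction, evaluated globally, and is invariant to that
noise. Degenerate curves that never dip below the diagonal (linear,
all-equal, concave) have no tangent point and yield zero supers with a
warning.

## Differential calls

**VELs.** The per-condition catalogs are merged into a union catalog
(spans overlapping ≥ 1 bp join; provenance flags record membership and
super status per condition). Each union locus gets
FC = (tumor_RPKM + 1)/(normal_RPKM + 1); gain ⟺ FC ≥ 2, lost ⟺
FC ≤ 0.5. The pseudocount (default 1 RPKM) prevents infinite ratios at
empty loci and is configurable.

**VSELs** apply the same fold-change rule restricted to loci super in at
least one condition; directionally, a gain VSEL must be super in tumor
and a lost VSEL super in normal (a pure fold-change-on-super-loci mode
is available via `directional=False`).

**DEGs.** FPKM = count / (length_kb × library/10⁶). A gene is up when
log2FC ≥ 1 and p < 0.05 (down symmetric), with
log2FC = log2((mean tumor FPKM + 1)/(mean normal FPKM + 1)). The
p-value comes from a Welch two-sided t-test on log2(FPKM + 1) — a
deliberately simple location test that is easy to calibrate (its null
false-positive rate is checked to sit near 0.05 in the suite) and whose
up-call set is ≥ 90 % Jaccard-concordant with a DESeq2-style
negative-binomial GLM (pydeseq2) on the synthetic data. Re-implementing
an NB GLM is out of scope; external DE tables can be supplied through
the same `DEGRecord` schema. P-values are raw, matching the p < 0.05
rule; Benjamini–Hochberg can be applied externally.

## Integration

"Proximal gene" = the gene whose TSS is nearest the locus center, ties
broken by lexicographically smaller gene_id, no distance cap by default
(a cap is exposed for sensitivity analysis). Gene-set analyses (gain-VEL
genes ∩ up DEGs, three-way TF target intersection, the coordinated-gene
triple overlap, top-n ranking by log2FC) compute full exclusive Venn
partitions, so inclusion–exclusion identities hold by construction and
are asserted in tests.

## Motif enrichment

Known-motif enrichment stands in for de-novo discovery (out of scope).
PWMs come from JASPAR text (counts → probabilities with 0.5 pseudocount
per cell) and are scored as log2 odds against the background
composition. A window is a hit at ≥ 0.8 of the maximum attainable
score (length-independent threshold; an absolute threshold can be
emulated by adjusting the fraction); both strands are scanned and an N
scores as the worst base at its position. Enrichment is a one-sided
Fisher exact test on sequences-with-hit (fg vs bg) — sequence-level
counting is robust to hit clustering within a sequence — and motifs are
ranked ascending by p with ties on motif_id. Backgrounds: exact
dinucleotide-preserving Euler-path shuffling (default) or length-matched
genomic sampling; the true background of the original motif analyses is
tool-internal and unstated, so both modes are provided.

## QC profiles

Genome-wide concordance: tracks are summed into 2 kb tiling windows
(last window may be short; binning conserves total signal exactly) and
compared by Spearman ρ with average ranks for ties. Windows that are
zero in both tracks are excluded by default — the empty genome otherwise
dominates ρ — with a flag to keep them. Metagene profiles average
signal in 50 bp bins over ±3 kb around peak *centers*; peaks truncated
at chromosome edges contribute only covered bins.

## Synthetic data generator

The generator emulates a paired tumor/normal H3K27ac + H3K4me1 ChIP-seq
study with an RNA-seq arm on a toy genome. Reference conditions
(defaults chosen once, at desk scale so a full run takes ~2 s):

| parameter | default | meaning |
|---|---|---|
| genome | 2 × 6 Mb | two chromosomes |
| loci | 200 typical + 12 super + 40 gain + 40 lost | super: 4 gain / 4 lost / 4 stable |
| super constituents | 3–5 peaks, gaps 2–8 kb | stitch into one locus by construction |
| feature spacing | ~30 kb | distinct loci never co-stitch (> 12.5 kb) |
| gain_fc / lost_fc | 4 / 0.25 | planted tumor/normal H3K27ac ratios |
| background / enrichment | 0.05 / 1.0 reads/bp | super constituents ×3 |
| n_replicates | 3 | per condition, both assays |
| rna_depth | 10⁶ reads/sample | ~3 k reads per gene |
| deg_lfc | 2.0 | planted expression log2FC |
| noise_dispersion | 0.05 | NB α (var = μ + αμ²), CV ≈ 22 % |
| motif_plant_fraction | 0.8 | gain loci carrying a TGACTCA site |

Key design points:

* **Placement guarantees.** Enhancer boundaries are ≥ 3 kb (actually
  5–12 kb) from every TSS, so planted loci survive the distal filter;
  each locus is wired to its own nearest-TSS gene; extra null genes sit
  15–17 kb from spans so they can never steal a nearest-TSS assignment.
* **Noise model.** Read counts are negative binomial per genome piece
  (segments split at constituent boundaries and chopped to ≤ 200 bp;
  values stored as reads/bp). Drawing per piece rather than literally
  per base pair leaves every downstream aggregate (locus RPKM, 2 kb
  bins) statistically identical at far lower cost; the Poisson limit
  (α → 0) is exercised in tests.
* **Mark semantics.** Status multipliers (gain_fc/lost_fc) act on
  H3K27ac only; H3K4me1 marks the enhancer equally in both conditions,
  so lost loci remain in the tumor active catalog via the union.
* **Super scale.** Super constituents carry 3× the per-bp enrichment:
  what makes a super enhancer exceptional is total signal, not span
  alone — without this a single 4×-gained peak rivals a small super
  cluster and the planted classes are not separable.
* **Compositional balance.** Down-gene baselines are rescaled so the
  up- and down-perturbations cancel in the library total. FPKM is a
  relative measure; with unbalanced planting, total-count normalisation
  shifts every gene's realised log2FC by the composition factor
  (~0.46 here) and the planted effect size is no longer the realised
  one. Balancing makes realised group-mean log2FC equal `deg_lfc`, so
  recovery tests measure the caller, not the normalisation artefact.
  Biologically this reads as lost tissue-identity genes being highly
  expressed in normal tissue.
* **Peak emission.** Peaks are the truth constituents whose simulated
  mean enrichment exceeds 2× background per track — an emulated
  upstream caller, since peak calling itself is out of scope.
* **Determinism.** Every generator draws from a substream of the single
  seed; two runs with the same seed are byte-identical on disk.

What the generator does **not** emulate: read-level artefacts (FASTQ,
fragment-size, GC bias), spatially varying background (background is
flat, so replicate Spearman ρ over genome bins is modest by
construction — only enhancer bins co-vary), unbalanced designs, batch
effects, and peak-caller boundary noise (emitted peaks have exact truth
coordinates). Passing recovery tests therefore demonstrates the
correctness of the analytical logic under the stated noise model, not
robustness to upstream artefacts in real data.

## Numerical choices and degenerate inputs

* Coordinates 0-based half-open everywhere; GTF converted on read.
* Chromosome names verbatim; disjoint namespaces raise, never silently
  overlap nothing.
* Rank-curve cutoff uses a 10⁻⁹ tolerance on the diagonal gap so an
  exactly-linear curve (gap ≡ 0 up to float round-off) yields zero
  supers.
* Fold-change and DEG thresholds are closed on the gain/up side
  (≥ 2, ≥ 1) and closed on the lost/down side (≤ 0.5, ≤ −1), exactly as
  stated; the super split is strict (> cutoff signal).
* Welch test on constant groups returns p = 1 (NaN guarded).
* Empty peak files warn and return empty sets; empty annotations are
  errors (distality is undefined without TSSs).

## Problem sizes

Validation workloads are desk-scale by design: recovery runs use the
default 292-locus/300-gene configuration (≈ 2 s per seed, 5 seeds),
null calibrations use 20 seeds (500 null genes for the DEG rate; the
default genome with zero enrichment for the VEL rate), oracle
equivalence checks use 50 random peak sets up to 1,000 peaks, and the
motif ranking check uses 20 seeds against 10 decoy PWMs.
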