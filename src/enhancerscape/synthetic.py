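"""Synthetic toy genome with planted enhancer / expression truth.

The generator emulates the statistical structure of a paired
tumor/normal H3K27ac + H3K4me1 ChIP-seq study with a matched RNA-seq
arm, at desk scale:

* a toy genome (2 x 6 Mb by default) carrying planted typical
  enhancers, clustered super enhancers (3-5 constituents within
  stitching range of each other), and gain / lost variant loci whose
  tumor H3K27ac is ``gain_fc`` / ``lost_fc`` times the normal level;
* each planted enhancer is wired to a proximal gene, and gain / lost
  enhancers drive genes planted up / down in the RNA counts;
* read noise is negative binomial (Poisson in the dispersion -> 0
  limit), drawn per <=200 bp genome piece and stored as reads/bp;
* enhancer DNA sequences with a TPA-response-element-like 7-mer
  (TGACTCA, the canonical AP-1 site) planted in a configurable fraction
  of gain loci, for motif-enrichment tests;
* synthetic TF target lists (Batf/Fos/Junb analogs) whose three-way
  intersection contains every gain-wired gene.

Placement guarantees, by construction: enhancer boundaries >= 3 kb from
every TSS (they survive the distal filter), constituents of one super
enhancer < 12.5 kb apart (they stitch into one locus), distinct planted
features ~30 kb apart (stitching never merges two truth records), and
each planted locus is nearest-TSS-wired to its own gene. Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import (
    CountMatrix,
    GeneAnnotation,
    GenomicInterval,
    PeakSet,
    SignalTrack,
)
from .motifs import PWM, pwm_from_consensus, write_fasta, write_jaspar

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "TruthEnhancer",
    "simulate_genome",
    "simulate_chip_tracks",
    "simulate_expression",
    "simulate_sequences",
    "make_motif_panel",
    "write_simulation",
]

AP1_CONSENSUS = "TGACTCA"
MARKS = ("H3K27ac", "H3K4me1")
CONDITIONS = ("normal", "tumor")


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic generator (defaults are
    the package's reference conditions; see docs/methods.md)."""

    n_chroms: int = 2
    chrom_length: int = 6_000_000
    n_genes: int = 300
    n_typical: int = 200
    n_super: int = 12
    n_super_gain: int = 4
    n_super_lost: int = 4
    n_gain_vel: int = 40
    n_lost_vel: int = 40
    super_constituent_range: tuple[int, int] = (3, 5)
    gain_fc: float = 4.0
    lost_fc: float = 0.25
    background_rate: float = 0.05    # reads per bp outside enhancers
    enrichment_rate: float = 1.0     # reads per bp inside enhancers (normal)
    super_enrichment_mult: float = 3.0  # extra per-bp rate on super constituents
    n_replicates: int = 3
    rna_depth: float = 1_000_000.0   # reads per RNA sample
    deg_lfc: float = 2.0             # planted log2 fold change
    noise_dispersion: float = 0.05   # NB dispersion alpha (var = mu + a mu^2)
    motif_plant_fraction: float = 0.8
    sequence_length: int = 500
    feature_spacing: int = 30_000    # gap between planted features
    piece_size: int = 200            # NB draw granularity, bp
    peak_min_fold: float = 2.0       # emit a peak at > fold x background
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_chroms, self.n_genes, self.n_typical, self.n_super,
                  self.n_gain_vel, self.n_lost_vel, self.n_replicates)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_super_gain + self.n_super_lost > self.n_super:
            raise ValueError("n_super_gain + n_super_lost > n_super")
        if self.gain_fc < 2 or self.lost_fc > 0.5:
            raise ValueError(
                "default-config invariant: gain_fc >= 2 and lost_fc <= 0.5 "
                "so planted truth clears the fold-change thresholds"
            )
        lo, hi = self.super_constituent_range
        if not (1 <= lo <= hi):
            raise ValueError("bad super_constituent_range")
        if self.noise_dispersion < 0:
            raise ValueError("noise_dispersion must be >= 0")

    @property
    def n_loci(self) -> int:
        return self.n_typical + self.n_super + self.n_gain_vel + self.n_lost_vel


@dataclass
class TruthEnhancer:
    name: str
    interval: GenomicInterval
    constituents: list[GenomicInterval]
    klass: str    # typical | super
    status: str   # gain | lost | stable
    gene_id: str


@dataclass
class TruthSet:
    """Planted ground truth: the acceptance surface for recovery tests."""

    enhancers: list[TruthEnhancer]
    genes: pd.DataFrame  # gene_id, chrom, start, end, strand, de_status
    motif_placements: list[tuple[str, int, str]] = field(default_factory=list)
    tf_targets: dict[str, set[str]] = field(default_factory=dict)

    def enhancer_by_name(self) -> dict[str, TruthEnhancer]:
        return {e.name: e for e in self.enhancers}

    def genes_with_status(self, status: str) -> set[str]:
        return set(self.genes.loc[self.genes["de_status"] == status, "gene_id"])


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_genome(config: SimulationConfig) -> tuple[GeneAnnotation, TruthSet]:
    """Place planted enhancers and their wired genes on the toy genome."""
    rng = _rng(config, 0)
    lo, hi = config.super_constituent_range

    specs: list[tuple[str, str]] = []  # (klass, status)
    specs += [("super", "gain")] * config.n_super_gain
    specs += [("super", "lost")] * config.n_super_lost
    specs += [("super", "stable")] * (
        config.n_super - config.n_super_gain - config.n_super_lost
    )
    specs += [("typical", "gain")] * config.n_gain_vel
    specs += [("typical", "lost")] * config.n_lost_vel
    specs += [("typical", "stable")] * config.n_typical
    order = rng.permutation(len(specs))
    specs = [specs[i] for i in order]

    if config.n_genes < len(specs):
        raise ValueError(
            f"n_genes={config.n_genes} < planted loci ({len(specs)}); every "
            "locus needs a wired gene"
        )

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    cursors = {c: 50_000 for c in chrom_names}
    enhancers: list[TruthEnhancer] = []
    gene_rows: list[dict] = []
    margin = 20_000

    for i, (klass, status) in enumerate(specs):
        chrom = min(chrom_names, key=lambda c: cursors[c])
        cursor = cursors[chrom] + int(rng.integers(0, 2000))
        if klass == "super":
            k = int(rng.integers(lo, hi + 1))
            constituents = []
            pos = cursor
            for _ in range(k):
                length = int(rng.integers(800, 1500))
                constituents.append(GenomicInterval(chrom, pos, pos + length))
                pos += length + int(rng.integers(2000, 8000))  # gap < 12.5 kb
        else:
            length = int(rng.integers(600, 1400))
            constituents = [GenomicInterval(chrom, cursor, cursor + length)]
        span = GenomicInterval(chrom, constituents[0].start, constituents[-1].end)
        name = f"enh_{i:04d}"
        gene_id = f"gene_{i:04d}"
        de_status = {"gain": "up", "lost": "down", "stable": "null"}[status]
        # wired gene: TSS 5-12 kb past the span end -> distal filter keeps
        # the enhancer, and this TSS is the nearest one to the locus center
        offset = int(rng.integers(5_000, 12_000))
        strand = "+" if rng.random() < 0.5 else "-"
        tss = span.end + offset
        if strand == "+":
            g_start, g_end = tss, tss + 2_000
        else:
            g_start, g_end = tss - 1_999, tss + 1
        gene_rows.append(dict(gene_id=gene_id, chrom=chrom, start=g_start,
                              end=g_end, strand=strand, de_status=de_status))
        enhancers.append(TruthEnhancer(name, span, constituents, klass,
                                       status, gene_id))
        cursors[chrom] = span.end + config.feature_spacing
        if cursors[chrom] + margin > config.chrom_length:
            raise ValueError(
                "planted features do not fit: increase chrom_length or "
                "reduce feature counts"
            )

    # unlinked null genes in inter-feature gaps, far from every enhancer
    n_extra = config.n_genes - len(specs)
    extra_sites = [
        (e.interval.chrom, e.interval.end + 15_000) for e in enhancers
    ]
    extra_sites = [extra_sites[i] for i in rng.permutation(len(extra_sites))]
    for j in range(n_extra):
        chrom, tss = extra_sites[j % len(extra_sites)]
        tss += (j // len(extra_sites)) * 400  # stay within the 15-17 kb slot
        gene_rows.append(dict(gene_id=f"gene_x{j:04d}", chrom=chrom,
                              start=tss, end=tss + 2_000, strand="+",
                              de_status="null"))

    genes_df = pd.DataFrame.from_records(gene_rows)
    annotation = GeneAnnotation(
        genes_df[["gene_id", "chrom", "start", "end", "strand"]].copy()
    )
    truth_genes = genes_df[["gene_id", "chrom", "start", "end", "strand",
                            "de_status"]].copy()

    # synthetic TF target lists: shared core covers every gain-wired gene
    gain_genes = sorted(e.gene_id for e in enhancers if e.status == "gain")
    null_ids = sorted(truth_genes.loc[truth_genes["de_status"] == "null",
                                      "gene_id"])
    null_pool = list(rng.permutation(null_ids))
    core_extra = null_pool[:30]
    core = set(gain_genes) | set(core_extra)
    tf_targets = {}
    for t, tf in enumerate(("Batf", "Fos", "Junb")):
        private = null_pool[30 + 20 * t: 30 + 20 * (t + 1)]
        tf_targets[tf] = core | set(private)

    truth = TruthSet(enhancers=enhancers, genes=truth_genes,
                     tf_targets=tf_targets)
    return annotation, truth


def _status_multiplier(mark: str, condition: str, status: str,
                       config: SimulationConfig) -> float:
    # status multipliers act on H3K27ac only; H3K4me1 marks the enhancer
    # in both conditions (primed/active chromatin does not follow the
    # acetylation change)
    if mark != "H3K27ac" or condition == "normal":
        return 1.0
    return {"gain": config.gain_fc, "lost": config.lost_fc,
            "stable": 1.0}[status]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             dispersion: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=np.float64)
    if dispersion <= 1e-12:
        return rng.poisson(mu)
    k = 1.0 / dispersion
    p = k / (k + mu)
    return rng.negative_binomial(k, p)


def _genome_pieces(truth: TruthSet, config: SimulationConfig
                   ) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per chrom: piece starts, ends, and truth-locus index (-1 = bg).

    Pieces are <= piece_size bp and never straddle a constituent
    boundary, so constituent-level sums are exact.
    """
    out = {}
    chroms = sorted({e.interval.chrom for e in truth.enhancers})
    for chrom in chroms:
        cuts = {0, config.chrom_length}
        spans = []  # (start, end, locus_index)
        for li, e in enumerate(truth.enhancers):
            if e.interval.chrom != chrom:
                continue
            for c in e.constituents:
                cuts.add(c.start)
                cuts.add(c.end)
                spans.append((c.start, c.end, li))
        edges = np.array(sorted(cuts), dtype=np.int64)
        starts_list, ends_list, label_list = [], [], []
        span_arr = np.array([(s, e) for s, e, _ in spans], dtype=np.int64)
        span_lab = np.array([li for _, _, li in spans], dtype=np.int64)
        for s, e in zip(edges[:-1], edges[1:]):
            grid = np.arange(s, e, config.piece_size, dtype=np.int64)
            p_starts = grid
            p_ends = np.minimum(grid + config.piece_size, e)
            if len(spans):
                inside = (span_arr[:, 0] <= s) & (e <= span_arr[:, 1])
                lab = int(span_lab[np.argmax(inside)]) if inside.any() else -1
            else:
                lab = -1
            starts_list.append(p_starts)
            ends_list.append(p_ends)
            label_list.append(np.full(len(p_starts), lab, dtype=np.int64))
        out[chrom] = (
            np.concatenate(starts_list),
            np.concatenate(ends_list),
            np.concatenate(label_list),
        )
    return out


def simulate_chip_tracks(
    truth: TruthSet, config: SimulationConfig
) -> dict[tuple[str, str, int], tuple[SignalTrack, PeakSet]]:
    """NB-noise signal tracks and emitted peak sets per (mark, condition,
    replicate).

    Mean reads/bp is ``background_rate`` outside enhancers and
    ``enrichment_rate`` x status multiplier inside (tumor H3K27ac:
    gain_fc x normal on gain loci, lost_fc x on lost loci). Peaks are the
    truth constituents whose simulated enrichment exceeds
    ``peak_min_fold`` x background — an emulated upstream peak caller.
    """
    rng = _rng(config, 1)
    pieces = _genome_pieces(truth, config)
    # super constituents sit at a higher per-bp rate: exceptional *total*
    # signal, not just span, is what makes a super enhancer exceptional
    base_mult = np.array(
        [config.super_enrichment_mult if e.klass == "super" else 1.0
         for e in truth.enhancers]
    )
    status_by_locus = [e.status for e in truth.enhancers]
    out: dict[tuple[str, str, int], tuple[SignalTrack, PeakSet]] = {}
    for mark in MARKS:
        for condition in CONDITIONS:
            mult = base_mult * np.array(
                [_status_multiplier(mark, condition, s, config)
                 for s in status_by_locus]
            )
            for rep in range(1, config.n_replicates + 1):
                runs = {}
                library = 0.0
                for chrom, (starts, ends, labels) in pieces.items():
                    lengths = (ends - starts).astype(np.float64)
                    rate = np.where(
                        labels < 0,
                        config.background_rate,
                        config.enrichment_rate
                        * mult[np.clip(labels, 0, None)],
                    )
                    counts = _nb_draw(rng, rate * lengths,
                                      config.noise_dispersion)
                    library += float(counts.sum())
                    runs[chrom] = (starts, ends, counts / lengths)
                track = SignalTrack(runs, library_size=library)
                peaks = []
                for e in truth.enhancers:
                    for c in e.constituents:
                        mean = track.interval_sum(
                            c.chrom, c.start, c.end) / c.length
                        if mean > config.peak_min_fold * config.background_rate:
                            peaks.append(c)
                out[(mark, condition, rep)] = (
                    track,
                    PeakSet(peaks,
                            source_label=f"{mark}_{condition}_rep{rep}"),
                )
    return out


def simulate_expression(truth: TruthSet, config: SimulationConfig
                        ) -> CountMatrix:
    """NB RNA counts: planted up genes at 2^deg_lfc x normal mean in
    tumor, down genes the inverse, null genes equal.

    Planted effects are compositionally balanced: baselines of the down
    genes are rescaled (they are highly expressed in normal tissue, as
    lost tissue-identity genes are) so the up- and down-perturbations
    cancel in the library total. Total-count FPKM normalisation is then
    unbiased and the realised group-mean log2FC matches ``deg_lfc``
    instead of absorbing a composition shift.
    """
    rng = _rng(config, 2)
    genes = truth.genes
    n = len(genes)
    baseline = (config.rna_depth / n) * rng.lognormal(0.0, 0.5, size=n)
    up = (genes["de_status"] == "up").to_numpy()
    down = (genes["de_status"] == "down").to_numpy()
    fc = np.ones(n)
    fc[up] = 2.0 ** config.deg_lfc
    fc[down] = 2.0 ** -config.deg_lfc
    excess = float(np.sum(baseline[up] * (fc[up] - 1.0)))
    deficit = float(np.sum(baseline[down] * (1.0 - fc[down])))
    if excess > 0 and deficit > 0:
        baseline[down] *= excess / deficit
    sample_ids, groups, cols = [], {}, []
    for condition in CONDITIONS:
        mean = baseline * (fc if condition == "tumor" else 1.0)
        for rep in range(1, config.n_replicates + 1):
            sid = f"{condition}_{rep}"
            sample_ids.append(sid)
            groups[sid] = condition
            cols.append(_nb_draw(rng, mean, config.noise_dispersion))
    lengths = (genes["end"] - genes["start"]).to_numpy(np.float64)
    return CountMatrix(
        gene_ids=list(genes["gene_id"]),
        sample_ids=sample_ids,
        counts=np.column_stack(cols),
        gene_lengths=lengths,
        groups=groups,
    )


def simulate_sequences(truth: TruthSet, config: SimulationConfig
                       ) -> list[tuple[str, str]]:
    """Per-locus random DNA with the AP-1 site planted in gain loci.

    Each enhancer gets an i.i.d. uniform ACGT sequence of
    ``sequence_length`` bp; a ``motif_plant_fraction`` of gain loci get
    one exact TGACTCA instance on a random strand at a random offset.
    Placements are recorded in ``truth.motif_placements``.
    """
    if config.sequence_length < len(AP1_CONSENSUS):
        raise ValueError("sequence_length shorter than the planted motif")
    rng = _rng(config, 3)
    bases = np.array(list("ACGT"))
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(AP1_CONSENSUS))
    records: list[tuple[str, str]] = []
    truth.motif_placements = []
    for e in truth.enhancers:
        seq = "".join(rng.choice(bases, size=config.sequence_length))
        if e.status == "gain" and rng.random() < config.motif_plant_fraction:
            offset = int(rng.integers(0, config.sequence_length
                                      - len(AP1_CONSENSUS) + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            instance = AP1_CONSENSUS if strand == "+" else rc
            seq = seq[:offset] + instance + seq[offset + len(instance):]
            truth.motif_placements.append((e.name, offset, strand))
        records.append((e.name, seq))
    return records


def make_motif_panel(seed: int = 0, n_decoys: int = 10) -> list[PWM]:
    """The AP-1 PWM plus random-consensus decoy PWMs (synthetic, not
    curated database motifs). Decoys never contain the AP-1 site."""
    rng = np.random.default_rng([seed, 4])
    bases = "ACGT"
    rc = "TGAGTCA"
    pwms = [pwm_from_consensus("MA_AP1", "AP-1", AP1_CONSENSUS)]
    seen = {AP1_CONSENSUS}
    while len(pwms) < n_decoys + 1:
        cons = "".join(bases[rng.integers(4)] for _ in range(7))
        if cons in seen or AP1_CONSENSUS in cons or rc in cons:
            continue
        seen.add(cons)
        i = len(pwms) - 1
        pwms.append(pwm_from_consensus(f"DECOY_{i:02d}", f"decoy{i}", cons))
    return pwms


def write_simulation(outdir: str | Path, annotation: GeneAnnotation,
                     truth: TruthSet,
                     tracks: dict[tuple[str, str, int],
                                  tuple[SignalTrack, PeakSet]],
                     counts: CountMatrix,
                     sequences: list[tuple[str, str]],
                     pwms: list[PWM]) -> None:
    """Write every simulated artifact in the formats the readers accept."""
    from .genome_io import write_gene_annotation, write_intervals, write_signal

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gene_annotation(annotation, outdir / "genes.bed")
    for (mark, condition, rep), (track, peaks) in tracks.items():
        stem = f"{mark}_{condition}_rep{rep}"
        write_signal(track, outdir / f"{stem}.bedgraph")
        write_intervals(peaks, outdir / f"{stem}_peaks.bed")
    df = pd.DataFrame(
        {sid: counts.counts[:, i] for i, sid in enumerate(counts.sample_ids)},
        index=pd.Index(counts.gene_ids, name="gene_id"),
    )
    df.insert(0, "length", counts.gene_lengths.astype(int))
    df.to_csv(outdir / "rna_counts.tsv", sep="\t")
    with open(outdir / "sample_groups.tsv", "w") as fh:
        for sid in counts.sample_ids:
            fh.write(f"{sid}\t{counts.groups[sid]}\n")
    write_fasta(sequences, outdir / "enhancer_sequences.fa")
    write_jaspar(pwms, outdir / "motif_panel.jaspar")
    rows = [
        dict(name=e.name, chrom=e.interval.chrom, start=e.interval.start,
             end=e.interval.end, klass=e.klass, status=e.status,
             gene_id=e.gene_id, n_constituents=len(e.constituents))
        for e in truth.enhancers
    ]
    pd.DataFrame(rows).to_csv(outdir / "truth_enhancers.tsv", sep="\t",
                              index=False)
    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    for tf, targets in truth.tf_targets.items():
        with open(outdir / f"targets_{tf}.txt", "w") as fh:
            for g in sorted(targets):
                fh.write(g + "\n")
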