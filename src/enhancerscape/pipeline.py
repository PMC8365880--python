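"""End-to-end orchestration: inputs -> enhancers -> VELs/VSELs -> DEGs ->
integration -> motif enrichment -> QC, with one config and a manifest.

Runs either on simulated data (planted truth, default) or on user files
via the same readers. All stage outputs are TSV/BED; the run manifest
records every parameter, the seed and a checksum per output so a rerun
with the same seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, enhancers, integration, motifs, qc
from .genome_io import (
    GeneAnnotation,
    PeakSet,
    SignalTrack,
    read_count_matrix,
    read_gene_annotation,
    read_intervals,
    read_signal,
    write_intervals,
)
from .synthetic import (
    CONDITIONS,
    MARKS,
    SimulationConfig,
    TruthSet,
    make_motif_panel,
    simulate_chip_tracks,
    simulate_expression,
    simulate_genome,
    simulate_sequences,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_all"]


@dataclass
class PipelineConfig:
    """All stage parameters, with the study's stated defaults."""

    stitch_gap: int = 12_500
    boundary_min_dist: int = 1_500
    center_min_dist: int = 3_000
    distal_combine: str = "or"
    active_enhancer_tss_dist: int = 2_000
    fc_up: float = 2.0
    fc_down: float = 0.5
    rpkm_pseudocount: float = 1.0
    lfc_min: float = 1.0
    alpha: float = 0.05
    fpkm_pseudocount: float = 1.0
    motif_threshold_fraction: float = 0.8
    qc_bin_size: int = 2_000
    metagene_flank: int = 3_000
    metagene_bin_size: int = 50
    seed: int = 0
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # used when simulate=False
    input_paths: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)


@dataclass
class PipelineResult:
    """In-memory handles on every stage product plus summary counts."""

    annotation: GeneAnnotation
    truth: TruthSet | None
    catalogs: dict            # condition -> list[StitchedEnhancer]
    rank_curves: dict         # condition -> RankCurve
    union_catalog: list
    vels: list
    vsels: list
    degs: list
    vel_deg_overlap: object
    tf_common: set
    coordinated: set
    top_genes: list
    enrichment: list
    qc_correlations: pd.DataFrame
    summary: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(config: PipelineConfig):
    p = config.input_paths
    required = ["genes", "rna_counts", "sample_groups"]
    for key in required:
        if key not in p:
            raise ValueError(f"missing input path for config key {key!r}")
    annotation = read_gene_annotation(p["genes"], format=p.get("genes_format", "bed6"))
    tracks = {}
    for mark in MARKS:
        for condition in CONDITIONS:
            rep = 1
            while f"{mark}_{condition}_rep{rep}" in p:
                stem = f"{mark}_{condition}_rep{rep}"
                track = read_signal(p[stem])
                peaks = read_intervals(p[f"{stem}_peaks"])
                tracks[(mark, condition, rep)] = (track, peaks)
                rep += 1
    counts = read_count_matrix(p["rna_counts"], p["sample_groups"])
    sequences = motifs.read_fasta(p["sequences"]) if "sequences" in p else []
    pwms = motifs.read_jaspar(p["motifs"]) if "motifs" in p else []
    return annotation, None, tracks, counts, sequences, pwms


def run_all(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Execute every stage and write the report bundle to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        sim = config.sim
        if sim.seed != config.seed:
            sim = SimulationConfig(**{**asdict(sim), "seed": config.seed})
        annotation, truth = simulate_genome(sim)
        tracks = simulate_chip_tracks(truth, sim)
        counts = simulate_expression(truth, sim)
        sequences = simulate_sequences(truth, sim)
        pwms = make_motif_panel(seed=config.seed)
    else:
        annotation, truth, tracks, counts, sequences, pwms = _load_inputs(config)

    n_reps = max(rep for (_, _, rep) in tracks)
    rules = enhancers.DistalFilterRules(
        boundary_min_dist=config.boundary_min_dist,
        center_min_dist=config.center_min_dist,
        combine=config.distal_combine,
        active_enhancer_tss_dist=config.active_enhancer_tss_dist,
    )

    # --- enhancer calling, per condition -----------------------------------
    catalogs, rank_curves, pooled = {}, {}, {}
    for condition in CONDITIONS:
        k27_tracks = [tracks[("H3K27ac", condition, r)][0]
                      for r in range(1, n_reps + 1)]
        k27_peaks = PeakSet(
            [iv for r in range(1, n_reps + 1)
             for iv in tracks[("H3K27ac", condition, r)][1]],
            source_label=f"H3K27ac_{condition}",
        )
        k4_peaks = PeakSet(
            [iv for r in range(1, n_reps + 1)
             for iv in tracks[("H3K4me1", condition, r)][1]],
            source_label=f"H3K4me1_{condition}",
        )
        pooled[condition] = differential.pool_replicates(k27_tracks)
        active = enhancers.filter_active(k27_peaks, k4_peaks)
        distal = enhancers.filter_distal(active, annotation, rules)
        stitched = enhancers.stitch(distal, stitch_gap=config.stitch_gap)
        enhancers.quantify(stitched, pooled[condition], mark="H3K27ac")
        rank_curves[condition] = enhancers.call_super(stitched, mark="H3K27ac")
        catalogs[condition] = stitched

        rows = [
            dict(chrom=e.interval.chrom, start=e.interval.start,
                 end=e.interval.end, name=f"enh_{i:05d}",
                 rpkm=e.signal["H3K27ac"]["rpkm"],
                 raw=e.signal["H3K27ac"]["raw"], rank=e.rank,
                 kind="super" if e.is_super else "typical")
            for i, e in enumerate(stitched)
        ]
        pd.DataFrame(rows).to_csv(outdir / f"enhancers_{condition}.tsv",
                                  sep="\t", index=False)
        curve = rank_curves[condition]
        pd.DataFrame({"rank": np.arange(len(curve.signals)),
                      "signal": curve.signals}).to_csv(
            outdir / f"rank_curve_{condition}.tsv", sep="\t", index=False)

    # --- differential -------------------------------------------------------
    union = differential.build_union_catalog(catalogs["normal"],
                                             catalogs["tumor"])
    vels = differential.call_vels(
        union, pooled["tumor"], pooled["normal"],
        fc_up=config.fc_up, fc_down=config.fc_down,
        pseudocount=config.rpkm_pseudocount,
    )
    vsels = differential.call_vsels(
        union, pooled["tumor"], pooled["normal"],
        fc_up=config.fc_up, fc_down=config.fc_down,
        pseudocount=config.rpkm_pseudocount,
    )
    degs = differential.call_degs(
        counts, lfc_min=config.lfc_min, alpha=config.alpha,
        pseudocount=config.fpkm_pseudocount,
    )

    # --- integration --------------------------------------------------------
    mapping = integration.assign_proximal_gene(
        [r.enhancer.interval for r in vels], annotation)
    for r in vels:
        r.proximal_gene = mapping[r.enhancer.interval]
    for r in vsels:
        r.proximal_gene = mapping.get(r.enhancer.interval)
    overlap = integration.overlap_vel_degs(vels, degs)

    if truth is not None:
        tf_lists = [integration.TFTargetList(tf, targets, "synthetic")
                    for tf, targets in sorted(truth.tf_targets.items())]
    else:
        tf_lists = [
            integration.TFTargetList(Path(p).stem, genes, str(p))
            for p, genes in (
                (path, set(Path(path).read_text().split()))
                for path in config.input_paths.get("tf_targets", [])
            )
        ]
    if len(tf_lists) >= 2:
        tf_common, tf_venn = integration.intersect_tf_targets(tf_lists)
    else:
        tf_common, tf_venn = set(), None
    up_degs = {d.gene_id for d in degs if d.status == "up"}
    gain_genes = {r.proximal_gene for r in vels
                  if r.status == "gain" and r.proximal_gene}
    coordinated, triple_venn = integration.triple_overlap(
        tf_common, up_degs, gain_genes)
    top = integration.rank_top(degs, gene_set=coordinated or up_degs, n=10)

    # --- motif enrichment ---------------------------------------------------
    enrichment = []
    if sequences and pwms:
        name_to_status = ({e.name: e.status for e in truth.enhancers}
                          if truth is not None else {})
        fg = [rec for rec in sequences
              if name_to_status.get(rec[0], "gain") == "gain"]
        bg = motifs.make_background(fg, "dinucleotide_shuffle",
                                    seed=config.seed)
        enrichment = motifs.enrich(
            fg, bg, pwms,
            threshold_fraction=config.motif_threshold_fraction)

    # --- QC -----------------------------------------------------------------
    chrom_sizes = {}
    for track, _ in tracks.values():
        for chrom in track.runs:
            _, ends, _ = track.runs[chrom]
            chrom_sizes[chrom] = max(chrom_sizes.get(chrom, 0), int(ends[-1]))
    binned = {
        key: qc.bin_track(t, chrom_sizes, bin_size=config.qc_bin_size)
        for key, (t, _) in sorted(tracks.items())
    }
    keys = sorted(binned)
    corr_rows = []
    for i, ka in enumerate(keys):
        for kb in keys[i + 1:]:
            corr_rows.append(dict(
                a="_".join(map(str, ka)), b="_".join(map(str, kb)),
                spearman_rho=qc.correlate(binned[ka], binned[kb]),
            ))
    corr_df = pd.DataFrame(corr_rows)
    profile = qc.metagene(
        tracks[("H3K27ac", "tumor", 1)][1], pooled["tumor"],
        flank=config.metagene_flank, bin_size=config.metagene_bin_size)

    # --- outputs ------------------------------------------------------------
    vel_rows = [
        dict(chrom=r.enhancer.interval.chrom, start=r.enhancer.interval.start,
             end=r.enhancer.interval.end, tumor_rpkm=r.tumor_rpkm,
             normal_rpkm=r.normal_rpkm, fold_change=r.fold_change,
             status=r.status, proximal_gene=r.proximal_gene)
        for r in vels
    ]
    pd.DataFrame(vel_rows).to_csv(outdir / "vels.tsv", sep="\t", index=False)
    for status in ("gain", "lost"):
        sel = PeakSet([r.enhancer.interval for r in vels
                       if r.status == status])
        write_intervals(sel, outdir / f"vels_{status}.bed")
    pd.DataFrame([
        dict(chrom=r.enhancer.interval.chrom, start=r.enhancer.interval.start,
             end=r.enhancer.interval.end, fold_change=r.fold_change,
             status=r.status, condition_of_super=r.condition_of_super)
        for r in vsels
    ]).to_csv(outdir / "vsels.tsv", sep="\t", index=False)
    pd.DataFrame([vars(d) for d in degs]).to_csv(
        outdir / "degs.tsv", sep="\t", index=False)
    with open(outdir / "coordinated_genes.txt", "w") as fh:
        for g in sorted(coordinated):
            fh.write(g + "\n")
    pd.DataFrame([
        dict(gene_id=d.gene_id, log2fc=d.log2fc, p_value=d.p_value)
        for d in top
    ]).to_csv(outdir / "top_genes.tsv", sep="\t", index=False)
    if enrichment:
        pd.DataFrame([vars(r) for r in enrichment]).to_csv(
            outdir / "motif_enrichment.tsv", sep="\t", index=False)
    corr_df.to_csv(outdir / "qc_correlations.tsv", sep="\t", index=False)
    pd.DataFrame({"offset": profile.offsets,
                  "mean_signal": profile.profile}).to_csv(
        outdir / "metagene_H3K27ac_tumor.tsv", sep="\t", index=False)

    summary = dict(
        n_enhancers_normal=len(catalogs["normal"]),
        n_enhancers_tumor=len(catalogs["tumor"]),
        n_super_normal=sum(e.is_super for e in catalogs["normal"]),
        n_super_tumor=sum(e.is_super for e in catalogs["tumor"]),
        n_union=len(union),
        n_gain_vels=sum(r.status == "gain" for r in vels),
        n_lost_vels=sum(r.status == "lost" for r in vels),
        n_gain_vsels=sum(r.status == "gain" for r in vsels),
        n_lost_vsels=sum(r.status == "lost" for r in vsels),
        n_up_degs=sum(d.status == "up" for d in degs),
        n_down_degs=sum(d.status == "down" for d in degs),
        n_tf_common=len(tf_common),
        n_coordinated=len(coordinated),
        top_motif=(enrichment[0].motif_id if enrichment else None),
    )

    manifest = dict(
        parameters={k: v for k, v in asdict(config).items()
                    if k not in ("sim", "input_paths")},
        sim_parameters=asdict(config.sim) if config.simulate else None,
        seed=config.seed,
        summary=summary,
        outputs={},
    )
    for path in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.bed")) \
            + sorted(outdir.glob("*.txt")):
        manifest["outputs"][path.name] = _sha256(path)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        annotation=annotation, truth=truth, catalogs=catalogs,
        rank_curves=rank_curves, union_catalog=union, vels=vels,
        vsels=vsels, degs=degs, vel_deg_overlap=overlap,
        tf_common=tf_common, coordinated=coordinated, top_genes=top,
        enrichment=enrichment, qc_correlations=corr_df, summary=summary,
    )
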