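"""Proximal-gene assignment and gene-set intersection analyses.

"Proximal gene" is pinned to the nearest TSS to the locus center, with
lexicographic gene_id tie-breaking and no distance cap by default; the
cap is exposed for sensitivity analyses. Venn partitions are computed
exactly, so inclusion-exclusion identities hold by construction and are
asserted in tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .differential import DEGRecord, VELRecord
from .genome_io import GeneAnnotation, GenomicInterval, check_shared_chromosomes

__all__ = [
    "GeneSetOverlap",
    "TFTargetList",
    "assign_proximal_gene",
    "overlap_vel_degs",
    "intersect_tf_targets",
    "venn_partition",
    "triple_overlap",
    "rank_top",
]


@dataclass
class GeneSetOverlap:
    """Named input sets plus their full Venn partition."""

    labels: list[str]
    sets: dict[str, set[str]]
    # region keys are frozensets of member labels -> exclusive region genes
    regions: dict[frozenset, set[str]] = field(default_factory=dict)

    def cardinality(self, *labels: str) -> int:
        """|intersection of the named sets| (not region-exclusive)."""
        out = set.intersection(*(self.sets[l] for l in labels))
        return len(out)

    def intersection(self, *labels: str) -> set[str]:
        return set.intersection(*(self.sets[l] for l in labels))


@dataclass
class TFTargetList:
    tf_name: str
    target_genes: set[str]
    source_label: str = ""


def assign_proximal_gene(
    loci: list[GenomicInterval],
    genes: GeneAnnotation,
    max_dist: int | None = None,
) -> dict[GenomicInterval, str | None]:
    """Map each locus to the gene whose TSS is nearest the locus center.

    Ties go to the lexicographically smaller gene_id; loci farther than
    ``max_dist`` (when set) map to None, as do loci on chromosomes with
    no annotated gene.
    """
    if len(genes) == 0:
        raise ValueError("empty gene annotation")
    if loci:
        check_shared_chromosomes(
            sorted({l.chrom for l in loci}),
            sorted(genes.genes["chrom"].unique()),
            "loci and gene annotation",
        )
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in genes.genes.groupby("chrom"):
        # sort by (tss, gene_id) so equidistant neighbours resolve to the
        # lexicographically smaller id deterministically
        sub = sub.sort_values(["tss", "gene_id"])
        per_chrom[chrom] = (
            sub["tss"].to_numpy(np.float64),
            sub["gene_id"].to_numpy(object),
        )
    mapping: dict[GenomicInterval, str | None] = {}
    for locus in loci:
        if locus.chrom not in per_chrom:
            mapping[locus] = None
            continue
        tss, ids = per_chrom[locus.chrom]
        center = locus.center
        dists = np.abs(tss - center)
        best = dists.min()
        if max_dist is not None and best > max_dist:
            mapping[locus] = None
            continue
        candidates = ids[dists == best]
        mapping[locus] = min(candidates)
    return mapping


def venn_partition(sets: dict[str, set[str]]) -> dict[frozenset, set[str]]:
    """Exclusive Venn regions over all non-empty label combinations."""
    labels = list(sets)
    regions: dict[frozenset, set[str]] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[l] for l in combo))
            outside = set.union(
                set(), *(sets[l] for l in labels if l not in combo)
            )
            regions[frozenset(combo)] = inside - outside
    return regions


def overlap_vel_degs(
    vels: list[VELRecord], degs: list[DEGRecord]
) -> GeneSetOverlap:
    """Overlap gain/lost VEL proximal genes with up/down DEGs.

    The headline sets are gain-VEL genes ∩ up DEGs and lost-VEL genes ∩
    down DEGs; all four marginals and the Venn partition come along.
    """
    if not vels or not degs:
        raise ValueError("need non-empty VEL and DEG inputs")
    gain_genes = {r.proximal_gene for r in vels
                  if r.status == "gain" and r.proximal_gene}
    lost_genes = {r.proximal_gene for r in vels
                  if r.status == "lost" and r.proximal_gene}
    up = {d.gene_id for d in degs if d.status == "up"}
    down = {d.gene_id for d in degs if d.status == "down"}
    sets = {
        "gain_vel_genes": gain_genes,
        "lost_vel_genes": lost_genes,
        "up_degs": up,
        "down_degs": down,
    }
    vel_genes = gain_genes | lost_genes
    deg_genes = up | down
    if vel_genes and deg_genes and not (vel_genes & deg_genes):
        warnings.warn("VEL and DEG gene namespaces are disjoint: empty overlaps")
    return GeneSetOverlap(
        labels=list(sets), sets=sets, regions=venn_partition(sets)
    )


def intersect_tf_targets(lists: list[TFTargetList]) -> tuple[set[str], GeneSetOverlap]:
    """Common targets of all TFs plus the full Venn partition."""
    if len(lists) < 2:
        raise ValueError("need >= 2 TF target lists")
    sets = {t.tf_name: set(t.target_genes) for t in lists}
    common = set.intersection(*sets.values())
    return common, GeneSetOverlap(
        labels=list(sets), sets=sets, regions=venn_partition(sets)
    )


def triple_overlap(
    tf_common: set[str], up_degs: set[str], gain_vel_genes: set[str]
) -> tuple[set[str], GeneSetOverlap]:
    """Three-way intersection (coordinated genes) with all Venn regions."""
    sets = {
        "tf_common": set(tf_common),
        "up_degs": set(up_degs),
        "gain_vel_genes": set(gain_vel_genes),
    }
    coordinated = tf_common & up_degs & gain_vel_genes
    return coordinated, GeneSetOverlap(
        labels=list(sets), sets=sets, regions=venn_partition(sets)
    )


def rank_top(records: list[DEGRecord], gene_set: set[str] | None = None,
             n: int = 10) -> list[DEGRecord]:
    """Top-n records by descending log2FC, ties by gene_id."""
    if n <= 0:
        raise ValueError("n must be > 0")
    pool = [r for r in records if gene_set is None or r.gene_id in gene_set]
    pool.sort(key=lambda r: (-r.log2fc, r.gene_id))
    return pool[:n]
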