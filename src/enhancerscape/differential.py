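"""Tumor-vs-normal differential calls: VELs, VSELs and DEGs.

Variant enhancer loci (VELs) are union-catalog enhancers whose pooled
H3K27ac RPKM changes at least two-fold between tumor and normal
(gain: tumor/normal >= 2; lost: <= 0.5). VSELs restrict the same logic
to loci that are super enhancers in at least one condition.

Differentially expressed genes use |log2FC| >= 1 and p < 0.05 on FPKM;
the p-value comes from a Welch two-sample test on log2(FPKM+1), a
deliberately simple, calibratable stand-in for a negative-binomial DE
fitter — an external DE result table can be plugged in through the same
DEGRecord schema.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .enhancers import StitchedEnhancer, quantify
from .genome_io import CountMatrix, GenomicInterval, SignalTrack

__all__ = [
    "VELRecord",
    "VSELRecord",
    "DEGRecord",
    "pool_replicates",
    "build_union_catalog",
    "call_vels",
    "call_vsels",
    "normalize_fpkm",
    "call_degs",
]


@dataclass
class VELRecord:
    enhancer: StitchedEnhancer
    tumor_rpkm: float
    normal_rpkm: float
    fold_change: float
    status: str  # gain | lost | stable
    proximal_gene: str | None = None


@dataclass
class VSELRecord(VELRecord):
    condition_of_super: str = "both"  # normal | tumor | both


@dataclass
class DEGRecord:
    gene_id: str
    normal_mean_fpkm: float
    tumor_mean_fpkm: float
    log2fc: float
    p_value: float
    status: str  # up | down | null


def pool_replicates(tracks: list[SignalTrack]) -> SignalTrack:
    """Sum per-bp values and library sizes across replicate tracks."""
    if not tracks:
        raise ValueError("cannot pool an empty list of tracks")
    if len(tracks) == 1:
        return tracks[0]
    chroms = sorted({c for t in tracks for c in t.runs})
    runs = {}
    for chrom in chroms:
        # union of breakpoints, then sum piecewise-constant values
        cuts = set()
        for t in tracks:
            if chrom in t.runs:
                s, e, _ = t.runs[chrom]
                cuts.update(s.tolist())
                cuts.update(e.tolist())
        edges = np.array(sorted(cuts), dtype=np.int64)
        starts, ends = edges[:-1], edges[1:]
        mids = (starts + ends) // 2
        total = np.zeros(len(starts), dtype=np.float64)
        for t in tracks:
            if chrom not in t.runs:
                continue
            s, e, v = t.runs[chrom]
            idx = np.searchsorted(s, mids, side="right") - 1
            valid = (idx >= 0) & (mids < e[np.clip(idx, 0, None)])
            total[valid] += v[idx[valid]]
        keep = total >= 0  # keep zero runs too: harmless, preserves coverage
        runs[chrom] = (starts[keep], ends[keep], total[keep])
    return SignalTrack(runs, library_size=sum(t.library_size for t in tracks))


def build_union_catalog(
    normal_enhancers: list[StitchedEnhancer],
    tumor_enhancers: list[StitchedEnhancer],
) -> list[StitchedEnhancer]:
    """Merge the two condition catalogs into union loci with provenance.

    Spans overlapping by >= 1 bp join one union locus; each carries flags
    in_normal / in_tumor / super_in_normal / super_in_tumor in
    ``signal['provenance']``.
    """
    tagged = [(e, "normal") for e in normal_enhancers] + [
        (e, "tumor") for e in tumor_enhancers
    ]
    tagged.sort(key=lambda t: t[0].interval.sort_key())
    out: list[StitchedEnhancer] = []
    group: list[tuple[StitchedEnhancer, str]] = []
    max_end = 0

    def flush() -> None:
        if not group:
            return
        chrom = group[0][0].interval.chrom
        start = min(e.interval.start for e, _ in group)
        end = max(e.interval.end for e, _ in group)
        prov = {
            "in_normal": any(c == "normal" for _, c in group),
            "in_tumor": any(c == "tumor" for _, c in group),
            "super_in_normal": any(c == "normal" and e.is_super for e, c in group),
            "super_in_tumor": any(c == "tumor" and e.is_super for e, c in group),
        }
        constituents = [p for e, _ in group for p in e.constituents]
        union = StitchedEnhancer(
            interval=GenomicInterval(chrom, start, end),
            constituents=sorted(constituents, key=GenomicInterval.sort_key),
        )
        union.signal["provenance"] = prov
        out.append(union)

    for item in tagged:
        iv = item[0].interval
        if group and iv.chrom == group[0][0].interval.chrom and iv.start < max_end:
            group.append(item)
            max_end = max(max_end, iv.end)
        else:
            flush()
            group = [item]
            max_end = iv.end
    flush()
    out.sort(key=lambda e: e.interval.sort_key())
    return out


def _classify(fc: float, fc_up: float, fc_down: float) -> str:
    if fc >= fc_up:
        return "gain"
    if fc <= fc_down:
        return "lost"
    return "stable"


def call_vels(
    catalog: list[StitchedEnhancer],
    tumor_track: SignalTrack,
    normal_track: SignalTrack,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    pseudocount: float = 1.0,
) -> list[VELRecord]:
    """Classify union-catalog loci by pooled H3K27ac fold change.

    fold_change = (tumor_rpkm + pseudocount) / (normal_rpkm + pseudocount);
    records are sorted by |log2 fold change| descending.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    quantify(catalog, tumor_track, mark="H3K27ac_tumor")
    quantify(catalog, normal_track, mark="H3K27ac_normal")
    records = []
    for enh in catalog:
        t = enh.signal["H3K27ac_tumor"]["rpkm"]
        n = enh.signal["H3K27ac_normal"]["rpkm"]
        fc = (t + pseudocount) / (n + pseudocount)
        records.append(
            VELRecord(
                enhancer=enh,
                tumor_rpkm=t,
                normal_rpkm=n,
                fold_change=fc,
                status=_classify(fc, fc_up, fc_down),
            )
        )
    records.sort(key=lambda r: (-abs(np.log2(r.fold_change)),
                                r.enhancer.interval.sort_key()))
    return records


def call_vsels(
    catalog: list[StitchedEnhancer],
    tumor_track: SignalTrack,
    normal_track: SignalTrack,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    pseudocount: float = 1.0,
    directional: bool = True,
) -> list[VSELRecord]:
    """VEL logic restricted to loci super in at least one condition.

    With ``directional=True`` (default) a gain VSEL additionally requires
    super-in-tumor and a lost VSEL super-in-normal; pure fold-change-on-
    super-loci behaviour is available with ``directional=False``.
    """
    super_loci = [
        e for e in catalog
        if e.signal.get("provenance", {}).get("super_in_normal")
        or e.signal.get("provenance", {}).get("super_in_tumor")
    ]
    vels = call_vels(super_loci, tumor_track, normal_track,
                     fc_up=fc_up, fc_down=fc_down, pseudocount=pseudocount)
    out = []
    for r in vels:
        prov = r.enhancer.signal["provenance"]
        s_n, s_t = prov["super_in_normal"], prov["super_in_tumor"]
        cond = "both" if (s_n and s_t) else ("normal" if s_n else "tumor")
        status = r.status
        if directional:
            if status == "gain" and not s_t:
                status = "stable"
            if status == "lost" and not s_n:
                status = "stable"
        out.append(
            VSELRecord(
                enhancer=r.enhancer,
                tumor_rpkm=r.tumor_rpkm,
                normal_rpkm=r.normal_rpkm,
                fold_change=r.fold_change,
                status=status,
                condition_of_super=cond,
            )
        )
    return out


def normalize_fpkm(counts: CountMatrix) -> np.ndarray:
    """FPKM matrix: counts / (gene length kb x library total / 1e6)."""
    totals = counts.counts.sum(axis=0).astype(np.float64)
    if np.any(totals <= 0):
        bad = [counts.sample_ids[i] for i in np.nonzero(totals <= 0)[0]]
        raise ValueError(f"zero library total for sample(s): {bad}")
    if np.any(counts.gene_lengths <= 0):
        raise ValueError("gene lengths must be > 0")
    length_kb = counts.gene_lengths[:, None] / 1000.0
    per_million = totals[None, :] / 1e6
    return counts.counts / (length_kb * per_million)


def call_degs(
    counts: CountMatrix,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> list[DEGRecord]:
    """Call DEGs: |log2FC| >= lfc_min and p < alpha on group-mean FPKM.

    p-values from Welch's two-sided t-test on log2(FPKM + pseudocount);
    no multiple-testing correction by default, matching the raw p < 0.05
    rule (apply BH externally if wanted).
    """
    normal_idx = counts.samples_in("normal")
    tumor_idx = counts.samples_in("tumor")
    if len(normal_idx) < 2 or len(tumor_idx) < 2:
        raise ValueError("need >= 2 samples per group for DE")
    fpkm = normalize_fpkm(counts)
    log_fpkm = np.log2(fpkm + pseudocount)
    normal_mean = fpkm[:, normal_idx].mean(axis=1)
    tumor_mean = fpkm[:, tumor_idx].mean(axis=1)
    log2fc = np.log2((tumor_mean + pseudocount) / (normal_mean + pseudocount))
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(
            log_fpkm[:, tumor_idx], log_fpkm[:, normal_idx],
            axis=1, equal_var=False,
        )
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    records = []
    for i, gene in enumerate(counts.gene_ids):
        if log2fc[i] >= lfc_min and pvals[i] < alpha:
            status = "up"
        elif log2fc[i] <= -lfc_min and pvals[i] < alpha:
            status = "down"
        else:
            status = "null"
        records.append(
            DEGRecord(
                gene_id=gene,
                normal_mean_fpkm=float(normal_mean[i]),
                tumor_mean_fpkm=float(tumor_mean[i]),
                log2fc=float(log2fc[i]),
                p_value=float(pvals[i]),
                status=status,
            )
        )
    return records
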