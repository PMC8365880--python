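"""Typical / super enhancer calling from H3K27ac peaks.

The procedure: keep H3K27ac peaks distal to every TSS (boundary >= 1.5 kb
or center >= 3 kb), merge peaks closer than 12.5 kb into stitched
enhancers, quantify H3K27ac over each stitched span (raw and RPKM), rank
ascending by total signal, and call super enhancers above the point where
a tangent of slope 1 touches the scaled rank curve.

The tangent point is found geometrically: on the [0,1]x[0,1]-scaled
curve the slope-1 tangent touches a convex curve exactly where the gap
below the unit diagonal, y - x, is most negative, so the cutoff is
argmin(y - x). This is equivalent to the first slope-1 crossing on a
smooth convex curve but is robust to the order-statistic noise of real
rank curves, where pointwise finite-difference slopes can spuriously
exceed 1 in the flat left tail. "Above the point" is a strict
inequality on signal. ROSE-style tools differ in these details, so the
rule is pinned here for reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome_io import (
    GeneAnnotation,
    GenomicInterval,
    PeakSet,
    SignalTrack,
    check_shared_chromosomes,
)

__all__ = [
    "DistalFilterRules",
    "StitchedEnhancer",
    "RankCurve",
    "filter_distal",
    "filter_active",
    "stitch",
    "quantify",
    "call_super",
]


@dataclass
class DistalFilterRules:
    """TSS-distance rules deciding which peaks count as distal.

    A peak passes for a given TSS when (boundary distance >=
    ``boundary_min_dist``) OR (center distance >= ``center_min_dist``);
    ``combine='and'`` switches the disjunction to a conjunction. The
    separate ``active_enhancer_tss_dist`` (2 kb) is the coarser
    active-enhancer pre-filter and is applied only when requested.
    """

    boundary_min_dist: int = 1500
    center_min_dist: int = 3000
    combine: str = "or"
    active_enhancer_tss_dist: int = 2000

    def __post_init__(self) -> None:
        if self.combine not in ("or", "and"):
            raise ValueError("combine must be 'or' or 'and'")
        for v in (self.boundary_min_dist, self.center_min_dist,
                  self.active_enhancer_tss_dist):
            if v < 0:
                raise ValueError("distances must be >= 0")


@dataclass
class StitchedEnhancer:
    """A merged run of distal peaks with per-mark signal."""

    interval: GenomicInterval
    constituents: list[GenomicInterval]
    signal: dict = field(default_factory=dict)  # mark -> {"raw": x, "rpkm": y}
    rank: int | None = None
    is_super: bool = False

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class RankCurve:
    """Ascending H3K27ac rank curve with the slope-1 tangent cutoff."""

    signals: np.ndarray          # ascending raw totals
    x_scaled: np.ndarray         # rank/(N-1) in [0, 1]
    y_scaled: np.ndarray         # signal/max in [0, 1]
    cutoff_index: int | None     # None when no slope ever exceeds 1
    cutoff_signal: float


def _boundary_distance(iv: GenomicInterval, tss: int) -> int:
    """Distance from a TSS to the nearest peak boundary; 0 inside the peak."""
    if tss < iv.start:
        return iv.start - tss
    if tss > iv.end:
        return tss - iv.end
    return 0


def _peak_is_distal(iv: GenomicInterval, tss_positions: np.ndarray,
                    rules: DistalFilterRules) -> bool:
    center = iv.center
    for tss in tss_positions:
        bdist = _boundary_distance(iv, int(tss))
        cdist = abs(center - tss)
        ok_b = bdist >= rules.boundary_min_dist
        ok_c = cdist >= rules.center_min_dist
        ok = (ok_b or ok_c) if rules.combine == "or" else (ok_b and ok_c)
        if not ok:
            return False
    return True


def filter_distal(peaks: PeakSet, genes: GeneAnnotation,
                  rules: DistalFilterRules | None = None) -> PeakSet:
    """Retain peaks distal to every TSS under the boundary/center rules."""
    if len(genes) == 0:
        raise ValueError("empty gene annotation: cannot define distal peaks")
    rules = rules or DistalFilterRules()
    check_shared_chromosomes(
        peaks.chroms(), sorted(genes.genes["chrom"].unique()),
        "peaks and gene annotation",
    )
    tss = genes.tss_by_chrom()
    # only TSSs within reach of the rules can reject a peak
    margin = max(rules.boundary_min_dist, rules.center_min_dist)
    kept = []
    for iv in peaks:
        positions = tss.get(iv.chrom, np.empty(0, dtype=np.int64))
        lo = np.searchsorted(positions, iv.start - margin - iv.length)
        hi = np.searchsorted(positions, iv.end + margin + iv.length)
        if _peak_is_distal(iv, positions[lo:hi], rules):
            kept.append(iv)
    return PeakSet(kept, source_label=peaks.source_label)


def filter_active(k27ac_peaks: PeakSet, k4me1_peaks: PeakSet,
                  min_overlap_fraction: float = 0.0) -> PeakSet:
    """Keep H3K27ac peaks supported by H3K4me1 (active enhancer definition).

    A peak qualifies when it overlaps an H3K4me1 peak by at least one bp;
    ``min_overlap_fraction`` optionally requires the overlap to cover that
    fraction of the H3K27ac peak.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in k4me1_peaks:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    starts = {c: np.array([p.start for p in ps]) for c, ps in by_chrom.items()}
    ends = {c: np.array([p.end for p in ps]) for c, ps in by_chrom.items()}
    kept = []
    for iv in k27ac_peaks:
        if iv.chrom not in by_chrom:
            continue
        s, e = starts[iv.chrom], ends[iv.chrom]
        ov = np.minimum(e, iv.end) - np.maximum(s, iv.start)
        best = ov.max(initial=0)
        if best >= 1 and best >= min_overlap_fraction * iv.length:
            kept.append(iv)
    return PeakSet(kept, source_label=k27ac_peaks.source_label)


def stitch(peaks: PeakSet, stitch_gap: int = 12500) -> list[StitchedEnhancer]:
    """Single-linkage merge of peaks with inter-peak gap < ``stitch_gap``.

    The gap between consecutive sorted peaks is next.start - prev.end
    (overlapping peaks have gap <= 0); a gap of exactly ``stitch_gap``
    splits — "shorter than" is a strict inequality.
    """
    out: list[StitchedEnhancer] = []
    current: list[GenomicInterval] = []

    def flush() -> None:
        if current:
            span = GenomicInterval(
                current[0].chrom,
                min(p.start for p in current),
                max(p.end for p in current),
            )
            out.append(StitchedEnhancer(interval=span, constituents=list(current)))

    max_end = 0
    for iv in peaks:  # PeakSet is sorted
        if (
            current
            and iv.chrom == current[0].chrom
            and iv.start - max_end < stitch_gap
        ):
            current.append(iv)
            max_end = max(max_end, iv.end)
        else:
            flush()
            current = [iv]
            max_end = iv.end
    flush()
    out.sort(key=lambda e: e.interval.sort_key())
    return out


def quantify(enhancers: list[StitchedEnhancer], track: SignalTrack,
             mark: str = "H3K27ac") -> list[StitchedEnhancer]:
    """Attach raw signal and RPKM over each stitched span, in place.

    raw  = sum(value x overlap length) over the span
    RPKM = raw / (length_kb x library_size / 1e6)
    """
    if track.library_size <= 0:
        raise ValueError("library_size must be > 0 for RPKM")
    per_million = track.library_size / 1e6
    for enh in enhancers:
        iv = enh.interval
        raw = track.interval_sum(iv.chrom, iv.start, iv.end)
        rpkm = raw / ((iv.length / 1000.0) * per_million)
        enh.signal[mark] = {"raw": raw, "rpkm": rpkm}
    return enhancers


def call_super(enhancers: list[StitchedEnhancer], mark: str = "H3K27ac",
               use: str = "raw") -> RankCurve:
    """Rank enhancers by total H3K27ac and split super from typical.

    Signals are sorted ascending; both axes are scaled to [0, 1]; the
    cutoff is the slope-1 tangent point, argmin(y - x) — the rank where
    the curve lies deepest below the unit diagonal — and enhancers with
    signal strictly above the cutoff signal are super. A curve that
    never dips below the diagonal (linear, all-equal, concave) has no
    tangent point and yields zero supers with a warning. Returns the
    RankCurve; ``is_super`` and ``rank`` are set in place.
    """
    if len(enhancers) < 3:
        raise ValueError("need >= 3 quantified enhancers to call supers")
    sig = np.array([e.signal[mark][use] for e in enhancers], dtype=np.float64)
    order = np.argsort(sig, kind="stable")
    y = sig[order]
    n = len(y)
    x = np.arange(n) / (n - 1)
    ymax = y[-1]
    if ymax <= 0 or np.all(y == y[0]):
        warnings.warn("degenerate rank curve (all signals equal): no super enhancers")
        curve = RankCurve(y, x, np.zeros_like(y) if ymax <= 0 else y / ymax,
                          None, float("inf"))
        for i, idx in enumerate(order):
            enhancers[idx].rank = i
            enhancers[idx].is_super = False
        return curve
    ys = y / ymax
    gap = ys - x
    # 1e-9 guards float round-off on exactly-linear curves (gap == 0)
    if gap.min() >= -1e-9:
        warnings.warn(
            "rank curve never dips below the unit diagonal (slope never "
            "exceeds 1 from below): no super enhancers"
        )
        cutoff_index, cutoff_signal = None, float("inf")
    else:
        cutoff_index = int(np.argmin(gap))
        cutoff_signal = float(y[cutoff_index])
    for i, idx in enumerate(order):
        enhancers[idx].rank = i
        enhancers[idx].is_super = bool(sig[idx] > cutoff_signal)
    return RankCurve(y, x, ys, cutoff_index, cutoff_signal)
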