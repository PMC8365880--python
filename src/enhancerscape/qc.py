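"""Track QC: genome-binned correlation and peak-centered metagene profiles.

Replicate and cross-mark concordance is measured by Spearman correlation
of signal summed into 2 kb genome windows; aggregate (metagene) profiles
average signal in fixed-width bins around peak centers over a +/-3 kb
flank by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome_io import PeakSet, SignalTrack

__all__ = ["BinnedTrack", "MetaProfile", "bin_track", "correlate", "metagene"]


@dataclass
class BinnedTrack:
    bin_size: int
    chrom_sizes: dict[str, int]
    values: dict[str, np.ndarray]  # per-chromosome per-bin sums

    def flat(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in sorted(self.values)])


@dataclass
class MetaProfile:
    flank: int
    bin_size: int
    profile: np.ndarray      # mean signal per offset bin
    offsets: np.ndarray      # bin-left offsets relative to peak center
    n_peaks: int


def bin_track(track: SignalTrack, chrom_sizes: dict[str, int],
              bin_size: int = 2000) -> BinnedTrack:
    """Sum value x overlap into tiling bins (last bin may be short)."""
    missing = [c for c in track.runs if c not in chrom_sizes]
    if missing:
        raise ValueError(f"track chromosome(s) missing from sizes: {missing}")
    values: dict[str, np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        n_bins = int(np.ceil(size / bin_size))
        out = np.zeros(n_bins, dtype=np.float64)
        if chrom in track.runs:
            starts, ends, vals = track.runs[chrom]
            for s, e, v in zip(starts, ends, vals):
                b0, b1 = int(s // bin_size), int((e - 1) // bin_size)
                if b0 == b1:
                    out[b0] += v * (e - s)
                else:
                    out[b0] += v * ((b0 + 1) * bin_size - s)
                    out[b0 + 1:b1] += v * bin_size
                    out[b1] += v * (e - b1 * bin_size)
        values[chrom] = out
    return BinnedTrack(bin_size=bin_size, chrom_sizes=dict(chrom_sizes),
                       values=values)


def correlate(a: BinnedTrack, b: BinnedTrack, method: str = "spearman",
              drop_joint_zero: bool = True) -> float:
    """Correlation over paired bins; bins zero in BOTH tracks excluded
    by default (sparse empty genome otherwise dominates the statistic)."""
    if a.bin_size != b.bin_size or a.chrom_sizes != b.chrom_sizes:
        raise ValueError("binning mismatch between tracks")
    x, y = a.flat(), b.flat()
    if drop_joint_zero:
        keep = (x != 0) | (y != 0)
        x, y = x[keep], y[keep]
    if method == "spearman":
        rho, _ = stats.spearmanr(x, y)
        return float(rho)
    if method == "pearson":
        r, _ = stats.pearsonr(x, y)
        return float(r)
    raise ValueError(f"unknown method {method!r}")


def metagene(peaks: PeakSet, track: SignalTrack, flank: int = 3000,
             bin_size: int = 50) -> MetaProfile:
    """Mean signal per offset bin over [center-flank, center+flank).

    Peaks truncated at chromosome edges contribute only their covered
    bins; the mean is over the peaks covering each bin.
    """
    if len(peaks) == 0:
        raise ValueError("need at least one peak for a metagene profile")
    if flank % bin_size:
        raise ValueError("flank must be a multiple of bin_size")
    n_bins = 2 * flank // bin_size
    total = np.zeros(n_bins, dtype=np.float64)
    count = np.zeros(n_bins, dtype=np.int64)
    for iv in peaks:
        center = int(iv.center)
        win_start = center - flank
        for b in range(n_bins):
            s = win_start + b * bin_size
            e = s + bin_size
            if s < 0:
                continue
            total[b] += track.interval_sum(iv.chrom, s, e) / bin_size
            count[b] += 1
    with np.errstate(invalid="ignore"):
        profile = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    offsets = np.arange(-flank, flank, bin_size)
    return MetaProfile(flank=flank, bin_size=bin_size, profile=profile,
                       offsets=offsets, n_peaks=len(peaks))
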