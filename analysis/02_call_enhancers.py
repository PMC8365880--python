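#!/usr/bin/env python
"""Call typical and super enhancers per condition from the simulated files.

For each condition: merge replicate H3K27ac peaks, keep those supported
by H3K4me1 (active enhancers) and distal to every TSS, stitch peaks
closer than 12.5 kb, quantify pooled H3K27ac RPKM, and split super from
typical at the rank-curve slope-1 tangent point.
"""

from pathlib import Path

import pandas as pd

from enhancerscape.differential import pool_replicates
from enhancerscape.enhancers import (
    call_super,
    filter_active,
    filter_distal,
    quantify,
    stitch,
)
from enhancerscape.genome_io import (
    PeakSet,
    read_gene_annotation,
    read_intervals,
    read_signal,
)

SIM_DIR = Path("scratch/sim")
RESULTS = Path("results")
N_REPS = 3


def main():
    RESULTS.mkdir(exist_ok=True)
    genes = read_gene_annotation(SIM_DIR / "genes.bed")
    for condition in ("normal", "tumor"):
        k27_tracks, k27_peaks, k4_peaks = [], [], []
        for rep in range(1, N_REPS + 1):
            stem = f"H3K27ac_{condition}_rep{rep}"
            k27_tracks.append(read_signal(SIM_DIR / f"{stem}.bedgraph"))
            k27_peaks.extend(read_intervals(SIM_DIR / f"{stem}_peaks.bed"))
            k4_peaks.extend(read_intervals(
                SIM_DIR / f"H3K4me1_{condition}_rep{rep}_peaks.bed"))
        pooled = pool_replicates(k27_tracks)
        active = filter_active(PeakSet(k27_peaks), PeakSet(k4_peaks))
        distal = filter_distal(active, genes)
        stitched = stitch(distal)
        quantify(stitched, pooled)
        curve = call_super(stitched)
        n_super = sum(e.is_super for e in stitched)
        print(f"{condition}: {len(active)} active peaks -> {len(distal)} "
              f"distal -> {len(stitched)} stitched enhancers, "
              f"{n_super} super (cutoff signal "
              f"{curve.cutoff_signal:.0f} at rank {curve.cutoff_index})")
        pd.DataFrame([
            dict(chrom=e.interval.chrom, start=e.interval.start,
                 end=e.interval.end, n_constituents=len(e.constituents),
                 raw=e.signal["H3K27ac"]["raw"],
                 rpkm=e.signal["H3K27ac"]["rpkm"], rank=e.rank,
                 kind="super" if e.is_super else "typical")
            for e in stitched
        ]).to_csv(RESULTS / f"02_enhancers_{condition}.tsv", sep="\t",
                  index=False)
        pd.DataFrame({"rank": range(len(curve.signals)),
                      "signal": curve.signals}).to_csv(
            RESULTS / f"02_rank_curve_{condition}.tsv", sep="\t",
            index=False)


if __name__ == "__main__":
    main()
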