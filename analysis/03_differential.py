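#!/usr/bin/env python
"""Call gain/lost VELs, VSELs and DEGs between tumor and normal.

Builds the union catalog from the per-condition enhancer tables (02),
classifies each locus by pooled H3K27ac fold change (gain >= 2, lost
<= 0.5), restricts to super loci for VSELs, and calls DEGs from the RNA
counts (|log2FC| >= 1, p < 0.05).
"""

from pathlib import Path

import pandas as pd

from enhancerscape.differential import (
    build_union_catalog,
    call_degs,
    call_vels,
    call_vsels,
    pool_replicates,
)
from enhancerscape.enhancers import StitchedEnhancer
from enhancerscape.genome_io import (
    GenomicInterval,
    read_count_matrix,
    read_signal,
)

SIM_DIR = Path("scratch/sim")
RESULTS = Path("results")
N_REPS = 3


def load_catalog(condition):
    df = pd.read_csv(RESULTS / f"02_enhancers_{condition}.tsv", sep="\t")
    out = []
    for row in df.itertuples():
        iv = GenomicInterval(row.chrom, row.start, row.end)
        e = StitchedEnhancer(interval=iv, constituents=[iv],
                             is_super=row.kind == "super")
        out.append(e)
    return out


def main():
    pooled = {}
    for condition in ("normal", "tumor"):
        pooled[condition] = pool_replicates([
            read_signal(SIM_DIR / f"H3K27ac_{condition}_rep{r}.bedgraph")
            for r in range(1, N_REPS + 1)])
    union = build_union_catalog(load_catalog("normal"),
                                load_catalog("tumor"))
    vels = call_vels(union, pooled["tumor"], pooled["normal"])
    vsels = call_vsels(union, pooled["tumor"], pooled["normal"])
    counts = read_count_matrix(SIM_DIR / "rna_counts.tsv",
                               SIM_DIR / "sample_groups.tsv")
    degs = call_degs(counts)

    n = lambda recs, s: sum(r.status == s for r in recs)
    print(f"union catalog: {len(union)} loci")
    print(f"VELs: {n(vels, 'gain')} gain, {n(vels, 'lost')} lost "
          f"(fold change >= 2 / <= 0.5 on pooled H3K27ac RPKM)")
    print(f"VSELs: {n(vsels, 'gain')} gain, {n(vsels, 'lost')} lost")
    print(f"DEGs: {n(degs, 'up')} up, {n(degs, 'down')} down "
          f"of {len(degs)} genes")

    pd.DataFrame([
        dict(chrom=r.enhancer.interval.chrom,
             start=r.enhancer.interval.start, end=r.enhancer.interval.end,
             tumor_rpkm=r.tumor_rpkm, normal_rpkm=r.normal_rpkm,
             fold_change=r.fold_change, status=r.status)
        for r in vels
    ]).to_csv(RESULTS / "03_vels.tsv", sep="\t", index=False)
    pd.DataFrame([
        dict(chrom=r.enhancer.interval.chrom,
             start=r.enhancer.interval.start, end=r.enhancer.interval.end,
             fold_change=r.fold_change, status=r.status,
             condition_of_super=r.condition_of_super)
        for r in vsels
    ]).to_csv(RESULTS / "03_vsels.tsv", sep="\t", index=False)
    pd.DataFrame([vars(d) for d in degs]).to_csv(
        RESULTS / "03_degs.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
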