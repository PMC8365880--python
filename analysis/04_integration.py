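#!/usr/bin/env python
"""Integrate VELs, DEGs and TF target lists via proximal genes.

Assigns each VEL its nearest-TSS proximal gene, overlaps gain/lost VEL
genes with up/down DEGs, intersects the three TF target lists
(Batf/Fos/Junb analogs), takes the three-way overlap of common targets
with up DEGs and gain-VEL genes (the coordinated gene set) and ranks its
top 10 genes by expression fold change.
"""

from pathlib import Path

import pandas as pd

from enhancerscape.differential import DEGRecord
from enhancerscape.genome_io import (
    GenomicInterval,
    read_gene_annotation,
    read_gene_sets,
)
from enhancerscape.integration import (
    TFTargetList,
    assign_proximal_gene,
    intersect_tf_targets,
    rank_top,
    triple_overlap,
)

SIM_DIR = Path("scratch/sim")
RESULTS = Path("results")


def main():
    genes = read_gene_annotation(SIM_DIR / "genes.bed")
    vels = pd.read_csv(RESULTS / "03_vels.tsv", sep="\t")
    degs_df = pd.read_csv(RESULTS / "03_degs.tsv", sep="\t")
    degs = [DEGRecord(**row) for row in degs_df.to_dict("records")]

    loci = [GenomicInterval(r.chrom, r.start, r.end)
            for r in vels.itertuples()]
    mapping = assign_proximal_gene(loci, genes)
    vels["proximal_gene"] = [mapping[iv] for iv in loci]
    vels.to_csv(RESULTS / "04_vels_annotated.tsv", sep="\t", index=False)

    gain_genes = set(vels.loc[vels.status == "gain", "proximal_gene"])
    lost_genes = set(vels.loc[vels.status == "lost", "proximal_gene"])
    up = {d.gene_id for d in degs if d.status == "up"}
    down = {d.gene_id for d in degs if d.status == "down"}
    print(f"gain VELs with up DEGs: {len(gain_genes & up)}; "
          f"lost VELs with down DEGs: {len(lost_genes & down)}")

    target_sets = read_gene_sets(sorted(SIM_DIR.glob("targets_*.txt")))
    tf_lists = [TFTargetList(name.replace("targets_", ""), s, name)
                for name, s in target_sets.items()]
    common, venn = intersect_tf_targets(tf_lists)
    print(f"genes targeted by all {len(tf_lists)} TFs: {len(common)} "
          f"(of union {len(set().union(*target_sets.values()))})")

    coordinated, _ = triple_overlap(common, up, gain_genes)
    print(f"coordinated genes (TF targets ∩ up DEGs ∩ gain-VEL genes): "
          f"{len(coordinated)}")
    (RESULTS / "04_coordinated_genes.txt").write_text(
        "".join(g + "\n" for g in sorted(coordinated)))

    top = rank_top(degs, gene_set=coordinated, n=10)
    top_df = pd.DataFrame([dict(gene_id=d.gene_id, log2fc=d.log2fc,
                                p_value=d.p_value) for d in top])
    top_df.to_csv(RESULTS / "04_top10_coordinated.tsv", sep="\t",
                  index=False)
    print("top 10 coordinated genes by log2FC:")
    print(top_df.to_string(index=False))


if __name__ == "__main__":
    main()
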