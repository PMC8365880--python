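#!/usr/bin/env python
"""Known-motif enrichment of gain-VEL sequences.

Scans the gain-locus sequences and a dinucleotide-shuffled background
with the motif panel (AP-1 plus decoys) and ranks motifs by one-sided
Fisher p on sequence-level hits — the analog of predicting the driving
transcription factors from gained enhancers.
"""

import argparse
from pathlib import Path

import pandas as pd

from enhancerscape.motifs import enrich, make_background, read_fasta, read_jaspar

SIM_DIR = Path("scratch/sim")
RESULTS = Path("results")


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    sequences = dict(read_fasta(SIM_DIR / "enhancer_sequences.fa"))
    truth = pd.read_csv(SIM_DIR / "truth_enhancers.tsv", sep="\t")
    gain_names = truth.loc[truth.status == "gain", "name"]
    fg = [(name, sequences[name]) for name in gain_names]
    bg = make_background(fg, "dinucleotide_shuffle", seed=args.seed)
    pwms = read_jaspar(SIM_DIR / "motif_panel.jaspar")

    results = enrich(fg, bg, pwms)
    df = pd.DataFrame([vars(r) for r in results])
    df.to_csv(RESULTS / "05_motif_enrichment.tsv", sep="\t", index=False)
    print(f"{len(fg)} gain-VEL sequences vs shuffled background, "
          f"{len(pwms)} motifs:")
    print(df.head(10).to_string(index=False))


if __name__ == "__main__":
    main()
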