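#!/usr/bin/env python
"""Ordination of the panel: UPGMA dendrogram and PCA over 59-SC
frequencies.

The C/G-bias gradient built into the panel should dominate the first
principal component and order the species diploid-like -> tetraploid-like
-> hexaploid-like along it, and the dendrogram should join the two
closest bias levels first.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from scubkit import codon_core as cc
from scubkit import multivariate as mv
from scubkit.genetic_code import SC_CODONS

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    manifest = pd.read_csv(ROOT / "results" / "panel_manifest.tsv", sep="\t")
    labels, rows = [], []
    for _, sp in manifest.iterrows():
        counts = pd.read_csv(
            ROOT / "scratch" / "run" / sp["species"] / "codon_counts.tsv", sep="\t"
        )
        table = cc.CodonCountTable(
            counts=dict(zip(counts["codon"], counts["count"])), scope=sp["species"]
        )
        freqs = cc.codon_frequencies(table, "sc59")
        labels.append(sp["species"])
        rows.append([freqs[c] for c in SC_CODONS])

    matrix = np.array(rows)
    tree = mv.hierarchical_cluster(matrix, labels=labels)
    (ROOT / "results" / "panel_upgma.nwk").write_text(tree.newick + "\n")
    res = mv.pca(matrix, labels=labels)
    scores = pd.DataFrame(res.scores[:, :2], columns=["PC1", "PC2"])
    scores.insert(0, "species", labels)
    scores["pc1_proportion"] = res.proportions[0]
    scores.to_csv(ROOT / "results" / "panel_pca_scores.tsv", sep="\t", index=False)

    print("UPGMA:", tree.newick)
    first = tree.merge_order[0]
    print("first join:", sorted(first[0] | first[1]), f"at d={first[2]:.4f}")
    print(scores.round(4).to_string(index=False))
    print(f"\nPC1 explains {res.proportions[0]:.1%} of the variance.")


if __name__ == "__main__":
    main()
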