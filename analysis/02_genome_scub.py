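#!/usr/bin/env python
"""Genome-wide SCUB per species: ending frequencies, per-amino-acid
ratios, RSCU, CAI/ENC, and cross-species chi-square letters.

Runs the full pipeline over the panel from 01_simulate_species.py and
reports whether the built-in C/G-bias gradient is recovered: NNC/G
frequency should rise from the diploid-like to the hexaploid-like species
and the species should carry distinct partition letters.
"""

from pathlib import Path

import pandas as pd

from scubkit.pipeline import RunConfig, SpeciesInput, run_pipeline

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    manifest = pd.read_csv(ROOT / "results" / "panel_manifest.tsv", sep="\t")
    config = RunConfig(
        species=[
            SpeciesInput(r["species"], r["fasta"], r["gff3"])
            for _, r in manifest.iterrows()
        ],
        out_dir=ROOT / "scratch" / "run",
    )
    report = run_pipeline(config)

    rows = []
    for label, profile in report.profiles.items():
        rows.append(
            {"species": label,
             **{f"f_NN{b}": profile.ending_freq[b] for b in "ATCG"},
             "f_NNAT": profile.combined["AT"], "f_NNCG": profile.combined["CG"],
             "at_cg_ratio": profile.at_cg_ratio,
             "letters": report.ending_partition.letters[label]}
        )
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "results" / "genome_scub.tsv", sep="\t", index=False)
    report.rscu_cv.to_csv(ROOT / "results" / "rscu_cv.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    ordered = df.sort_values("f_NNCG")["species"].tolist()
    print(f"\nNNC/G frequency order (low -> high): {' < '.join(ordered)}")
    print("Distinct letters mark species whose third-base ending counts "
          "differ by pairwise chi-square at alpha = 0.05.")


if __name__ == "__main__":
    main()
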