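#!/usr/bin/env python
"""SCUB by exon count and exon position.

Reuses the per-species strata tables written by 02_genome_scub.py and
summarizes the two positional signals the analysis is built around: the
NNA/T : NNC/G ratio as a function of exon count, and the
interior-vs-terminal contrast per exon count. Under the panel's default
generator settings there is no positional tilt, so the position curves
should be flat; rerunning 01 with ``interior_tilt`` > 1 produces the
convex interior enrichment instead.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    manifest = pd.read_csv(ROOT / "results" / "panel_manifest.tsv", sep="\t")
    count_rows, pos_rows = [], []
    for label in manifest["species"]:
        run_dir = ROOT / "scratch" / "run" / label
        count_rows.append(pd.read_csv(run_dir / "strata_exon_count.tsv", sep="\t"))
        pos_rows.append(pd.read_csv(run_dir / "strata_exon_position.tsv", sep="\t"))
    by_count = pd.concat(count_rows, ignore_index=True)
    by_pos = pd.concat(pos_rows, ignore_index=True)
    by_count.to_csv(ROOT / "results" / "scub_by_exon_count.tsv", sep="\t", index=False)
    by_pos.to_csv(ROOT / "results" / "scub_by_exon_position.tsv", sep="\t", index=False)

    print("NNA/T : NNC/G ratio by exon count:")
    print(
        by_count.pivot(index="exon_count", columns="species", values="at_cg_ratio")
        .round(3).to_string()
    )
    interior = by_pos[(by_pos["position"] > 1) & (by_pos["position"] < by_pos["exon_count"])]
    terminal = by_pos[(by_pos["position"] == 1) | (by_pos["position"] == by_pos["exon_count"])]
    print("\nmean f(NNA/T): interior %.4f vs terminal %.4f"
          % (interior["f_NNAT"].mean(), terminal["f_NNAT"].mean()))


if __name__ == "__main__":
    main()
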