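"""End-to-end orchestration: extract -> count -> strata -> methylation ->
stats -> ordination, with TSV outputs and a verification pass.

One run covers any number of species (FASTA + GFF3 each). Outputs live
under one directory: per-species tables (accepted genes, rejects log,
codon counts, RSCU, per-gene CAI/ENC, stratified ending frequencies,
methylation-context counts) and cross-species comparisons (chi-square
partition letters on third-base ending counts, CVs of RSCU across species,
per-codon frequency correlations, an average-linkage dendrogram and PCA
over the 59-SC frequency matrix). Every reported ratio is recomputable
from the emitted count tables; ``verify_outputs`` re-derives and diffs
them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import codon_core, genome_io, methylation, multivariate, stats, strata
from .genetic_code import SC_CODONS

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


@dataclass
class SpeciesInput:
    label: str
    fasta: str | Path
    gff3: str | Path
    subgenome_rule: Mapping[str, str] | None = None


@dataclass
class RunConfig:
    species: list[SpeciesInput]
    out_dir: str | Path
    max_exons: int = strata.DEFAULT_MAX_EXONS
    alpha: float = 0.05
    cai_reference_genes: list[str] | None = None
    ortholog_table: str | Path | None = None
    seed: int = 0

    def validate(self) -> None:
        labels = [s.label for s in self.species]
        if len(set(labels)) != len(labels):
            raise ValueError("species labels must be unique")
        for s in self.species:
            for p in (s.fasta, s.gff3):
                if not Path(p).exists():
                    raise FileNotFoundError(f"{s.label}: input {p} does not exist")


@dataclass
class ComparisonReport:
    profiles: dict[str, codon_core.ScubProfile]
    count_tables: dict[str, codon_core.CodonCountTable]
    ending_partition: stats.PartitionResult | None
    rscu_cv: pd.DataFrame | None
    frequency_correlation: pd.DataFrame | None
    cluster: multivariate.ClusterTree | None
    pca: multivariate.PcaResult | None


def restrict_to_orthologs(
    records_by_species: dict[str, list[genome_io.CdsRecord]],
    table: pd.DataFrame,
) -> dict[str, list[genome_io.CdsRecord]]:
    """Keep only genes listed in a precomputed ortholog table.

    The table has columns group_id, species_label, gene_id. Groups missing
    any species present in the run are dropped with a warning; listed
    genes absent from a species' records are warned about and skipped.
    """
    required = {"group_id", "species_label", "gene_id"}
    if not required <= set(table.columns):
        raise ValueError(f"ortholog table needs columns {sorted(required)}")
    if table.empty:
        log.warning("ortholog table is empty; all species will have no genes")
        return {label: [] for label in records_by_species}
    species = set(records_by_species)
    keep_genes: dict[str, set[str]] = {label: set() for label in species}
    known = {
        label: {r.gene_id for r in recs}
        for label, recs in records_by_species.items()
    }
    for group_id, grp in table.groupby("group_id"):
        present = set(grp["species_label"])
        if not species <= present:
            log.warning(
                "ortholog group %s missing species %s; dropped",
                group_id, sorted(species - present),
            )
            continue
        ok = True
        for _, row in grp.iterrows():
            label = row["species_label"]
            if label in species and row["gene_id"] not in known[label]:
                log.warning(
                    "ortholog group %s lists unknown gene %s in %s; skipped",
                    group_id, row["gene_id"], label,
                )
                ok = False
        if not ok:
            continue
        for _, row in grp.iterrows():
            if row["species_label"] in species:
                keep_genes[row["species_label"]].add(row["gene_id"])
    return {
        label: [r for r in recs if r.gene_id in keep_genes[label]]
        for label, recs in records_by_species.items()
    }


def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def _profile_row(scope: dict, profile: codon_core.ScubProfile) -> dict:
    row = dict(scope)
    for b in "ATCG":
        row[f"f_NN{b}"] = profile.ending_freq[b]
    row["f_NNAT"] = profile.combined["AT"]
    row["f_NNCG"] = profile.combined["CG"]
    row["at_cg_ratio"] = profile.at_cg_ratio
    row["cg_at_ratio"] = profile.cg_at_ratio
    return row


def _species_outputs(
    label: str,
    records: list[genome_io.CdsRecord],
    out: Path,
    max_exons: int,
    cai_reference_genes: list[str] | None,
) -> tuple[codon_core.CodonCountTable, codon_core.ScubProfile]:
    accepted = genome_io.accepted_records(records)
    n_rejected = len(records) - len(accepted)
    log.info(
        "%s: %d genes seen, %d accepted, %d rejected",
        label, len(records), len(accepted), n_rejected,
    )
    _write(genome_io.rejects_table(records), out / "rejects.tsv")
    _write(
        pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "transcript_id": r.transcript_id,
                    "chromosome": r.chromosome,
                    "subgenome": r.subgenome,
                    "n_exons": r.n_exons,
                    "cds_length": len(r.cds_sequence),
                }
                for r in accepted
            ]
        ),
        out / "accepted.tsv",
    )

    table = codon_core.count_codons(accepted, scope=label)
    counts_df = pd.DataFrame(
        {"codon": list(table.counts), "count": list(table.counts.values())}
    )
    _write(counts_df, out / "codon_counts.tsv")

    profile = codon_core.scub_profile(table)
    _write(pd.DataFrame([_profile_row({"species": label}, profile)]),
           out / "profile.tsv")
    _write(
        pd.DataFrame(
            [{"amino_acid": aa, "cg_at_ratio": v}
             for aa, v in profile.per_aa_ratio.items()]
        ),
        out / "per_aa_scub_ratio.tsv",
    )
    rscu_values = codon_core.rscu(table)
    _write(
        pd.DataFrame([{"codon": c, "rscu": rscu_values[c]} for c in SC_CODONS]),
        out / "rscu.tsv",
    )

    # per-gene CAI and ENC against the chosen reference
    if cai_reference_genes:
        ref_records = [r for r in accepted if r.gene_id in set(cai_reference_genes)]
        ref_table = codon_core.count_codons(ref_records, scope=f"{label}:reference")
    else:
        ref_table = table
    weights = codon_core.reference_weights(ref_table)
    gene_rows = []
    for r in accepted:
        gene_table = codon_core.count_codons([r], scope=r.gene_id)
        try:
            gene_cai = codon_core.cai(gene_table, weights).value
        except ValueError:
            gene_cai = float("nan")
        gene_rows.append(
            {"gene_id": r.gene_id, "cai": gene_cai,
             "enc": codon_core.enc(gene_table)}
        )
    _write(pd.DataFrame(gene_rows), out / "gene_indices.tsv")

    # strata
    by_count = strata.stratify_by_exon_count(accepted, max_exons)
    by_pos = strata.stratify_by_exon_position(accepted, max_exons)
    rows = [
        _profile_row({"species": label, "exon_count": e}, p)
        for e, p in sorted(strata.stratum_profiles(by_count).items())
    ]
    _write(pd.DataFrame(rows), out / "strata_exon_count.tsv")
    rows = [
        _profile_row({"species": label, "exon_count": e, "position": p}, prof)
        for (e, p), prof in sorted(strata.stratum_profiles(by_pos).items())
    ]
    _write(pd.DataFrame(rows), out / "strata_exon_position.tsv")

    # methylation context
    second = methylation.second_position_counts(table)
    junctions = methylation.junction_triplet_counts(accepted)
    meth_rows = []
    for b in "ACGT":
        meth_rows.append(
            {
                "species": label, "second_base": b,
                "NXA": second.nxa[b], "NXG": second.nxg[b],
                "NXA_NXG_ratio": methylation.nxa_nxg_ratios(second)[b],
                "NTX": junctions.ntx[b], "NCX": junctions.ncx[b],
                "NTX_NCX_ratio": methylation.ntx_ncx_ratios(junctions)[b],
            }
        )
    _write(pd.DataFrame(meth_rows), out / "methylation_context.tsv")
    _write(
        pd.DataFrame(
            [
                {"amino_acid": v.amino_acid, "group": v.group,
                 "a_count": v.a_count, "g_count": v.g_count, "ratio": v.ratio}
                for v in methylation.per_aa_a_g_ratio(table).values()
            ]
        ),
        out / "per_aa_a_g_ratio.tsv",
    )
    by_strata = methylation.methylation_by_strata(accepted, max_exons)
    rows = []
    for e in sorted(by_strata.second_by_stratum):
        s = by_strata.second_by_stratum[e]
        j = by_strata.junction_by_stratum.get(e, methylation.JunctionTripletTable())
        for b in "ACGT":
            rows.append(
                {"species": label, "exon_count": e, "second_base": b,
                 "NXA": s.nxa[b], "NXG": s.nxg[b],
                 "NTX": j.ntx[b], "NCX": j.ncx[b]}
            )
    _write(pd.DataFrame(rows), out / "methylation_by_stratum.tsv")
    return table, profile


def run_pipeline(config: RunConfig) -> ComparisonReport:
    """Run every stage for every species and the cross-species comparison."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records_by_species: dict[str, list[genome_io.CdsRecord]] = {}
    for sp in config.species:
        records_by_species[sp.label] = genome_io.extract_cds_records(
            sp.fasta, sp.gff3, species_label=sp.label,
            subgenome_rule=sp.subgenome_rule,
        )
    if config.ortholog_table is not None:
        table = pd.read_csv(config.ortholog_table, sep="\t")
        accepted_only = {
            label: genome_io.accepted_records(recs)
            for label, recs in records_by_species.items()
        }
        records_by_species = restrict_to_orthologs(accepted_only, table)

    count_tables: dict[str, codon_core.CodonCountTable] = {}
    profiles: dict[str, codon_core.ScubProfile] = {}
    for sp in config.species:
        table, profile = _species_outputs(
            sp.label,
            records_by_species[sp.label],
            out_dir / sp.label,
            config.max_exons,
            config.cai_reference_genes,
        )
        count_tables[sp.label] = table
        profiles[sp.label] = profile

    labels = [sp.label for sp in config.species]
    ending_partition = None
    rscu_cv = None
    freq_corr = None
    cluster = None
    pca_result = None
    if len(labels) >= 2:
        ending_matrix = [
            [count_tables[lab].ending_count(b) for b in "ATCG"] for lab in labels
        ]
        ending_partition = stats.chisq_partition_pairwise(
            ending_matrix, labels=labels, alpha=config.alpha
        )
        _write(
            pd.DataFrame(
                [
                    {"species": lab, "letters": ending_partition.letters[lab],
                     "overall_chi2": ending_partition.overall.statistic,
                     "overall_p": ending_partition.overall.p}
                    for lab in labels
                ]
            ),
            out_dir / "comparison" / "ending_chi2_letters.tsv",
        )

        rscu_by_species = {
            lab: codon_core.rscu(count_tables[lab]) for lab in labels
        }
        cv_rows = []
        for c in SC_CODONS:
            values = [rscu_by_species[lab][c] for lab in labels]
            cv_rows.append(
                {"codon": c,
                 "cv": stats.coefficient_of_variation(values).value}
            )
        rscu_cv = pd.DataFrame(cv_rows)
        _write(rscu_cv, out_dir / "comparison" / "rscu_cv.tsv")

        freq = {
            lab: codon_core.codon_frequencies(count_tables[lab], "sc59")
            for lab in labels
        }
        corr = np.ones((len(labels), len(labels)))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    r = stats.pearson_correlation(
                        [freq[a][c] for c in SC_CODONS],
                        [freq[b][c] for c in SC_CODONS],
                    ).value
                    corr[i, j] = corr[j, i] = r
        freq_corr = pd.DataFrame(corr, index=labels, columns=labels)
        freq_corr.index.name = "species"
        (out_dir / "comparison").mkdir(exist_ok=True)
        freq_corr.to_csv(
            out_dir / "comparison" / "frequency_correlation.tsv",
            sep="\t", float_format=FLOAT_FORMAT,
        )

        feature_matrix = np.array(
            [[freq[lab][c] for c in SC_CODONS] for lab in labels]
        )
        cluster = multivariate.hierarchical_cluster(feature_matrix, labels=labels)
        (out_dir / "comparison" / "cluster.nwk").write_text(cluster.newick + "\n")
        if len(labels) >= 3:
            pca_result = multivariate.pca(feature_matrix, labels=labels)
            _write(
                pd.DataFrame(
                    {
                        "component": [f"PC{i+1}" for i in range(len(pca_result.proportions))],
                        "eigenvalue": pca_result.eigenvalues,
                        "proportion": pca_result.proportions,
                    }
                ),
                out_dir / "comparison" / "pca_eigenvalues.tsv",
            )
            scores = pd.DataFrame(
                pca_result.scores,
                columns=[f"PC{i+1}" for i in range(pca_result.scores.shape[1])],
            )
            scores.insert(0, "species", labels)
            _write(scores, out_dir / "comparison" / "pca_scores.tsv")

    return ComparisonReport(
        profiles=profiles,
        count_tables=count_tables,
        ending_partition=ending_partition,
        rscu_cv=rscu_cv,
        frequency_correlation=freq_corr,
        cluster=cluster,
        pca=pca_result,
    )


def verify_outputs(out_dir: str | Path, labels: list[str]) -> list[str]:
    """Re-derive profile ratios from emitted count tables and diff them.

    Returns a list of mismatch descriptions (empty = verified).
    """
    out_dir = Path(out_dir)
    problems: list[str] = []
    for label in labels:
        counts_df = pd.read_csv(out_dir / label / "codon_counts.tsv", sep="\t")
        table = codon_core.CodonCountTable(
            counts=dict(zip(counts_df["codon"], counts_df["count"])), scope=label
        )
        written = pd.read_csv(out_dir / label / "profile.tsv", sep="\t").iloc[0]
        profile = codon_core.scub_profile(table)
        for b in "ATCG":
            if abs(written[f"f_NN{b}"] - profile.ending_freq[b]) > 1e-9:
                problems.append(
                    f"{label}: f_NN{b} written {written[f'f_NN{b}']} "
                    f"!= recomputed {profile.ending_freq[b]}"
                )
        if abs(written["at_cg_ratio"] - profile.at_cg_ratio) > 1e-9:
            problems.append(f"{label}: at_cg_ratio mismatch")
    return problems
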