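"""Genome FASTA / GFF3 input and CDS assembly.

The unit of analysis is one coding sequence per gene: the first annotated
transcript (by order of appearance in the GFF3 file) has its CDS segments
concatenated in 5'->3' order, reverse-complemented on the minus strand, and
is then screened by four rules — length a multiple of 3, no ambiguous
bases, ATG start, canonical stop. Each codon of an accepted CDS is assigned
to a single exon; a codon interrupted by an intron after its first
nucleotide belongs to the downstream exon, one interrupted after its second
nucleotide to the upstream exon (equivalently: the exon containing the
codon's second nucleotide).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from gffutils.feature import feature_from_line

log = logging.getLogger(__name__)

#: Bases accepted in input genomes. Anything outside rejects the record later.
IUPAC_LETTERS = frozenset("ACGTNRYSWKMBDHV")

STOPS = ("TAA", "TAG", "TGA")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message names the offending record."""


@dataclass
class TranscriptModel:
    """One mRNA's CDS layout as annotated.

    ``cds_segments`` are 1-based inclusive genomic intervals ordered 5'->3'
    in transcript orientation (ascending start on '+', descending on '-').
    ``file_rank`` is the order of first appearance of the mRNA feature in
    the GFF3 file and drives "first transcript" selection.
    """

    gene_id: str
    transcript_id: str
    seq_id: str
    strand: str
    cds_segments: list[tuple[int, int]]
    file_rank: int

    def __post_init__(self) -> None:
        self.sort_segments()

    def sort_segments(self) -> None:
        self.cds_segments.sort(key=lambda s: s[0], reverse=(self.strand == "-"))


@dataclass
class CdsRecord:
    """An assembled (and possibly filtered) coding sequence.

    ``segment_lengths`` follow transcript order, so their running sum maps
    CDS coordinates back onto exons. ``codon_exon_index`` holds one 1-based
    exon index per codon once :func:`assign_codons_to_exons` has run.
    ``status`` is ``None`` until :func:`filter_cds`; then ``"accepted"`` or
    ``"rejected"`` with ``reason`` set.
    """

    gene_id: str
    transcript_id: str
    chromosome: str
    cds_sequence: str
    segment_lengths: list[int]
    species_label: str = ""
    subgenome: str = "unassigned"
    status: str | None = None
    reason: str | None = None
    detail: str | None = None
    codon_exon_index: list[int] = field(default_factory=list)

    @property
    def n_exons(self) -> int:
        return len(self.segment_lengths)

    @property
    def codons(self) -> list[str]:
        s = self.cds_sequence
        return [s[i : i + 3] for i in range(0, len(s) - len(s) % 3, 3)]

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


def read_genome(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{identifier: uppercase sequence}``.

    Raises :class:`FastaParseError` on duplicate identifiers or characters
    outside the IUPAC nucleotide alphabet.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FastaParseError(f"duplicate sequence identifier {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC_LETTERS
        if bad:
            raise FastaParseError(
                f"record {rec.id!r} contains non-IUPAC characters {sorted(bad)}"
            )
        sequences[rec.id] = seq
    return sequences


def read_annotation(path: str | Path) -> dict[str, list[TranscriptModel]]:
    """Parse a GFF3 file into transcript models grouped by gene.

    One :class:`TranscriptModel` per mRNA/transcript feature, with CDS lines
    attached through their ``Parent`` attribute. CDS lines whose Parent
    resolves to a gene that has no mRNA features become a single gene-level
    transcript (logged); CDS lines with no resolvable Parent are skipped
    with a warning. Coordinates stay 1-based inclusive as in GFF3.
    """
    transcripts: dict[str, TranscriptModel] = {}
    gene_ids: set[str] = set()
    orphan_cds: list = []
    rank = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = feature_from_line(line)
            ftype = feat.featuretype.lower()
            if ftype == "gene":
                fid = feat.attributes.get("ID", [None])[0]
                if fid:
                    gene_ids.add(fid)
            elif ftype in ("mrna", "transcript"):
                fid = feat.attributes.get("ID", [None])[0]
                parent = feat.attributes.get("Parent", [fid])[0]
                if fid is None:
                    log.warning("mRNA feature without ID skipped: %s", line)
                    continue
                transcripts[fid] = TranscriptModel(
                    gene_id=parent or fid,
                    transcript_id=fid,
                    seq_id=feat.seqid,
                    strand=feat.strand,
                    cds_segments=[],
                    file_rank=rank,
                )
                rank += 1
            elif ftype == "cds":
                orphan_cds.append(feat)

    gene_level: dict[str, TranscriptModel] = {}
    for feat in orphan_cds:
        parents = feat.attributes.get("Parent", [])
        attached = False
        for parent in parents:
            if parent in transcripts:
                transcripts[parent].cds_segments.append((feat.start, feat.end))
                attached = True
            elif parent in gene_ids:
                # Gene-level CDS with no mRNA: synthesize one transcript.
                if parent not in gene_level:
                    log.info("gene %s has CDS but no mRNA; using gene-level CDS", parent)
                    gene_level[parent] = TranscriptModel(
                        gene_id=parent,
                        transcript_id=parent,
                        seq_id=feat.seqid,
                        strand=feat.strand,
                        cds_segments=[],
                        file_rank=rank,
                    )
                    rank += 1
                gene_level[parent].cds_segments.append((feat.start, feat.end))
                attached = True
        if not attached:
            log.warning(
                "CDS %s-%s on %s has no resolvable Parent %r; skipped",
                feat.start, feat.end, feat.seqid, list(parents),
            )
    transcripts.update(gene_level)

    grouped: dict[str, list[TranscriptModel]] = {}
    for t in transcripts.values():
        if not t.cds_segments:
            continue
        t.sort_segments()
        grouped.setdefault(t.gene_id, []).append(t)
    return grouped


def select_primary_transcript(transcripts: list[TranscriptModel]) -> TranscriptModel:
    """The gene's first transcript: smallest file rank, then lexicographic id."""
    if not transcripts:
        raise ValueError("gene has no transcripts")
    return min(transcripts, key=lambda t: (t.file_rank, t.transcript_id))


def assemble_cds(
    t: TranscriptModel,
    genome: Mapping[str, str],
    species_label: str = "",
) -> CdsRecord:
    """Concatenate a transcript's CDS segments into an mRNA-sense string.

    Minus-strand segments are reverse-complemented; ``segment_lengths``
    follow transcript (5'->3') order. Out-of-bounds segments yield a record
    already rejected with reason ``"coords"``.
    """
    chrom = genome.get(t.seq_id)
    rec = CdsRecord(
        gene_id=t.gene_id,
        transcript_id=t.transcript_id,
        chromosome=t.seq_id,
        cds_sequence="",
        segment_lengths=[],
        species_label=species_label,
    )
    if chrom is None:
        rec.status, rec.reason = "rejected", "coords"
        rec.detail = f"chromosome {t.seq_id!r} absent from genome"
        return rec
    parts: list[str] = []
    for start, end in t.cds_segments:
        if start < 1 or end > len(chrom) or start > end:
            rec.status, rec.reason = "rejected", "coords"
            rec.detail = f"segment [{start},{end}] outside {t.seq_id} (len {len(chrom)})"
            return rec
        seg = chrom[start - 1 : end]
        if t.strand == "-":
            seg = str(Seq(seg).reverse_complement())
        parts.append(seg)
    rec.cds_sequence = "".join(parts)
    rec.segment_lengths = [len(p) for p in parts]
    return rec


def filter_cds(rec: CdsRecord) -> CdsRecord:
    """Apply the four acceptance rules, setting ``status``/``reason``.

    Checked in order: length multiple of 3; no ambiguous base (any
    non-ACGT letter, reason ``ambiguous_base`` with the letter in
    ``detail``); ATG start; TAA/TAG/TGA final codon. Idempotent: an already
    rejected record passes through unchanged.
    """
    if rec.status == "rejected":
        return rec
    s = rec.cds_sequence
    if len(s) % 3 != 0:
        rec.status, rec.reason = "rejected", "length"
        rec.detail = f"length {len(s)} not a multiple of 3"
        return rec
    bad = set(s) - set("ACGT")
    if bad:
        rec.status, rec.reason = "rejected", "ambiguous_base"
        rec.detail = ",".join(sorted(bad))
        return rec
    if len(s) < 6:
        rec.status, rec.reason = "rejected", "length"
        rec.detail = "too short to contain start and stop codons"
        return rec
    if s[:3] != "ATG":
        rec.status, rec.reason = "rejected", "start_codon"
        rec.detail = s[:3]
        return rec
    if s[-3:] not in STOPS:
        rec.status, rec.reason = "rejected", "stop_codon"
        rec.detail = s[-3:]
        return rec
    rec.status, rec.reason, rec.detail = "accepted", None, None
    return rec


def assign_codons_to_exons(rec: CdsRecord) -> list[int]:
    """Map each codon to one exon index (1-based) under the split-codon rule.

    A codon belongs to the exon containing its second nucleotide: a 1|2
    intron split puts it in the downstream exon, a 2|3 split in the
    upstream exon. Sets and returns ``rec.codon_exon_index``.
    """
    if not rec.accepted:
        raise ValueError(f"record {rec.gene_id} is not accepted")
    total = sum(rec.segment_lengths)
    if total != len(rec.cds_sequence):
        raise RuntimeError(
            f"segment lengths sum to {total} but CDS length is {len(rec.cds_sequence)}"
        )
    # Exon index of each nucleotide position, then take the middle base.
    boundaries: list[int] = []  # cumulative end position (1-based) per exon
    acc = 0
    for length in rec.segment_lengths:
        acc += length
        boundaries.append(acc)

    index: list[int] = []
    exon = 0
    for codon_i in range(len(rec.cds_sequence) // 3):
        mid = 3 * codon_i + 2  # 1-based position of the second nucleotide
        while mid > boundaries[exon]:
            exon += 1
        index.append(exon + 1)
    rec.codon_exon_index = index
    return index


_SUBGENOME_RE = re.compile(r"^(?:chr)?[1-7]([ABD])(?:$|[^A-Za-z0-9])", re.IGNORECASE)


def assign_subgenome(
    chromosome_name: str,
    rule: Mapping[str, str] | None = None,
) -> str:
    """Map a chromosome name to wheat subgenome A, B or D.

    Default rule: the trailing letter of a leading ``chr?[1-7][ABD]`` token
    ("3B" -> "B", "chr1A" -> "A"); anything else -> "unassigned". A custom
    ``rule`` maps regex patterns to labels and is tried first.
    """
    if rule:
        for pattern, label in rule.items():
            if re.search(pattern, chromosome_name):
                return label
    m = _SUBGENOME_RE.match(chromosome_name)
    if m:
        return m.group(1).upper()
    return "unassigned"


def extract_cds_records(
    fasta_path: str | Path,
    gff3_path: str | Path,
    species_label: str = "",
    subgenome_rule: Mapping[str, str] | None = None,
) -> list[CdsRecord]:
    """Full extraction for one species: read, select, assemble, filter, index.

    Returns one record per gene (accepted or rejected). Accepted records
    carry ``codon_exon_index`` and a subgenome label.
    """
    genome = read_genome(fasta_path)
    genes = read_annotation(gff3_path)
    records: list[CdsRecord] = []
    for gene_id in sorted(genes):
        t = select_primary_transcript(genes[gene_id])
        rec = assemble_cds(t, genome, species_label=species_label)
        rec.subgenome = assign_subgenome(t.seq_id, subgenome_rule)
        filter_cds(rec)
        if rec.accepted:
            assign_codons_to_exons(rec)
        records.append(rec)
    return records


def accepted_records(records: Iterable[CdsRecord]) -> list[CdsRecord]:
    return [r for r in records if r.accepted]


def rejects_table(records: Iterable[CdsRecord]):
    """Rejects log as a DataFrame (gene_id, reason, detail)."""
    import pandas as pd

    rows = [
        {"gene_id": r.gene_id, "reason": r.reason, "detail": r.detail}
        for r in records
        if r.status == "rejected"
    ]
    return pd.DataFrame(rows, columns=["gene_id", "reason", "detail"])
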