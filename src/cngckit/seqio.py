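"""Sequence and annotation I/O plus the shared domain types.

All coordinates are 1-based inclusive (GFF3 native). Exon lists are kept in
transcription order: ascending genomic order on the + strand, descending on
the - strand. Any half-open arithmetic is local to a function and noted there.

U<->T conversion between DNA and RNA space is always explicit (``to_rna`` /
``to_dna``), never silent.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

# "-" is permitted everywhere so aligned sequences reuse the same type
DNA_ALPHABET = set("ACGTN-")
RNA_ALPHABET = set("ACGUN-")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*-")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class SequenceIOError(ValueError):
    """Structured error for malformed sequence/annotation inputs."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence over a declared alphabet (DNA, RNA or protein)."""

    id: str
    residues: str
    alphabet: str = "protein"  # one of {"DNA", "RNA", "protein"}
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceIOError(f"empty sequence for record {self.id!r}")
        if self.alphabet not in ("DNA", "RNA", "protein"):
            raise SequenceIOError(f"unknown alphabet {self.alphabet!r}")
        allowed = {"DNA": DNA_ALPHABET, "RNA": RNA_ALPHABET,
                   "protein": PROTEIN_ALPHABET}[self.alphabet]
        bad = set(self.residues.upper()) - allowed
        if bad:
            raise SequenceIOError(
                f"record {self.id!r}: residues {sorted(bad)} not in "
                f"{self.alphabet} alphabet")

    def __len__(self) -> int:
        return len(self.residues)

    def to_rna(self) -> "SequenceRecord":
        """Explicit DNA->RNA conversion (T -> U)."""
        if self.alphabet == "RNA":
            return self
        if self.alphabet != "DNA":
            raise SequenceIOError("to_rna requires a nucleotide record")
        return SequenceRecord(self.id, self.residues.upper().replace("T", "U"),
                              "RNA", self.description)

    def to_dna(self) -> "SequenceRecord":
        """Explicit RNA->DNA conversion (U -> T)."""
        if self.alphabet == "DNA":
            return self
        if self.alphabet != "RNA":
            raise SequenceIOError("to_dna requires a nucleotide record")
        return SequenceRecord(self.id, self.residues.upper().replace("U", "T"),
                              "DNA", self.description)


@dataclass
class GeneModel:
    """A gene's genomic placement and CDS segments.

    ``exons`` holds CDS segments as (start, end) 1-based inclusive pairs in
    transcription order. ``complete_cds`` is False (a flag, not an error) when
    the summed exon length is not divisible by 3.
    """

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    family_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise SequenceIOError(f"{self.gene_id}: strand must be + or -")
        if self.start > self.end:
            raise SequenceIOError(f"{self.gene_id}: start > end")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise SequenceIOError(f"{self.gene_id}: overlapping exons")
        for s, e in self.exons:
            if s < self.start or e > self.end or s > e:
                raise SequenceIOError(
                    f"{self.gene_id}: exon ({s},{e}) outside gene bounds")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def complete_cds(self) -> bool:
        return self.cds_length % 3 == 0


@dataclass(frozen=True)
class DomainAnnotation:
    """Domain labels attached to one protein (stand-in for SMART/CDD scans)."""

    protein_id: str
    domain_labels: frozenset[str]
    source: str = ""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def infer_alphabet(residues: str) -> str:
    letters = set(residues.upper())
    if letters <= DNA_ALPHABET:
        return "DNA"
    if letters <= RNA_ALPHABET:
        return "RNA"
    return "protein"


def read_fasta(path: str | os.PathLike, alphabet: str | None = None
               ) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, order preserved.

    Wrapped sequence lines are concatenated. The alphabet is inferred per
    record unless supplied. Empty files and duplicate ids are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceIOError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        records.append(SequenceRecord(
            id=rec.id, residues=seq,
            alphabet=alphabet or infer_alphabet(seq),
            description=rec.description[len(rec.id):].strip()))
    if not records:
        raise SequenceIOError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike,
                width: int = 80) -> None:
    """Write records as multi-line FASTA (<= ``width`` columns)."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene/mRNA/CDS features into GeneModels (one per mRNA).

    CDS segments are sorted 5'->3' in transcription order; coordinates stay
    1-based inclusive. A CDS without a Parent, or mixed strands within one
    mRNA, is an error.
    """
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    models: list[GeneModel] = []
    for cds in db.features_of_type("CDS"):
        if "Parent" not in cds.attributes:
            raise SequenceIOError(
                f"CDS at {cds.seqid}:{cds.start}-{cds.end} has no Parent")
    for mrna in db.features_of_type("mRNA"):
        cds_feats = list(db.children(mrna, featuretype="CDS"))
        if not cds_feats:
            continue
        strands = {c.strand for c in cds_feats} | {mrna.strand}
        if len(strands) != 1:
            raise SequenceIOError(f"mixed strands within mRNA {mrna.id}")
        strand = strands.pop()
        exons = sorted((c.start, c.end) for c in cds_feats)
        if strand == "-":
            exons = exons[::-1]
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.id
        fam = mrna.attributes.get("family_id", [None])[0]
        models.append(GeneModel(
            gene_id=gene_id, chromosome=mrna.seqid, strand=strand,
            start=mrna.start, end=mrna.end, exons=exons, family_id=fam))
    return models


def write_gff3(models: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Serialize GeneModels as a minimal gene/mRNA/CDS GFF3 file."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fam = f";family_id={m.family_id}" if m.family_id else ""
            fh.write(f"{m.chromosome}\tcngckit\tgene\t{m.start}\t{m.end}\t.\t"
                     f"{m.strand}\t.\tID={m.gene_id}\n")
            mrna_id = f"{m.gene_id}.t1"
            fh.write(f"{m.chromosome}\tcngckit\tmRNA\t{m.start}\t{m.end}\t.\t"
                     f"{m.strand}\t.\tID={mrna_id};Parent={m.gene_id}{fam}\n")
            for i, (s, e) in enumerate(sorted(m.exons), 1):
                fh.write(f"{m.chromosome}\tcngckit\tCDS\t{s}\t{e}\t.\t"
                         f"{m.strand}\t0\tID={mrna_id}.cds{i};Parent={mrna_id}\n")


# ---------------------------------------------------------------------------
# TSV reports
# ---------------------------------------------------------------------------

def write_tsv_report(rows: pd.DataFrame, path: str | os.PathLike,
                     float_precision: int = 4) -> None:
    """Write a DataFrame as a TSV report with fixed float precision."""
    rows.to_csv(path, sep="\t", index=False,
                float_format=f"%.{float_precision}f")


def read_tsv_report(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
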