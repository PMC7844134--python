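"""Genome input/output and the coordinate-safe internal genome model.

Annotated genomes enter the pipeline as a GFF3 file (1-based, inclusive
coordinates on disk), a genomic FASTA and a protein FASTA.  Internally all
features use 0-based half-open coordinates so that window arithmetic
(``end - start`` is the length, adjacent intervals share an endpoint) never
needs a ``+1``.  Gene presence/absence matrices are read from TSV with the
typography used in printed tables: ``+`` for present, ``−`` (Unicode minus)
or ``-`` for absent, and an empty cell for unknown.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

PRESENT = "present"
ABSENT = "absent"
UNKNOWN = "unknown"

_TOKEN_TO_STATE = {"+": PRESENT, "-": ABSENT, "−": ABSENT, "": UNKNOWN}
_STATE_TO_TOKEN = {PRESENT: "+", ABSENT: "−", UNKNOWN: ""}


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class Contig:
    """A replicon or assembly fragment.

    ``sequence`` is optional: presence/absence work needs only coordinates,
    nucleotide-level comparison needs the sequence itself.
    """

    id: str
    length: int
    circular: bool = False
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError(f"contig {self.id}: negative length")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(f"contig {self.id}: sequence/length mismatch")


@dataclass
class GeneFeature:
    """A coding gene on a contig, 0-based half-open, with its protein."""

    contig_id: str
    start: int
    end: int
    strand: str
    locus_tag: str
    declared_symbol: Optional[str] = None
    protein: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_tag}: strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.locus_tag}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class AnnotatedGenome:
    """Contigs plus strand-aware gene features; the unit every stage consumes."""

    genome_id: str
    contigs: list[Contig] = field(default_factory=list)
    features: list[GeneFeature] = field(default_factory=list)
    completeness: Optional[float] = None
    contamination: Optional[float] = None

    def __post_init__(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.genome_id}: duplicate contig ids")
        known = set(ids)
        for f in self.features:
            if f.contig_id not in known:
                raise FormatError(
                    f"{self.genome_id}: feature {f.locus_tag} references "
                    f"unknown contig {f.contig_id}"
                )
        for name, value in (("completeness", self.completeness),
                            ("contamination", self.contamination)):
            if value is not None and not (0 <= value <= 100):
                raise ValueError(f"{self.genome_id}: {name} outside [0, 100]")
        self.sort_features()

    def sort_features(self) -> None:
        self.features.sort(key=lambda f: (f.contig_id, f.start, f.end, f.locus_tag))

    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(contig_id)

    def features_on(self, contig_id: str) -> list[GeneFeature]:
        return [f for f in self.features if f.contig_id == contig_id]

    def coding_features(self) -> list[GeneFeature]:
        """Features that carry a protein and can enter homology search."""
        return [f for f in self.features if f.protein]


class PresenceMatrix:
    """Genomes x markers with three-state cells (present/absent/unknown)."""

    STATES = frozenset({PRESENT, ABSENT, UNKNOWN})

    def __init__(self, df: pd.DataFrame):
        bad = set(df.to_numpy().ravel()) - self.STATES
        if bad:
            raise ValueError(f"invalid presence states: {sorted(bad)}")
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].tolist()
            raise FormatError(f"duplicate genome id(s): {dupes}")
        self.df = df

    @property
    def genomes(self) -> list[str]:
        return list(self.df.index)

    @property
    def markers(self) -> list[str]:
        return list(self.df.columns)

    def row(self, genome_id: str) -> pd.Series:
        return self.df.loc[genome_id]

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PresenceMatrix) and self.df.equals(other.df)

    def to_tsv(self, path: Path | str) -> None:
        out = self.df.replace(_STATE_TO_TOKEN)
        out.to_csv(path, sep="\t", index_label="genome_id")


def read_presence_matrix(tsv_path: Path | str) -> PresenceMatrix:
    """Read a marker presence/absence TSV (``genome_id<TAB>marker1<TAB>...``).

    Tokens: ``+`` present; ``-`` or ``−`` absent; empty cell unknown.
    """
    df = pd.read_csv(tsv_path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].tolist()
        raise FormatError(f"{tsv_path}: duplicate genome id(s): {dupes}")

    def convert(token: str) -> str:
        token = token.strip()
        if token not in _TOKEN_TO_STATE:
            raise FormatError(f"{tsv_path}: unknown presence token {token!r}")
        return _TOKEN_TO_STATE[token]

    return PresenceMatrix(df.map(convert))


# --- GFF3 + FASTA round trip -------------------------------------------------

def read_annotated_genome(
    gff_path: Path | str,
    genome_fasta: Path | str,
    protein_fasta: Path | str,
    genome_id: Optional[str] = None,
    completeness: Optional[float] = None,
    contamination: Optional[float] = None,
) -> AnnotatedGenome:
    """Read GFF3 + genomic FASTA + protein FASTA into an :class:`AnnotatedGenome`.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention.  Proteins are joined to CDS features by the
    shared identifier (``ID``/``locus_tag`` attribute vs FASTA record id).
    A CDS without a protein record is kept, with a warning, but is invisible
    to homology search.
    """
    gff_path = Path(gff_path)
    contig_seqs = {rec.id: str(rec.seq).upper()
                   for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    proteins = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(protein_fasta), "fasta")}

    circular: dict[str, bool] = {}
    features: list[GeneFeature] = []
    with open(gff_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{gff_path}: malformed GFF3 line: {line[:80]}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            attributes = _parse_attributes(attrs)
            if ftype == "region":
                circular[seqid] = attributes.get("Is_circular", "").lower() == "true"
                continue
            if ftype != "CDS":
                continue
            if seqid not in contig_seqs:
                raise FormatError(
                    f"{gff_path}: feature references unknown contig {seqid!r}"
                )
            locus = attributes.get("ID") or attributes.get("locus_tag")
            if not locus:
                raise FormatError(f"{gff_path}: CDS without ID/locus_tag: {line[:80]}")
            protein = proteins.get(locus)
            if protein is None:
                warnings.warn(f"no protein record for {locus}; feature kept "
                              "without protein", stacklevel=2)
            features.append(GeneFeature(
                contig_id=seqid,
                start=int(start) - 1,   # 1-based inclusive -> 0-based half-open
                end=int(end),
                strand=strand,
                locus_tag=locus,
                declared_symbol=attributes.get("gene"),
                protein=protein,
            ))

    contigs = [Contig(id=cid, length=len(seq), circular=circular.get(cid, False),
                      sequence=seq)
               for cid, seq in contig_seqs.items()]
    return AnnotatedGenome(
        genome_id=genome_id or gff_path.stem,
        contigs=contigs,
        features=features,
        completeness=completeness,
        contamination=contamination,
    )


def write_annotated_genome(genome: AnnotatedGenome, gff_path: Path | str,
                           genome_fasta: Path | str,
                           protein_fasta: Path | str) -> None:
    """Emit GFF3 (1-based inclusive) + genomic FASTA + protein FASTA."""
    with open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for c in genome.contigs:
            gff.write(f"##sequence-region {c.id} 1 {c.length}\n")
        for c in genome.contigs:
            attrs = f"ID=region-{c.id}"
            if c.circular:
                attrs += ";Is_circular=true"
            gff.write(f"{c.id}\tgemmapgc\tregion\t1\t{c.length}\t.\t+\t.\t{attrs}\n")
        for f in genome.features:
            attrs = f"ID={f.locus_tag}"
            if f.declared_symbol:
                attrs += f";gene={f.declared_symbol}"
            gff.write(
                f"{f.contig_id}\tgemmapgc\tCDS\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t0\t{attrs}\n"
            )
    SeqIO.write(
        [SeqRecord(Seq(c.sequence or "N" * c.length), id=c.id, description="")
         for c in genome.contigs],
        str(genome_fasta), "fasta")
    SeqIO.write(
        [SeqRecord(Seq(f.protein), id=f.locus_tag, description="")
         for f in genome.features if f.protein],
        str(protein_fasta), "fasta")


def _parse_attributes(attrs: str) -> dict[str, str]:
    out = {}
    for part in attrs.split(";"):
        part = part.strip()
        if part and "=" in part:
            key, value = part.split("=", 1)
            out[key] = value
    return out
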