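"""Domain types and readers/writers for the formats every pipeline stage touches.

Coordinate conventions
----------------------
All intervals are 0-based half-open internally (BED convention), so
``length == end - start`` and a single-base variant occupies ``[pos, pos + 1)``.
Variant tables are read and written 1-based (VCF convention) and converted at
the boundary.  DNA is uppercased on input; T and U are unified to U at the
FASTA boundary, since downstream folding works on RNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

STRANDS = ("+", "-", ".")
DNA_BASES = frozenset("ACGT")
RNA_BASES = frozenset("ACGU")
IUPAC = frozenset("ACGTUNRYSWKMBDHV")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A", "N": "N"}
RNA_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A", "N": "N"}


class ParseError(ValueError):
    """Malformed input file content."""


class ValidationError(ValueError):
    """Record content violates a domain invariant."""


class SchemaError(ValueError):
    """Table is missing a required column or has an untypable value."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def stranded(self) -> bool:
        return self.strand in ("+", "-")

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of overlapping bases with ``other`` (0 on different chroms)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_pos(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class GeneModel:
    """A gene with an exon chain; exons sorted, non-overlapping, same strand."""

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: gene must have >= 1 exon")
        prev_end = None
        for exon in self.exons:
            if not self.interval.contains(exon):
                raise ValidationError(f"{self.gene_id}: exon outside gene interval")
            if exon.strand != self.interval.strand:
                raise ValidationError(f"{self.gene_id}: exon strand differs from gene")
            if prev_end is not None and exon.start < prev_end:
                raise ValidationError(f"{self.gene_id}: exons unsorted or overlapping")
            prev_end = exon.end
        if self.biotype not in ("protein_coding", "lncRNA", "pseudogene", "other"):
            raise ValidationError(f"{self.gene_id}: unknown biotype {self.biotype!r}")

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass(frozen=True)
class LncRNAGene(GeneModel):
    """A lncRNA gene, optionally carrying its spliced transcript sequence (RNA)."""

    biotype: str = "lncRNA"
    transcript_seq: Optional[str] = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.biotype != "lncRNA":
            raise ValidationError(f"{self.gene_id}: LncRNAGene biotype must be lncRNA")
        if self.transcript_seq is not None:
            if set(self.transcript_seq) - RNA_BASES:
                raise ValidationError(f"{self.gene_id}: transcript has non-ACGU bases")
            if len(self.transcript_seq) != self.exonic_length:
                raise ValidationError(
                    f"{self.gene_id}: transcript length {len(self.transcript_seq)} "
                    f"!= exonic length {self.exonic_length}"
                )


@dataclass(frozen=True)
class Variant:
    """A biallelic SNV with per-disease association p-values.

    ``pos`` is stored 0-based; input tables carry it 1-based.
    """

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    assoc_p: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValidationError(f"{self.id}: negative position")
        if self.ref not in DNA_BASES or self.alt not in DNA_BASES:
            raise ValidationError(f"{self.id}: ref/alt must be single A/C/G/T")
        if self.ref == self.alt:
            raise ValidationError(f"{self.id}: ref == alt ({self.ref})")
        for label, p in self.assoc_p.items():
            if not (0.0 < p <= 1.0):
                raise ValidationError(f"{self.id}: p[{label}] = {p} outside (0, 1]")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def _parse_bed_line(line: str, lineno: int, biotype: str) -> GeneModel:
    fields = line.split()
    if len(fields) not in (6, 12):
        raise ParseError(f"line {lineno}: expected BED6 or BED12, got {len(fields)} fields")
    chrom, start_s, end_s, name = fields[0], fields[1], fields[2], fields[3]
    strand = fields[5]
    if strand == ".":
        strand = "."
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-integer coordinates") from exc
    if end <= start:
        raise ValidationError(f"line {lineno}: end <= start")
    try:
        interval = GenomicInterval(chrom, start, end, strand)
    except ValidationError as exc:
        raise ValidationError(f"line {lineno}: {exc}") from exc
    if len(fields) == 6:
        exons = (interval,)
    else:
        try:
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        except ValueError as exc:
            raise ParseError(f"line {lineno}: malformed block fields") from exc
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise ParseError(f"line {lineno}: blockCount != number of blocks")
        exons = tuple(
            GenomicInterval(chrom, start + off, start + off + size, strand)
            for off, size in zip(starts, sizes)
        )
    cls = LncRNAGene if biotype == "lncRNA" else GeneModel
    if cls is LncRNAGene:
        return LncRNAGene(gene_id=name, interval=interval, exons=exons)
    return GeneModel(gene_id=name, interval=interval, exons=exons, biotype=biotype)


def read_gene_bed(path: str | Path, biotype: str = "protein_coding") -> list[GeneModel]:
    """Read gene models from a BED6 or BED12 file.

    BED12 block fields populate exons; BED6 yields single-exon genes.  A strand
    column of ``.`` maps to unstranded.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            genes.append(_parse_bed_line(line, lineno, biotype))
    return genes


def write_gene_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12."""
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            sizes = ",".join(str(len(e)) for e in g.exons) + ","
            starts = ",".join(str(e.start - iv.start) for e in g.exons) + ","
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{iv.strand}\t"
                f"{iv.start}\t{iv.end}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

_VARIANT_FIXED_COLS = ["id", "chrom", "pos", "ref", "alt"]


def read_variant_table(path: str | Path) -> list[Variant]:
    """Read a variant TSV with one p-value column per disease label.

    Positions are converted from 1-based (as written) to 0-based (internal).
    Missing/empty p-values mean the variant carries no entry for that disease.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    missing = [c for c in _VARIANT_FIXED_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"variant table missing columns: {missing}")
    disease_cols = [c for c in df.columns if c not in _VARIANT_FIXED_COLS]
    variants = []
    for row in df.itertuples(index=False):
        assoc = {}
        for label in disease_cols:
            p = getattr(row, label)
            if pd.isna(p):
                continue
            assoc[label] = float(p)
        variants.append(
            Variant(
                id=str(row.id),
                chrom=str(row.chrom),
                pos=int(row.pos) - 1,
                ref=str(row.ref).upper(),
                alt=str(row.alt).upper(),
                assoc_p=assoc,
            )
        )
    return variants


def write_variant_table(variants: Sequence[Variant], path: str | Path) -> None:
    """Write variants as TSV (1-based positions, one column per disease)."""
    labels = sorted({label for v in variants for label in v.assoc_p})
    rows = []
    for v in variants:
        row = {
            "id": v.id,
            "chrom": v.chrom,
            "pos": v.pos + 1,
            "ref": v.ref,
            "alt": v.alt,
        }
        for label in labels:
            row[label] = v.assoc_p.get(label, "")
        rows.append(row)
    pd.DataFrame(rows, columns=_VARIANT_FIXED_COLS + labels).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{id: sequence}``; T is transcribed to U.

    Record ids are the first whitespace-delimited token of the header.
    Duplicate ids and non-IUPAC characters raise errors.
    """
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"duplicate FASTA id: {rec.id}")
        seq = str(rec.seq).upper().replace("T", "U")
        bad = set(seq) - IUPAC
        if bad:
            raise ParseError(f"{rec.id}: non-IUPAC characters {sorted(bad)}")
        out[rec.id] = seq
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Generic typed tables and the RepeatMasker .out dialect
# ---------------------------------------------------------------------------

def read_table(path: str | Path, schema: Mapping[str, type]) -> pd.DataFrame:
    """Read a header-bearing TSV and type-check it against ``schema``.

    ``schema`` maps required column names to python types (str/int/float).
    Unknown extra columns are preserved as strings.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    for col, typ in schema.items():
        if typ is str:
            continue
        try:
            df[col] = df[col].astype(float if typ is float else int)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: column {col!r} not coercible to {typ.__name__}") from exc
    return df


@dataclass(frozen=True)
class RepeatRecord:
    """One RepeatMasker annotation, reduced to interval + class + name."""

    interval: GenomicInterval
    repeat_class: str
    repeat_name: str


REPEAT_CLASSES = ("SINE", "LINE", "LTR", "DNA", "Simple", "Low_complexity", "Other")

_REPEAT_CLASS_MAP = {
    "SINE": "SINE",
    "LINE": "LINE",
    "LTR": "LTR",
    "DNA": "DNA",
    "Simple_repeat": "Simple",
    "Low_complexity": "Low_complexity",
}


def read_repeatmasker_out(path: str | Path) -> list[RepeatRecord]:
    """Read the RepeatMasker ``.out`` dialect (3 header lines, whitespace-split).

    The class/family column (e.g. ``SINE/Alu``) is collapsed to the class
    vocabulary ``SINE/LINE/LTR/DNA/Simple/Low_complexity/Other``.
    """
    records = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, raw in enumerate(lines[3:], start=4):
        fields = raw.split()
        if not fields:
            continue
        if len(fields) < 11:
            raise ParseError(f"line {lineno}: too few fields for RepeatMasker .out")
        chrom, begin, end = fields[4], fields[5], fields[6]
        strand = "+" if fields[8] == "+" else "-"
        name, family = fields[9], fields[10]
        try:
            # .out coordinates are 1-based inclusive
            iv = GenomicInterval(chrom, int(begin) - 1, int(end), strand)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: bad coordinates") from exc
        cls = _REPEAT_CLASS_MAP.get(family.split("/")[0], "Other")
        records.append(RepeatRecord(interval=iv, repeat_class=cls, repeat_name=name))
    return records


def write_repeatmasker_out(records: Iterable[RepeatRecord], path: str | Path) -> None:
    """Write records in a minimal RepeatMasker .out dialect (for fixtures)."""
    header = (
        "   SW   perc perc perc  query    position in query        matching"
        "  repeat       position in repeat\n"
        "score   div. del. ins.  sequence begin end      (left)    repeat"
        "       class/family  begin  end    (left)  ID\n"
        "\n"
    )
    inverse = {v: k for k, v in _REPEAT_CLASS_MAP.items()}
    with open(path, "w") as fh:
        fh.write(header)
        for i, rec in enumerate(records, start=1):
            iv = rec.interval
            fam = inverse.get(rec.repeat_class, "Unknown")
            strand = "+" if iv.strand != "-" else "C"
            fh.write(
                f"  225   10.0  0.0  0.0  {iv.chrom} {iv.start + 1} {iv.end} (0) "
                f"{strand} {rec.repeat_name} {fam}/{rec.repeat_name} 1 {len(iv)} (0) {i}\n"
            )


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def revcomp_dna(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def revcomp_rna(seq: str) -> str:
    return "".join(RNA_COMPLEMENT[b] for b in reversed(seq))
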