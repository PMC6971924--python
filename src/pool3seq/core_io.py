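"""Plate layouts, barcodes, and on-disk formats for pooled 3'-end RNA-seq.

The library model is a dual-indexed hybrid design: every library molecule
carries a Nextera-style i5 index (8 nt) identifying the *pool* a sample was
mixed into after reverse transcription, and a TruSeq-style i7 index (6 nt)
identifying the *sample* within that pool.  On a 96-well plate pooled by row,
the i5 index is the row index and the i7 index is the column index.

Formats handled here:

* CSV sample sheet (columns ``well,sample_id,condition,i5,i7``)
* single-end FASTQ with the dual index carried in the header comment as
  ``i7+i5`` (the post-demultiplexing Illumina convention)
* a small GTF dialect for transcript-level feature annotation
* TSV table of ERCC spike-in species (id, length, relative concentration)

Coordinates are 0-based half-open everywhere in memory; GTF emission converts
to 1-based closed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Barcode",
    "Well",
    "PlateLayout",
    "FeatureSegment",
    "FeatureAnnotation",
    "ErccTable",
    "ReadRecord",
    "FormatError",
    "LayoutError",
    "BarcodeCollisionError",
    "CapacityError",
    "ValidationError",
    "DEFAULT_I5_POOL",
    "DEFAULT_I7_POOL",
    "parse_sample_sheet",
    "write_sample_sheet",
    "make_row_pooling_layout",
    "read_fastq",
    "write_fastq",
    "read_gtf",
    "write_gtf",
    "read_ercc_table",
    "write_ercc_table",
]

I5_LENGTH = 8
I7_LENGTH = 6
_ALPHABET = frozenset("ACGT")

#: Bundled default index pools.  All pairwise Hamming distances are >= 3
#: within each pool, so single-substitution demultiplexing can never be
#: ambiguous.  These are synthetic stand-ins, not vendor sequences.
DEFAULT_I7_POOL: tuple[str, ...] = (
    "TTTCCT", "CATGCA", "ATTCAA", "AACCAT", "GTCCGT", "GGCGAA",
    "ATAGTA", "GAGGAT", "ACCAAA", "TTCCTC", "CTTATT", "CTAACC",
)
DEFAULT_I5_POOL: tuple[str, ...] = (
    "ACGATCAG", "CAGTTCGG", "CTTGTGAG", "GTCTTCGC",
    "CGGGTGGT", "CTCCCGCA", "TTTATACC", "TTGCTGGC",
)

FEATURE_CLASSES = ("CDS", "UTR3", "UTR5", "rRNA", "ERCC")

# GTF feature-column spelling <-> internal class names
_CLASS_TO_GTF = {
    "CDS": "CDS",
    "UTR3": "three_prime_utr",
    "UTR5": "five_prime_utr",
    "rRNA": "rRNA",
    "ERCC": "ERCC",
}
_GTF_TO_CLASS = {v: k for k, v in _CLASS_TO_GTF.items()}


class FormatError(ValueError):
    """A file or record violates the expected on-disk format."""


class LayoutError(ValueError):
    """A well or plate description is inconsistent."""


class BarcodeCollisionError(LayoutError):
    """Two wells share the same (i5, i7) barcode pair."""


class CapacityError(LayoutError):
    """An index pool is too small for the requested plate."""


class ValidationError(ValueError):
    """An annotation violates its structural invariants."""


@dataclass(frozen=True)
class Barcode:
    """Dual index: 8 nt pool (i5) + 6 nt sample (i7) barcode."""

    i5: str
    i7: str

    def __post_init__(self) -> None:
        for name, seq, length in (("i5", self.i5, I5_LENGTH), ("i7", self.i7, I7_LENGTH)):
            if len(seq) != length:
                raise FormatError(f"{name} barcode {seq!r} must be {length} nt")
            if not _ALPHABET.issuperset(seq):
                raise FormatError(f"{name} barcode {seq!r} contains non-ACGT characters")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.i5, self.i7)


@dataclass(frozen=True)
class Well:
    row: int  # 0-based, row A == 0
    col: int  # 0-based, column 1 == 0
    sample_id: str
    condition: str
    barcode: Barcode

    @property
    def name(self) -> str:
        return f"{chr(ord('A') + self.row)}{self.col + 1}"


def _parse_well_name(name: str) -> tuple[int, int]:
    name = name.strip().upper()
    if len(name) < 2 or not name[0].isalpha() or not name[1:].isdigit():
        raise LayoutError(f"malformed well name {name!r}")
    return ord(name[0]) - ord("A"), int(name[1:]) - 1


@dataclass
class PlateLayout:
    """Wells of a plate with their dual barcodes and pooling scheme.

    Under the ``row_pool`` scheme all wells in a row share an i5 (pool)
    index and carry distinct i7 (sample) indices.
    """

    rows: int
    cols: int
    wells: list[Well] = field(default_factory=list)
    scheme: str = "row_pool"

    def __post_init__(self) -> None:
        if self.scheme not in ("row_pool", "column_pool"):
            raise LayoutError(f"unknown pooling scheme {self.scheme!r}")
        self.validate()

    def validate(self) -> None:
        seen_pairs: dict[tuple[str, str], str] = {}
        seen_ids: set[str] = set()
        for w in self.wells:
            if not (0 <= w.row < self.rows and 0 <= w.col < self.cols):
                raise LayoutError(
                    f"well {w.name} outside a {self.rows}x{self.cols} plate"
                )
            if w.barcode.pair in seen_pairs:
                raise BarcodeCollisionError(
                    f"wells {seen_pairs[w.barcode.pair]} and {w.sample_id} "
                    f"share barcode pair {w.barcode.pair}"
                )
            seen_pairs[w.barcode.pair] = w.sample_id
            if w.sample_id in seen_ids:
                raise LayoutError(f"duplicate sample_id {w.sample_id!r}")
            seen_ids.add(w.sample_id)

    @property
    def sample_ids(self) -> list[str]:
        return [w.sample_id for w in self.wells]

    def barcode_map(self) -> dict[tuple[str, str], str]:
        """(i5, i7) pair -> sample_id."""
        return {w.barcode.pair: w.sample_id for w in self.wells}

    def pool_of(self) -> dict[str, int]:
        """sample_id -> pool group (row under row_pool, column otherwise)."""
        if self.scheme == "row_pool":
            return {w.sample_id: w.row for w in self.wells}
        return {w.sample_id: w.col for w in self.wells}

    def row_of(self) -> dict[str, int]:
        return {w.sample_id: w.row for w in self.wells}

    def col_of(self) -> dict[str, int]:
        return {w.sample_id: w.col for w in self.wells}

    def condition_of(self) -> dict[str, str]:
        return {w.sample_id: w.condition for w in self.wells}


def make_row_pooling_layout(
    rows: int,
    cols: int,
    i5_pool: Sequence[str] = DEFAULT_I5_POOL,
    i7_pool: Sequence[str] = DEFAULT_I7_POOL,
    conditions: Sequence[str] | None = None,
) -> PlateLayout:
    """Assign barcodes for a plate pooled by row.

    Well (r, c) receives barcode (i5_pool[r], i7_pool[c]): one i5 pool index
    per row, one i7 sample index per column, giving rows x cols unique pairs.
    A full standard plate needs 8 i5 and 12 i7 indices; an 8-row by 10-column
    arrangement (80 samples) fits the same pools.

    Parameters
    ----------
    conditions
        Optional per-well condition labels in row-major order; defaults to
        ``"untreated"`` everywhere.
    """
    if rows < 1 or cols < 1:
        raise LayoutError("plate must have at least one row and one column")
    if len(set(i5_pool)) != len(i5_pool) or len(set(i7_pool)) != len(i7_pool):
        raise CapacityError("index pools must be internally unique")
    if len(i5_pool) < rows:
        raise CapacityError(f"need {rows} i5 indices, pool has {len(i5_pool)}")
    if len(i7_pool) < cols:
        raise CapacityError(f"need {cols} i7 indices, pool has {len(i7_pool)}")
    if conditions is not None and len(conditions) != rows * cols:
        raise LayoutError("conditions must have one entry per well")
    wells = []
    for r in range(rows):
        for c in range(cols):
            cond = conditions[r * cols + c] if conditions is not None else "untreated"
            wells.append(
                Well(
                    row=r,
                    col=c,
                    sample_id=f"{chr(ord('A') + r)}{c + 1}",
                    condition=cond,
                    barcode=Barcode(i5=i5_pool[r], i7=i7_pool[c]),
                )
            )
    return PlateLayout(rows=rows, cols=cols, wells=wells, scheme="row_pool")


def parse_sample_sheet(path: str | Path, rows: int = 8, cols: int = 12) -> PlateLayout:
    """Read a CSV sample sheet (well,sample_id,condition,i5,i7) into a layout."""
    df = pd.read_csv(path, dtype=str)
    required = {"well", "sample_id", "condition", "i5", "i7"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
    wells = []
    for rec in df.itertuples(index=False):
        r, c = _parse_well_name(rec.well)
        wells.append(
            Well(
                row=r,
                col=c,
                sample_id=rec.sample_id,
                condition=rec.condition,
                barcode=Barcode(i5=rec.i5, i7=rec.i7),
            )
        )
    return PlateLayout(rows=rows, cols=cols, wells=wells)


def write_sample_sheet(layout: PlateLayout, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "well": [w.name for w in layout.wells],
            "sample_id": [w.sample_id for w in layout.wells],
            "condition": [w.condition for w in layout.wells],
            "i5": [w.barcode.i5 for w in layout.wells],
            "i7": [w.barcode.i7 for w in layout.wells],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# FASTQ


@dataclass
class ReadRecord:
    """A single-end read with its dual index.

    ``i7`` and ``i5`` are the observed index reads; in FASTQ they are carried
    in the header comment as ``1:N:0:<i7>+<i5>``.
    """

    read_id: str
    sequence: str
    quality: str
    i7: str
    i5: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise FormatError(
                f"read {self.read_id}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quality)}"
            )

    @property
    def header_comment(self) -> str:
        return f"1:N:0:{self.i7}+{self.i5}"


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> int:
    """Write 4-line FASTQ with the dual index in the header comment."""
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            if len(rec.sequence) != len(rec.quality):
                raise FormatError(f"read {rec.read_id}: length mismatch")
            fh.write(f"@{rec.read_id} {rec.header_comment}\n{rec.sequence}\n+\n{rec.quality}\n")
            n += 1
    return n


def _parse_index_comment(description: str, read_id: str, strict: bool) -> tuple[str, str]:
    parts = description.split()
    if len(parts) >= 2:
        fields = parts[-1].split(":")
        if fields and "+" in fields[-1]:
            i7, _, i5 = fields[-1].partition("+")
            return i7, i5
    if strict:
        raise FormatError(f"read {read_id}: missing i7+i5 index in header comment")
    return "", ""


def read_fastq(path: str | Path, strict: bool = True) -> Iterator[ReadRecord]:
    """Parse FASTQ, recovering the dual index from the header comment.

    With ``strict`` a record lacking the ``i7+i5`` comment raises
    :class:`FormatError`; otherwise empty index fields are returned.
    """
    for rec in SeqIO.parse(str(path), "fastq"):
        i7, i5 = _parse_index_comment(rec.description, rec.id, strict)
        quality = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        yield ReadRecord(
            read_id=rec.id,
            sequence=str(rec.seq),
            quality=quality,
            i7=i7,
            i5=i5,
        )


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Feature annotation (GTF dialect)


@dataclass(frozen=True)
class FeatureSegment:
    feature_class: str  # one of FEATURE_CLASSES
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise FormatError(f"unknown feature class {self.feature_class!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"segment [{self.start}, {self.end}) is empty or negative"
            )


@dataclass
class FeatureAnnotation:
    """Ordered, non-overlapping feature segments on one transcript."""

    gene_id: str
    length: int  # transcript length in nt (annotated portion)
    strand: str = "+"
    segments: list[FeatureSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.segments:
            raise ValidationError(f"{self.gene_id}: annotation has no segments")
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")
        ordered = sorted(self.segments, key=lambda s: s.start)
        prev_end = 0
        for seg in ordered:
            if seg.start < prev_end:
                raise ValidationError(
                    f"{self.gene_id}: segment [{seg.start},{seg.end}) overlaps previous"
                )
            if seg.end > self.length:
                raise ValidationError(
                    f"{self.gene_id}: segment [{seg.start},{seg.end}) exceeds "
                    f"transcript length {self.length}"
                )
            prev_end = seg.end
        self.segments = ordered

    def class_at(self, pos: int) -> str:
        """Feature class covering a transcript position, 'other' if none."""
        for seg in self.segments:
            if seg.start <= pos < seg.end:
                return seg.feature_class
        return "other"


def write_gtf(annotations: Iterable[FeatureAnnotation], path: str | Path) -> None:
    """Emit the transcript-level GTF dialect (1-based closed coordinates).

    Each transcript gets a ``gene`` line spanning its full length plus one
    line per feature segment.  The seqname column is the transcript id
    (features live on transcript coordinates, not a genome).
    """
    with open(path, "w") as fh:
        for ann in annotations:
            attrs = f'gene_id "{ann.gene_id}";'
            fh.write(
                f"{ann.gene_id}\tpool3seq\tgene\t1\t{ann.length}\t.\t{ann.strand}\t.\t{attrs}\n"
            )
            for seg in ann.segments:
                fh.write(
                    f"{ann.gene_id}\tpool3seq\t{_CLASS_TO_GTF[seg.feature_class]}\t"
                    f"{seg.start + 1}\t{seg.end}\t.\t{ann.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: str | Path) -> dict[str, FeatureAnnotation]:
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"line {line_no}: expected 9 GTF columns")
            seqname, _source, feature, start, end, _score, strand, _frame, attrs = cols
            if 'gene_id "' not in attrs:
                raise FormatError(f"line {line_no}: missing gene_id attribute")
            gene_id = attrs.split('gene_id "', 1)[1].split('"', 1)[0]
            start0, end0 = int(start) - 1, int(end)  # 1-based closed -> half-open
            entry = genes.setdefault(
                gene_id, {"length": 0, "strand": strand, "segments": []}
            )
            if feature == "gene":
                entry["length"] = max(entry["length"], end0)
                entry["strand"] = strand
            elif feature in _GTF_TO_CLASS:
                entry["segments"].append(
                    FeatureSegment(_GTF_TO_CLASS[feature], start0, end0)
                )
            else:
                raise FormatError(f"line {line_no}: unknown feature {feature!r}")
    out = {}
    for gene_id, entry in genes.items():
        length = entry["length"] or max(s.end for s in entry["segments"])
        out[gene_id] = FeatureAnnotation(
            gene_id=gene_id,
            length=length,
            strand=entry["strand"],
            segments=entry["segments"],
        )
    return out


# ---------------------------------------------------------------------------
# ERCC table


@dataclass
class ErccTable:
    """Spike-in species with lengths and known relative concentrations."""

    table: pd.DataFrame  # columns: ercc_id, length, concentration

    def __post_init__(self) -> None:
        required = {"ercc_id", "length", "concentration"}
        if not required.issubset(self.table.columns):
            raise FormatError(f"ERCC table needs columns {sorted(required)}")
        if (self.table["concentration"] <= 0).any():
            raise FormatError("ERCC concentrations must be strictly positive")
        if self.table["ercc_id"].duplicated().any():
            raise FormatError("duplicate ERCC ids")

    @property
    def ids(self) -> list[str]:
        return self.table["ercc_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def concentrations(self) -> pd.Series:
        return self.table.set_index("ercc_id")["concentration"]


def read_ercc_table(path: str | Path) -> ErccTable:
    return ErccTable(pd.read_csv(path, sep="\t"))


def write_ercc_table(table: ErccTable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index=False)
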