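"""Readers and writers for on-disk artifacts.

Canonical dialects: FASTA wrapped at 80 columns; tab-separated UTF-8 tables
with Unix newlines and no quoting; newick with branch lengths and integer
support labels (written by :mod:`panlineage.core_phylogeny`).

Internally all coordinates are 0-based half-open; anything written for human
consumption (spacer tables, amplicon coordinates) is 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "SegmentAssignmentError",
    "AgeSegment",
    "AgeSegmentation",
    "DEFAULT_SEGMENTATION",
    "StrainRecord",
    "parse_fasta",
    "write_fasta",
    "parse_metadata",
    "write_metadata",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """Malformed on-disk artifact (duplicate ids, ragged table, bad residue)."""


class SegmentAssignmentError(ValueError):
    """An age could not be assigned to any segment of a segmentation."""


@dataclass(frozen=True)
class AgeSegment:
    """One host-age bin: the half-open interval ``[min_age, max_age)`` in years."""

    label: str
    min_age: float
    max_age: float

    def contains(self, age: float) -> bool:
        return self.min_age <= age < self.max_age


@dataclass(frozen=True)
class AgeSegmentation:
    """Ordered, non-overlapping age bins jointly covering ``[0, max)``.

    The default 14-bin segmentation follows the cohort design this package
    emulates: three infant bins (preweaning, weaning, weaned toddler), one
    child bin, then decadal bins up to 104 years.  The infant bin boundaries
    are configurable because cohort tables typically report only group means.
    """

    segments: tuple[AgeSegment, ...]

    def __post_init__(self) -> None:
        segs = self.segments
        if not segs:
            raise ValueError("segmentation must contain at least one segment")
        for a, b in zip(segs, segs[1:]):
            if not (a.min_age < b.min_age and a.max_age == b.min_age):
                raise ValueError(
                    f"segments must be ordered and contiguous: {a.label!r} -> {b.label!r}"
                )

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.segments]

    def assign(self, age: float, strain_id: str = "?") -> str:
        """Return the label of the unique segment containing *age*."""
        if age < 0:
            raise SegmentAssignmentError(
                f"strain {strain_id}: negative age {age!r}"
            )
        for seg in self.segments:
            if seg.contains(age):
                return seg.label
        raise SegmentAssignmentError(
            f"strain {strain_id}: age {age!r} outside all segments "
            f"[{self.segments[0].min_age}, {self.segments[-1].max_age})"
        )

    def index_of(self, label: str) -> int:
        for i, seg in enumerate(self.segments):
            if seg.label == label:
                return i
        raise KeyError(label)


def _default_segments() -> tuple[AgeSegment, ...]:
    rows: list[tuple[str, float, float]] = [
        ("Preweaning", 0.0, 0.5),
        ("Weaning", 0.5, 1.5),
        ("weaned-3", 1.5, 4.0),
        ("4-9 years old", 4.0, 10.0),
    ]
    for lo in range(10, 100, 10):
        rows.append((f"{lo}-{lo + 9} years old", float(lo), float(lo + 10)))
    rows.append(("100-104 years old", 100.0, 105.0))
    return tuple(AgeSegment(*r) for r in rows)


#: The 14-bin default host-age segmentation (Preweaning ... 100-104 years old).
DEFAULT_SEGMENTATION = AgeSegmentation(_default_segments())


@dataclass
class StrainRecord:
    """One sequenced isolate: genome, proteome, and host metadata."""

    strain_id: str
    subject_id: str
    family_id: str = ""
    age_years: float = 0.0
    sex: str = "unknown"
    age_segment: str = ""
    proteins: list[tuple[str, str]] = field(default_factory=list)
    contigs: list[tuple[str, str]] = field(default_factory=list)
    #: optional per-gene nucleotide CDS (same gene ids as ``proteins``);
    #: required only by the core-phylogeny stage
    cds: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.proteins)

    @property
    def genome_length(self) -> int:
        return sum(len(s) for _, s in self.contigs)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_fasta(path: str | Path, alphabet: str = "nucleotide") -> list[tuple[str, str]]:
    """Parse a multi-record FASTA file into ``[(id, sequence), ...]``.

    Sequences are uppercased; characters outside the declared alphabet
    (protein: 20 amino acids + X; nucleotide: ACGT + N) raise
    :class:`FormatError`, as do duplicate record ids.  An empty file yields
    an empty list with a warning.
    """
    if alphabet == "protein":
        allowed = PROTEIN_ALPHABET
    elif alphabet == "nucleotide":
        allowed = NUCLEOTIDE_ALPHABET
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - allowed
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains characters {sorted(bad)} "
                f"outside the {alphabet} alphabet"
            )
        out.append((rec.id, seq))
    if not out:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, wrap: int = 80) -> Path:
    """Write ``(id, sequence)`` pairs as FASTA wrapped at *wrap* columns."""
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")
    return path


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

_META_COLUMNS = ["strain_id", "subject_id", "family_id", "age_years", "sex"]


def parse_metadata(
    path: str | Path,
    segmentation: AgeSegmentation = DEFAULT_SEGMENTATION,
) -> list[StrainRecord]:
    """Parse a metadata TSV into :class:`StrainRecord` stubs.

    Expected header: ``strain_id  subject_id  family_id  age_years  sex``.
    Each record is assigned the unique age segment containing its age;
    an unassignable age raises :class:`SegmentAssignmentError` naming the
    strain.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        age = float(row.age_years)
        sex = row.sex if row.sex in ("M", "F") else "unknown"
        records.append(
            StrainRecord(
                strain_id=row.strain_id,
                subject_id=row.subject_id,
                family_id=row.family_id,
                age_years=age,
                sex=sex,
                age_segment=segmentation.assign(age, row.strain_id),
            )
        )
    return records


def write_metadata(records: Sequence[StrainRecord], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "strain_id": [r.strain_id for r in records],
            "subject_id": [r.subject_id for r in records],
            "family_id": [r.family_id for r in records],
            "age_years": [repr(float(r.age_years)) for r in records],
            "sex": [r.sex for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

def write_matrix_tsv(
    matrix: np.ndarray,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    path: str | Path,
) -> Path:
    """Write a rectangular matrix as a TSV with row and column ids.

    Real values are written at 10 significant digits, which round-trips
    binary and typical rate/score matrices losslessly for this package's
    purposes.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2-dimensional")
    if matrix.shape != (len(row_ids), len(col_ids)):
        raise ValueError(
            f"matrix shape {matrix.shape} does not match ids "
            f"({len(row_ids)} rows, {len(col_ids)} cols)"
        )
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        fh.write("id\t" + "\t".join(col_ids) + "\n")
        for rid, row in zip(row_ids, matrix):
            fh.write(rid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    return path


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a matrix TSV written by :func:`write_matrix_tsv`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        col_ids = header.split("\t")[1:]
        row_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(col_ids) + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected {len(col_ids) + 1} fields, got {len(parts)}"
                )
            row_ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    matrix = np.array(rows, dtype=float) if rows else np.empty((0, len(col_ids)))
    return matrix, row_ids, col_ids
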