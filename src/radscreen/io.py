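"""Readers and writers for the tabular formats the pipeline consumes.

Dialects
--------
SEG            tab-delimited segmented copy number; 1-based inclusive
               coordinates on disk, converted to 0-based half-open in memory.
               Chromosome labels are kept verbatim (no "chr" normalisation)
               and must match verbatim across inputs.
GMT            one gene set per line: name, description, then member symbols.
matrix         tab-delimited numeric grid, first column row ids, header row
               of sample ids. Empty cells and the tokens NA / NaN are missing.
mutations      MAF-like TSV with gene symbol, sample id and a protein-change
               string (e.g. "p.E79K") from which the residue index is parsed.

All writers emit UTF-8 with LF line endings and full-precision floats
(repr), so a write/read cycle is lossless.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

MISSING_TOKENS = {"", "NA", "NaN"}

VALUE_KINDS = {"expression", "copy_number", "luminescence", "generic"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentRecord:
    """One segment of a copy-number profile.

    Coordinates are 0-based half-open; ``log2_ratio`` is the segment mean
    of log2(CN/2).
    """

    sample_id: str
    chromosome: str
    start: int
    end: int
    log2_ratio: float
    n_probes: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"segment end must exceed start (got {self.start}..{self.end})"
            )
        if not np.isfinite(self.log2_ratio):
            raise ValueError("segment log2_ratio must be finite")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MutationRecord:
    """One mutation call: gene, sample and (optionally) the residue hit."""

    gene: str
    sample_id: str
    protein_position: int | None = None
    variant_label: str = ""

    def __post_init__(self) -> None:
        if self.protein_position is not None and self.protein_position < 1:
            raise ValueError("protein_position must be >= 1")


@dataclass
class NamedMatrix:
    """A labelled numeric grid (genes x samples, wells x replicates, ...)."""

    row_ids: list[str]
    column_ids: list[str]
    values: np.ndarray
    value_kind: str = "generic"

    def __post_init__(self) -> None:
        self.row_ids = list(self.row_ids)
        self.column_ids = list(self.column_ids)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate row ids")
        if len(set(self.column_ids)) != len(self.column_ids):
            raise ValueError("duplicate column ids")
        if self.values.shape != (len(self.row_ids), len(self.column_ids)):
            raise ValueError(
                f"value grid {self.values.shape} inconsistent with "
                f"{len(self.row_ids)} rows x {len(self.column_ids)} columns"
            )
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.column_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, value_kind: str = "generic") -> "NamedMatrix":
        return cls(
            row_ids=[str(r) for r in frame.index],
            column_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            value_kind=value_kind,
        )

    def row(self, row_id: str) -> np.ndarray:
        return self.values[self.row_ids.index(row_id)]

    def column(self, column_id: str) -> np.ndarray:
        return self.values[:, self.column_ids.index(column_id)]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols (GMT line)."""

    name: str
    description: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


# ---------------------------------------------------------------------------
# SEG
# ---------------------------------------------------------------------------

_SEG_COLUMNS = ("Sample", "Chromosome", "Start", "End", "Segment_Mean")


def read_seg(path) -> list[SegmentRecord]:
    """Read a SEG file into segment records.

    On-disk coordinates are 1-based inclusive; in-memory records are
    0-based half-open. Records are returned in file order.
    """
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty SEG file")
        header = header_line.rstrip("\n").split("\t")
        for col in _SEG_COLUMNS:
            if col not in header:
                raise FormatError(f"{path}: SEG header missing column {col!r}")
        idx = {c: header.index(c) for c in header}
        has_probes = "Num_Probes" in idx
        records: list[SegmentRecord] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise FormatError(f"{path}:{lineno}: expected {len(header)} fields")
            try:
                mean = float(fields[idx["Segment_Mean"]])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric Segment_Mean "
                    f"{fields[idx['Segment_Mean']]!r}"
                ) from exc
            try:
                start = int(fields[idx["Start"]])
                end = int(fields[idx["End"]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            n_probes = None
            if has_probes and fields[idx["Num_Probes"]] not in MISSING_TOKENS:
                n_probes = int(fields[idx["Num_Probes"]])
            records.append(
                SegmentRecord(
                    sample_id=fields[idx["Sample"]],
                    chromosome=fields[idx["Chromosome"]],
                    start=start - 1,  # 1-based inclusive -> 0-based half-open
                    end=end,
                    log2_ratio=mean,
                    n_probes=n_probes,
                )
            )
    return records


def write_seg(path, records: Iterable[SegmentRecord]) -> None:
    records = list(records)
    has_probes = any(r.n_probes is not None for r in records)
    cols = ["Sample", "Chromosome", "Start", "End"]
    if has_probes:
        cols.append("Num_Probes")
    cols.append("Segment_Mean")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            row = [r.sample_id, r.chromosome, str(r.start + 1), str(r.end)]
            if has_probes:
                row.append("" if r.n_probes is None else str(r.n_probes))
            row.append(repr(r.log2_ratio))
            fh.write("\t".join(row) + "\n")


def group_segments_by_sample(records: Iterable[SegmentRecord]) -> dict[str, list[SegmentRecord]]:
    grouped: dict[str, list[SegmentRecord]] = {}
    for r in records:
        grouped.setdefault(r.sample_id, []).append(r)
    return grouped


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path) -> list[GeneSet]:
    """Read a GMT gene-set collection, one set per line, in file order.

    Duplicate member symbols within a line are deduplicated with a warning;
    a line whose member list is empty is a format error.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 member"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            unique = set(members)
            if len(unique) != len(members):
                logger.warning(
                    "%s:%d: gene set %s contains duplicate members; deduplicated",
                    path, lineno, name,
                )
            sets.append(GeneSet(name=name, description=description, members=frozenset(unique)))
    return sets


def write_gmt(path, sets: Iterable[GeneSet]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def read_matrix(path, value_kind: str = "generic") -> NamedMatrix:
    """Read a tab-delimited matrix (row ids in the first column)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"{path}: matrix header needs >=1 sample column")
        column_ids = header[1:]
        row_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: ragged row ({len(fields)} fields, "
                    f"expected {len(header)})"
                )
            row_ids.append(fields[0])
            try:
                rows.append(
                    [np.nan if v in MISSING_TOKENS else float(v) for v in fields[1:]]
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric cell") from exc
    if len(set(row_ids)) != len(row_ids):
        dup = next(r for r in row_ids if row_ids.count(r) > 1)
        raise FormatError(f"{path}: duplicate row id {dup!r}")
    return NamedMatrix(
        row_ids=row_ids,
        column_ids=column_ids,
        values=np.asarray(rows, dtype=float),
        value_kind=value_kind,
    )


def write_matrix(path, matrix: NamedMatrix, id_header: str = "id") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join([id_header, *matrix.column_ids]) + "\n")
        for rid, row in zip(matrix.row_ids, matrix.values):
            cells = ["NA" if not np.isfinite(v) else repr(float(v)) for v in row]
            fh.write("\t".join([rid, *cells]) + "\n")


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------

# "p.E79K", "p.E79_T80del", "p.*757L" ... -> first residue index
_PROTEIN_POS_RE = re.compile(r"^p\.[^0-9]*(\d+)")


def parse_protein_position(protein_change: str) -> int | None:
    """First residue index of a protein-change string, or None."""
    m = _PROTEIN_POS_RE.match(protein_change.strip())
    if m is None:
        return None
    pos = int(m.group(1))
    return pos if pos >= 1 else None


def read_mutations(path) -> list[MutationRecord]:
    """Read a MAF-like mutation TSV.

    Requires gene and sample columns (``Hugo_Symbol``/``gene`` and
    ``Tumor_Sample_Barcode``/``sample``); the protein-change column
    (``Protein_Change``/``protein_change``) is optional per row and its
    residue index is parsed when it matches ``p.<AA><int>...``.
    """
    gene_cols = ("Hugo_Symbol", "gene")
    sample_cols = ("Tumor_Sample_Barcode", "sample", "sample_id")
    change_cols = ("Protein_Change", "protein_change")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        gene_col = next((c for c in gene_cols if c in header), None)
        sample_col = next((c for c in sample_cols if c in header), None)
        if gene_col is None:
            raise FormatError(f"{path}: mutation table missing a gene column")
        if sample_col is None:
            raise FormatError(f"{path}: mutation table missing a sample column")
        change_col = next((c for c in change_cols if c in header), None)
        idx = {c: header.index(c) for c in header}
        records: list[MutationRecord] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise FormatError(f"{path}:{lineno}: ragged row")
            change = fields[idx[change_col]] if change_col else ""
            records.append(
                MutationRecord(
                    gene=fields[idx[gene_col]],
                    sample_id=fields[idx[sample_col]],
                    protein_position=parse_protein_position(change) if change else None,
                    variant_label=change,
                )
            )
    return records


def write_mutations(path, records: Iterable[MutationRecord]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tsample\tprotein_change\n")
        for r in records:
            fh.write(f"{r.gene}\t{r.sample_id}\t{r.variant_label}\n")


# ---------------------------------------------------------------------------
# BED-like gene coordinates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneInterval:
    """Gene coordinates, 0-based half-open, same system as segments."""

    chromosome: str
    start: int
    end: int
    gene: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene}: end must exceed start")


def read_gene_intervals(path) -> list[GeneInterval]:
    """Read BED-like gene coordinates (chrom, start, end, gene); no header."""
    intervals: list[GeneInterval] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected chrom, start, end, gene")
            intervals.append(
                GeneInterval(fields[0], int(fields[1]), int(fields[2]), fields[3])
            )
    return intervals


def write_gene_intervals(path, intervals: Sequence[GeneInterval]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for iv in intervals:
            fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{iv.gene}\n")
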