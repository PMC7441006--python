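"""Readers, writers and the expression-scale transform shared by the pipeline.

File formats are deliberately plain: tab-separated expression matrices
(first column gene id, header row of sample ids), MSigDB-style GMT gene-set
collections, BED3/BED6 interval files and bedGraph coverage tracks. All
genomic coordinates are 0-based half-open (BED convention) throughout the
package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Scale",
    "ExpressionMatrix",
    "SignatureCollection",
    "TransformParams",
    "Interval",
    "IntervalSet",
    "CoverageTrack",
    "FormatError",
    "read_expression_matrix",
    "write_expression_matrix",
    "cpm_log2",
    "read_gmt",
    "write_gmt",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class Scale(str, Enum):
    counts = "counts"
    FPKM = "FPKM"
    log2CPM = "log2CPM"


@dataclass
class ExpressionMatrix:
    """Dense genes x samples expression grid with a declared value scale.

    ``values`` is a pandas DataFrame indexed by gene id with sample ids as
    columns. Identifiers must be unique; values must be finite, and
    non-negative on the counts/FPKM scales.
    """

    values: pd.DataFrame
    scale: Scale

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            raise FormatError("expression values must be finite")
        if self.scale in (Scale.counts, Scale.FPKM) and (arr < 0).any():
            raise FormatError(f"{self.scale.value} values must be >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class SignatureCollection:
    """Named gene sets; gene order within a set is preserved.

    ``entries`` maps signature name -> ordered list of gene ids;
    ``descriptions`` carries the GMT description field per entry.
    """

    entries: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.entries.items():
            if not genes:
                raise FormatError(f"signature {name!r} is empty")
            if len(set(genes)) != len(genes):
                seen: set[str] = set()
                dup = next(g for g in genes if g in seen or seen.add(g))
                raise FormatError(f"signature {name!r} has duplicate gene {dup!r}")
        for name in self.entries:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> list[str]:
        return self.entries[name]

    def __iter__(self):
        return iter(self.entries)

    def items(self):
        return self.entries.items()


@dataclass(frozen=True)
class TransformParams:
    """Parameters of the counts -> log2 CPM transform."""

    pseudocount: float = 1.0
    per_million_base: float = 1e6

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.per_million_base <= 0:
            raise ValueError("per_million_base must be > 0")


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise FormatError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise FormatError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


class IntervalSet:
    """Ordered collection of intervals (duplicates allowed, order preserved)."""

    def __init__(self, intervals: Iterable[Interval] = ()):
        self.intervals: list[Interval] = list(intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self.intervals == other.intervals

    def by_chrom(self) -> dict[str, list[Interval]]:
        out: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


class CoverageTrack:
    """Per-chromosome sorted, non-overlapping runs of (start, end, depth >= 0).

    Stored as three parallel numpy arrays per chromosome for fast interval
    arithmetic.
    """

    def __init__(self, runs: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None):
        # chrom -> (starts, ends, depths)
        self.runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if runs:
            for chrom, (s, e, d) in runs.items():
                self._add_chrom(chrom, np.asarray(s), np.asarray(e), np.asarray(d))

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int, float]]) -> "CoverageTrack":
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, depth in records:
            per_chrom.setdefault(chrom, []).append((start, end, depth))
        track = cls()
        for chrom, rows in per_chrom.items():
            rows.sort(key=lambda r: r[0])
            s = np.array([r[0] for r in rows], dtype=np.int64)
            e = np.array([r[1] for r in rows], dtype=np.int64)
            d = np.array([r[2] for r in rows], dtype=np.float64)
            track._add_chrom(chrom, s, e, d)
        return track

    def _add_chrom(self, chrom: str, s: np.ndarray, e: np.ndarray, d: np.ndarray) -> None:
        s = s.astype(np.int64)
        e = e.astype(np.int64)
        d = d.astype(np.float64)
        if (s < 0).any():
            raise FormatError(f"negative coordinate on {chrom}")
        if (e <= s).any():
            i = int(np.argmax(e <= s))
            raise FormatError(f"run end <= start on {chrom}: {s[i]}-{e[i]}")
        if (d < 0).any():
            raise FormatError(f"negative depth on {chrom}")
        order = np.argsort(s, kind="stable")
        s, e, d = s[order], e[order], d[order]
        if len(s) > 1 and (s[1:] < e[:-1]).any():
            i = int(np.argmax(s[1:] < e[:-1]))
            raise FormatError(
                f"overlapping runs on {chrom}: {s[i]}-{e[i]} and {s[i + 1]}-{e[i + 1]}"
            )
        self.runs[chrom] = (s, e, d)

    def chroms(self) -> list[str]:
        return list(self.runs)

    def scaled(self, factor: float) -> "CoverageTrack":
        """Return a copy with every depth multiplied by ``factor``."""
        out = CoverageTrack()
        for chrom, (s, e, d) in self.runs.items():
            out.runs[chrom] = (s.copy(), e.copy(), d * factor)
        return out

    def records(self) -> list[tuple[str, int, int, float]]:
        rows: list[tuple[str, int, int, float]] = []
        for chrom in sorted(self.runs):
            s, e, d = self.runs[chrom]
            rows.extend((chrom, int(a), int(b), float(v)) for a, b, v in zip(s, e, d))
        return rows

    def __eq__(self, other) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        if set(self.runs) != set(other.runs):
            return False
        return all(
            np.array_equal(self.runs[c][0], other.runs[c][0])
            and np.array_equal(self.runs[c][1], other.runs[c][1])
            and np.allclose(self.runs[c][2], other.runs[c][2])
            for c in self.runs
        )


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def read_expression_matrix(path: str | Path, scale_hint: Scale | str) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene id, header sample ids).

    Ragged rows, duplicate identifiers and non-numeric cells raise
    :class:`FormatError` naming the offending line or identifier. Windows
    line endings are accepted.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.replace("\r\n", "\n").replace("\r", "\n").split("\n")
    lines = [ln for ln in lines if ln != ""]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{path}: duplicate sample ids in header")
    n_fields = len(header)
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n_fields:
            raise FormatError(
                f"{path}:{lineno}: expected {n_fields} fields, got {len(fields)}"
            )
        gid = fields[0].upper()
        if gid in seen:
            raise FormatError(f"{path}:{lineno}: duplicate gene id {gid!r}")
        seen.add(gid)
        try:
            rows.append([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
        gene_ids.append(gid)
    values = pd.DataFrame(rows, index=gene_ids, columns=sample_ids, dtype=float)
    return ExpressionMatrix(values=values, scale=Scale(scale_hint))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for gid, row in matrix.values.iterrows():
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def cpm_log2(
    matrix: ExpressionMatrix, params: TransformParams = TransformParams()
) -> ExpressionMatrix:
    """Transform a counts matrix to log2 counts-per-million.

    value(g, s) = log2( count(g, s) / libsize(s) * 1e6 + pseudocount ).
    """
    if matrix.scale is not Scale.counts:
        raise ValueError(f"cpm_log2 requires a counts matrix, got {matrix.scale.value}")
    libsize = matrix.values.sum(axis=0)
    zero = libsize[libsize <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    cpm = matrix.values.div(libsize, axis=1) * params.per_million_base
    transformed = np.log2(cpm + params.pseudocount)
    return ExpressionMatrix(values=transformed, scale=Scale.log2CPM)


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> SignatureCollection:
    """Read an MSigDB-style GMT file: name TAB description TAB gene TAB gene..."""
    path = Path(path)
    entries: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    text = path.read_text().replace("\r\n", "\n").replace("\r", "\n")
    for lineno, line in enumerate(text.split("\n"), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
        name, desc, *genes = fields
        genes = [g.upper() for g in genes if g != ""]
        if name in entries:
            raise FormatError(f"{path}:{lineno}: duplicate signature name {name!r}")
        if len(set(genes)) != len(genes):
            raise FormatError(f"{path}:{lineno}: duplicate gene within set {name!r}")
        if not genes:
            raise FormatError(f"{path}:{lineno}: signature {name!r} has no genes")
        entries[name] = genes
        descriptions[name] = desc
    return SignatureCollection(entries=entries, descriptions=descriptions)


def write_gmt(collection: SignatureCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# BED intervals and bedGraph coverage
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> IntervalSet:
    """Read BED3/BED6 (extra columns ignored); 0-based half-open coordinates."""
    path = Path(path)
    intervals: list[Interval] = []
    text = path.read_text().replace("\r\n", "\n").replace("\r", "\n")
    for lineno, line in enumerate(text.split("\n"), start=1):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: BED line has <3 fields")
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinate") from None
        name = fields[3] if len(fields) > 3 else "."
        try:
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric score") from None
        strand = fields[5] if len(fields) > 5 else "."
        try:
            intervals.append(
                Interval(chrom=chrom, start=start, end=end, name=name, score=score, strand=strand)
            )
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    return IntervalSet(intervals)


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """Read bedGraph coverage; runs per chromosome must be non-overlapping."""
    path = Path(path)
    records: list[tuple[str, int, int, float]] = []
    text = path.read_text().replace("\r\n", "\n").replace("\r", "\n")
    for lineno, line in enumerate(text.split("\n"), start=1):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: bedGraph line has <4 fields")
        try:
            records.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
        except ValueError:
            raise FormatError(f"{path}:{lineno}: malformed bedGraph fields") from None
    try:
        return CoverageTrack.from_records(records)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for chrom, start, end, depth in track.records():
            fh.write(f"{chrom}\t{start}\t{end}\t{depth:g}\n")
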