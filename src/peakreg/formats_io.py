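"""Typed readers and writers for the on-disk formats the pipeline consumes.

All genomic coordinates are BED-style: 0-based, half-open ``[start, end)``.
Strand "." means unstranded. Every reader validates its input eagerly and
raises with a line number, so downstream modules can assume the invariants
of the in-memory types hold.

Formats
-------
- BED6 / ENCODE narrowPeak (10 columns) for peak sets
- 4-column bedGraph for coverage tracks (gaps are implicit zeros)
- gene model TSV: gene_id, chrom, strand, start, end
- differential-expression TSV: gene_id, fold_change, padj, mean_expr_cpm
- checkerboard dose CSV: first row / first column are the dose ladders,
  interior cells are % viability relative to the untreated control
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "Peak",
    "CoverageTrack",
    "GeneModel",
    "DERecord",
    "DoseMatrix",
    "FormatError",
    "read_peaks",
    "write_peaks",
    "read_bedgraph",
    "write_bedgraph",
    "read_gene_model",
    "write_gene_model",
    "read_de_table",
    "write_de_table",
    "read_dose_matrix",
    "write_dose_matrix",
]


class FormatError(ValueError):
    """Malformed or invariant-violating input file."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        """True if the intervals share at least ``min_bp`` bases."""
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_bp


@dataclass(frozen=True)
class Peak:
    """A called binding interval with optional summit (narrowPeak semantics)."""

    interval: GenomicInterval
    name: str
    score: float = 0.0
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.summit_offset is not None:
            if not (0 <= self.summit_offset < len(self.interval)):
                raise ValueError(
                    f"summit_offset {self.summit_offset} outside peak "
                    f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
                )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


class CoverageTrack:
    """Sparse step-function coverage over a genome.

    Holds, per chromosome, sorted non-overlapping (start, end, value) steps
    plus the total mapped-read count of the source library, which is what
    RPKM scaling divides by. Positions not covered by a step have value 0.

    Internally each chromosome keeps a prefix integral over step starts so
    that the integral of the track over any interval is an O(log n) query.
    """

    def __init__(
        self,
        steps: dict[str, np.ndarray] | dict[str, Sequence[tuple[int, int, float]]],
        total_reads: float,
        resolution_note: str = "",
    ) -> None:
        if total_reads <= 0:
            raise ValueError("total_reads must be > 0")
        self.total_reads = float(total_reads)
        self.resolution_note = resolution_note
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        self._prefix: dict[str, np.ndarray] = {}
        for chrom, chrom_steps in steps.items():
            arr = np.asarray(chrom_steps, dtype=float)
            if arr.size == 0:
                arr = arr.reshape(0, 3)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError("steps must be (start, end, value) triples")
            order = np.argsort(arr[:, 0], kind="stable")
            arr = arr[order]
            starts, ends, values = arr[:, 0], arr[:, 1], arr[:, 2]
            if np.any(values < 0):
                raise FormatError(f"negative coverage value on {chrom}")
            if np.any(starts >= ends):
                raise FormatError(f"empty or inverted step on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise FormatError(f"overlapping steps on {chrom}")
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._values[chrom] = values
            # prefix[i] = integral of the track over [0, starts[i])
            areas = values * (ends - starts)
            self._prefix[chrom] = np.concatenate(([0.0], np.cumsum(areas)))

    @property
    def chromosomes(self) -> list[str]:
        return list(self._starts)

    def steps(self, chrom: str) -> np.ndarray:
        """(n, 3) array of (start, end, value) steps for one chromosome."""
        return np.column_stack(
            (self._starts[chrom], self._ends[chrom], self._values[chrom])
        )

    def _cum(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Integral of the track over [0, pos) for each position, vectorized."""
        starts = self._starts[chrom]
        ends = self._ends[chrom]
        values = self._values[chrom]
        prefix = self._prefix[chrom]
        pos = np.maximum(np.asarray(pos, dtype=float), 0.0)
        idx = np.searchsorted(starts, pos, side="right") - 1
        safe = np.maximum(idx, 0)
        inside = np.clip(pos - starts[safe], 0.0, ends[safe] - starts[safe])
        inside = np.where(idx >= 0, values[safe] * inside, 0.0)
        return prefix[np.maximum(idx, 0) * (idx >= 0)] + inside

    def integral(self, chrom: str, start: float, end: float) -> float:
        """Integral of per-base coverage over [start, end)."""
        if chrom not in self._starts:
            return 0.0
        lo, hi = self._cum(chrom, np.array([start, end]))
        return float(hi - lo)

    def integral_many(self, chrom: str, edges: np.ndarray) -> np.ndarray:
        """Integrals over consecutive [edges[i], edges[i+1]) windows."""
        if chrom not in self._starts:
            return np.zeros(len(edges) - 1)
        cum = self._cum(chrom, edges)
        return np.diff(cum)

    def total_signal(self) -> float:
        """Integral of the track over the whole genome."""
        return float(sum(p[-1] for p in self._prefix.values()))


@dataclass(frozen=True)
class GeneModel:
    """A gene span with strand; the TSS is implied by the strand."""

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        """Transcription start site: start on +, end-1 on - (half-open)."""
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(frozen=True)
class DERecord:
    """Per-gene differential-expression result.

    ``fold_change`` is the signed linear convention: +x means x-fold up in
    condition vs control, -x means a 1/x ratio; no-change is encoded +1.
    """

    gene_id: str
    fold_change: float
    padj: float
    mean_expr: float

    def __post_init__(self) -> None:
        if abs(self.fold_change) < 1:
            raise ValueError(
                f"gene {self.gene_id}: |fold_change| must be >= 1 "
                "(signed linear convention; no-change is +1)"
            )
        if not (0 <= self.padj <= 1):
            raise ValueError(f"gene {self.gene_id}: padj outside [0, 1]")
        if self.mean_expr < 0:
            raise ValueError(f"gene {self.gene_id}: negative mean expression")


@dataclass(frozen=True)
class DoseMatrix:
    """Checkerboard viability matrix, % of untreated control.

    Row 0 / column 0 hold single-agent responses (first dose of each drug
    is 0); cell [0, 0] is the untreated control, 100 by construction.
    """

    drug_a_doses: tuple[float, ...]
    drug_b_doses: tuple[float, ...]
    viability: np.ndarray  # shape (len(a_doses), len(b_doses))

    def __post_init__(self) -> None:
        v = np.asarray(self.viability, dtype=float)
        object.__setattr__(self, "viability", v)
        a = np.asarray(self.drug_a_doses)
        b = np.asarray(self.drug_b_doses)
        if v.shape != (len(a), len(b)):
            raise ValueError("viability shape does not match dose vectors")
        if np.any(v < 0):
            raise ValueError("negative viability")
        for name, doses in (("drug_a", a), ("drug_b", b)):
            if len(doses) < 2 or doses[0] != 0:
                raise ValueError(f"{name} doses must start at 0 with >= 2 levels")
            if np.any(np.diff(doses) <= 0):
                raise ValueError(f"{name} doses must be strictly increasing")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _lines(path: str) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield i, line


def read_peaks(path: str, format: str = "narrowPeak") -> list[Peak]:
    """Read a BED6 or ENCODE narrowPeak file into validated peaks, in file order.

    narrowPeak column 10 is the summit offset from the peak start; -1 means
    no summit was called.
    """
    if format not in {"BED6", "narrowPeak"}:
        raise ValueError(f"unknown peak format {format!r}")
    min_fields = 6 if format == "BED6" else 10
    peaks: list[Peak] = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < min_fields:
            raise FormatError(
                f"{path}:{lineno}: expected >= {min_fields} fields, got {len(fields)}"
            )
        try:
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            score = float(fields[4]) if fields[4] != "." else 0.0
            strand = fields[5]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        summit: int | None = None
        if format == "narrowPeak":
            try:
                raw = int(fields[9])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad summit field") from exc
            summit = None if raw == -1 else raw
        try:
            peaks.append(
                Peak(GenomicInterval(chrom, start, end, strand), name, score, summit)
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str, format: str = "narrowPeak") -> None:
    with open(path, "w") as fh:
        for p in peaks:
            bed6 = [p.chrom, str(p.start), str(p.end), p.name, f"{p.score:g}",
                    p.interval.strand]
            if format == "BED6":
                fh.write("\t".join(bed6) + "\n")
            else:
                summit = -1 if p.summit_offset is None else p.summit_offset
                fh.write("\t".join(bed6 + ["0", "-1", "-1", str(summit)]) + "\n")


def read_bedgraph(path: str, total_reads: float, resolution_note: str = "") -> CoverageTrack:
    """Read a 4-column bedGraph into a CoverageTrack.

    Gaps between steps are implicit zeros. Overlapping steps or negative
    values are rejected.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: expected 4 fields")
        try:
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        if value < 0:
            raise FormatError(f"{path}:{lineno}: negative coverage value")
        if start >= end:
            raise FormatError(f"{path}:{lineno}: empty or inverted step")
        per_chrom.setdefault(chrom, []).append((start, end, value))
    try:
        return CoverageTrack(per_chrom, total_reads, resolution_note)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_bedgraph(track: CoverageTrack, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in track.chromosomes:
            for start, end, value in track.steps(chrom):
                fh.write(f"{chrom}\t{int(start)}\t{int(end)}\t{value:g}\n")


_GENE_COLUMNS = ["gene_id", "chrom", "strand", "start", "end"]


def read_gene_model(path: str) -> list[GeneModel]:
    """Read a gene-model TSV (gene_id, chrom, strand, start, end)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _GENE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    genes = []
    for row in df.itertuples(index=False):
        try:
            genes.append(
                GeneModel(
                    str(row.gene_id),
                    GenomicInterval(str(row.chrom), int(row.start), int(row.end),
                                    str(row.strand)),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: gene {row.gene_id}: {exc}") from exc
    return genes


def write_gene_model(genes: Sequence[GeneModel], path: str) -> None:
    rows = [
        (g.gene_id, g.chrom, g.strand, g.interval.start, g.interval.end)
        for g in genes
    ]
    pd.DataFrame(rows, columns=_GENE_COLUMNS).to_csv(path, sep="\t", index=False)


_DE_COLUMNS = ["gene_id", "fold_change", "padj", "mean_expr_cpm"]


def read_de_table(path: str) -> list[DERecord]:
    """Read a differential-expression TSV into validated records."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _DE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        try:
            records.append(
                DERecord(str(row.gene_id), float(row.fold_change), float(row.padj),
                         float(row.mean_expr_cpm))
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return records


def write_de_table(records: Sequence[DERecord], path: str) -> None:
    rows = [(r.gene_id, r.fold_change, r.padj, r.mean_expr) for r in records]
    pd.DataFrame(rows, columns=_DE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_dose_matrix(path: str) -> DoseMatrix:
    """Read a checkerboard CSV: first row/column are doses, body is % viability."""
    df = pd.read_csv(path, index_col=0)
    try:
        a_doses = tuple(float(x) for x in df.index)
        b_doses = tuple(float(x) for x in df.columns)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric dose header: {exc}") from exc
    try:
        return DoseMatrix(a_doses, b_doses, df.to_numpy(dtype=float))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_dose_matrix(matrix: DoseMatrix, path: str) -> None:
    df = pd.DataFrame(
        matrix.viability,
        index=[f"{d:g}" for d in matrix.drug_a_doses],
        columns=[f"{d:g}" for d in matrix.drug_b_doses],
    )
    df.to_csv(path)
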