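"""Domain types and I/O for intervals, genes, tags and expression tables.

Coordinates are 0-based half-open throughout (BED convention); a gene TSS
is a single 0-based position.  All higher stages build on the interval
arithmetic defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-", ".")

GENE_TABLE_COLUMNS = ["gene_id", "symbol", "chrom", "strand", "tss", "tes"]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Peak:
    """A bound region: an interval plus optional summit, score and sample tag.

    ``score`` is conventionally -log10(p) from the caller; ``sample``
    labels the originating library (cell type + state).
    """

    interval: GenomicInterval
    name: str | None = None
    summit_offset: int | None = None
    score: float | None = None
    sample: str | None = None

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.length
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside "
                f"[0, {self.interval.length})"
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

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint


@dataclass(frozen=True)
class GeneModel:
    """TSS-anchored gene record.  ``tss`` and ``tes`` are 0-based positions;
    for a minus-strand gene tss > tes."""

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be '+' or '-'")
        if self.tss == self.tes:
            raise ValueError(f"{self.gene_id}: tss == tes")
        if min(self.tss, self.tes) < 0:
            raise ValueError(f"{self.gene_id}: negative coordinate")

    @property
    def length(self) -> int:
        return abs(self.tes - self.tss)


@dataclass
class ExpressionMatrix:
    """log2 expression values (genes x samples) plus a sample sheet.

    ``samples`` is indexed by sample label with at least a ``group``
    column tagging each replicate WT or KO; ``cell_type`` and ``state``
    are free metadata.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if "group" not in self.samples.columns:
            raise ValueError("sample sheet needs a 'group' column")
        unknown = set(self.samples["group"]) - {"WT", "KO"}
        if unknown:
            raise ValueError(f"unknown groups {sorted(unknown)}")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing from sheet: {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def group_columns(self, group: str) -> pd.DataFrame:
        cols = [c for c in self.values.columns
                if self.samples.loc[c, "group"] == group]
        return self.values[cols]


@dataclass
class TagLibrary:
    """Per-chromosome sorted 5' tag positions with strands.

    ``positions[chrom]`` is a sorted int array; ``strands[chrom]`` the
    matching '+'/'-' array.  ``chrom_sizes`` is carried when known so the
    peak caller can enumerate windows.
    """

    positions: dict[str, np.ndarray]
    strands: dict[str, np.ndarray] = field(default_factory=dict)
    chrom_sizes: dict[str, int] | None = None

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            if np.any(np.diff(pos) < 0):
                pos = np.sort(pos)
            self.positions[chrom] = pos
            if self.chrom_sizes is not None and len(pos):
                size = self.chrom_sizes.get(chrom)
                if size is not None and (pos[0] < 0 or pos[-1] >= size):
                    raise ValueError(f"tag outside {chrom} bounds")

    @property
    def total_count(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------

def interval_overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Shared base pairs between two half-open intervals (0 across chroms)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _peak_key(p: Peak) -> tuple[str, int, int]:
    return (p.chrom, p.start, p.end)


def is_sorted(peaks: Sequence[Peak]) -> bool:
    return all(_peak_key(peaks[i]) <= _peak_key(peaks[i + 1])
               for i in range(len(peaks) - 1))


def sort_peaks(peaks: Iterable[Peak]) -> list[Peak]:
    return sorted(peaks, key=_peak_key)


def intersect_sets(a: Sequence[Peak], b: Sequence[Peak]
                   ) -> list[tuple[Peak, Peak]]:
    """All pairs (one from each sorted list) sharing >= 1 bp, each once.

    Sweep per chromosome with a two-pointer lower bound; equals the
    all-pairs check on every instance but skips non-overlapping spans.
    """
    for name, peaks in (("first", a), ("second", b)):
        if not is_sorted(peaks):
            raise ValueError(
                f"{name} peak list is unsorted; sort by (chrom, start) first"
            )
    by_chrom_b: dict[str, list[Peak]] = {}
    for p in b:
        by_chrom_b.setdefault(p.chrom, []).append(p)
    # prefix running max of ends lets the cursor skip any b prefix that
    # ends entirely before the (non-decreasing) current a.start
    prefix_max: dict[str, list[int]] = {}
    for chrom, bs in by_chrom_b.items():
        acc: list[int] = []
        cur = 0
        for p in bs:
            cur = max(cur, p.end)
            acc.append(cur)
        prefix_max[chrom] = acc
    pairs: list[tuple[Peak, Peak]] = []
    cursor: dict[str, int] = {c: 0 for c in by_chrom_b}
    for pa in a:
        bs = by_chrom_b.get(pa.chrom)
        if not bs:
            continue
        lo = cursor[pa.chrom]
        pmax = prefix_max[pa.chrom]
        while lo < len(bs) and pmax[lo] <= pa.start:
            lo += 1
        cursor[pa.chrom] = lo
        k = lo
        while k < len(bs) and bs[k].start < pa.end:
            if bs[k].end > pa.start:
                pairs.append((pa, bs[k]))
            k += 1
    return pairs


# ---------------------------------------------------------------------------
# BED and gene-table I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, sample: str | None = None) -> list[Peak]:
    """Read BED3/BED5(+) into sorted Peaks.

    Columns 4/5, when present, map to name/score.  Malformed lines raise
    with their 1-based line number.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated "
                    f"columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if end <= start:
                raise ValueError(
                    f"{path}: line {lineno}: end {end} <= start {start}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            peaks.append(
                Peak(GenomicInterval(chrom, start, end), name=name,
                     score=score, sample=sample)
            )
    return sort_peaks(peaks)


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.name if p.name is not None else f"peak_{i + 1}"
            score = f"{p.score:g}" if p.score is not None else "0"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{score}\n")


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a headered TSV (gene_id, symbol, chrom, strand, tss, tes)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene_id(s): "
                         f"{sorted(set(dup))[:5]}")
    return [
        GeneModel(row.gene_id, row.symbol, row.chrom, row.strand,
                  int(row.tss), int(row.tes))
        for row in df.itertuples()
    ]


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.symbol, g.chrom, g.strand, g.tss, g.tes)
         for g in genes],
        columns=GENE_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def deduplicate_symbols(genes: Sequence[GeneModel]) -> list[GeneModel]:
    """Collapse duplicate symbols keeping the longest gene per symbol."""
    best: dict[str, GeneModel] = {}
    for g in genes:
        cur = best.get(g.symbol)
        if cur is None or g.length > cur.length:
            best[g.symbol] = g
    return sorted(best.values(), key=lambda g: (g.chrom, min(g.tss, g.tes)))


# ---------------------------------------------------------------------------
# expression and tag I/O
# ---------------------------------------------------------------------------

def read_expression(matrix_path: str | Path,
                    sample_sheet_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    samples = pd.read_csv(sample_sheet_path, sep="\t", index_col=0)
    return ExpressionMatrix(values=values, samples=samples)


def write_expression(matrix: ExpressionMatrix, matrix_path: str | Path,
                     sample_sheet_path: str | Path) -> None:
    matrix.values.to_csv(matrix_path, sep="\t")
    matrix.samples.to_csv(sample_sheet_path, sep="\t")


def read_tags(path: str | Path,
              chrom_sizes: dict[str, int] | None = None) -> TagLibrary:
    """Read a 3-column TSV (chrom, position, strand) into a TagLibrary."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "pos", "strand"],
                     dtype={"chrom": str, "pos": np.int64, "strand": str})
    positions: dict[str, np.ndarray] = {}
    strands: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        order = np.argsort(sub["pos"].to_numpy(), kind="stable")
        positions[str(chrom)] = sub["pos"].to_numpy()[order]
        strands[str(chrom)] = sub["strand"].to_numpy()[order]
    return TagLibrary(positions=positions, strands=strands,
                      chrom_sizes=chrom_sizes)


def write_tags(library: TagLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(library.positions):
            pos = library.positions[chrom]
            strand = library.strands.get(
                chrom, np.full(len(pos), "+", dtype=object))
            for p, s in zip(pos, strand):
                fh.write(f"{chrom}\t{p}\t{s}\n")


def write_fasta(sequences: Mapping[str, str], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
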