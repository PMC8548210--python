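"""Coordinate model, interval arithmetic, and annotation I/O.

All coordinates are 0-based, half-open (BED convention).  Overlap and
distance ignore strand; strand is retained only for orientation-sensitive
operations (metaprofiles, TSS definition).  Distance between intervals on
different chromosomes is ``math.inf`` so "closest feature" never crosses a
chromosome boundary.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

NO_NEIGHBOR = ("", math.inf)
"""Sentinel returned by :func:`nearest_feature` when no same-chromosome
feature exists."""

VALID_STRANDS = {"+", "-", "."}


class ValidationError(ValueError):
    """An interval, layout, or annotation violates its invariants."""


@dataclass(frozen=True)
class GenomeLayout:
    """Named chromosomes with lengths, the substrate of every overlap,
    distance, and shuffle.

    Parameters
    ----------
    chromosomes
        Ordered mapping of chromosome name to length in bp.
    """

    chromosomes: dict[str, int]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValidationError("genome layout needs at least one chromosome")
        for name, length in self.chromosomes.items():
            if not name:
                raise ValidationError("chromosome names must be non-empty")
            if not isinstance(length, (int, np.integer)) or length <= 0:
                raise ValidationError(
                    f"chromosome {name!r} has non-positive length {length!r}"
                )

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def length(self, chrom: str) -> int:
        try:
            return self.chromosomes[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_bp(self) -> int:
        return sum(self.chromosomes.values())

    def validate_interval(self, interval: "GenomicInterval") -> None:
        """Raise :class:`ValidationError` if *interval* exceeds its
        chromosome bounds or names an unknown chromosome."""
        if interval.end > self.length(interval.chrom):
            raise ValidationError(
                f"interval {interval} exceeds {interval.chrom} length "
                f"{self.length(interval.chrom)}"
            )


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"strand must be one of {VALID_STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared bp with *other* (0 if disjoint or on a
        different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def expanded(self, flank_bp: int, layout: GenomeLayout | None = None) -> "GenomicInterval":
        """Interval grown by *flank_bp* on both sides, clipped to the
        chromosome when a layout is given."""
        start = max(0, self.start - flank_bp)
        end = self.end + flank_bp
        if layout is not None:
            end = min(end, layout.length(self.chrom))
        return GenomicInterval(self.chrom, start, end, self.strand, self.id)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene model: interval, identifier, biotype, and TSS.

    The TSS is the first transcribed base: ``start`` on the plus strand,
    ``end - 1`` on the minus strand.
    """

    interval: GenomicInterval
    gene_id: str
    biotype: str = "coding"
    tss: int = field(default=-1)

    BIOTYPES = ("coding", "lincRNA", "other")

    def __post_init__(self) -> None:
        if self.biotype not in self.BIOTYPES:
            raise ValidationError(f"unknown biotype {self.biotype!r}")
        if self.tss == -1:
            tss = (
                self.interval.start
                if self.interval.strand != "-"
                else self.interval.end - 1
            )
            object.__setattr__(self, "tss", tss)
        if not (self.interval.start <= self.tss < self.interval.end):
            raise ValidationError(
                f"TSS {self.tss} outside gene body {self.interval}"
            )


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Gap in bp between two intervals; 0 when they overlap or abut,
    ``math.inf`` when they lie on different chromosomes."""
    if a.chrom != b.chrom:
        return math.inf
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def intersect_sets(
    A: Sequence[GenomicInterval],
    B: Sequence[GenomicInterval],
    min_overlap_bp: int = 1,
) -> tuple[list[bool], list[tuple[int, int]]]:
    """Flag each A-interval that shares at least *min_overlap_bp* with some
    B-interval, and list every qualifying (A index, B index) pair once.

    The result is independent of input ordering: flags follow A's order and
    the pair list is sorted.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    flags = [False] * len(A)
    pairs: list[tuple[int, int]] = []
    by_chrom: dict[str, list[int]] = {}
    for j, b in enumerate(B):
        by_chrom.setdefault(b.chrom, []).append(j)
    for chrom, j_idx in by_chrom.items():
        b_start = np.array([B[j].start for j in j_idx])
        b_end = np.array([B[j].end for j in j_idx])
        for i, a in enumerate(A):
            if a.chrom != chrom:
                continue
            ov = np.minimum(a.end, b_end) - np.maximum(a.start, b_start)
            hits = np.nonzero(ov >= min_overlap_bp)[0]
            if hits.size:
                flags[i] = True
                pairs.extend((i, j_idx[k]) for k in hits)
    pairs.sort()
    return flags, pairs


def merge_intervals(
    intervals: Iterable[GenomicInterval], merge_abutting: bool = True
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merge intervals into disjoint runs per chromosome.

    Returns ``{chrom: (starts, ends)}`` with both arrays sorted.  Merging
    abutting intervals preserves the union as a point set, so overlap
    queries against the merged runs equal queries against the raw set.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        starts: list[int] = []
        ends: list[int] = []
        for s, e in pairs:
            joins = ends and (s < ends[-1] or (merge_abutting and s == ends[-1]))
            if joins:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.array(starts), np.array(ends))
    return merged


def overlaps_merged(
    interval: GenomicInterval,
    merged: dict[str, tuple[np.ndarray, np.ndarray]],
    max_gap: int = 0,
) -> bool:
    """True when *interval* lies within *max_gap* bp of a merged run
    (``max_gap=0`` means strict >=1 bp overlap is NOT required: gap 0,
    i.e. overlap or abutment, qualifies when ``max_gap=0`` only through
    overlap; see :func:`overlap_flags_merged` for the strict form)."""
    if interval.chrom not in merged:
        return False
    starts, ends = merged[interval.chrom]
    if starts.size == 0:
        return False
    i = bisect_right(starts, interval.end + max_gap) - 1
    return i >= 0 and ends[i] + max_gap >= interval.start


def overlap_flags_merged(
    starts: np.ndarray,
    ends: np.ndarray,
    merged_starts: np.ndarray,
    merged_ends: np.ndarray,
) -> np.ndarray:
    """Vectorised strict-overlap (>=1 bp) query of intervals against
    disjoint sorted merged runs on one chromosome."""
    if merged_starts.size == 0:
        return np.zeros(len(starts), dtype=bool)
    idx = np.searchsorted(merged_starts, ends, side="left") - 1
    idx_clip = np.clip(idx, 0, None)
    return (idx >= 0) & (merged_ends[idx_clip] > starts)


def compute_rpkm(read_count: float, length_bp: int, library_size: int) -> float:
    """Reads per kilobase of region per million mapped reads."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if read_count < 0:
        raise ValueError("read_count must be non-negative")
    return read_count / ((length_bp / 1000.0) * (library_size / 1e6))


def nearest_feature(
    query: GenomicInterval, features: Sequence[GeneAnnotation]
) -> tuple[str, float]:
    """Closest feature by interval-to-interval distance.

    Ties break to the smallest start, then lexicographic gene id.  Returns
    :data:`NO_NEIGHBOR` when no feature shares the query's chromosome.
    """
    best: tuple[float, int, str] | None = None
    best_id = ""
    for f in features:
        if f.interval.chrom != query.chrom:
            continue
        d = interval_distance(query, f.interval)
        key = (d, f.interval.start, f.gene_id)
        if best is None or key < best:
            best = key
            best_id = f.gene_id
    if best is None:
        return NO_NEIGHBOR
    return best_id, best[0]


# ---------------------------------------------------------------------------
# I/O: BED3/BED6, chrom.sizes, and the 7-column gene-annotation dialect
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    chroms: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, length = line.split("\t")
        chroms[name] = int(length)
    return GenomeLayout(chroms)


def write_chrom_sizes(layout: GenomeLayout, path: str | Path) -> None:
    lines = [f"{name}\t{length}\n" for name, length in layout.chromosomes.items()]
    Path(path).write_text("".join(lines))


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3 or BED6 (tab-separated, half-open coordinates)."""
    out: list[GenomicInterval] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        name = f[3] if len(f) > 3 and f[3] != "." else None
        strand = f[5] if len(f) > 5 else "."
        out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand, name))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    """Write sorted BED6 records (name '.', score 0 when unset)."""
    recs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    lines = [
        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id or '.'}\t0\t{iv.strand}\n"
        for iv in recs
    ]
    Path(path).write_text("".join(lines))


def read_gene_bed(path: str | Path) -> list[GeneAnnotation]:
    """Read the 7-column gene dialect: BED6 plus a biotype column."""
    genes: list[GeneAnnotation] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 7:
            raise ValidationError(
                f"gene annotation needs 7 columns (BED6 + biotype), got {len(f)}"
            )
        iv = GenomicInterval(f[0], int(f[1]), int(f[2]), f[5], f[3])
        genes.append(GeneAnnotation(iv, gene_id=f[3], biotype=f[6]))
    return genes


def write_gene_bed(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    recs = sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start))
    lines = [
        f"{g.interval.chrom}\t{g.interval.start}\t{g.interval.end}\t"
        f"{g.gene_id}\t0\t{g.interval.strand}\t{g.biotype}\n"
        for g in recs
    ]
    Path(path).write_text("".join(lines))
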