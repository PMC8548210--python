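"""Stringent PAR-CLIP peak selection and descriptive statistics.

PAR-CLIP labels nascent RNA with 4-thiouridine; crosslinked uridines read
out as T-to-C transitions, so a genuine RNA-protein contact site carries
both strong read enrichment over input and a measurable conversion rate.
The stringent peak set demands (i) consistent calling in two biological
replicates, (ii) overlap with a conversion-bearing cluster, and (iii) read
density above an RPKM cutoff (default 10).

The built-in window caller is a deliberately simple stand-in: fixed
non-overlapping windows scored with a conditional binomial exact test of
IP versus library-scaled input.  It exists so the downstream filters can
be exercised end-to-end on synthetic tracks; it makes no claim to model
crosslink-induced read truncation or kernel-density peak shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import (
    GenomeLayout,
    GenomicInterval,
    GeneAnnotation,
    ValidationError,
    compute_rpkm,
    intersect_sets,
    merge_intervals,
    overlap_flags_merged,
)


@dataclass(frozen=True)
class Peak:
    """Genomic interval with per-replicate read counts and T-to-C
    conversion evidence.

    ``read_counts`` and ``library_sizes`` are parallel per-replicate
    tuples; ``read_total`` and ``conversion_count`` are totals over reads
    in the peak.  The peak RPKM is the mean of per-replicate RPKMs, each
    computed with its own library size.
    """

    interval: GenomicInterval
    read_counts: tuple[float, ...]
    library_sizes: tuple[int, ...]
    conversion_count: int = 0
    read_total: float = -1.0
    supporting_clusters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.read_counts) != len(self.library_sizes):
            raise ValidationError(
                "read_counts and library_sizes must have equal replicate arity"
            )
        if any(c < 0 for c in self.read_counts):
            raise ValidationError("negative read count")
        if any(s <= 0 for s in self.library_sizes):
            raise ValidationError("library sizes must be positive")
        if self.conversion_count < 0:
            raise ValidationError("negative conversion count")
        if self.read_total < 0:
            object.__setattr__(self, "read_total", float(sum(self.read_counts)))

    @property
    def rpkm(self) -> float:
        vals = [
            compute_rpkm(c, self.interval.length, s)
            for c, s in zip(self.read_counts, self.library_sizes)
        ]
        return float(np.mean(vals))


@dataclass(frozen=True)
class PeakContextSummary:
    """Counts of peaks by genomic context with precedence
    coding > lincRNA > intergenic."""

    coding: int
    lincRNA: int
    intergenic: int

    @property
    def total(self) -> int:
        return self.coding + self.lincRNA + self.intergenic

    def fractions(self) -> dict[str, float]:
        t = self.total or 1
        return {
            "coding": self.coding / t,
            "lincRNA": self.lincRNA / t,
            "intergenic": self.intergenic / t,
        }


def peak_conversion_rate(peak: Peak) -> float:
    """T-to-C conversions per read within the peak."""
    if peak.read_total <= 0:
        raise ValueError("conversion rate undefined for a peak with no reads")
    return peak.conversion_count / peak.read_total


@dataclass(frozen=True)
class WindowedTrack:
    """Fixed-width non-overlapping window counts over a genome."""

    layout: GenomeLayout
    window_bp: int
    counts: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.window_bp < 1:
            raise ValueError("window_bp must be >= 1")
        for chrom in self.counts:
            expected = -(-self.layout.length(chrom) // self.window_bp)
            if len(self.counts[chrom]) != expected:
                raise ValidationError(
                    f"track on {chrom}: expected {expected} windows, "
                    f"got {len(self.counts[chrom])}"
                )

    @property
    def total(self) -> float:
        return float(sum(np.sum(v) for v in self.counts.values()))


def call_enriched_windows(
    ip: WindowedTrack,
    control: WindowedTrack,
    min_fold: float = 2.0,
    alpha: float = 1e-5,
) -> list[Peak]:
    """Call IP-enriched windows against a scaled input track and merge
    adjacent calls into peaks.

    A window is called when IP / expected >= *min_fold* (expected = the
    library-scaled input count floored at a pseudo-expectation of 1 read)
    and the one-sided enrichment p-value falls below *alpha*.  The p-value
    conditions on the window's combined IP+input total (binomial with the
    library-share success probability): this keeps exchangeable IP/input
    tracks exactly calibrated, where a Poisson tail at the noisy
    input-estimated mean would be anti-conservative, and converges to that
    Poisson tail as input counts grow.
    """
    if ip.window_bp != control.window_bp or set(ip.counts) != set(control.counts):
        raise ValueError("IP and input tracks must share the same window grid")
    if control.total <= 0:
        raise ValueError("input track has zero total reads")
    scale = ip.total / control.total
    ip_lib = int(round(ip.total)) or 1
    peaks: list[Peak] = []
    for chrom in ip.counts:
        ipc = np.asarray(ip.counts[chrom], dtype=float)
        ctc = np.asarray(control.counts[chrom], dtype=float)
        expected = np.maximum(ctc * scale, 1.0)
        fold = ipc / expected
        # conditional on the combined total, the IP count is binomial with
        # the library-share success probability; floor input at 1 read
        share = scale / (1.0 + scale)
        n1 = np.round(ipc).astype(int)
        total = n1 + np.maximum(np.round(ctc).astype(int), 1)
        pval = stats.binom.sf(n1 - 1, total, share)
        called = (fold >= min_fold) & (pval < alpha)
        idx = np.nonzero(called)[0]
        if idx.size == 0:
            continue
        # merge runs of adjacent called windows
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        chrom_len = ip.layout.length(chrom)
        for s, e in zip(starts, ends):
            w0, w1 = idx[s], idx[e]
            iv = GenomicInterval(
                chrom, w0 * ip.window_bp, min((w1 + 1) * ip.window_bp, chrom_len)
            )
            total = float(ipc[w0 : w1 + 1].sum())
            peaks.append(
                Peak(iv, read_counts=(total,), library_sizes=(ip_lib,))
            )
    return peaks


def stringent_peak_set(
    caller_rep1: Sequence[Peak],
    caller_rep2: Sequence[Peak],
    conversion_clusters: Sequence[Peak],
    rpkm_cutoff: float = 10.0,
) -> list[Peak]:
    """Triple filter yielding the stringent PAR-CLIP set.

    Retains replicate-1 peaks that (i) overlap a replicate-2 peak by >=1 bp,
    (ii) overlap a conversion cluster by >=1 bp, and (iii) exceed the RPKM
    cutoff.  Each retained peak records the ids of its supporting clusters.
    """
    for k, cl in enumerate(conversion_clusters):
        if cl.conversion_count < 1:
            raise ValidationError(
                f"conversion cluster {k} carries no conversion reads"
            )
    rep2_flags, _ = intersect_sets(
        [p.interval for p in caller_rep1], [p.interval for p in caller_rep2]
    )
    clust_flags, pairs = intersect_sets(
        [p.interval for p in caller_rep1],
        [c.interval for c in conversion_clusters],
    )
    support: dict[int, list[str]] = {}
    for i, j in pairs:
        cid = conversion_clusters[j].interval.id or f"cluster_{j}"
        support.setdefault(i, []).append(cid)
    out: list[Peak] = []
    for i, peak in enumerate(caller_rep1):
        if rep2_flags[i] and clust_flags[i] and peak.rpkm > rpkm_cutoff:
            out.append(replace(peak, supporting_clusters=tuple(support[i])))
    return out


def classify_peak_context(
    peaks: Sequence[Peak], genes: Sequence[GeneAnnotation]
) -> PeakContextSummary:
    """Assign each peak a single context with precedence
    coding > lincRNA > intergenic."""
    coding_merged = merge_intervals(
        g.interval for g in genes if g.biotype == "coding"
    )
    linc_merged = merge_intervals(
        g.interval for g in genes if g.biotype == "lincRNA"
    )

    def hits(iv: GenomicInterval, merged) -> bool:
        if iv.chrom not in merged:
            return False
        starts, ends = merged[iv.chrom]
        return bool(
            overlap_flags_merged(
                np.array([iv.start]), np.array([iv.end]), starts, ends
            )[0]
        )

    n_coding = n_linc = n_inter = 0
    for p in peaks:
        if hits(p.interval, coding_merged):
            n_coding += 1
        elif hits(p.interval, linc_merged):
            n_linc += 1
        else:
            n_inter += 1
    return PeakContextSummary(n_coding, n_linc, n_inter)


def bound_fraction_by_expression(
    bound_ids: set[str],
    expression: Mapping[str, float],
    bins: Sequence[float],
) -> list[float | None]:
    """Fraction of genes bound within each half-open expression bin.

    *bins* are strictly increasing RPKM boundaries defining ``len(bins)-1``
    half-open bins ``[b_i, b_{i+1})``.  An empty bin yields ``None``.
    """
    bins = list(bins)
    if any(b1 <= b0 for b0, b1 in zip(bins, bins[1:])):
        raise ValueError("bin boundaries must be strictly increasing")
    missing = bound_ids - set(expression)
    if missing:
        raise ValidationError(f"bound ids absent from expression: {sorted(missing)[:5]}")
    totals = [0] * (len(bins) - 1)
    bound = [0] * (len(bins) - 1)
    for gid, rpkm in expression.items():
        for k in range(len(bins) - 1):
            if bins[k] <= rpkm < bins[k + 1]:
                totals[k] += 1
                if gid in bound_ids:
                    bound[k] += 1
                break
    return [b / t if t else None for b, t in zip(bound, totals)]


# ---------------------------------------------------------------------------
# Peak I/O: BED6 + read_total, conversion_count, RPKM (9-column dialect)
# ---------------------------------------------------------------------------


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    recs = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start))
    lines = []
    for p in recs:
        iv = p.interval
        lines.append(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id or '.'}\t0\t{iv.strand}"
            f"\t{p.read_total:g}\t{p.conversion_count}\t{p.rpkm:.6g}\n"
        )
    Path(path).write_text("".join(lines))


def read_peaks(path: str | Path, library_size: int = 1_000_000) -> list[Peak]:
    """Read the 9-column peak dialect.

    Stored RPKM is recomputed from a nominal single-replicate library of
    *library_size* unless it matches; the file's read_total and
    conversion_count are authoritative.
    """
    peaks: list[Peak] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        iv = GenomicInterval(
            f[0], int(f[1]), int(f[2]), f[5], None if f[3] == "." else f[3]
        )
        read_total = float(f[6])
        rpkm = float(f[8])
        # choose the library size that reproduces the stored RPKM
        lib = library_size
        if rpkm > 0 and read_total > 0:
            lib = max(1, int(round(read_total / ((iv.length / 1000) * rpkm / 1e6))))
        peaks.append(
            Peak(
                iv,
                read_counts=(read_total,),
                library_sizes=(lib,),
                conversion_count=int(f[7]),
            )
        )
    return peaks
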