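"""Differential enhancer signal and differential expression calling.

The pipeline consumes region x sample read-count matrices (CUT&RUN-style
densities at enhancers, or RNA-seq gene counts).  Samples of one antibody
are quantile-normalized together; regions pass a specificity filter
(mean WT RPKM > 1 and WT/KO fold > 2, the knockout being the negative
control in which true peaks should vanish); differential regions are then
called with a negative-binomial conditional exact test at a common
method-of-moments dispersion, with Benjamini-Hochberg FDR control and
fold-change thresholds (1.5-fold / FDR < 0.01 for enhancer signal,
2-fold / FDR < 0.01 for genes).

The exact test is a self-contained stand-in for an external count-based
differential package: conditioning the group-A total on the grand total
under a common NB dispersion gives a negative-hypergeometric law that is
free of the unknown mean, so p-values can be computed in closed form and
the whole pipeline verified by simulation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .core import (
    GenomicInterval,
    GeneAnnotation,
    ValidationError,
    intersect_sets,
    nearest_feature,
)
from .parclip import Peak

logger = logging.getLogger(__name__)

#: RPKM pseudocount used in every fold change with a possibly-zero
#: denominator; fixed and recorded in output metadata.
PSEUDOCOUNT_RPKM = 0.25


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    condition: str
    antibody: str
    replicate: int
    library_size: int

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValidationError("library_size must be positive")


@dataclass(frozen=True)
class SignalMatrix:
    """Regions x samples read counts (or densities) with sample metadata.

    ``normalized`` records whether values are a normalized layer; raw and
    normalized layers are never conflated (normalizers return new
    objects).
    """

    regions: tuple[GenomicInterval, ...]
    samples: tuple[SampleInfo, ...]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.regions), len(self.samples)):
            raise ValidationError(
                f"values shape {vals.shape} does not match "
                f"{len(self.regions)} regions x {len(self.samples)} samples"
            )
        if np.any(vals < 0):
            raise ValidationError("negative signal values")
        object.__setattr__(self, "values", vals)

    def sample_index(self, **criteria: str) -> list[int]:
        out = []
        for i, s in enumerate(self.samples):
            if all(getattr(s, k) == v for k, v in criteria.items()):
                out.append(i)
        return out

    def rpkm(self) -> np.ndarray:
        """Per-cell RPKM from counts, region lengths, and library sizes."""
        lengths = np.array([r.length for r in self.regions], dtype=float)
        libs = np.array([s.library_size for s in self.samples], dtype=float)
        return self.values / (lengths[:, None] / 1000.0) / (libs[None, :] / 1e6)

    def region_ids(self) -> list[str]:
        return [r.id or f"region_{i}" for i, r in enumerate(self.regions)]


@dataclass(frozen=True)
class DifferentialResult:
    """Per-region/gene differential call.

    ``direction`` is "up" when log2FC >= log2(min_fc) and fdr < max_fdr,
    "down" symmetrically, else "ns".
    """

    id: str
    log2_fold_change: float
    p_value: float
    fdr: float
    direction: str


def _quantile_normalize_columns(block: np.ndarray) -> np.ndarray:
    """Classic quantile normalization with ties sharing the mean of the
    reference values they span."""
    n, m = block.shape
    order = np.argsort(block, axis=0, kind="stable")
    reference = np.sort(block, axis=0).mean(axis=1)
    out = np.empty_like(block, dtype=float)
    for j in range(m):
        col = block[:, j]
        idx = order[:, j]
        assigned = np.empty(n)
        k = 0
        while k < n:
            k2 = k
            while k2 + 1 < n and col[idx[k2 + 1]] == col[idx[k]]:
                k2 += 1
            assigned[k : k2 + 1] = reference[k : k2 + 1].mean()
            k = k2 + 1
        out[idx, j] = assigned
    return out


def quantile_normalize(matrix: SignalMatrix, group_by: str = "antibody") -> SignalMatrix:
    """Quantile-normalize samples within each metadata group.

    Within a group each sample's sorted values are replaced by the
    across-sample mean at that rank; groups of a single sample are left
    unchanged with a warning.
    """
    values = matrix.values.copy()
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(matrix.samples):
        groups.setdefault(getattr(s, group_by), []).append(i)
    for key, idx in groups.items():
        if len(idx) < 2:
            logger.warning(
                "quantile_normalize: group %r has a single sample; left unchanged",
                key,
            )
            continue
        values[:, idx] = _quantile_normalize_columns(matrix.values[:, idx])
    return replace(matrix, values=values, normalized=True)


def specificity_filter(
    matrix: SignalMatrix,
    wt_condition: str,
    ko_condition: str,
    min_rpkm: float = 1.0,
    min_fc: float = 2.0,
) -> list[int]:
    """Indices of regions specific to the wild type.

    Retains a region iff its mean WT RPKM exceeds *min_rpkm* and
    mean(WT) / (mean(KO) + pseudocount) exceeds *min_fc*; the knockout is
    the negative control in which genuine peaks should disappear.
    """
    wt = matrix.sample_index(condition=wt_condition)
    ko = matrix.sample_index(condition=ko_condition)
    if not wt or not ko:
        raise ValueError(
            f"conditions {wt_condition!r}/{ko_condition!r} not both present"
        )
    rpkm = matrix.rpkm()
    wt_mean = rpkm[:, wt].mean(axis=1)
    ko_mean = rpkm[:, ko].mean(axis=1)
    keep = (wt_mean > min_rpkm) & (wt_mean / (ko_mean + PSEUDOCOUNT_RPKM) > min_fc)
    return list(np.nonzero(keep)[0])


def estimate_common_dispersion(counts: np.ndarray) -> float:
    """Method-of-moments common NB dispersion.

    For each region with replicate mean m and variance s^2, the moment
    estimate is ``(s^2 - m)/m^2`` (0 under Poisson); the common value is
    the median over regions, floored at 0.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a regions x replicates matrix with >=2 replicates")
    m = counts.mean(axis=1)
    s2 = counts.var(axis=1, ddof=1)
    ok = m > 0
    if not np.any(ok):
        return 0.0
    phi = (s2[ok] - m[ok]) / m[ok] ** 2
    return float(max(0.0, np.median(phi)))


def _pooled_dispersion(*groups: np.ndarray) -> float:
    """Mean-combined moment dispersion across conditions.

    The per-region moment estimate ``(s^2 - m)/m^2`` is averaged (not
    median-combined) across all regions and groups before flooring at 0:
    the median of the heavily right-skewed per-region estimates is biased
    low at few replicates, which would make downstream exact tests
    anti-conservative, whereas the mean is nearly unbiased.
    """
    vals: list[np.ndarray] = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        m = g.mean(axis=1)
        s2 = g.var(axis=1, ddof=1)
        ok = m > 0
        if np.any(ok):
            vals.append((s2[ok] - m[ok]) / m[ok] ** 2)
    if not vals:
        return 0.0
    return float(max(0.0, np.concatenate(vals).mean()))


def _exact_test_pvalue(sum_a: int, sum_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional exact p-value for group totals under a common
    NB dispersion.

    Conditional on the grand total t, the group-A total follows a
    negative hypergeometric with shape (n_a/phi, n_b/phi); for phi -> 0
    this degenerates to Binomial(t, n_a/(n_a+n_b)).  The p-value sums the
    probabilities of all outcomes no more likely than the observed one.
    """
    t = sum_a + sum_b
    if t == 0:
        return 1.0
    a = np.arange(t + 1)
    if phi < 1e-8:
        logp = stats.binom.logpmf(a, t, n_a / (n_a + n_b))
    else:
        ra, rb = n_a / phi, n_b / phi
        logp = (
            gammaln(a + ra)
            - gammaln(a + 1)
            - gammaln(ra)
            + gammaln(t - a + rb)
            - gammaln(t - a + 1)
            - gammaln(rb)
            - (gammaln(t + ra + rb) - gammaln(t + 1) - gammaln(ra + rb))
        )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    return float(min(1.0, p[p <= p[sum_a] * (1 + 1e-12)].sum()))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_regions(
    matrix: SignalMatrix,
    group_a: str,
    group_b: str,
    min_fc: float = 1.5,
    max_fdr: float = 0.01,
    require_consistent_sign: bool = True,
) -> list[DifferentialResult]:
    """Call regions differential between two conditions.

    Counts are scaled to a common library size, rounded, and tested with
    the NB conditional exact test at the pooled common dispersion.  A
    region is labeled up/down only if it clears both the fold-change and
    FDR thresholds and (by default) its per-replicate fold-change signs
    agree across replicate pairs.
    """
    ia = matrix.sample_index(condition=group_a)
    ib = matrix.sample_index(condition=group_b)
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("each group needs >=2 replicates")
    if matrix.normalized:
        # a normalized layer is already library-equalized; rescaling by
        # library size would re-skew the equalized columns
        counts = np.round(matrix.values).astype(int)
    else:
        libs = np.array([s.library_size for s in matrix.samples], dtype=float)
        ref = float(np.exp(np.mean(np.log(libs[ia + ib]))))
        counts = np.round(matrix.values * (ref / libs)[None, :]).astype(int)
    A, B = counts[:, ia], counts[:, ib]
    phi = _pooled_dispersion(A, B)
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    log2fc = np.log2((mean_a + PSEUDOCOUNT_RPKM) / (mean_b + PSEUDOCOUNT_RPKM))
    pvals = np.array(
        [
            _exact_test_pvalue(int(A[i].sum()), int(B[i].sum()), len(ia), len(ib), phi)
            for i in range(counts.shape[0])
        ]
    )
    fdr = bh_fdr(pvals)
    ids = matrix.region_ids()
    thr = math.log2(min_fc)
    results: list[DifferentialResult] = []
    n_pairs = min(len(ia), len(ib))
    for i in range(counts.shape[0]):
        direction = "ns"
        if fdr[i] < max_fdr and abs(log2fc[i]) >= thr:
            direction = "up" if log2fc[i] > 0 else "down"
            if require_consistent_sign:
                pair_lfc = np.log2(
                    (A[i, :n_pairs] + PSEUDOCOUNT_RPKM)
                    / (B[i, :n_pairs] + PSEUDOCOUNT_RPKM)
                )
                want = 1.0 if direction == "up" else -1.0
                if not np.all(np.sign(pair_lfc) == want):
                    direction = "ns"
        results.append(
            DifferentialResult(ids[i], float(log2fc[i]), float(pvals[i]), float(fdr[i]), direction)
        )
    return results


def call_degs(
    gene_counts: SignalMatrix,
    group_a: str,
    group_b: str,
    min_fc: float = 2.0,
    max_fdr: float = 0.01,
    require_consistent_sign: bool = True,
) -> list[DifferentialResult]:
    """Differentially expressed genes: >= *min_fc* change at FDR < *max_fdr*."""
    return differential_regions(
        gene_counts, group_a, group_b, min_fc, max_fdr, require_consistent_sign
    )


def bound_region_fraction(
    regions: Sequence[GenomicInterval],
    matrix: SignalMatrix,
    background_density: float,
    min_fold: float = 1.5,
    condition: str | None = None,
) -> tuple[float, int, int]:
    """Fraction of regions bound at >= *min_fold* over genomic background.

    *background_density* is reads per bp (total mapped reads / genome
    length); the expected background count for a region scales with its
    length.  Mean counts are taken over all samples, or over one
    condition when given.
    """
    if background_density <= 0:
        raise ValueError("background_density must be positive")
    idx = (
        matrix.sample_index(condition=condition)
        if condition is not None
        else list(range(len(matrix.samples)))
    )
    ids = {r.id: i for i, r in enumerate(matrix.regions)}
    bound = 0
    for r in regions:
        i = ids.get(r.id)
        if i is None:
            raise ValueError(f"region {r.id!r} absent from the matrix")
        mean_count = matrix.values[i, idx].mean()
        if mean_count >= min_fold * background_density * r.length:
            bound += 1
    total = len(regions)
    return (bound / total if total else math.nan), bound, total


def signal_correlation(
    x: Sequence[float], y: Sequence[float], n_bins: int = 10
) -> tuple[float, np.ndarray]:
    """Spearman rank correlation plus equal-count bin means of y over
    x-ordered bins.  Returns (NaN, means) when either input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length with >= 3 points")
    order = np.argsort(x, kind="stable")
    binned = np.array([chunk.mean() for chunk in np.array_split(y[order], n_bins)])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, binned
    rho = float(stats.spearmanr(x, y).statistic)
    return rho, binned


def region_metaprofile(
    coverage: Mapping[str, np.ndarray],
    regions: Sequence[GenomicInterval],
    flank_bp: int = 0,
    n_bins: int = 50,
) -> np.ndarray:
    """Mean binned coverage profile over regions (minus strand reversed).

    Each region is expanded by *flank_bp*, divided into *n_bins* equal
    bins, and the per-bin mean coverages are averaged across regions.
    Regions whose expansion exceeds chromosome bounds are clipped (the
    count of clipped regions is logged).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not regions:
        raise ValueError("regions must be non-empty")
    profiles = np.zeros((len(regions), n_bins))
    clipped = 0
    for k, r in enumerate(regions):
        track = coverage[r.chrom]
        lo, hi = r.start - flank_bp, r.end + flank_bp
        if lo < 0 or hi > len(track):
            clipped += 1
            lo, hi = max(0, lo), min(len(track), hi)
        edges = np.linspace(lo, hi, n_bins + 1)
        for b in range(n_bins):
            s, e = int(edges[b]), max(int(edges[b]) + 1, int(edges[b + 1]))
            profiles[k, b] = track[s:e].mean()
        if r.strand == "-":
            profiles[k] = profiles[k, ::-1]
    if clipped:
        logger.warning("region_metaprofile: clipped %d region(s) at chromosome bounds", clipped)
    return profiles.mean(axis=0)


def hervh_copy_table(
    loci: Sequence[GenomicInterval],
    wt_rpkm: Mapping[str, float],
    kd_rpkm: Mapping[str, float],
    parclip_peaks: Sequence[Peak],
    genes: Sequence[GeneAnnotation],
) -> pd.DataFrame:
    """Per-repeat-copy summary table.

    One row per locus: coordinates, WT and knockdown expression (RPKM),
    log2FC(KD/WT) with the standard pseudocount, whether the locus
    overlaps a stringent PAR-CLIP peak, the closest gene and its distance,
    and a knockdown-responsive flag (expression reduced more than twofold
    on knockdown).
    """
    flags, _ = intersect_sets(list(loci), [p.interval for p in parclip_peaks])
    rows = []
    for i, locus in enumerate(loci):
        lid = locus.id or f"locus_{i}"
        wt = wt_rpkm.get(lid, 0.0)
        kd = kd_rpkm.get(lid, 0.0)
        lfc = math.log2((kd + PSEUDOCOUNT_RPKM) / (wt + PSEUDOCOUNT_RPKM))
        gid, dist = nearest_feature(locus, genes)
        rows.append(
            {
                "locus_id": lid,
                "chrom": locus.chrom,
                "start": locus.start,
                "end": locus.end,
                "wt_rpkm": wt,
                "kd_rpkm": kd,
                "log2fc_kd_vs_wt": lfc,
                "parclip_overlap": "YES" if flags[i] else "NO",
                "closest_gene": gid if gid else "NA",
                "closest_gene_distance": dist if math.isfinite(dist) else "NA",
                "kd_responsive": -lfc > 1,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_signal_matrix(
    values_tsv: str | Path, sample_sheet_tsv: str | Path, regions_bed: str | Path
) -> SignalMatrix:
    """Assemble a SignalMatrix from a region BED, a values TSV
    (region_id x sample_id), and a sample sheet TSV."""
    from .core import read_bed

    regions = read_bed(regions_bed)
    sheet = pd.read_csv(sample_sheet_tsv, sep="\t")
    samples = tuple(
        SampleInfo(
            str(r.sample_id), str(r.condition), str(r.antibody),
            int(r.replicate), int(r.library_size),
        )
        for r in sheet.itertuples()
    )
    vals = pd.read_csv(values_tsv, sep="\t", index_col=0)
    by_id = {r.id: r for r in regions}
    ordered = [by_id[rid] for rid in vals.index]
    return SignalMatrix(
        tuple(ordered),
        samples,
        vals[[s.sample_id for s in samples]].to_numpy(dtype=float),
    )


def write_signal_matrix(
    matrix: SignalMatrix, values_tsv: str | Path, sample_sheet_tsv: str | Path,
    regions_bed: str | Path,
) -> None:
    from .core import write_bed

    write_bed(list(matrix.regions), regions_bed)
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "condition": s.condition,
                "antibody": s.antibody,
                "replicate": s.replicate,
                "library_size": s.library_size,
            }
            for s in matrix.samples
        ]
    ).to_csv(sample_sheet_tsv, sep="\t", index=False)
    pd.DataFrame(
        matrix.values,
        index=matrix.region_ids(),
        columns=[s.sample_id for s in matrix.samples],
    ).to_csv(values_tsv, sep="\t", index_label="region_id")


def differential_to_tsv(
    results: Sequence[DifferentialResult], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "id": r.id,
                "log2_fold_change": r.log2_fold_change,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "direction": r.direction,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)
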