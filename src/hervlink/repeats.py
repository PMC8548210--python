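"""Repeat-family overlap statistics against a matched-random-loci null.

The question: does a peak set overlap a given repeat family (HERVH, L1,
SINE, ...) more often than the same number of random genomic loci of the
same lengths would?  The null is built by drawing, per iteration, a
length-matched random locus set; the observed overlap count is compared to
the null mean/SD as a Gaussian Z-score, with a plus-one-smoothed empirical
P reported alongside to guard against non-normal nulls at small iteration
counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    GenomeLayout,
    GenomicInterval,
    ValidationError,
    merge_intervals,
    overlap_flags_merged,
)
from .parclip import Peak


@dataclass(frozen=True)
class RepeatAnnotation:
    """A RepeatMasker-style repeat copy with its family label."""

    interval: GenomicInterval
    family: str

    def __post_init__(self) -> None:
        if not self.family:
            raise ValidationError("repeat family label must be non-empty")


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed statistic versus a permutation null.

    ``fold = observed / null_mean``; ``z = (observed - null_mean)/null_sd``
    (NaN when the null is degenerate); ``p_gauss`` is the one-sided
    upper-tail normal probability; ``p_emp = (1 + #{null >= observed}) /
    (n_iter + 1)`` so it never reaches zero.  ``p_gauss_lower`` reports the
    depletion tail separately.
    """

    observed: float
    null_mean: float
    null_sd: float
    fold: float
    z: float
    p_gauss: float
    p_emp: float
    n_iter: int
    seed: int
    p_gauss_lower: float = math.nan
    null_skewness: float = math.nan

    @classmethod
    def from_null(
        cls, observed: float, null: np.ndarray, seed: int
    ) -> "EnrichmentResult":
        null = np.asarray(null, dtype=float)
        n_iter = null.size
        if n_iter < 1:
            raise ValueError("need at least one null iteration")
        mu = float(null.mean())
        sd = float(null.std(ddof=1)) if n_iter > 1 else 0.0
        fold = observed / mu if mu > 0 else math.inf if observed > 0 else math.nan
        if sd > 0:
            z = (observed - mu) / sd
            p_gauss = float(stats.norm.sf(z))
            p_lower = float(stats.norm.cdf(z))
        else:
            z = math.nan
            p_gauss = math.nan
            p_lower = math.nan
        p_emp = (1 + int(np.sum(null >= observed))) / (n_iter + 1)
        skew = float(stats.skew(null)) if n_iter > 2 and sd > 0 else math.nan
        return cls(
            observed=float(observed),
            null_mean=mu,
            null_sd=sd,
            fold=fold,
            z=z,
            p_gauss=p_gauss,
            p_emp=p_emp,
            n_iter=n_iter,
            seed=seed,
            p_gauss_lower=p_lower,
            null_skewness=skew,
        )


def _family_merged(
    repeats: Sequence[RepeatAnnotation],
) -> dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]:
    fams: dict[str, list[GenomicInterval]] = {}
    for r in repeats:
        fams.setdefault(r.family, []).append(r.interval)
    return {fam: merge_intervals(ivs) for fam, ivs in fams.items()}


def _count_overlaps(
    intervals: Sequence[GenomicInterval] | tuple[np.ndarray, ...],
    merged: dict[str, tuple[np.ndarray, np.ndarray]],
) -> int:
    """Count intervals overlapping (>=1 bp) the merged family runs."""
    total = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:  # type: ignore[union-attr]
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, pairs in by_chrom.items():
        if chrom not in merged:
            continue
        starts = np.array([p[0] for p in pairs])
        ends = np.array([p[1] for p in pairs])
        ms, me = merged[chrom]
        total += int(overlap_flags_merged(starts, ends, ms, me).sum())
    return total


def family_overlap_fraction(
    peaks: Sequence[Peak], repeats: Sequence[RepeatAnnotation]
) -> dict[str, float]:
    """Per-family fraction of peaks overlapping >=1 repeat of the family.

    A peak overlapping several families counts once for each; several
    copies of one family count once.
    """
    if not peaks:
        raise ValueError("empty peak list")
    fams = _family_merged(repeats)
    ivs = [p.interval for p in peaks]
    return {fam: _count_overlaps(ivs, merged) / len(peaks) for fam, merged in fams.items()}


def sample_matched_random_loci(
    template: Sequence[GenomicInterval],
    genome: GenomeLayout,
    rng: np.random.Generator | int,
    exclusions: Sequence[GenomicInterval] | None = None,
    mode: str = "genome_wide",
    max_attempts: int = 1000,
) -> list[GenomicInterval]:
    """Draw length-matched random loci, uniform over valid start positions.

    For each template interval a chromosome is chosen with probability
    proportional to its number of valid starts (``genome_wide`` mode) or
    fixed to the template's chromosome (``same_chromosome`` mode), then a
    start is drawn uniformly.  Draws overlapping *exclusions* are rejected
    and redrawn.  Loci may overlap each other.
    """
    if mode not in ("genome_wide", "same_chromosome"):
        raise ValueError(f"unknown placement mode {mode!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    excl = merge_intervals(exclusions) if exclusions else None
    chrom_names = list(genome.chromosomes)
    chrom_lens = np.array([genome.chromosomes[c] for c in chrom_names])
    out: list[GenomicInterval] = []
    for t in template:
        L = t.length
        if mode == "same_chromosome":
            cands = [chrom_names.index(t.chrom)]
            weights = np.array([1.0])
        else:
            valid = np.maximum(chrom_lens - L + 1, 0)
            if valid.sum() == 0:
                raise ValueError(
                    f"template length {L} exceeds every chromosome"
                )
            cands = list(range(len(chrom_names)))
            weights = valid / valid.sum()
        placed = False
        for _ in range(max_attempts):
            ci = int(rng.choice(cands, p=weights)) if len(cands) > 1 else cands[0]
            n_starts = chrom_lens[ci] - L + 1
            if n_starts <= 0:
                raise ValueError(
                    f"template length {L} exceeds chromosome {chrom_names[ci]}"
                )
            start = int(rng.integers(0, n_starts))
            iv = GenomicInterval(chrom_names[ci], start, start + L, t.strand, t.id)
            if excl is not None and iv.chrom in excl:
                ms, me = excl[iv.chrom]
                if overlap_flags_merged(
                    np.array([iv.start]), np.array([iv.end]), ms, me
                )[0]:
                    continue
            out.append(iv)
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place a {L}-bp locus outside exclusions "
                f"after {max_attempts} attempts"
            )
    return out


def run_permutations(
    n_iter: int,
    seed: int,
    one_iteration,
    threads: int = 1,
):
    """Run *n_iter* seeded null iterations, optionally across threads.

    Each iteration receives its own child generator spawned from *seed*,
    so the null stream is identical for every thread count.
    ``one_iteration(rng)`` returns the iteration's statistic(s).
    """
    if threads < 1:
        raise ValueError("threads must be >= 1")
    seqs = np.random.SeedSequence(seed).spawn(n_iter)
    rngs = [np.random.default_rng(s) for s in seqs]
    if threads == 1:
        return [one_iteration(r) for r in rngs]
    from concurrent.futures import ThreadPoolExecutor

    with ThreadPoolExecutor(max_workers=threads) as pool:
        return list(pool.map(one_iteration, rngs))


def repeat_family_enrichment(
    peaks: Sequence[Peak],
    repeats: Sequence[RepeatAnnotation],
    genome: GenomeLayout,
    n_iter: int = 1000,
    seed: int = 0,
    mode: str = "genome_wide",
    threads: int = 1,
) -> dict[str, EnrichmentResult]:
    """Per-family enrichment of peak overlap against matched random loci."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not peaks:
        raise ValueError("empty peak list")
    fams = _family_merged(repeats)
    fam_names = list(fams)
    template = [p.interval for p in peaks]
    observed = {
        fam: _count_overlaps(template, merged) for fam, merged in fams.items()
    }

    def one(rng: np.random.Generator) -> list[int]:
        loci = sample_matched_random_loci(template, genome, rng, mode=mode)
        return [_count_overlaps(loci, fams[fam]) for fam in fam_names]

    rows = np.asarray(run_permutations(n_iter, seed, one, threads), dtype=float)
    return {
        fam: EnrichmentResult.from_null(observed[fam], rows[:, k], seed)
        for k, fam in enumerate(fam_names)
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_repeat_bed(path: str | Path) -> list[RepeatAnnotation]:
    """BED6 with the family label in the name column."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        iv = GenomicInterval(f[0], int(f[1]), int(f[2]), f[5] if len(f) > 5 else ".")
        out.append(RepeatAnnotation(iv, family=f[3]))
    return out


def write_repeat_bed(repeats: Sequence[RepeatAnnotation], path: str | Path) -> None:
    recs = sorted(repeats, key=lambda r: (r.interval.chrom, r.interval.start))
    lines = [
        f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
        f"{r.family}\t0\t{r.interval.strand}\n"
        for r in recs
    ]
    Path(path).write_text("".join(lines))


def read_repeatmasker_out(path: str | Path) -> list[RepeatAnnotation]:
    """Parse RepeatMasker ``.out`` (whitespace-delimited, 1-based inclusive
    coordinates, converted here to 0-based half-open).

    The repeat name column (e.g. ``HERVH-int``) is used verbatim as the
    family label; class/family strings like ``LTR/ERV1`` are ignored.
    """
    out: list[RepeatAnnotation] = []
    for line in Path(path).read_text().splitlines():
        f = line.split()
        if len(f) < 11 or not f[0].replace(".", "").isdigit():
            continue  # header / blank lines
        chrom, begin, end = f[4], int(f[5]), int(f[6])
        strand = "+" if f[8] == "+" else "-"
        name = f[9]
        out.append(
            RepeatAnnotation(GenomicInterval(chrom, begin - 1, end, strand), name)
        )
    return out


def enrichment_to_tsv(
    results: dict[str, EnrichmentResult], path: str | Path
) -> None:
    rows = []
    for fam in sorted(results):
        r = results[fam]
        rows.append(
            {
                "family": fam,
                "observed": r.observed,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "fold": r.fold,
                "z": r.z,
                "p_gauss": r.p_gauss,
                "p_gauss_lower": r.p_gauss_lower,
                "p_emp": r.p_emp,
                "null_skewness": r.null_skewness,
                "n_iter": r.n_iter,
                "seed": r.seed,
            }
        )
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(f"# seed={rows[0]['seed'] if rows else 'NA'}\n")
        df.to_csv(fh, sep="\t", index=False)
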