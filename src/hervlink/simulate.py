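"""Synthetic toy genomes with planted truth for every pipeline stage.

The generator emulates the statistical structure the analyses assume —
repeat families with one family enriched in a peak set, multi-replicate
negative-binomial count matrices with planted condition effects, spatial
clustering of differentially expressed genes near affected enhancers, and
Hill-law titrations — at a scale (two 1-Mb chromosomes by default) where
the full pipeline runs in a couple of minutes.  No sequence is simulated:
all artifacts are coordinates, counts, and curves.

Every generator is a pure function of its inputs and a seed; all
randomness flows from one master seed through named substreams so each
stage reproduces in isolation.  Planted truth is kept in a separate
:class:`SyntheticTruth` object and never leaks into emitted data files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import (
    GeneAnnotation,
    GenomeLayout,
    GenomicInterval,
    merge_intervals,
    overlap_flags_merged,
)
from .curves import BindingCurve
from .diffsignal import SampleInfo, SignalMatrix
from .parclip import Peak
from .repeats import RepeatAnnotation

#: default repeat-family composition: (copies per Mb, mean length bp).
#: Coverage works out near 25%, comparable to the LTR+LINE+SINE load of a
#: mammalian genome, with HERVH the sparsest family.
DEFAULT_FAMILIES: dict[str, tuple[int, int]] = {
    "HERVH": (30, 600),
    "HERVK": (40, 900),
    "HERVL": (40, 900),
    "L1": (60, 1500),
    "L2": (50, 800),
    "SINE": (150, 300),
}

_STREAMS = {
    "genome": 1,
    "parclip": 2,
    "signal": 3,
    "proximity": 4,
    "curves": 5,
    "expression": 6,
}


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Named child RNG of the master seed (stage-level reproducibility)."""
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(_STREAMS[name],))
    )


@dataclass
class SyntheticTruth:
    """Planted ground truth, serialized separately from emitted data."""

    seed: int
    genome_lengths: dict[str, int] = field(default_factory=dict)
    target_family: str = ""
    planted_enrichment_factor: float = 1.0
    realized_target_overlap_rate: float = math.nan
    background_target_overlap_rate: float = math.nan
    planted_differential: dict[str, float] = field(default_factory=dict)
    planted_degs: dict[str, float] = field(default_factory=dict)
    planted_proximity_fold: float = math.nan
    expected_near_count: float = math.nan
    realized_near_count: int = -1
    dispersion: float = math.nan
    conversion_rate: float = math.nan
    hill_params: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def _place_non_overlapping(
    layout: GenomeLayout,
    lengths: Sequence[int],
    rng: np.random.Generator,
    prefix: str,
) -> list[GenomicInterval]:
    """Place features non-overlappingly, chromosomes loaded proportionally
    to length, free space distributed as Dirichlet gaps (uniform
    exchangeable spacing).  Raises when the features cannot pack."""
    chroms = list(layout.chromosomes)
    clens = np.array([layout.chromosomes[c] for c in chroms], dtype=float)
    assign = rng.choice(len(chroms), size=len(lengths), p=clens / clens.sum())
    intervals: list[GenomicInterval] = []
    counter = 0
    for ci, chrom in enumerate(chroms):
        lens = [lengths[k] for k in range(len(lengths)) if assign[k] == ci]
        if not lens:
            continue
        free = layout.chromosomes[chrom] - sum(lens)
        if free < 0:
            raise ValueError(
                f"features ({sum(lens)} bp) exceed chromosome {chrom} "
                f"({layout.chromosomes[chrom]} bp)"
            )
        order = rng.permutation(len(lens))
        gaps = rng.dirichlet(np.ones(len(lens) + 1)) * free
        pos = 0.0
        for g, k in zip(gaps, order):
            pos += g
            start = int(pos)
            intervals.append(
                GenomicInterval(
                    chrom, start, start + lens[k],
                    strand="+" if rng.random() < 0.5 else "-",
                    id=f"{prefix}_{counter}",
                )
            )
            counter += 1
            pos = start + lens[k]
    return intervals


def make_genome(
    n_chroms: int = 2,
    lengths: Sequence[int] | None = None,
    seed: int = 0,
    families: Mapping[str, tuple[int, int]] | None = None,
    n_enhancers: int = 300,
    n_genes: int = 400,
    gene_length_mean: int = 2000,
    enhancer_length_mean: int = 800,
) -> tuple[
    GenomeLayout,
    list[RepeatAnnotation],
    list[GenomicInterval],
    list[GeneAnnotation],
]:
    """Build a toy genome with repeats, enhancers, and gene models.

    Family copy numbers in *families* are per Mb; each feature class is
    internally non-overlapping, classes are placed independently.
    """
    if lengths is None:
        lengths = [1_000_000] * n_chroms
    if any(l <= 0 for l in lengths):
        raise ValueError("chromosome lengths must be positive")
    layout = GenomeLayout({f"chr{i+1}": int(l) for i, l in enumerate(lengths)})
    rng = substream(seed, "genome")
    families = dict(families or DEFAULT_FAMILIES)
    mb = layout.total_bp / 1e6

    fam_lengths: list[int] = []
    fam_labels: list[str] = []
    for fam, (per_mb, mean_len) in families.items():
        n = max(1, int(round(per_mb * mb)))
        ls = np.maximum(
            20, rng.lognormal(math.log(mean_len), 0.3, size=n)
        ).astype(int)
        fam_lengths.extend(int(v) for v in ls)
        fam_labels.extend([fam] * n)
    perm = rng.permutation(len(fam_lengths))
    rep_ivs = _place_non_overlapping(
        layout, [fam_lengths[k] for k in perm], rng, "rep"
    )
    repeats = [
        RepeatAnnotation(iv, fam_labels[perm[k]]) for k, iv in enumerate(rep_ivs)
    ]

    enh_lens = np.maximum(
        100, rng.lognormal(math.log(enhancer_length_mean), 0.3, size=n_enhancers)
    ).astype(int)
    enhancers = _place_non_overlapping(layout, [int(v) for v in enh_lens], rng, "enh")

    gene_lens = np.maximum(
        300, rng.lognormal(math.log(gene_length_mean), 0.5, size=n_genes)
    ).astype(int)
    gene_ivs = _place_non_overlapping(layout, [int(v) for v in gene_lens], rng, "gene")
    biotypes = rng.choice(
        GeneAnnotation.BIOTYPES, size=len(gene_ivs), p=[0.7, 0.15, 0.15]
    )
    genes = [
        GeneAnnotation(iv, gene_id=iv.id or f"gene_{k}", biotype=str(biotypes[k]))
        for k, iv in enumerate(gene_ivs)
    ]
    return layout, repeats, enhancers, genes


def _overlap_probability(
    layout: GenomeLayout,
    merged: dict[str, tuple[np.ndarray, np.ndarray]],
    peak_len: int,
) -> float:
    """Probability that a uniformly placed peak of *peak_len* overlaps the
    merged runs (boundary effects of run spacing ignored; runs are far
    apart relative to peak length at default scales)."""
    total_starts = sum(
        max(0, layout.chromosomes[c] - peak_len + 1) for c in layout.chromosomes
    )
    hit_starts = 0.0
    for chrom, (ms, me) in merged.items():
        hit_starts += float(np.sum(me - ms + peak_len - 1))
    return min(1.0, hit_starts / total_starts)


def simulate_parclip(
    layout: GenomeLayout,
    repeats: Sequence[RepeatAnnotation],
    target_family: str = "HERVH",
    enrichment_factor: float = 5.0,
    n_peaks: int = 1000,
    conversion_rate: float = 0.1,
    seed: int = 0,
    peak_length_mean: int = 300,
    read_mean: float = 20.0,
    emit_replicates: bool = True,
    library_size: int = 1_000_000,
) -> tuple[list[Peak], list[Peak], list[Peak], SyntheticTruth]:
    """Plant peaks overlapping *target_family* at *enrichment_factor*
    times the uniform background rate.

    Returns (replicate-1 peaks, replicate-2 peaks, conversion clusters,
    truth).  Replicate 2 is a jittered 90% subset of replicate 1;
    conversion clusters are sub-intervals of 85% of peaks, each carrying
    at least one conversion read.
    """
    if enrichment_factor < 0:
        raise ValueError("enrichment_factor must be >= 0")
    rng = substream(seed, "parclip")
    target = merge_intervals(
        r.interval for r in repeats if r.family == target_family
    )
    if not any(s.size for s, _ in target.values()):
        raise ValueError(f"no repeats of family {target_family!r}")
    p0 = _overlap_probability(layout, target, peak_length_mean)
    q = enrichment_factor * p0
    if q > 1:
        raise ValueError(
            f"enrichment factor {enrichment_factor} unattainable: background "
            f"overlap rate {p0:.4f} caps the factor at {1 / p0:.2f}"
        )
    chroms = list(layout.chromosomes)
    clens = np.array([layout.chromosomes[c] for c in chroms], dtype=float)

    def draw_uniform(L: int) -> GenomicInterval:
        valid = np.maximum(clens - L + 1, 0)
        ci = int(rng.choice(len(chroms), p=valid / valid.sum()))
        s = int(rng.integers(0, clens[ci] - L + 1))
        return GenomicInterval(chroms[ci], s, s + L)

    def overlaps_target(iv: GenomicInterval) -> bool:
        if iv.chrom not in target:
            return False
        ms, me = target[iv.chrom]
        return bool(
            overlap_flags_merged(np.array([iv.start]), np.array([iv.end]), ms, me)[0]
        )

    rep1: list[Peak] = []
    n_hit = 0
    for k in range(n_peaks):
        L = max(50, int(rng.lognormal(math.log(peak_length_mean), 0.3)))
        want_hit = rng.random() < q
        for _ in range(10_000):
            iv = draw_uniform(L)
            if overlaps_target(iv) == want_hit:
                break
        else:  # pragma: no cover - unattainable at default scales
            raise ValueError("rejection sampling failed to satisfy overlap status")
        n_hit += int(want_hit)
        reads = max(3, int(rng.lognormal(math.log(read_mean), 1.2)))
        conv = int(rng.binomial(reads, conversion_rate))
        rep1.append(
            Peak(
                GenomicInterval(iv.chrom, iv.start, iv.end, id=f"peak_{k}"),
                read_counts=(float(reads),),
                library_sizes=(library_size,),
                conversion_count=conv,
            )
        )

    rep2: list[Peak] = []
    clusters: list[Peak] = []
    if emit_replicates:
        for p in rep1:
            iv = p.interval
            if rng.random() < 0.9:
                shift = int(rng.integers(-30, 31))
                s = max(0, iv.start + shift)
                e = min(layout.length(iv.chrom), iv.end + shift)
                if e > s:
                    rep2.append(
                        Peak(
                            GenomicInterval(iv.chrom, s, e, id=f"{iv.id}_rep2"),
                            read_counts=p.read_counts,
                            library_sizes=p.library_sizes,
                        )
                    )
            if rng.random() < 0.85:
                cl = min(40, iv.length)
                off = int(rng.integers(0, iv.length - cl + 1))
                clusters.append(
                    Peak(
                        GenomicInterval(
                            iv.chrom, iv.start + off, iv.start + off + cl,
                            id=f"{iv.id}_cluster",
                        ),
                        read_counts=(max(1.0, p.read_total * 0.5),),
                        library_sizes=p.library_sizes,
                        conversion_count=max(1, p.conversion_count),
                    )
                )

    truth = SyntheticTruth(
        seed=seed,
        genome_lengths=dict(layout.chromosomes),
        target_family=target_family,
        planted_enrichment_factor=enrichment_factor,
        realized_target_overlap_rate=n_hit / n_peaks,
        background_target_overlap_rate=p0,
        conversion_rate=conversion_rate,
    )
    return rep1, rep2, clusters, truth


def simulate_signal_matrix(
    regions: Sequence[GenomicInterval],
    conditions: Sequence[str] = ("WT", "KO"),
    n_replicates: int = 4,
    planted: Mapping[str, float] | None = None,
    dispersion: float = 0.1,
    base_mean: float = 100.0,
    antibody: str = "H3K27ac",
    lib_jitter: float = 0.2,
    region_mean_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[SignalMatrix, SyntheticTruth]:
    """Negative-binomial counts with planted condition effects.

    *planted* maps region id -> fold applied to the second condition
    (fold < 1 means the signal drops there, the knockout direction).
    Library sizes are jittered by +-*lib_jitter* and expected counts
    scale with them.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if base_mean <= 0:
        raise ValueError("base_mean must be positive")
    if len(conditions) != 2:
        raise ValueError("exactly two conditions are supported")
    rng = substream(seed, "signal")
    planted = dict(planted or {})
    ids = [r.id or f"region_{i}" for i, r in enumerate(regions)]
    unknown = set(planted) - set(ids)
    if unknown:
        raise ValueError(f"planted ids absent from regions: {sorted(unknown)[:5]}")

    samples: list[SampleInfo] = []
    libs: list[int] = []
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            lib = int(round(1e6 * rng.uniform(1 - lib_jitter, 1 + lib_jitter)))
            samples.append(SampleInfo(f"{cond}_rep{rep}", cond, antibody, rep, lib))
            libs.append(lib)

    base = (
        base_mean
        * np.exp(rng.normal(0.0, region_mean_sigma, size=len(regions)))
        if region_mean_sigma > 0
        else np.full(len(regions), base_mean)
    )
    values = np.zeros((len(regions), len(samples)))
    for j, s in enumerate(samples):
        lib_factor = libs[j] / 1e6
        for i, rid in enumerate(ids):
            fold = planted.get(rid, 1.0) if s.condition == conditions[1] else 1.0
            mu = base[i] * fold * lib_factor
            if dispersion < 1e-12:
                values[i, j] = rng.poisson(mu)
            else:
                r = 1.0 / dispersion
                values[i, j] = rng.negative_binomial(r, r / (r + mu))
    matrix = SignalMatrix(tuple(regions), tuple(samples), values)
    truth = SyntheticTruth(
        seed=seed,
        planted_differential=dict(planted),
        dispersion=dispersion,
    )
    return matrix, truth


def genes_near_enhancers(
    enhancers: Sequence[GenomicInterval],
    genes: Sequence[GeneAnnotation],
    window_bp: int,
) -> np.ndarray:
    """Boolean flag per gene: within *window_bp* of some enhancer."""
    from .proximity import count_features_within  # single-source the rule

    return np.array(
        [count_features_within(enhancers, [g], window_bp) == 1 for g in genes]
    )


def simulate_proximity(
    enhancers: Sequence[GenomicInterval],
    genes: Sequence[GeneAnnotation],
    planted_fold: float = 3.0,
    window_bp: int = 100_000,
    n_degs: int = 50,
    seed: int = 0,
) -> tuple[list[str], SyntheticTruth]:
    """Assign DEG labels so the expected near-enhancer DEG count is
    *planted_fold* times the uniform-assignment expectation."""
    if planted_fold < 1:
        raise ValueError("planted_fold must be >= 1")
    rng = substream(seed, "proximity")
    near = genes_near_enhancers(enhancers, genes, window_bp)
    n_near = int(near.sum())
    G = len(genes)
    if n_degs > G:
        raise ValueError("more DEGs requested than genes available")
    expected_uniform = n_degs * n_near / G
    k_near = int(round(planted_fold * expected_uniform))
    if k_near > min(n_near, n_degs):
        raise ValueError(
            f"planted fold {planted_fold} exceeds the geometric maximum "
            f"{min(n_near, n_degs) / expected_uniform:.2f} for this layout"
        )
    near_idx = np.nonzero(near)[0]
    far_idx = np.nonzero(~near)[0]
    n_far = n_degs - k_near
    if n_far > far_idx.size:
        raise ValueError("not enough far genes for the requested DEG count")
    chosen = np.concatenate(
        [
            rng.choice(near_idx, size=k_near, replace=False),
            rng.choice(far_idx, size=n_far, replace=False),
        ]
    )
    deg_ids = sorted(genes[int(i)].gene_id for i in chosen)
    truth = SyntheticTruth(
        seed=seed,
        planted_proximity_fold=planted_fold,
        expected_near_count=planted_fold * expected_uniform,
        realized_near_count=k_near,
        planted_degs={gid: math.nan for gid in deg_ids},
    )
    return deg_ids, truth


def simulate_binding_curve(
    bmax: float,
    kd: float,
    h: float,
    x: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "curve",
) -> tuple[BindingCurve, SyntheticTruth]:
    """Hill-law titration with additive Gaussian noise, clipped to
    [0, 1.05*Bmax]."""
    if kd <= 0:
        raise ValueError("Kd must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = substream(seed, "curves")
    xs = np.asarray(x, dtype=float)
    y = bmax * xs**h / (kd**h + xs**h)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=xs.size)
    y = np.clip(y, 0.0, 1.05 * bmax)
    curve = BindingCurve(tuple(float(v) for v in xs), tuple(float(v) for v in y), label=label)
    truth = SyntheticTruth(
        seed=seed,
        hill_params={label: {"bmax": bmax, "kd": kd, "h": h, "noise_sd": noise_sd}},
    )
    return curve, truth


def simulate_expression(
    genes: Sequence[GeneAnnotation],
    deg_ids: Sequence[str],
    deg_fold: float = 4.0,
    n_replicates: int = 3,
    dispersion: float = 0.05,
    base_mean: float = 100.0,
    seed: int = 0,
) -> tuple[SignalMatrix, SyntheticTruth]:
    """Gene-level count matrix with the chosen DEG set planted at
    *deg_fold* (up in the second condition)."""
    planted = {gid: deg_fold for gid in deg_ids}
    matrix, truth = simulate_signal_matrix(
        [g.interval for g in genes],
        conditions=("WT", "KD"),
        n_replicates=n_replicates,
        planted=planted,
        dispersion=dispersion,
        base_mean=base_mean,
        antibody="RNA",
        seed=seed,
    )
    truth.planted_degs = dict(planted)
    return matrix, truth
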