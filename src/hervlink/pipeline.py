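"""End-to-end orchestration: simulate -> PAR-CLIP filter -> repeat
enrichment -> differential signal -> proximity permutation -> curves.

A :class:`RunConfig` carries every stage parameter; defaults are the
analysis thresholds used throughout the package (RPKM cutoff 10,
specificity min RPKM 1 and fold 2, differential 1.5-fold / FDR 0.01,
DEG 2-fold / FDR 0.01, 100-kb proximity window, 1,000 permutations).
Runs are deterministic per master seed; the manifest lists every artifact
with a SHA-256 digest and contains no timestamps, so two runs from one
config are byte-identical (timestamps appear only in the log).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import diffsignal, parclip, proximity, repeats, simulate
from .core import write_bed, write_chrom_sizes, write_gene_bed
from .curves import fit_hill, fits_to_tsv
from .diffsignal import differential_to_tsv, write_signal_matrix
from .parclip import write_peaks
from .repeats import enrichment_to_tsv, write_repeat_bed

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters; round-trips through YAML."""

    seed: int = 0
    outdir: str = "hervlink_run"
    #: worker threads for the permutation loops only; results are
    #: identical for any value (per-iteration seeds are pre-spawned)
    threads: int = 1
    # synthetic genome
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_enhancers: int = 300
    n_genes: int = 400
    # PAR-CLIP simulation + filtering
    target_family: str = "HERVH"
    enrichment_factor: float = 5.0
    n_peaks: int = 1000
    conversion_rate: float = 0.1
    rpkm_cutoff: float = 10.0
    # repeat enrichment
    repeat_n_iter: int = 1000
    # differential signal
    n_replicates: int = 4
    base_mean: float = 100.0
    dispersion: float = 0.1
    n_diff_enhancers: int = 20
    diff_fold: float = 4.0
    specificity_min_rpkm: float = 1.0
    specificity_min_fc: float = 2.0
    diff_min_fc: float = 1.5
    diff_max_fdr: float = 0.01
    deg_min_fc: float = 2.0
    deg_max_fdr: float = 0.01
    # proximity
    window_bp: int = 100_000
    proximity_n_iter: int = 1000
    proximity_planted_fold: float = 1.0
    n_degs: int = 50
    shuffle_mode: str = "genome_wide"
    # binding curves
    curve_specs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "segment_strong": {"bmax": 1.0, "kd": 7.7, "h": 1.5, "noise_sd": 0.03},
            "segment_weak": {"bmax": 1.0, "kd": 13.1, "h": 1.5, "noise_sd": 0.03},
        }
    )
    write_plots: bool = False

    def validate(self) -> None:
        if self.repeat_n_iter < 1 or self.proximity_n_iter < 1:
            raise ValueError("permutation iteration counts must be >= 1")
        if self.n_chroms < 1 or self.chrom_length < 1:
            raise ValueError("invalid genome specification")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage on a synthetic dataset; returns the manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("hervlink")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest: dict[str, Any] = {
        "config": dataclasses.asdict(config),
        "stages": [],
        "artifacts": {},
        "warnings": 0,
    }
    artifacts: list[Path] = []

    def emit(name: str, path: Path) -> None:
        artifacts.append(path)

    try:
        logger.info("stage simulate: genome + annotations (seed=%d)", config.seed)
        layout, reps, enhancers, genes = simulate.make_genome(
            n_chroms=config.n_chroms,
            lengths=[config.chrom_length] * config.n_chroms,
            seed=config.seed,
            n_enhancers=config.n_enhancers,
            n_genes=config.n_genes,
        )
        write_chrom_sizes(layout, out / "genome.chrom.sizes")
        write_repeat_bed(reps, out / "repeats.bed")
        write_bed(enhancers, out / "enhancers.bed")
        write_gene_bed(genes, out / "genes.bed")
        for f in ("genome.chrom.sizes", "repeats.bed", "enhancers.bed", "genes.bed"):
            emit("simulate", out / f)
        manifest["stages"].append("simulate")

        logger.info("stage parclip: %d peaks, planted %gx %s",
                    config.n_peaks, config.enrichment_factor, config.target_family)
        rep1, rep2, clusters, clip_truth = simulate.simulate_parclip(
            layout, reps,
            target_family=config.target_family,
            enrichment_factor=config.enrichment_factor,
            n_peaks=config.n_peaks,
            conversion_rate=config.conversion_rate,
            seed=config.seed,
        )
        stringent = parclip.stringent_peak_set(
            rep1, rep2, clusters, rpkm_cutoff=config.rpkm_cutoff
        )
        write_peaks(stringent, out / "stringent_peaks.bed")
        clip_truth.to_json(out / "parclip_truth.json")
        context = parclip.classify_peak_context(stringent, genes)
        (out / "peak_context.json").write_text(
            json.dumps(
                {
                    "coding": context.coding,
                    "lincRNA": context.lincRNA,
                    "intergenic": context.intergenic,
                    "total": context.total,
                },
                indent=2,
            )
            + "\n"
        )
        rates = [
            parclip.peak_conversion_rate(p) for p in stringent if p.read_total > 0
        ]
        logger.info(
            "stringent set: %d/%d peaks, mean conversion rate %.3f",
            len(stringent), len(rep1), float(np.mean(rates)) if rates else math.nan,
        )
        for f in ("stringent_peaks.bed", "parclip_truth.json", "peak_context.json"):
            emit("parclip", out / f)
        manifest["stages"].append("parclip")

        logger.info("stage repeats: %d permutations", config.repeat_n_iter)
        enr = repeats.repeat_family_enrichment(
            stringent, reps, layout,
            n_iter=config.repeat_n_iter, seed=config.seed,
            threads=config.threads,
        )
        enrichment_to_tsv(enr, out / "repeat_enrichment.tsv")
        emit("repeats", out / "repeat_enrichment.tsv")
        manifest["stages"].append("repeats")

        logger.info("stage diff: enhancer signal %d vs %d replicates",
                    config.n_replicates, config.n_replicates)
        rng = simulate.substream(config.seed, "signal")
        diff_ids = [
            enhancers[int(i)].id
            for i in rng.choice(
                len(enhancers), size=config.n_diff_enhancers, replace=False
            )
        ]
        half = len(diff_ids) // 2
        planted = {
            rid: (config.diff_fold if k < half else 1.0 / config.diff_fold)
            for k, rid in enumerate(diff_ids)
        }
        matrix, sig_truth = simulate.simulate_signal_matrix(
            enhancers,
            conditions=("WT", "KO"),
            n_replicates=config.n_replicates,
            planted=planted,
            dispersion=config.dispersion,
            base_mean=config.base_mean,
            seed=config.seed + 1,
        )
        write_signal_matrix(
            matrix, out / "signal_values.tsv", out / "signal_samples.tsv",
            out / "signal_regions.bed",
        )
        sig_truth.to_json(out / "signal_truth.json")
        normed = diffsignal.quantile_normalize(matrix)
        keep = diffsignal.specificity_filter(
            matrix, "WT", "KO",
            min_rpkm=config.specificity_min_rpkm, min_fc=config.specificity_min_fc,
        )
        logger.info("specificity filter retained %d/%d regions",
                    len(keep), len(matrix.regions))
        diff = diffsignal.differential_regions(
            normed, "KO", "WT",
            min_fc=config.diff_min_fc, max_fdr=config.diff_max_fdr,
        )
        differential_to_tsv(diff, out / "differential_enhancers.tsv")

        deg_ids, prox_truth = simulate.simulate_proximity(
            [e for e in enhancers if e.id in set(diff_ids)],
            genes,
            planted_fold=config.proximity_planted_fold,
            window_bp=config.window_bp,
            n_degs=config.n_degs,
            seed=config.seed,
        )
        expr, expr_truth = simulate.simulate_expression(
            genes, deg_ids, seed=config.seed + 2,
            n_replicates=max(2, config.n_replicates - 1),
        )
        degs = diffsignal.call_degs(
            expr, "KD", "WT", min_fc=config.deg_min_fc, max_fdr=config.deg_max_fdr
        )
        differential_to_tsv(degs, out / "degs.tsv")
        expr_truth.to_json(out / "expression_truth.json")
        for f in (
            "signal_values.tsv", "signal_samples.tsv", "signal_regions.bed",
            "signal_truth.json", "differential_enhancers.tsv", "degs.tsv",
            "expression_truth.json",
        ):
            emit("diff", out / f)
        manifest["stages"].append("diff")

        logger.info("stage proximity: %d shuffles, %d-bp window",
                    config.proximity_n_iter, config.window_bp)
        up_enh = {r.id for r in diff if r.direction == "up"}
        called_deg_up = [d.id for d in degs if d.direction == "up"]
        gene_by_id = {g.gene_id: g for g in genes}
        pairings = {
            "diff_enhancers_vs_degs": (
                [e for e in enhancers if e.id in set(diff_ids)],
                [gene_by_id[g] for g in deg_ids],
            ),
            "called_up_enhancers_vs_called_up_degs": (
                [e for e in enhancers if e.id in up_enh],
                [gene_by_id[g] for g in called_deg_up if g in gene_by_id],
            ),
        }
        prox_results = {}
        for name, (enh_set, feats) in pairings.items():
            if not enh_set or not feats:
                logger.warning("proximity pairing %s empty; skipped", name)
                continue
            prox_results[name] = proximity.proximity_enrichment_test(
                enh_set, feats, layout,
                window_bp=config.window_bp,
                n_iter=config.proximity_n_iter,
                seed=config.seed,
                mode=config.shuffle_mode,
                threads=config.threads,
            )
        proximity.proximity_results_to_tsv(
            prox_results, out / "proximity_enrichment.tsv", mode=config.shuffle_mode
        )
        prox_truth.to_json(out / "proximity_truth.json")
        emit("proximity", out / "proximity_enrichment.tsv")
        emit("proximity", out / "proximity_truth.json")
        manifest["stages"].append("proximity")

        logger.info("stage curves: %d titrations", len(config.curve_specs))
        x_grid = [1, 2, 4, 8, 16, 32, 64, 128]
        fits = {}
        for k, (label, spec) in enumerate(sorted(config.curve_specs.items())):
            curve, _ = simulate.simulate_binding_curve(
                spec["bmax"], spec["kd"], spec["h"], x_grid,
                noise_sd=spec.get("noise_sd", 0.0),
                seed=config.seed + 10 + k, label=label,
            )
            fits[label] = fit_hill(curve)
            if config.write_plots:
                from .curves import plot_curve

                plot_curve(curve, fits[label], out / f"curve_{label}.png")
        fits_to_tsv(fits, out / "hill_fits.tsv")
        emit("curves", out / "hill_fits.tsv")
        manifest["stages"].append("curves")

    except Exception:
        manifest["failed_after"] = manifest["stages"]
        _write_manifest(manifest, artifacts, out)
        root.removeHandler(handler)
        handler.close()
        raise

    _write_manifest(manifest, artifacts, out)
    root.removeHandler(handler)
    handler.close()
    return manifest


def _write_manifest(manifest: dict[str, Any], artifacts: list[Path], out: Path) -> None:
    for p in artifacts:
        manifest["artifacts"][p.name] = _sha256(p)
    manifest["artifacts"]["run.log"] = "excluded (timestamps)"
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
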