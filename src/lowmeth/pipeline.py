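"""Pipeline orchestration: simulate -> call tables -> global -> calibrate ->
scan -> quantify/classify -> qPCR, with one governing seed and TSV reports.

Each stage is an ordinary function over files plus the library API, so
stages are individually re-runnable; ``run_pipeline`` chains them and
writes a run log (parameter echo, seeds, package version) for provenance.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .amplification import quantify_cohort, quants_to_frame, density_scan
from .bisulfite import conversion_efficiency
from .calibration import bootstrap_margins, call_pool, default_grid, fit_asymptotic, predict_margin
from .cohort import CohortConfig, simulate_cohort
from .globalmeth import global_estimate, partition_by_annotation
from .io import read_call_table, read_manifest, write_call_table, write_manifest
from .qpcr import analyse as qpcr_analyse, read_ct_table, simulate_ct_table
from .types import Region, SampleMethylome

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and sample."""


@dataclass
class RunConfig:
    outdir: str = "lowmeth_run"
    seed: int = 1
    n_reads: int = 1_000_000
    global_window: int = 20_000
    density_window: int = 50_000
    min_calls: int = 10_000
    region: Optional[str] = None  # contig:start-end; default: simulated rDNA unit
    high_fraction: float = 1.0
    intermediate_meth_max: float = 30.0
    calib_grid: tuple[int, int, int] = (100, 30_000, 30)
    calib_B: int = 1000
    calib_ci: float = 99.0
    qpcr_fold_threshold: float = 5.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        if "calib_grid" in data:
            data["calib_grid"] = tuple(data["calib_grid"])
        return cls(**data)


def _load_samples(manifest: pd.DataFrame, base: Path) -> list[SampleMethylome]:
    samples = []
    for row in manifest.itertuples():
        path = Path(row.calls_path)
        if not path.is_absolute():
            path = base / path
        if not path.exists():
            raise PipelineError(f"stage call-load, sample {row.sample_id}: missing {path}")
        s = read_call_table(path)
        s.sample_id = row.sample_id
        s.germline = row.role == "germline"
        samples.append(s)
    return samples


def stage_simulate(config: RunConfig, outdir: Path) -> Path:
    """Simulate the reference cohort and write genome, calls and manifest."""
    cohort = simulate_cohort(config.seed, CohortConfig(n_reads=config.n_reads))
    calls_dir = outdir / "calls"
    calls_dir.mkdir(parents=True, exist_ok=True)
    cohort.genome.write_fasta(outdir / "genome.fa")
    cohort.genome.write_repeat_bed(outdir / "repeats.bed")
    rows = []
    for spec, sample in zip(cohort.specs, cohort.samples):
        path = calls_dir / f"{spec.sample_id}.calls.tsv"
        write_call_table(sample, path)
        rows.append(
            dict(
                sample_id=spec.sample_id,
                role="germline" if spec.germline else "control",
                phenotype=spec.phenotype,
                timepoint="",
                calls_path=str(path.relative_to(outdir)),
                reads_path="",
            )
        )
    write_manifest(pd.DataFrame(rows), outdir / "manifest.tsv")
    cohort.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    with open(outdir / "region.txt", "w") as fh:
        fh.write(str(cohort.region) + "\n")
    return outdir / "manifest.tsv"


def stage_global(config: RunConfig, outdir: Path, margin_coefficient: Optional[float] = None) -> pd.DataFrame:
    manifest = read_manifest(outdir / "manifest.tsv")
    repeats = None
    bed = outdir / "repeats.bed"
    if bed.exists():
        from .genome import read_repeat_bed

        repeats = read_repeat_bed(bed)
    rows = []
    for s in _load_samples(manifest, outdir):
        win = global_estimate(s, "windowed", window_size=config.global_window, min_calls=config.min_calls)
        pool = global_estimate(s, "pooled", min_calls=config.min_calls)
        try:
            ce = conversion_efficiency(s)
        except ValueError:
            ce = float("nan")
        rec = dict(
            sample_id=s.sample_id,
            stage="global",
            seed=config.seed,
            n_cg_calls=win.n_calls,
            windowed_pct=win.value,
            pooled_pct=pool.value,
            conversion_efficiency_pct=ce,
            low_coverage=win.low_coverage,
        )
        if margin_coefficient is not None and win.n_calls > 0:
            rec["margin_pp"] = predict_margin(margin_coefficient, win.n_calls)
        if repeats is not None:
            rep, nonrep, frac = partition_by_annotation(s, repeats)
            rec.update(repeat_pct=rep, nonrepeat_pct=nonrep, repeat_call_fraction_pct=frac)
        rows.append(rec)
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "global.tsv", sep="\t", index=False)
    return df


def stage_calibrate(config: RunConfig, outdir: Path) -> float:
    """Bootstrap a margin curve from the deepest control sample's call pool."""
    manifest = read_manifest(outdir / "manifest.tsv")
    controls = manifest[manifest["role"] == "control"]
    if controls.empty:
        raise PipelineError("stage calibrate: no control samples in manifest")
    samples = _load_samples(controls, outdir)
    pool_sample = max(samples, key=lambda s: s.n_cg_calls)
    pool = call_pool(pool_sample)
    lo, hi, steps = config.calib_grid
    curve = bootstrap_margins(
        pool, default_grid(lo, hi, steps), B=config.calib_B, ci=config.calib_ci, seed=config.seed
    )
    c = fit_asymptotic(curve)
    df = curve.to_frame()
    df.insert(0, "sample_id", pool_sample.sample_id)
    df.insert(1, "stage", "calibrate")
    df.insert(2, "seed", config.seed)
    df.to_csv(outdir / "calibration.tsv", sep="\t", index=False)
    return c


def stage_scan(config: RunConfig, outdir: Path) -> pd.DataFrame:
    manifest = read_manifest(outdir / "manifest.tsv")
    germ = manifest[manifest["role"] == "germline"]
    samples = _load_samples(germ if not germ.empty else manifest, outdir)
    df = density_scan(samples, window_size=config.density_window)
    df.insert(0, "stage", "scan")
    df.insert(1, "seed", config.seed)
    df.to_csv(outdir / "density.tsv", sep="\t", index=False)
    return df


def stage_quantify(config: RunConfig, outdir: Path) -> pd.DataFrame:
    manifest = read_manifest(outdir / "manifest.tsv")
    samples = _load_samples(manifest, outdir)
    if config.region:
        region = Region.parse(config.region)
    else:
        region_file = outdir / "region.txt"
        if not region_file.exists():
            raise PipelineError("stage quantify: no --region and no simulated region.txt")
        region = Region.parse(region_file.read_text().strip())
    quants = quantify_cohort(
        samples,
        region,
        high_fraction=config.high_fraction,
        intermediate_meth_max=config.intermediate_meth_max,
    )
    df = quants_to_frame(quants)
    df.insert(1, "stage", "quantify")
    df.insert(2, "seed", config.seed)
    df.to_csv(outdir / "quant.tsv", sep="\t", index=False)
    return df


def stage_qpcr(config: RunConfig, outdir: Path, ct_table: Optional[Path] = None) -> pd.DataFrame:
    if ct_table is not None:
        samples = read_ct_table(ct_table)
    else:
        truth_path = outdir / "truth.tsv"
        if not truth_path.exists():
            raise PipelineError("stage qpcr: no Ct table given and no simulated truth")
        truth = pd.read_csv(truth_path, sep="\t")
        copy_factors = dict(zip(truth["sample_id"], truth["rdna_copy_factor"]))
        roles = {
            r.sample_id: ("germline" if r.germline else "control") for r in truth.itertuples()
        }
        samples = simulate_ct_table(copy_factors, roles, seed=config.seed)
    df = qpcr_analyse(samples, fold_threshold=config.qpcr_fold_threshold)
    df.insert(1, "stage", "qpcr")
    df.insert(2, "seed", config.seed)
    df.to_csv(outdir / "qpcr.tsv", sep="\t", index=False)
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns a summary dict (also written as run.json)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: outdir=%s seed=%d", outdir, config.seed)
    stage_simulate(config, outdir)
    c = stage_calibrate(config, outdir)
    global_df = stage_global(config, outdir, margin_coefficient=c)
    density = stage_scan(config, outdir)
    quant = stage_quantify(config, outdir)
    qpcr_df = stage_qpcr(config, outdir)
    summary = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "margin_coefficient": c,
        "margin_pp_at_10k": predict_margin(c, 10_000),
        "mean_windowed_pct": float(global_df["windowed_pct"].mean()),
        "top_density_window": density.iloc[0][["contig", "start", "end", "density_ratio"]].to_dict(),
        "class_counts": quant["class"].value_counts().to_dict(),
        "qpcr_amplified": int(qpcr_df["amplified"].sum()),
    }
    with open(outdir / "run.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    logger.info("pipeline done")
    return summary
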