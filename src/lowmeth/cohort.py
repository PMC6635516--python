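"""A reference synthetic cohort mirroring the study conditions.

Twenty samples over one toy genome: five strongly amplified germline
samples (rDNA sampling weight x100-x650, region methylation 2%), three
moderately amplified germline samples (x3-x10 at 10%), and twelve
background samples (no amplification, region methylation ~75%), eight of
which are non-germline controls that define the background level. Global
CG methylation is planted per sample in the 78-84% range and bisulfite
conversion efficiency in 96-100%.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genome import MethylomeModel, ToyGenome, generate_genome, generate_methylome
from .simulate import SampleSpec, SimulationResult, simulate_sample
from .types import Region, SampleMethylome

AMPLIFIED_FACTORS = (100.0, 200.0, 350.0, 500.0, 650.0)
INTERMEDIATE_FACTORS = (3.0, 5.0, 10.0)
N_BACKGROUND = 12
N_CONTROLS = 8  # of the background samples, these are non-germline

AMPLIFIED_REGION_METH = 0.02
INTERMEDIATE_REGION_METH = 0.10
BACKGROUND_REGION_METH = 0.75
GLOBAL_RANGE = (0.78, 0.84)
CONVERSION_RANGE = (0.96, 1.0)


@dataclass
class CohortConfig:
    contig_sizes: dict[str, int] = field(
        default_factory=lambda: {"chrA": 1_600_000, "chrB": 1_600_000, "chrC": 800_000}
    )
    rdna_contig: str = "chrB"
    rdna_start: int = 1_200_001
    rdna_unit_length: int = 1_900
    rdna_reference_copies: int = 1
    rdna_gc: float = 0.45
    rdna_cg_every: int = 25
    repeat_density: float = 0.30
    n_reads: int = 1_000_000
    read_length: int = 150


@dataclass
class CohortResult:
    genome: ToyGenome
    region: Region
    specs: list[SampleSpec]
    samples: list[SampleMethylome]
    truth: pd.DataFrame  # one row per sample: planted and realized quantities
    methylomes: dict[str, MethylomeModel]


def _background_mean_for(
    genome: ToyGenome, target: float, repeat_mean: float, rdna_mean: float
) -> float:
    """Solve the background compartment mean so the CG-site mean hits target."""
    n_total = 0
    n_rep = 0
    n_rdna = 0
    rep_by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, s, e in genome.repeat_intervals:
        rep_by_contig.setdefault(contig, []).append((s, e))
    for contig in genome.contigs:
        pos = genome.cg_positions(contig)
        n_total += len(pos)
        for s, e in rep_by_contig.get(contig, []):
            n_rep += int(((pos >= s) & (pos <= e)).sum())
        r = genome.rdna_unit
        if r is not None and contig == r.contig:
            n_rdna += int(((pos >= r.start) & (pos <= r.end)).sum())
    f_rep = n_rep / n_total
    f_rdna = n_rdna / n_total
    bg = (target - f_rep * repeat_mean - f_rdna * rdna_mean) / (1 - f_rep - f_rdna)
    return float(np.clip(bg, 0.0, 1.0))


def cohort_specs(seed: int, config: Optional[CohortConfig] = None) -> list[dict]:
    """Per-sample plan: spec parameters plus planted class and global target."""
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    plan: list[dict] = []

    def draw_global() -> float:
        return float(rng.uniform(*GLOBAL_RANGE))

    def draw_conversion() -> float:
        return float(rng.uniform(*CONVERSION_RANGE))

    for i, k in enumerate(AMPLIFIED_FACTORS):
        plan.append(
            dict(sample_id=f"amp{i+1:02d}", germline=True, phenotype="female",
                 rdna_copy_factor=k, rdna_methylation_override=AMPLIFIED_REGION_METH,
                 planted_class="amplified", target_global=draw_global(),
                 conversion_efficiency=draw_conversion())
        )
    for i, k in enumerate(INTERMEDIATE_FACTORS):
        plan.append(
            dict(sample_id=f"int{i+1:02d}", germline=True, phenotype="female",
                 rdna_copy_factor=k, rdna_methylation_override=INTERMEDIATE_REGION_METH,
                 planted_class="intermediate", target_global=draw_global(),
                 conversion_efficiency=draw_conversion())
        )
    for i in range(N_BACKGROUND):
        control = i < N_CONTROLS
        plan.append(
            dict(sample_id=f"bg{i+1:02d}", germline=not control,
                 phenotype="control" if control else ("male" if i % 2 else "undiff"),
                 rdna_copy_factor=1.0, rdna_methylation_override=None,
                 planted_class="background", target_global=draw_global(),
                 conversion_efficiency=draw_conversion())
        )
    for j, row in enumerate(plan):
        row["seed"] = int(rng.integers(2**31))
    return plan


def simulate_cohort(
    seed: int,
    config: Optional[CohortConfig] = None,
    *,
    mode: str = "calls",
) -> CohortResult:
    """Generate the full reference cohort; deterministic for a fixed seed."""
    config = config or CohortConfig()
    ss = np.random.SeedSequence(seed)
    genome_seed, meth_seed, plan_seed = [int(s) for s in ss.generate_state(3) >> 1]
    genome = generate_genome(
        config.contig_sizes,
        seed=genome_seed,
        repeat_density=config.repeat_density,
        rdna_contig=config.rdna_contig,
        rdna_start=config.rdna_start,
        rdna_unit_length=config.rdna_unit_length,
        rdna_reference_copies=config.rdna_reference_copies,
        rdna_gc=config.rdna_gc,
        rdna_cg_every=config.rdna_cg_every,
        min_read_length=config.read_length,
    )
    region = genome.rdna_unit
    plan = cohort_specs(plan_seed, config)

    samples: list[SampleMethylome] = []
    specs: list[SampleSpec] = []
    methylomes: dict[str, MethylomeModel] = {}
    truth_rows = []
    meth_rng = np.random.default_rng(meth_seed)
    for contig in genome.contigs:  # pre-warm the CG-position cache
        genome.cg_positions(contig)
    for row in plan:
        target = row["target_global"]
        repeat_mean = min(target + 0.07, 0.97)
        background_mean = _background_mean_for(genome, target, repeat_mean, BACKGROUND_REGION_METH)
        methylome = generate_methylome(
            genome,
            seed=int(meth_rng.integers(2**31)),
            background_mean=background_mean,
            repeat_mean=repeat_mean,
            rdna_mean=BACKGROUND_REGION_METH,
        )
        spec = SampleSpec(
            sample_id=row["sample_id"],
            germline=row["germline"],
            phenotype=row["phenotype"],
            rdna_copy_factor=row["rdna_copy_factor"],
            rdna_methylation_override=row["rdna_methylation_override"],
            conversion_efficiency=row["conversion_efficiency"],
            n_reads=config.n_reads,
            read_length=config.read_length,
            seed=row["seed"],
        )
        result: SimulationResult = simulate_sample(genome, methylome, spec, mode=mode)
        sample = result.sample
        if sample is None:  # reads mode: caller maps/extracts; keep empty shell
            sample = SampleMethylome(
                sample_id=spec.sample_id, phenotype=spec.phenotype, germline=spec.germline,
                total_mapped_reads=spec.n_reads,
            )
        samples.append(sample)
        specs.append(spec)
        methylomes[spec.sample_id] = methylome
        t = result.truth
        truth_rows.append(
            dict(
                sample_id=t.sample_id,
                planted_class=row["planted_class"],
                rdna_copy_factor=t.rdna_copy_factor,
                target_global_pct=100 * target,
                model_global_observed_pct=100 * t.model_global_observed,
                realized_global_pct=100 * t.realized_global_cg,
                conversion_efficiency_pct=100 * t.conversion_efficiency,
                realized_conversion_pct=100 * t.realized_conversion_efficiency,
                expected_region_call_fraction_pct=100 * t.expected_region_call_fraction,
                realized_region_read_fraction_pct=100 * t.realized_region_read_fraction,
                planted_fold=t.planted_fold,
                germline=row["germline"],
            )
        )
    truth = pd.DataFrame(truth_rows)
    return CohortResult(
        genome=genome, region=region, specs=specs, samples=samples, truth=truth,
        methylomes=methylomes,
    )
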