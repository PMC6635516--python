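"""Bisulfite read and call-table simulation with ground truth.

Emulates a PBAT (post-bisulfite adaptor tagging) library: single-end,
adapter-free reads originating from the two strands complementary to the
bisulfite-converted genome (CTOT and CTOB). Amplification of the rDNA-like
unit is modelled as a read-sampling weight on the unit — the biological
picture of extrachromosomal rolling-circle copies all mapping back to one
collapsed reference unit.

Two output paths share one sampling model:

* ``mode="reads"`` builds actual read sequences (FASTQ) plus a truth table
  of the per-site calls an error-free extractor should recover; used at
  small scale and by the mapper tests.
* ``mode="calls"`` draws per-site methylation counts directly from the
  realized read coverage — statistically identical to simulating, mapping
  and extracting error-free reads, but vectorised, so cohorts with 10^5-10^6
  CG calls per sample are cheap.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .genome import MethylomeModel, ToyGenome
from .types import CALL_COLUMNS, Region, SampleMethylome, empty_call_frame

_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@dataclass
class SampleSpec:
    """Everything that distinguishes one simulated sample."""

    sample_id: str
    germline: bool = False
    phenotype: str = "control"  # undiff / female / male / control
    rdna_copy_factor: float = 1.0
    rdna_methylation_override: Optional[float] = None
    conversion_efficiency: float = 0.98
    n_reads: int = 10_000
    read_length: int = 150
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conversion_efficiency", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.rdna_methylation_override is not None and not (
            0.0 <= self.rdna_methylation_override <= 1.0
        ):
            raise ValueError("rdna_methylation_override must lie in [0,1]")
        if self.rdna_copy_factor < 1:
            raise ValueError("rdna_copy_factor must be >= 1")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")


@dataclass
class TruthRow:
    """Realized and planted quantities for one simulated sample."""

    sample_id: str
    n_reads: int
    rdna_copy_factor: float
    conversion_efficiency: float
    # realized, from the draws actually made
    realized_global_cg: float  # observed meth fraction over CG calls (weighted)
    realized_region_read_fraction: float
    realized_conversion_efficiency: float
    # planted, analytic under the sampling model
    expected_region_read_fraction: float
    expected_region_call_fraction: float
    planted_fold: float  # expected call-fraction ratio vs an unamplified sample
    model_global_observed: float  # unweighted mean observed-meth prob over CG sites
    undefined: bool = False  # n_reads == 0


@dataclass
class SimulationResult:
    truth: TruthRow
    sample: Optional[SampleMethylome] = None  # calls mode
    reads: list[tuple[str, str]] = field(default_factory=list)  # (read_id, sequence)
    realized_calls: Optional[pd.DataFrame] = None  # reads mode: error-free expectation

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, seq in self.reads:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# sampling model shared by both output paths


def _start_segments(genome: ToyGenome, read_length: int, copy_factor: float):
    """Weighted read-start segments: (contig, lo, hi, weight), starts 1-based.

    Starts whose read overlaps the rDNA array by >=1 bp carry the
    amplification weight.
    """
    segs: list[tuple[str, int, int, float]] = []
    L = read_length
    for contig, seq in genome.contigs.items():
        n_starts = len(seq) - L + 1
        if n_starts <= 0:
            continue
        r = genome.rdna_unit
        if r is not None and contig == r.contig and copy_factor != 1.0:
            lo = max(1, r.start - L + 1)
            hi = min(n_starts, r.end)
            if lo > 1:
                segs.append((contig, 1, lo - 1, 1.0))
            segs.append((contig, lo, hi, copy_factor))
            if hi < n_starts:
                segs.append((contig, hi + 1, n_starts, 1.0))
        else:
            segs.append((contig, 1, n_starts, 1.0))
    return segs


def _expected_read_fraction(genome: ToyGenome, read_length: int, copy_factor: float) -> float:
    segs = _start_segments(genome, read_length, copy_factor)
    total = sum((hi - lo + 1) * w for _, lo, hi, w in segs)
    region = sum((hi - lo + 1) * w for _, lo, hi, w in segs if w == copy_factor and copy_factor != 1.0)
    if copy_factor == 1.0:
        # unweighted: overlap window of the region
        r = genome.rdna_unit
        if r is None:
            return 0.0
        L = read_length
        n_starts = len(genome.contigs[r.contig]) - L + 1
        lo = max(1, r.start - L + 1)
        hi = min(n_starts, r.end)
        region = hi - lo + 1
    return region / total


def _coverage_from_starts(starts0: np.ndarray, size: int, read_length: int) -> np.ndarray:
    """Per-base coverage given 0-based read starts (reads of fixed length)."""
    cnt = np.bincount(starts0, minlength=size)
    cs = np.cumsum(cnt)
    cov = cs.copy()
    cov[read_length:] -= cs[:-read_length]
    return cov


def _expected_call_masses(genome: ToyGenome, read_length: int, copy_factor: float):
    """Expected CG-observation mass inside the rDNA region and in total.

    The expected coverage of a site is proportional to the summed start
    weights within ``read_length`` upstream; strand assignment is symmetric
    and cancels in the fractions.
    """
    cache = genome.__dict__.setdefault("_call_mass_cache", {})
    key = (read_length, float(copy_factor))
    if key in cache:
        return cache[key]
    L = read_length
    region_mass = 0.0
    total_mass = 0.0
    r = genome.rdna_unit
    for contig, seq in genome.contigs.items():
        size = len(seq)
        n_starts = size - L + 1
        w = np.ones(n_starts)
        if r is not None and contig == r.contig and copy_factor != 1.0:
            lo = max(1, r.start - L + 1)
            hi = min(n_starts, r.end)
            w[lo - 1 : hi] = copy_factor
        cs = np.cumsum(w)
        CS = np.empty(size)  # CS[j] = total weight of starts at 0-based index <= j
        CS[:n_starts] = cs
        CS[n_starts:] = cs[-1]
        cov = CS.copy()
        cov[L:] -= CS[:-L]
        # cov[j] = weight of starts in [j-L+1, j] (0-based): expected coverage mass
        pos = genome.cg_positions(contig)  # 1-based C coordinates; partner G at pos+1
        site_mass = cov[pos - 1] + cov[pos]  # top C plus bottom C coverage mass
        total_mass += float(site_mass.sum())
        if r is not None and contig == r.contig:
            in_region = (pos >= r.start) & (pos <= r.end)
            region_mass += float(site_mass[in_region].sum())
    cache[key] = (region_mass, total_mass)
    return region_mass, total_mass


def expected_call_fraction(genome: ToyGenome, read_length: int, copy_factor: float) -> float:
    region, total = _expected_call_masses(genome, read_length, copy_factor)
    return region / total if total > 0 else 0.0


def planted_fold(genome: ToyGenome, read_length: int, copy_factor: float) -> float:
    """Expected region call-fraction ratio of an amplified vs unamplified sample."""
    f1 = expected_call_fraction(genome, read_length, 1.0)
    fk = expected_call_fraction(genome, read_length, copy_factor)
    return fk / f1 if f1 > 0 else float("nan")


def _sample_positions(genome: ToyGenome, spec: SampleSpec, rng: np.random.Generator):
    """Draw (contig, start, strand) for every read. strand 0=CTOT, 1=CTOB."""
    segs = _start_segments(genome, spec.read_length, spec.rdna_copy_factor)
    weights = np.array([(hi - lo + 1) * w for _, lo, hi, w in segs])
    counts = rng.multinomial(spec.n_reads, weights / weights.sum())
    contigs: list[str] = []
    starts: list[np.ndarray] = []
    for (contig, lo, hi, _w), cnt in zip(segs, counts):
        contigs.extend([contig] * int(cnt))
        starts.append(rng.integers(lo, hi + 1, size=int(cnt)))
    start_arr = np.concatenate(starts) if starts else np.empty(0, dtype=np.int64)
    strand = rng.integers(0, 2, size=spec.n_reads)
    return np.array(contigs, dtype=object), start_arr, strand


def _effective_probs(
    genome: ToyGenome, methylome: MethylomeModel, spec: SampleSpec, contig: str
) -> np.ndarray:
    """Per-CG methylation probabilities with any sample rDNA override applied."""
    p = methylome.probs[contig].copy()
    r = genome.rdna_unit
    if spec.rdna_methylation_override is not None and r is not None and contig == r.contig:
        pos = methylome.positions[contig]
        mask = (pos >= r.start) & (pos <= r.end)
        p[mask] = spec.rdna_methylation_override
    return p


def model_global_observed(
    genome: ToyGenome, methylome: MethylomeModel, spec: SampleSpec
) -> float:
    """Unweighted mean probability that a CG site reads as methylated.

    A failed conversion leaves an unmethylated C looking methylated, so the
    observable is p + (1-p)(1-efficiency).
    """
    ce = spec.conversion_efficiency
    vals = [
        _effective_probs(genome, methylome, spec, c) for c in sorted(genome.contigs)
    ]
    p = np.concatenate(vals)
    return float((p + (1 - p) * (1 - ce)).mean())


# ---------------------------------------------------------------------------
# call-table path


def _simulate_calls(
    genome: ToyGenome, methylome: MethylomeModel, spec: SampleSpec, rng: np.random.Generator
) -> tuple[SampleMethylome, dict]:
    L = spec.read_length
    ce = spec.conversion_efficiency
    nu = methylome.non_cg_level
    contigs_arr, starts, strands = _sample_positions(genome, spec, rng)

    frames = []
    tot_unmeth_states = 0
    tot_converted = 0
    cg_meth_obs = 0
    cg_total_obs = 0
    noncg_meth_obs = 0
    noncg_total_obs = 0
    region_reads = 0
    r = genome.rdna_unit

    for contig in genome.contigs:
        size = len(genome.contigs[contig])
        sel = contigs_arr == contig
        if not sel.any():
            continue
        c_starts = starts[sel].astype(np.int64) - 1
        c_strands = strands[sel]
        if r is not None and contig == r.contig:
            ends = c_starts + L  # exclusive, 0-based
            region_reads += int(((c_starts < r.end) & (ends > r.start - 1)).sum())
        cov_ctot = _coverage_from_starts(c_starts[c_strands == 0], size, L)
        cov_ctob = _coverage_from_starts(c_starts[c_strands == 1], size, L)

        pos = methylome.positions[contig]  # 1-based top-strand CG C positions
        p = _effective_probs(genome, methylome, spec, contig)
        q = p + (1 - p) * (1 - ce)  # observed-methylation probability

        n_top = cov_ctot[pos - 1]  # CTOT reads report top-strand cytosines
        n_bot = cov_ctob[pos]  # bottom C sits at the G coordinate (pos+1)
        for strand_label, n_obs, site_pos in (
            ("+", n_top, pos),
            ("-", n_bot, pos + 1),
        ):
            covered = n_obs > 0
            if not covered.any():
                continue
            n_c = n_obs[covered]
            p_c = p[covered]
            meth_states = rng.binomial(n_c, p_c)
            unmeth_states = n_c - meth_states
            unconverted = rng.binomial(unmeth_states, 1 - ce)
            meth_obs = meth_states + unconverted
            tot_unmeth_states += int(unmeth_states.sum())
            tot_converted += int((unmeth_states - unconverted).sum())
            cg_meth_obs += int(meth_obs.sum())
            cg_total_obs += int(n_c.sum())
            frames.append(
                pd.DataFrame(
                    {
                        "contig": contig,
                        "pos": site_pos[covered],
                        "strand": strand_label,
                        "context": "CG",
                        "meth": meth_obs,
                        "unmeth": n_c - meth_obs,
                    }
                )
            )

        # non-CG cytosines, aggregated (conversion-report style)
        arr = np.frombuffer(genome.contigs[contig].encode(), dtype="S1")
        cg_c = np.zeros(size, dtype=bool)
        cg_c[pos - 1] = True
        top_noncg = (arr == b"C") & ~cg_c
        cg_g = np.zeros(size, dtype=bool)
        cg_g[pos] = True
        bot_noncg = (arr == b"G") & ~cg_g
        n_nc = int(cov_ctot[top_noncg].sum() + cov_ctob[bot_noncg].sum())
        meth_states = rng.binomial(n_nc, nu)
        unmeth_states = n_nc - meth_states
        unconverted = rng.binomial(unmeth_states, 1 - ce)
        tot_unmeth_states += int(unmeth_states)
        tot_converted += int(unmeth_states - unconverted)
        noncg_meth_obs += int(meth_states + unconverted)
        noncg_total_obs += n_nc

    calls = (
        pd.concat(frames, ignore_index=True)[CALL_COLUMNS]
        if frames
        else empty_call_frame()
    )
    sample = SampleMethylome(
        sample_id=spec.sample_id,
        calls=calls,
        phenotype=spec.phenotype,
        germline=spec.germline,
        total_mapped_reads=spec.n_reads,
        noncg_meth=noncg_meth_obs,
        noncg_total=noncg_total_obs,
    )
    stats = {
        "cg_meth_obs": cg_meth_obs,
        "cg_total_obs": cg_total_obs,
        "unmeth_states": tot_unmeth_states,
        "converted": tot_converted,
        "region_reads": region_reads,
    }
    return sample, stats


# ---------------------------------------------------------------------------
# read (FASTQ) path


def _context_top(seq: str, i0: int) -> str:
    """Context of a top-strand C at 0-based index i0."""
    if i0 + 1 < len(seq) and seq[i0 + 1] == "G":
        return "CG"
    if i0 + 2 < len(seq) and seq[i0 + 2] == "G":
        return "CHG"
    return "CHH"


def _context_bottom(seq: str, i0: int) -> str:
    """Context of a bottom-strand C sitting under a top-strand G at i0."""
    if i0 - 1 >= 0 and seq[i0 - 1] == "C":
        return "CG"
    if i0 - 2 >= 0 and seq[i0 - 2] == "C":
        return "CHG"
    return "CHH"


def _simulate_reads(
    genome: ToyGenome, methylome: MethylomeModel, spec: SampleSpec, rng: np.random.Generator
) -> tuple[list[tuple[str, str]], pd.DataFrame, dict]:
    L = spec.read_length
    ce = spec.conversion_efficiency
    nu = methylome.non_cg_level
    contigs_arr, starts, strands = _sample_positions(genome, spec, rng)

    prob_by_pos = {
        contig: dict(
            zip(
                methylome.positions[contig].tolist(),
                _effective_probs(genome, methylome, spec, contig).tolist(),
            )
        )
        for contig in genome.contigs
    }

    reads: list[tuple[str, str]] = []
    site_counts: dict[tuple, list[int]] = {}
    tot_unmeth_states = 0
    tot_converted = 0
    cg_meth_obs = 0
    cg_total_obs = 0
    region_reads = 0
    r = genome.rdna_unit
    strand_names = ("CTOT", "CTOB")

    for i in range(spec.n_reads):
        contig = contigs_arr[i]
        start = int(starts[i])  # 1-based leftmost top coordinate
        sname = strand_names[int(strands[i])]
        seq = genome.contigs[contig]
        frag = bytearray(seq[start - 1 : start - 1 + L], "ascii")
        if r is not None and contig == r.contig and start <= r.end and start + L - 1 >= r.start:
            region_reads += 1

        if sname == "CTOT":
            # report top-strand cytosines
            for j in range(L):
                if frag[j] != ord("C"):
                    continue
                gpos = start + j
                ctx = _context_top(seq, gpos - 1)
                if ctx == "CG":
                    p = prob_by_pos[contig].get(gpos, 0.0)
                else:
                    p = nu
                meth = rng.random() < p
                observed_meth = True
                if not meth:
                    tot_unmeth_states += 1
                    if rng.random() < ce:
                        tot_converted += 1
                        frag[j] = ord("T")
                        observed_meth = False
                key = (contig, gpos, "+", ctx)
                cnt = site_counts.setdefault(key, [0, 0])
                cnt[0 if observed_meth else 1] += 1
                if ctx == "CG":
                    cg_total_obs += 1
                    cg_meth_obs += int(observed_meth)
            # read is the complement of the converted top fragment, 5'->3'
            read_seq = bytes(frag).translate(_COMPLEMENT)[::-1].decode()
        else:
            # CTOB: report bottom-strand cytosines (top-strand G positions)
            bot = bytearray(bytes(frag).translate(_COMPLEMENT))  # bottom, top orientation
            for j in range(L):
                if bot[j] != ord("C"):
                    continue
                gpos = start + j  # coordinate of the top-strand G
                ctx = _context_bottom(seq, gpos - 1)
                if ctx == "CG":
                    p = prob_by_pos[contig].get(gpos - 1, nu)
                else:
                    p = nu
                meth = rng.random() < p
                observed_meth = True
                if not meth:
                    tot_unmeth_states += 1
                    if rng.random() < ce:
                        tot_converted += 1
                        bot[j] = ord("T")
                        observed_meth = False
                key = (contig, gpos, "-", ctx)
                cnt = site_counts.setdefault(key, [0, 0])
                cnt[0 if observed_meth else 1] += 1
                if ctx == "CG":
                    cg_total_obs += 1
                    cg_meth_obs += int(observed_meth)
            # CTOB read = complement of the converted bottom strand, which in
            # top orientation is simply its base-complement left to right
            read_seq = bytes(bot).translate(_COMPLEMENT).decode()

        if spec.error_rate > 0:
            arr = bytearray(read_seq, "ascii")
            for j in range(L):
                if rng.random() < spec.error_rate:
                    arr[j] = b"ACGT"[int(rng.integers(4))]
            read_seq = arr.decode()
        reads.append((f"{spec.sample_id}:{i}|{contig}|{start}|{sname}", read_seq))

    rows = [
        (contig, pos, strand, ctx, m, u)
        for (contig, pos, strand, ctx), (m, u) in sorted(site_counts.items())
    ]
    realized = pd.DataFrame(rows, columns=CALL_COLUMNS) if rows else empty_call_frame()
    stats = {
        "cg_meth_obs": cg_meth_obs,
        "cg_total_obs": cg_total_obs,
        "unmeth_states": tot_unmeth_states,
        "converted": tot_converted,
        "region_reads": region_reads,
    }
    return reads, realized, stats


# ---------------------------------------------------------------------------


def simulate_sample(
    genome: ToyGenome,
    methylome: MethylomeModel,
    spec: SampleSpec,
    *,
    mode: str = "reads",
) -> SimulationResult:
    """Simulate one sample; ``mode`` selects FASTQ reads or a direct call table."""
    if mode not in ("reads", "calls"):
        raise ValueError("mode must be 'reads' or 'calls'")
    rng = np.random.default_rng(spec.seed)
    exp_read_frac = (
        _expected_read_fraction(genome, spec.read_length, spec.rdna_copy_factor)
        if genome.rdna_unit is not None
        else 0.0
    )
    exp_call_frac = (
        expected_call_fraction(genome, spec.read_length, spec.rdna_copy_factor)
        if genome.rdna_unit is not None
        else 0.0
    )
    fold = (
        planted_fold(genome, spec.read_length, spec.rdna_copy_factor)
        if genome.rdna_unit is not None
        else float("nan")
    )
    base = dict(
        sample_id=spec.sample_id,
        n_reads=spec.n_reads,
        rdna_copy_factor=spec.rdna_copy_factor,
        conversion_efficiency=spec.conversion_efficiency,
        expected_region_read_fraction=exp_read_frac,
        expected_region_call_fraction=exp_call_frac,
        planted_fold=fold,
        model_global_observed=model_global_observed(genome, methylome, spec),
    )
    if spec.n_reads == 0:
        truth = TruthRow(
            realized_global_cg=float("nan"),
            realized_region_read_fraction=float("nan"),
            realized_conversion_efficiency=float("nan"),
            undefined=True,
            **base,
        )
        sample = SampleMethylome(sample_id=spec.sample_id, phenotype=spec.phenotype,
                                 germline=spec.germline, total_mapped_reads=0)
        return SimulationResult(truth=truth, sample=sample if mode == "calls" else None)

    if mode == "calls":
        sample, stats = _simulate_calls(genome, methylome, spec, rng)
        reads: list[tuple[str, str]] = []
        realized = None
    else:
        reads, realized, stats = _simulate_reads(genome, methylome, spec, rng)
        sample = None

    truth = TruthRow(
        realized_global_cg=(
            stats["cg_meth_obs"] / stats["cg_total_obs"] if stats["cg_total_obs"] else float("nan")
        ),
        realized_region_read_fraction=stats["region_reads"] / spec.n_reads,
        realized_conversion_efficiency=(
            stats["converted"] / stats["unmeth_states"] if stats["unmeth_states"] else float("nan")
        ),
        **base,
    )
    return SimulationResult(truth=truth, sample=sample, reads=reads, realized_calls=realized)
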