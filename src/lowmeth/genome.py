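"""Toy genomes and per-CG methylation landscapes with known ground truth.

The generator emulates, at reduced scale, the genomic context the pipeline
is built for: a few contigs with interspersed repeats, and one tandem
45S-rDNA-like unit that is CG-dense relative to background (ribosomal DNA
is GC-rich). Methylation probabilities are drawn per CG dinucleotide from
compartment-specific Beta distributions: background, repeat and rDNA-unit
compartments each have their own mean.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .types import Region

BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigurationError(ValueError):
    """Raised for contradictory generator configuration."""


@dataclass
class ToyGenome:
    """A small multi-contig genome with annotated repeats and one rDNA array.

    ``rdna_unit`` spans the full tandem array (1-based inclusive);
    ``rdna_unit_length`` is the length of one repeat unit, so the span
    length equals ``rdna_unit_length * rdna_reference_copies``.
    """

    contigs: dict[str, str]
    repeat_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    rdna_unit: Optional[Region] = None
    rdna_unit_length: int = 0
    rdna_reference_copies: int = 1

    def __post_init__(self) -> None:
        for contig, start, end in self.repeat_intervals:
            if contig not in self.contigs:
                raise ConfigurationError(f"repeat interval on unknown contig {contig}")
            if not (1 <= start <= end <= len(self.contigs[contig])):
                raise ConfigurationError(f"repeat interval out of bounds: {contig}:{start}-{end}")
        if self.rdna_unit is not None:
            r = self.rdna_unit
            if r.contig not in self.contigs or r.end > len(self.contigs[r.contig]):
                raise ConfigurationError(f"rDNA unit out of bounds: {r}")
            if r.length != self.rdna_unit_length * self.rdna_reference_copies:
                raise ConfigurationError("rDNA span does not equal unit length x copies")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def cg_positions(self, contig: str) -> np.ndarray:
        """1-based positions of the C of each top-strand CG dinucleotide."""
        cache = self.__dict__.setdefault("_cg_cache", {})
        if contig not in cache:
            arr = np.frombuffer(self.contigs[contig].encode(), dtype="S1")
            is_c = arr[:-1] == b"C"
            is_g = arr[1:] == b"G"
            cache[contig] = np.flatnonzero(is_c & is_g) + 1
        return cache[contig]

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_repeat_bed(self, path: str | Path) -> None:
        """Write repeat annotation as BED3 (0-based half-open)."""
        with open(path, "w") as fh:
            for contig, start, end in self.repeat_intervals:
                fh.write(f"{contig}\t{start - 1}\t{end}\n")


def read_repeat_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED3 intervals back to 1-based inclusive tuples."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {i}")
            out.append((parts[0], int(parts[1]) + 1, int(parts[2])))
    return out


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=n, p=p)


def _rdna_unit_seq(rng: np.random.Generator, length: int, gc: float, cg_every: int) -> np.ndarray:
    """One rDNA-like unit: GC-rich with CG dinucleotides forced periodically."""
    seq = _random_seq(rng, length, gc)
    for i in range(0, length - 1, cg_every):
        seq[i] = b"C"
        seq[i + 1] = b"G"
    return seq


def generate_genome(
    contig_sizes: dict[str, int],
    *,
    seed: int,
    gc_content: float = 0.40,
    repeat_density: float = 0.30,
    repeat_length: int = 2000,
    rdna_contig: Optional[str] = None,
    rdna_start: Optional[int] = None,
    rdna_unit_length: int = 11_500,
    rdna_reference_copies: int = 1,
    rdna_gc: float = 0.55,
    rdna_cg_every: int = 14,
    min_read_length: int = 150,
) -> ToyGenome:
    """Generate a toy genome; deterministic for a fixed seed.

    Repeats are copies of a small set of consensus sequences pasted at
    random non-overlapping locations until ``repeat_density`` of each
    contig is covered; they never overlap the rDNA array.
    """
    if not contig_sizes:
        raise ConfigurationError("no contigs requested")
    for name, size in contig_sizes.items():
        if size < 10 * min_read_length:
            raise ConfigurationError(f"contig {name} shorter than 10x read length")
    rng = np.random.default_rng(seed)

    rdna_region: Optional[Region] = None
    span = rdna_unit_length * rdna_reference_copies
    if rdna_contig is not None:
        if rdna_start is None:
            rdna_start = contig_sizes[rdna_contig] // 2
        if rdna_start + span - 1 > contig_sizes[rdna_contig]:
            raise ConfigurationError("rDNA array exceeds its contig")
        rdna_region = Region(rdna_contig, rdna_start, rdna_start + span - 1)

    # a few repeat consensus families shared across contigs
    n_families = 4
    families = [_random_seq(rng, repeat_length, gc_content + 0.05) for _ in range(n_families)]

    contigs: dict[str, str] = {}
    repeat_intervals: list[tuple[str, int, int]] = []
    for name, size in contig_sizes.items():
        seq = _random_seq(rng, size, gc_content)
        forbidden = None
        if rdna_region is not None and name == rdna_region.contig:
            unit = _rdna_unit_seq(rng, rdna_unit_length, rdna_gc, rdna_cg_every)
            tandem = np.tile(unit, rdna_reference_copies)
            seq[rdna_region.start - 1 : rdna_region.end] = tandem
            forbidden = (rdna_region.start, rdna_region.end)
        target = int(size * repeat_density)
        covered = 0
        attempts = 0
        occupied: list[tuple[int, int]] = [] if forbidden is None else [forbidden]
        while covered < target and attempts < 10_000:
            attempts += 1
            start = int(rng.integers(1, size - repeat_length + 1))
            end = start + repeat_length - 1
            if any(start <= e and end >= s for s, e in occupied):
                continue
            fam = families[int(rng.integers(n_families))].copy()
            # light divergence between copies
            n_mut = max(1, repeat_length // 100)
            idx = rng.integers(0, repeat_length, size=n_mut)
            fam[idx] = rng.choice(BASES, size=n_mut)
            seq[start - 1 : end] = fam
            occupied.append((start, end))
            repeat_intervals.append((name, start, end))
            covered += repeat_length
        contigs[name] = seq.tobytes().decode()

    repeat_intervals.sort()
    return ToyGenome(
        contigs=contigs,
        repeat_intervals=repeat_intervals,
        rdna_unit=rdna_region,
        rdna_unit_length=rdna_unit_length if rdna_region is not None else 0,
        rdna_reference_copies=rdna_reference_copies if rdna_region is not None else 1,
    )


@dataclass
class MethylomeModel:
    """Per-CG methylation probabilities on the top strand.

    ``positions[contig]`` are the 1-based C coordinates of top-strand CGs,
    ``probs[contig]`` the matching methylation probabilities. Methylation is
    taken as symmetric: the bottom-strand cytosine of a CpG shares its
    partner's probability. ``non_cg_level`` is the probability that a non-CG
    cytosine reads as methylated; it pools true non-CG methylation and any
    signal indistinguishable from it.
    """

    positions: dict[str, np.ndarray]
    probs: dict[str, np.ndarray]
    background_mean: float
    repeat_mean: float
    rdna_mean: float
    non_cg_level: float = 0.0

    def prob_at(self, contig: str, pos: int) -> float:
        idx = np.searchsorted(self.positions[contig], pos)
        if idx >= len(self.positions[contig]) or self.positions[contig][idx] != pos:
            raise KeyError(f"no CG at {contig}:{pos}")
        return float(self.probs[contig][idx])

    @property
    def genome_mean(self) -> float:
        """Unweighted mean methylation probability over all CG sites."""
        allp = np.concatenate([self.probs[c] for c in sorted(self.probs)])
        return float(allp.mean())

    def n_sites(self) -> int:
        return sum(len(v) for v in self.positions.values())


def _beta_draw(rng: np.random.Generator, mean: float, concentration: float, n: int) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    if mean <= 0.0:
        return np.zeros(n)
    if mean >= 1.0:
        return np.ones(n)
    if not np.isfinite(concentration):
        return np.full(n, mean)
    return rng.beta(mean * concentration, (1 - mean) * concentration, size=n)


def _interval_mask(positions: np.ndarray, intervals: list[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(len(positions), dtype=bool)
    for start, end in intervals:
        lo = np.searchsorted(positions, start, side="left")
        hi = np.searchsorted(positions, end, side="right")
        mask[lo:hi] = True
    return mask


def generate_methylome(
    genome: ToyGenome,
    *,
    seed: int,
    background_mean: float = 0.77,
    repeat_mean: float = 0.87,
    rdna_mean: float = 0.75,
    concentration: float = 20.0,
    non_cg_level: float = 0.0,
) -> MethylomeModel:
    """Draw a per-CG methylation landscape over a toy genome.

    Compartment assignment: CGs inside the rDNA array get ``rdna_mean``,
    CGs inside annotated repeats get ``repeat_mean``, everything else
    ``background_mean``. ``concentration`` is the Beta concentration
    (a+b); ``inf`` collapses each compartment to its exact mean.
    """
    for m in (background_mean, repeat_mean, rdna_mean):
        if not 0.0 <= m <= 1.0:
            raise ValueError("compartment means must lie in [0,1]")
    rng = np.random.default_rng(seed)
    positions: dict[str, np.ndarray] = {}
    probs: dict[str, np.ndarray] = {}
    rep_by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end in genome.repeat_intervals:
        rep_by_contig.setdefault(contig, []).append((start, end))
    for contig in genome.contigs:
        pos = genome.cg_positions(contig)
        p = _beta_draw(rng, background_mean, concentration, len(pos))
        rep_mask = _interval_mask(pos, rep_by_contig.get(contig, []))
        if rep_mask.any():
            p[rep_mask] = _beta_draw(rng, repeat_mean, concentration, int(rep_mask.sum()))
        if genome.rdna_unit is not None and contig == genome.rdna_unit.contig:
            r = genome.rdna_unit
            rd_mask = _interval_mask(pos, [(r.start, r.end)])
            if rd_mask.any():
                p[rd_mask] = _beta_draw(rng, rdna_mean, concentration, int(rd_mask.sum()))
        positions[contig] = pos
        probs[contig] = p
    return MethylomeModel(
        positions=positions,
        probs=probs,
        background_mean=background_mean,
        repeat_mean=repeat_mean,
        rdna_mean=rdna_mean,
        non_cg_level=non_cg_level,
    )
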