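"""Four-strand bisulfite reference conversion, toy read mapping, call extraction.

Bisulfite conversion of a genome yields four alignable strands: the
converted original top (OT, every C->T) and bottom (OB), and their
complements (CTOT, CTOB) — the strands a PBAT library actually sequences.
The mapper here is deliberately simple: exact k-mer seed, full-length
mismatch count, unique-best hit. Its contract is correctness on clean
simulated data, not sensitivity on real reads.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .genome import ToyGenome
from .types import CALL_COLUMNS, SampleMethylome, empty_call_frame

logger = logging.getLogger(__name__)

_C2T = str.maketrans("C", "T")
_G2A = str.maketrans("G", "A")
_COMP = str.maketrans("ACGT", "TGCA")

STRANDS = ("OT", "OB", "CTOT", "CTOB")
#: strands whose reference string runs in top-strand orientation
_TOP_ORIENTED = {"OT", "CTOB"}
#: strands whose reads report top-strand cytosines
TOP_REPORTING = {"OT", "CTOT"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Alignment:
    read_id: str
    contig: str
    start: int  # 1-based top-strand coordinate of the leftmost covered base
    strand: str  # OT / OB / CTOT / CTOB
    mismatches: int
    length: int
    unique: bool = True


class ConvertedReference:
    """Bisulfite-converted reference with a k-mer seed index per strand."""

    def __init__(self, genome: ToyGenome, seed_length: int = 20):
        self.genome = genome
        self.seed_length = seed_length
        self.strands: dict[str, dict[str, str]] = {s: {} for s in STRANDS}
        for contig, seq in genome.contigs.items():
            ot = seq.translate(_C2T)
            ob = revcomp(seq).translate(_C2T)
            self.strands["OT"][contig] = ot
            self.strands["OB"][contig] = ob
            self.strands["CTOT"][contig] = revcomp(ot)
            self.strands["CTOB"][contig] = revcomp(ob)
        self._index: dict[str, list[tuple[str, str, int]]] = {}
        k = seed_length
        for strand in STRANDS:
            for contig, s in self.strands[strand].items():
                for off in range(len(s) - k + 1):
                    self._index.setdefault(s[off : off + k], []).append((strand, contig, off))

    def seed_hits(self, kmer: str) -> list[tuple[str, str, int]]:
        return self._index.get(kmer, [])

    def top_start(self, strand: str, contig: str, offset: int, length: int) -> int:
        """Map a match offset on a strand string to a 1-based top-strand start."""
        if strand in _TOP_ORIENTED:
            return offset + 1
        n = len(self.genome.contigs[contig])
        return n - offset - length + 1


def _read_for_strand(read: str, strand: str) -> str:
    """Methylation-insensitive conversion of a read for a candidate strand.

    OT/OB-derived reads carry unconverted (methylated) Cs, removed by C->T;
    CTOT/CTOB-derived reads carry the complementary Gs, removed by G->A.
    """
    return read.translate(_C2T) if strand in ("OT", "OB") else read.translate(_G2A)


def _mismatches(a: str, b: str, limit: int) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def map_read(
    read_id: str,
    read: str,
    reference: ConvertedReference,
    *,
    pbat: bool = True,
    max_mismatches: int = 5,
) -> Optional[Alignment]:
    """Align one read; returns None when unmapped (short, no hit, or tied)."""
    k = reference.seed_length
    L = len(read)
    if L < k:
        logger.debug("read %s shorter than seed length, unmapped", read_id)
        return None
    candidates = ("CTOT", "CTOB") if pbat else STRANDS
    best: Optional[tuple[int, str, str, int]] = None  # (mm, strand, contig, offset)
    tie = False
    seen: set[tuple[str, str, int]] = set()
    converted = {s: _read_for_strand(read, s) for s in set(candidates)}
    for strand in candidates:
        conv = converted[strand]
        for hit_strand, contig, off in reference.seed_hits(conv[:k]):
            if hit_strand != strand or (hit_strand, contig, off) in seen:
                continue
            seen.add((hit_strand, contig, off))
            window = reference.strands[strand][contig][off : off + L]
            if len(window) < L:
                continue
            mm = _mismatches(conv, window, max_mismatches)
            if mm > max_mismatches:
                continue
            if best is None or mm < best[0]:
                best = (mm, strand, contig, off)
                tie = False
            elif mm == best[0] and (strand, contig, off) != best[1:]:
                tie = True
    if best is None or tie:
        return None
    mm, strand, contig, off = best
    return Alignment(
        read_id=read_id,
        contig=contig,
        start=reference.top_start(strand, contig, off, L),
        strand=strand,
        mismatches=mm,
        length=L,
    )


def map_reads(
    reads: Iterable[tuple[str, str]],
    reference: ConvertedReference,
    *,
    pbat: bool = True,
    max_mismatches: int = 5,
) -> list[Alignment]:
    out = []
    for rid, seq in reads:
        aln = map_read(rid, seq, reference, pbat=pbat, max_mismatches=max_mismatches)
        if aln is not None:
            out.append(aln)
    return out


class CallExtractionError(ValueError):
    pass


def _fragment_views(read: str, strand: str) -> str:
    """Return the read as a converted-strand fragment in top orientation.

    For top-reporting strands the result lists the converted *top* strand
    left to right; for bottom-reporting strands it lists the converted
    *bottom* strand's bases at ascending top coordinates.
    """
    if strand == "OT":
        return read
    if strand == "CTOT":
        return revcomp(read)
    if strand == "OB":
        return read[::-1]  # bottom 5'->3' reversed lists bottom bases in top order
    if strand == "CTOB":
        return read.translate(_COMP)
    raise ValueError(strand)


def extract_calls(
    alignments: Iterable[Alignment],
    reads: dict[str, str],
    genome: ToyGenome,
) -> pd.DataFrame:
    """Per-cytosine methylation calls from alignments.

    At each reference cytosine covered by a read: an unconverted base (C on
    the reporting strand) counts as methylated, a converted one (T) as
    unmethylated; anything else (sequencing error) is ignored. Context is
    assigned from the reference trinucleotide, per strand.
    """
    counts: dict[tuple, list[int]] = {}
    for aln in alignments:
        seq = genome.contigs[aln.contig]
        L = aln.length
        if aln.start < 1 or aln.start + L - 1 > len(seq):
            raise CallExtractionError(f"alignment beyond contig end: {aln}")
        read = reads[aln.read_id]
        frag = _fragment_views(read, aln.strand)
        top = aln.strand in TOP_REPORTING
        ref = seq[aln.start - 1 : aln.start - 1 + L]
        for j in range(L):
            gpos = aln.start + j  # 1-based
            if top and ref[j] == "C":
                base = frag[j]
                if base not in "CT":
                    continue
                i0 = gpos - 1
                if i0 + 1 < len(seq) and seq[i0 + 1] == "G":
                    ctx = "CG"
                elif i0 + 2 < len(seq) and seq[i0 + 2] == "G":
                    ctx = "CHG"
                else:
                    ctx = "CHH"
                key = (aln.contig, gpos, "+", ctx)
            elif not top and ref[j] == "G":
                base = frag[j]
                if base not in "CT":
                    continue
                i0 = gpos - 1
                if i0 - 1 >= 0 and seq[i0 - 1] == "C":
                    ctx = "CG"
                elif i0 - 2 >= 0 and seq[i0 - 2] == "C":
                    ctx = "CHG"
                else:
                    ctx = "CHH"
                key = (aln.contig, gpos, "-", ctx)
            else:
                continue
            cnt = counts.setdefault(key, [0, 0])
            cnt[0 if base == "C" else 1] += 1
    rows = [
        (contig, pos, strand, ctx, m, u)
        for (contig, pos, strand, ctx), (m, u) in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=CALL_COLUMNS) if rows else empty_call_frame()


def conversion_efficiency(sample: SampleMethylome | pd.DataFrame) -> float:
    """Bisulfite conversion efficiency (%) from non-CG methylation.

    Unmethylated cytosines outside CG context should read fully converted,
    so 100 minus the non-CG methylation percentage estimates efficiency.
    Raises ValueError when no non-CG observation is available.
    """
    if isinstance(sample, pd.DataFrame):
        sample = SampleMethylome(sample_id="<frame>", calls=sample)
    meth, total = sample.noncg_counts()
    if total == 0:
        raise ValueError("conversion efficiency undefined: no non-CG calls")
    return 100.0 - 100.0 * meth / total
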