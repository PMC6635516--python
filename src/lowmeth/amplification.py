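"""rDNA amplification detection: density scan, region quantification,
fold computation and three-cluster sample classification.

An amplified repeat announces itself twice in low-coverage bisulfite data:
its genomic window soaks up a disproportionate share of CG calls (density
scan), and the fraction of reads mapping to the region rises orders of
magnitude above the background level seen in non-germline controls. Samples
then fall into three states: background (non-amplified, methylated),
intermediate (moderately amplified, lowly methylated) and amplified
(strongly amplified, essentially unmethylated).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import Region, SampleMethylome

#: read-fraction above which a sample counts as strongly amplified (percent)
HIGH_FRACTION_DEFAULT = 1.0
#: region methylation below which a moderately enriched sample is 'intermediate'
INTERMEDIATE_METH_MAX_DEFAULT = 30.0
MIN_REGION_CALLS = 10

CLASSES = ("background", "intermediate", "amplified")


@dataclass
class RegionQuant:
    sample_id: str
    region: Region
    read_fraction: float  # percent of total; call-fraction fallback when flagged
    fraction_source: str  # "reads" or "calls"
    n_region_calls: int
    meth: Optional[float]  # percent, None below MIN_REGION_CALLS
    fold_vs_background: Optional[float] = None
    label: Optional[str] = None
    low_evidence: bool = False


def density_scan(
    samples: Iterable[SampleMethylome],
    window_size: int = 1_000_000,
    *,
    contig_sizes: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """CG-call density ratio per window, replicates pooled before counting.

    Each window's call count is divided by the mean count over all windows,
    so the ratios average to exactly 1. When ``contig_sizes`` is given the
    windows tile the whole genome and empty windows count as zero;
    otherwise only windows containing calls enter the mean. Returns contig,
    start, end, n_cg_calls, density_ratio sorted by descending ratio.
    """
    frames = [s.cg_calls for s in samples]
    if not frames:
        raise ValueError("no samples given")
    cg = pd.concat(frames, ignore_index=True)
    if cg.empty:
        raise ValueError("no CG calls to scan")
    win = (cg["pos"] - 1) // window_size
    counts = (cg["meth"] + cg["unmeth"]).groupby([cg["contig"], win]).sum()
    if contig_sizes is not None:
        index = [
            (contig, w)
            for contig, size in contig_sizes.items()
            for w in range((size + window_size - 1) // window_size)
        ]
        counts = counts.reindex(pd.MultiIndex.from_tuples(index), fill_value=0)
    mean = counts.mean()
    rows = [
        (contig, int(w) * window_size + 1, (int(w) + 1) * window_size, int(n), float(n / mean))
        for (contig, w), n in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "n_cg_calls", "density_ratio"])
    return df.sort_values("density_ratio", ascending=False, ignore_index=True)


def region_call_counts(sample: SampleMethylome, region: Region) -> tuple[int, int]:
    """(methylated, total) CG calls whose position lies inside the region."""
    cg = sample.cg_calls
    sel = (
        (cg["contig"] == region.contig)
        & (cg["pos"] >= region.start)
        & (cg["pos"] <= region.end)
    )
    sub = cg[sel]
    return int(sub["meth"].sum()), int((sub["meth"] + sub["unmeth"]).sum())


def region_read_fraction(
    sample: SampleMethylome,
    region: Region,
    *,
    region_reads: Optional[int] = None,
) -> tuple[float, str]:
    """Percent of the library attributable to the region.

    With alignment-level information (``region_reads`` = reads overlapping
    the region by >=1 bp, with ``sample.total_mapped_reads`` set) this is a
    true read fraction. From a call table alone it falls back to region CG
    calls over total CG calls; the second return value names the source.
    """
    if region_reads is not None:
        if not sample.total_mapped_reads:
            raise ValueError("read fraction undefined: zero mapped reads")
        return 100.0 * region_reads / sample.total_mapped_reads, "reads"
    _, total_region = region_call_counts(sample, region)
    total = sample.n_cg_calls
    if total == 0:
        raise ValueError("read fraction undefined: no calls")
    return 100.0 * total_region / total, "calls"


def count_region_reads(alignments, region: Region) -> int:
    """Reads whose alignment overlaps the region by at least one base."""
    n = 0
    for aln in alignments:
        if (
            aln.contig == region.contig
            and aln.start <= region.end
            and aln.start + aln.length - 1 >= region.start
        ):
            n += 1
    return n


def region_methylation(
    sample: SampleMethylome, region: Region, min_calls: int = MIN_REGION_CALLS
) -> Optional[float]:
    """Pooled CG methylation (%) over the region; None below ``min_calls``."""
    meth, total = region_call_counts(sample, region)
    if total < min_calls:
        return None
    return 100.0 * meth / total


def fold_amplification(sample_fraction: float, background_fraction: float) -> float:
    """Ratio of region fractions; background is a mean over control samples."""
    if background_fraction <= 0:
        raise ValueError("fold undefined: background fraction is zero")
    return sample_fraction / background_fraction


def classify_sample(
    read_fraction: float,
    meth: Optional[float],
    *,
    background_fraction: float,
    high_fraction: float = HIGH_FRACTION_DEFAULT,
    intermediate_meth_max: float = INTERMEDIATE_METH_MAX_DEFAULT,
) -> tuple[str, bool]:
    """Three-state amplification/methylation call for one sample.

    amplified: region fraction above ``high_fraction`` percent;
    intermediate: fraction above the control background mean with defined
    region methylation below ``intermediate_meth_max``; background
    otherwise (flagged low-evidence when methylation was unquantifiable).
    Returns (label, low_evidence).
    """
    if read_fraction > high_fraction:
        return "amplified", False
    if meth is not None and meth < intermediate_meth_max and read_fraction > background_fraction:
        return "intermediate", False
    return "background", meth is None


def quantify_cohort(
    samples: Sequence[SampleMethylome],
    region: Region,
    *,
    region_reads: Optional[dict[str, int]] = None,
    control_ids: Optional[Sequence[str]] = None,
    high_fraction: float = HIGH_FRACTION_DEFAULT,
    intermediate_meth_max: float = INTERMEDIATE_METH_MAX_DEFAULT,
    min_calls: int = MIN_REGION_CALLS,
) -> list[RegionQuant]:
    """Region quantification and classification for a whole cohort.

    The background level is the mean region fraction over the designated
    control samples (``control_ids``; defaults to samples whose metadata
    marks them non-germline). Fractions use alignment read counts when
    ``region_reads`` provides them, else the call-fraction fallback.
    """
    if control_ids is None:
        control_ids = [s.sample_id for s in samples if not s.germline]
    if not control_ids:
        raise ValueError("no control samples to define the background level")
    quants: list[RegionQuant] = []
    for s in samples:
        rr = region_reads.get(s.sample_id) if region_reads else None
        frac, source = region_read_fraction(s, region, region_reads=rr)
        _, n_calls = region_call_counts(s, region)
        quants.append(
            RegionQuant(
                sample_id=s.sample_id,
                region=region,
                read_fraction=frac,
                fraction_source=source,
                n_region_calls=n_calls,
                meth=region_methylation(s, region, min_calls=min_calls),
            )
        )
    by_id = {q.sample_id: q for q in quants}
    background = float(np.mean([by_id[c].read_fraction for c in control_ids]))
    for q in quants:
        q.fold_vs_background = (
            fold_amplification(q.read_fraction, background) if background > 0 else None
        )
        q.label, q.low_evidence = classify_sample(
            q.read_fraction,
            q.meth,
            background_fraction=background,
            high_fraction=high_fraction,
            intermediate_meth_max=intermediate_meth_max,
        )
    return quants


def quants_to_frame(quants: Sequence[RegionQuant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [q.sample_id for q in quants],
            "region": [str(q.region) for q in quants],
            "read_fraction_pct": [q.read_fraction for q in quants],
            "fraction_source": [q.fraction_source for q in quants],
            "n_region_calls": [q.n_region_calls for q in quants],
            "region_meth_pct": [q.meth if q.meth is not None else np.nan for q in quants],
            "fold_vs_background": [
                q.fold_vs_background if q.fold_vs_background is not None else np.nan
                for q in quants
            ],
            "class": [q.label for q in quants],
            "low_evidence": [q.low_evidence for q in quants],
        }
    )
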