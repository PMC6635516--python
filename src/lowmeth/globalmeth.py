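"""Windowed and pooled global CG methylation, repeat partitioning.

The windowed statistic (unweighted mean of per-window methylation over
non-overlapping windows with enough calls) is robust to a single region
being massively over-represented in the library — the property that lets a
low-coverage pipeline report stable global methylation even when an
amplified repeat soaks up a large share of the reads. The pooled statistic
(all calls lumped together) lacks that robustness, and the gap between the
two is itself a diagnostic for amplification.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .types import SampleMethylome

#: the paper-scale default; toy genomes pass a smaller --window
DEFAULT_WINDOW = 10_000_000
MIN_CALLS_DEFAULT = 10_000
MIN_CALLS_PER_WINDOW = 10


@dataclass
class GlobalEstimate:
    mode: str  # windowed / pooled
    value: float  # percent
    n_calls: int
    margin_of_error: Optional[float] = None  # percentage points, from calibration
    low_coverage: bool = False


def window_methylation(
    sample: SampleMethylome, window_size: int = DEFAULT_WINDOW, min_calls: int = 1
) -> pd.DataFrame:
    """Per-window CG call counts and methylation fractions.

    Windows tile each contig half-open on 1-based coordinates: position p
    falls in window floor((p-1)/size). Fractions are NaN below ``min_calls``.
    Returns a DataFrame with contig, start, end, n_cg_calls, meth_fraction.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    cg = sample.cg_calls
    if cg.empty:
        return pd.DataFrame(columns=["contig", "start", "end", "n_cg_calls", "meth_fraction"])
    win = (cg["pos"] - 1) // window_size
    grouped = cg.groupby([cg["contig"], win], sort=True)[["meth", "unmeth"]].sum()
    rows = []
    for (contig, w), row in grouped.iterrows():
        n = int(row["meth"] + row["unmeth"])
        frac = row["meth"] / n if n >= min_calls else np.nan
        rows.append((contig, int(w) * window_size + 1, (int(w) + 1) * window_size, n, frac))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "n_cg_calls", "meth_fraction"])


def global_estimate(
    sample: SampleMethylome,
    mode: str = "windowed",
    *,
    window_size: int = DEFAULT_WINDOW,
    min_calls: int = MIN_CALLS_DEFAULT,
    min_calls_per_window: int = MIN_CALLS_PER_WINDOW,
) -> GlobalEstimate:
    """Global CG methylation (%) by pooling or by unweighted window mean.

    Samples below ``min_calls`` total CG calls are still estimated but
    flagged low-coverage, mirroring a sequencing-depth floor of 10,000 CG
    calls below which the margin of error becomes unacceptable.
    """
    if mode not in ("windowed", "pooled"):
        raise ValueError("mode must be 'windowed' or 'pooled'")
    cg = sample.cg_calls
    n_calls = int((cg["meth"] + cg["unmeth"]).sum())
    low = n_calls < min_calls
    if n_calls == 0:
        return GlobalEstimate(mode=mode, value=float("nan"), n_calls=0, low_coverage=True)
    if mode == "pooled":
        value = 100.0 * cg["meth"].sum() / n_calls
    else:
        win = window_methylation(sample, window_size, min_calls=min_calls_per_window)
        fracs = win["meth_fraction"].dropna()
        value = 100.0 * fracs.mean() if len(fracs) else float("nan")
    return GlobalEstimate(mode=mode, value=float(value), n_calls=n_calls, low_coverage=low)


def partition_by_annotation(
    sample: SampleMethylome, repeat_intervals: Sequence[tuple[str, int, int]]
) -> tuple[float, float, float]:
    """Split CG calls by repeat annotation.

    Returns (repeat methylation %, non-repeat methylation %,
    repeat call fraction %). A call is 'repeat' iff its position lies inside
    any interval (1-based inclusive). Percentages are NaN for empty
    partitions.
    """
    cg = sample.cg_calls
    if cg.empty:
        return float("nan"), float("nan"), float("nan")
    trees: dict[str, IntervalTree] = {}
    for contig, start, end in repeat_intervals:
        trees.setdefault(contig, IntervalTree()).addi(start, end + 1)
    in_repeat = np.zeros(len(cg), dtype=bool)
    pos = cg["pos"].to_numpy()
    contigs = cg["contig"].to_numpy()
    for contig, tree in trees.items():
        sel = np.flatnonzero(contigs == contig)
        if len(sel) == 0:
            continue
        # sorted non-overlapping interval scan beats per-call tree queries here
        tree.merge_overlaps(strict=False)
        ivs = sorted((iv.begin, iv.end - 1) for iv in tree)
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        idx = np.searchsorted(starts, pos[sel], side="right") - 1
        ok = idx >= 0
        in_repeat[sel[ok]] = pos[sel][ok] <= ends[idx[ok]]
    meth = cg["meth"].to_numpy()
    total = meth + cg["unmeth"].to_numpy()
    rep_total = int(total[in_repeat].sum())
    non_total = int(total[~in_repeat].sum())
    rep_pct = 100.0 * meth[in_repeat].sum() / rep_total if rep_total else float("nan")
    non_pct = 100.0 * meth[~in_repeat].sum() / non_total if non_total else float("nan")
    frac = 100.0 * rep_total / (rep_total + non_total)
    return float(rep_pct), float(non_pct), float(frac)


@dataclass
class PairedTestResult:
    statistic: float
    pvalue: float
    n: int
    degenerate: bool = False


def paired_partition_test(pairs: Sequence[tuple[float, float]]) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on per-sample (repeat, non-repeat)
    methylation pairs. Requires at least 6 samples; identical pairs give a
    degenerate (flagged) result."""
    if len(pairs) < 6:
        raise ValueError("need at least 6 paired samples")
    a = np.array([p[0] for p in pairs], dtype=float)
    b = np.array([p[1] for p in pairs], dtype=float)
    if np.all(a == b):
        return PairedTestResult(statistic=float("nan"), pvalue=1.0, n=len(pairs), degenerate=True)
    res = stats.wilcoxon(a, b, alternative="two-sided")
    return PairedTestResult(statistic=float(res.statistic), pvalue=float(res.pvalue), n=len(pairs))
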