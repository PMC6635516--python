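"""Bootstrap margin-of-error calibration for global methylation estimates.

How many CG calls does a low-coverage library need before its global
methylation estimate is trustworthy? Empirical bootstrap: subsample n calls
with replacement from a deep call pool, B times; the half-width of the
central 99% interval of the subsample methylation values is the margin of
error at depth n. Margins follow an asymptotic square-root law
``margin = c / sqrt(n)`` (fractional scale), and the single coefficient c
summarises a tissue's calibration curve; at the 10,000-call sequencing
floor typical coefficients translate to roughly +-1-2 methylation
percentage points.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import SampleMethylome


def default_grid(lo: int = 100, hi: int = 30_000, steps: int = 30) -> np.ndarray:
    """Regularly spaced call-count grid."""
    return np.unique(np.linspace(lo, hi, steps).round().astype(int))


@dataclass
class BootstrapCurve:
    n_calls: np.ndarray  # strictly increasing
    margin_pp: np.ndarray  # percentage points
    B: int = 1000
    ci_level: float = 99.0
    coefficient: Optional[float] = None  # c in margin_fraction = c / sqrt(n)
    degenerate: bool = False
    pool_size: int = 0
    seed: Optional[int] = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"n_calls": self.n_calls, "margin_pp": self.margin_pp})
        if self.coefficient is not None:
            df["fitted_pp"] = predict_margin(self.coefficient, df["n_calls"].to_numpy())
            df["residual_pp"] = df["margin_pp"] - df["fitted_pp"]
        return df


def call_pool(sample: SampleMethylome) -> np.ndarray:
    """Per-observation 0/1 CG methylation pool from a sample's call table."""
    cg = sample.cg_calls
    meth = int(cg["meth"].sum())
    unmeth = int(cg["unmeth"].sum())
    return np.concatenate([np.ones(meth, dtype=np.uint8), np.zeros(unmeth, dtype=np.uint8)])


def bootstrap_margins(
    pool: np.ndarray,
    n_grid: Optional[Sequence[int]] = None,
    *,
    B: int = 1000,
    ci: float = 99.0,
    seed: int = 0,
    by_site: bool = False,
    site_meth: Optional[np.ndarray] = None,
    site_cov: Optional[np.ndarray] = None,
) -> BootstrapCurve:
    """Empirical bootstrap margin-of-error curve over a call-count grid.

    ``pool`` holds one 0/1 entry per CG observation. For each n in the grid,
    B subsamples of n calls are drawn with replacement and the margin is
    half the central ``ci``% percentile interval (linear interpolation) of
    their methylation fractions, in percentage points. For a 0/1 pool the
    with-replacement subsample total is exactly Binomial(n, pool mean),
    which is drawn directly.

    ``by_site=True`` resamples whole sites (with their full call counts)
    instead of individual calls, capturing the extra spread produced when
    calls arrive clustered by locus; supply ``site_meth``/``site_cov``.
    """
    if n_grid is None:
        n_grid = default_grid()
    n_grid = np.asarray(sorted(set(int(n) for n in n_grid)))
    if n_grid.size == 0:
        raise ValueError("empty n_grid")
    if (n_grid <= 0).any():
        raise ValueError("grid entries must be positive")
    pool = np.asarray(pool)
    if pool.size < n_grid.max():
        raise ValueError(
            f"pool of {pool.size} calls smaller than largest grid point {n_grid.max()}"
        )
    rng = np.random.default_rng(seed)
    lo_q, hi_q = (100 - ci) / 2, 100 - (100 - ci) / 2
    phat = float(pool.mean()) if pool.size else float("nan")
    margins = np.empty(n_grid.size)
    if by_site:
        if site_meth is None or site_cov is None:
            raise ValueError("by_site requires site_meth and site_cov")
        site_meth = np.asarray(site_meth, dtype=np.int64)
        site_cov = np.asarray(site_cov, dtype=np.int64)
        mean_cov = site_cov.mean()
    for i, n in enumerate(n_grid):
        child = np.random.default_rng(rng.integers(2**31))  # per-n stream
        if by_site:
            k = max(1, int(round(n / mean_cov)))
            idx = child.integers(0, len(site_cov), size=(B, k))
            num = site_meth[idx].sum(axis=1)
            den = site_cov[idx].sum(axis=1)
            fracs = num / np.maximum(den, 1)
        else:
            fracs = child.binomial(int(n), phat, size=B) / n
        lo, hi = np.percentile(fracs, [lo_q, hi_q])
        margins[i] = 100.0 * (hi - lo) / 2
    return BootstrapCurve(
        n_calls=n_grid, margin_pp=margins, B=B, ci_level=ci, pool_size=pool.size, seed=seed
    )


def fit_asymptotic(curve: BootstrapCurve) -> float:
    """Least-squares coefficient c of margin_fraction = c / sqrt(n).

    Closed form: c = sum(m_i / sqrt(n_i)) / sum(1 / n_i) with m_i on the
    fractional scale. Stored on the curve and returned.
    """
    if curve.n_calls.size < 3:
        raise ValueError("need at least 3 grid points to fit")
    m = curve.margin_pp / 100.0
    n = curve.n_calls.astype(float)
    if np.allclose(m, 0):
        curve.coefficient = 0.0
        curve.degenerate = True
        return 0.0
    c = float((m / np.sqrt(n)).sum() / (1.0 / n).sum())
    curve.coefficient = c
    return c


def predict_margin(c: float, n) -> float | np.ndarray:
    """Predicted margin of error in percentage points at n CG calls."""
    n = np.asarray(n, dtype=float)
    if (n <= 0).any():
        raise ValueError("n must be positive")
    out = 100.0 * c / np.sqrt(n)
    return float(out) if out.ndim == 0 else out
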