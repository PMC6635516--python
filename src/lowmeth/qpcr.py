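"""Relative quantification of rDNA copy number by the ddCt method.

The target assay (fem-rDNA) is normalised against a somatic multi-copy rDNA
control assay within each sample (dCt = Ct_target - Ct_reference), then
against the mean dCt of designated non-germline control samples
(ddCt = dCt - baseline). Fold change assumes classic doubling per cycle:
fold = 2^-ddCt; samples above a fold threshold (default 5) are called
amplified.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

FOLD_THRESHOLD_DEFAULT = 5.0
TARGET_ASSAY = "fem"
REFERENCE_ASSAY = "som"


@dataclass
class QpcrSample:
    sample_id: str
    role: str  # germline / control
    ct_target: list[float] = field(default_factory=list)  # replicate Ct, fem-rDNA
    ct_reference: list[float] = field(default_factory=list)  # replicate Ct, som-rDNA
    delta_ct: Optional[float] = None
    delta_delta_ct: Optional[float] = None
    fold: Optional[float] = None
    amplified: Optional[bool] = None

    def __post_init__(self) -> None:
        if any(ct <= 0 for ct in self.ct_target + self.ct_reference):
            raise ValueError("Ct values must be positive")


def delta_ct(sample: QpcrSample) -> float:
    """mean(Ct target) - mean(Ct reference); replicates are averaged."""
    if not sample.ct_target or not sample.ct_reference:
        raise ValueError(f"{sample.sample_id}: missing assay replicates")
    d = float(np.mean(sample.ct_target) - np.mean(sample.ct_reference))
    sample.delta_ct = d
    return d


def baseline(controls: Sequence[QpcrSample]) -> float:
    """Mean dCt over non-germline control samples."""
    if not controls:
        raise ValueError("no control samples for baseline")
    return float(np.mean([delta_ct(c) if c.delta_ct is None else c.delta_ct for c in controls]))


def fold_change(
    sample_delta_ct: float, baseline_delta_ct: float, *, fold_threshold: float = FOLD_THRESHOLD_DEFAULT
) -> tuple[float, bool]:
    """fold = 2^-(dCt - baseline); amplified iff fold exceeds the threshold."""
    fold = float(2.0 ** -(sample_delta_ct - baseline_delta_ct))
    return fold, fold > fold_threshold


def analyse(
    samples: Sequence[QpcrSample], *, fold_threshold: float = FOLD_THRESHOLD_DEFAULT
) -> pd.DataFrame:
    """Full ddCt analysis of a plate: per-sample dCt, ddCt, fold, call."""
    controls = [s for s in samples if s.role == "control"]
    base = baseline(controls)
    rows = []
    for s in samples:
        d = delta_ct(s) if s.delta_ct is None else s.delta_ct
        s.delta_delta_ct = d - base
        s.fold, s.amplified = fold_change(d, base, fold_threshold=fold_threshold)
        rows.append((s.sample_id, s.role, d, s.delta_delta_ct, s.fold, s.amplified))
    return pd.DataFrame(
        rows, columns=["sample_id", "role", "delta_ct", "delta_delta_ct", "fold", "amplified"]
    )


def read_ct_table(path: str | Path) -> list[QpcrSample]:
    """Read a Ct TSV with columns sample_id, role, assay, replicate, ct.

    Assay labels containing 'fem' map to the target, 'som' to the reference.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "role", "assay", "ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    out: list[QpcrSample] = []
    for (sid, role), grp in df.groupby(["sample_id", "role"], sort=False):
        s = QpcrSample(sample_id=str(sid), role=str(role))
        for _, row in grp.iterrows():
            assay = str(row["assay"]).lower()
            if TARGET_ASSAY in assay:
                s.ct_target.append(float(row["ct"]))
            elif REFERENCE_ASSAY in assay:
                s.ct_reference.append(float(row["ct"]))
            else:
                raise ValueError(f"{path}: unrecognised assay {row['assay']!r}")
        out.append(s)
    return out


def simulate_ct_table(
    copy_factors: dict[str, float],
    roles: dict[str, str],
    *,
    seed: int = 0,
    intercept: float = 18.0,
    reference_ct: float = 15.0,
    noise_sd: float = 0.15,
    replicates: int = 2,
) -> list[QpcrSample]:
    """Synthetic Ct data: Ct = intercept - log2(copy number) + noise.

    Useful for verifying that recovered folds match planted copy-number
    ratios; controls should carry copy factor 1.
    """
    rng = np.random.default_rng(seed)
    out = []
    for sid, k in copy_factors.items():
        s = QpcrSample(sample_id=sid, role=roles.get(sid, "control"))
        for _ in range(replicates):
            s.ct_target.append(intercept - float(np.log2(k)) + rng.normal(0, noise_sd))
            s.ct_reference.append(reference_ct + rng.normal(0, noise_sd))
        out.append(s)
    return out
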