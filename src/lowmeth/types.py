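"""Core containers shared across the pipeline.

Coordinates are 1-based inclusive throughout the public API (the convention
of genome browsers and of Bismark coverage files). BED output is converted
to 0-based half-open at the file boundary only.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: column order of the canonical call table
CALL_COLUMNS = ["contig", "pos", "strand", "context", "meth", "unmeth"]

CONTEXTS = ("CG", "CHG", "CHH")


@dataclass(frozen=True)
class CGCall:
    """A single cytosine observation record.

    ``pos`` is the 1-based coordinate of the cytosine on its contig (for
    bottom-strand cytosines this is the coordinate of the G on the top
    strand, as Bismark reports it). ``context`` is assigned from the
    reference, never from the read.
    """

    contig: str
    pos: int
    strand: str  # "+" or "-"
    context: str  # CG / CHG / CHH
    meth: int
    unmeth: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"bad context {self.context!r}")
        if self.meth < 0 or self.unmeth < 0:
            raise ValueError("negative call counts")

    @property
    def coverage(self) -> int:
        return self.meth + self.unmeth


def empty_call_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "context": pd.Series(dtype=str),
            "meth": pd.Series(dtype=np.int64),
            "unmeth": pd.Series(dtype=np.int64),
        }
    )


def calls_to_frame(calls) -> pd.DataFrame:
    """Build a canonical call DataFrame from an iterable of CGCall."""
    rows = [(c.contig, c.pos, c.strand, c.context, c.meth, c.unmeth) for c in calls]
    if not rows:
        return empty_call_frame()
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


@dataclass
class SampleMethylome:
    """A sample's cytosine calls plus bookkeeping metadata.

    ``calls`` is a DataFrame with columns contig, pos, strand, context,
    meth, unmeth — one row per observed cytosine per strand. Non-CG calls
    may be present per-site, or summarised in ``noncg_meth``/``noncg_total``
    when only aggregate counts are available (as in a conversion report
    accompanying a CG-only coverage file); :func:`noncg_counts` merges both.
    """

    sample_id: str
    calls: pd.DataFrame = field(default_factory=empty_call_frame)
    phenotype: str = "control"  # undiff / female / male / control
    germline: bool = False
    timepoint: Optional[float] = None  # days post-fertilisation
    total_mapped_reads: Optional[int] = None
    noncg_meth: int = 0
    noncg_total: int = 0

    @property
    def cg_calls(self) -> pd.DataFrame:
        return self.calls[self.calls["context"] == "CG"]

    @property
    def n_cg_calls(self) -> int:
        cg = self.cg_calls
        return int((cg["meth"] + cg["unmeth"]).sum())

    def noncg_counts(self) -> tuple[int, int]:
        """(methylated, total) non-CG observations, per-site plus aggregate."""
        noncg = self.calls[self.calls["context"] != "CG"]
        meth = int(noncg["meth"].sum()) + self.noncg_meth
        total = int((noncg["meth"] + noncg["unmeth"]).sum()) + self.noncg_total
        return meth, total


@dataclass(frozen=True)
class Region:
    """A genomic interval, 1-based inclusive."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region {self}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def parse(cls, spec: str) -> "Region":
        """Parse ``contig:start-end`` (commas in numbers tolerated)."""
        try:
            contig, span = spec.rsplit(":", 1)
            lo, hi = span.replace(",", "").split("-")
            return cls(contig, int(lo), int(hi))
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"cannot parse region spec {spec!r}") from exc

    def __str__(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"
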