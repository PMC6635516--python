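"""Readers and writers for call tables, FASTQ and sample manifests.

Two call-table dialects are supported:

* ``native`` — TSV with contig, pos, strand, context, meth, unmeth columns
  and ``#key=value`` header lines carrying sample metadata (including the
  aggregate non-CG counts, Bismark-splitting-report style);
* ``bismark`` — the Bismark coverage format (chrom, start, end, meth%,
  count_meth, count_unmeth), CG-only, strandless (read back as top strand).
"""
from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .types import CALL_COLUMNS, SampleMethylome, empty_call_frame

logger = logging.getLogger(__name__)


class CallTableError(ValueError):
    pass


def write_call_table(sample: SampleMethylome, path: str | Path, *, dialect: str = "native") -> None:
    path = Path(path)
    if dialect == "native":
        with open(path, "w") as fh:
            fh.write(f"#sample_id={sample.sample_id}\n")
            fh.write(f"#phenotype={sample.phenotype}\n")
            fh.write(f"#germline={int(sample.germline)}\n")
            if sample.timepoint is not None:
                fh.write(f"#timepoint={sample.timepoint}\n")
            if sample.total_mapped_reads is not None:
                fh.write(f"#total_mapped_reads={sample.total_mapped_reads}\n")
            fh.write(f"#noncg_meth={sample.noncg_meth}\n")
            fh.write(f"#noncg_total={sample.noncg_total}\n")
            fh.write("\t".join(CALL_COLUMNS) + "\n")
            sample.calls.to_csv(fh, sep="\t", header=False, index=False)
    elif dialect == "bismark":
        cg = sample.cg_calls
        cov = cg["meth"] + cg["unmeth"]
        pct = (100.0 * cg["meth"] / cov.where(cov > 0)).fillna(0.0)
        out = pd.DataFrame(
            {
                "chrom": cg["contig"],
                "start": cg["pos"],
                "end": cg["pos"],
                "meth_pct": pct.round(6),
                "meth": cg["meth"],
                "unmeth": cg["unmeth"],
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _sniff_dialect(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") or first.startswith("contig\t"):
        return "native"
    return "bismark"


def read_call_table(path: str | Path, *, dialect: str | None = None) -> SampleMethylome:
    """Read a call table; dialect is sniffed from the header when omitted."""
    path = Path(path)
    if path.stat().st_size == 0:
        logger.warning("empty call table %s: returning empty methylome", path)
        return SampleMethylome(sample_id=path.stem)
    if dialect is None:
        dialect = _sniff_dialect(path)
    if dialect == "native":
        meta: dict[str, str] = {}
        header_rows = 0
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    header_rows += 1
                    key, _, value = line[1:].strip().partition("=")
                    meta[key] = value
                else:
                    break
        try:
            calls = pd.read_csv(
                path,
                sep="\t",
                skiprows=header_rows,
                dtype={
                    "contig": str,
                    "pos": "int64",
                    "strand": str,
                    "context": str,
                    "meth": "int64",
                    "unmeth": "int64",
                },
            )
        except (ValueError, pd.errors.ParserError) as exc:
            raise CallTableError(f"{path}: {exc}") from exc
        if list(calls.columns) != CALL_COLUMNS:
            raise CallTableError(f"{path}: expected columns {CALL_COLUMNS}, got {list(calls.columns)}")
        bad = ~calls["strand"].isin(["+", "-"])
        if bad.any():
            raise CallTableError(f"{path}: malformed strand at line {header_rows + 2 + int(bad.idxmax())}")
        return SampleMethylome(
            sample_id=meta.get("sample_id", path.stem),
            calls=calls if len(calls) else empty_call_frame(),
            phenotype=meta.get("phenotype", "control"),
            germline=bool(int(meta.get("germline", "0"))),
            timepoint=float(meta["timepoint"]) if "timepoint" in meta else None,
            total_mapped_reads=(
                int(meta["total_mapped_reads"]) if "total_mapped_reads" in meta else None
            ),
            noncg_meth=int(meta.get("noncg_meth", "0")),
            noncg_total=int(meta.get("noncg_total", "0")),
        )
    if dialect == "bismark":
        rows = []
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 6:
                    raise CallTableError(f"{path}: malformed coverage line {i}")
                try:
                    rows.append((parts[0], int(parts[1]), "+", "CG", int(parts[4]), int(parts[5])))
                except ValueError as exc:
                    raise CallTableError(f"{path}: malformed coverage line {i}") from exc
        calls = pd.DataFrame(rows, columns=CALL_COLUMNS) if rows else empty_call_frame()
        return SampleMethylome(sample_id=path.stem, calls=calls)
    raise ValueError(f"unknown dialect {dialect!r}")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


MANIFEST_COLUMNS = ["sample_id", "role", "phenotype", "timepoint", "calls_path", "reads_path"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest TSV; role is 'germline' or 'control'."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("sample_id", "role") if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns: {missing}")
    bad = ~df["role"].isin(["germline", "control"])
    if bad.any():
        raise ValueError(f"manifest {path}: role must be germline/control")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
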