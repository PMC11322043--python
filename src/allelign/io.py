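"""Readers and writers for the supported file dialects.

Inputs
------
- summary statistics: delimited text with a header; column roles are assigned
  by a :class:`~allelign.core.DatasetSpec` (the effect allele plays the ALT
  role, the other allele the REF role)
- PLINK2 ``.pvar``: ``#CHROM POS ID REF ALT`` header line, ``##`` meta-lines
  skipped; extra columns are carried through untouched
- PLINK1 ``.bim``: six headerless columns (chrom, id, cM, pos, a1, a2);
  a1 is treated as the ALT role and a2 as the REF role

All coordinates are 1-based.  Readers return both the raw string-typed frame
(used to rewrite outputs with the original column layout) and a standardized
frame with columns ``chrom, pos, id, a1, a2`` plus whatever statistic roles
the spec maps; the two share a row index.

Report files are TSVs with ``# key=value`` comment headers carrying dataset
label, registry identity and chromosome, so downstream merge/intersect can
validate provenance without a side channel.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import DatasetSpec, normalize_chromosome_series
from .errors import MissingColumn

__all__ = [
    "SUMSTATS_MANDATORY_ROLES",
    "SUMSTATS_OPTIONAL_ROLES",
    "read_dataset",
    "write_report",
    "read_report",
]

SUMSTATS_MANDATORY_ROLES = ("chrom", "pos", "id", "effect_allele", "other_allele")
SUMSTATS_OPTIONAL_ROLES = ("effect_size", "effect_allele_freq", "p_value")

_STAT_ROLES = ("effect_size", "effect_allele_freq", "p_value")
FLOAT_FORMAT = "%.10g"


def _standardize(
    raw: pd.DataFrame,
    chrom_col: str,
    pos_col: str,
    id_col: str,
    alt_col: str,
    ref_col: str,
    stat_cols: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    std = pd.DataFrame(index=raw.index)
    std["chrom"] = normalize_chromosome_series(raw[chrom_col])
    std["pos"] = pd.to_numeric(raw[pos_col], errors="raise").astype(np.int64)
    std["id"] = raw[id_col].astype(str)
    std["a1"] = raw[alt_col].astype(str).str.strip().str.upper()
    std["a2"] = raw[ref_col].astype(str).str.strip().str.upper()
    for role, col in (stat_cols or {}).items():
        std[role] = pd.to_numeric(raw[col], errors="coerce")
    return std


def _read_sumstats(spec: DatasetSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    raw = pd.read_csv(spec.path, sep=spec.delimiter, dtype=str)
    missing = [r for r in SUMSTATS_MANDATORY_ROLES if r not in spec.columns]
    if missing:
        raise MissingColumn(
            f"dataset spec for {spec.dataset_label!r} lacks mandatory role(s): "
            + ", ".join(missing)
        )
    absent = [
        f"{role}={spec.columns[role]!r}"
        for role in spec.columns
        if spec.columns[role] not in raw.columns
    ]
    if absent:
        raise MissingColumn(
            f"column(s) not found in {spec.path}: " + ", ".join(absent)
        )
    stat_cols = {r: spec.columns[r] for r in _STAT_ROLES if r in spec.columns}
    std = _standardize(
        raw,
        chrom_col=spec.columns["chrom"],
        pos_col=spec.columns["pos"],
        id_col=spec.columns["id"],
        alt_col=spec.columns["effect_allele"],
        ref_col=spec.columns["other_allele"],
        stat_cols=stat_cols,
    )
    return raw, std


def _read_pvar(spec: DatasetSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    with open(spec.path) as fh:
        lines = [ln for ln in fh if not ln.startswith("##")]
    if not lines or not lines[0].startswith("#CHROM"):
        raise MissingColumn(f"{spec.path}: expected a '#CHROM ...' header line")
    text = "".join(lines)
    raw = pd.read_csv(_io.StringIO(text), sep="\t", dtype=str)
    raw.columns = [c.lstrip("#") for c in raw.columns]
    for col in ("CHROM", "POS", "ID", "REF", "ALT"):
        if col not in raw.columns:
            raise MissingColumn(f"{spec.path}: .pvar lacks column {col}")
    std = _standardize(raw, "CHROM", "POS", "ID", "ALT", "REF")
    return raw, std


_BIM_COLUMNS = ["CHROM", "ID", "CM", "POS", "A1", "A2"]


def _read_bim(spec: DatasetSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    raw = pd.read_csv(spec.path, sep=r"\s+", header=None, dtype=str)
    if raw.shape[1] != 6:
        raise MissingColumn(
            f"{spec.path}: .bim requires 6 columns, found {raw.shape[1]}"
        )
    raw.columns = _BIM_COLUMNS
    std = _standardize(raw, "CHROM", "POS", "ID", "A1", "A2")
    return raw, std


def read_dataset(spec: DatasetSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an input per its spec; returns (raw frame, standardized frame)."""
    if spec.format == "sumstats":
        return _read_sumstats(spec)
    if spec.format == "pvar":
        return _read_pvar(spec)
    return _read_bim(spec)


# ------------------------------------------------------------------- reports


def write_report(
    df: pd.DataFrame,
    path: Union[str, Path],
    *,
    dataset: str,
    registry: str,
    chrom: str,
) -> None:
    """Write a per-chromosome report TSV with provenance comment headers."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# dataset={dataset}\n")
        fh.write(f"# registry={registry}\n")
        fh.write(f"# chrom={chrom}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_report(path: Union[str, Path]) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a report TSV; returns (frame, provenance metadata)."""
    path = Path(path)
    meta: dict[str, str] = {}
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# ") and "=" in line:
                key, _, value = line[2:].rstrip("\n").partition("=")
                meta[key] = value
            else:
                body.append(line)
    frame = pd.read_csv(_io.StringIO("".join(body)), sep="\t", dtype=str)
    return frame, meta
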