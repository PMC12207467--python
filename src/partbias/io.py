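"""File formats and result tables.

Reads LDSC-dialect summary statistics (whitespace/tab-delimited, header
SNP A1 A2 N Z, optionally gzipped) and LD-score tables (SNP, L2), and writes
tab-separated result tables with a provenance header (version, configuration
hash, seeds) in ``#``-prefixed comment lines.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger("partbias.io")

from . import __version__

__all__ = ["read_sumstats", "read_ldscores", "write_sumstats", "write_ldscores",
           "write_results", "provenance_header"]

_SUMSTATS_COLS = ["SNP", "A1", "A2", "N", "Z"]


def _read_table(path) -> pd.DataFrame:
    # pandas autodetects gzip from the extension; sep=r"\s+" covers both
    # whitespace- and tab-delimited dialects
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    df.columns = [c.upper() for c in df.columns]
    return df


def read_sumstats(path) -> pd.DataFrame:
    """Read an LDSC-style ``.sumstats[.gz]`` table, validating its contract."""
    df = _read_table(path)
    missing = [c for c in _SUMSTATS_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing sumstats columns {missing}")
    df = df[_SUMSTATS_COLS]
    dup = df["SNP"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicate SNP id {df['SNP'][dup].iloc[0]!r}")
    bad = ~pd.to_numeric(df["Z"], errors="coerce").notna() | (df["N"] <= 0)
    if bad.any():
        if bad.mean() > 0.01:
            raise ValueError(f"{path}: {int(bad.sum())} unparseable/invalid rows (>1%)")
        logger.warning("%s: dropped %d unparseable/invalid rows", path, int(bad.sum()))
        df = df[~bad]
    df = df.astype({"N": float, "Z": float})
    if not df["Z"].apply(lambda v: v == v and abs(v) != float("inf")).all():
        raise ValueError(f"{path}: non-finite Z statistics")
    return df.reset_index(drop=True)


def read_ldscores(path) -> pd.DataFrame:
    """Read an ``.l2.ldscore[.gz]``-style table (columns SNP, L2)."""
    df = _read_table(path)
    if "L2" not in df.columns or "SNP" not in df.columns:
        raise ValueError(f"{path}: LD score table must have columns SNP, L2")
    df = df[["SNP", "L2"]].astype({"L2": float})
    if len(df) == 0:
        raise ValueError(f"{path}: empty LD score table")
    return df


def write_sumstats(df: pd.DataFrame, path) -> None:
    df[_SUMSTATS_COLS].to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_ldscores(df: pd.DataFrame, path) -> None:
    df[["SNP", "L2"]].to_csv(path, sep="\t", index=False, float_format="%.6g")


def provenance_header(config: dict) -> str:
    """Provenance comment block: version, config hash, and the config itself."""
    blob = json.dumps(config, sort_keys=True, default=str)
    digest = hashlib.sha256(blob.encode()).hexdigest()[:12]
    lines = [f"# partbias {__version__}", f"# config_hash {digest}"]
    lines += [f"# {k} = {v}" for k, v in sorted(config.items())]
    return "\n".join(lines) + "\n"


def write_results(table: pd.DataFrame, path, config: dict | None = None,
                  float_format: str = "%.6g") -> None:
    """Write a result TSV with a provenance header; fixed column order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(provenance_header(config))
        table.to_csv(fh, sep="\t", index=False, float_format=float_format)
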