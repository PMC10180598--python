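"""Reading and writing the pipeline's file formats.

The phenotype table is a CSV with one row per planted tree:

    tree_id, family, trial, series, rep, row, col, status,
    height_m, dbh_cm, survival [, provenance, lat, long]

``status`` is ``live``/``dead``/``filler``; growth traits are missing
exactly for dead and filler trees; ``(trial, row, col)`` is unique.
Files deposited alongside publications often start with a block of
metadata lines (``skip_rows``) and use their own column names
(``column_map``).  Missing values may be written as the empty string,
``NA`` or ``.``.

All report writers use a deterministic column order and 6-significant-
digit floats, and every run directory carries a manifest (config hash,
seed, package version, timestamp) so two runs on identical input
produce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "read_phenotypes",
    "write_phenotypes",
    "write_reports",
]

REQUIRED_COLUMNS = [
    "tree_id",
    "family",
    "trial",
    "series",
    "rep",
    "row",
    "col",
    "status",
    "height_m",
    "dbh_cm",
    "survival",
]
OPTIONAL_COLUMNS = ["provenance", "lat", "long"]
NA_TOKENS = ["", "NA", "."]
VALID_STATUS = {"live", "dead", "filler"}


def read_phenotypes(
    path,
    skip_rows: int = 0,
    column_map: dict | None = None,
) -> pd.DataFrame:
    """Read and validate a phenotype CSV.

    Parameters
    ----------
    path : path-like
    skip_rows : int
        Leading metadata lines to skip before the header (files
        deposited with publications commonly carry such a block).
    column_map : dict, optional
        Mapping from the file's column names to the canonical names in
        :data:`REQUIRED_COLUMNS`.

    Raises
    ------
    ValueError
        Listing any missing required column, duplicated (trial, row,
        col) cells, invalid survival codes or non-numeric trait values
        (with their line numbers).
    """
    frame = pd.read_csv(
        path,
        skiprows=skip_rows,
        na_values=NA_TOKENS,
        keep_default_na=False,
        dtype={"status": str},
    )
    if column_map:
        frame = frame.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")

    frame["trial"] = frame["trial"].astype(str)
    dup = frame.duplicated(subset=["trial", "row", "col"], keep=False)
    if dup.any():
        offenders = frame.loc[dup, ["trial", "row", "col"]].drop_duplicates().head(5)
        raise ValueError(f"duplicate (trial,row,col) cells:\n{offenders.to_string(index=False)}")
    bad_status = set(frame["status"].dropna()) - VALID_STATUS
    if bad_status:
        raise ValueError(f"invalid status value(s): {sorted(bad_status)}")
    for col in ("height_m", "dbh_cm", "survival", "row", "col"):
        try:
            frame[col] = pd.to_numeric(frame[col])
        except (ValueError, TypeError):
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = frame.index[coerced.isna() & frame[col].notna()][0]
            raise ValueError(
                f"non-numeric value {frame.loc[bad, col]!r} in column {col!r} "
                f"(data line {bad + 1})"
            ) from None
    sv = frame["survival"].dropna()
    if not set(np.unique(sv)) <= {0.0, 1.0}:
        raise ValueError("survival must be 0/1")
    filler = frame["status"] == "filler"
    if frame.loc[filler, ["height_m", "dbh_cm"]].notna().any().any():
        raise ValueError("filler trees must not carry trait values")
    return frame


def _format_float(x) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    return f"{x:.6g}" if isinstance(x, (float, np.floating)) else str(x)


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    out = frame.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(_format_float)
    out.to_csv(path, index=False, na_rep="")


def write_phenotypes(frame: pd.DataFrame, path) -> None:
    """Write a phenotype table (canonical column order, '' for missing).

    Round-trips exactly through :func:`read_phenotypes`.
    """
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in frame.columns]
    frame[cols].to_csv(path, index=False, na_rep="")


def config_hash(config: dict) -> str:
    """Stable SHA-256 of a JSON-serialisable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_reports(suite, out_dir, config: dict | None = None, seed=None) -> dict:
    """Write the suite's report files to ``out_dir``.

    Produces ``parameters.csv`` (variance components + heritabilities
    per trait x model), ``criteria.csv`` (AIC/BIC with deltas against
    the complete-blocking benchmark), one ``blup_<trait>_<model>.csv``
    per fit, and ``manifest.json``.  Table content is deterministic;
    only the manifest carries a timestamp.  Returns {name: path}.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}

    params = suite.parameter_table()
    if not params.empty:
        params = params.sort_values(["trait", "model"]).reset_index(drop=True)
    _write_csv(params, out_dir / "parameters.csv")
    written["parameters"] = out_dir / "parameters.csv"

    crit = suite.criteria_table()
    if not crit.empty:
        crit = crit.sort_values(["trait", "model"]).reset_index(drop=True)
    _write_csv(crit, out_dir / "criteria.csv")
    written["criteria"] = out_dir / "criteria.csv"

    for (trait, model), res in sorted(suite.fits.items()):
        bv = res.breeding_values()
        name = f"blup_{trait}_{model}.csv"
        _write_csv(bv, out_dir / name)
        written[name] = out_dir / name

    manifest = {
        "config_hash": config_hash(config or {}),
        "seed": seed,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "n_fits": len(suite.fits),
        "failures": {f"{k[0]}/{k[1]}": v for k, v in suite.failures.items()},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    written["manifest"] = out_dir / "manifest.json"
    return written
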