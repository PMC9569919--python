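"""Reading and writing site data as CSV, plus result/manifest JSON helpers.

The interchange format is a single CSV with header ``site_id, y,
<covariate columns...>``; rows are grouped by site_id preserving file order
within a site, outcomes parse strictly as 0/1 and the intercept column is
prepended automatically unless the file declares one named ``intercept``.
Floats are written at full precision (repr), so a write/read round-trip
reproduces every value exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .model_core import SiteData

__all__ = ["read_sites", "write_sites", "write_json", "read_json"]

_RESERVED = ("site_id", "y")


def read_sites(path) -> list[SiteData]:
    """Load one CSV of patient rows into per-site design matrices.

    Raises :class:`FormatError` with 1-based data row numbers (the header is
    row 1) for missing columns, non-binary outcomes or an empty file.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    for col in _RESERVED:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    covar_cols = [c for c in df.columns if c not in _RESERVED]
    if not covar_cols:
        raise FormatError(f"{path}: no covariate columns")

    y = pd.to_numeric(df["y"], errors="coerce")
    bad = df.index[~y.isin([0.0, 1.0])]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
        raise FormatError(f"{path}: outcome y must be 0 or 1 (bad rows: {rows})")
    X = df[covar_cols].apply(pd.to_numeric, errors="coerce")
    bad = df.index[X.isna().any(axis=1)]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:5])
        raise FormatError(f"{path}: non-numeric covariate values (bad rows: {rows})")

    sites = []
    for site_id, grp in df.groupby("site_id", sort=False):
        Xg = grp[covar_cols].to_numpy(dtype=float)
        if "intercept" not in covar_cols:
            Xg = np.column_stack([np.ones(len(grp)), Xg])
        sites.append(SiteData(site_id=str(site_id), X=Xg, y=grp["y"].to_numpy(dtype=float)))
    return sites


def write_sites(sites: list[SiteData], path, covariate_names=None) -> None:
    """Write sites to one CSV, full-precision floats, intercept column kept."""
    path = Path(path)
    p = sites[0].p
    if covariate_names is None:
        covariate_names = ["intercept"] + [f"x{j}" for j in range(1, p)]
    if len(covariate_names) != p:
        raise FormatError(f"{len(covariate_names)} covariate names for p={p} columns")
    with path.open("w") as fh:
        fh.write(",".join(["site_id", "y", *covariate_names]) + "\n")
        for site in sites:
            for j in range(site.n_i):
                vals = [repr(float(v)) for v in site.X[j]]
                fh.write(",".join([site.site_id, str(int(site.y[j])), *vals]) + "\n")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj
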