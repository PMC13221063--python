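"""Shared I/O: site tables (CSV), fitted curves (CSV/JSON), and ESRI
ASCII grids.

The grid dialect is the plain-text raster format used by desktop GIS
exports: a six-line header (ncols, nrows, xllcorner|xllcenter,
yllcorner|yllcenter, cellsize, NODATA_value) followed by row-major cell
values, north row first. NODATA cells become NaN in memory and are excluded
from every downstream statistic.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import SuitabilityCurve

__all__ = [
    "REQUIRED_SITE_COLUMNS",
    "read_site_table",
    "write_site_table",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_curves",
    "write_curves",
]

REQUIRED_SITE_COLUMNS = ("site_id", "abundance")


def read_site_table(path, expected_parameters=None) -> pd.DataFrame:
    """Read and validate a site CSV.

    Requires ``site_id`` and ``abundance`` columns; any other columns are
    treated as environmental parameters or substrate fractions. Negative
    abundance is a hard error naming the offending row. When
    ``expected_parameters`` is given, columns outside the expected set are
    preserved but reported with a warning.
    """
    df = pd.read_csv(path)
    if expected_parameters is not None:
        known = set(REQUIRED_SITE_COLUMNS) | set(expected_parameters) | {
            "sand", "silt", "clay", "gravel", "true_suitability",
        }
        extra = [c for c in df.columns if c not in known]
        if extra:
            warnings.warn(f"site table has unexpected column(s) {extra}; kept as-is",
                          stacklevel=2)
    missing = [c for c in REQUIRED_SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site table missing required columns: {missing}")
    na_rows = df.index[df[list(REQUIRED_SITE_COLUMNS)].isna().any(axis=1)]
    if len(na_rows):
        raise ValueError(
            f"rows with missing required fields: {list(na_rows + 2)} "
            "(1-based, counting the header)"
        )
    bad = df.index[df["abundance"] < 0]
    if len(bad):
        raise ValueError(
            f"negative abundance in row(s) {list(bad + 2)} (1-based, counting "
            "the header)"
        )
    return df


def write_site_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Parse an ESRI ASCII grid into (array, header dict).

    NODATA cells are returned as NaN. Center-registered files (xllcenter /
    yllcenter) are converted to the canonical corner registration.
    """
    tokens_header: dict[str, float] = {}
    values: list[float] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
            "yllcenter", "cellsize", "nodata_value",
        }:
            tokens_header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for line in lines[i:]:
        values.extend(float(t) for t in line.split())

    for key in ("ncols", "nrows", "cellsize"):
        if key not in tokens_header:
            raise ValueError(f"grid header missing {key!r}")
    ncols = int(tokens_header["ncols"])
    nrows = int(tokens_header["nrows"])
    cell = tokens_header["cellsize"]
    if len(values) != nrows * ncols:
        raise ValueError(
            f"value count {len(values)} does not match header "
            f"{nrows} x {ncols} = {nrows * ncols}"
        )
    # convert center registration to corner
    if "xllcenter" in tokens_header:
        tokens_header["xllcorner"] = tokens_header.pop("xllcenter") - cell / 2.0
    if "yllcenter" in tokens_header:
        tokens_header["yllcorner"] = tokens_header.pop("yllcenter") - cell / 2.0
    tokens_header.setdefault("xllcorner", 0.0)
    tokens_header.setdefault("yllcorner", 0.0)
    nodata = tokens_header.get("nodata_value")
    arr = np.array(values, dtype=float).reshape(nrows, ncols)
    if nodata is not None:
        arr[arr == nodata] = np.nan
    meta = {
        "ncols": ncols,
        "nrows": nrows,
        "xllcorner": tokens_header["xllcorner"],
        "yllcorner": tokens_header["yllcorner"],
        "cellsize": cell,
        "nodata_value": nodata if nodata is not None else -9999.0,
    }
    return arr, meta


def write_ascii_grid(arr: np.ndarray, path, meta: dict | None = None) -> None:
    """Write a 2-D array as an ESRI ASCII grid; NaN becomes NODATA."""
    a = np.asarray(arr, dtype=float)
    if a.ndim != 2:
        raise ValueError("grid must be 2-D")
    meta = meta or {}
    nodata = meta.get("nodata_value", -9999.0)
    header = (
        f"ncols {a.shape[1]}\n"
        f"nrows {a.shape[0]}\n"
        f"xllcorner {meta.get('xllcorner', 0.0)}\n"
        f"yllcorner {meta.get('yllcorner', 0.0)}\n"
        f"cellsize {meta.get('cellsize', 1.0)}\n"
        f"NODATA_value {nodata}\n"
    )
    body = np.where(np.isfinite(a), a, nodata)
    with open(path, "w") as fh:
        fh.write(header)
        for row in body:
            fh.write(" ".join(format(v, ".10g") for v in row) + "\n")


def write_curves(curves: dict[str, SuitabilityCurve], path) -> None:
    """Serialise fitted curves to CSV (parameter, mu, sigma, low, high)."""
    rows = [dataclasses.asdict(c) for c in curves.values()]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_curves(path) -> dict[str, SuitabilityCurve]:
    """Read curves back from CSV or JSON, losslessly."""
    path = Path(path)
    if path.suffix == ".json":
        rows = json.loads(path.read_text())
    else:
        rows = pd.read_csv(path).to_dict("records")
    return {
        r["parameter"]: SuitabilityCurve(
            parameter=str(r["parameter"]),
            mu=float(r["mu"]),
            sigma=float(r["sigma"]),
            low=float(r["low"]),
            high=float(r["high"]),
        )
        for r in rows
    }
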