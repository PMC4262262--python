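"""Esri ASCII grid I/O for per-layer landscape initialization and output.

Only the plain-text ``.asc`` dialect is supported: a six-line header
(ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value) followed by
nrows whitespace-separated data rows, top row first.  NODATA cells are
returned as NaN.
"""

from __future__ import annotations

import numpy as np

__all__ = ["RasterFormatError", "read_ascii_grid", "write_ascii_grid"]

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


class RasterFormatError(ValueError):
    """Malformed Esri ASCII grid; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Read an Esri ASCII grid.

    Returns ``(values, meta)`` where ``values`` is a float array of shape
    (nrows, ncols) with NODATA replaced by NaN, and ``meta`` holds the
    header fields (keys as in :data:`_HEADER_KEYS`).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    meta: dict[str, float] = {}
    for i, key in enumerate(_HEADER_KEYS):
        if i >= len(lines):
            raise RasterFormatError(f"missing header line '{key}'", i + 1)
        parts = lines[i].split()
        if len(parts) != 2 or parts[0].lower() != key:
            raise RasterFormatError(
                f"expected header '{key} <value>', got {lines[i]!r}", i + 1
            )
        try:
            meta[key] = float(parts[1])
        except ValueError:
            raise RasterFormatError(f"non-numeric value for '{key}'", i + 1) from None

    ncols, nrows = int(meta["ncols"]), int(meta["nrows"])
    if ncols <= 0 or nrows <= 0:
        raise RasterFormatError("ncols and nrows must be positive", 1)

    rows = []
    for j, line in enumerate(lines[len(_HEADER_KEYS):], start=len(_HEADER_KEYS) + 1):
        if not line.strip():
            continue
        try:
            row = np.array(line.split(), dtype=float)
        except ValueError:
            raise RasterFormatError("non-numeric data value", j) from None
        if row.size != ncols:
            raise RasterFormatError(
                f"expected {ncols} values per row, got {row.size}", j
            )
        rows.append(row)
    if len(rows) != nrows:
        raise RasterFormatError(
            f"expected {nrows} data rows, got {len(rows)}", len(lines)
        )

    values = np.vstack(rows)
    values[values == meta["nodata_value"]] = np.nan
    return values, meta


def write_ascii_grid(
    values: np.ndarray,
    path,
    cellsize: float = 10.0,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    nodata_value: float = -9999.0,
) -> None:
    """Write a 2-D array as an Esri ASCII grid; NaN becomes NODATA."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("raster values must be a 2-D array")
    nrows, ncols = values.shape
    out = np.where(np.isnan(values), nodata_value, values)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {xllcorner:.10g}\n")
        fh.write(f"yllcorner {yllcorner:.10g}\n")
        fh.write(f"cellsize {cellsize:.10g}\n")
        fh.write(f"NODATA_value {nodata_value:.10g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
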