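"""Assemble per-scan-point fit results into 2-D parameter maps.

Scan points follow a row-major raster (x/column fastest).  Maps carry a
validity mask; invalid cells (missing or non-converged points, or points
below an intensity threshold) stay masked through rendering, where they map
to gray level 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ScanGrid:
    """Scanning-stage raster: n_rows × n_cols points spaced by ``step`` μm."""

    n_rows: int
    n_cols: int
    step: float
    origin: tuple[float, float] = (0.0, 0.0)
    raster: str = "row_major_x_fast"

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.step > 0:
            raise ValueError("step must be positive")

    @property
    def n_points(self) -> int:
        return self.n_rows * self.n_cols


@dataclass
class ParameterMap:
    """2-D field of one fitted parameter over the scan grid."""

    values: np.ndarray
    valid_mask: np.ndarray
    parameter_name: str = ""
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape or self.values.ndim != 2:
            raise ValueError("values and valid_mask must be matching 2-D arrays")

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]


def assemble(
    fit_table: pd.DataFrame,
    grid: ScanGrid,
    parameter: str,
    valid_column: str | None = None,
) -> ParameterMap:
    """Place one fit-table column onto the scan grid.

    ``fit_table`` needs integer ``x_index``/``y_index`` columns (column /
    row of the scan raster).  Cells with no row, NaN values, or a falsy
    ``valid_column`` entry are masked.  Duplicate points are an error.
    """
    required = {"x_index", "y_index", parameter}
    missing = required - set(fit_table.columns)
    if missing:
        raise ValueError(f"fit table missing columns: {sorted(missing)}")
    xi = fit_table["x_index"].to_numpy(dtype=int)
    yi = fit_table["y_index"].to_numpy(dtype=int)
    if np.any((xi < 0) | (xi >= grid.n_cols) | (yi < 0) | (yi >= grid.n_rows)):
        raise ValueError("fit table indices outside the scan grid")
    flat = yi * grid.n_cols + xi
    if len(np.unique(flat)) != len(flat):
        raise ValueError("duplicate scan point in fit table")
    values = np.full((grid.n_rows, grid.n_cols), np.nan)
    values[yi, xi] = fit_table[parameter].to_numpy(dtype=float)
    valid = np.zeros_like(values, dtype=bool)
    ok = np.isfinite(fit_table[parameter].to_numpy(dtype=float))
    if valid_column is not None:
        ok &= fit_table[valid_column].to_numpy(dtype=bool)
    valid[yi[ok], xi[ok]] = True
    values[~valid] = np.nan
    return ParameterMap(values, valid, parameter_name=parameter)


def disassemble(pmap: ParameterMap) -> pd.DataFrame:
    """Inverse of :func:`assemble` for complete maps (row per grid point)."""
    nr, nc = pmap.values.shape
    yi, xi = np.divmod(np.arange(nr * nc), nc)
    return pd.DataFrame({
        "x_index": xi,
        "y_index": yi,
        pmap.parameter_name or "value": pmap.values.ravel(),
    })


def threshold_mask(
    pmap: ParameterMap,
    intensity_map: ParameterMap,
    threshold: float,
) -> ParameterMap:
    """Mask map cells whose companion intensity falls below ``threshold``.

    Used to suppress artefactual spacings at points with little or no peak
    intensity.  Idempotent and monotone in the threshold.
    """
    if intensity_map.values.shape != pmap.values.shape:
        raise ValueError("map shapes differ")
    keep = pmap.valid_mask & intensity_map.valid_mask & \
        (intensity_map.values >= threshold)
    values = np.where(keep, pmap.values, np.nan)
    return replace(pmap, values=values, valid_mask=keep)


def render_grayscale(
    pmap: ParameterMap,
    value_range: tuple[float, float] | None = None,
    bit_depth: int = 8,
) -> np.ndarray:
    """Render a parameter map to a grayscale integer image for DIC.

    Values are scaled linearly over ``value_range`` (default: the 1st–99th
    percentile of valid cells, which keeps hot cells from compressing the
    contrast) and clipped; masked cells render as 0.  Deterministic.
    """
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    if value_range is None:
        vv = pmap.valid_values
        if vv.size == 0:
            lo, hi = 0.0, 1.0
        else:
            lo, hi = np.percentile(vv, [1.0, 99.0])
    else:
        lo, hi = map(float, value_range)
        if not lo < hi:
            raise ValueError("value_range must be increasing")
    span = max(hi - lo, np.finfo(float).tiny)
    top = 2 ** bit_depth - 1
    scaled = np.clip((pmap.values - lo) / span, 0.0, 1.0) * top
    scaled = np.where(pmap.valid_mask, scaled, 0.0)
    return np.rint(scaled).astype(np.uint8 if bit_depth == 8 else np.uint16)


def rescale_grayscale(image: np.ndarray, value_range: tuple[float, float],
                      bit_depth: int = 8) -> np.ndarray:
    """Map a rendered grayscale image back to parameter units."""
    lo, hi = map(float, value_range)
    return lo + image.astype(float) / (2 ** bit_depth - 1) * (hi - lo)
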