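"""Fibril-level strain and reorientation from matched scan points.

Comparing the same tissue volume across load steps requires matching scan
points between the undeformed and deformed maps: each reference point is
carried through the DIC displacement field and snapped to the nearest
deformed scan point.  Matched pairs then give

* fibril strain        ε_F = (D_def − D_ref) / D_ref,
* reorientation        the change in the (180°-periodic) deviation of the
  mean fibril angle χ₀ from the loading axis, positive toward the axis,
* width changes        Δw_χ (angular spread) and Δw_q (axial disorder).

Distribution summaries (histogram + Gaussian KDE with Silverman
bandwidth) describe D-period and orientation populations per load state.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .dic import DisplacementField, displace_points
from .mapping import ScanGrid

logger = logging.getLogger(__name__)


def signed_axis_deviation(chi: float, axis: float) -> float:
    """Signed shortest-arc deviation of a 180°-periodic angle from an axis."""
    return ((chi - axis + 90.0) % 180.0) - 90.0


def axis_deviation(chi: float, axis: float) -> float:
    """Unsigned shortest-arc deviation (degrees in [0, 90])."""
    return abs(signed_axis_deviation(chi, axis))


def circular_sd_180(angles_deg) -> float:
    """Circular standard deviation of 180°-periodic angles, in degrees."""
    a = np.radians(2.0 * np.asarray(angles_deg, dtype=float))
    R = abs(np.mean(np.exp(1j * a)))
    if R <= 0:
        return float("inf")
    return math.degrees(math.sqrt(max(-2.0 * math.log(R), 0.0))) / 2.0


@dataclass
class MatchedPointPair:
    """A reference scan point paired with its deformed counterpart."""

    ref_index: tuple[int, int]      # (row, col) on the reference grid
    def_index: tuple[int, int]
    ref_params: dict | None
    def_params: dict | None
    snap_distance: float            # scan steps from displaced point to snap
    flagged: bool                   # snap beyond one step, or fallback used


def match_points(
    ref_grid: ScanGrid,
    def_grid: ScanGrid,
    field: DisplacementField,
    map_scale: float = 1.0,
    ref_table: pd.DataFrame | None = None,
    def_table: pd.DataFrame | None = None,
) -> list[MatchedPointPair]:
    """Match reference scan points to deformed scan points through DIC.

    The DIC field must have been computed on the rendered maps of the same
    two scans; ``map_scale`` is the rendered pixels per scan step.  Each
    reference point is displaced, converted to deformed-grid indices and
    snapped to the nearest deformed point; snaps beyond one scan step are
    flagged, displaced points outside the deformed scan are dropped (with a
    log entry).  Per-point fit records are attached when tables are given.
    """
    def lookup(table):
        if table is None:
            return None
        return {(int(r.y_index), int(r.x_index)): r._asdict()
                for r in table.itertuples(index=False)}

    ref_lut, def_lut = lookup(ref_table), lookup(def_table)
    rows, cols = np.meshgrid(np.arange(ref_grid.n_rows), np.arange(ref_grid.n_cols),
                             indexing="ij")
    points_px = np.stack([rows.ravel(), cols.ravel()], axis=1) * map_scale
    displaced, interp_ok = displace_points(points_px, field)
    displaced_steps = displaced / map_scale

    pairs: list[MatchedPointPair] = []
    dropped = 0
    for k, (r, c) in enumerate(zip(rows.ravel(), cols.ravel())):
        dr, dc = displaced_steps[k]
        ir, ic = int(round(dr)), int(round(dc))
        if not (0 <= ir < def_grid.n_rows and 0 <= ic < def_grid.n_cols):
            dropped += 1
            continue
        snap = float(np.hypot(dr - ir, dc - ic))
        pairs.append(MatchedPointPair(
            ref_index=(int(r), int(c)),
            def_index=(ir, ic),
            ref_params=None if ref_lut is None else ref_lut.get((int(r), int(c))),
            def_params=None if def_lut is None else def_lut.get((ir, ic)),
            snap_distance=snap,
            flagged=snap > 1.0 or not bool(interp_ok[k]),
        ))
    if dropped:
        logger.info("match_points: %d displaced points fell outside the deformed scan",
                    dropped)
    return pairs


def _param(params, key):
    if params is None or key not in params:
        return float("nan")
    return params[key]


def fibril_strain(pair: MatchedPointPair) -> float:
    """ε_F = (D_def − D_ref)/D_ref; NaN when either D fit is invalid."""
    d_ref = _param(pair.ref_params, "D")
    d_def = _param(pair.def_params, "D")
    for params in (pair.ref_params, pair.def_params):
        if params is not None and "collagen_converged" in params \
                and not bool(params["collagen_converged"]):
            return float("nan")
    if not (np.isfinite(d_ref) and np.isfinite(d_def) and d_ref > 0):
        return float("nan")
    return (d_def - d_ref) / d_ref


def reorientation(pair: MatchedPointPair, loading_axis: float = 90.0):
    """(Δχ₀ toward the loading axis, Δw_χ) for a matched pair, degrees.

    The deviation of χ₀ from the axis is measured on the 180°-periodic
    circle (shortest arc); a positive first component means the fibril
    angle moved toward the loading axis.  Isotropic-flagged points give
    NaN.
    """
    for params in (pair.ref_params, pair.def_params):
        if params is not None and bool(params.get("isotropic", False)):
            return float("nan"), float("nan")
    chi_ref = _param(pair.ref_params, "chi0")
    chi_def = _param(pair.def_params, "chi0")
    w_ref = _param(pair.ref_params, "w_chi")
    w_def = _param(pair.def_params, "w_chi")
    if not (np.isfinite(chi_ref) and np.isfinite(chi_def)):
        return float("nan"), float("nan")
    toward = axis_deviation(chi_ref, loading_axis) - axis_deviation(chi_def, loading_axis)
    return float(toward), float(w_def - w_ref)


@dataclass
class DistributionSummary:
    """Histogram + kernel density summary of a parameter population."""

    hist_edges: np.ndarray
    hist_counts: np.ndarray
    kde_grid: np.ndarray
    kde_density: np.ndarray
    mode: float
    mean: float
    sd: float


def distribution_summary(values, weights=None, bins: int = 20,
                         grid_points: int = 512) -> DistributionSummary:
    """Summarize a sample with a histogram and a Gaussian KDE.

    The KDE uses Silverman's bandwidth; the mode is the argmax of the
    density on a ``grid_points`` grid.  An all-equal sample degenerates to
    a delta at the common value (represented by a numerically narrow
    Gaussian so the density still integrates to one).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 5:
        raise ValueError("at least 5 finite values are required")
    w = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)[: v.size]
    mean = float(np.average(v, weights=w))
    sd = float(math.sqrt(np.average((v - mean) ** 2, weights=w)))
    counts, edges = np.histogram(v, bins=bins, weights=w)
    if sd == 0.0:
        eps = max(abs(mean), 1.0) * 1e-9
        grid = np.linspace(mean - 5 * eps, mean + 5 * eps, grid_points)
        density = np.exp(-0.5 * ((grid - mean) / eps) ** 2) / (eps * math.sqrt(2 * math.pi))
        return DistributionSummary(edges, counts, grid, density, mean, mean, 0.0)
    kde = gaussian_kde(v, bw_method="silverman", weights=w)
    h = kde.factor * sd
    grid = np.linspace(v.min() - 3 * h, v.max() + 3 * h, grid_points)
    density = kde(grid)
    mode = float(grid[int(np.argmax(density))])
    return DistributionSummary(edges, counts, grid, density, mode, mean, sd)


def line_profile(pairs, loading_axis: float = 90.0) -> pd.DataFrame:
    """Before/after table of D, w_q, w_χ and |χ₀ − axis| along one scan row.

    All pairs must share a reference row; flagged or missing parameters
    appear as NaN, never dropped, so the row structure is preserved for
    plotting.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty pair selection")
    rows = {p.ref_index[0] for p in pairs}
    if len(rows) != 1:
        raise ValueError("pairs must share a single reference row")
    records = []
    for p in sorted(pairs, key=lambda p: p.ref_index[1]):
        chi_ref = _param(p.ref_params, "chi0")
        chi_def = _param(p.def_params, "chi0")
        records.append({
            "ref_row": p.ref_index[0],
            "ref_col": p.ref_index[1],
            "D_before": _param(p.ref_params, "D"),
            "D_after": _param(p.def_params, "D"),
            "w_q_before": _param(p.ref_params, "w_q"),
            "w_q_after": _param(p.def_params, "w_q"),
            "w_chi_before": _param(p.ref_params, "w_chi"),
            "w_chi_after": _param(p.def_params, "w_chi"),
            "axis_dev_before": axis_deviation(chi_ref, loading_axis)
            if np.isfinite(chi_ref) else float("nan"),
            "axis_dev_after": axis_deviation(chi_def, loading_axis)
            if np.isfinite(chi_def) else float("nan"),
            "snap_distance": p.snap_distance,
            "flagged": p.flagged,
        })
    return pd.DataFrame.from_records(records)


def fibril_to_tissue_ratio(fibril_strain: float, tissue_strain: float) -> float:
    """ε_F/ε_T, the fraction of tissue strain carried by the fibrils."""
    if tissue_strain == 0:
        raise ValueError("tissue strain must be nonzero")
    return fibril_strain / tissue_strain


def prestrain_stress(d_variation: float, fibril_modulus_mpa: float = 500.0) -> float:
    """Stress scale (MPa) of a fractional D-period variation.

    Multiplies the relative D-period spread (e.g. 0.0023 for a 0.23%
    variation) by the collagen fibril modulus.
    """
    return d_variation * fibril_modulus_mpa
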