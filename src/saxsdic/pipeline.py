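"""End-to-end orchestration: frames → fits → maps → DIC → fibril mechanics.

These helpers chain the individual modules the way an experiment is
processed: every frame of a scan is reduced to radial and azimuthal
profiles and fitted (collagen 5th order, IFC 2nd order, paired azimuthal
lobes); the per-point results become parameter maps; the collagen peak
intensity maps of two load states drive the DIC matching; matched pairs
yield fibril strain and reorientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import peaks
from .dic import DICConfig, DisplacementField, correlate
from .geometry import DetectorFrame, DetectorGeometry, azimuthal_integrate, radial_integrate
from .mapping import ParameterMap, ScanGrid, assemble, render_grayscale
from .nanomech import fibril_strain, match_points, reorientation
from .synth import ScanSim

DEFAULT_Q_RANGE = (0.06, 0.88)
DEFAULT_N_BINS = 330   # ≈ 0.0025 nm⁻¹ bins


def reduce_frame(
    frame: DetectorFrame,
    geometry: DetectorGeometry,
    q_range=DEFAULT_Q_RANGE,
    n_bins: int = DEFAULT_N_BINS,
    chi_band=peaks.COLLAGEN_WINDOW,
    chi_bins: int = 72,
):
    """Radial I(q) plus azimuthal I(χ) (over the 5th-order band) profiles."""
    radial = radial_integrate(frame, geometry, q_range, n_bins)
    azimuthal = azimuthal_integrate(frame, geometry, chi_band, chi_bins)
    return radial, azimuthal


def fit_point(
    frame: DetectorFrame,
    geometry: DetectorGeometry,
    collagen_window=peaks.COLLAGEN_WINDOW,
    ifc_window=peaks.IFC_WINDOW,
    background: str = "exponential",
    q_range=DEFAULT_Q_RANGE,
    n_bins: int = DEFAULT_N_BINS,
    chi_bins: int = 72,
) -> dict:
    """Fit one scan point; returns the flat record used in fit tables."""
    radial, azim = reduce_frame(frame, geometry, q_range=q_range, n_bins=n_bins,
                                chi_band=collagen_window, chi_bins=chi_bins)
    col = peaks.fit_collagen(radial, window=collagen_window, background=background)
    ifc = peaks.fit_ifc(radial, window=ifc_window, background=background)
    azi = peaks.fit_azimuthal(azim)
    return {
        "I_total": peaks.total_intensity(radial),
        "I_c": col.I_c,
        "D": col.D,
        "w_q": col.w_q,
        "collagen_converged": col.fit.converged,
        "collagen_plausible": col.plausible,
        "I_ifc": ifc.I_ifc,
        "D_ifc": ifc.D_ifc,
        "ifc_converged": ifc.fit.converged,
        "chi0": azi.chi0,
        "chi0_raw": azi.chi0_raw,
        "w_chi": azi.w_chi,
        "azimuthal_converged": azi.converged,
        "isotropic": azi.isotropic,
    }


def fit_scan(scan: ScanSim, **fit_kwargs) -> pd.DataFrame:
    """Per-point fit table for a scan (columns x_index, y_index, parameters)."""
    records = []
    for k, frame in enumerate(scan.frames):
        r, c = divmod(k, scan.n_cols)
        rec = {"x_index": c, "y_index": r}
        rec.update(fit_point(frame, scan.geometry, **fit_kwargs))
        records.append(rec)
    return pd.DataFrame.from_records(records)


def collagen_intensity_map(table: pd.DataFrame, grid: ScanGrid) -> ParameterMap:
    return assemble(table, grid, "I_c", valid_column="collagen_converged")


@dataclass
class LoadStepResult:
    """Everything the two-load-step comparison produces."""

    ref_table: pd.DataFrame
    def_table: pd.DataFrame
    ref_map: ParameterMap
    def_map: ParameterMap
    field: DisplacementField
    pairs: list
    fibril_strains: np.ndarray       # per matched pair (NaN where invalid)
    reorientations: np.ndarray       # Δχ₀ toward the loading axis, degrees

    @property
    def unflagged(self) -> np.ndarray:
        return np.array([not p.flagged for p in self.pairs], dtype=bool)


def analyze_load_step(
    ref_scan: ScanSim,
    def_scan: ScanSim,
    dic_config: DICConfig | None = None,
    loading_axis: float = 90.0,
    scan_step_um: float = 15.0,
    bit_depth: int = 16,
    **fit_kwargs,
) -> LoadStepResult:
    """Full diffraction-contrast load-step analysis of two scans.

    Fits both scans, renders their collagen peak-intensity maps, runs DIC
    between them (map scale: one rendered pixel per scan step), matches
    scan points through the displacement field and computes per-pair
    fibril strain and reorientation.
    """
    if dic_config is None:
        # maps are small (one pixel per scan point), so the subset is scaled
        # down from the 25-px default used on full-size maps, and further if
        # the scan grid itself is tiny (images must be >= 2x the subset)
        limit = min(ref_scan.n_rows, ref_scan.n_cols) // 2
        subset = min(13, limit if limit % 2 == 1 else limit - 1)
        dic_config = DICConfig(subset_size=max(subset, 5), step=1,
                               search_radius=7, strain_window=7,
                               correlation_min=0.4)
    ref_table = fit_scan(ref_scan, **fit_kwargs)
    def_table = fit_scan(def_scan, **fit_kwargs)
    ref_grid = ScanGrid(ref_scan.n_rows, ref_scan.n_cols, scan_step_um)
    def_grid = ScanGrid(def_scan.n_rows, def_scan.n_cols, scan_step_um)
    ref_map = collagen_intensity_map(ref_table, ref_grid)
    def_map = collagen_intensity_map(def_table, def_grid)
    # shared gray scaling so DIC sees the same contrast transfer in both states
    vv = np.concatenate([ref_map.valid_values, def_map.valid_values])
    vrange = tuple(np.percentile(vv, [1.0, 99.0]))
    ref_img = render_grayscale(ref_map, vrange, bit_depth=bit_depth)
    def_img = render_grayscale(def_map, vrange, bit_depth=bit_depth)
    field = correlate(ref_img.astype(float), def_img.astype(float), dic_config)
    pairs = match_points(ref_grid, def_grid, field, map_scale=1.0,
                         ref_table=ref_table, def_table=def_table)
    strains = np.array([fibril_strain(p) for p in pairs])
    reor = np.array([reorientation(p, loading_axis)[0] for p in pairs])
    return LoadStepResult(ref_table, def_table, ref_map, def_map, field,
                          pairs, strains, reor)
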