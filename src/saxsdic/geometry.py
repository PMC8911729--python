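"""Detector geometry and reduction of 2-D scattering frames to 1-D profiles.

A small-angle scattering frame records photon counts on a flat detector a
distance ``L`` behind the sample.  A pixel at radius ``r`` from the beam
center scatters at angle ``2θ = atan(r / L)`` and probes the wavevector

    q = (4π / λ) · sin θ        [nm⁻¹]

The azimuth χ is measured counterclockwise from the detector +x (column)
axis, in degrees on [0, 360); a pixel displaced purely along +y (increasing
row index) has χ = 90°.  The full ``atan``/``sin`` geometry is used
throughout — no small-angle approximation.

Reduction bins unmasked pixels into radial I(q) or azimuthal I(χ)
profiles.  The bin statistic is the *mean* pixel count, so intensities are
comparable between bins with different pixel populations; empty bins are
flagged (NaN intensity, zero count), never interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

#: hc in keV·nm: E [keV] · λ [nm] = 1.23984
HC_KEV_NM = 1.23984

RADIAL_Q = "radial_q"
AZIMUTHAL_CHI = "azimuthal_chi"


def energy_to_wavelength(energy: float) -> float:
    """X-ray wavelength in nm for a photon energy in keV (λ = 1.23984 / E)."""
    if not energy > 0:
        raise ValueError(f"energy must be positive, got {energy}")
    return HC_KEV_NM / energy


@dataclass(frozen=True)
class DetectorGeometry:
    """Experiment geometry for a flat photon-counting detector.

    Parameters
    ----------
    distance : float
        Sample-to-detector distance in meters.
    pixel_size : float
        Detector pixel pitch in micrometers.
    beam_center : (float, float)
        Direct-beam position as (row, col) pixel coordinates; may be
        fractional.
    energy : float
        Photon energy in keV.
    frame_shape : (int, int)
        Expected frame shape (rows, cols).
    """

    distance: float
    pixel_size: float
    beam_center: tuple[float, float]
    energy: float
    frame_shape: tuple[int, int]

    def __post_init__(self):
        if not self.distance > 0:
            raise ValueError("distance must be positive")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not self.energy > 0:
            raise ValueError("energy must be positive")
        object.__setattr__(self, "beam_center", tuple(float(c) for c in self.beam_center))
        object.__setattr__(self, "frame_shape", tuple(int(s) for s in self.frame_shape))
        nr, nc = self.frame_shape
        r0, c0 = self.beam_center
        # allow the center to sit somewhat off-frame, but not absurdly so
        if not (-nr <= r0 <= 2 * nr and -nc <= c0 <= 2 * nc):
            raise ValueError("beam_center far outside frame bounds")

    @property
    def wavelength(self) -> float:
        """Wavelength in nm."""
        return energy_to_wavelength(self.energy)


@dataclass
class DetectorFrame:
    """Photon-count image plus exclusion mask (True = excluded pixel)."""

    counts: np.ndarray
    mask: np.ndarray = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if self.mask is None:
            self.mask = np.zeros(self.counts.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.counts.shape:
            raise ValueError("mask shape must match counts shape")
        unmasked = self.counts[~self.mask]
        if unmasked.size and (not np.all(np.isfinite(unmasked)) or np.any(unmasked < 0)):
            raise ValueError("unmasked counts must be finite and non-negative")


@dataclass
class Profile1D:
    """1-D reduced profile: intensity versus q (nm⁻¹) or χ (degrees)."""

    axis_kind: str
    grid: np.ndarray
    intensity: np.ndarray
    counts_per_bin: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.counts_per_bin = np.asarray(self.counts_per_bin, dtype=int)
        if self.axis_kind not in (RADIAL_Q, AZIMUTHAL_CHI):
            raise ValueError(f"unknown axis_kind {self.axis_kind!r}")
        if not (self.grid.shape == self.intensity.shape == self.counts_per_bin.shape):
            raise ValueError("grid, intensity, counts_per_bin must share shape")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")

    @property
    def populated(self) -> np.ndarray:
        return self.counts_per_bin > 0


# ---------------------------------------------------------------------------
# pixel <-> (q, chi)
# ---------------------------------------------------------------------------

def pixel_to_q(pixel, geometry: DetectorGeometry):
    """Map a (row, col) pixel to (q [nm⁻¹], χ [deg]).

    The beam-center pixel returns (0, 0) by convention.
    """
    row, col = float(pixel[0]), float(pixel[1])
    drow = row - geometry.beam_center[0]
    dcol = col - geometry.beam_center[1]
    r_m = geometry.pixel_size * 1e-6 * np.hypot(drow, dcol)
    if r_m == 0.0:
        return 0.0, 0.0
    two_theta = np.arctan2(r_m, geometry.distance)
    q = 4.0 * np.pi / geometry.wavelength * np.sin(two_theta / 2.0)
    chi = np.degrees(np.arctan2(drow, dcol)) % 360.0
    return float(q), float(chi)


def q_chi_to_pixel(q: float, chi: float, geometry: DetectorGeometry):
    """Inverse of :func:`pixel_to_q`: (q, χ) to fractional (row, col)."""
    if q < 0:
        raise ValueError("q must be non-negative")
    sin_theta = q * geometry.wavelength / (4.0 * np.pi)
    if sin_theta > 1:
        raise ValueError("q outside the accessible range for this wavelength")
    two_theta = 2.0 * np.arcsin(sin_theta)
    r_px = geometry.distance * np.tan(two_theta) / (geometry.pixel_size * 1e-6)
    chi_rad = np.radians(chi)
    row = geometry.beam_center[0] + r_px * np.sin(chi_rad)
    col = geometry.beam_center[1] + r_px * np.cos(chi_rad)
    return float(row), float(col)


@lru_cache(maxsize=8)
def _pixel_maps(geometry: DetectorGeometry):
    """Per-pixel q [nm⁻¹] and χ [deg] maps for a geometry (cached)."""
    nr, nc = geometry.frame_shape
    drow = np.arange(nr, dtype=float)[:, None] - geometry.beam_center[0]
    dcol = np.arange(nc, dtype=float)[None, :] - geometry.beam_center[1]
    r_m = geometry.pixel_size * 1e-6 * np.hypot(drow, dcol)
    two_theta = np.arctan2(r_m, geometry.distance)
    q = 4.0 * np.pi / geometry.wavelength * np.sin(two_theta / 2.0)
    chi = np.degrees(np.arctan2(drow, dcol)) % 360.0
    q.setflags(write=False)
    chi.setflags(write=False)
    return q, chi


def pixel_q_map(geometry: DetectorGeometry) -> np.ndarray:
    """Per-pixel wavevector map q(row, col) in nm⁻¹."""
    return _pixel_maps(geometry)[0]


def pixel_chi_map(geometry: DetectorGeometry) -> np.ndarray:
    """Per-pixel azimuth map χ(row, col) in degrees [0, 360)."""
    return _pixel_maps(geometry)[1]


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _check_frame(frame: DetectorFrame, geometry: DetectorGeometry):
    if frame.counts.shape != geometry.frame_shape:
        raise ValueError(
            f"frame shape {frame.counts.shape} does not match geometry "
            f"frame_shape {geometry.frame_shape}"
        )


def _chi_sector_mask(chi: np.ndarray, chi_sector) -> np.ndarray:
    lo, hi = (float(chi_sector[0]) % 360.0, float(chi_sector[1]) % 360.0)
    if lo == hi:
        raise ValueError("chi_sector has zero angular width")
    if lo < hi:
        return (chi >= lo) & (chi < hi)
    return (chi >= lo) | (chi < hi)  # sector wraps through 0°


def radial_integrate(
    frame: DetectorFrame,
    geometry: DetectorGeometry,
    q_range: tuple[float, float],
    n_bins: int,
    chi_sector: tuple[float, float] | None = None,
) -> Profile1D:
    """Azimuthally averaged radial profile I(q).

    Each unmasked pixel with q inside ``q_range`` (and χ inside
    ``chi_sector``, if given) contributes to its q bin; the bin intensity is
    the mean pixel count and the pixel population is recorded.
    """
    _check_frame(frame, geometry)
    q_lo, q_hi = map(float, q_range)
    if not q_lo < q_hi:
        raise ValueError("q_range must be increasing")
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    q_map, chi_map = _pixel_maps(geometry)
    select = (~frame.mask) & (q_map >= q_lo) & (q_map < q_hi)
    if chi_sector is not None:
        select &= _chi_sector_mask(chi_map, chi_sector)
    if not select.any():
        raise ValueError("no unmasked pixels in the requested q range / sector")
    edges = np.linspace(q_lo, q_hi, n_bins + 1)
    idx = np.clip(((q_map[select] - q_lo) / (q_hi - q_lo) * n_bins).astype(int), 0, n_bins - 1)
    counts_per_bin = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=frame.counts[select], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        intensity = np.where(counts_per_bin > 0, sums / np.maximum(counts_per_bin, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Profile1D(RADIAL_Q, centers, intensity, counts_per_bin,
                     meta={"q_range": (q_lo, q_hi), "chi_sector": chi_sector})


def azimuthal_integrate(
    frame: DetectorFrame,
    geometry: DetectorGeometry,
    q_band: tuple[float, float],
    n_bins: int,
) -> Profile1D:
    """Azimuthal profile I(χ) over the full circle for pixels with q in ``q_band``."""
    _check_frame(frame, geometry)
    inner, outer = map(float, q_band)
    if not (0 < inner < outer):
        raise ValueError("q_band must satisfy 0 < inner < outer")
    if n_bins < 8:
        raise ValueError("n_bins must be at least 8")
    q_map, chi_map = _pixel_maps(geometry)
    select = (~frame.mask) & (q_map >= inner) & (q_map < outer)
    if not select.any():
        raise ValueError("q band outside detector coverage")
    idx = np.clip((chi_map[select] / 360.0 * n_bins).astype(int), 0, n_bins - 1)
    counts_per_bin = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=frame.counts[select], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        intensity = np.where(counts_per_bin > 0, sums / np.maximum(counts_per_bin, 1), np.nan)
    centers = (np.arange(n_bins) + 0.5) * 360.0 / n_bins
    return Profile1D(AZIMUTHAL_CHI, centers, intensity, counts_per_bin,
                     meta={"q_band": (inner, outer)})


# ---------------------------------------------------------------------------
# distance refinement from calibrant rings
# ---------------------------------------------------------------------------

@dataclass
class DistanceRefinement:
    """Result of fitting the sample-detector distance to calibrant rings."""

    geometry: DetectorGeometry
    residual_px: float
    consistent: bool


def refine_distance(
    ring_radii,
    known_spacings,
    geometry: DetectorGeometry,
    tolerance_px: float = 0.5,
) -> DistanceRefinement:
    """Refine the sample-detector distance from calibrant ring radii.

    For a ring of known real-space spacing d the scattering ring sits at
    q = 2π/d, i.e. at pixel radius r = L·tan(2θ)/p — linear in L — so the
    least-squares distance has the closed form L = Σ rᵢtᵢ / Σ tᵢ² with
    tᵢ = tan(2θᵢ)/p.  Rings whose residual exceeds ``tolerance_px`` flag the
    result inconsistent (and emit a warning) but are not dropped.
    """
    radii = np.asarray(ring_radii, dtype=float)
    spacings = np.asarray(known_spacings, dtype=float)
    if radii.size == 0:
        raise ValueError("at least one calibrant ring is required")
    if radii.shape != spacings.shape:
        raise ValueError("ring_radii and known_spacings must have equal length")
    if np.any(spacings <= 0) or np.any(radii <= 0):
        raise ValueError("radii and spacings must be positive")
    q = 2.0 * np.pi / spacings
    sin_theta = q * geometry.wavelength / (4.0 * np.pi)
    if np.any(sin_theta >= 1):
        raise ValueError("calibrant spacing outside accessible range")
    t = np.tan(2.0 * np.arcsin(sin_theta)) / (geometry.pixel_size * 1e-6)  # px per meter
    distance = float(np.sum(radii * t) / np.sum(t * t))
    residual = float(np.sqrt(np.mean((radii - distance * t) ** 2)))
    consistent = residual <= tolerance_px
    if not consistent:
        warnings.warn(
            f"calibrant rings inconsistent: rms residual {residual:.2f} px "
            f"exceeds {tolerance_px} px", stacklevel=2,
        )
    return DistanceRefinement(replace(geometry, distance=distance), residual, consistent)
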