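"""Forward simulation of scattering frames, scans and deformed scan pairs.

The generator emulates a Pilatus-like photon-counting detector viewing a
collagenous tissue volume:

* meridional collagen orders n = 1..6 as narrow Gaussian rings in q at
  n·2π/D with angular Gaussian lobes at χ₀ and χ₀+180°, order amplitudes
  ∝ |cₙ|² of a two-level axial step density with gap fraction
  f = 1 − overlap_fraction (cₙ = sin(πnf)/(πn)),
* a broad interfibrillar (IFC) ring at orders m = 1, 2 of the
  interfibrillar spacing, with lobes rotated 90° from χ₀; the m = 1 ring
  sits partly under the beamstop,
* a diffuse exponential background A·exp(−q·τ),
* Poisson counting noise (photon-counting detector: no read noise), and
* a circular beamstop shadow recorded in the frame mask.

Deformed scans are sampled through a known warp of the scan plane with an
imposed fibril strain (ΔD/D) and reorientation toward a loading axis; the
true point correspondence is recorded so recovery pipelines can be scored
against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter

from ._interp import Spline2D
from .geometry import DetectorFrame, DetectorGeometry, pixel_chi_map, pixel_q_map

DEFAULT_BEAMSTOP_Q = 0.055  # nm⁻¹; m=1 IFC ring (q ≈ 0.066) is partly shadowed


def order_amplitude(n: int, overlap_fraction: float) -> float:
    """Relative intensity |cₙ|² of meridional order n.

    For a two-level axial step density with gap fraction
    f = 1 − overlap_fraction the Fourier coefficients are
    cₙ = sin(πnf)/(πn); even orders vanish at f = 1/2.
    """
    if not 0 < overlap_fraction < 1:
        raise ValueError("overlap_fraction must lie in (0, 1)")
    f = 1.0 - overlap_fraction
    return (math.sin(math.pi * n * f) / (math.pi * n)) ** 2


@dataclass(frozen=True)
class FibrilGroundTruth:
    """True nanoscale parameters of one scattering volume.

    Intensity weights are in expected counts at the respective feature
    maxima (before the global ``flux`` scale); widths are Gaussian sigmas.
    """

    D: float = 65.0                  # nm, collagen axial period
    overlap_fraction: float = 0.52   # fraction of D in the overlap zone
    chi0: float = 161.0              # deg, mean fibril angle
    chi_spread: float = 25.0         # deg, angular lobe sigma
    collagen_weight: float = 30.0    # counts at the 5th-order lobe peak
    collagen_width: float = 0.003    # nm⁻¹, radial sigma of collagen rings
    ifc_spacing: float = 95.0        # nm, interfibrillar period
    ifc_width: float = 0.016         # nm⁻¹, radial sigma of the IFC rings
    ifc_weight: float = 10.0         # counts at the 2nd-order IFC lobe peak
    bg_amplitude: float = 20.0       # counts at q = 0
    bg_decay: float = 6.0            # nm, exponential background scale
    flux: float = 1.0                # global expected-count multiplier

    def __post_init__(self):
        if self.D <= 0 or self.ifc_spacing <= 0:
            raise ValueError("periods must be positive")
        for name in ("collagen_weight", "ifc_weight", "bg_amplitude", "flux"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def synthetic_geometry(
    shape: tuple[int, int] = (512, 512),
    q_max: float = 0.9,
    distance: float = 5.5,
    energy: float = 14.0,
    beam_center: tuple[float, float] | None = None,
) -> DetectorGeometry:
    """Desk-scale detector geometry.

    Keeps the real beamline's distance and energy but chooses the pixel
    pitch so that ``q_max`` falls at half the smaller frame dimension —
    the q range that carries collagen orders 1–6 and IFC orders 1–2 —
    instead of the full-size detector's much larger span.
    """
    wavelength = 1.23984 / energy
    sin_theta = q_max * wavelength / (4.0 * math.pi)
    r_m = distance * math.tan(2.0 * math.asin(sin_theta))
    half_px = min(shape) / 2.0
    pixel_um = r_m / half_px * 1e6
    if beam_center is None:
        beam_center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    return DetectorGeometry(distance=distance, pixel_size=pixel_um,
                            beam_center=beam_center, energy=energy,
                            frame_shape=tuple(shape))


def _lobes(chi: np.ndarray, center: float, spread: float) -> np.ndarray:
    """180°-paired angular Gaussian lobes with ±360° wrap replicates."""
    out = np.zeros_like(chi)
    for c in (center % 360.0, (center + 180.0) % 360.0):
        for k in (-360.0, 0.0, 360.0):
            out += np.exp(-0.5 * ((chi - c + k) / spread) ** 2)
    return out


def expected_frame(
    truth: FibrilGroundTruth,
    geometry: DetectorGeometry,
    n_orders: int = 6,
    ifc_orders: int = 2,
) -> np.ndarray:
    """Noise-free expected counts per pixel for a ground-truth volume."""
    q = pixel_q_map(geometry)
    chi = pixel_chi_map(geometry)
    model = truth.bg_amplitude * np.exp(-q * truth.bg_decay)
    if truth.collagen_weight > 0:
        ref = order_amplitude(5, truth.overlap_fraction)
        lobes = _lobes(chi, truth.chi0, truth.chi_spread)
        q1 = 2.0 * math.pi / truth.D
        radial = np.zeros_like(q)
        for n in range(1, n_orders + 1):
            rel = order_amplitude(n, truth.overlap_fraction) / ref
            radial += rel * np.exp(-0.5 * ((q - n * q1) / truth.collagen_width) ** 2)
        model += truth.collagen_weight * radial * lobes
    if truth.ifc_weight > 0:
        lobes = _lobes(chi, truth.chi0 + 90.0, truth.chi_spread)
        qm = 2.0 * math.pi / truth.ifc_spacing
        radial = np.zeros_like(q)
        for m in range(1, ifc_orders + 1):
            rel = (2.0 / m) ** 2   # fundamental stronger than the 2nd order
            radial += rel * np.exp(-0.5 * ((q - m * qm) / truth.ifc_width) ** 2)
        # rel_2 = 1: the weight is defined at the 2nd-order lobe peak
        model += truth.ifc_weight * radial * lobes
    return truth.flux * model


def beamstop_mask(geometry: DetectorGeometry,
                  beamstop_q: float = DEFAULT_BEAMSTOP_Q) -> np.ndarray:
    """Circular beamstop shadow: True where the direct beam is blocked."""
    return pixel_q_map(geometry) < beamstop_q


def simulate_frame(
    truth: FibrilGroundTruth,
    geometry: DetectorGeometry,
    seed: int,
    beamstop_q: float = DEFAULT_BEAMSTOP_Q,
) -> DetectorFrame:
    """Poisson-sampled detector frame with beamstop mask.

    Identical seeds give bit-identical frames.
    """
    expected = expected_frame(truth, geometry)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected).astype(float)
    return DetectorFrame(counts=counts, mask=beamstop_mask(geometry, beamstop_q))


# ---------------------------------------------------------------------------
# warps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AffineWarp:
    """Affine map x ↦ A·x + b on (row, col) coordinates; a bijection."""

    A: tuple = ((1.0, 0.0), (0.0, 1.0))
    b: tuple = (0.0, 0.0)

    def _mat(self):
        return np.asarray(self.A, dtype=float), np.asarray(self.b, dtype=float)

    def forward(self, points: np.ndarray) -> np.ndarray:
        A, b = self._mat()
        return np.atleast_2d(np.asarray(points, dtype=float)) @ A.T + b

    def inverse(self, points: np.ndarray) -> np.ndarray:
        A, b = self._mat()
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - b
        return np.linalg.solve(A, pts.T).T

    @classmethod
    def identity(cls):
        return cls()

    @classmethod
    def translation(cls, drow: float, dcol: float):
        return cls(b=(drow, dcol))

    @classmethod
    def stretch_rows(cls, factor: float, anchor_row: float = 0.0):
        """Uniform stretch along rows, anchored at ``anchor_row``."""
        return cls(A=((factor, 0.0), (0.0, 1.0)),
                   b=(anchor_row * (1.0 - factor), 0.0))

    @classmethod
    def uniform_strain(cls, eyy: float, exx: float, center=(0.0, 0.0)):
        A = ((1.0 + eyy, 0.0), (0.0, 1.0 + exx))
        b = (-center[0] * eyy, -center[1] * exx)
        return cls(A=A, b=b)

    @classmethod
    def shear(cls, k: float):
        """Rows displaced along columns proportionally to the row index."""
        return cls(A=((1.0, 0.0), (k, 1.0)))


@dataclass(frozen=True)
class WarpGroundTruth:
    """Imposed tissue-plane warp plus nanoscale changes per point."""

    warp: AffineWarp
    delta_D_over_D: float = 0.0        # imposed uniform fibril strain
    reorientation_factor: float = 1.0  # multiplies the signed χ₀ deviation
    loading_axis: float = 90.0         # deg


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

@dataclass
class ScanSim:
    """A simulated scan: row-major frames plus the ground-truth table."""

    frames: list
    n_rows: int
    n_cols: int
    geometry: DetectorGeometry
    truth_table: pd.DataFrame

    def frame_at(self, row: int, col: int) -> DetectorFrame:
        return self.frames[row * self.n_cols + col]


_FIELD_NAMES = ("D", "overlap_fraction", "chi0", "chi_spread", "collagen_weight",
                "collagen_width", "ifc_spacing", "ifc_width", "ifc_weight",
                "bg_amplitude", "bg_decay", "flux")


def _truth_table(truths) -> pd.DataFrame:
    n_rows, n_cols = truths.shape
    records = []
    for r in range(n_rows):
        for c in range(n_cols):
            t = truths[r, c]
            rec = {"x_index": c, "y_index": r}
            rec.update({name: getattr(t, name) for name in _FIELD_NAMES})
            records.append(rec)
    return pd.DataFrame.from_records(records)


def simulate_scan(
    truths: np.ndarray,
    geometry: DetectorGeometry,
    seed: int,
    beamstop_q: float = DEFAULT_BEAMSTOP_Q,
) -> ScanSim:
    """One frame per grid point from a 2-D array of ground truths."""
    truths = np.asarray(truths, dtype=object)
    n_rows, n_cols = truths.shape
    seeds = np.random.SeedSequence(seed).generate_state(n_rows * n_cols)
    frames = []
    for k in range(n_rows * n_cols):
        r, c = divmod(k, n_cols)
        frames.append(simulate_frame(truths[r, c], geometry, int(seeds[k]),
                                     beamstop_q=beamstop_q))
    return ScanSim(frames, n_rows, n_cols, geometry, _truth_table(truths))


def heterogeneous_truths(
    n_rows: int,
    n_cols: int,
    seed: int,
    base: FibrilGroundTruth = FibrilGroundTruth(),
    feature_scale: float = 3.0,
    weight_cv: float = 0.6,
    d_spread: float = 0.08,
    chi_spread_deg: float = 20.0,
    ifc_spacing_spread: float = 6.0,
) -> np.ndarray:
    """Spatially heterogeneous ground-truth fields over a scan grid.

    Smooth band-limited random fields (correlation length ``feature_scale``
    scan steps) modulate the collagen and IFC weights (log-normally, with
    coefficient of variation ``weight_cv`` — this is the texture the DIC
    tracks), the D-period (± ``d_spread`` nm about the base value), the
    mean fibril angle (± ``chi_spread_deg``) and the IFC spacing.
    """
    rng = np.random.default_rng(seed)

    def smooth(scale=1.0):
        f = gaussian_filter(rng.standard_normal((n_rows, n_cols)),
                            sigma=feature_scale / 2.355, mode="wrap")
        f = (f - f.mean()) / max(f.std(), 1e-12)
        return scale * f

    log_w = smooth(math.sqrt(math.log(1 + weight_cv ** 2)))
    weight = np.exp(log_w - log_w.var() / 2.0)
    ifc_w = np.exp(smooth(math.sqrt(math.log(1 + weight_cv ** 2))))
    d_field = base.D + smooth(d_spread)
    chi_field = base.chi0 + smooth(chi_spread_deg)
    ifc_field = base.ifc_spacing + smooth(ifc_spacing_spread)
    truths = np.empty((n_rows, n_cols), dtype=object)
    for r in range(n_rows):
        for c in range(n_cols):
            truths[r, c] = replace(
                base,
                D=float(d_field[r, c]),
                chi0=float(chi_field[r, c] % 360.0),
                collagen_weight=float(base.collagen_weight * weight[r, c]),
                ifc_spacing=float(np.clip(ifc_field[r, c], 60.0, 150.0)),
                ifc_weight=float(base.ifc_weight * ifc_w[r, c]),
            )
    return truths


def _interpolators(truths: np.ndarray):
    n_rows, n_cols = truths.shape
    axes = (np.arange(n_rows, dtype=float), np.arange(n_cols, dtype=float))
    grids = {}
    for name in _FIELD_NAMES:
        if name == "chi0":
            continue
        arr = np.array([[getattr(truths[r, c], name) for c in range(n_cols)]
                        for r in range(n_rows)], dtype=float)
        grids[name] = RegularGridInterpolator(axes, arr, method="linear")
    # orientation interpolated on the doubled-angle circle (180°-periodic)
    chi = np.radians(2.0 * np.array(
        [[truths[r, c].chi0 for c in range(n_cols)] for r in range(n_rows)]))
    grids["_chi_cos"] = RegularGridInterpolator(axes, np.cos(chi), method="linear")
    grids["_chi_sin"] = RegularGridInterpolator(axes, np.sin(chi), method="linear")
    return grids


def simulate_deformed_scan(
    ref_truths: np.ndarray,
    warp_truth: WarpGroundTruth,
    geometry: DetectorGeometry,
    seed: int,
    beamstop_q: float = DEFAULT_BEAMSTOP_Q,
) -> tuple[ScanSim, pd.DataFrame]:
    """Sample a second scan of warped tissue with imposed nanoscale changes.

    The deformed scan re-rasters the *same lab-frame grid*: the scan point
    (i, j) images the material point warp⁻¹(i, j).  Inside the tissue the
    ground-truth fields are interpolated bilinearly (orientation on the
    doubled-angle circle), the D-period is scaled by 1 + ΔD/D and χ₀ is
    pulled toward the loading axis by the reorientation factor; outside
    the tissue only the diffuse background remains.  Returns the deformed
    scan plus the true point-correspondence table with columns
    ``ref_row, ref_col, def_row, def_col, inside``.
    """
    ref_truths = np.asarray(ref_truths, dtype=object)
    n_rows, n_cols = ref_truths.shape
    interp = _interpolators(ref_truths)
    wt = warp_truth
    base = ref_truths[0, 0]

    truths = np.empty((n_rows, n_cols), dtype=object)
    for i in range(n_rows):
        for j in range(n_cols):
            m = wt.warp.inverse([(float(i), float(j))])[0]
            if 0.0 <= m[0] <= n_rows - 1 and 0.0 <= m[1] <= n_cols - 1:
                vals = {name: float(interp[name](m)[0]) for name in _FIELD_NAMES
                        if name != "chi0"}
                chi0 = math.degrees(math.atan2(
                    float(interp["_chi_sin"](m)[0]),
                    float(interp["_chi_cos"](m)[0]))) / 2.0 % 180.0
                dev = ((chi0 - wt.loading_axis + 90.0) % 180.0) - 90.0
                chi0 = (wt.loading_axis + dev * wt.reorientation_factor) % 360.0
                vals["D"] = vals["D"] * (1.0 + wt.delta_D_over_D)
                truths[i, j] = FibrilGroundTruth(chi0=chi0, **vals)
            else:
                truths[i, j] = replace(base, collagen_weight=0.0, ifc_weight=0.0)
    deformed = simulate_scan(truths, geometry, seed, beamstop_q=beamstop_q)

    records = []
    for i in range(n_rows):
        for j in range(n_cols):
            lab = wt.warp.forward([(float(i), float(j))])[0]
            di, dj = int(round(lab[0])), int(round(lab[1]))
            inside = 0 <= di < n_rows and 0 <= dj < n_cols
            records.append({"ref_row": i, "ref_col": j,
                            "def_row": di if inside else -1,
                            "def_col": dj if inside else -1,
                            "inside": inside})
    return deformed, pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# speckle fixtures for DIC
# ---------------------------------------------------------------------------

def speckle_pair(
    size: tuple[int, int],
    feature_scale: float,
    warp: AffineWarp,
    seed: int,
    contrast: float = 0.2,
    mean_level: float = 0.5,
):
    """Band-limited random texture and its warped resampling.

    The second image is the first sampled at warp⁻¹ of each pixel through
    the same degree-6 spline the DIC engine uses, so interpolation model
    error does not enter subpixel-accuracy tests.  Returns
    ``(reference, deformed)``.
    """
    if feature_scale < 3:
        raise ValueError("feature_scale must be at least 3 px")
    size = tuple(size)
    # generate on a larger canvas and crop, so the deformed frame carries
    # true warped texture right up to its borders (no mirror seam)
    corners = np.array([[0.0, 0.0], [0.0, size[1] - 1.0],
                        [size[0] - 1.0, 0.0], [size[0] - 1.0, size[1] - 1.0]])
    reach = np.abs(warp.inverse(corners) - corners).max()
    margin = int(np.ceil(reach)) + 8
    rng = np.random.default_rng(seed)
    canvas = gaussian_filter(
        rng.standard_normal((size[0] + 2 * margin, size[1] + 2 * margin)),
        sigma=feature_scale / 2.355)
    canvas = mean_level + contrast * (canvas - canvas.mean()) / canvas.std()
    ref = canvas[margin:margin + size[0], margin:margin + size[1]].copy()
    spline = Spline2D(canvas, degree=6)
    rr, cc = np.meshgrid(np.arange(size[0], dtype=float),
                         np.arange(size[1], dtype=float), indexing="ij")
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
    deformed = spline(warp.inverse(pts) + margin).reshape(size)
    return ref, deformed
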