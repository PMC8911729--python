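"""Subset-based digital image correlation on diffraction-contrast maps.

The engine tracks square subsets of a reference image into a deformed
image in two stages:

1. an integer-pixel search maximizing the zero-normalized cross
   correlation (ZNCC) inside ``search_radius`` — ZNCC is invariant to the
   gain/offset differences expected between load steps;
2. subpixel refinement by inverse-compositional Gauss–Newton (IC-GN) on a
   translation + affine subset shape function, with deformed gray levels
   evaluated through a degree-6 tensor-product spline and subset pixels
   weighted by a round window (circular support, raised-cosine radial
   taper).

Both images are mirror-padded so subsets near borders stay evaluable.
Local strains come from least-squares plane fits of (u_x, v_y) over a
``strain_window`` × ``strain_window`` neighborhood of subsets.

Coordinates follow numpy imaging convention: x = column, y = row;
``u_x``/``v_y`` are the displacements along those axes in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from ._interp import Spline2D


@dataclass(frozen=True)
class DICConfig:
    """Correlation parameters (defaults match a scanning-SAXS map workflow)."""

    subset_size: int = 25
    step: int = 3
    window: str = "round_weighted"
    interpolation_order: int = 6
    strain_window: int = 7
    search_radius: int = 10
    correlation_min: float = 0.5
    max_iterations: int = 50
    convergence_tol: float = 1e-4   # px, norm of the IC-GN update
    pyramid: bool = False           # 2× downsampled pre-pass seeds the search

    def __post_init__(self):
        if self.subset_size % 2 != 1 or self.subset_size < 5:
            raise ValueError("subset_size must be odd and ≥ 5")
        if self.step < 1:
            raise ValueError("step must be ≥ 1")
        if self.strain_window % 2 != 1 or self.strain_window < 3:
            raise ValueError("strain_window must be odd and ≥ 3")
        if self.window != "round_weighted":
            raise ValueError("only the round_weighted window is implemented")
        if self.search_radius < 1:
            raise ValueError("search_radius must be ≥ 1")


@dataclass
class DisplacementField:
    """Subset-grid displacements with per-subset correlation quality."""

    row_centers: np.ndarray     # (nr,) subset-center rows, px
    col_centers: np.ndarray     # (nc,) subset-center cols, px
    u_x: np.ndarray             # (nr, nc) displacement along x (col), px
    v_y: np.ndarray             # (nr, nc) displacement along y (row), px
    correlation: np.ndarray     # (nr, nc) final ZNCC in [-1, 1]
    valid: np.ndarray           # (nr, nc) bool
    config: DICConfig = None
    #: subsets whose support lies fully inside the frame; border subsets are
    #: evaluated against mirror-extended gray levels and are best-effort
    interior: np.ndarray = None


@dataclass
class StrainField:
    """Local in-plane strains from windowed plane fits of the displacements."""

    row_centers: np.ndarray
    col_centers: np.ndarray
    exx: np.ndarray
    eyy: np.ndarray
    exy: np.ndarray
    valid: np.ndarray


def round_window_weights(subset_size: int) -> np.ndarray:
    """Circular subset window with a raised-cosine radial taper.

    Weight 1 at the subset center falling to 0 at radius (subset_size−1)/2;
    pixels outside the inscribed circle get weight 0.
    """
    radius = (subset_size - 1) / 2.0
    offsets = np.arange(subset_size, dtype=float) - radius
    r = np.hypot(offsets[:, None], offsets[None, :])
    w = 0.5 * (1.0 + np.cos(np.pi * np.minimum(r / radius, 1.0)))
    return w


def _subset_grid(length: int, step: int) -> np.ndarray:
    # step grid centered inside [0, length-1]
    n = (length - 1) // step + 1
    start = (length - 1 - (n - 1) * step) // 2
    return np.arange(n) * step + start


def _zncc_integer_search(ref_pad, def_pad, centers_pad, weights, half, radius):
    """Best integer displacement per subset by weighted ZNCC grid search."""
    s = 2 * half + 1
    w = weights.ravel()
    wsum = w.sum()
    n = centers_pad.shape[0]
    best_d = np.zeros((n, 2), dtype=int)
    best_c = np.full(n, -np.inf)
    from numpy.lib.stride_tricks import sliding_window_view
    for i, (r0, c0) in enumerate(centers_pad):
        f = ref_pad[r0 - half:r0 + half + 1, c0 - half:c0 + half + 1].ravel()
        fm = (w * f).sum() / wsum
        fd = f - fm
        denom_f = np.sqrt((w * fd * fd).sum())
        if denom_f <= 1e-12:
            continue  # zero-variance subset: leave invalid
        region = def_pad[r0 - half - radius:r0 + half + radius + 1,
                         c0 - half - radius:c0 + half + radius + 1]
        patches = sliding_window_view(region, (s, s)).reshape((2 * radius + 1) ** 2, s * s)
        pm = patches @ w / wsum
        cross = patches @ (w * fd)
        var_p = (patches * patches) @ w - wsum * pm * pm
        with np.errstate(invalid="ignore", divide="ignore"):
            zncc = cross / (denom_f * np.sqrt(np.maximum(var_p, 0.0)))
        zncc[~np.isfinite(zncc)] = -np.inf
        k = int(np.argmax(zncc))
        dr, dc = divmod(k, 2 * radius + 1)
        best_d[i] = (dr - radius, dc - radius)
        best_c[i] = zncc[k]
    return best_d, best_c


def correlate(
    reference: np.ndarray,
    deformed: np.ndarray,
    config: DICConfig = DICConfig(),
    reference_mask: np.ndarray | None = None,
) -> DisplacementField:
    """Displacement field mapping ``reference`` into ``deformed``.

    ``reference_mask`` (True = excluded) zeroes the window weights of
    masked pixels; subsets with more than half their weight masked are
    invalid.  Subsets are invalid when the final ZNCC falls below
    ``config.correlation_min``, when the subset has no gray-level variance,
    or when the optimizer diverges.
    """
    ref = np.asarray(reference, dtype=float)
    def_ = np.asarray(deformed, dtype=float)
    if ref.shape != def_.shape:
        raise ValueError("reference and deformed images must share a shape")
    if min(ref.shape) < 2 * config.subset_size:
        raise ValueError("images must be at least twice the subset size")
    half = config.subset_size // 2
    radius = config.search_radius
    pad = half + radius + 2

    ref_pad = np.pad(ref, pad, mode="reflect")
    def_pad = np.pad(def_, pad, mode="reflect")
    weights = round_window_weights(config.subset_size)

    rows = _subset_grid(ref.shape[0], config.step)
    cols = _subset_grid(ref.shape[1], config.step)
    nr, nc = len(rows), len(cols)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    centers = np.stack([rr.ravel(), cc.ravel()], axis=1)
    centers_pad = centers + pad
    n = centers.shape[0]

    # per-subset weights with mask propagation
    w_stack = np.broadcast_to(weights, (n, *weights.shape)).copy()
    subset_valid = np.ones(n, dtype=bool)
    if reference_mask is not None:
        mask_pad = np.pad(np.asarray(reference_mask, dtype=bool), pad, mode="reflect")
        for i, (r0, c0) in enumerate(centers_pad):
            m = mask_pad[r0 - half:r0 + half + 1, c0 - half:c0 + half + 1]
            w_stack[i][m] = 0.0
            if w_stack[i].sum() < 0.5 * weights.sum():
                subset_valid[i] = False

    # --- integer-pixel search (optionally seeded by a 2× coarse pre-pass)
    if config.pyramid and min(ref.shape) >= 4 * config.subset_size:
        coarse_cfg = DICConfig(
            subset_size=max(2 * (half // 2) + 1, 5), step=1,
            search_radius=max(radius, 2), correlation_min=-1.0,
            pyramid=False,
        )
        r2 = ref[: ref.shape[0] // 2 * 2, : ref.shape[1] // 2 * 2]
        d2 = def_[: def_.shape[0] // 2 * 2, : def_.shape[1] // 2 * 2]
        r2 = r2.reshape(r2.shape[0] // 2, 2, r2.shape[1] // 2, 2).mean(axis=(1, 3))
        d2 = d2.reshape(d2.shape[0] // 2, 2, d2.shape[1] // 2, 2).mean(axis=(1, 3))
        coarse = correlate(r2, d2, coarse_cfg)
        seed_u = np.nanmedian(np.where(coarse.valid, coarse.u_x, np.nan))
        seed_v = np.nanmedian(np.where(coarse.valid, coarse.v_y, np.nan))
        seed = np.array([2 * seed_v, 2 * seed_u])
        seed = np.rint(np.nan_to_num(seed)).astype(int)
    else:
        seed = np.zeros(2, dtype=int)

    best_d, best_c = _zncc_integer_search(
        ref_pad, def_pad, centers_pad + seed, weights, half, radius)
    best_d = best_d + seed  # displacements relative to the reference centers
    subset_valid &= np.isfinite(best_c)

    # --- IC-GN subpixel refinement, batched over subsets
    offs = np.arange(-half, half + 1, dtype=float)
    xi_y, xi_x = np.meshgrid(offs, offs, indexing="ij")   # local (row, col) offsets
    xi_x = xi_x.ravel(); xi_y = xi_y.ravel()
    npix = xi_x.size

    gy, gx = np.gradient(ref_pad)
    spline = Spline2D(def_pad, degree=config.interpolation_order)

    f = np.empty((n, npix))
    J = np.empty((n, npix, 6))
    for i, (r0, c0) in enumerate(centers_pad):
        sl = (slice(r0 - half, r0 + half + 1), slice(c0 - half, c0 + half + 1))
        f[i] = ref_pad[sl].ravel()
        fx = gx[sl].ravel(); fy = gy[sl].ravel()
        J[i] = np.stack([fx, fx * xi_x, fx * xi_y, fy, fy * xi_x, fy * xi_y], axis=1)

    w = w_stack.reshape(n, npix)
    wsum = w.sum(axis=1)
    fmean = (w * f).sum(axis=1) / np.maximum(wsum, 1e-30)
    ftil = f - fmean[:, None]
    fnorm = np.sqrt((w * ftil * ftil).sum(axis=1))
    subset_valid &= fnorm > 1e-12

    H = np.einsum("np,npi,npj->nij", w, J, J)
    Hinv = np.full((n, 6, 6), np.nan)
    ok = subset_valid.copy()
    for i in np.nonzero(ok)[0]:
        try:
            Hinv[i] = np.linalg.inv(H[i])
        except np.linalg.LinAlgError:
            ok[i] = False
    subset_valid &= ok

    # warp state as 3x3 affine matrices acting on (ξx, ξy, 1)
    M = np.tile(np.eye(3), (n, 1, 1))
    M[:, 0, 2] = best_d[:, 1]   # u (x = col)
    M[:, 1, 2] = best_d[:, 0]   # v (y = row)

    active = subset_valid.copy()
    correlation = np.full(n, np.nan)
    for _ in range(config.max_iterations):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        m = M[idx]
        gx_w = m[:, 0, 0, None] * xi_x + m[:, 0, 1, None] * xi_y + m[:, 0, 2, None]
        gy_w = m[:, 1, 0, None] * xi_x + m[:, 1, 1, None] * xi_y + m[:, 1, 2, None]
        pts = np.stack([
            centers_pad[idx, 0, None] + gy_w,
            centers_pad[idx, 1, None] + gx_w,
        ], axis=-1)
        with np.errstate(over="ignore", invalid="ignore"):
            g = spline(pts.reshape(-1, 2)).reshape(len(idx), npix)
            g = np.nan_to_num(g, nan=0.0, posinf=1e30, neginf=-1e30)
            wi = w[idx]
            gmean = (wi * g).sum(axis=1) / np.maximum(wsum[idx], 1e-30)
            gtil = g - gmean[:, None]
            gnorm = np.sqrt((wi * gtil * gtil).sum(axis=1))
        bad = (gnorm <= 1e-12) | ~np.isfinite(gnorm)
        err = gtil / np.maximum(gnorm, 1e-30)[:, None] - ftil[idx] / fnorm[idx, None]
        rhs = np.einsum("np,npi,np->ni", wi, J[idx], err) * fnorm[idx, None]
        dp = np.einsum("nij,nj->ni", Hinv[idx], rhs)
        # inverse-compositional update: W <- W ∘ W(dp)^(-1)
        dM = np.tile(np.eye(3), (len(idx), 1, 1))
        dM[:, 0, 0] += dp[:, 1]; dM[:, 0, 1] = dp[:, 2]; dM[:, 0, 2] = dp[:, 0]
        dM[:, 1, 0] = dp[:, 4]; dM[:, 1, 1] += dp[:, 5]; dM[:, 1, 2] = dp[:, 3]
        try:
            dM_inv = np.linalg.inv(dM)
        except np.linalg.LinAlgError:
            dM_inv = np.tile(np.eye(3), (len(idx), 1, 1))
        M[idx] = np.einsum("nij,njk->nik", m, dM_inv)
        # divergence guard: non-finite state or translation far outside the
        # search range means the subset left the trustworthy domain
        trans = np.abs(M[idx][:, :2, 2]).max(axis=1)
        affine_dev = np.abs(M[idx][:, :2, :2] - np.eye(2)).reshape(len(idx), 4).max(axis=1)
        diverged = ~np.isfinite(trans) | (trans > radius + half + 2) | \
            (affine_dev > 1.5) | ~np.isfinite(dp).all(axis=1)
        if diverged.any():
            div = idx[diverged]
            correlation[div] = -1.0
            active[div] = False
            subset_valid[div] = False
            bad = bad | diverged
        # convergence measured as the update norm at the subset scale
        upd = np.sqrt(dp[:, 0] ** 2 + dp[:, 3] ** 2 +
                      (half * dp[:, 1]) ** 2 + (half * dp[:, 2]) ** 2 +
                      (half * dp[:, 4]) ** 2 + (half * dp[:, 5]) ** 2)
        done = (upd < config.convergence_tol) | bad
        # final ZNCC for subsets finishing this iteration
        fin = idx[done]
        if fin.size:
            zn = (wi[done] * ftil[fin] / fnorm[fin, None] *
                  gtil[done] / np.maximum(gnorm[done], 1e-30)[:, None]).sum(axis=1)
            correlation[fin] = np.where(bad[done], -1.0, zn)
        active[fin] = False
    # subsets that never met the update tolerance are treated as divergent
    correlation[np.nonzero(active)[0]] = -1.0
    subset_valid &= np.isfinite(correlation) & (correlation >= config.correlation_min)

    u = np.where(subset_valid, M[:, 0, 2], np.nan).reshape(nr, nc)
    v = np.where(subset_valid, M[:, 1, 2], np.nan).reshape(nr, nc)
    interior_rows = (rows >= half) & (rows <= ref.shape[0] - 1 - half)
    interior_cols = (cols >= half) & (cols <= ref.shape[1] - 1 - half)
    return DisplacementField(
        row_centers=rows.astype(float),
        col_centers=cols.astype(float),
        u_x=u, v_y=v,
        correlation=correlation.reshape(nr, nc),
        valid=subset_valid.reshape(nr, nc),
        config=config,
        interior=interior_rows[:, None] & interior_cols[None, :],
    )


def compute_strain(field: DisplacementField, config: DICConfig | None = None) -> StrainField:
    """Local strains by plane-fitting displacements over the strain window.

    At each subset, u and v are fitted with a plane over the surrounding
    ``strain_window`` × ``strain_window`` valid subsets (physical spacing =
    the subset step); exx = ∂u/∂x, eyy = ∂v/∂y, exy = ½(∂u/∂y + ∂v/∂x).
    Cells need at least half the window valid (and never fewer than 6
    subsets) to be reported.
    """
    config = config or field.config or DICConfig()
    half = config.strain_window // 2
    nr, nc = field.u_x.shape
    exx = np.full((nr, nc), np.nan)
    eyy = np.full((nr, nc), np.nan)
    exy = np.full((nr, nc), np.nan)
    valid = np.zeros((nr, nc), dtype=bool)
    min_count = max(6, (config.strain_window ** 2 + 1) // 2)
    cols_px = field.col_centers
    rows_px = field.row_centers
    for i in range(nr):
        for j in range(nc):
            i0, i1 = max(0, i - half), min(nr, i + half + 1)
            j0, j1 = max(0, j - half), min(nc, j + half + 1)
            sub_valid = field.valid[i0:i1, j0:j1]
            count = int(sub_valid.sum())
            if count < min_count:
                continue
            yy, xx = np.meshgrid(rows_px[i0:i1], cols_px[j0:j1], indexing="ij")
            x = xx[sub_valid] - cols_px[j]
            y = yy[sub_valid] - rows_px[i]
            A = np.column_stack([np.ones_like(x), x, y])
            try:
                coef_u, *_ = np.linalg.lstsq(A, field.u_x[i0:i1, j0:j1][sub_valid], rcond=None)
                coef_v, *_ = np.linalg.lstsq(A, field.v_y[i0:i1, j0:j1][sub_valid], rcond=None)
            except np.linalg.LinAlgError:
                continue
            exx[i, j] = coef_u[1]
            eyy[i, j] = coef_v[2]
            exy[i, j] = 0.5 * (coef_u[2] + coef_v[1])
            valid[i, j] = True
    return StrainField(field.row_centers, field.col_centers, exx, eyy, exy, valid)


def displace_points(points: np.ndarray, field: DisplacementField):
    """Carry reference (row, col) points to the deformed image.

    Displacements are bilinearly interpolated from the subset grid; points
    outside the grid's hull (or whose interpolation cell contains invalid
    subsets) fall back to the nearest valid subset's displacement and are
    flagged.  A point coinciding with a valid subset center always receives
    exactly that subset's displacement (bilinear weight 1 when the cell is
    clean, nearest-subset = itself otherwise).

    Returns ``(deformed_points, interpolated_ok)``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    u = np.where(field.valid, field.u_x, np.nan)
    v = np.where(field.valid, field.v_y, np.nan)
    interp_u = RegularGridInterpolator(
        (field.row_centers, field.col_centers), u,
        method="linear", bounds_error=False, fill_value=np.nan)
    interp_v = RegularGridInterpolator(
        (field.row_centers, field.col_centers), v,
        method="linear", bounds_error=False, fill_value=np.nan)
    du = interp_u(pts)
    dv = interp_v(pts)
    ok = np.isfinite(du) & np.isfinite(dv)
    if not ok.all():
        vi, vj = np.nonzero(field.valid)
        if vi.size == 0:
            raise ValueError("displacement field has no valid subsets")
        centers = np.stack([field.row_centers[vi], field.col_centers[vj]], axis=1)
        for k in np.nonzero(~ok)[0]:
            nearest = int(np.argmin(((centers - pts[k]) ** 2).sum(axis=1)))
            du[k] = field.u_x[vi[nearest], vj[nearest]]
            dv[k] = field.v_y[vi[nearest], vj[nearest]]
    out = pts + np.stack([dv, du], axis=1)   # (row, col) + (v_y, u_x)
    return out, ok
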