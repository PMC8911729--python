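"""Tensor-product B-spline image interpolation of arbitrary degree.

``scipy.ndimage.map_coordinates`` caps the spline order at 5, so the
degree-6 gray-level interpolant used by the DIC engine is assembled here
from two 1-D interpolating splines (one per image axis) and evaluated
through :class:`scipy.interpolate.NdBSpline`.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import NdBSpline, make_interp_spline


class Spline2D:
    """Interpolating tensor-product spline over a 2-D array.

    Coordinates are (row, col) in pixel units, matching numpy indexing.
    Evaluation outside the grid is the spline's polynomial extrapolation;
    callers that need safe borders should pad the image first (the DIC
    engine mirror-pads).
    """

    def __init__(self, image: np.ndarray, degree: int = 6):
        image = np.asarray(image, dtype=float)
        if image.ndim != 2:
            raise ValueError("image must be 2-D")
        if min(image.shape) <= degree:
            raise ValueError("image too small for requested spline degree")
        rows = np.arange(image.shape[0], dtype=float)
        cols = np.arange(image.shape[1], dtype=float)
        s0 = make_interp_spline(rows, image, k=degree, axis=0)
        s1 = make_interp_spline(cols, s0.c, k=degree, axis=1)
        # make_interp_spline(axis=1) stores coefficients with the spline
        # axis first; transpose back to (row-coef, col-coef).
        self._nd = NdBSpline((s0.t, s1.t), s1.c.T, k=(degree, degree))
        self.degree = degree
        self.shape = image.shape

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Evaluate at ``points`` of shape (..., 2) given as (row, col)."""
        return self._nd(np.asarray(points, dtype=float))
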