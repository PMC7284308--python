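"""Moment-based ellipse fitting and raster overlap of ellipses.

Per-slice nuclear cross sections are summarised by the ellipse sharing the
pixel set's centroid, principal axes and area.  Overlap between ellipses of
adjacent optical sections (the linking criterion of the 3D reconstruction)
is measured by rasterizing both on the common pixel grid and counting shared
pixels, so "interaction" has an exact, grid-level meaning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["Ellipse2D", "fit_ellipse", "rasterize_ellipse", "ellipse_overlap"]

#: minor semi-axis floor (px) for degenerate, collinear pixel sets
_MIN_SEMI_AXIS = 0.5


@dataclass(frozen=True)
class Ellipse2D:
    """An ellipse in pixel coordinates.

    ``center`` is (row, col); ``a`` and ``b`` are the major/minor semi-axes
    in px (``a >= b``); ``theta`` is the angle of the major axis measured
    from the +x (column) axis toward +y, in ``(-pi/2, pi/2]``.
    """

    center: tuple[float, float]
    a: float
    b: float
    theta: float

    @property
    def area(self) -> float:
        return float(np.pi * self.a * self.b)


def fit_ellipse(rows: np.ndarray, cols: np.ndarray) -> Ellipse2D:
    """Fit an equal-area ellipse to a pixel set from second central moments.

    The principal axes come from the eigendecomposition of the pixel
    covariance; both semi-axes are then rescaled by a common factor so that
    ``pi * a * b`` equals the pixel count exactly.  Collinear pixel sets get
    the minor axis floored at 0.5 px (with a warning) before normalization.
    """
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    n = rows.size
    if n == 0:
        raise ValueError("cannot fit an ellipse to an empty pixel set")
    cy, cx = rows.mean(), cols.mean()
    dy, dx = rows - cy, cols - cx
    # covariance in (x, y) order so theta is measured from the +x axis
    mxx = float(np.mean(dx * dx))
    myy = float(np.mean(dy * dy))
    mxy = float(np.mean(dx * dy))
    cov = np.array([[mxx, mxy], [mxy, myy]])
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam_minor, lam_major = max(evals[0], 0.0), max(evals[1], 0.0)
    vx, vy = evecs[0, 1], evecs[1, 1]  # major-axis direction
    theta = float(np.arctan2(vy, vx))
    # fold into (-pi/2, pi/2]
    if theta <= -np.pi / 2:
        theta += np.pi
    elif theta > np.pi / 2:
        theta -= np.pi
    # an ellipse with matching normalized second moments has semi-axes 2*sqrt(lambda)
    a = 2.0 * np.sqrt(lam_major)
    b = 2.0 * np.sqrt(lam_minor)
    if b < _MIN_SEMI_AXIS:
        warnings.warn(
            "degenerate pixel set: minor semi-axis floored at 0.5 px",
            stacklevel=2,
        )
        b = _MIN_SEMI_AXIS
        a = max(a, b)
        # preserve the pixel area with the floored minor axis
        a = n / (np.pi * b)
        return Ellipse2D((float(cy), float(cx)), float(a), float(b), theta)
    # equal-area normalization: scale both axes so pi*a*b == pixel count
    scale = np.sqrt(n / (np.pi * a * b))
    return Ellipse2D((float(cy), float(cx)), float(a * scale), float(b * scale), theta)


def _contains(e: Ellipse2D, rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
    """Boolean mask of pixel centers (rr, cc) inside the ellipse."""
    dy = rr - e.center[0]
    dx = cc - e.center[1]
    ct, st = np.cos(e.theta), np.sin(e.theta)
    u = dx * ct + dy * st  # along major axis
    v = -dx * st + dy * ct
    return (u / e.a) ** 2 + (v / e.b) ** 2 <= 1.0


def rasterize_ellipse(e: Ellipse2D) -> tuple[np.ndarray, np.ndarray]:
    """Integer pixel coordinates (rows, cols) whose centers fall inside."""
    r = max(e.a, e.b)
    r0 = int(np.floor(e.center[0] - r))
    r1 = int(np.ceil(e.center[0] + r))
    c0 = int(np.floor(e.center[1] - r))
    c1 = int(np.ceil(e.center[1] + r))
    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    inside = _contains(e, rr, cc)
    return rr[inside], cc[inside]


def ellipse_overlap(
    e1: Ellipse2D, e2: Ellipse2D, subsample: int = 4
) -> float:
    """Shared area of two ellipses in px², by counting common raster cells.

    Each pixel is subdivided ``subsample``× per axis, so the area
    resolution is ``1/subsample²`` px² (with ``subsample=1`` this is plain
    common-pixel counting).  Two sections of adjacent slices "interact"
    iff the shared area is >= 1 px².
    """
    # quick reject: farther apart than the sum of the bounding radii
    d = np.hypot(e1.center[0] - e2.center[0], e1.center[1] - e2.center[1])
    if d > max(e1.a, e1.b) + max(e2.a, e2.b):
        return 0.0
    r0 = np.floor(max(e1.center[0] - e1.a, e2.center[0] - e2.a))
    r1 = np.ceil(min(e1.center[0] + e1.a, e2.center[0] + e2.a))
    c0 = np.floor(max(e1.center[1] - e1.a, e2.center[1] - e2.a))
    c1 = np.ceil(min(e1.center[1] + e1.a, e2.center[1] + e2.a))
    if r1 < r0 or c1 < c0:
        return 0.0
    step = 1.0 / subsample
    rows = np.arange(r0, r1 + step / 2, step)
    cols = np.arange(c0, c1 + step / 2, step)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    both = _contains(e1, rr, cc) & _contains(e2, rr, cc)
    return float(both.sum()) * step * step
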