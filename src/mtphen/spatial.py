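"""Nuclear packing metrics.

For each nucleus the distances to its 12 nearest neighbours are computed
(in μm, so axial anisotropy is already corrected) and summarised by their
median — the "most probable" neighbour distance.  The tissue-level packing
statistic is the mean (and SD) of these per-nucleus medians.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["knn_median_distance", "mt_average_distance"]


def knn_median_distance(centroids_um: np.ndarray, k: int = 12) -> np.ndarray:
    """Per-nucleus median distance (μm) to its k nearest neighbours.

    ``k`` is capped at ``n - 1`` for small samples.  The even-count median
    is the mean of the two central values.  Coincident points produce zero
    medians and a warning.
    """
    pts = np.asarray(centroids_um, dtype=float)
    if pts.ndim != 2:
        raise ValueError("centroids must be an (n, d) array")
    n = pts.shape[0]
    if n < 2:
        raise ValueError("need at least 2 centroids")
    k = min(k, n - 1)
    tree = cKDTree(pts)
    # first neighbour is the point itself (distance 0)
    dists, _ = tree.query(pts, k=k + 1)
    med = np.median(dists[:, 1:], axis=1)
    if np.any(dists[:, 1] == 0):
        warnings.warn("coincident centroids found", stacklevel=2)
    return med


def mt_average_distance(medians_um: np.ndarray) -> tuple[float, float]:
    """Mean and SD (n-1 denominator) of the per-nucleus medians."""
    med = np.asarray(medians_um, dtype=float)
    if med.size == 0:
        raise ValueError("no medians given")
    sd = float(med.std(ddof=1)) if med.size > 1 else 0.0
    return float(med.mean()), sd
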