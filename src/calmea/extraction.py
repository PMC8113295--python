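"""Cell detection and trace extraction from image stacks.

A deliberately simple detector: cell bodies are found as local intensity
maxima on the nuclear channel (or, when none is available, on the
temporal-mean image), non-maximum-suppressed at a minimum distance, and
represented as fixed-radius disk ROIs.  Traces are the mean pixel
intensity inside each disk per frame.  This is sufficient for
blob-rendered synthetic fields; it makes no attempt at full segmentation,
motion correction or demixing of overlapping cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage.feature import peak_local_max

from .core import CellTrace


@dataclass
class CellROI:
    """A fixed-radius disk region of interest.

    ``centroid`` is 0-based ``(row, col)`` in pixels.
    """

    cell_id: int
    centroid: Tuple[float, float]
    radius: float


def detect_cells(
    image,
    min_distance: int = 6,
    intensity_quantile: float = 0.95,
    radius: float = 4.0,
) -> List[CellROI]:
    """Detect cell bodies as local maxima of a 2-D image.

    Local maxima above the given intensity quantile are kept, suppressed
    within ``min_distance`` pixels of a brighter maximum, and returned as
    disk ROIs of the given radius sorted by ``(row, col)``.  A blank or
    constant image yields an empty list.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_cells expects a 2-D image")
    if img.size == 0 or np.ptp(img) == 0:
        return []
    threshold = float(np.quantile(img, intensity_quantile))
    coords = peak_local_max(
        img,
        min_distance=min_distance,
        threshold_abs=threshold,
        exclude_border=False,
    )
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    coords = coords[order]
    return [
        CellROI(cell_id=i, centroid=(float(r), float(c)), radius=radius)
        for i, (r, c) in enumerate(coords)
    ]


def _disk_indices(
    centroid: Tuple[float, float], radius: float, shape: Tuple[int, int]
) -> Tuple[np.ndarray, np.ndarray]:
    """Pixel indices with (dy^2 + dx^2) <= radius^2, clipped to the image."""
    cy, cx = int(round(centroid[0])), int(round(centroid[1]))
    r = int(radius)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy**2 + dx**2 <= radius**2
    rows, cols = cy + dy[keep], cx + dx[keep]
    inside = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
    return rows[inside], cols[inside]


def extract_traces(stack, rois: Sequence[CellROI]) -> List[CellTrace]:
    """Mean ROI intensity per frame for each disk ROI.

    Parameters
    ----------
    stack : array-like, shape (n_frames, height, width)
    rois : sequence of :class:`CellROI`

    Returns one :class:`~calmea.core.CellTrace` per ROI, in ROI order.
    """
    arr = np.asarray(stack, dtype=float)
    if arr.ndim != 3 or arr.shape[0] == 0:
        raise ValueError("stack must be (n_frames, H, W) with n_frames >= 1")
    traces = []
    for roi in rois:
        rows, cols = _disk_indices(roi.centroid, roi.radius, arr.shape[1:])
        if rows.size == 0:
            raise ValueError(f"ROI {roi.cell_id} lies outside the image")
        traces.append(
            CellTrace(
                cell_id=roi.cell_id,
                fluorescence=arr[:, rows, cols].mean(axis=1),
                centroid=roi.centroid,
            )
        )
    return traces


def match_rois_to_centroids(
    rois: Sequence[CellROI], centroids: np.ndarray, max_distance: float = 3.0
) -> Tuple[List[Tuple[int, int]], List[int]]:
    """Greedy nearest-neighbour matching of detected ROIs to true centroids.

    Returns ``(matches, spurious)`` where ``matches`` is a list of
    ``(roi_index, centroid_index)`` pairs within ``max_distance`` pixels
    and ``spurious`` the indices of unmatched ROIs.  Used to validate the
    detector against generator ground truth.
    """
    centroids = np.asarray(centroids, dtype=float)
    unused = set(range(len(centroids)))
    matches, spurious = [], []
    for i, roi in enumerate(rois):
        if not unused:
            spurious.append(i)
            continue
        cand = sorted(
            unused,
            key=lambda j: (roi.centroid[0] - centroids[j, 0]) ** 2
            + (roi.centroid[1] - centroids[j, 1]) ** 2,
        )
        j = cand[0]
        d = np.hypot(
            roi.centroid[0] - centroids[j, 0], roi.centroid[1] - centroids[j, 1]
        )
        if d <= max_distance:
            matches.append((i, j))
            unused.discard(j)
        else:
            spurious.append(i)
    return matches, spurious
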