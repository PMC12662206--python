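"""Morphological midline extraction for elongated organoid masks.

The midline of an organoid section is defined as the least-cost path over
the ridge of the Euclidean distance transform (EDT) of the structure mask,
anchored at the two detected corners closest to the ends of the mask's
moment-ellipse major axis.  The pipeline is:

1. ``segment_structure`` — turn a binarized cell-segmentation image into a
   single solid structure mask (closing, hole filling, opening, largest
   component), padding the grid when the structure touches the border.
2. ``extract_midline`` — EDT, Meijering ridge enhancement, Harris corner
   anchoring, and 8-connected minimum-cost routing over ``1 - ridge``.

All coordinates are 0-based ``(row, col)`` pixels with the origin at the
top-left of the image; distances are in pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_fill_holes, distance_transform_edt
from scipy.spatial.distance import cdist
from skimage.feature import corner_harris, corner_peaks
from skimage.filters import meijering
from skimage.graph import route_through_array
from skimage.measure import label, regionprops
from skimage.morphology import isotropic_closing, isotropic_opening

logger = logging.getLogger(__name__)

#: cost assigned to pixels outside the structure so the routed path can
#: never leave the mask (finite to keep the graph search well-defined)
_OUTSIDE_COST = 1.0e6


@dataclass
class Mask:
    """A 2-D boolean pixel grid, optionally padded.

    Parameters
    ----------
    grid
        Boolean array, True inside the structure.
    pad_offset
        ``(rows, cols)`` added to the top/left during segmentation.  Cell
        centroids recorded in the unpadded frame must be shifted by this
        offset before being compared against ``grid``.
    """

    grid: np.ndarray
    pad_offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")

    @property
    def area(self) -> int:
        return int(self.grid.sum())


@dataclass
class Midline:
    """An ordered 8-connected pixel path with arc-length parameterization.

    ``arclen`` accumulates unit steps for axis moves and ``sqrt(2)`` for
    diagonal moves; ``frac = arclen / arclen[-1]`` gives the normalized
    position of each path point along the midline.
    """

    path: np.ndarray  # (n, 2) int array of (row, col)
    arclen: np.ndarray = field(init=False)
    endpoints: tuple[tuple[int, int], tuple[int, int]] = field(init=False)

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=int)
        if self.path.ndim != 2 or self.path.shape[1] != 2 or len(self.path) < 2:
            raise ValueError("midline path must be an (n>=2, 2) array")
        steps = np.abs(np.diff(self.path, axis=0))
        if np.any(steps.max(axis=1) != 1):
            raise ValueError("consecutive midline points must be 8-neighbors")
        lengths = np.where(steps.sum(axis=1) == 2, np.sqrt(2.0), 1.0)
        self.arclen = np.concatenate([[0.0], np.cumsum(lengths)])
        self.endpoints = (tuple(self.path[0]), tuple(self.path[-1]))

    def __len__(self) -> int:
        return len(self.path)

    @property
    def length(self) -> float:
        """Total arc length in pixels."""
        return float(self.arclen[-1])

    @property
    def frac(self) -> np.ndarray:
        """Arc-length fraction in [0, 1] of every path point."""
        return self.arclen / self.arclen[-1]


def segment_structure(
    cell_mask: Mask | np.ndarray,
    close_radius: float = 50,
    open_radius: float = 20,
    pad: int = 100,
    border_trigger: int = 50,
) -> Mask:
    """Segment the organoid structure from a binarized cell mask.

    Applies morphological closing (disc radius ``close_radius``), hole
    filling and opening (disc radius ``open_radius``), then keeps only the
    largest 8-connected component.  If any foreground pixel lies within
    ``border_trigger`` pixels of the image boundary the grid is first padded
    by ``pad`` pixels on every side (recorded in ``pad_offset``) so the
    morphology does not clip against the border.
    """
    grid = cell_mask.grid if isinstance(cell_mask, Mask) else np.asarray(cell_mask, bool)
    if not grid.any():
        raise ValueError("cell mask is empty")

    rows, cols = np.nonzero(grid)
    h, w = grid.shape
    near_border = (
        rows.min() < border_trigger
        or cols.min() < border_trigger
        or rows.max() >= h - border_trigger
        or cols.max() >= w - border_trigger
    )
    offset = (0, 0)
    if near_border:
        grid = np.pad(grid, pad)
        offset = (pad, pad)

    grid = isotropic_closing(grid, close_radius)
    grid = binary_fill_holes(grid)
    grid = isotropic_opening(grid, open_radius)
    if not grid.any():
        raise ValueError("structure vanished after morphological opening")

    labels = label(grid, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    grid = labels == counts.argmax()
    return Mask(grid, pad_offset=offset)


def _major_axis_endpoints(grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """The two ends of the mask's major axis, in (row, col).

    The ends are the mask pixels extremal along the moment-ellipse
    orientation (the points where the segmentation ends along its major
    axis).  For bent structures these stay on the mask, unlike the
    centroid +/- half-length ellipse endpoints, which drift off the arc
    and would mis-anchor the corner selection.
    """
    props = regionprops(grid.astype(np.uint8))[0]
    theta = props.orientation
    # direction of the major axis in (row, col) for skimage's orientation
    # convention (angle measured from the row axis)
    drow, dcol = -np.cos(theta), -np.sin(theta)
    rr, cc = np.nonzero(grid)
    along = rr * drow + cc * dcol
    p1 = np.array([rr[along.argmax()], cc[along.argmax()]], dtype=float)
    p2 = np.array([rr[along.argmin()], cc[along.argmin()]], dtype=float)
    return p1, p2


def extract_midline(
    struct_mask: Mask | np.ndarray,
    ridge_sigmas: tuple[float, ...] = (1, 3, 5, 7),
    harris_k: float = 0.05,
    corner_threshold_rel: float = 0.01,
    corner_min_distance: int = 10,
) -> Midline:
    """Extract the morphological midline of a segmented structure.

    The Euclidean distance transform of the mask is ridge-enhanced with a
    Meijering neuriteness filter (bright ridges, maximum response over
    ``ridge_sigmas``) and rescaled to [0, 1]; candidate endpoints are Harris
    corner peaks of the mask, of which the two closest to the moment-ellipse
    major-axis endpoints are selected; the midline is the minimum-cost
    8-connected path between them over the cost map ``1 - ridge`` with
    geometric step weighting.
    """
    grid = struct_mask.grid if isinstance(struct_mask, Mask) else np.asarray(struct_mask, bool)
    if not grid.any():
        raise ValueError("structure mask is empty")
    if label(grid, connectivity=2).max() != 1:
        raise ValueError("structure mask must be a single connected component")

    edt = distance_transform_edt(grid)
    ridge = meijering(edt, sigmas=ridge_sigmas, black_ridges=False)
    lo, hi = ridge.min(), ridge.max()
    if hi <= lo:
        raise ValueError("ridge response is constant; cannot route a midline")
    ridge = (ridge - lo) / (hi - lo)

    cost = 1.0 - ridge
    cost[~grid] = _OUTSIDE_COST

    harris = corner_harris(grid.astype(float), k=harris_k)
    corners = corner_peaks(
        harris, min_distance=corner_min_distance, threshold_rel=corner_threshold_rel
    )
    if len(corners) < 2:
        raise ValueError(f"found {len(corners)} corner candidates; need at least 2")

    p1, p2 = _major_axis_endpoints(grid)
    d1 = np.linalg.norm(corners - p1, axis=1)
    d2 = np.linalg.norm(corners - p2, axis=1)
    i1, i2 = int(d1.argmin()), int(d2.argmin())
    if i1 == i2:
        # same candidate nearest to both ellipse ends: give the end it fits
        # best its choice and the other end its runner-up
        if d1[i1] <= d2[i2]:
            i2 = int(np.argsort(d2)[1])
        else:
            i1 = int(np.argsort(d1)[1])
    start, end = tuple(corners[i1]), tuple(corners[i2])

    path, _ = route_through_array(cost, start, end, fully_connected=True, geometric=True)
    path = np.asarray(path, dtype=int)
    if not grid[path[:, 0], path[:, 1]].all():
        raise RuntimeError("routed midline left the structure mask")
    return Midline(path)


def midline_deviation(
    midline: Midline | np.ndarray, reference: np.ndarray
) -> float:
    """Mean distance (px) from each midline point to its nearest reference point."""
    pts = midline.path if isinstance(midline, Midline) else np.asarray(midline, float)
    ref = np.asarray(reference, dtype=float)
    if len(pts) == 0 or len(ref) == 0:
        raise ValueError("midline and reference must be non-empty")
    return float(cdist(pts.astype(float), ref).min(axis=1).mean())
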