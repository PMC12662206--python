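"""Crowding-penalized projection of cells onto the morphological midline.

Projecting every cell to its nearest midline coordinate piles most cells
onto a few coordinates.  The remedy is a multiplicative crowding penalty:
cell c is assigned to the coordinate i minimizing

    D'_{i,c} = D_{i,c} * exp(alpha * N_i)

where D is the Euclidean pixel distance and N_i the number of cells
already associated with coordinate i.  Cells are processed sequentially
(ascending cell_id, for determinism) and N is updated after each
assignment; alpha = 0.01 by default, and alpha = 0 recovers plain
nearest-coordinate projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .midline import Mask, Midline

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01


@dataclass
class ProjectionResult:
    """Cell-to-midline assignment with per-coordinate occupancy.

    ``assignment`` maps cell_id to midline path index; ``occupancy[i]`` is
    the final N_i; ``coord_frac[i]`` is the arc-length fraction of midline
    point i (used later to place cells on the 0-1 axis); ``s`` holds the
    oriented axial positions once the proximal end is known.
    """

    assignment: pd.Series
    occupancy: np.ndarray
    alpha: float
    coord_frac: np.ndarray
    s: pd.Series | None = None


def filter_cells_in_structure(cells: pd.DataFrame, struct_mask: Mask) -> pd.DataFrame:
    """Keep cells whose rounded centroid lies on a true structure pixel.

    Centroids are first shifted by the mask's ``pad_offset`` so tables
    recorded in the unpadded image frame line up with the segmented grid;
    the returned coordinates are in the padded frame.  Centroids outside
    the grid bounds are dropped with a warning.
    """
    grid = struct_mask.grid
    out = cells.copy()
    out["row"] = out["row"] + struct_mask.pad_offset[0]
    out["col"] = out["col"] + struct_mask.pad_offset[1]
    rr = np.round(out["row"].to_numpy(float)).astype(int)
    cc = np.round(out["col"].to_numpy(float)).astype(int)
    in_bounds = (rr >= 0) & (rr < grid.shape[0]) & (cc >= 0) & (cc < grid.shape[1])
    n_oob = int((~in_bounds).sum())
    if n_oob:
        logger.warning("%d cell centroids fall outside the grid; dropped", n_oob)
    keep = in_bounds.copy()
    keep[in_bounds] = grid[rr[in_bounds], cc[in_bounds]]
    return out.loc[keep].reset_index(drop=True)


def project_cells(
    cells: pd.DataFrame, midline: Midline, alpha: float = DEFAULT_ALPHA
) -> ProjectionResult:
    """Assign each cell to a midline coordinate under the crowding penalty.

    Cells are processed in ascending cell_id order; ties in the penalized
    argmin break toward the smaller midline index.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    order = cells.sort_values("cell_id")
    pts = order[["row", "col"]].to_numpy(dtype=float)
    coords = midline.path.astype(float)
    n_coords = len(coords)

    occupancy = np.zeros(n_coords, dtype=int)
    assigned = np.empty(len(order), dtype=int)
    dist = cdist(pts, coords)
    for k in range(len(order)):
        penalized = dist[k] * np.exp(alpha * occupancy)
        i = int(penalized.argmin())  # argmin keeps the lower index on ties
        assigned[k] = i
        occupancy[i] += 1

    assignment = pd.Series(assigned, index=pd.Index(order["cell_id"], name="cell_id"))
    return ProjectionResult(
        assignment=assignment,
        occupancy=occupancy,
        alpha=alpha,
        coord_frac=midline.frac.copy(),
    )


def crowding_curve(
    cells: pd.DataFrame, midline: Midline, alphas: list[float]
) -> pd.DataFrame:
    """Maximum coordinate occupancy as a function of the penalty strength."""
    if not alphas:
        raise ValueError("need at least one alpha")
    rows = []
    for a in alphas:
        res = project_cells(cells, midline, alpha=a)
        rows.append({"alpha": a, "max_occupancy": int(res.occupancy.max())})
    return pd.DataFrame(rows)
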