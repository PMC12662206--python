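"""Synthetic elongated-organoid generator with known ground truth.

Real inputs to the axis pipeline are organoid section masks, per-cell
centroids from in situ profiling, and a cell-by-gene count matrix.  This
module emulates all three so that every downstream stage — midline
extraction, cell projection, orientation, polarity classification, domain
summaries — can be scored against a known truth:

* the organoid shape is a capsule (stadium: a rectangle with semicircular
  caps), optionally bent along a circular arc, mimicking a sphere that has
  elongated and curved;
* cells are scattered uniformly over the mask, each carrying its true
  axial position ``s_true`` (arc-length fraction along the true midline);
* counts follow a Poisson (or negative-binomial) model in which one gene
  set (chondrogenic) decreases and the other (fibroblast) increases
  monotonically from the proximal to the distal end, on top of flat
  background genes.

All randomness flows from the single ``SimParams.seed`` through a
``numpy.random.SeedSequence``, so identical parameters yield bit-identical
masks, tables and matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .midline import Mask

#: Gene sets used to orient the proximal-distal axis: cartilage program
#: (high at the proximal end) vs fibroblast program (high at the distal end).
DEFAULT_GENE_SETS: dict[str, list[str]] = {
    "chondrogenic": ["Sox9", "Acan", "Col2a1", "Col9a1", "Col9a2", "Col11a1"],
    "fibroblast": ["Col1a1", "Col3a1"],
}

FIRST_IS_PROXIMAL = "first-is-proximal"
LAST_IS_PROXIMAL = "last-is-proximal"

_MIDLINE_SPACING = 0.5  # px between true-midline samples


@dataclass(frozen=True)
class SimParams:
    """Parameters of one synthetic organoid.

    ``length_px`` is the total tip-to-tip length of the capsule and
    ``width_px`` its width (cap diameter); ``curvature`` (1/px) bends the
    capsule spine along a circular arc (0 = straight).  ``base_rate`` is the
    mean count per gene per cell for background genes; ``effect_size`` is
    the gradient strength beta, giving set-gene means
    ``base_rate * (1 + beta * (1 - p))`` (chondrogenic) and
    ``base_rate * (1 + beta * p)`` (fibroblast) at proximal-referenced
    axial position p.  ``dispersion`` d selects negative-binomial noise with
    variance ``mu + d * mu**2`` (d = 0: Poisson).
    """

    length_px: int = 400
    width_px: int = 100
    curvature: float = 0.0
    n_cells: int = 600
    n_background_genes: int = 123
    base_rate: float = 2.0
    effect_size: float = 4.0
    dispersion: float = 0.0
    seed: int = 0
    margin_px: int = 20

    def __post_init__(self) -> None:
        if not self.length_px > self.width_px > 0:
            raise ValueError(
                f"capsule must be elongated: need length_px > width_px > 0, "
                f"got {self.length_px} x {self.width_px}"
            )
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be positive")
        if self.effect_size < 0 or self.dispersion < 0:
            raise ValueError("effect_size and dispersion must be non-negative")
        if self.curvature < 0:
            raise ValueError("curvature must be non-negative")
        if self.curvature > 0:
            # spine must bend gently enough that the inner cap edge does not
            # self-intersect
            if 1.0 / self.curvature <= self.width_px / 2:
                raise ValueError("curvature radius must exceed half the width")


@dataclass
class SyntheticOrganoid:
    """A generated organoid with its ground truth.

    ``true_midline`` runs tip to tip through the cap centers (float (row,
    col) samples at <= 1 px spacing); ``true_orientation`` records which end
    of it is proximal.  ``cells`` and ``counts`` are None until populated by
    :func:`scatter_cells` / :func:`simulate_counts` (or use
    :func:`simulate_organoid` for the full object).
    """

    mask: Mask
    true_midline: np.ndarray
    true_orientation: str
    params: SimParams
    cells: pd.DataFrame | None = None
    counts: ad.AnnData | None = None
    _midline_tree: cKDTree = field(init=False, repr=False)
    _midline_frac: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seg = np.linalg.norm(np.diff(self.true_midline, axis=0), axis=1)
        arclen = np.concatenate([[0.0], np.cumsum(seg)])
        self._midline_frac = arclen / arclen[-1]
        self._midline_tree = cKDTree(self.true_midline)

    def axial_fraction(self, points: np.ndarray) -> np.ndarray:
        """True-midline arc-length fraction of the nearest midline point.

        Ties in the nearest-point query resolve to the lower arc-length
        index.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if len(self.true_midline) * len(pts) <= 2_000_000:
            d = np.linalg.norm(
                pts[:, None, :] - self.true_midline[None, :, :], axis=2
            )
            idx = d.argmin(axis=1)  # argmin takes the first (lower) index on ties
        else:
            _, idx = self._midline_tree.query(pts)
        return self._midline_frac[idx]


def _spine_points(params: SimParams, spacing: float) -> np.ndarray:
    """Sample the full tip-to-tip spine in local (x, y) coordinates.

    The central portion of length ``length_px - width_px`` follows a
    circular arc of the given curvature; the axis is extended straight along
    the end tangents by ``width_px / 2`` so that it reaches the cap tips.
    """
    half_w = params.width_px / 2.0
    arc_len = params.length_px - params.width_px
    n_arc = max(int(np.ceil(arc_len / spacing)), 2) + 1
    t = np.linspace(0.0, arc_len, n_arc)
    if params.curvature == 0:
        xy = np.column_stack([t - arc_len / 2.0, np.zeros_like(t)])
        tan0 = tan1 = np.array([1.0, 0.0])
    else:
        radius = 1.0 / params.curvature
        phi = (t - arc_len / 2.0) / radius
        xy = np.column_stack([radius * np.sin(phi), radius * (1.0 - np.cos(phi))])
        tan0 = np.array([np.cos(phi[0]), np.sin(phi[0])])
        tan1 = np.array([np.cos(phi[-1]), np.sin(phi[-1])])
    n_cap = max(int(np.ceil(half_w / spacing)), 2)
    ext = np.linspace(spacing, half_w, n_cap)
    head = xy[0] - tan0 * ext[::-1, None]
    tail = xy[-1] + tan1 * ext[:, None]
    return np.vstack([head, xy, tail])


def make_organoid_mask(params: SimParams) -> SyntheticOrganoid:
    """Rasterize a (possibly bent) capsule mask with its true midline.

    The mask is the set of pixels within ``width_px / 2`` of the capsule
    spine (the central arc, not the tip extensions), which yields a solid,
    hole-free, single-component stadium; the grid is sized automatically to
    hold the shape plus ``margin_px``.  The proximal end label is drawn from
    the seed so that orientation recovery is a fair test downstream.
    """
    spine = _spine_points(params, _MIDLINE_SPACING)
    half_w = params.width_px / 2.0
    n_cap = max(int(np.ceil(half_w / _MIDLINE_SPACING)), 2)
    arc = spine[n_cap:-n_cap]  # spine without the tip extensions

    lo = arc.min(axis=0) - half_w - params.margin_px
    hi = arc.max(axis=0) + half_w + params.margin_px
    origin = lo  # (x, y) of pixel (col=0, row=0)
    n_cols = int(np.ceil(hi[0] - lo[0])) + 1
    n_rows = int(np.ceil(hi[1] - lo[1])) + 1

    cols, rows = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    px_xy = np.column_stack([cols.ravel() + origin[0], rows.ravel() + origin[1]])
    dist, _ = cKDTree(arc).query(px_xy)
    grid = (dist <= half_w).reshape(n_rows, n_cols)

    midline_rc = np.column_stack([spine[:, 1] - origin[1], spine[:, 0] - origin[0]])
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0]))
    orientation = FIRST_IS_PROXIMAL if rng.random() < 0.5 else LAST_IS_PROXIMAL
    return SyntheticOrganoid(
        mask=Mask(grid),
        true_midline=midline_rc,
        true_orientation=orientation,
        params=params,
    )


def scatter_cells(
    organoid: SyntheticOrganoid, n_cells: int, seed: int
) -> pd.DataFrame:
    """Scatter cell centroids uniformly over true mask pixels.

    Each cell gets a sub-pixel jitter (so centroids are float but still
    round back onto their source pixel) and its true axial position
    ``s_true``.  Returns a table with columns ``cell_id, row, col, s_true``.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    grid = organoid.mask.grid
    if not grid.any():
        raise ValueError("organoid mask is empty")
    cols = ["cell_id", "row", "col", "s_true"]
    if n_cells == 0:
        return pd.DataFrame(columns=cols)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    rr, cc = np.nonzero(grid)
    pick = rng.integers(0, len(rr), size=n_cells)
    jitter = rng.uniform(-0.49, 0.49, size=(n_cells, 2))
    pts = np.column_stack([rr[pick], cc[pick]]).astype(float) + jitter
    s_true = organoid.axial_fraction(pts)
    return pd.DataFrame(
        {
            "cell_id": [f"cell_{i:05d}" for i in range(n_cells)],
            "row": pts[:, 0],
            "col": pts[:, 1],
            "s_true": s_true,
        }
    )


def simulate_counts(
    cells: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    params: SimParams,
    true_orientation: str = FIRST_IS_PROXIMAL,
) -> ad.AnnData:
    """Draw a cell-by-gene count matrix with opposing axial gradients.

    With p the axial position measured from the proximal end, chondrogenic
    genes have mean ``base_rate * (1 + beta * (1 - p))``, fibroblast genes
    ``base_rate * (1 + beta * p)`` and background genes ``base_rate``.
    Counts are Poisson when ``dispersion == 0``, otherwise negative binomial
    with variance ``mu + dispersion * mu**2``.
    """
    if "s_true" not in cells.columns:
        raise ValueError("cells table lacks s_true; scatter cells on an organoid first")
    chond = list(gene_sets["chondrogenic"])
    fibro = list(gene_sets["fibroblast"])
    overlap = set(chond) & set(fibro)
    if overlap:
        raise ValueError(f"gene sets overlap: {sorted(overlap)}")

    s = cells["s_true"].to_numpy(dtype=float)
    p = s if true_orientation == FIRST_IS_PROXIMAL else 1.0 - s
    beta, base = params.effect_size, params.base_rate

    genes = chond + fibro + [f"Bg{i:03d}" for i in range(params.n_background_genes)]
    mu = np.empty((len(cells), len(genes)))
    mu[:, : len(chond)] = (base * (1.0 + beta * (1.0 - p)))[:, None]
    mu[:, len(chond) : len(chond) + len(fibro)] = (base * (1.0 + beta * p))[:, None]
    mu[:, len(chond) + len(fibro) :] = base

    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    if params.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / params.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))

    adata = ad.AnnData(
        X=counts.astype(np.int64),
        obs=pd.DataFrame(index=pd.Index(cells["cell_id"], name="cell_id")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.obs["s_true"] = s
    return adata


def simulate_organoid(
    params: SimParams,
    gene_sets: dict[str, list[str]] | None = None,
    geometry: SyntheticOrganoid | None = None,
) -> SyntheticOrganoid:
    """Generate a complete organoid: mask, midline, cells and counts.

    ``geometry`` lets callers reuse a previously rasterized mask when
    simulating many organoids that differ only in seed (the mask depends
    only on the geometric parameters); the orientation, cells and counts
    are still redrawn from ``params.seed``.
    """
    gene_sets = gene_sets or DEFAULT_GENE_SETS
    if geometry is None:
        organoid = make_organoid_mask(params)
    else:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0]))
        orientation = FIRST_IS_PROXIMAL if rng.random() < 0.5 else LAST_IS_PROXIMAL
        organoid = SyntheticOrganoid(
            mask=geometry.mask,
            true_midline=geometry.true_midline,
            true_orientation=orientation,
            params=params,
        )
    organoid.cells = scatter_cells(organoid, params.n_cells, params.seed)
    organoid.counts = simulate_counts(
        organoid.cells, gene_sets, params, organoid.true_orientation
    )
    return organoid


def make_intensity_image(
    organoid: SyntheticOrganoid, gradient: float
) -> np.ndarray:
    """Grayscale image whose in-mask intensity is affine in axial position.

    Intensity is ``0.5 + gradient * (s - 0.5)`` at axial fraction s (so
    ``gradient=1`` spans [0, 1] tip to tip and ``gradient=0`` is constant
    0.5), clipped to [0, 1], and exactly 0 outside the mask.
    """
    grid = organoid.mask.grid
    if not grid.any():
        raise ValueError("organoid mask is empty")
    rr, cc = np.nonzero(grid)
    s = organoid.axial_fraction(np.column_stack([rr, cc]).astype(float))
    img = np.zeros(grid.shape, dtype=float)
    img[rr, cc] = np.clip(0.5 + gradient * (s - 0.5), 0.0, 1.0)
    return img


def make_crowded_cells(
    organoid: SyntheticOrganoid, n_cells: int = 200, seed: int = 7
) -> pd.DataFrame:
    """Cells clustered near one midline end — a crowding stress fixture.

    Centroids are drawn from an isotropic Gaussian (sigma = width/6)
    centred on the midline point at arc fraction 0.1, rejection-sampled to
    stay inside the mask.  Used to exercise the crowding penalty of the
    projection step.
    """
    grid = organoid.mask.grid
    centre = organoid.true_midline[
        int(np.searchsorted(organoid._midline_frac, 0.1))
    ]
    sigma = organoid.params.width_px / 6.0
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    pts: list[np.ndarray] = []
    while len(pts) < n_cells:
        cand = rng.normal(centre, sigma, size=(4 * n_cells, 2))
        ij = np.round(cand).astype(int)
        ok = (
            (ij[:, 0] >= 0)
            & (ij[:, 0] < grid.shape[0])
            & (ij[:, 1] >= 0)
            & (ij[:, 1] < grid.shape[1])
        )
        ok[ok] = grid[ij[ok, 0], ij[ok, 1]]
        pts.extend(cand[ok])
    pts_arr = np.asarray(pts[:n_cells])
    return pd.DataFrame(
        {
            "cell_id": [f"cell_{i:05d}" for i in range(n_cells)],
            "row": pts_arr[:, 0],
            "col": pts_arr[:, 1],
            "s_true": organoid.axial_fraction(pts_arr),
        }
    )


def with_params(params: SimParams, **overrides) -> SimParams:
    """Convenience: return a copy of ``params`` with fields replaced."""
    return replace(params, **overrides)
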