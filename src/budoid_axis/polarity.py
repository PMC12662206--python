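"""Expression normalization, gene-set scoring, axis orientation and
polarization classification.

Sections profiled in situ are independent, so their midlines have no
consistent left/right convention.  Orientation uses two marker programs:
a chondrogenic set (Sox9, Acan, Col2a1, Col9a1, Col9a2, Col11a1) marking
the cartilage-forming proximal end and a fibroblast set (Col1a1, Col3a1)
marking the distal end.  Cells are grouped into four equidistant
arc-length bins, bin-averaged normalized expression is scored against
expression-matched control genes, and the midline half with the higher
chondrogenic score is called proximal; positions are then rescaled so 0 is
proximal and 1 distal.  An organoid is "polarized" when both the proximal
(chondrogenic) and distal (fibroblast) scores exceed 0.01, "invalid" when
both fall below it, and "nonpolarized" otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

from .projection import ProjectionResult
from .simulate import DEFAULT_GENE_SETS, FIRST_IS_PROXIMAL, LAST_IS_PROXIMAL

logger = logging.getLogger(__name__)

POLARIZATION_THRESHOLD = 0.01
N_AXIS_BINS = 4

PROXIMAL = "proximal"
DISTAL = "distal"


@dataclass(frozen=True)
class PolarityScores:
    proximal_score: float  # chondrogenic enrichment of the proximal half
    distal_score: float  # fibroblast enrichment of the distal half
    polarization_class: str  # polarized | nonpolarized | invalid
    orientation: str  # which midline end is proximal
    incomplete_bins: bool = False  # some axis bins held no cells


def normalize_expression(
    adata: ad.AnnData, target_sum: float = 1.0e4
) -> ad.AnnData:
    """Total-count normalize to ``target_sum`` per cell, then log1p.

    Stores the result in ``adata.layers["norm"]`` and returns ``adata``.
    Cells with zero total counts stay all-zero.
    """
    X = np.asarray(adata.X, dtype=float)
    totals = X.sum(axis=1)
    if not np.any(totals > 0):
        raise ValueError("all cells have zero total counts")
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals), where=totals > 0)
    adata.layers["norm"] = np.log1p(X * scale[:, None])
    return adata


def resolve_gene_sets(
    gene_sets: dict[str, list[str]], panel: pd.Index | list[str]
) -> dict[str, list[str]]:
    """Intersect gene sets with the measured panel.

    Missing members are dropped with a warning; overlapping or fully
    absent sets are errors.
    """
    panel = pd.Index(panel)
    resolved: dict[str, list[str]] = {}
    for name, genes in gene_sets.items():
        present = [g for g in genes if g in panel]
        missing = sorted(set(genes) - set(present))
        if missing:
            logger.warning("gene set %r: dropping absent genes %s", name, missing)
        if not present:
            raise ValueError(f"gene set {name!r} has no genes in the panel")
        resolved[name] = present
    seen: dict[str, str] = {}
    for name, genes in resolved.items():
        for g in genes:
            if g in seen:
                raise ValueError(f"gene {g!r} appears in sets {seen[g]!r} and {name!r}")
            seen[g] = name
    return resolved


def gene_set_score(
    profiles: pd.DataFrame,
    gene_set: list[str],
    n_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Control-matched enrichment score of a gene set, per profile row.

    Genes are ranked by their average expression across profiles and cut
    into ``n_bins`` equal-size bins; for each set gene, up to ``ctrl_size``
    control genes are drawn (seeded, without replacement) from its bin,
    excluding set members.  The score of a profile is the mean expression
    of the set genes minus the mean expression of the pooled controls, so
    a constant matrix scores 0 and an additive shift leaves it unchanged.
    """
    genes = pd.Index(profiles.columns)
    gene_set = [g for g in gene_set if g in genes]
    if not gene_set:
        raise ValueError("gene set has no genes in the profile panel")

    mean_expr = profiles.mean(axis=0)
    ranks = mean_expr.rank(method="first") - 1
    bin_of = (ranks * n_bins // len(genes)).astype(int)

    rng = np.random.default_rng(seed)
    in_set = genes.isin(gene_set)
    controls: set[str] = set()
    for g in gene_set:
        pool = genes[(bin_of == bin_of[g]).to_numpy() & ~in_set]
        if len(pool) == 0:
            pool = genes[~in_set]  # degenerate bin: fall back to the whole panel
        take = min(ctrl_size, len(pool))
        controls.update(rng.choice(pool, size=take, replace=False))

    set_mean = profiles[gene_set].mean(axis=1).to_numpy()
    ctrl_mean = profiles[sorted(controls)].mean(axis=1).to_numpy()
    return set_mean - ctrl_mean


def orient_and_scale(
    projection: ProjectionResult,
    adata: ad.AnnData,
    gene_sets: dict[str, list[str]] | None = None,
    n_axis_bins: int = N_AXIS_BINS,
    threshold: float = POLARIZATION_THRESHOLD,
    score_scope: str = "halves",
    seed: int = 0,
) -> tuple[PolarityScores, pd.Series]:
    """Orient the midline proximal-to-distal and score polarization.

    Cells are split into ``n_axis_bins`` equidistant arc-length bins and
    the normalized expression is averaged per bin; the half with the
    higher mean chondrogenic score becomes proximal.  Returns the scores
    (chondrogenic score of the proximal half, fibroblast score of the
    distal half, or whole-organoid scores when ``score_scope="whole"``)
    and the oriented axial position s in [0, 1] per cell (0 = proximal).
    """
    if "norm" not in adata.layers:
        raise ValueError("run normalize_expression first (missing 'norm' layer)")
    if n_axis_bins % 2:
        raise ValueError("n_axis_bins must be even to split into two halves")
    gene_sets = resolve_gene_sets(
        gene_sets or DEFAULT_GENE_SETS, adata.var_names
    )
    chond, fibro = gene_sets["chondrogenic"], gene_sets["fibroblast"]

    cell_ids = projection.assignment.index
    frac = projection.coord_frac[projection.assignment.to_numpy()]
    norm = pd.DataFrame(
        np.asarray(adata[cell_ids.to_numpy()].layers["norm"]),
        index=cell_ids,
        columns=adata.var_names,
    )

    bins = np.minimum((frac * n_axis_bins).astype(int), n_axis_bins - 1)
    profiles = norm.groupby(bins).mean()
    incomplete = len(profiles) < n_axis_bins
    if incomplete:
        logger.warning(
            "only %d of %d axis bins contain cells; scores use available bins",
            len(profiles), n_axis_bins,
        )

    chond_scores = pd.Series(
        gene_set_score(profiles, chond, seed=seed), index=profiles.index
    )
    fibro_scores = pd.Series(
        gene_set_score(profiles, fibro, seed=seed + 1), index=profiles.index
    )
    half = n_axis_bins // 2
    first_half = profiles.index < half
    first_chond = chond_scores[first_half].mean()
    last_chond = chond_scores[~first_half].mean()
    orientation = (
        FIRST_IS_PROXIMAL if first_chond >= last_chond else LAST_IS_PROXIMAL
    )

    if score_scope == "halves":
        prox_mask = first_half if orientation == FIRST_IS_PROXIMAL else ~first_half
        proximal_score = float(chond_scores[prox_mask].mean())
        distal_score = float(fibro_scores[~prox_mask].mean())
    elif score_scope == "whole":
        whole = norm.mean(axis=0).to_frame().T
        proximal_score = float(gene_set_score(whole, chond, seed=seed)[0])
        distal_score = float(gene_set_score(whole, fibro, seed=seed + 1)[0])
    else:
        raise ValueError(f"unknown score_scope {score_scope!r}")

    s = frac if orientation == FIRST_IS_PROXIMAL else 1.0 - frac
    scores = PolarityScores(
        proximal_score=proximal_score,
        distal_score=distal_score,
        polarization_class=classify_polarization(
            proximal_score, distal_score, threshold
        ),
        orientation=orientation,
        incomplete_bins=incomplete,
    )
    return scores, pd.Series(s, index=cell_ids, name="s")


def classify_polarization(
    proximal_score: float,
    distal_score: float,
    threshold: float = POLARIZATION_THRESHOLD,
) -> str:
    """Three-way polarization call from the two domain scores.

    Both scores strictly above the threshold: "polarized"; both strictly
    below: "invalid"; anything else (including scores exactly at the
    threshold): "nonpolarized".
    """
    if not (np.isfinite(proximal_score) and np.isfinite(distal_score)):
        raise ValueError("scores must be finite")
    if proximal_score > threshold and distal_score > threshold:
        return "polarized"
    if proximal_score < threshold and distal_score < threshold:
        return "invalid"
    return "nonpolarized"


def split_halves(s: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Label each cell by axis half: s < 0.5 proximal, s >= 0.5 distal."""
    labels = np.where(np.asarray(s, float) < 0.5, PROXIMAL, DISTAL)
    if isinstance(s, pd.Series):
        return pd.Series(labels, index=s.index, name="domain")
    return labels
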