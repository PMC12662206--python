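"""Sample QC, per-domain expression summaries, and domain-separation PCA.

A "sample" is one profiled organoid section; after orientation each cell
belongs to the proximal or distal half.  This module filters samples by
detected-gene count (< 180 detected genes excluded), averages normalized
expression per domain, and compares conditions by the distance between
the proximal and distal centroids in PCA space: strongly polarized
conditions separate the two domains, mixed conditions do not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

MIN_DETECTED_GENES = 180
MIN_CELL_FRACTION = 0.01

WHOLE = "whole"


@dataclass
class DomainSummary:
    """Mean normalized expression over the cells of one domain of one sample."""

    sample_id: str
    condition: str
    domain: str  # proximal | distal | whole
    mean_expression: pd.Series  # indexed by gene
    n_cells: int


@dataclass
class PcaResult:
    embedding: pd.DataFrame  # rows (sample, condition, domain), cols PC1..
    explained_variance: np.ndarray
    centroid_distance: dict[str, float]  # per condition


def detected_genes(adata: ad.AnnData) -> int:
    """Number of genes with at least one count in at least one cell."""
    return int((np.asarray(adata.X).sum(axis=0) >= 1).sum())


def qc_filter_samples(
    matrices: dict[str, ad.AnnData], min_genes: int = MIN_DETECTED_GENES
) -> list[str]:
    """Keep samples whose detected-gene count is at least ``min_genes``."""
    kept = [sid for sid, a in matrices.items() if detected_genes(a) >= min_genes]
    dropped = sorted(set(matrices) - set(kept))
    if dropped:
        logger.info("QC excluded %d samples: %s", len(dropped), dropped)
    return kept


def summarize_domains(
    adata: ad.AnnData,
    domains: pd.Series,
    sample_id: str,
    condition: str = "",
    include_whole: bool = True,
) -> list[DomainSummary]:
    """Per-domain mean of the normalized layer.

    ``domains`` maps cell_id to "proximal"/"distal".  Domains without
    cells are omitted with a warning; the whole-section mean is appended
    when ``include_whole``.
    """
    if "norm" not in adata.layers:
        raise ValueError("run normalize_expression first (missing 'norm' layer)")
    cells = domains.index.intersection(adata.obs_names)
    norm = pd.DataFrame(
        np.asarray(adata[cells.to_numpy()].layers["norm"]),
        index=cells,
        columns=adata.var_names,
    )
    out: list[DomainSummary] = []
    for dom in ("proximal", "distal"):
        sel = norm.loc[domains.loc[cells] == dom]
        if sel.empty:
            logger.warning("sample %s: domain %r has no cells; omitted", sample_id, dom)
            continue
        out.append(
            DomainSummary(sample_id, condition, dom, sel.mean(axis=0), len(sel))
        )
    if include_whole and not norm.empty:
        out.append(
            DomainSummary(sample_id, condition, WHOLE, norm.mean(axis=0), len(norm))
        )
    return out


def summaries_to_frame(summaries: list[DomainSummary]) -> pd.DataFrame:
    """Stack summaries into a (sample, condition, domain) x gene frame."""
    idx = pd.MultiIndex.from_tuples(
        [(s.sample_id, s.condition, s.domain) for s in summaries],
        names=["sample_id", "condition", "domain"],
    )
    return pd.DataFrame([s.mean_expression for s in summaries], index=idx)


def gene_cell_fractions(matrices: dict[str, ad.AnnData]) -> pd.Series:
    """Fraction of pooled cells in which each gene has a count >= 1."""
    expressed = None
    n_cells = 0
    for a in matrices.values():
        e = pd.Series(
            (np.asarray(a.X) >= 1).sum(axis=0), index=a.var_names, dtype=float
        )
        expressed = e if expressed is None else expressed.add(e, fill_value=0)
        n_cells += a.n_obs
    if expressed is None or n_cells == 0:
        raise ValueError("no cells pooled across samples")
    return expressed / n_cells


def pca_domains(
    summaries: list[DomainSummary],
    cell_fraction: pd.Series | None = None,
    min_cell_fraction: float = MIN_CELL_FRACTION,
    n_components: int = 2,
    distance_components: int | None = None,
) -> PcaResult:
    """PCA of domain summaries and per-condition centroid separation.

    Genes expressed in fewer than ``min_cell_fraction`` of pooled cells
    (when ``cell_fraction`` is given) are dropped; missing values are
    imputed with per-gene means; each gene is standardized to zero mean
    and unit variance (zero-variance genes dropped).  For each condition
    with both domains present, ``centroid_distance`` is the Euclidean
    distance between the mean embeddings of its proximal and its distal
    summaries in the first ``distance_components`` (default: all
    ``n_components``) components.
    """
    core = [s for s in summaries if s.domain != WHOLE]
    if len(core) < 3:
        raise ValueError("need at least 3 proximal/distal summaries for PCA")
    mat = summaries_to_frame(core)

    if cell_fraction is not None:
        keep = cell_fraction.reindex(mat.columns, fill_value=0.0) >= min_cell_fraction
        mat = mat.loc[:, keep.to_numpy()]
    mat = mat.apply(lambda col: col.fillna(col.mean()), axis=0)
    variable = mat.std(axis=0, ddof=0) > 0
    if not variable.all():
        logger.info("dropping %d zero-variance genes", int((~variable).sum()))
        mat = mat.loc[:, variable]
    if mat.shape[1] == 0:
        raise ValueError("no genes left after filtering")

    scaled = StandardScaler().fit_transform(mat.to_numpy())
    n_components = min(n_components, min(scaled.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    emb = pca.fit_transform(scaled)
    embedding = pd.DataFrame(
        emb, index=mat.index, columns=[f"PC{i + 1}" for i in range(n_components)]
    )

    k = n_components if distance_components is None else min(distance_components, n_components)
    distances: dict[str, float] = {}
    for cond, grp in embedding.groupby(level="condition"):
        doms = grp.index.get_level_values("domain")
        prox = grp.loc[doms == "proximal"]
        dist = grp.loc[doms == "distal"]
        if len(prox) and len(dist):
            delta = prox.iloc[:, :k].mean(axis=0) - dist.iloc[:, :k].mean(axis=0)
            distances[cond] = float(np.linalg.norm(delta))
    return PcaResult(
        embedding=embedding,
        explained_variance=pca.explained_variance_,
        centroid_distance=distances,
    )


def domain_marker_table(
    summaries: list[DomainSummary], markers: list[str]
) -> pd.DataFrame:
    """Mean expression of marker genes per (condition, domain) — heatmap-ready.

    Rows are markers, columns (condition, domain) pairs averaged across
    samples.  Markers absent from the panel are omitted with a warning.
    """
    if not markers:
        raise ValueError("marker list is empty")
    mat = summaries_to_frame([s for s in summaries if s.domain != WHOLE])
    present = [m for m in markers if m in mat.columns]
    missing = sorted(set(markers) - set(present))
    if missing:
        logger.warning("markers absent from panel, omitted: %s", missing)
    if not present:
        raise ValueError("no markers present in the panel")
    grouped = mat[present].groupby(level=["condition", "domain"]).mean()
    return grouped.T


def domain_difference_tests(
    summaries: list[DomainSummary], genes: list[str] | None = None
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum of proximal vs distal per gene.

    Operates on per-sample domain means; p-values are Benjamini-Hochberg
    adjusted.  Returns a frame with statistic, pvalue and qvalue per gene.
    """
    mat = summaries_to_frame([s for s in summaries if s.domain != WHOLE])
    doms = mat.index.get_level_values("domain")
    prox, dist = mat.loc[doms == "proximal"], mat.loc[doms == "distal"]
    if prox.empty or dist.empty:
        raise ValueError("need both proximal and distal summaries")
    cols = genes or list(mat.columns)
    stat, pval = stats.ranksums(
        prox[cols].to_numpy(), dist[cols].to_numpy(), axis=0
    )
    qval = stats.false_discovery_control(pval)
    return pd.DataFrame({"statistic": stat, "pvalue": pval, "qvalue": qval}, index=cols)
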