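"""Stratification of a focal cell type into spatially defined groups.

Two strategies: inherit the region label of the hosting spot
(``split_by_region``), or derive spatially weighted gene co-expression
modules and label each cell by its top module activity score (the
"scoexp" route: Gaussian-kernel smoothing of expression over cell
coordinates, Pearson correlation of the smoothed gene vectors,
average-linkage clustering into k modules, and bin-matched control-gene
activity scores per cell).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .datatypes import CellAnnotation, CellSpotAssignment, GeneExpressionMatrix, GroupLabels, SpatialSlide

logger = logging.getLogger(__name__)

__all__ = [
    "GroupLabels",
    "split_by_region",
    "median_pairwise_distance",
    "spatially_weighted_correlation",
    "detect_modules",
    "score_modules",
    "assign_by_max_score",
]


def split_by_region(
    a: CellSpotAssignment,
    slide: SpatialSlide,
    annotation: CellAnnotation,
    focal_type: str,
) -> GroupLabels:
    """Each focal cell inherits the region label of its assigned spot.

    Focal cells in unlabeled spots are excluded with a warning.
    """
    if slide.region_labels is None:
        raise ValueError("slide has no region labels")
    focal = annotation.cell_types.index[annotation.cell_types == focal_type]
    focal = [c for c in focal if c in a.mapping.index]
    if not focal:
        raise ValueError(f"no cells of focal type {focal_type!r} in the assignment")
    spots = a.mapping.loc[focal]
    regions = slide.region_labels.reindex(spots.to_numpy(object))
    labels = pd.Series(regions.to_numpy(object), index=focal)
    unlabeled = labels.isna()
    if unlabeled.any():
        warnings.warn(
            f"{int(unlabeled.sum())} focal cell(s) in unlabeled spots excluded",
            stacklevel=2,
        )
        labels = labels[~unlabeled]
    if labels.empty:
        raise ValueError("no focal cells in any labeled region")
    gl = GroupLabels(labels)
    logger.info("split_by_region: group sizes %s", gl.sizes().to_dict())
    return gl


def median_pairwise_distance(coords: np.ndarray) -> float:
    """Default kernel bandwidth: median pairwise Euclidean distance."""
    return float(np.median(pdist(np.asarray(coords, dtype=float))))


def spatially_weighted_correlation(
    expr_norm: np.ndarray,
    coords: np.ndarray,
    sigma: float,
):
    """Gene-gene Pearson correlation of spatially smoothed expression.

    The kernel K_ij = exp(-d_ij^2 / (2 sigma^2)) is row-normalized and
    applied to each gene's per-cell vector before correlating, so the
    sigma -> 0 limit is the plain per-cell Pearson correlation.  Genes
    constant after smoothing have their correlations set to 0 and are
    flagged.

    Parameters
    ----------
    expr_norm : (n_genes, n_cells) normalized expression
    coords : (n_cells, 2) cell coordinates in slide units
    sigma : kernel bandwidth, slide units (> 0)

    Returns
    -------
    corr : (n_genes, n_genes) matrix; flags : boolean array of constant genes
    """
    expr_norm = np.asarray(expr_norm, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n_genes, n_cells = expr_norm.shape
    if n_cells < 10:
        raise ValueError(f"need >= 10 focal cells, got {n_cells}")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    d2 = squareform(pdist(coords)) ** 2
    with np.errstate(under="ignore"):
        k = np.exp(-d2 / (2.0 * sigma * sigma))
    k /= k.sum(axis=1, keepdims=True)
    smoothed = expr_norm @ k.T  # genes x cells
    sd = smoothed.std(axis=1)
    const = sd <= 1e-12 * (1.0 + np.abs(smoothed).max(axis=1))
    if const.any():
        logger.info("spatially_weighted_correlation: %d constant gene(s) flagged", int(const.sum()))
    centered = smoothed - smoothed.mean(axis=1, keepdims=True)
    denom = np.where(const, 1.0, sd) * np.sqrt(n_cells)
    z = centered / denom[:, None]
    corr = z @ z.T
    corr[const, :] = 0.0
    corr[:, const] = 0.0
    np.fill_diagonal(corr, np.where(const, 0.0, 1.0))
    return np.clip(corr, -1.0, 1.0), const


def detect_modules(
    corr: np.ndarray,
    gene_ids,
    k: int,
    min_size: int = 10,
) -> dict:
    """Cut an average-linkage dendrogram on distance 1 - correlation into
    ``k`` clusters; clusters below ``min_size`` genes are dropped.
    Module names M1..Mk are ordered by size (largest first), then by
    first gene id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    gene_ids = np.asarray(gene_ids, dtype=object)
    if k == 1:
        if len(gene_ids) < min_size:
            raise ValueError("all clusters below min_size")
        return {"M1": list(gene_ids)}
    dist = 1.0 - np.asarray(corr, dtype=float)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform((dist + dist.T) / 2.0, checks=False)
    tree = linkage(condensed, method="average")
    flat = fcluster(tree, t=k, criterion="maxclust")
    clusters = []
    for c in np.unique(flat):
        members = gene_ids[flat == c]
        if len(members) >= min_size:
            clusters.append(sorted(members, key=str))
    if not clusters:
        raise ValueError("all clusters below min_size")
    clusters.sort(key=lambda m: (-len(m), str(m[0])))
    return {f"M{i + 1}": list(m) for i, m in enumerate(clusters)}


def score_modules(
    expr: GeneExpressionMatrix,
    modules: dict,
    n_bins: int = 24,
    n_controls: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell module activity scores against bin-matched controls.

    score(cell, module) = mean normalized expression of the module genes
    minus the mean over a control set; for each module gene,
    ``n_controls`` control genes are drawn (seeded, without replacement
    within the draw) from the same average-expression bin among
    ``n_bins`` equal-count bins of all genes, excluding the module's own
    genes.
    """
    if expr.norm is None:
        raise ValueError("normalized layer required")
    rng = np.random.default_rng(seed)
    x = expr.norm
    avg = x.mean(axis=1)
    order = np.argsort(avg, kind="stable")
    bins = np.empty(expr.n_genes, dtype=int)
    bins[order] = np.minimum((np.arange(expr.n_genes) * n_bins) // expr.n_genes, n_bins - 1)
    gidx = expr.gene_index()

    scores = {}
    for name in sorted(modules):
        genes = [g for g in modules[name] if g in gidx]
        if not genes:
            raise ValueError(f"module {name} empty after intersection with matrix genes")
        rows = np.array([gidx[g] for g in genes])
        module_set = set(rows.tolist())
        ctrl_rows = []
        for r in rows:
            pool = np.flatnonzero(bins == bins[r])
            pool = pool[[p not in module_set for p in pool]]
            if len(pool) == 0:
                continue
            take = min(n_controls, len(pool))
            ctrl_rows.append(rng.choice(pool, size=take, replace=False))
        if ctrl_rows:
            ctrl = np.concatenate(ctrl_rows)
            ctrl_mean = x[ctrl, :].mean(axis=0)
        else:
            ctrl_mean = np.zeros(expr.n_cells)
        scores[name] = x[rows, :].mean(axis=0) - ctrl_mean
    out = pd.DataFrame(scores, index=expr.cell_ids)
    if not np.all(np.isfinite(out.to_numpy())):
        raise ValueError("non-finite module scores")
    return out


def assign_by_max_score(scores: pd.DataFrame) -> GroupLabels:
    """Label each cell by its highest-scoring module; ties break to the
    lexicographically first module name."""
    if scores.shape[1] < 2:
        raise ValueError("need >= 2 modules to assign groups")
    if scores.empty:
        raise ValueError("empty score matrix")
    ordered = scores[sorted(scores.columns)]
    labels = ordered.idxmax(axis=1)  # first occurrence wins ties
    gl = GroupLabels(pd.Series(labels.to_numpy(object), index=scores.index))
    logger.info("assign_by_max_score: group sizes %s", gl.sizes().to_dict())
    return gl
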