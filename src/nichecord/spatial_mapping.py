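"""Assignment of single cells to spatial spots.

Two routes are provided.  ``map_cells_to_spots`` is an explicit,
simplified capacity-constrained assignment: the cost of placing a cell
in a spot is 1 - Pearson correlation of their log-normalized profiles
over a shared gene subset, and the exact minimum-cost assignment is
solved on the capacity-expanded bipartite problem (each spot duplicated
once per unit of capacity).  ``snap_to_nearest_spot`` converts
coordinate-valued mappings to spots by Euclidean distance.  Externally
produced assignment tables can be ingested at any stage through
:func:`nichecord.io_core.read_assignment`.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .datatypes import CellSpotAssignment, GeneExpressionMatrix, SpatialSlide

logger = logging.getLogger(__name__)

__all__ = [
    "CellSpotAssignment",
    "estimate_spot_capacities",
    "map_cells_to_spots",
    "snap_to_nearest_spot",
]


def estimate_spot_capacities(slide: SpatialSlide, n_cells_total: int) -> pd.Series:
    """Per-spot cell capacities proportional to spot total counts.

    capacity_i = max(1, round(n_cells_total * total_i / sum totals)); any
    rounding deficit is distributed one cell at a time to the
    largest-total spots, so the capacities always sum to at least
    ``n_cells_total``.
    """
    if n_cells_total < 1:
        raise ValueError("n_cells_total must be >= 1")
    if slide.spot_expr is None:
        raise ValueError("slide has no spot expression to derive capacities from")
    totals = slide.spot_expr.counts.sum(axis=0).astype(float)
    share = n_cells_total * totals / totals.sum()
    caps = np.maximum(1, np.floor(share + 0.5).astype(int))
    deficit = n_cells_total - caps.sum()
    if deficit > 0:
        order = sorted(range(len(totals)), key=lambda i: (-totals[i], str(slide.spot_expr.cell_ids[i])))
        for k in range(deficit):
            caps[order[k % len(order)]] += 1
    return pd.Series(caps, index=slide.spot_expr.cell_ids)


def _column_standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd_safe, sd == 0


def _profile_correlation(cells: np.ndarray, spots: np.ndarray, method: str) -> np.ndarray:
    """(n_cells, n_spots) Pearson (or Spearman) correlation over genes."""
    if method == "spearman":
        cells = np.apply_along_axis(rankdata, 0, cells)
        spots = np.apply_along_axis(rankdata, 0, spots)
    cz, c_const = _column_standardize(cells)
    sz, s_const = _column_standardize(spots)
    corr = cz.T @ sz / cells.shape[0]
    corr[c_const, :] = 0.0
    corr[:, s_const] = 0.0
    return corr


def map_cells_to_spots(
    cells_norm: GeneExpressionMatrix,
    spots_norm: GeneExpressionMatrix,
    capacities: pd.Series,
    gene_subset,
    method: str = "pearson",
    greedy: bool = False,
) -> CellSpotAssignment:
    """Capacity-constrained expression-matching assignment.

    Exact minimum-total-cost assignment by default (capacity expansion +
    Hungarian algorithm); ``greedy=True`` switches to a fast heuristic
    for large instances, with a logged optimality disclaimer.  Cells and
    spots are processed in lexicographic id order so ties resolve
    deterministically.
    """
    shared = [g for g in gene_subset
              if g in set(cells_norm.gene_ids) and g in set(spots_norm.gene_ids)]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes in gene_subset; need >= 3")
    if cells_norm.norm is None or spots_norm.norm is None:
        raise ValueError("normalized layers required on both matrices")

    cell_order = np.argsort(cells_norm.cell_ids.astype(str), kind="stable")
    spot_order = np.argsort(spots_norm.cell_ids.astype(str), kind="stable")
    cell_ids = cells_norm.cell_ids[cell_order]
    spot_ids = spots_norm.cell_ids[spot_order]

    gi_c = cells_norm.gene_index()
    gi_s = spots_norm.gene_index()
    xc = cells_norm.norm[[gi_c[g] for g in shared], :][:, cell_order]
    xs = spots_norm.norm[[gi_s[g] for g in shared], :][:, spot_order]

    caps = capacities.reindex(spot_ids)
    if caps.isna().any():
        raise ValueError("capacities missing for some spots")
    caps = caps.astype(int).to_numpy()
    n_cells = len(cell_ids)
    if caps.sum() < n_cells:
        raise ValueError(f"total capacity {caps.sum()} < {n_cells} cells")

    cost = 1.0 - _profile_correlation(xc, xs, method)

    if greedy:
        logger.warning("greedy assignment: total cost is not guaranteed optimal")
        remaining = caps.copy()
        chosen = np.empty(n_cells, dtype=int)
        for i in range(n_cells):
            open_spots = np.flatnonzero(remaining > 0)
            j = open_spots[np.argmin(cost[i, open_spots])]
            chosen[i] = j
            remaining[j] -= 1
    else:
        slot_spot = np.repeat(np.arange(len(spot_ids)), caps)
        _, col = linear_sum_assignment(cost[:, slot_spot])
        chosen = slot_spot[col]

    mapping = pd.Series(spot_ids[chosen], index=cell_ids)
    return CellSpotAssignment(mapping, capacities=pd.Series(caps, index=spot_ids))


def snap_to_nearest_spot(cell_coords: pd.DataFrame, slide: SpatialSlide) -> CellSpotAssignment:
    """Assign each cell to its nearest spot by Euclidean distance;
    exact ties break to the lexicographically smaller spot id."""
    if slide.n_spots == 0:
        raise ValueError("empty slide")
    if not {"cell_id", "x", "y"}.issubset(cell_coords.columns):
        raise ValueError("cell_coords must have columns cell_id, x, y")
    order = np.argsort(slide.spot_ids.astype(str), kind="stable")
    spot_ids = slide.spot_ids[order]
    d = cdist(cell_coords[["x", "y"]].to_numpy(float), slide.coords[order])
    nearest = d.argmin(axis=1)  # first occurrence wins -> lexicographic tie-break
    return CellSpotAssignment(
        pd.Series(spot_ids[nearest], index=cell_coords["cell_id"].to_numpy(object))
    )
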