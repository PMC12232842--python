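"""Colocalization and concordance with predicted communication.

The binary spot-presence matrix scores a spot 1 for a cell type if at
least one cell of that type is assigned there; Jaccard similarities
between the type columns quantify colocalization.  The headline
statistic correlates, per focal spatial group, the partner-type vector
of significant ligand-receptor counts with the partner-type vector of
Jaccard values (Spearman).  A subsampling control equalizes group sizes
before communication inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import CellAnnotation, CellSpotAssignment, SpatialSlide

logger = logging.getLogger(__name__)

__all__ = [
    "ConcordanceReport",
    "build_presence_matrix",
    "jaccard_matrix",
    "spot_sharing_fraction",
    "spearman",
    "concordance",
    "subsample_equalize",
    "run_pipeline",
]


def build_presence_matrix(
    a: CellSpotAssignment,
    labels: pd.Series,
    slide: SpatialSlide | None = None,
) -> pd.DataFrame:
    """Spots x types binary matrix over ALL slide spots (empty spots are
    zero rows).  ``labels`` maps each assigned cell to the column it
    contributes to - cell types, with focal spatial groups already
    substituted for their parent type where applicable."""
    missing = set(labels.index) - set(a.mapping.index)
    if missing:
        raise ValueError(f"labeled cells missing from assignment: {sorted(missing)[:5]}")
    spot_ids = (np.asarray(slide.spot_ids, dtype=object) if slide is not None
                else np.asarray(sorted(set(a.mapping)), dtype=object))
    types = sorted(pd.unique(labels))
    mat = pd.DataFrame(0, index=spot_ids, columns=types, dtype=int)
    spots = a.mapping.loc[labels.index]
    for t in types:
        occupied = pd.unique(spots[labels == t])
        mat.loc[[s for s in occupied if s in mat.index], t] = 1
    return mat


def jaccard_matrix(p: pd.DataFrame):
    """Pairwise Jaccard similarity of the type presence columns.

    J(A, B) = |spots(A) & spots(B)| / |spots(A) | spots(B)|, defined 0
    (and flagged) when both presence sets are empty.
    """
    if p.shape[1] < 2:
        raise ValueError("need >= 2 type columns")
    x = p.to_numpy(dtype=float)
    inter = x.T @ x
    sizes = x.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    both_empty = union == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(both_empty, 0.0, inter / np.where(both_empty, 1.0, union))
    flags = pd.DataFrame(both_empty, index=p.columns, columns=p.columns)
    if both_empty.any():
        logger.info("jaccard_matrix: %d empty-vs-empty pair(s) set to 0", int(both_empty.sum()))
    return pd.DataFrame(jac, index=p.columns, columns=p.columns), flags


def spot_sharing_fraction(p: pd.DataFrame, focal: str) -> float:
    """Fraction of focal-occupied spots also hosting >= 1 other type."""
    if focal not in p.columns:
        raise ValueError(f"unknown focal column {focal!r}")
    focal_spots = p[focal].to_numpy(bool)
    if not focal_spots.any():
        raise ValueError(f"focal column {focal!r} is all-zero")
    others = p.drop(columns=[focal]).to_numpy(bool).any(axis=1)
    return float((focal_spots & others).sum() / focal_spots.sum())


def spearman(x, y):
    """Spearman rank correlation with average-rank tie handling and a
    t-approximation p-value (n - 2 df); returns (nan, nan) for constant
    input, flagged by the caller."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need >= 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class ConcordanceReport:
    """Per focal group: aligned partner vectors of significant-LR counts
    and Jaccard values, with their Spearman correlation."""

    per_group: dict = field(default_factory=dict)  # group -> dict(rho, p, n, table)

    def rho(self, group: str) -> float:
        return self.per_group[group]["rho"]

    def summary_frame(self) -> pd.DataFrame:
        rows = [{"focal_group": g, "rho": d["rho"], "pval": d["p"], "n_partners": d["n"]}
                for g, d in sorted(self.per_group.items())]
        return pd.DataFrame(rows, columns=["focal_group", "rho", "pval", "n_partners"])


def concordance(
    counts: pd.DataFrame,
    coloc: pd.DataFrame,
    focal_groups,
    include_sibling: bool = True,
) -> ConcordanceReport:
    """Spearman correlation of significant-LR counts vs Jaccard
    colocalization over the shared partner list of each focal group.

    The focal group itself is never a partner; the sibling focal groups
    are included by default.  Requires >= 3 shared partners.
    """
    report = ConcordanceReport()
    focal_groups = list(focal_groups)
    for f in focal_groups:
        partners = [g for g in counts.index if g in coloc.index and g != f]
        if not include_sibling:
            partners = [g for g in partners if g not in focal_groups]
        if len(partners) < 3:
            raise ValueError(f"only {len(partners)} shared partners for {f!r}; need >= 3")
        cvec = counts.loc[partners, f].to_numpy(float)
        jvec = coloc.loc[partners, f].to_numpy(float)
        rho, p = spearman(cvec, jvec)
        if np.isnan(rho):
            logger.warning("concordance: constant vector for focal group %s; rho undefined", f)
        report.per_group[f] = {
            "rho": rho,
            "p": p,
            "n": len(partners),
            "table": pd.DataFrame({"partner": partners, "lr_count": cvec, "jaccard": jvec}),
        }
    return report


def subsample_equalize(
    labels: pd.Series,
    n_datasets: int = 10,
    seed: int = 0,
    max_attempts: int = 1000,
) -> list:
    """Equalize group sizes by downsampling every group (without
    replacement) to the smallest group's size, ``n_datasets`` times.

    Datasets are pairwise distinct when combinatorially possible
    (rejection sampling, capped; duplicates are then accepted with a
    warning).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    sizes = labels.value_counts()
    if (sizes == 0).any() or len(sizes) < 2:
        raise ValueError("need >= 2 non-empty groups")
    n_min = int(sizes.min())
    groups = sorted(sizes.index)
    out, seen = [], set()
    attempts = 0
    while len(out) < n_datasets:
        picked = []
        for g in groups:
            members = sorted(labels.index[labels == g])
            picked.extend(rng.choice(members, size=n_min, replace=False))
        key = frozenset(picked)
        attempts += 1
        if key in seen and attempts < max_attempts:
            continue
        if key in seen:
            logger.warning("subsample_equalize: accepting duplicate dataset (tiny groups)")
        seen.add(key)
        out.append(labels.loc[sorted(picked)])
    return out


# run_pipeline orchestrates every stage end to end; it lives in
# nichecord.pipeline and is re-exported here (lazily, to avoid a module
# cycle) as part of this module's public surface.
def __getattr__(name):
    if name == "run_pipeline":
        from .pipeline import run_pipeline

        return run_pipeline
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")
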