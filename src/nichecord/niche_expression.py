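"""Niche-dependent expression statistics.

Global comparisons use pairwise cosine distances between normalized
expression profiles (within / between spatial groups, and against the
background of all other types), with distribution shifts assessed by the
two-sample Kolmogorov-Smirnov test.  Gene-level comparisons use two
complementary differential-expression routes: a tie-corrected Wilcoxon
rank-sum test on normalized values with Benjamini-Hochberg correction,
and a pseudobulk negative-binomial Wald test on summed raw counts from
seeded pseudo-replicates (median-of-ratios size factors, method-of-
moments dispersion; no dispersion or fold-change shrinkage - an
explicitly simplified count-model test, not a re-implementation of the
full reference method).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from scipy.spatial.distance import cdist, pdist
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneExpressionMatrix

logger = logging.getLogger(__name__)

EPS = 1e-9          # pseudo-count making log2FC total
DISP_FLOOR = 1e-8   # NB dispersion floor

__all__ = [
    "DistanceComparison",
    "Pseudobulk",
    "pairwise_cosine_distances",
    "ks_compare",
    "deg_wilcoxon",
    "make_pseudobulk",
    "pseudobulk_deg",
]


# ---------------------------------------------------------------------------
# cosine distances + KS
# ---------------------------------------------------------------------------

@dataclass
class DistanceComparison:
    """Labeled cosine-distance samples with per-set medians and pairwise
    KS comparisons."""

    samples: dict                      # set name -> 1-D array of distances
    medians: dict = field(default_factory=dict)
    ks: dict = field(default_factory=dict)  # (name_a, name_b) -> (D, p)

    def __post_init__(self) -> None:
        self.medians = {k: float(np.median(v)) if len(v) else float("nan")
                        for k, v in self.samples.items()}

    def compare(self, name_a: str, name_b: str):
        d, p = ks_compare(self.samples[name_a], self.samples[name_b])
        self.ks[(name_a, name_b)] = (d, p)
        return d, p

    def to_frame(self) -> pd.DataFrame:
        rows = [{"pair_set": k, "distance": v} for k, vals in sorted(self.samples.items())
                for v in vals]
        return pd.DataFrame(rows, columns=["pair_set", "distance"])


def _nonzero_columns(x: np.ndarray, what: str) -> np.ndarray:
    keep = np.linalg.norm(x, axis=0) > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} zero vector(s) excluded from {what}", stacklevel=3)
    return x[:, keep]


def pairwise_cosine_distances(
    m: GeneExpressionMatrix,
    labels: pd.Series,
    pair_spec: dict,
) -> DistanceComparison:
    """Cosine distances (1 - cosine similarity) between normalized
    profiles.

    ``pair_spec`` maps a sample name to either ``("within", label)`` -
    all unordered same-label pairs - or ``("between", label_a, label_b)``
    - all cross-label pairs.  Zero vectors are excluded with a warning.
    """
    if m.norm is None:
        raise ValueError("normalized layer required")
    cidx = m.cell_index()

    def columns(label):
        cells = labels.index[labels == label]
        return np.array([cidx[c] for c in cells if c in cidx], dtype=int)

    samples = {}
    for name, spec in pair_spec.items():
        kind = spec[0]
        if kind == "within":
            idx = columns(spec[1])
            if len(idx) < 2:
                raise ValueError(f"label {spec[1]!r} has {len(idx)} cells; need >= 2 for within-pairs")
            x = _nonzero_columns(m.norm[:, idx], f"pair set {name!r}")
            samples[name] = pdist(x.T, metric="cosine")
        elif kind == "between":
            ia, ib = columns(spec[1]), columns(spec[2])
            if len(ia) == 0 or len(ib) == 0:
                raise ValueError(f"empty label in between-pair {name!r}")
            xa = _nonzero_columns(m.norm[:, ia], f"pair set {name!r}")
            xb = _nonzero_columns(m.norm[:, ib], f"pair set {name!r}")
            samples[name] = cdist(xa.T, xb.T, metric="cosine").ravel()
        else:
            raise ValueError(f"unknown pair kind {kind!r}")
        samples[name] = np.clip(samples[name], 0.0, None)
    return DistanceComparison(samples)


def ks_compare(sample_a, sample_b):
    """Two-sample KS: D = sup |ECDF_a - ECDF_b| with asymptotic p."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if len(a) < 2 or len(b) < 2:
        warnings.warn("KS on a sample of size < 2: p-value unreliable", stacklevel=2)
    res = scipy.stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# Wilcoxon DEG
# ---------------------------------------------------------------------------

def _log2_fold_change(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """log2 ratio of mean expm1(norm) values with a pseudo-count."""
    m1 = np.expm1(x1).mean(axis=1)
    m2 = np.expm1(x2).mean(axis=1)
    return np.log2((m1 + EPS) / (m2 + EPS))


def deg_wilcoxon(
    m: GeneExpressionMatrix,
    labels: pd.Series,
    group1: str,
    group2: str,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum on normalized values
    (tie-corrected asymptotic p), BH-adjusted; a gene is flagged
    significant when its linear fold change exceeds ``fc_threshold`` in
    either direction and adjusted p < alpha."""
    if m.norm is None:
        raise ValueError("normalized layer required")
    cidx = m.cell_index()
    i1 = np.array([cidx[c] for c in labels.index[labels == group1] if c in cidx], dtype=int)
    i2 = np.array([cidx[c] for c in labels.index[labels == group2] if c in cidx], dtype=int)
    if len(i1) < 3 or len(i2) < 3:
        raise ValueError(f"each group needs >= 3 cells (got {len(i1)}, {len(i2)})")
    x1, x2 = m.norm[:, i1], m.norm[:, i2]
    res = scipy.stats.mannwhitneyu(x1, x2, axis=1, alternative="two-sided",
                                   method="asymptotic")
    pvals = np.asarray(res.pvalue, dtype=float)
    log2fc = _log2_fold_change(x1, x2)
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    sig = (np.abs(log2fc) > np.log2(fc_threshold)) & (padj < alpha)
    return pd.DataFrame({
        "gene": m.gene_ids,
        "log2fc": log2fc,
        "pval": pvals,
        "padj": padj,
        "significant": sig,
        "method": "wilcoxon",
    })


# ---------------------------------------------------------------------------
# pseudobulk NB Wald
# ---------------------------------------------------------------------------

@dataclass
class Pseudobulk:
    """Summed raw counts per (group, replicate) with the seeded
    replicate partition that produced them."""

    counts: np.ndarray         # genes x samples
    gene_ids: np.ndarray
    sample_groups: np.ndarray  # group name per sample column
    replicate_cells: list      # list of cell-id lists, one per sample


def make_pseudobulk(
    m: GeneExpressionMatrix,
    labels: pd.Series,
    group1: str,
    group2: str,
    n_reps: int = 3,
    seed: int = 0,
) -> Pseudobulk:
    """Randomly partition each group's cells into ``n_reps`` near-equal
    subsets (seeded) and sum raw counts per subset."""
    rng = np.random.default_rng(seed)
    cidx = m.cell_index()
    cols, groups, cell_lists = [], [], []
    for g in (group1, group2):
        cells = [c for c in labels.index[labels == g] if c in cidx]
        if len(cells) < n_reps:
            raise ValueError(f"group {g!r} has {len(cells)} cells < n_reps={n_reps}")
        perm = rng.permutation(len(cells))
        for chunk in np.array_split(perm, n_reps):
            chunk_cells = [cells[i] for i in chunk]
            cols.append(m.counts[:, [cidx[c] for c in chunk_cells]].sum(axis=1))
            groups.append(g)
            cell_lists.append(chunk_cells)
    return Pseudobulk(
        counts=np.column_stack(cols),
        gene_ids=m.gene_ids.copy(),
        sample_groups=np.asarray(groups, dtype=object),
        replicate_cells=cell_lists,
    )


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors; falls back to total-count ratios
    when almost every gene has a zero somewhere."""
    all_pos = (counts > 0).all(axis=1)
    if all_pos.mean() < 0.1:
        totals = counts.sum(axis=0).astype(float)
        return totals / scipy.stats.gmean(np.maximum(totals, 1.0))
    logc = np.log(counts[all_pos].astype(float))
    log_geo = logc.mean(axis=1, keepdims=True)
    return np.exp(np.median(logc - log_geo, axis=0))


def pseudobulk_deg(
    pb: Pseudobulk,
    lfc_threshold: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group NB Wald test on pseudobulk counts.

    Size factors by median-of-ratios; per-gene dispersion by method of
    moments on size-factor-normalized counts (floored at 1e-8); Wald z =
    log fold change / SE from a log-link NB fit with offset log size
    factors; BH over all genes.  Flag: |log2FC| > ``lfc_threshold``
    (log2 scale) and adjusted p < alpha.
    """
    groups = pd.unique(pb.sample_groups)
    if len(groups) != 2:
        raise ValueError("pseudobulk must contain exactly 2 groups")
    g1, g2 = groups
    n1 = int((pb.sample_groups == g1).sum())
    n2 = int((pb.sample_groups == g2).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 replicates per group")
    for g in groups:
        if pb.counts[:, pb.sample_groups == g].sum() == 0:
            raise ValueError(f"degenerate design: group {g!r} has all-zero totals")

    sf = _size_factors(pb.counts)
    normed = pb.counts / sf
    # coefficient is log(mean g1 / mean g2), matching the Wilcoxon branch
    is_g1 = (pb.sample_groups == g1).astype(float)
    design = sm.add_constant(is_g1)
    offset = np.log(sf)

    # method-of-moments dispersion on normalized counts, pooled within groups
    disp = np.empty(pb.counts.shape[0])
    grand = np.empty(pb.counts.shape[0])
    for i in range(pb.counts.shape[0]):
        y = normed[i]
        mvals, vvals = [], []
        for g in groups:
            sel = pb.sample_groups == g
            mvals.append(y[sel].mean())
            vvals.append(y[sel].var(ddof=1))
        m_bar = float(np.mean(mvals))
        v_bar = float(np.mean(vvals))
        grand[i] = m_bar
        disp[i] = max((v_bar - m_bar) / m_bar**2, DISP_FLOOR) if m_bar > 0 else DISP_FLOOR

    n_genes = pb.counts.shape[0]
    beta = np.zeros(n_genes)
    pvals = np.ones(n_genes)
    mean1 = pb.counts[:, pb.sample_groups == g1].sum(axis=1) / sf[pb.sample_groups == g1].sum()
    mean2 = pb.counts[:, pb.sample_groups == g2].sum(axis=1) / sf[pb.sample_groups == g2].sum()
    for i in range(n_genes):
        y = pb.counts[i].astype(float)
        if mean1[i] == 0 and mean2[i] == 0:
            continue  # LFC 0, p 1
        if mean1[i] == 0 or mean2[i] == 0:
            beta[i] = np.log((mean1[i] + EPS) / (mean2[i] + EPS))
            continue  # infinite-MLE direction: effect reported, p left at 1
        try:
            fit = sm.GLM(
                y, design, family=sm.families.NegativeBinomial(alpha=disp[i]),
                offset=offset,
            ).fit(maxiter=100, tol=1e-8)
            if np.isfinite(fit.bse[1]) and fit.bse[1] > 0:
                beta[i] = fit.params[1]
                z = fit.params[1] / fit.bse[1]
                pvals[i] = 2.0 * scipy.stats.norm.sf(abs(z))
            else:
                beta[i] = np.log((mean1[i] + EPS) / (mean2[i] + EPS))
        except Exception:  # pragma: no cover - rare IRLS failures
            beta[i] = np.log((mean1[i] + EPS) / (mean2[i] + EPS))

    log2fc = beta / np.log(2.0)
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    sig = (np.abs(log2fc) > lfc_threshold) & (padj < alpha)
    return pd.DataFrame({
        "gene": pb.gene_ids,
        "log2fc": log2fc,
        "pval": pvals,
        "padj": padj,
        "significant": sig,
        "method": "pseudobulk",
    })
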