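"""Readers, writers and preprocessing for all pipeline inputs.

Formats are deliberately plain: Matrix Market triplets (1-based on disk)
with one-id-per-line gene/barcode files or a dense TSV fallback for
counts; TSV tables for coordinates, annotations and assignments; a CSV
ligand-receptor table with "_"-joined complex subunits.  All ids are
opaque case-sensitive strings.  Every writer round-trips exactly through
its reader.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import (
    CellAnnotation,
    CellSpotAssignment,
    GeneExpressionMatrix,
    LRDatabase,
    LRInteraction,
    SpatialSlide,
)
from .config import PipelineConfig  # noqa: F401  (module surface)

logger = logging.getLogger(__name__)

COMPONENT_SEP = "_"

__all__ = [
    "read_counts",
    "write_counts",
    "normalize_log",
    "qc_filter_spots",
    "select_hvg",
    "map_orthologs",
    "read_lr_database",
    "write_lr_database",
    "read_assignment",
    "write_assignment",
    "read_annotation",
    "write_annotation",
    "read_slide",
    "write_slide",
    "PipelineConfig",
]


# ---------------------------------------------------------------------------
# counts I/O
# ---------------------------------------------------------------------------

def _read_labels(path) -> np.ndarray:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return np.asarray([ln for ln in lines if ln], dtype=object)


def read_counts(matrix_path, gene_label_path, cell_label_path) -> GeneExpressionMatrix:
    """Read a gene x cell count matrix.

    ``matrix_path`` is Matrix Market coordinate format (``.mtx``) or a
    dense TSV (genes in rows, cells in columns, no header/index).  Label
    files carry one id per line, in matrix order.
    """
    matrix_path = Path(matrix_path)
    genes = _read_labels(gene_label_path)
    cells = _read_labels(cell_label_path)
    if matrix_path.suffix == ".mtx":
        mat = scipy.io.mmread(matrix_path)
        counts = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    else:
        counts = pd.read_csv(matrix_path, sep="\t", header=None).to_numpy()
    if counts.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {counts.shape} does not match label files "
            f"({len(genes)} genes, {len(cells)} cells)"
        )
    return GeneExpressionMatrix(gene_ids=genes, cell_ids=cells, counts=counts)


def write_counts(m: GeneExpressionMatrix, matrix_path, gene_label_path, cell_label_path) -> None:
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        scipy.io.mmwrite(matrix_path, scipy.sparse.coo_matrix(m.counts), field="integer")
    else:
        pd.DataFrame(m.counts).to_csv(matrix_path, sep="\t", header=False, index=False)
    Path(gene_label_path).write_text("".join(f"{g}\n" for g in m.gene_ids))
    Path(cell_label_path).write_text("".join(f"{c}\n" for c in m.cell_ids))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def normalize_log(m: GeneExpressionMatrix, target_sum: float = 1e4,
                  base: str = "e") -> GeneExpressionMatrix:
    """Library-size normalize to ``target_sum`` per cell, then log1p.

    Cells with zero total counts are left as all-zero columns and
    reported with a warning rather than dropped, so downstream set sizes
    stay predictable.
    """
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    if base not in ("e", "2"):
        raise ValueError("base must be 'e' or '2'")
    totals = m.counts.sum(axis=0).astype(float)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} cell(s) with zero total counts left as zeros",
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, totals)
    scaled = m.counts * (target_sum / safe)
    norm = np.log1p(scaled)
    if base == "2":
        norm = norm / np.log(2.0)
    norm[:, zero] = 0.0
    return GeneExpressionMatrix(m.gene_ids.copy(), m.cell_ids.copy(), m.counts.copy(), norm)


def qc_filter_spots(
    m: GeneExpressionMatrix,
    min_counts: float = 5000,
    max_counts: float = 35000,
    max_mito_pct: float = 20.0,
    min_spots_per_gene: int = 10,
    mito_prefix: str = "MT-",
) -> GeneExpressionMatrix:
    """Spot-level QC: keep spots with min_counts < total < max_counts and
    mitochondrial fraction <= max_mito_pct, then drop genes detected in
    fewer than ``min_spots_per_gene`` of the remaining spots."""
    totals = m.counts.sum(axis=0).astype(float)
    mito = np.array([str(g).startswith(mito_prefix) for g in m.gene_ids])
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(totals > 0, 100.0 * m.counts[mito, :].sum(axis=0) / np.maximum(totals, 1.0), 0.0)
    keep_lo = totals > min_counts
    keep_hi = totals < max_counts
    keep_mt = mito_pct <= max_mito_pct
    keep = keep_lo & keep_hi & keep_mt
    if not keep.any():
        binding = "min_counts" if not keep_lo.any() else (
            "max_counts" if not keep_hi.any() else "max_mito_pct")
        raise ValueError(f"all spots removed by QC; binding threshold: {binding}")
    counts = m.counts[:, keep]
    detected = (counts > 0).sum(axis=1)
    keep_genes = detected >= min_spots_per_gene
    logger.info(
        "qc_filter_spots: kept %d/%d spots, %d/%d genes",
        int(keep.sum()), m.n_cells, int(keep_genes.sum()), m.n_genes,
    )
    return GeneExpressionMatrix(
        gene_ids=m.gene_ids[keep_genes],
        cell_ids=m.cell_ids[keep],
        counts=counts[keep_genes, :],
    )


def select_hvg(m: GeneExpressionMatrix, n: int, n_bins: int = 20) -> list:
    """Top-``n`` genes by normalized dispersion of expm1(norm).

    Dispersion (variance / mean) is z-standardized within equal-count
    bins of mean expression; ties at the cutoff break lexicographically
    by gene id.  Returns all genes when ``n`` >= gene count.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if m.norm is None:
        raise ValueError("norm layer required; call normalize_log first")
    if n >= m.n_genes:
        return list(m.gene_ids)
    x = np.expm1(m.norm)
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1) if m.n_cells > 1 else np.zeros(m.n_genes)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    # equal-count bins of mean expression; keep >= 20 genes per bin so the
    # within-bin spread is estimable
    n_bins = max(1, min(n_bins, m.n_genes // 20))
    order = np.argsort(mean, kind="stable")
    bins = np.empty(m.n_genes, dtype=int)
    bins[order] = np.minimum((np.arange(m.n_genes) * n_bins) // m.n_genes, n_bins - 1)
    z = np.zeros(m.n_genes)
    for b in np.unique(bins):
        sel = bins == b
        center = np.median(disp[sel])
        scale = 1.4826 * np.median(np.abs(disp[sel] - center))  # robust: the
        # high-dispersion outliers being selected must not inflate their
        # own bin's spread
        if scale == 0:
            scale = disp[sel].std(ddof=1) if sel.sum() > 1 else 0.0
        z[sel] = (disp[sel] - center) / scale if scale > 0 else 0.0
    rank = sorted(range(m.n_genes), key=lambda i: (-z[i], str(m.gene_ids[i])))
    return [m.gene_ids[i] for i in rank[:n]]


def map_orthologs(m: GeneExpressionMatrix, table: pd.DataFrame) -> GeneExpressionMatrix:
    """Rename genes via a two-column (source_id, target_id) table.

    Genes absent from the table are dropped (count logged); many-to-one
    targets are collapsed by summing counts; for a source listed with
    several targets only the first target in table order is kept.
    """
    if table is None or len(table) == 0:
        raise ValueError("empty ortholog table")
    tab = table.iloc[:, :2].copy()
    tab.columns = ["source", "target"]
    n_multi = int(tab.duplicated(subset="source").sum())
    if n_multi:
        logger.info("map_orthologs: %d one-to-many source rows ignored (first target kept)", n_multi)
    tab = tab.drop_duplicates(subset="source", keep="first")
    lut = dict(zip(tab["source"], tab["target"]))
    targets, rows = [], {}
    dropped = 0
    for i, g in enumerate(m.gene_ids):
        t = lut.get(g)
        if t is None:
            dropped += 1
            continue
        if t not in rows:
            rows[t] = []
            targets.append(t)
        rows[t].append(i)
    logger.info("map_orthologs: dropped %d unmapped genes", dropped)
    if not targets:
        raise ValueError("no genes left after ortholog mapping")
    counts = np.vstack([m.counts[rows[t], :].sum(axis=0) for t in targets])
    return GeneExpressionMatrix(np.asarray(targets, dtype=object), m.cell_ids.copy(), counts)


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def read_lr_database(path) -> LRDatabase:
    df = pd.read_csv(path, dtype=str)
    required = {"interaction_id", "ligand", "receptor"}
    if not required.issubset(df.columns):
        raise ValueError(f"LR database must have columns {sorted(required)}")
    records = [
        LRInteraction(
            interaction_id=row.interaction_id,
            ligand_components=tuple(row.ligand.split(COMPONENT_SEP)),
            receptor_components=tuple(row.receptor.split(COMPONENT_SEP)),
        )
        for row in df.itertuples()
    ]
    return LRDatabase(records)


def write_lr_database(db: LRDatabase, path) -> None:
    pd.DataFrame(
        {
            "interaction_id": [r.interaction_id for r in db],
            "ligand": [COMPONENT_SEP.join(r.ligand_components) for r in db],
            "receptor": [COMPONENT_SEP.join(r.receptor_components) for r in db],
        }
    ).to_csv(path, index=False)


def read_assignment(path, slide: SpatialSlide | None = None) -> CellSpotAssignment:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"cell_id", "spot_id"}.issubset(df.columns):
        raise ValueError("assignment table must have columns cell_id, spot_id")
    if df["cell_id"].duplicated().any():
        raise ValueError("duplicate cell ids in assignment table")
    if slide is not None:
        unknown = set(df["spot_id"]) - set(slide.spot_ids)
        if unknown:
            raise ValueError(f"assignment references unknown spots: {sorted(unknown)[:5]}")
    return CellSpotAssignment(pd.Series(df["spot_id"].to_numpy(object),
                                        index=df["cell_id"].to_numpy(object)))


def write_assignment(a: CellSpotAssignment, path) -> None:
    pd.DataFrame({"cell_id": a.mapping.index, "spot_id": a.mapping.to_numpy(object)}).to_csv(
        path, sep="\t", index=False
    )


def read_annotation(path) -> CellAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"cell_id", "cell_type"}.issubset(df.columns):
        raise ValueError("annotation table must have columns cell_id, cell_type")
    if df["cell_id"].duplicated().any():
        raise ValueError("duplicate cell ids in annotation table")
    idx = df["cell_id"].to_numpy(object)
    groups = None
    if "group" in df.columns:
        has = df["group"].notna()
        groups = pd.Series(df.loc[has, "group"].to_numpy(object), index=idx[has.to_numpy()])
    return CellAnnotation(pd.Series(df["cell_type"].to_numpy(object), index=idx), groups)


def write_annotation(ann: CellAnnotation, path) -> None:
    df = pd.DataFrame({"cell_id": ann.cell_types.index, "cell_type": ann.cell_types.to_numpy(object)})
    if ann.groups is not None:
        df["group"] = ann.groups.reindex(ann.cell_types.index).to_numpy(object)
    df.to_csv(path, sep="\t", index=False)


def read_slide(path) -> SpatialSlide:
    """Spot coordinate table: spot_id <TAB> x <TAB> y [<TAB> region]."""
    df = pd.read_csv(path, sep="\t", dtype={"spot_id": str, "region": str})
    if not {"spot_id", "x", "y"}.issubset(df.columns):
        raise ValueError("slide table must have columns spot_id, x, y")
    if df["spot_id"].duplicated().any():
        raise ValueError("duplicate spot ids in slide table")
    region = None
    if "region" in df.columns:
        has = df["region"].notna()
        region = pd.Series(df.loc[has, "region"].to_numpy(object),
                           index=df.loc[has, "spot_id"].to_numpy(object))
    return SpatialSlide(
        spot_ids=df["spot_id"].to_numpy(object),
        coords=df[["x", "y"]].to_numpy(float),
        region_labels=region,
    )


def write_slide(slide: SpatialSlide, path) -> None:
    df = pd.DataFrame({
        "spot_id": slide.spot_ids,
        "x": slide.coords[:, 0],
        "y": slide.coords[:, 1],
    })
    if slide.region_labels is not None:
        df["region"] = slide.region_labels.reindex(slide.spot_ids).to_numpy(object)
    df.to_csv(path, sep="\t", index=False)
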