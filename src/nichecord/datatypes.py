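"""Shared domain containers for the pipeline.

Every stage of the pipeline exchanges a small set of typed containers:
a gene-by-cell (or gene-by-spot) count matrix with an optional normalized
layer, a slide of spot coordinates, cell annotations, a ligand-receptor
database, and a cell-to-spot assignment.  They are plain dataclasses over
numpy / pandas objects; validation happens at construction so that
downstream code can rely on the invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneExpressionMatrix",
    "SpatialSlide",
    "CellAnnotation",
    "LRInteraction",
    "LRDatabase",
    "CellSpotAssignment",
    "GroupLabels",
]


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(pd.unique(ids)):
        dupes = pd.Series(ids).value_counts()
        dupes = dupes[dupes > 1].index.tolist()[:5]
        raise ValueError(f"duplicate {what}: {dupes}")


@dataclass
class GeneExpressionMatrix:
    """Gene x cell raw counts plus an optional log-normalized layer.

    ``counts`` is dense int64 (genes in rows, cells in columns); ``norm``
    when present has identical shape and holds log-scale normalized values.
    """

    gene_ids: np.ndarray
    cell_ids: np.ndarray
    counts: np.ndarray
    norm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.cell_ids, "cell ids")
        if self.counts.size:
            if np.any(self.counts < 0):
                raise ValueError("counts contain negative entries")
            if not np.issubdtype(self.counts.dtype, np.integer):
                if not np.allclose(self.counts, np.round(self.counts)):
                    raise ValueError("counts contain non-integral entries")
                self.counts = np.round(self.counts).astype(np.int64)
            else:
                self.counts = self.counts.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if self.norm is not None:
            self.norm = np.asarray(self.norm, dtype=float)
            if self.norm.shape != self.counts.shape:
                raise ValueError("norm layer shape does not match counts")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def cell_index(self) -> dict:
        return {c: i for i, c in enumerate(self.cell_ids)}

    def subset_genes(self, genes) -> "GeneExpressionMatrix":
        idx = [self.gene_index()[g] for g in genes]
        return GeneExpressionMatrix(
            gene_ids=self.gene_ids[idx],
            cell_ids=self.cell_ids.copy(),
            counts=self.counts[idx, :],
            norm=None if self.norm is None else self.norm[idx, :],
        )

    def subset_cells(self, cells) -> "GeneExpressionMatrix":
        cidx = self.cell_index()
        idx = [cidx[c] for c in cells]
        return GeneExpressionMatrix(
            gene_ids=self.gene_ids.copy(),
            cell_ids=self.cell_ids[idx],
            counts=self.counts[:, idx],
            norm=None if self.norm is None else self.norm[:, idx],
        )

    def equals(self, other: "GeneExpressionMatrix") -> bool:
        same = (
            np.array_equal(self.gene_ids, other.gene_ids)
            and np.array_equal(self.cell_ids, other.cell_ids)
            and np.array_equal(self.counts, other.counts)
        )
        if not same:
            return False
        if (self.norm is None) != (other.norm is None):
            return False
        if self.norm is not None:
            return np.allclose(self.norm, other.norm)
        return True


@dataclass
class SpatialSlide:
    """Spot layout of one slide: ids, coordinates, optional expression
    and optional per-spot region labels (e.g. histological annotation)."""

    spot_ids: np.ndarray
    coords: np.ndarray  # (n_spots, 2) x/y in slide units
    spot_expr: GeneExpressionMatrix | None = None
    region_labels: pd.Series | None = None  # spot_id -> region name

    def __post_init__(self) -> None:
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.spot_ids), 2):
            raise ValueError("coords must be (n_spots, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("spot coordinates must be finite")
        _check_unique(self.spot_ids, "spot ids")
        if self.region_labels is not None:
            self.region_labels = pd.Series(self.region_labels)
            unknown = set(self.region_labels.index) - set(self.spot_ids)
            if unknown:
                raise ValueError(f"region labels for unknown spots: {sorted(unknown)[:5]}")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    def spot_index(self) -> dict:
        return {s: i for i, s in enumerate(self.spot_ids)}


@dataclass
class CellAnnotation:
    """cell_id -> cell_type, with an optional cell_id -> group mapping
    (spatial group labels layered on top of the cell types)."""

    cell_types: pd.Series
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        self.cell_types = pd.Series(self.cell_types)
        _check_unique(self.cell_types.index.to_numpy(object), "annotated cell ids")
        if self.groups is not None:
            self.groups = pd.Series(self.groups)
            unknown = set(self.groups.index) - set(self.cell_types.index)
            if unknown:
                raise ValueError(f"group labels for unannotated cells: {sorted(unknown)[:5]}")

    def validate_against(self, m: GeneExpressionMatrix) -> None:
        missing = set(self.cell_types.index) - set(m.cell_ids)
        if missing:
            raise ValueError(
                f"{len(missing)} annotated cells absent from expression matrix, "
                f"e.g. {sorted(missing)[:5]}"
            )


@dataclass(frozen=True)
class LRInteraction:
    interaction_id: str
    ligand_components: tuple
    receptor_components: tuple

    def __post_init__(self) -> None:
        if not self.ligand_components or not self.receptor_components:
            raise ValueError(f"{self.interaction_id}: empty component list")


@dataclass
class LRDatabase:
    """Curated ligand-receptor interactions; multi-subunit complexes are
    tuples of gene ids."""

    records: list

    def __post_init__(self) -> None:
        ids = [r.interaction_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate interaction ids in LR database")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class CellSpotAssignment:
    """cell_id -> spot_id mapping, optionally with the capacities used."""

    mapping: pd.Series
    capacities: pd.Series | None = None

    def __post_init__(self) -> None:
        self.mapping = pd.Series(self.mapping)
        _check_unique(self.mapping.index.to_numpy(object), "assigned cell ids")
        if self.capacities is not None:
            self.capacities = pd.Series(self.capacities)
            used = self.mapping.value_counts()
            over = used[used > self.capacities.reindex(used.index).fillna(0)]
            if len(over):
                raise ValueError(f"capacity exceeded at spots {over.index.tolist()[:5]}")

    @property
    def n_cells(self) -> int:
        return len(self.mapping)

    def cells_in_spot(self, spot_id) -> list:
        return self.mapping.index[self.mapping == spot_id].tolist()


@dataclass
class GroupLabels:
    """Spatial group labels for the focal cell type."""

    labels: pd.Series  # cell_id -> group name
    group_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels)
        if not self.group_names:
            self.group_names = sorted(pd.unique(self.labels))

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().reindex(self.group_names).fillna(0).astype(int)
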