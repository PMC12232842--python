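"""Paired single-cell + spot-level data with planted ground truth.

The generator emulates the structure of a Visium-style experiment with a
matched dissociated single-cell dataset: a lattice of spots partitioned
into labeled tissue regions, 1-9 cells per spot, negative-binomial counts
driven by cell-type marker signatures, niche-dependent expression shifts
of stated log2 fold change for a focal type in a named region, and
ligand-receptor activity that is either restricted to spatially
colocalized type pairs ("coupled") or independent of space ("decoupled").
Every planted feature is returned in a :class:`SyntheticTruth` so each
pipeline stage can be validated against known answers.

Counts follow NB(mu, theta) with variance mu + mu^2/theta (single global
theta).  Marker signatures give each type an exclusive gene block whose
log2 mean is offset by ``signature_strength`` over a shared baseline.
"Colocalized" for planting purposes means sharing >= 1 spot under the
true assignment - the same predicate the pipeline later estimates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    CellAnnotation,
    CellSpotAssignment,
    GeneExpressionMatrix,
    LRDatabase,
    LRInteraction,
    SpatialSlide,
)

__all__ = [
    "Region",
    "NicheEffect",
    "LREdge",
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_dataset",
    "aggregate_spot_expression",
    "scenario_presets",
    "write_fixtures",
    "PRESET_NAMES",
]

PRESET_NAMES = ("breast_like", "layered_like", "node_like")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    """Rectangular block of the spot grid with per-type abundance weights.

    ``rows``/``cols`` are half-open index ranges into the grid; a cell of
    type t chooses region r with probability proportional to
    weights[t] * n_spots(r).
    """

    name: str
    rows: tuple
    cols: tuple
    weights: dict


@dataclass(frozen=True)
class NicheEffect:
    """Planted differential expression: cells of ``cell_type`` located in
    ``region`` get the NB mean of ``n_genes`` dedicated genes multiplied
    by 2**log2fc."""

    cell_type: str
    region: str
    n_genes: int
    log2fc: float


@dataclass(frozen=True)
class LREdge:
    """One active ligand-receptor interaction from sender to receiver.

    ``sender_region`` / ``receiver_region`` restrict the planted activity
    to the focal group of that type inside the named region (the
    spatially resolved groups the pipeline later reconstructs); ``None``
    means the whole type.
    """

    sender: str
    receiver: str
    sender_region: str | None = None
    receiver_region: str | None = None


@dataclass
class SyntheticConfig:
    cell_types: tuple
    cells_per_type: int
    n_genes: int
    grid: tuple = (12, 12)          # (n_rows, n_cols)
    spacing: float = 100.0          # slide units between lattice points
    regions: tuple = ()
    cells_per_spot_range: tuple = (1, 9)
    nb_dispersion: float = 2.0
    markers_per_type: int = 10
    signature_strength: float = 2.0  # log2 offset of marker genes
    base_expr: float = 0.3
    base_sigma: float = 0.8
    marker_base: float = 0.25
    niche_effect: tuple = ()
    lr_truth: tuple = ()
    n_lr_background: int = 16
    lr_base_mean: float = 0.03
    lr_strength: float = 4.0         # log2 elevation of active LR genes
    receptor_subunits_every: int = 4  # every k-th background receptor is a 2-subunit complex
    coupling_mode: str = "coupled"   # {"coupled", "decoupled"}
    noise: float = 0.0               # Poisson extra-count rate per gene per spot
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cells_per_spot_range
        if not (1 <= lo <= hi):
            raise ValueError("cells_per_spot_range must satisfy 1 <= min <= max")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.coupling_mode not in ("coupled", "decoupled"):
            raise ValueError("coupling_mode must be 'coupled' or 'decoupled'")
        for r in self.regions:
            w = [r.weights.get(t, 0.0) for t in self.cell_types]
            if any(v < 0 for v in w):
                raise ValueError(f"region {r.name}: negative abundance weight")
        for t in self.cell_types:
            if not any(r.weights.get(t, 0.0) > 0 for r in self.regions):
                raise ValueError(f"type {t} has zero weight in every region")
        for e in self.niche_effect:
            if not np.isfinite(e.log2fc):
                raise ValueError("niche effect log2fc must be finite")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regions"] = [dataclasses.asdict(r) for r in self.regions]
        d["niche_effect"] = [dataclasses.asdict(e) for e in self.niche_effect]
        d["lr_truth"] = [dataclasses.asdict(e) for e in self.lr_truth]
        return d


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted next to every generated dataset."""

    assignment: CellSpotAssignment
    cell_regions: pd.Series                  # cell_id -> region name of its true spot
    deg_table: pd.DataFrame                  # gene, cell_type, region, log2fc
    edges: pd.DataFrame                      # interaction_id, sender(+region), receiver(+region), active
    presence: dict                           # type -> frozenset of occupied spot ids
    spot_regions: pd.Series                  # spot_id -> region name


@dataclass
class SyntheticDataset:
    cells: GeneExpressionMatrix
    slide: SpatialSlide
    annotation: CellAnnotation
    lrdb: LRDatabase
    truth: SyntheticTruth
    config: SyntheticConfig


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _spot_fill_counts(n_cells: int, n_spots: int, lo: int, hi: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Occupancy counts for the spots of one region: each occupied spot
    receives between lo and hi cells (the last-filled spot may fall below
    lo when the region total does not divide)."""
    if n_cells > hi * n_spots:
        raise ValueError(
            f"grid too small: {n_cells} cells exceed capacity {hi * n_spots} "
            f"({n_spots} spots at max {hi} cells/spot)"
        )
    counts = []
    remaining = n_cells
    while remaining > 0:
        spots_left = n_spots - len(counts)
        # keep the tail feasible: the remaining spots must be able to
        # absorb what is left at max capacity
        floor = max(lo, remaining - hi * (spots_left - 1)) if spots_left > 1 else remaining
        c = int(rng.integers(floor, hi + 1))
        c = min(c, remaining)
        counts.append(c)
        remaining -= c
    # borrow so the trailing spot reaches lo where possible
    if counts and counts[-1] < lo:
        for j in range(len(counts) - 1):
            while counts[j] > lo and counts[-1] < lo:
                counts[j] -= 1
                counts[-1] += 1
    out = np.zeros(n_spots, dtype=int)
    out[: len(counts)] = counts
    return out


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Draw one complete dataset; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n_rows, n_cols = cfg.grid
    lo, hi = cfg.cells_per_spot_range
    types = list(cfg.cell_types)
    n_cells_total = cfg.cells_per_type * len(types)
    if n_cells_total > hi * n_rows * n_cols:
        raise ValueError("grid too small to host requested cells at max capacity")

    # --- spots and regions -------------------------------------------------
    spot_ids = np.asarray(
        [f"s{r:02d}x{c:02d}" for r in range(n_rows) for c in range(n_cols)], dtype=object
    )
    coords = np.asarray(
        [(c * cfg.spacing, r * cfg.spacing) for r in range(n_rows) for c in range(n_cols)],
        dtype=float,
    )
    spot_region = np.empty(len(spot_ids), dtype=object)
    region_spots = {}
    for i, (r, c) in enumerate((r, c) for r in range(n_rows) for c in range(n_cols)):
        for reg in cfg.regions:
            if reg.rows[0] <= r < reg.rows[1] and reg.cols[0] <= c < reg.cols[1]:
                spot_region[i] = reg.name
                region_spots.setdefault(reg.name, []).append(i)
                break
        else:
            raise ValueError(f"spot ({r},{c}) not covered by any region")

    # --- gene catalog ------------------------------------------------------
    gene_ids = np.asarray([f"g{i:04d}" for i in range(cfg.n_genes)], dtype=object)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        if cursor + k > cfg.n_genes:
            raise ValueError("n_genes too small for requested markers/effects/LR genes")
        out = np.arange(cursor, cursor + k)
        cursor += k
        return out

    marker_rows = {t: take(cfg.markers_per_type) for t in types}
    effect_rows = {e: take(e.n_genes) for e in cfg.niche_effect}

    lr_records, edge_meta = [], []
    for k, e in enumerate(cfg.lr_truth):
        lig = take(1)
        rec = take(1)
        iid = f"LR{k:03d}"
        lr_records.append(
            LRInteraction(iid, tuple(gene_ids[lig]), tuple(gene_ids[rec]))
        )
        edge_meta.append((iid, e, lig, rec))
    for k in range(cfg.n_lr_background):
        n_sub = 2 if cfg.receptor_subunits_every and (k % cfg.receptor_subunits_every == 0) else 1
        lig = take(1)
        rec = take(n_sub)
        lr_records.append(
            LRInteraction(f"BG{k:03d}", tuple(gene_ids[lig]), tuple(gene_ids[rec]))
        )
    lr_rows = np.arange(len(marker_rows) * cfg.markers_per_type
                        + sum(e.n_genes for e in cfg.niche_effect), cursor)

    base = rng.lognormal(np.log(cfg.base_expr), cfg.base_sigma, cfg.n_genes)
    for t in types:
        base[marker_rows[t]] = cfg.marker_base
    base[lr_rows] = cfg.lr_base_mean

    # --- cell placement ----------------------------------------------------
    cell_ids, cell_types_list = [], []
    for t in types:
        for j in range(cfg.cells_per_type):
            cell_ids.append(f"{t}_{j:04d}")
            cell_types_list.append(t)
    cell_ids = np.asarray(cell_ids, dtype=object)
    cell_types_arr = np.asarray(cell_types_list, dtype=object)

    region_names = [r.name for r in cfg.regions]
    cell_region = np.empty(n_cells_total, dtype=object)
    for t in types:
        sel = np.flatnonzero(cell_types_arr == t)
        w = np.array(
            [next(r for r in cfg.regions if r.name == nm).weights.get(t, 0.0)
             * len(region_spots.get(nm, [])) for nm in region_names],
            dtype=float,
        )
        p = w / w.sum()
        cell_region[sel] = rng.choice(region_names, size=len(sel), p=p)

    # relocate overflow from regions past max capacity
    for nm in region_names:
        cap = hi * len(region_spots.get(nm, []))
        members = np.flatnonzero(cell_region == nm)
        if len(members) > cap:
            excess = rng.choice(members, size=len(members) - cap, replace=False)
            for i in excess:
                t = cell_types_arr[i]
                options = [
                    r.name for r in cfg.regions
                    if r.name != nm and r.weights.get(t, 0.0) > 0
                    and (cell_region == r.name).sum() < hi * len(region_spots.get(r.name, []))
                ]
                if not options:
                    raise ValueError("grid too small to host requested cells at max capacity")
                cell_region[i] = options[0]

    cell_spot = np.empty(n_cells_total, dtype=object)
    for nm in region_names:
        members = np.flatnonzero(cell_region == nm)
        if len(members) == 0:
            continue
        spots = np.array(region_spots[nm], dtype=int)
        spots = spots[rng.permutation(len(spots))]
        fill = _spot_fill_counts(len(members), len(spots), lo, hi, rng)
        members = members[rng.permutation(len(members))]
        pos = 0
        for s, k in zip(spots, fill):
            if k == 0:
                break
            cell_spot[members[pos: pos + k]] = spot_ids[s]
            pos += k

    # --- presence sets and coupling gate -----------------------------------
    def entity_cells(t: str, region: str | None) -> np.ndarray:
        mask = cell_types_arr == t
        if region is not None:
            mask &= cell_region == region
        return np.flatnonzero(mask)

    def entity_spots(t: str, region: str | None) -> frozenset:
        return frozenset(cell_spot[entity_cells(t, region)])

    presence = {t: entity_spots(t, None) for t in types}

    # --- per-cell NB means --------------------------------------------------
    mu = np.tile(base[:, None], (1, n_cells_total))
    for t in types:
        mu[np.ix_(marker_rows[t], np.flatnonzero(cell_types_arr == t))] *= 2.0 ** cfg.signature_strength

    deg_rows = []
    for e in cfg.niche_effect:
        cells_idx = entity_cells(e.cell_type, e.region)
        rows = effect_rows[e]
        mu[np.ix_(rows, cells_idx)] *= 2.0 ** e.log2fc
        for g in gene_ids[rows]:
            deg_rows.append({"gene": g, "cell_type": e.cell_type,
                             "region": e.region, "log2fc": e.log2fc})

    edge_rows = []
    for iid, e, lig, rec in edge_meta:
        if cfg.coupling_mode == "coupled":
            active = bool(entity_spots(e.sender, e.sender_region)
                          & entity_spots(e.receiver, e.receiver_region))
        else:
            active = True
        if active:
            mu[np.ix_(lig, entity_cells(e.sender, e.sender_region))] *= 2.0 ** cfg.lr_strength
            mu[np.ix_(rec, entity_cells(e.receiver, e.receiver_region))] *= 2.0 ** cfg.lr_strength
        edge_rows.append({
            "interaction_id": iid, "sender": e.sender, "receiver": e.receiver,
            "sender_region": e.sender_region or "", "receiver_region": e.receiver_region or "",
            "active": active,
        })

    # --- sample counts (gamma-Poisson mixture == NB) ------------------------
    lam = rng.gamma(cfg.nb_dispersion, mu / cfg.nb_dispersion)
    counts = rng.poisson(lam)

    cells = GeneExpressionMatrix(gene_ids, cell_ids, counts)
    assignment = CellSpotAssignment(pd.Series(cell_spot, index=cell_ids))
    spot_expr = aggregate_spot_expression(
        cells, assignment, cfg.noise, spot_ids=spot_ids, rng=rng
    )
    slide = SpatialSlide(
        spot_ids=spot_ids,
        coords=coords,
        spot_expr=spot_expr,
        region_labels=pd.Series(spot_region, index=spot_ids),
    )
    annotation = CellAnnotation(pd.Series(cell_types_arr, index=cell_ids))
    truth = SyntheticTruth(
        assignment=assignment,
        cell_regions=pd.Series(cell_region, index=cell_ids),
        deg_table=pd.DataFrame(deg_rows, columns=["gene", "cell_type", "region", "log2fc"]),
        edges=pd.DataFrame(edge_rows, columns=["interaction_id", "sender", "receiver",
                                               "sender_region", "receiver_region", "active"]),
        presence=presence,
        spot_regions=pd.Series(spot_region, index=spot_ids),
    )
    return SyntheticDataset(cells, slide, annotation, LRDatabase(lr_records), truth, cfg)


def aggregate_spot_expression(
    cells: GeneExpressionMatrix,
    a: CellSpotAssignment,
    noise_rate: float = 0.0,
    spot_ids: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> GeneExpressionMatrix:
    """Spot counts = sum of constituent cells' counts, plus
    Poisson(noise_rate) extra counts per gene per spot.  With noise 0 the
    slide grand total equals the assigned-cell grand total."""
    missing = set(a.mapping.index) - set(cells.cell_ids)
    if missing:
        raise ValueError(f"assigned cells absent from matrix: {sorted(missing)[:5]}")
    if spot_ids is None:
        spot_ids = np.asarray(sorted(set(a.mapping)), dtype=object)
    spot_idx = {s: i for i, s in enumerate(spot_ids)}
    out = np.zeros((cells.n_genes, len(spot_ids)), dtype=np.int64)
    cidx = cells.cell_index()
    for cell, spot in a.mapping.items():
        out[:, spot_idx[spot]] += cells.counts[:, cidx[cell]]
    if noise_rate > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        out += rng.poisson(noise_rate, size=out.shape)
    return GeneExpressionMatrix(cells.gene_ids.copy(), spot_ids, out)


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

def _repeat(edges) -> tuple:
    out = []
    for e, n in edges:
        out.extend([e] * n)
    return tuple(out)


def _breast_like(seed: int, coupling_mode: str) -> SyntheticConfig:
    """Two tissue blocks hosting the focal ("tumor") type with graded
    partner compositions on each side, mirroring a slide with spatially
    separated tumor niches."""
    types = ("tumor", "tcell", "myeloid", "bcell", "peri", "endo", "epi", "caf")
    # per-type (region_A, region_B) placement weights; regions have equal
    # spot counts so the split fraction is w_A / (w_A + w_B)
    wA = {"tumor": 0.5, "tcell": 1.0, "myeloid": 0.78, "bcell": 0.55,
          "peri": 0.40, "endo": 0.25, "epi": 0.10, "caf": 0.0}
    regions = (
        Region("region_A", (0, 12), (0, 6), {t: wA[t] for t in types}),
        Region("region_B", (0, 12), (6, 12), {t: 1.0 - wA[t] for t in types}),
    )
    if coupling_mode == "coupled":
        # communication restricted to colocalized pairs, intensity graded
        # with the designed colocalization gradient of each tumor group
        lr = _repeat([
            (LREdge("tumor", "tcell", sender_region="region_A"), 8),
            (LREdge("tumor", "myeloid", sender_region="region_A"), 6),
            (LREdge("tumor", "bcell", sender_region="region_A"), 4),
            (LREdge("tumor", "peri", sender_region="region_A"), 2),
            (LREdge("tumor", "caf", sender_region="region_B"), 8),
            (LREdge("tumor", "epi", sender_region="region_B"), 6),
            (LREdge("tumor", "endo", sender_region="region_B"), 4),
            (LREdge("tumor", "peri", sender_region="region_B"), 2),
        ])
    else:
        # space-agnostic communication: a fixed intensity gradient whose
        # rank pattern has zero rank-correlation with the colocalization
        # ordering of either tumor group (see docs/methods.md)
        lr = _repeat([
            (LREdge("tumor", "tcell"), 6),
            (LREdge("tumor", "myeloid"), 12),
            (LREdge("tumor", "bcell"), 4),
            (LREdge("tumor", "peri"), 14),
            (LREdge("tumor", "endo"), 2),
            (LREdge("tumor", "epi"), 10),
            (LREdge("tumor", "caf"), 8),
            (LREdge("tumor", "tumor"), 4),
        ])
    return SyntheticConfig(
        cell_types=types,
        cells_per_type=90,
        n_genes=800,
        grid=(12, 12),
        regions=regions,
        cells_per_spot_range=(1, 6),
        niche_effect=(
            NicheEffect("tumor", "region_A", 25, 2.0),
            NicheEffect("tumor", "region_B", 25, 2.0),
        ),
        lr_truth=lr,
        coupling_mode=coupling_mode,
        seed=seed,
    )


def _layered_like(seed: int, coupling_mode: str) -> SyntheticConfig:
    """A focal type spanning three contiguous bands with band-specific
    neighbors and band-specific co-expression programs, emulating a
    layered cortical structure."""
    types = ("L5", "L4", "L6", "astro", "endo")
    regions = (
        Region("outer", (0, 4), (0, 12), {"L5": 1, "L4": 1, "L6": 0, "astro": 1, "endo": 0.5}),
        Region("middle", (4, 8), (0, 12), {"L5": 1, "L4": 0.05, "L6": 0.05, "astro": 1, "endo": 1}),
        Region("inner", (8, 12), (0, 12), {"L5": 1, "L4": 0, "L6": 1, "astro": 1, "endo": 0.5}),
    )
    lr = _repeat([
        (LREdge("L5", "L4", sender_region="outer"), 3),
        (LREdge("L5", "L6", sender_region="inner"), 3),
    ])
    return SyntheticConfig(
        cell_types=types,
        cells_per_type=120,
        n_genes=600,
        grid=(12, 12),
        regions=regions,
        cells_per_spot_range=(1, 6),
        nb_dispersion=5.0,
        niche_effect=(
            NicheEffect("L5", "outer", 15, 2.5),
            NicheEffect("L5", "middle", 15, 2.5),
            NicheEffect("L5", "inner", 15, 2.5),
        ),
        lr_truth=lr,
        coupling_mode=coupling_mode,
        seed=seed,
    )


def _node_like(seed: int, coupling_mode: str) -> SyntheticConfig:
    """A compact annotated node dominated by one type (fibroblasts)
    embedded in surrounding myocardium."""
    types = ("fibro", "cardio", "endo", "myeloid", "neural")
    regions = (
        Region("node", (4, 8), (4, 8),
               {"fibro": 3.0, "cardio": 0.02, "endo": 0.1, "myeloid": 0.1, "neural": 0.3}),
        Region("myocardium", (0, 12), (0, 12),
               {"fibro": 0.3, "cardio": 2.0, "endo": 1.0, "myeloid": 1.0, "neural": 0.5}),
    )
    lr = _repeat([
        (LREdge("fibro", "cardio", sender_region="myocardium"), 3),
        (LREdge("fibro", "neural", sender_region="node"), 3),
    ])
    return SyntheticConfig(
        cell_types=types,
        cells_per_type=90,
        n_genes=600,
        grid=(12, 12),
        regions=regions,
        cells_per_spot_range=(1, 6),
        niche_effect=(
            NicheEffect("fibro", "node", 15, 2.0),
            NicheEffect("fibro", "myocardium", 15, 2.0),
        ),
        lr_truth=lr,
        coupling_mode=coupling_mode,
        seed=seed,
    )


_PRESETS = {"breast_like": _breast_like, "layered_like": _layered_like, "node_like": _node_like}

FOCAL_TYPES = {"breast_like": "tumor", "layered_like": "L5", "node_like": "fibro"}


def scenario_presets(name: str, seed: int = 0, coupling_mode: str = "coupled") -> SyntheticConfig:
    """Fully populated config for one of the built-in scenarios."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return _PRESETS[name](seed, coupling_mode)


# note: node rectangle is listed first so it wins the overlap with the
# surrounding block (first-match region lookup)


# ---------------------------------------------------------------------------
# fixture export
# ---------------------------------------------------------------------------

def write_fixtures(ds: SyntheticDataset, outdir) -> None:
    """Write the full fixture set in the pipeline's on-disk formats,
    plus truth tables and the config used."""
    from . import io_core

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io_core.write_counts(ds.cells, out / "cells.mtx", out / "genes.tsv", out / "barcodes.tsv")
    if ds.slide.spot_expr is not None:
        io_core.write_counts(ds.slide.spot_expr, out / "spots.mtx",
                             out / "spot_genes.tsv", out / "spot_barcodes.tsv")
    io_core.write_slide(ds.slide, out / "slide.tsv")
    io_core.write_annotation(ds.annotation, out / "annotation.tsv")
    io_core.write_lr_database(ds.lrdb, out / "lr_database.csv")
    io_core.write_assignment(ds.truth.assignment, out / "true_assignment.tsv")
    ds.truth.deg_table.to_csv(out / "true_degs.tsv", sep="\t", index=False)
    ds.truth.edges.to_csv(out / "true_lr_edges.tsv", sep="\t", index=False)
    pd.DataFrame({
        "cell_id": ds.truth.cell_regions.index,
        "region": ds.truth.cell_regions.to_numpy(object),
    }).to_csv(out / "true_cell_regions.tsv", sep="\t", index=False)
    (out / "config_used.yaml").write_text(yaml.safe_dump(ds.config.to_dict(), sort_keys=True))
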