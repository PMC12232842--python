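"""Permutation-based ligand-receptor communication inference.

For every ordered (sender group, receiver group) pair and database
interaction, the observed score is the arithmetic mean of the ligand
value in the sender and the receptor value in the receiver, where a
(possibly multi-subunit) complex value is the minimum over subunits of
the group-mean normalized expression.  Significance comes from permuting
the group labels over all cells: p = (1 + #{permuted score >= observed})
/ (n_perm + 1), so a p-value of exactly 0 is never reported.  A triple
is additionally gated on every subunit being expressed in more than
``expr_prop`` of the group's cells; gated-out triples carry p = 1.  An
exhaustive mode enumerates every distinct two-group label arrangement
instead of sampling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import GeneExpressionMatrix, LRDatabase

logger = logging.getLogger(__name__)

__all__ = [
    "CCCResult",
    "group_mean_expression",
    "score_interactions",
    "permutation_pvalues",
    "count_significant",
    "ingest_external_ccc",
    "export_ccc",
]


@dataclass
class CCCResult:
    """Per (sender, receiver, interaction) scores, permutation p-values
    and significance flags, plus the run metadata."""

    table: pd.DataFrame  # sender, receiver, interaction_id, score, pval, gate, significant
    meta: dict = field(default_factory=dict)

    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def group_mean_expression(
    m: GeneExpressionMatrix,
    cells_of_group,
    components,
    expr_prop: float = 0.1,
):
    """(value, gate) for one complex in one group: value is the minimum
    over subunits of the group-mean normalized expression; the gate is
    true iff every subunit is expressed (> 0) in more than ``expr_prop``
    of the group's cells.  Absent genes force value 0 / gate false."""
    if not components:
        raise ValueError("empty component list")
    if m.norm is None:
        raise ValueError("normalized layer required")
    cidx = m.cell_index()
    cols = np.array([cidx[c] for c in cells_of_group], dtype=int)
    gidx = m.gene_index()
    vals, fracs = [], []
    for g in components:
        if g not in gidx:
            warnings.warn(f"component gene {g!r} absent from matrix", stacklevel=2)
            return 0.0, False
        row = m.norm[gidx[g], cols]
        vals.append(float(row.mean()))
        fracs.append(float((row > 0).mean()))
    return min(vals), all(f > expr_prop for f in fracs)


class _LRMachinery:
    """Pre-indexed data for fast repeated scoring under permuted labels."""

    def __init__(self, m: GeneExpressionMatrix, labels: pd.Series, lrdb: LRDatabase,
                 min_cells: int, expr_prop: float):
        if m.norm is None:
            raise ValueError("normalized layer required")
        labels = labels[labels.index.isin(m.cell_ids)]
        sizes = labels.value_counts()
        eligible = sorted(sizes.index[sizes >= min_cells])
        dropped = sorted(set(sizes.index) - set(eligible))
        if dropped:
            warnings.warn(f"groups below min_cells={min_cells} excluded: {dropped}",
                          stacklevel=3)
        if not eligible:
            raise ValueError("no groups with enough cells")
        cidx = m.cell_index()
        cells = [c for c in labels.index if labels[c] in set(eligible)]
        cols = np.array([cidx[c] for c in cells], dtype=int)
        group_of = {g: i for i, g in enumerate(eligible)}
        y = np.array([group_of[labels[c]] for c in cells], dtype=int)

        gidx = m.gene_index()
        genes = []
        for rec in lrdb:
            genes.extend(rec.ligand_components)
            genes.extend(rec.receptor_components)
        genes = sorted(set(genes))
        present = {}
        for g in genes:
            if g in gidx:
                present[g] = len(present)
        absent = [g for g in genes if g not in present]
        if absent:
            warnings.warn(f"{len(absent)} LR gene(s) absent from matrix", stacklevel=3)

        self.lrdb = lrdb
        self.expr_prop = expr_prop
        self.groups = eligible
        self.n_groups = len(eligible)
        self.n_int = len(lrdb)
        self.y = y
        self.x = m.norm[[gidx[g] for g in present], :][:, cols]
        self.onehot = np.eye(self.n_groups)[y]
        self.sizes = self.onehot.sum(axis=0)
        self.side = {}
        for side in ("ligand", "receptor"):
            comp_rows, comp_int = [], []
            valid = np.ones(self.n_int, dtype=bool)
            for i, rec in enumerate(lrdb):
                comps = (rec.ligand_components if side == "ligand"
                         else rec.receptor_components)
                if all(g in present for g in comps):
                    for g in comps:
                        comp_rows.append(present[g])
                        comp_int.append(i)
                else:
                    valid[i] = False
            self.side[side] = (np.asarray(comp_rows, dtype=int),
                               np.asarray(comp_int, dtype=int), valid)

    def complex_values(self, means: np.ndarray, side: str) -> np.ndarray:
        """(n_int, n_groups) minimum over subunit rows; interactions with
        absent subunits get -inf (never significant)."""
        comp_rows, comp_int, valid = self.side[side]
        out = np.full((self.n_int, means.shape[1]), np.inf)
        np.minimum.at(out, comp_int, means[comp_rows])
        out[~valid] = -np.inf
        return out

    def group_means(self, onehot: np.ndarray) -> np.ndarray:
        return self.x @ onehot / self.sizes

    def score_tensor(self, onehot: np.ndarray) -> np.ndarray:
        means = self.group_means(onehot)
        lig = self.complex_values(means, "ligand")
        rec = self.complex_values(means, "receptor")
        return 0.5 * (lig[:, :, None] + rec[:, None, :])

    def gates(self) -> np.ndarray:
        """(n_int, sender, receiver) expression gates on the observed labels."""
        fracs = (self.x > 0).astype(float) @ self.onehot / self.sizes
        gate_side = {}
        for side in ("ligand", "receptor"):
            comp_rows, comp_int, valid = self.side[side]
            ok = np.ones((self.n_int, self.n_groups), dtype=bool)
            expressed = fracs[comp_rows] > self.expr_prop
            np.logical_and.at(ok, comp_int, expressed)
            ok[~valid] = False
            gate_side[side] = ok
        return gate_side["ligand"][:, :, None] & gate_side["receptor"][:, None, :]


def _machinery(m, labels, lrdb, min_cells, expr_prop) -> _LRMachinery:
    return _LRMachinery(m, labels, lrdb, min_cells, expr_prop)


def _tensor_to_table(mach: _LRMachinery, score, gate) -> pd.DataFrame:
    rows = []
    for s, sg in enumerate(mach.groups):
        for r, rg in enumerate(mach.groups):
            for i, rec in enumerate(mach.lrdb):
                val = score[i, s, r]
                rows.append({
                    "sender": sg,
                    "receiver": rg,
                    "interaction_id": rec.interaction_id,
                    "score": float(max(val, 0.0)) if np.isfinite(val) else 0.0,
                    "gate": bool(gate[i, s, r]),
                })
    return pd.DataFrame(rows)


def score_interactions(
    m: GeneExpressionMatrix,
    labels: pd.Series,
    lrdb: LRDatabase,
    min_cells: int = 10,
    expr_prop: float = 0.1,
) -> pd.DataFrame:
    """Observed mean-expression scores and expression gates for every
    ordered group pair x interaction (autocrine pairs included)."""
    mach = _machinery(m, labels, lrdb, min_cells, expr_prop)
    return _tensor_to_table(mach, mach.score_tensor(mach.onehot), mach.gates())


def permutation_pvalues(
    m: GeneExpressionMatrix,
    labels: pd.Series,
    lrdb: LRDatabase,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    min_cells: int = 10,
    expr_prop: float = 0.1,
    exhaustive: bool = False,
) -> CCCResult:
    """Permutation significance of the observed interaction scores.

    Labels are shuffled across ALL cells of the eligible groups (cluster
    label permutation semantics).  In exhaustive mode (two groups only)
    every distinct label arrangement is enumerated and
    p = #{arrangements with score >= observed} / n_arrangements.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    mach = _machinery(m, labels, lrdb, min_cells, expr_prop)
    obs = mach.score_tensor(mach.onehot)
    n_cells = mach.x.shape[1]
    eye = np.eye(mach.n_groups)

    count_ge = np.zeros_like(obs, dtype=np.int64)
    if exhaustive:
        if mach.n_groups != 2:
            raise ValueError("exhaustive mode supports exactly 2 groups")
        n1 = int(mach.sizes[0])
        arrangements = list(combinations(range(n_cells), n1))
        for arr in arrangements:
            yv = np.ones(n_cells, dtype=int)
            yv[list(arr)] = 0
            count_ge += mach.score_tensor(eye[yv]) >= obs - 1e-12
        pvals = count_ge / len(arrangements)
        n_perm_used = len(arrangements)
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(n_cells)
            count_ge += mach.score_tensor(mach.onehot[perm]) >= obs - 1e-12
        pvals = (1.0 + count_ge) / (n_perm + 1.0)
        n_perm_used = n_perm

    table = _tensor_to_table(mach, obs, mach.gates())
    flat_p = pvals.transpose(1, 2, 0).reshape(-1)  # matches sender, receiver, interaction order
    flat_p = np.where(table["gate"].to_numpy(), flat_p, 1.0)
    table = table.assign(pval=np.clip(flat_p, np.nextafter(0.0, 1.0), 1.0))
    table["significant"] = (table["pval"] < alpha) & table["gate"]
    return CCCResult(
        table=table,
        meta={
            "n_permutations": n_perm_used,
            "exhaustive": bool(exhaustive),
            "expr_prop": expr_prop,
            "min_cells": min_cells,
            "alpha": alpha,
            "seed": seed,
            "groups": list(mach.groups),
        },
    )


def count_significant(
    ccc: CCCResult,
    focal_groups,
    direction_mode: str = "both_summed",
) -> pd.DataFrame:
    """Significant-interaction counts per (focal group, partner group).

    ``direction_mode``: sender_only counts triples with the focal group
    as sender, receiver_only as receiver, both_summed adds the two.
    Partners are all groups other than the focal group itself.
    """
    if direction_mode not in ("sender_only", "receiver_only", "both_summed"):
        raise ValueError(f"unknown direction_mode {direction_mode!r}")
    groups = ccc.meta.get("groups") or sorted(
        set(ccc.table["sender"]) | set(ccc.table["receiver"]))
    for f in focal_groups:
        if f not in groups:
            raise ValueError(f"unknown focal group {f!r}")
    sig = ccc.table[ccc.table["significant"].astype(bool)]
    out = {}
    for f in focal_groups:
        partners = [g for g in groups if g != f]
        as_sender = sig[sig["sender"] == f].groupby("receiver").size()
        as_receiver = sig[sig["receiver"] == f].groupby("sender").size()
        counts = pd.Series(0, index=partners, dtype=float)
        if direction_mode in ("sender_only", "both_summed"):
            counts = counts.add(as_sender.reindex(partners).fillna(0), fill_value=0)
        if direction_mode in ("receiver_only", "both_summed"):
            counts = counts.add(as_receiver.reindex(partners).fillna(0), fill_value=0)
        out[f] = counts.astype(int)
    return pd.DataFrame(out)


DEFAULT_DIALECT = {"source": "source", "target": "target",
                   "interaction": "interaction", "p": "p"}


def ingest_external_ccc(path, dialect: dict | None = None, alpha: float = 0.05) -> CCCResult:
    """Normalize an externally produced long-format significance table
    (e.g. from other communication tools) into a CCCResult; scores are
    absent, gates true, significance recomputed at ``alpha``."""
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    df = pd.read_csv(path, sep="\t")
    missing = [v for v in dialect.values() if v not in df.columns]
    if missing:
        raise ValueError(f"missing mapped columns: {missing}")
    out = pd.DataFrame({
        "sender": df[dialect["source"]].astype(str),
        "receiver": df[dialect["target"]].astype(str),
        "interaction_id": df[dialect["interaction"]].astype(str),
        "score": np.nan,
        "gate": True,
        "pval": df[dialect["p"]].astype(float),
    })
    dup = out.duplicated(subset=["sender", "receiver", "interaction_id"])
    if dup.any():
        dupes = out.loc[dup, ["sender", "receiver", "interaction_id"]].head(5)
        raise ValueError(f"duplicate triples in external table:\n{dupes}")
    out["significant"] = out["pval"] < alpha
    groups = sorted(set(out["sender"]) | set(out["receiver"]))
    return CCCResult(out, meta={"alpha": alpha, "groups": groups, "external": True})


def export_ccc(ccc: CCCResult, path) -> None:
    ccc.table.to_csv(path, sep="\t", index=False)
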