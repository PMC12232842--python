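from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from nichecord import ccc as ccc_mod
from nichecord.datatypes import GeneExpressionMatrix, LRDatabase, LRInteraction


def _gem(norm, genes=None, cells=None):
    norm = np.asarray(norm, dtype=float)
    genes = genes or [f"g{i}" for i in range(norm.shape[0])]
    cells = cells or [f"c{j}" for j in range(norm.shape[1])]
    return GeneExpressionMatrix(genes, cells, np.zeros(norm.shape, dtype=int), norm)


def _labels(groups_sizes):
    cells, labels = [], []
    k = 0
    for g, n in groups_sizes:
        for _ in range(n):
            cells.append(f"c{k}")
            labels.append(g)
            k += 1
    return pd.Series(labels, index=cells)


# ---------------------------------------------------------------------------
# group mean expression
# ---------------------------------------------------------------------------

def test_unexpressed_gene_gates_out():
    m = _gem([[0.0, 0.0, 0.0]], genes=["lig"])
    value, gate = ccc_mod.group_mean_expression(m, m.cell_ids, ["lig"])
    assert value == 0.0 and gate is False


def test_complex_value_is_minimum_over_subunits():
    m = _gem([[2.0, 2.0], [0.5, 0.5]], genes=["sub1", "sub2"])
    value, gate = ccc_mod.group_mean_expression(m, m.cell_ids, ["sub1", "sub2"])
    assert value == pytest.approx(0.5)
    assert gate is True


def test_absent_component_warns_and_gates_out():
    m = _gem([[1.0]], genes=["other"])
    with pytest.warns(UserWarning, match="absent"):
        value, gate = ccc_mod.group_mean_expression(m, m.cell_ids, ["missing"])
    assert value == 0.0 and gate is False


# ---------------------------------------------------------------------------
# observed scores
# ---------------------------------------------------------------------------

def _two_group_setup():
    # lig mean 1.0 in A, 0 in B; rec mean 3.0 in B, 0 in A
    norm = np.array([
        [1.0] * 10 + [0.0] * 10,
        [0.0] * 10 + [3.0] * 10,
    ])
    m = _gem(norm, genes=["lig", "rec"])
    labels = _labels([("A", 10), ("B", 10)])
    db = LRDatabase([LRInteraction("I1", ("lig",), ("rec",))])
    return m, labels, db


def test_score_is_mean_of_ligand_and_receptor_values():
    m, labels, db = _two_group_setup()
    tab = ccc_mod.score_interactions(m, labels, db)
    row = tab.set_index(["sender", "receiver"]).loc[("A", "B")]
    assert row["score"] == pytest.approx(2.0)
    assert row["gate"]


def test_autocrine_pairs_scored_by_same_rule():
    m, labels, db = _two_group_setup()
    tab = ccc_mod.score_interactions(m, labels, db)
    row = tab.set_index(["sender", "receiver"]).loc[("A", "A")]
    assert row["score"] == pytest.approx(0.5)  # (1.0 + 0.0) / 2
    assert not row["gate"]  # receptor unexpressed in A


def test_small_groups_excluded_with_warning():
    m, labels, db = _two_group_setup()
    labels.iloc[:3] = "tiny"
    with pytest.warns(UserWarning, match="min_cells"):
        tab = ccc_mod.score_interactions(m, labels, db, min_cells=5)
    assert "tiny" not in set(tab["sender"])


# ---------------------------------------------------------------------------
# permutation p-values
# ---------------------------------------------------------------------------

def test_exhaustive_p_matches_independent_enumeration(rng):
    """2 groups x 3 cells, 1 interaction: p equals a from-scratch
    enumeration of all 20 label arrangements."""
    norm = rng.lognormal(0.0, 0.5, size=(2, 6))
    m = _gem(norm, genes=["lig", "rec"])
    labels = _labels([("A", 3), ("B", 3)])
    db = LRDatabase([LRInteraction("I1", ("lig",), ("rec",))])
    res = ccc_mod.permutation_pvalues(m, labels, db, min_cells=1, expr_prop=0.0,
                                      exhaustive=True)
    assert res.meta["n_permutations"] == 20

    lig, rec = norm[0], norm[1]
    for sender, receiver in (("A", "B"), ("B", "A"), ("A", "A")):
        obs_row = res.table.set_index(["sender", "receiver"]).loc[(sender, receiver)]
        count = 0
        for combo in combinations(range(6), 3):
            in_a = np.zeros(6, dtype=bool)
            in_a[list(combo)] = True
            sender_mask = in_a if sender == "A" else ~in_a
            receiver_mask = in_a if receiver == "A" else ~in_a
            score = 0.5 * (lig[sender_mask].mean() + rec[receiver_mask].mean())
            if score >= obs_row["score"] - 1e-12:
                count += 1
        assert obs_row["pval"] == pytest.approx(count / 20.0)


def test_sampled_mode_agrees_with_exhaustive_within_binomial_error(rng):
    norm = rng.lognormal(0.0, 0.5, size=(2, 6))
    m = _gem(norm, genes=["lig", "rec"])
    labels = _labels([("A", 3), ("B", 3)])
    db = LRDatabase([LRInteraction("I1", ("lig",), ("rec",))])
    exact = ccc_mod.permutation_pvalues(m, labels, db, min_cells=1, expr_prop=0.0,
                                        exhaustive=True)
    sampled = ccc_mod.permutation_pvalues(m, labels, db, min_cells=1, expr_prop=0.0,
                                          n_perm=10000, seed=5)
    key = ["sender", "receiver", "interaction_id"]
    e = exact.table.set_index(key)["pval"]
    s = sampled.table.set_index(key)["pval"]
    for idx in e.index:
        se = 3 * np.sqrt(e[idx] * (1 - e[idx]) / 10000) + 2e-4
        assert abs(s[idx] - e[idx]) <= se + 1e-9


def test_pvalues_invariant_to_cell_order_and_seeded(rng):
    norm = rng.lognormal(0.0, 0.5, size=(4, 40))
    m = _gem(norm, genes=["l1", "r1", "l2", "r2"])
    labels = _labels([("A", 20), ("B", 20)])
    db = LRDatabase([LRInteraction("I1", ("l1",), ("r1",)),
                     LRInteraction("I2", ("l2",), ("r2",))])
    res1 = ccc_mod.permutation_pvalues(m, labels, db, n_perm=300, seed=9, expr_prop=0.0)
    perm = rng.permutation(m.n_cells)
    m2 = GeneExpressionMatrix(m.gene_ids, m.cell_ids[perm],
                              m.counts[:, perm], m.norm[:, perm])
    res2 = ccc_mod.permutation_pvalues(m2, labels, db, n_perm=300, seed=9, expr_prop=0.0)
    key = ["sender", "receiver", "interaction_id"]
    t1 = res1.table.set_index(key).sort_index()
    t2 = res2.table.set_index(key).sort_index()
    assert np.allclose(t1["score"], t2["score"])
    assert np.allclose(t1["pval"], t2["pval"])


def test_higher_observed_score_never_raises_pvalue(rng):
    """Monotonicity against a fixed permutation null."""
    norm = rng.lognormal(0.0, 0.4, size=(2, 30))
    labels = _labels([("A", 15), ("B", 15)])
    db = LRDatabase([LRInteraction("I1", ("lig",), ("rec",))])
    pvals = []
    for bump in (0.0, 0.5, 1.5):
        boosted = norm.copy()
        boosted[0, :15] += bump  # raise ligand mean in sender A only
        m = _gem(boosted, genes=["lig", "rec"])
        res = ccc_mod.permutation_pvalues(m, labels, db, n_perm=400, seed=3,
                                          expr_prop=0.0)
        pvals.append(res.table.set_index(["sender", "receiver"])
                     .loc[("A", "B"), "pval"])
    assert pvals[0] >= pvals[1] >= pvals[2]


def test_gated_triples_carry_p_one():
    m, labels, db = _two_group_setup()
    res = ccc_mod.permutation_pvalues(m, labels, db, n_perm=100, seed=0)
    gated = res.table[~res.table["gate"]]
    assert len(gated) > 0
    assert (gated["pval"] == 1.0).all()
    assert not gated["significant"].any()


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def _result_with(sig_triples, groups):
    rows = [{"sender": s, "receiver": r, "interaction_id": i, "score": 1.0,
             "gate": True, "pval": 0.01, "significant": True}
            for s, r, i in sig_triples]
    table = pd.DataFrame(rows, columns=["sender", "receiver", "interaction_id",
                                        "score", "gate", "pval", "significant"])
    return ccc_mod.CCCResult(table, meta={"groups": groups})


def test_count_significant_direction_modes():
    triples = ([("F", "P", f"i{k}") for k in range(3)]
               + [("P", "F", f"j{k}") for k in range(2)])
    res = _result_with(triples, ["F", "P"])
    both = ccc_mod.count_significant(res, ["F"], "both_summed")
    assert both.loc["P", "F"] == 5
    sender = ccc_mod.count_significant(res, ["F"], "sender_only")
    assert sender.loc["P", "F"] == 3
    receiver = ccc_mod.count_significant(res, ["F"], "receiver_only")
    assert receiver.loc["P", "F"] == 2


def test_count_significant_empty_and_unknown():
    res = _result_with([], ["F", "P"])
    res.table = res.table.iloc[0:0]
    counts = ccc_mod.count_significant(res, ["F"])
    assert (counts["F"] == 0).all()
    with pytest.raises(ValueError, match="unknown focal group"):
        ccc_mod.count_significant(res, ["nope"])


# ---------------------------------------------------------------------------
# external ingestion
# ---------------------------------------------------------------------------

def test_ingest_minimal_table(tmp_path):
    p = tmp_path / "ext.tsv"
    p.write_text("source\ttarget\tinteraction\tp\nA\tB\tI1\t0.01\n")
    res = ccc_mod.ingest_external_ccc(p)
    assert len(res.table) == 1
    assert bool(res.table["significant"].iloc[0])


def test_ingest_duplicate_triples_raise(tmp_path):
    p = tmp_path / "ext.tsv"
    p.write_text("source\ttarget\tinteraction\tp\nA\tB\tI1\t0.01\nA\tB\tI1\t0.2\n")
    with pytest.raises(ValueError, match="duplicate"):
        ccc_mod.ingest_external_ccc(p)


def test_export_then_ingest_preserves_counts(tmp_path, rng):
    norm = rng.lognormal(0.3, 0.5, size=(2, 40))
    m = _gem(norm, genes=["lig", "rec"])
    labels = _labels([("A", 20), ("B", 20)])
    db = LRDatabase([LRInteraction("I1", ("lig",), ("rec",))])
    res = ccc_mod.permutation_pvalues(m, labels, db, n_perm=200, seed=1, expr_prop=0.0)
    ccc_mod.export_ccc(res, tmp_path / "ccc.tsv")
    back = ccc_mod.ingest_external_ccc(
        tmp_path / "ccc.tsv",
        dialect={"source": "sender", "target": "receiver",
                 "interaction": "interaction_id", "p": "pval"})
    orig = ccc_mod.count_significant(res, ["A", "B"])
    again = ccc_mod.count_significant(back, ["A", "B"])
    assert orig.equals(again)
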