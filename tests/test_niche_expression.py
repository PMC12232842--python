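import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from nichecord import niche_expression as ne
from nichecord.datatypes import GeneExpressionMatrix
from nichecord.io_core import normalize_log
from conftest import make_matrix


def _gem_from_norm(norm, genes=None, cells=None):
    norm = np.asarray(norm, dtype=float)
    genes = genes or [f"g{i}" for i in range(norm.shape[0])]
    cells = cells or [f"c{j}" for j in range(norm.shape[1])]
    return GeneExpressionMatrix(genes, cells, np.zeros(norm.shape, dtype=int), norm)


# ---------------------------------------------------------------------------
# cosine distances
# ---------------------------------------------------------------------------

def test_cosine_distance_examples():
    norm = np.array([[1.0, 1.0, 1.0, 0.0],
                     [2.0, 2.0, 0.0, 1.0]])
    m = _gem_from_norm(norm, cells=["a1", "a2", "b1", "b2"])
    labels = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "C"})
    d = ne.pairwise_cosine_distances(m, labels, {
        "within_A": ("within", "A"),
        "between": ("between", "B", "C"),
    })
    assert d.samples["within_A"][0] == pytest.approx(0.0, abs=1e-12)   # identical
    # orthogonal vectors (1,0) vs (0,1) are at distance exactly 1
    assert d.samples["between"][0] == pytest.approx(1.0, abs=1e-12)


def test_cosine_distance_formula_value():
    m = _gem_from_norm([[1.0, 1.0], [1.0, 0.0]], cells=["x", "y"])
    labels = pd.Series({"x": "A", "y": "B"})
    d = ne.pairwise_cosine_distances(m, labels, {"ab": ("between", "A", "B")})
    assert d.samples["ab"][0] == pytest.approx(1 - 1 / np.sqrt(2), abs=1e-12)


def test_cosine_excludes_zero_vectors_with_warning():
    m = _gem_from_norm([[1.0, 0.0, 2.0]], cells=["x", "z", "y"])
    labels = pd.Series({"x": "A", "z": "A", "y": "A"})
    with pytest.warns(UserWarning, match="zero vector"):
        d = ne.pairwise_cosine_distances(m, labels, {"w": ("within", "A")})
    assert len(d.samples["w"]) == 1  # only the x-y pair remains


def test_cosine_small_group_raises():
    m = _gem_from_norm([[1.0]], cells=["x"])
    with pytest.raises(ValueError, match="need >= 2"):
        ne.pairwise_cosine_distances(m, pd.Series({"x": "A"}), {"w": ("within", "A")})


# ---------------------------------------------------------------------------
# KS
# ---------------------------------------------------------------------------

def test_ks_identical_samples():
    d, p = ne.ks_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert d == 0.0 and p == 1.0


def test_ks_fully_separated_supports():
    d, _ = ne.ks_compare([0.0, 0.1, 0.2], [5.0, 6.0, 7.0])
    assert d == 1.0


def brute_force_ks(a, b):
    grid = np.sort(np.concatenate([a, b]))
    ecdf_a = np.searchsorted(np.sort(a), grid, side="right") / len(a)
    ecdf_b = np.searchsorted(np.sort(b), grid, side="right") / len(b)
    return np.max(np.abs(ecdf_a - ecdf_b))


def test_ks_matches_brute_force_ecdf(rng):
    for _ in range(20):
        a = rng.normal(size=rng.integers(5, 40))
        b = rng.normal(0.3, 1.2, size=rng.integers(5, 40))
        d, _ = ne.ks_compare(a, b)
        assert d == pytest.approx(brute_force_ks(a, b), abs=1e-12)


# ---------------------------------------------------------------------------
# Wilcoxon DEG
# ---------------------------------------------------------------------------

def _two_group_matrix(rng, n_genes, n_per_group, mu, theta, planted=None):
    mu_mat = np.tile(np.asarray(mu, dtype=float)[:, None], (1, 2 * n_per_group))
    if planted:
        for row, fc in planted.items():
            mu_mat[row, :n_per_group] *= fc
    lam = rng.gamma(theta, mu_mat / theta)
    counts = rng.poisson(lam)
    cells = [f"c{i}" for i in range(2 * n_per_group)]
    labels = pd.Series(["a"] * n_per_group + ["b"] * n_per_group, index=cells)
    m = normalize_log(GeneExpressionMatrix([f"g{i}" for i in range(n_genes)], cells, counts))
    return m, labels


def test_wilcoxon_null_calibrated(rng):
    m, labels = _two_group_matrix(rng, 2000, 100, np.full(2000, 1.0), 5.0)
    tab = ne.deg_wilcoxon(m, labels, "a", "b")
    assert (tab["pval"] < 0.05).mean() <= 0.05 + 0.02


def test_wilcoxon_flags_planted_gene(rng):
    m, labels = _two_group_matrix(rng, 50, 100, np.full(50, 1.0), 20.0, planted={0: 4.0})
    tab = ne.deg_wilcoxon(m, labels, "a", "b")
    assert bool(tab.loc[tab["gene"] == "g0", "significant"].iloc[0])


def test_fold_change_gate_blocks_small_effects():
    """A gene with tiny p but linear FC below 1.5 is not flagged."""
    n = 100
    norm = np.zeros((1, 2 * n))
    norm[0, :n] = np.log1p(1.2)   # mean expm1 exactly 1.2
    norm[0, n:] = np.log1p(1.0)   # vs 1.0 -> FC 1.2, ranks fully separated
    m = _gem_from_norm(norm)
    labels = pd.Series(["a"] * n + ["b"] * n, index=m.cell_ids)
    tab = ne.deg_wilcoxon(m, labels, "a", "b")
    assert tab["padj"].iloc[0] < 1e-10
    assert not bool(tab["significant"].iloc[0])


def test_wilcoxon_invariant_to_cell_and_gene_order(rng):
    m, labels = _two_group_matrix(rng, 40, 20, np.full(40, 1.0), 5.0, planted={3: 3.0})
    tab = ne.deg_wilcoxon(m, labels, "a", "b").set_index("gene")
    perm_c = rng.permutation(m.n_cells)
    perm_g = rng.permutation(m.n_genes)
    shuffled = GeneExpressionMatrix(m.gene_ids[perm_g], m.cell_ids[perm_c],
                                    m.counts[np.ix_(perm_g, perm_c)],
                                    m.norm[np.ix_(perm_g, perm_c)])
    tab2 = ne.deg_wilcoxon(shuffled, labels, "a", "b").set_index("gene")
    tab2 = tab2.reindex(tab.index)
    assert np.allclose(tab["pval"], tab2["pval"])
    assert np.allclose(tab["log2fc"], tab2["log2fc"])


def test_wilcoxon_small_group_raises():
    m = _gem_from_norm(np.ones((2, 4)))
    labels = pd.Series(["a", "a", "b", "b"], index=m.cell_ids)
    with pytest.raises(ValueError, match=">= 3"):
        ne.deg_wilcoxon(m, labels, "a", "b")


@given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=40))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_bh_adjustment_matches_brute_force(pvals):
    """BH as used by the DEG stages equals the textbook step-up rule."""
    p = np.asarray(pvals)
    _, padj, _, _ = multipletests(p, method="fdr_bh")
    m = len(p)
    order = np.argsort(p, kind="stable")
    brute = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        brute[i] = running
    assert np.allclose(padj, brute, atol=1e-12)
    assert np.all(padj >= p - 1e-15)


# ---------------------------------------------------------------------------
# pseudobulk
# ---------------------------------------------------------------------------

def test_pseudobulk_partition_sizes_and_conservation():
    counts = np.arange(36).reshape(2, 18)
    m = make_matrix(counts)
    labels = pd.Series(["a"] * 9 + ["b"] * 9, index=m.cell_ids)
    pb = ne.make_pseudobulk(m, labels, "a", "b", n_reps=3, seed=0)
    assert [len(c) for c in pb.replicate_cells] == [3] * 6
    group_a = pb.counts[:, pb.sample_groups == "a"].sum(axis=1)
    assert np.array_equal(group_a, counts[:, :9].sum(axis=1))


def test_pseudobulk_partition_deterministic():
    m = make_matrix(np.ones((3, 12), dtype=int))
    labels = pd.Series(["a"] * 6 + ["b"] * 6, index=m.cell_ids)
    p1 = ne.make_pseudobulk(m, labels, "a", "b", seed=42)
    p2 = ne.make_pseudobulk(m, labels, "a", "b", seed=42)
    assert p1.replicate_cells == p2.replicate_cells


def test_pseudobulk_group_too_small_raises():
    m = make_matrix(np.ones((2, 4), dtype=int))
    labels = pd.Series(["a", "a", "b", "b"], index=m.cell_ids)
    with pytest.raises(ValueError, match="n_reps"):
        ne.make_pseudobulk(m, labels, "a", "b", n_reps=3)


def test_pseudobulk_deg_flags_planted_gene(rng):
    n, npg = 300, 200
    mu = np.full(n, 1.0)
    m, labels = _two_group_matrix(rng, n, npg, mu, 5.0, planted={5: 2.0**3})
    pb = ne.make_pseudobulk(
        GeneExpressionMatrix(m.gene_ids, m.cell_ids, m.counts), labels, "a", "b", seed=0)
    tab = ne.pseudobulk_deg(pb)
    row = tab.loc[tab["gene"] == "g5"].iloc[0]
    assert row["significant"]
    assert row["log2fc"] == pytest.approx(3.0, abs=0.6)


def test_pseudobulk_equal_groups_give_zero_lfc():
    counts = np.array([[10, 20, 30, 10, 20, 30],
                       [5, 5, 5, 5, 5, 5]])
    pb = ne.Pseudobulk(counts, np.array(["g0", "g1"], dtype=object),
                       np.array(["a", "a", "a", "b", "b", "b"], dtype=object),
                       [[f"c{i}"] for i in range(6)])
    tab = ne.pseudobulk_deg(pb)
    assert np.allclose(tab["log2fc"], 0.0, atol=1e-6)


def test_pseudobulk_degenerate_group_raises():
    counts = np.zeros((2, 4), dtype=int)
    counts[:, :2] = 5
    pb = ne.Pseudobulk(counts, np.array(["g0", "g1"], dtype=object),
                       np.array(["a", "a", "b", "b"], dtype=object),
                       [[f"c{i}"] for i in range(4)])
    with pytest.raises(ValueError, match="degenerate"):
        ne.pseudobulk_deg(pb)


def test_pseudobulk_cross_check_against_reference_wald(rng):
    """Independent oracle: unshrunk fold changes agree in direction and
    roughly in size with the reference count-model implementation."""
    pydeseq2 = pytest.importorskip("pydeseq2")
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    n, npg = 120, 150
    m, labels = _two_group_matrix(rng, n, npg, np.full(n, 2.0), 5.0,
                                  planted={0: 8.0, 1: 0.25})
    pb = ne.make_pseudobulk(
        GeneExpressionMatrix(m.gene_ids, m.cell_ids, m.counts), labels, "a", "b", seed=0)
    ours = ne.pseudobulk_deg(pb).set_index("gene")

    counts_df = pd.DataFrame(pb.counts.T, columns=pb.gene_ids)
    meta = pd.DataFrame({"condition": pb.sample_groups})
    dds = DeseqDataSet(counts=counts_df, metadata=meta, design="~condition", quiet=True)
    dds.deseq2()
    res = DeseqStats(dds, contrast=["condition", "a", "b"], quiet=True)
    res.summary()
    ref = res.results_df
    for gene in ("g0", "g1"):
        assert np.sign(ours.loc[gene, "log2fc"]) == np.sign(ref.loc[gene, "log2FoldChange"])
        assert ours.loc[gene, "log2fc"] == pytest.approx(
            ref.loc[gene, "log2FoldChange"], abs=0.75)
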