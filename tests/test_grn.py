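import itertools

import numpy as np
import pytest
from scipy import stats

from grnpipe import grn, synthetic
from grnpipe.grn import (
    DirectedAdjacency,
    SimilarityMatrix,
    adjacency_from_threshold,
    clustering_coefficients,
    degree_ranking,
    expected_random_cc,
    select_threshold,
    similarity_matrix,
)


def piecewise_adjacency_oracle(s: np.ndarray, tau: float) -> np.ndarray:
    """Direct evaluation of the sign-directed threshold rule, pair by pair."""
    n = s.shape[0]
    a = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(s[i, j]) >= tau and s[i, j] > 0:
                a[i, j] = 1
            elif abs(s[i, j]) >= tau and s[i, j] < 0:
                a[j, i] = 1
    return a


def cc_oracle(sym: np.ndarray) -> np.ndarray:
    """Brute-force triad enumeration."""
    n = sym.shape[0]
    out = []
    for i in range(n):
        nb = [j for j in range(n) if sym[i, j]]
        if len(nb) < 2:
            out.append(0.0)
            continue
        links = sum(1 for a, b in itertools.combinations(nb, 2) if sym[a, b])
        out.append(2.0 * links / (len(nb) * (len(nb) - 1)))
    return np.array(out)


def random_similarity(rng, n):
    r = rng.uniform(-1.0, 1.0, size=(n, n))
    s = (r + r.T) / 2.0
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix([f"G{i:02d}" for i in range(n)], s, "spearman")


# ------------------------------------------------------------- similarity


def test_spearman_perfect_monotone(expr_factory):
    expr = expr_factory([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]])
    s = similarity_matrix(expr, "spearman")
    assert s.values[0, 1] == pytest.approx(1.0)


def test_spearman_perfect_antitone(expr_factory):
    expr = expr_factory([[1.0, 2.0, 3.0], [6.0, 4.0, 2.0]])
    s = similarity_matrix(expr, "spearman")
    assert s.values[0, 1] == pytest.approx(-1.0)


def test_spearman_matches_rank_pearson_oracle(expr_factory, rng):
    values = rng.normal(size=(5, 8))
    expr = expr_factory(values)
    s = similarity_matrix(expr, "spearman").values
    oracle = np.corrcoef(stats.rankdata(values, axis=1))
    assert np.max(np.abs(s - oracle)) < 1e-12


def test_constant_row_similarity_zero_with_warning(expr_factory, rng):
    values = rng.normal(size=(3, 10))
    values[1] = 5.0
    expr = expr_factory(values)
    with pytest.warns(UserWarning, match="G002"):
        s = similarity_matrix(expr, "spearman")
    assert np.all(s.values[1, [0, 2]] == 0.0)
    assert np.all(s.values[[0, 2], 1] == 0.0)
    assert s.values[1, 1] == 1.0


def test_kendall_monotone(expr_factory):
    expr = expr_factory([[1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 7.0, 9.0]])
    s = similarity_matrix(expr, "kendall")
    assert s.values[0, 1] == pytest.approx(1.0)


def test_mutual_information_magnitude_and_sign(expr_factory, rng):
    x = rng.normal(size=100)
    expr = expr_factory(np.vstack([x, 2 * x + rng.normal(0, 0.1, 100), -x]))
    s = similarity_matrix(expr, "mutual_information")
    assert np.all(np.abs(s.values) <= 1.0)
    assert np.all(np.diag(s.values) == 1.0)
    assert s.values[0, 1] > 0.3
    assert s.values[0, 2] < -0.3


def test_similarity_requires_three_samples(expr_factory):
    with pytest.raises(ValueError):
        expr = expr_factory(np.ones((2, 2)))


def test_unknown_method_rejected(expr_factory, rng):
    expr = expr_factory(rng.normal(size=(3, 5)))
    with pytest.raises(ValueError, match="method"):
        similarity_matrix(expr, "pearson")


# -------------------------------------------------------------- adjacency


@pytest.mark.parametrize(
    "sij,tau,expect",
    [
        (0.9, 0.5, (1, 0)),   # strong positive: i -> j
        (-0.9, 0.5, (0, 1)),  # strong negative: j -> i
        (0.3, 0.5, (0, 0)),   # below threshold
    ],
)
def test_adjacency_branches(sij, tau, expect):
    s = np.array([[1.0, sij], [sij, 1.0]])
    adj = adjacency_from_threshold(SimilarityMatrix(["a", "b"], s, "spearman"), tau)
    assert (adj.a[0, 1], adj.a[1, 0]) == expect


def test_adjacency_tau_out_of_range(rng):
    s = random_similarity(rng, 4)
    for tau in (-0.1, 1.5):
        with pytest.raises(ValueError, match="tau"):
            adjacency_from_threshold(s, tau)


def test_adjacency_matches_piecewise_oracle(rng):
    for _ in range(25):
        n = int(rng.integers(3, 16))
        s = random_similarity(rng, n)
        for tau in rng.uniform(0, 1, size=4):
            adj = adjacency_from_threshold(s, tau)
            assert np.array_equal(adj.a, piecewise_adjacency_oracle(s.values, tau))


def test_adjacency_tau_zero_and_above_max(rng):
    s = random_similarity(rng, 8)
    adj0 = adjacency_from_threshold(s, 0.0)
    iu = np.triu_indices(8, 1)
    nonzero_pairs = int((s.values[iu] != 0).sum())
    assert adj0.n_edges == nonzero_pairs
    assert adjacency_from_threshold(s, 1.0).n_edges <= (np.abs(s.values[iu]) >= 1).sum()


def test_monotone_thinning(rng):
    s = random_similarity(rng, 20)
    counts = [
        adjacency_from_threshold(s, t).n_edges for t in np.linspace(0, 1, 50)
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_adjacency_invariants_rejected():
    with pytest.raises(ValueError, match="diagonal"):
        DirectedAdjacency(["a", "b"], np.array([[1, 0], [0, 0]]), 0.5)
    with pytest.raises(ValueError, match="one of"):
        DirectedAdjacency(["a", "b"], np.array([[0, 1], [1, 0]]), 0.5)


# ------------------------------------------------- clustering coefficients


def _adj_from_sym(sym):
    a = np.triu(sym, k=1)
    return DirectedAdjacency([f"G{i}" for i in range(sym.shape[0])], a, 0.5)


def test_cc_triangle():
    sym = np.ones((3, 3)) - np.eye(3)
    cc, mean = clustering_coefficients(_adj_from_sym(sym))
    assert np.allclose(cc, 1.0) and mean == pytest.approx(1.0)


def test_cc_star():
    sym = np.zeros((5, 5))
    sym[0, 1:] = sym[1:, 0] = 1
    cc, mean = clustering_coefficients(_adj_from_sym(sym))
    assert np.allclose(cc, 0.0) and mean == 0.0


def test_cc_matches_bruteforce_oracle(rng):
    for _ in range(20):
        n = int(rng.integers(4, 13))
        sym = (rng.random((n, n)) < 0.4).astype(int)
        sym = np.triu(sym, 1)
        sym = sym + sym.T
        cc, mean = clustering_coefficients(_adj_from_sym(sym))
        assert np.allclose(cc, cc_oracle(sym))
        assert mean == pytest.approx(cc_oracle(sym).mean())


def test_expected_random_cc_extremes():
    empty = _adj_from_sym(np.zeros((5, 5)))
    full = _adj_from_sym(np.ones((5, 5)) - np.eye(5))
    assert expected_random_cc(empty) == 0.0
    assert expected_random_cc(full) == pytest.approx(1.0)


# ------------------------------------------------------ threshold selection


def block_similarity(n_blocks=2, block=6, within=0.9, between=0.1):
    n = n_blocks * block
    s = np.full((n, n), between)
    for b in range(n_blocks):
        sl = slice(b * block, (b + 1) * block)
        s[sl, sl] = within
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix([f"G{i:02d}" for i in range(n)], s, "spearman")


def test_select_threshold_block_matrix():
    scan = select_threshold(block_similarity())
    assert 0.1 < scan.tau_star <= 0.9
    # exhaustive check: the selected threshold attains the max criterion
    diffs = scan.diff
    assert diffs[np.searchsorted(scan.grid, scan.tau_star)] == diffs.max()


def test_select_threshold_degenerate_all_equal():
    n = 6
    s = np.full((n, n), 0.5)
    np.fill_diagonal(s, 1.0)
    sim = SimilarityMatrix([f"G{i}" for i in range(n)], s, "spearman")
    with pytest.warns(UserWarning, match="degenerate"):
        scan = select_threshold(sim)
    assert scan.tau_star == scan.grid[0]


def test_select_threshold_gene_order_invariance(rng):
    s = random_similarity(rng, 15)
    scan = select_threshold(s)
    perm = rng.permutation(15)
    sp = SimilarityMatrix(
        [s.genes[i] for i in perm], s.values[np.ix_(perm, perm)], "spearman"
    )
    scan_p = select_threshold(sp)
    assert scan_p.tau_star == scan.tau_star
    adj = adjacency_from_threshold(s, scan.tau_star)
    adj_p = adjacency_from_threshold(sp, scan_p.tau_star)
    # the undirected network is permutation-equivariant; the direction of
    # positive edges follows gene order by construction of the pair rule
    assert np.array_equal(
        adj_p.symmetrized(), adj.symmetrized()[np.ix_(perm, perm)]
    )


def test_select_threshold_tie_breaks_to_smallest():
    scan = select_threshold(block_similarity(), grid=[0.5, 0.6])
    # both thresholds give the identical network, hence identical criterion
    assert scan.tau_star == 0.5


def test_grid_values_validated(rng):
    with pytest.raises(ValueError, match="grid"):
        select_threshold(random_similarity(rng, 5), grid=[0.2, 1.4])


def test_planted_network_recovery_f1():
    expr, truth = synthetic.simulate_expression(synthetic.SimConfig(seed=0))
    s = similarity_matrix(expr)
    scan = select_threshold(s, grid=np.linspace(0, 1, 201))
    adj = adjacency_from_threshold(s, scan.tau_star)
    pred = {
        frozenset((adj.genes[i], adj.genes[j])) for i, j in zip(*np.nonzero(adj.a))
    }
    tr = truth.undirected_pairs()
    tp = len(pred & tr)
    precision = tp / len(pred)
    recall = tp / len(tr)
    f1 = 2 * precision * recall / (precision + recall)
    assert f1 >= 0.8 - 1e-9


# ----------------------------------------------------------- degree ranking


def test_degree_ranking_hub_first(rng):
    sym = np.zeros((5, 5))
    sym[0, 1:] = 1
    adj = _adj_from_sym(sym)
    table = degree_ranking(adj)
    assert table.iloc[0]["gene"] == "G0"
    assert table.iloc[0]["total"] == 4


def test_degree_totals_match_matrix_sums(rng):
    s = random_similarity(rng, 12)
    adj = adjacency_from_threshold(s, 0.4)
    table = degree_ranking(adj).set_index("gene")
    expected = adj.a.sum(axis=1) + adj.a.sum(axis=0)
    for i, g in enumerate(adj.genes):
        assert table.loc[g, "total"] == expected[i]


def test_degree_ranking_empty_network_lexicographic():
    genes = ["b", "a", "c"]
    adj = DirectedAdjacency(genes, np.zeros((3, 3), dtype=int), 0.9)
    table = degree_ranking(adj)
    assert list(table["gene"]) == ["a", "b", "c"]
    assert (table["total"] == 0).all()
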