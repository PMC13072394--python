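from itertools import combinations

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.special import comb
from sklearn.decomposition import TruncatedSVD
from sklearn.metrics import adjusted_rand_score

from gafa.embed_cluster import (
    LatentEmbedding,
    NeighborGraph,
    batch_mixing_score,
    build_knn_graph,
    differential_expression,
    embed_batch_aware,
    identify_nk_clusters,
    leiden_cluster,
    rank_marker_genes,
)
from gafa.io_qc import normalize_log
from gafa.synthetic import SyntheticConfig, generate_dataset

from conftest import make_expression_matrix


def test_single_batch_equals_plain_truncated_svd():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(50, 30))
    emb = embed_batch_aware(X, batches=None, d=5, seed=0)
    ref = TruncatedSVD(n_components=5, algorithm="randomized", random_state=0)
    expected = ref.fit_transform(X - X.mean(axis=0))
    assert np.allclose(emb.coords, expected)


def test_embedding_dimension_and_validation():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(40, 30))
    emb = embed_batch_aware(X, batches=None, d=20, seed=0)
    assert emb.coords.shape == (40, 20)
    with pytest.raises(ValueError, match="d="):
        embed_batch_aware(X, d=30)
    with pytest.raises(NotImplementedError):
        embed_batch_aware(X, d=5, backend="vae")


def test_batch_covariate_improves_mixing(normalized):
    norm, _, _ = normalized
    batches = norm.cell_meta["batch"].to_numpy()
    with_cov = embed_batch_aware(norm, batches, d=20, seed=0)
    without = embed_batch_aware(norm, None, d=20, seed=0)
    assert batch_mixing_score(with_cov, batches) > batch_mixing_score(without, batches)


def test_batch_mixing_improvement_replicates():
    # embedding contract holds across independently generated datasets
    wins = 0
    n_rep = 20
    for seed in range(n_rep):
        cfg = SyntheticConfig(seed=100 + seed, n_cells=300, batch_shift_sd=0.3)
        m, _ = generate_dataset(cfg)
        norm = normalize_log(m)
        batches = norm.cell_meta["batch"].to_numpy()
        with_cov = embed_batch_aware(norm, batches, d=10, seed=0)
        without = embed_batch_aware(norm, None, d=10, seed=0)
        wins += batch_mixing_score(with_cov, batches) > batch_mixing_score(without, batches)
    assert wins >= 0.95 * n_rep


def test_knn_graph_equilateral_triangle_is_complete():
    coords = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
    g = build_knn_graph(LatentEmbedding(coords), k=2)
    assert g.adjacency.nnz == 6  # K3, both directions
    assert (g.adjacency.diagonal() == 0).all()
    assert (abs(g.adjacency - g.adjacency.T) > 1e-12).nnz == 0


def test_knn_graph_no_cross_blob_edges():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 0.5, size=(40, 3))
    b = rng.normal(50, 0.5, size=(40, 3))
    coords = np.vstack([a, b])
    g = build_knn_graph(LatentEmbedding(coords), k=5)
    cross = g.adjacency[:40, 40:]
    assert cross.nnz == 0
    # brute-force distance check: each node's 5 nearest really are same-blob
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    for i in range(80):
        nn = set(np.argsort(d2[i])[1:6].tolist())
        same_blob = set(range(40)) if i < 40 else set(range(40, 80))
        assert nn <= same_blob
        assert nn <= set(np.nonzero(g.adjacency[i].toarray().ravel())[0].tolist())
    with pytest.raises(ValueError, match="k must be"):
        build_knn_graph(LatentEmbedding(coords), k=0)


def _clique_graph(sizes, weight=1.0):
    n = sum(sizes)
    A = np.zeros((n, n))
    start = 0
    for s in sizes:
        A[start : start + s, start : start + s] = weight
        start += s
    np.fill_diagonal(A, 0)
    return NeighborGraph(adjacency=sp.csr_matrix(A), k=max(sizes) - 1)


def test_leiden_disconnected_cliques_and_determinism():
    g = _clique_graph([10, 10])
    lab = leiden_cluster(g, resolution=1.0, seed=0)
    assert lab.n_clusters == 2
    assert len(set(lab.labels[:10])) == 1 and len(set(lab.labels[10:])) == 1
    lab2 = leiden_cluster(g, resolution=1.0, seed=0)
    assert np.array_equal(lab.labels, lab2.labels)
    with pytest.raises(ValueError, match="empty"):
        leiden_cluster(NeighborGraph(adjacency=sp.csr_matrix((0, 0)), k=1))


def test_leiden_recovers_planted_states(normalized):
    norm, kept, truth = normalized
    batches = norm.cell_meta["batch"].to_numpy()
    emb = embed_batch_aware(norm, batches, d=20, seed=1)
    g = build_knn_graph(emb, k=15)
    lab = leiden_cluster(g, resolution=1.0, seed=1)
    ari = adjusted_rand_score(truth.true_state[kept], lab.labels)
    assert ari > 0.7


def test_identify_nk_clusters(normalized):
    norm, kept, truth = normalized
    # true states as "clusters": on-path states carry the gating markers
    from gafa.embed_cluster import ClusterLabels

    labels = ClusterLabels(labels=truth.true_state[kept])
    flagged = identify_nk_clusters(norm, labels, markers=("NCAM1", "FCGR3A"), quantile=0.25)
    assert 5 not in flagged  # the off-path state is not NK-gated
    assert len(flagged) >= 3

    with pytest.raises(KeyError, match="NOPE"):
        identify_nk_clusters(norm, labels, markers=("NOPE",))


def test_identify_nk_no_signal_returns_empty():
    from gafa.embed_cluster import ClusterLabels

    m = make_expression_matrix(np.ones((40, 3), dtype=int), ["NCAM1", "FCGR3A", "G"])
    norm = normalize_log(m)
    labels = ClusterLabels(labels=np.repeat([0, 1], 20))
    with pytest.warns(UserWarning, match="no cluster"):
        flagged = identify_nk_clusters(norm, labels)
    assert flagged == set()


def test_exact_wilcoxon_small_sample():
    # [1,2] vs [3,4]: 1 of C(4,2)=6 orderings is as extreme, two-sided p=1/3
    vals = np.array([[1.0], [2.0], [3.0], [4.0]])
    tab = differential_expression(vals, np.array([True, True, False, False]))
    assert tab["p_value"].iloc[0] == pytest.approx(1 / 3)


def _brute_force_wilcoxon_p(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    obs = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
    stats = []
    for idx in combinations(range(len(pooled)), n1):
        a = pooled[list(idx)]
        b = np.delete(pooled, list(idx))
        stats.append(sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b))
    stats = np.array(stats)
    mu = len(x) * len(y) / 2
    return float((np.abs(stats - mu) >= np.abs(obs - mu) - 1e-12).mean())


def test_wilcoxon_matches_brute_force_enumeration():
    rng = np.random.default_rng(3)
    x = rng.normal(size=5)
    y = rng.normal(1.0, size=5)
    tab = differential_expression(
        np.concatenate([x, y])[:, None], np.repeat([True, False], 5)
    )
    assert tab["p_value"].iloc[0] == pytest.approx(_brute_force_wilcoxon_p(x, y))


def test_rank_marker_genes_exclusive_gene():
    rng = np.random.default_rng(0)
    n = 25
    base = rng.poisson(5, size=(2 * n, 10)).astype(float)
    base[:n, 0] += 50  # gene 0 expressed only highly in cluster 0
    genes = [f"G{i}" for i in range(10)]
    m = make_expression_matrix(base.astype(int), genes)
    norm = normalize_log(m)
    from gafa.embed_cluster import ClusterLabels

    labels = ClusterLabels(labels=np.repeat([0, 1], n))
    tab = rank_marker_genes(norm, labels)
    top0 = tab[tab["cluster"] == 0].iloc[0]
    assert top0["gene"] == "G0"
    assert top0["p_adj"] < 0.05
    assert (tab["p_adj"] >= tab["p_value"] - 1e-15).all()
    assert tab["p_adj"].between(0, 1).all()


def test_batch_mixing_score_limits():
    # perfectly interleaved batches on a line
    coords = np.arange(100, dtype=float)[:, None]
    batches = np.array(["A", "B"] * 50)
    e = LatentEmbedding(coords)
    assert batch_mixing_score(e, batches, k=14) > 0.95
    # fully separated
    separated = np.array(["A"] * 50 + ["B"] * 50)
    assert batch_mixing_score(e, separated, k=10) < 0.15
    with pytest.warns(UserWarning, match="single batch"):
        assert batch_mixing_score(e, np.array(["A"] * 100), k=10) == 1.0


def test_batch_mixing_random_assignment_monte_carlo():
    rng = np.random.default_rng(0)
    coords = rng.normal(size=(1000, 5))
    batches = rng.choice(["A", "B"], size=1000)
    score = batch_mixing_score(LatentEmbedding(coords), batches, k=15)
    assert 0.9 <= score <= 1.0
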