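import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from gafa.grn import (
    MessagePassingParams,
    PriorNetwork,
    WeightedGRN,
    _tanimoto,
    _znorm,
    annotate_outcome_bias,
    assemble_prior,
    compute_centralities,
    compute_coexpression,
    export_graph,
    filter_edges,
    mcl_modules,
    message_passing,
    read_graphml_edges,
    regulon_activity,
)
from gafa.io_qc import normalize_log, qc_filter
from gafa.synthetic import SyntheticConfig, generate_dataset, generate_prior_networks


# ----------------------------------------------------------------- priors


def test_assemble_prior_union_and_string_cutoff(tmp_path):
    f1 = tmp_path / "src1.tsv"
    f1.write_text("tf\ttarget\nTF1\tGA\nTF1\tGB\n")
    f2 = tmp_path / "src2.tsv"
    f2.write_text("tf\ttarget\nTF1\tGA\nTF2\tGB\nTF2\tGX\n")  # GX not in universe
    ppi = tmp_path / "ppi.tsv"
    ppi.write_text("a\tb\tcombined_score\nTF1\tTF2\t700\nTF1\tTF1\t650\n")
    prior = assemble_prior([f1, f2], ppi, ["GA", "GB", "TF1", "TF2"])
    W = pd.DataFrame(prior.W0, index=prior.tf_ids, columns=prior.gene_ids)
    assert W.loc["TF1", "GA"] == 1.0  # present in two sources, still 1
    assert W.loc["TF2", "GB"] == 1.0
    assert W.to_numpy().sum() == 3.0
    P = pd.DataFrame(prior.P, index=prior.tf_ids, columns=prior.tf_ids)
    assert P.loc["TF1", "TF2"] == pytest.approx(0.7)  # score 700 kept at 0.7
    assert P.loc["TF1", "TF1"] == 1.0
    assert np.allclose(prior.P, prior.P.T)


def test_assemble_prior_score_650_excluded(tmp_path):
    f1 = tmp_path / "src.tsv"
    f1.write_text("tf\ttarget\nTF1\tGA\nTF2\tGA\n")
    ppi = tmp_path / "ppi.tsv"
    ppi.write_text("a\tb\tcombined_score\nTF1\tTF2\t650\n")
    prior = assemble_prior([f1], ppi, ["GA", "TF1", "TF2"])
    P = pd.DataFrame(prior.P, index=prior.tf_ids, columns=prior.tf_ids)
    assert P.loc["TF1", "TF2"] == 0.0


def test_assemble_prior_requires_tfs(tmp_path):
    f1 = tmp_path / "src.tsv"
    f1.write_text("tf\ttarget\nTFX\tGX\n")
    ppi = tmp_path / "ppi.tsv"
    ppi.write_text("a\tb\tcombined_score\n")
    with pytest.raises(ValueError, match="no TF"):
        assemble_prior([f1], ppi, ["GA"])


# ----------------------------------------------------- co-expression


def test_coexpression_properties():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(1000, 4))
    X[:, 1] = X[:, 0]  # duplicate
    X[:, 2] = -X[:, 0]  # anti-correlated
    C = compute_coexpression(X)
    assert C[0, 1] == pytest.approx(1.0)
    assert C[0, 2] == pytest.approx(-1.0)
    assert abs(C[0, 3]) < 0.1  # independent noise at n=1000
    assert np.allclose(np.diag(C), 1.0)
    with pytest.raises(ValueError, match=">= 3 cells"):
        compute_coexpression(X[:2])


def test_coexpression_zero_variance_gene():
    X = np.column_stack([np.ones(10), np.arange(10.0)])
    with pytest.warns(UserWarning, match="zero-variance"):
        C = compute_coexpression(X)
    assert C[0, 1] == 0.0 and C[0, 0] == 1.0


# ------------------------------------------------- message passing


def test_tanimoto_identity_on_unit_vector():
    x = np.array([[0.6, 0.8]])
    assert _tanimoto(x, x.T)[0, 0] == pytest.approx(1.0)


def test_alpha_zero_is_exact_fixed_point():
    rng = np.random.default_rng(0)
    W0 = (rng.random((4, 12)) < 0.3).astype(float)
    P = np.eye(4)
    C = compute_coexpression(rng.normal(size=(30, 12)))
    prior = PriorNetwork(W0=W0, P=P, gene_ids=[f"G{i}" for i in range(12)],
                         tf_ids=[f"T{i}" for i in range(4)])
    grn = message_passing(prior, C, MessagePassingParams(alpha=0.0, n_iter=25))
    assert np.array_equal(grn.W, _znorm(W0))
    assert len(grn.trace) == 25 and all(d == 0.0 for d in grn.trace)


def test_message_passing_recovers_planted_network():
    cfg = SyntheticConfig(seed=4)
    m, truth = generate_dataset(cfg)
    norm = normalize_log(qc_filter(m))
    prior = generate_prior_networks(cfg, truth, fraction=0.6)
    C = compute_coexpression(norm.dense())
    grn = message_passing(prior, C, MessagePassingParams())
    adj = np.zeros_like(prior.W0, dtype=bool)
    trow = {t: i for i, t in enumerate(prior.tf_ids)}
    gcol = {g: i for i, g in enumerate(prior.gene_ids)}
    for tf, g, _s in truth.planted_edges:
        adj[trow[tf], gcol[g]] = True
    assert grn.W[adj].mean() > grn.W[~adj].mean()
    auc_prior = roc_auc_score(adj.ravel(), prior.W0.ravel())
    auc_final = roc_auc_score(adj.ravel(), grn.W.ravel())
    assert auc_final > auc_prior
    # convergence: update norm trends downward
    assert grn.trace[-1] < grn.trace[0]
    assert all(np.isfinite(grn.trace))


# ------------------------------------------------------ edge filter


def _toy_grn(weights):
    weights = np.asarray(weights, dtype=float)
    n_tf, n_g = weights.shape
    return WeightedGRN(
        W=weights,
        C=np.eye(n_g),
        gene_ids=[f"G{i}" for i in range(n_g)],
        tf_ids=[f"T{i}" for i in range(n_tf)],
        params=MessagePassingParams(),
    )


def test_filter_edges_abs_threshold():
    grn = _toy_grn([[0.5, 0.2, -0.4]])
    kept = filter_edges(grn, mode="abs_threshold", value=0.3)
    assert set(zip(kept["gene"], kept["weight"])) == {("G0", 0.5), ("G2", -0.4)}
    assert kept.loc[kept["gene"] == "G2", "sign"].item() == -1


def test_filter_edges_top_fraction_ceiling():
    rng = np.random.default_rng(0)
    grn = _toy_grn(rng.normal(size=(10, 100)))
    all_edges = filter_edges(grn, mode="top_fraction", value=1.0)
    assert len(all_edges) == 1000
    top = filter_edges(grn, mode="top_fraction", value=0.015)
    assert len(top) == 15  # ceil(0.015 * 1000)
    cutoff = np.sort(np.abs(grn.W).ravel())[::-1][14]
    assert np.abs(top["weight"]).min() == pytest.approx(cutoff)
    with pytest.raises(ValueError, match="unknown filter mode"):
        filter_edges(grn, mode="nope", value=1)


# ------------------------------------------------------ centralities


def test_pagerank_uniform_on_directed_ring():
    edges = pd.DataFrame(
        {"tf": [f"N{i}" for i in range(6)],
         "gene": [f"N{(i + 1) % 6}" for i in range(6)],
         "weight": 1.0, "sign": 1}
    )
    tab = compute_centralities(edges, tf_ids=[f"N{i}" for i in range(6)])
    assert np.allclose(tab["pagerank"], 1 / 6)
    assert tab["pagerank"].sum() == pytest.approx(1.0, abs=1e-9)


def _pagerank_power_iteration(nodes, edges, damping=0.85, n_iter=500):
    """Independent oracle: dense power iteration with dangling redistribution."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for tf, gene, w in edges[["tf", "gene", "weight"]].itertuples(index=False):
        A[idx[tf], idx[gene]] = abs(w)
    out = A.sum(axis=1)
    p = np.full(n, 1 / n)
    for _ in range(n_iter):
        new = np.full(n, (1 - damping) / n)
        for i in range(n):
            if out[i] > 0:
                new += damping * p[i] * A[i] / out[i]
            else:
                new += damping * p[i] / n
        p = new
    return {nd: p[idx[nd]] for nd in nodes}


def test_pagerank_matches_power_iteration_on_chain():
    edges = pd.DataFrame(
        {"tf": ["a", "b"], "gene": ["b", "c"], "weight": [1.0, 1.0], "sign": 1}
    )
    tab = compute_centralities(edges, tf_ids=["a", "b"]).set_index("node")
    oracle = _pagerank_power_iteration(["a", "b", "c"], edges)
    for node in ("a", "b", "c"):
        assert tab.loc[node, "pagerank"] == pytest.approx(oracle[node], abs=1e-8)
    assert tab["pagerank"].sum() == pytest.approx(1.0, abs=1e-9)


def test_high_centrality_flag_only_on_tfs(normalized):
    rng = np.random.default_rng(1)
    grn = _toy_grn(rng.normal(size=(10, 50)))
    edges = filter_edges(grn, mode="top_fraction", value=0.1)
    tab = compute_centralities(edges, tf_ids=grn.tf_ids)
    assert (~tab.loc[~tab["is_tf"], "high_centrality"]).all()
    assert tab.loc[tab["high_centrality"], "node"].str.startswith("T").all()


# ------------------------------------------------------------- MCL


def _edges_from_pairs(pairs):
    return pd.DataFrame(
        [(a, b, 1.0, 1) for a, b in pairs], columns=["tf", "gene", "weight", "sign"]
    )


def test_mcl_disconnected_triangles():
    tri1 = [("a", "b"), ("b", "c"), ("a", "c")]
    tri2 = [("x", "y"), ("y", "z"), ("x", "z")]
    modules = mcl_modules(_edges_from_pairs(tri1 + tri2))
    assert len(set(modules.values())) == 2
    assert modules["a"] == modules["b"] == modules["c"]
    assert modules["x"] == modules["y"] == modules["z"]
    assert modules["a"] != modules["x"]


def test_mcl_complete_graph_single_module():
    k4 = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")]
    modules = mcl_modules(_edges_from_pairs(k4))
    assert len(set(modules.values())) == 1


def test_mcl_barbell_splits_at_bridge():
    left = [(f"l{i}", f"l{j}") for i in range(5) for j in range(i + 1, 5)]
    right = [(f"r{i}", f"r{j}") for i in range(5) for j in range(i + 1, 5)]
    bridge = [("l0", "r0")]
    modules = mcl_modules(_edges_from_pairs(left + right + bridge), inflation=2.2)
    left_ids = {modules[f"l{i}"] for i in range(5)}
    right_ids = {modules[f"r{i}"] for i in range(5)}
    assert len(left_ids) == 1 and len(right_ids) == 1
    assert left_ids != right_ids
    assert len(set(modules.values())) == 2


# ------------------------------------------------- outcome annotation


def test_annotate_outcome_bias_rules():
    edges = _edges_from_pairs([("T1", "g1"), ("T1", "g2"), ("T1", "g3"), ("T1", "g4")])
    de = pd.DataFrame(
        {"logFC": [1.2, -0.9, -0.8, 0.4], "p_adj": [0.001, 0.2, 0.01, 0.001]},
        index=["g1", "g2", "g3", "g4"],
    )
    ann, per_tf = annotate_outcome_bias(edges, de)
    labels = dict(zip(ann["gene"], ann["outcome"]))
    assert labels == {
        "g1": "TFR_up", "g2": "unchanged", "g3": "Relapse_up", "g4": "TFR_up"
    }
    assert per_tf.loc["T1", "TFR_up"] == 2
    assert per_tf.loc["T1", "Relapse_up"] == 1
    assert per_tf.loc["T1", "unchanged"] == 1


def test_annotate_missing_target_warns():
    edges = _edges_from_pairs([("T1", "gX")])
    de = pd.DataFrame({"logFC": [1.0], "p_adj": [0.01]}, index=["g1"])
    with pytest.warns(UserWarning, match="missing"):
        ann, _ = annotate_outcome_bias(edges, de)
    assert ann.loc[ann["gene"] == "gX", "outcome"].item() == "unchanged"


def test_regulon_activity_minmax_scaled():
    rng = np.random.default_rng(0)
    values = rng.normal(size=(40, 3))
    edges = _edges_from_pairs([("T1", "G0"), ("T1", "G1")])
    act = regulon_activity(values, ["G0", "G1", "G2"], edges)
    assert act["T1"].min() == pytest.approx(0.0)
    assert act["T1"].max() == pytest.approx(1.0)


# ------------------------------------------------------------ export


def test_export_sif_and_graphml_round_trip(tmp_path):
    edges = pd.DataFrame(
        {"tf": ["T1", "T2"], "gene": ["g1", "g2"], "weight": [0.5, -0.7],
         "sign": [1, -1]}
    )
    sif = export_graph(edges, tmp_path / "net.sif", fmt="SIF")
    lines = sif.read_text().strip().splitlines()
    assert lines == ["T1\tregulates\tg1", "T2\tregulates\tg2"]

    ann = pd.DataFrame({"gene": ["g1"], "outcome": ["TFR_up"]})
    gml = export_graph(edges, tmp_path / "net.graphml", fmt="GraphML", annotations=ann)
    back = read_graphml_edges(gml)
    assert back[["tf", "gene", "weight", "sign"]].equals(
        edges.sort_values(["tf", "gene"]).reset_index(drop=True)
    )
    assert 'outcome' in gml.read_text()
    with pytest.raises(ValueError, match="unknown export format"):
        export_graph(edges, tmp_path / "x", fmt="dot")
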