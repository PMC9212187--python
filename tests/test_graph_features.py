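import itertools

import numpy as np
import pandas as pd
import pytest

from evoconn import AtlasConfig, BrainGraph, FeatureTable, assemble_features, compute_measure_set, default_atlas
from evoconn.graph_features import (
    MEASURES,
    average_path_length,
    betweenness_centrality,
    clustering_coefficient,
    cost,
    degree_centrality,
    global_efficiency,
    local_efficiency,
)

from conftest import graph_from_edges, random_graph


# --------------------------------------------------------------------------
# independent oracle: Floyd-Warshall + shortest-path-count dynamic program


def _fw_paths(a):
    n = len(a)
    INF = float("inf")
    d = [[0 if i == j else (1 if a[i][j] else INF) for j in range(n)] for i in range(n)]
    sigma = [[1 if a[i][j] else 0 for j in range(n)] for i in range(n)]
    for i in range(n):
        sigma[i][i] = 1
    for k in range(n):
        for i in range(n):
            if i == k:
                continue
            for j in range(n):
                if j == k or j == i:
                    continue
                alt = d[i][k] + d[k][j]
                if alt < d[i][j]:
                    d[i][j] = alt
                    sigma[i][j] = sigma[i][k] * sigma[k][j]
                elif alt == d[i][j] and alt < INF:
                    sigma[i][j] += sigma[i][k] * sigma[k][j]
    return d, sigma


def oracle_measures(adj):
    a = np.asarray(adj, dtype=int)
    n = len(a)
    d, sigma = _fw_paths(a)
    rows = {}
    for v in range(n):
        deg = int(a[v].sum())
        # betweenness
        bc = 0.0
        if n >= 3:
            for s, t in itertools.combinations([u for u in range(n) if u != v], 2):
                if d[s][t] == float("inf") or sigma[s][t] == 0:
                    continue
                through = sigma[s][v] * sigma[v][t] if d[s][v] + d[v][t] == d[s][t] else 0
                bc += through / sigma[s][t]
            bc /= (n - 1) * (n - 2) / 2
        reach = [d[v][u] for u in range(n) if u != v and d[v][u] < float("inf")]
        apl = sum(reach) / len(reach) if reach else 0.0
        nbrs = [u for u in range(n) if a[v][u]]
        if deg >= 2:
            among = sum(a[x][y] for x, y in itertools.combinations(nbrs, 2))
            cc = among / (deg * (deg - 1) / 2)
        else:
            cc = 0.0
        cst = deg / (n - 1)
        geff = sum(1.0 / d[v][u] for u in range(n) if u != v and d[v][u] < float("inf")) / (n - 1)
        if deg >= 2:
            sub = a[np.ix_(nbrs, nbrs)]
            ds, _ = _fw_paths(sub)
            pairs = list(itertools.combinations(range(deg), 2))
            leff = sum(1.0 / ds[x][y] for x, y in pairs if ds[x][y] < float("inf")) / len(pairs)
        else:
            leff = 0.0
        rows[v] = (deg, bc, apl, cc, cst, leff, geff)
    return rows


def assert_matches_oracle(g):
    got = compute_measure_set(g)
    want = oracle_measures(g.adjacency)
    for i, lab in enumerate(g.roi_labels):
        np.testing.assert_allclose(
            got.loc[lab, list(MEASURES)].to_numpy(float),
            np.array(want[i]),
            atol=1e-10,
            err_msg=f"node {lab} of graph with edges {g.adjacency.tolist()}",
        )


# --------------------------------------------------------------------------
# single-measure examples


def test_degree_centrality_examples(k3, edgeless3, paw4):
    assert degree_centrality(k3, "a") == 2
    assert degree_centrality(edgeless3, "b") == 0
    assert degree_centrality(paw4, "c") == 3
    with pytest.raises(KeyError):
        degree_centrality(k3, "zz")


def test_betweenness_examples(k3, p3):
    assert betweenness_centrality(p3, "b") == pytest.approx(1.0)
    assert betweenness_centrality(p3, "a") == 0.0
    assert betweenness_centrality(k3, "a") == 0.0


def test_average_path_length_examples(k3, p3):
    assert average_path_length(k3, "a") == pytest.approx(1.0)
    assert average_path_length(p3, "a") == pytest.approx(1.5)
    iso = graph_from_edges(3, [("a", "b")])
    assert average_path_length(iso, "c") == 0.0


def test_clustering_examples(k3, p3, paw4):
    assert clustering_coefficient(k3, "a") == pytest.approx(1.0)
    assert clustering_coefficient(p3, "b") == 0.0
    assert clustering_coefficient(paw4, "c") == pytest.approx(1 / 3)


def test_cost_examples(k3, p3, edgeless3):
    assert cost(k3, "a") == pytest.approx(1.0)
    assert cost(p3, "a") == pytest.approx(0.5)
    assert cost(edgeless3, "a") == 0.0


def test_local_efficiency_examples(k3, p3):
    assert local_efficiency(k3, "a") == pytest.approx(1.0)
    assert local_efficiency(p3, "b") == 0.0
    star_rim = graph_from_edges(4, [("s", "a"), ("s", "b"), ("s", "c"), ("a", "b")], ["s", "a", "b", "c"])
    assert local_efficiency(star_rim, "s") == pytest.approx(1 / 3)


def test_global_efficiency_examples(k3, p3):
    assert global_efficiency(k3, "a") == pytest.approx(1.0)
    assert global_efficiency(p3, "a") == pytest.approx(0.75)
    iso = graph_from_edges(3, [("a", "b")])
    assert global_efficiency(iso, "c") == 0.0


def test_measure_set_k3_and_edgeless(k3, edgeless3):
    row = compute_measure_set(k3).loc["a"]
    np.testing.assert_allclose(row.to_numpy(float), [2, 0, 1, 1, 1, 1, 1])
    assert (compute_measure_set(edgeless3).to_numpy() == 0).all()


# --------------------------------------------------------------------------
# oracle equivalence and structural properties


def test_all_four_node_graphs_match_oracle():
    pairs = list(itertools.combinations(range(4), 2))
    for bits in range(2 ** len(pairs)):
        a = np.zeros((4, 4), dtype=int)
        for p, (i, j) in enumerate(pairs):
            if bits >> p & 1:
                a[i, j] = a[j, i] = 1
        assert_matches_oracle(BrainGraph(a, [f"n{i}" for i in range(4)]))


def test_random_graphs_match_oracle():
    rng = np.random.default_rng(11)
    for _ in range(60):
        n = int(rng.integers(5, 9))
        assert_matches_oracle(random_graph(rng, n, p=float(rng.uniform(0.15, 0.7))))


def test_permutation_equivariance():
    rng = np.random.default_rng(12)
    g = random_graph(rng, 9, 0.35)
    perm = rng.permutation(9)
    a2 = g.adjacency[np.ix_(perm, perm)]
    labels2 = [g.roi_labels[i] for i in perm]
    m1 = compute_measure_set(g)
    m2 = compute_measure_set(BrainGraph(a2, labels2))
    pd.testing.assert_frame_equal(m1.loc[labels2], m2, check_exact=False, atol=1e-12)


def test_edge_addition_monotonicity():
    rng = np.random.default_rng(13)
    for _ in range(15):
        g = random_graph(rng, 7, 0.3)
        m1 = compute_measure_set(g)
        free = np.argwhere(np.triu(g.adjacency == 0, 1))
        free = [p for p in free if p[0] != p[1]]
        if not free:
            continue
        i, j = free[int(rng.integers(len(free)))]
        a2 = g.adjacency.copy()
        a2[i, j] = a2[j, i] = 1
        m2 = compute_measure_set(BrainGraph(a2, g.roi_labels))
        for col in ("degree_centrality", "cost", "global_efficiency"):
            assert (m2[col].to_numpy() >= m1[col].to_numpy() - 1e-12).all()


def test_global_efficiency_is_one_iff_adjacent_to_all(k3, p3):
    m_k3 = compute_measure_set(k3)
    assert np.allclose(m_k3["global_efficiency"], 1.0)
    m_p3 = compute_measure_set(p3)
    assert m_p3.loc["b", "global_efficiency"] == 1.0
    assert m_p3.loc["a", "global_efficiency"] < 1.0


# --------------------------------------------------------------------------
# feature assembly


def test_default_atlas_feature_count_is_1155():
    atlas = default_atlas()
    names = atlas.feature_names()
    assert atlas.n_features == len(names) == 1155
    assert len(set(names)) == 1155


def test_assemble_minimal_atlas_and_global_mean():
    atlas = AtlasConfig(
        atlas_roi_labels=["x"],
        networks={"net": ["n1", "n2", "n3", "n4"]},
        include_global=True,
    )
    assert atlas.n_features == (1 + 4 + 1) * 7 == 42
    roi = pd.DataFrame(np.ones((1, 7)), index=["x"], columns=list(MEASURES))
    net = pd.DataFrame(
        np.tile([[0.0], [0.5], [1.0], [0.5]], (1, 7)), index=["n1", "n2", "n3", "n4"], columns=list(MEASURES)
    )
    values, names = assemble_features(roi, net, atlas)
    assert len(values) == len(names) == 42
    global_block = dict(zip(names[-7:], values[-7:]))
    assert global_block["GLOBAL::clustering_coefficient"] == pytest.approx(0.5)

    atlas_single = AtlasConfig(atlas_roi_labels=["x"], networks={}, include_global=True, global_over="all")
    assert atlas_single.n_features == 14


def test_assemble_reports_missing_nodes():
    atlas = AtlasConfig(atlas_roi_labels=["x", "y"], networks={}, include_global=False)
    roi = pd.DataFrame(np.ones((1, 7)), index=["x"], columns=list(MEASURES))
    with pytest.raises(KeyError, match="y"):
        assemble_features(roi, roi, atlas)


def test_feature_table_tsv_roundtrip(tmp_path):
    rng = np.random.default_rng(14)
    table = FeatureTable(
        data=rng.standard_normal((6, 4)),
        feature_names=[f"n{i}::degree_centrality" for i in range(4)],
        labels=[0, 0, 0, 1, 1, 1],
        group_names=("HC", "EMCI"),
    )
    path = tmp_path / "feat.tsv"
    table.to_tsv(path)
    back = FeatureTable.from_tsv(path, group_names=("HC", "EMCI"))
    np.testing.assert_allclose(back.data, table.data)
    assert back.feature_names == table.feature_names
    assert np.array_equal(back.labels, table.labels)
    assert back.subject_ids == table.subject_ids
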