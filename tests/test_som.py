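"""Batch SOM: convergence fixed points, k-means limit, portraits,
variance map, metagene correlation edges, persistence."""

import numpy as np
import pandas as pd
import pytest

from cdsom import (
    BatchSOM,
    ExpressionMatrix,
    SOMModel,
    metagene_correlation_edges,
    portraits,
    train_som,
    variance_map,
)


def _centralized(values):
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )
    return ExpressionMatrix(df, stage="centralized")


def _toy_model(prototypes, grid, gene_to_node=None, gene_ids=None):
    prototypes = np.asarray(prototypes, dtype=float)
    n_genes = len(gene_to_node) if gene_to_node is not None else prototypes.shape[0]
    return SOMModel(
        gene_ids=gene_ids or [f"g{i}" for i in range(n_genes)],
        sample_ids=[f"s{j}" for j in range(prototypes.shape[1])],
        prototypes=prototypes,
        gene_to_node=np.asarray(
            gene_to_node if gene_to_node is not None else range(prototypes.shape[0])
        ),
        grid_rows=grid[0],
        grid_cols=grid[1],
        training_meta={},
    )


def test_grid_size_sets_prototype_count():
    rng = np.random.default_rng(0)
    m = _centralized(rng.normal(size=(300, 8)))
    model = train_som(m, grid_rows=50, grid_cols=50, epochs=3, seed=0)
    assert model.prototypes.shape == (2500, 8)
    assert model.n_nodes == 2500


def test_single_node_grid_learns_the_mean_gene():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(120, 5))
    model = train_som(_centralized(x), grid_rows=1, grid_cols=1, epochs=5, seed=0)
    np.testing.assert_allclose(model.prototypes[0], x.mean(axis=0), atol=1e-9)


def test_two_cluster_kmeans_limit():
    """With a 1x2 grid and vanishing final radius the batch SOM reduces to
    2-means; prototypes land on the two cluster centroids."""
    rng = np.random.default_rng(2)
    a = rng.normal(0.0, 0.05, size=(60, 4)) + np.array([3, 3, -3, -3])
    b = rng.normal(0.0, 0.05, size=(60, 4)) + np.array([-3, -3, 3, 3])
    x = np.vstack([a, b])
    model = train_som(
        _centralized(x), grid_rows=1, grid_cols=2, epochs=30, seed=0,
        final_radius=1e-3,
    )
    centroids = sorted([a.mean(axis=0), b.mean(axis=0)], key=lambda c: c[0])
    protos = sorted(model.prototypes, key=lambda c: c[0])
    np.testing.assert_allclose(protos[0], centroids[0], atol=1e-6)
    np.testing.assert_allclose(protos[1], centroids[1], atol=1e-6)


def test_zero_radius_update_is_a_fixed_point():
    """At radius ~ 0 each non-empty prototype equals the mean of its
    assigned genes: one extra batch step changes nothing."""
    rng = np.random.default_rng(3)
    centers = rng.normal(0, 5, size=(16, 6))
    x = np.repeat(centers, 25, axis=0) + rng.normal(0, 0.01, size=(400, 6))
    som = BatchSOM(grid_rows=4, grid_cols=4, epochs=60, final_radius=1e-3,
                   random_state=0).fit(x)
    for node in range(16):
        members = x[som.labels_ == node]
        if len(members):
            np.testing.assert_allclose(
                som.prototypes_[node], members.mean(axis=0), atol=1e-6
            )


def test_training_is_deterministic(centralized):
    a = train_som(centralized, grid_rows=8, grid_cols=8, epochs=10, seed=5)
    b = train_som(centralized, grid_rows=8, grid_cols=8, epochs=10, seed=5)
    np.testing.assert_array_equal(a.prototypes, b.prototypes)
    np.testing.assert_array_equal(a.gene_to_node, b.gene_to_node)


def test_quantization_error_non_increasing_late(som_model, centralized):
    som = BatchSOM(grid_rows=20, grid_cols=20, epochs=50, random_state=1).fit(
        centralized.values
    )
    qe = som.quantization_errors_[-10:]
    assert np.all(np.diff(qe) <= 1e-9)


def test_train_som_requires_centralized_stage():
    em = ExpressionMatrix(
        pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"]), stage="raw"
    )
    with pytest.raises(ValueError):
        train_som(em, grid_rows=2, grid_cols=2, epochs=2)


def test_empty_matrix_rejected():
    with pytest.raises(ValueError):
        BatchSOM(grid_rows=2, grid_cols=2).fit(np.empty((0, 4)))


def test_portrait_definitions():
    proto = np.arange(8.0).reshape(4, 2)  # 2x2 grid, 2 samples
    model = _toy_model(proto, (2, 2), gene_to_node=[0, 1, 2, 3])
    grouping = pd.Series({"s0": "x", "s1": "y"})
    ps = portraits(model, grouping=grouping, diff_pairs=[("x", "x"), ("x", "y")])
    by = {(p.kind, p.label): p for p in ps}
    np.testing.assert_allclose(
        by[("sample", "s0")].values, proto[:, 0].reshape(2, 2)
    )
    # singleton group portrait equals the sample portrait
    np.testing.assert_allclose(
        by[("group_mean", "x")].values, by[("sample", "s0")].values
    )
    np.testing.assert_allclose(by[("difference", "x-x")].values, 0.0)
    np.testing.assert_allclose(
        by[("difference", "x-y")].values,
        by[("sample", "s0")].values - by[("sample", "s1")].values,
    )


def test_portraits_reject_unknown_samples():
    model = _toy_model(np.zeros((4, 2)), (2, 2), gene_to_node=[0, 1, 2, 3])
    with pytest.raises(ValueError):
        portraits(model, grouping=pd.Series({"nope": "x"}))


def test_variance_map_basics():
    const = _toy_model(np.ones((4, 3)), (2, 2), gene_to_node=[0, 1, 2, 3])
    np.testing.assert_allclose(variance_map(const).values, 0.0)
    rng = np.random.default_rng(4)
    proto = rng.normal(size=(4, 6))
    m1 = _toy_model(proto, (2, 2), gene_to_node=[0, 1, 2, 3])
    m2 = _toy_model(proto[:, ::-1], (2, 2), gene_to_node=[0, 1, 2, 3])
    np.testing.assert_allclose(variance_map(m1).values, variance_map(m2).values)


def test_variance_map_highlights_planted_modules(som_model, footprints):
    v = variance_map(som_model).values.ravel()
    top_decile = set(np.argsort(-v)[: som_model.n_nodes // 10])
    for lab in "ABCE":  # strongly planted modules
        core = footprints[lab]
        assert len(core & top_decile) / len(core) >= 0.5


def test_correlation_edges_symmetric_unordered():
    rng = np.random.default_rng(5)
    proto = rng.normal(size=(9, 12))
    model = _toy_model(proto, (3, 3), gene_to_node=list(range(9)))
    edges = metagene_correlation_edges(model, 0.0)
    pairs = {(u, v) for u, v, _ in edges}
    assert len(pairs) == 9 * 8 // 2  # every unordered pair once, no self pairs
    assert all(u < v for u, v in pairs)


def test_correlation_edges_exclude_zero_variance_nodes():
    proto = np.vstack([np.zeros(5), np.arange(5.0), -np.arange(5.0), np.ones(5)])
    model = _toy_model(proto, (2, 2), gene_to_node=[0, 1, 2, 3])
    with pytest.warns(UserWarning):
        edges = metagene_correlation_edges(model, 0.9)
    assert {(u, v) for u, v, _ in edges} == {(1, 2)}
    assert edges[0][2] == pytest.approx(-1.0)


def test_crypt_blocks_anticorrelate(som_model, truth):
    """The planted upper- and lower-crypt blocks are antagonistic: their
    central metagenes correlate strongly negatively."""
    g2n = dict(zip(som_model.gene_ids, som_model.gene_to_node))
    upper = sorted({int(g2n[g]) for g in truth.crypt_genes["upper_crypt"]})
    lower = sorted({int(g2n[g]) for g in truth.crypt_genes["lower_crypt"]})
    r = np.corrcoef(
        som_model.prototypes[upper].mean(axis=0),
        som_model.prototypes[lower].mean(axis=0),
    )[0, 1]
    assert r <= -0.8


def test_topology_preservation(som_model):
    r = np.corrcoef(som_model.prototypes)
    rows, cols = np.divmod(np.arange(som_model.n_nodes), som_model.grid_cols)
    adjacent = []
    for i in range(som_model.n_nodes):
        j = i + 1
        if (i + 1) % som_model.grid_cols:
            adjacent.append(r[i, i + 1])
        j = i + som_model.grid_cols
        if j < som_model.n_nodes:
            adjacent.append(r[i, j])
    rng = np.random.default_rng(0)
    ii = rng.integers(0, som_model.n_nodes, 4000)
    jj = rng.integers(0, som_model.n_nodes, 4000)
    random_pairs = [r[a, b] for a, b in zip(ii, jj) if a != b]
    assert np.mean(adjacent) > np.mean(random_pairs)


def test_model_save_load_roundtrip(tmp_path):
    rng = np.random.default_rng(6)
    m = _centralized(rng.normal(size=(50, 4)))
    model = train_som(m, grid_rows=3, grid_cols=3, epochs=5, seed=2)
    model.save(tmp_path / "som")
    loaded = SOMModel.load(tmp_path / "som")
    np.testing.assert_allclose(loaded.prototypes, model.prototypes)
    np.testing.assert_array_equal(loaded.gene_to_node, model.gene_to_node)
    assert loaded.sample_ids == model.sample_ids
    assert (loaded.grid_rows, loaded.grid_cols) == (3, 3)
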