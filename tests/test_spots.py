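"""Spot segmentation: summary map, flood-fill equivalence, activation,
co-occurrence, gene-list accumulation/depletion."""

from collections import deque

import numpy as np
import pandas as pd
import pytest

from cdsom import (
    Portrait,
    detect_spots,
    gene_list_spot_association,
    overexpression_summary_map,
    spot_activation_table,
    spot_cooccurrence,
)
from tests.test_som import _toy_model


def _floodfill_components(mask):
    """Independent 8-connected component oracle (BFS flood fill)."""
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] and not seen[r, c]:
                comp = set()
                q = deque([(r, c)])
                seen[r, c] = True
                while q:
                    y, x = q.popleft()
                    comp.add(y * mask.shape[1] + x)
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if (
                                0 <= yy < mask.shape[0]
                                and 0 <= xx < mask.shape[1]
                                and mask[yy, xx]
                                and not seen[yy, xx]
                            ):
                                seen[yy, xx] = True
                                q.append((yy, xx))
                comps.append(comp)
    return comps


def test_summary_map_is_pointwise_max(som_model):
    summary = overexpression_summary_map(som_model)
    for j in range(0, som_model.n_samples, 9):
        portrait = som_model.prototypes[:, j].reshape(summary.values.shape)
        assert (summary.values >= portrait - 1e-12).all()
    np.testing.assert_allclose(
        summary.values.ravel(), som_model.prototypes.max(axis=1)
    )


def test_summary_of_single_sample_model_equals_its_portrait():
    proto = np.arange(9.0).reshape(9, 1)
    model = _toy_model(proto, (3, 3), gene_to_node=list(range(9)))
    summary = overexpression_summary_map(model)
    np.testing.assert_allclose(summary.values, proto.reshape(3, 3))


def test_summary_peak_inside_a_planted_module(som_model, footprints):
    summary = overexpression_summary_map(som_model)
    peak = int(np.argmax(summary.values.ravel()))
    assert any(peak in nodes for nodes in footprints.values())


def test_constant_map_yields_no_spots():
    spots = detect_spots(Portrait(np.ones((10, 10)), "c", "summary"))
    assert len(spots) == 0


def test_detect_spots_matches_floodfill_oracle():
    rng = np.random.default_rng(0)
    values = rng.normal(0, 0.01, size=(15, 15))
    values[2:5, 2:5] += 10.0
    values[10:14, 9:13] += 8.0
    spots = detect_spots(
        Portrait(values, "two bumps", "summary"), quantile_threshold=0.85, min_size=5
    )
    mask = values > np.quantile(values, 0.85)
    oracle = [c for c in _floodfill_components(mask) if len(c) >= 5]
    assert len(spots) == len(oracle) == 2
    assert {frozenset(s.member_nodes) for s in spots} == {
        frozenset(c) for c in oracle
    }
    # labels ordered by decreasing peak height
    assert spots.spots[0].peak_height >= spots.spots[1].peak_height
    assert spots.labels == ["A", "B"]


def test_small_components_are_discarded():
    values = np.zeros((10, 10))
    values[0, 0:3] = 5.0  # 3-node component < min_size
    spots = detect_spots(
        Portrait(values, "tiny", "summary"), quantile_threshold=0.9, min_size=5
    )
    assert len(spots) == 0


def test_detection_invariant_to_additive_constant():
    rng = np.random.default_rng(1)
    values = rng.normal(size=(12, 12))
    values[4:8, 4:8] += 6.0
    a = detect_spots(Portrait(values, "a", "summary"), quantile_threshold=0.9)
    b = detect_spots(Portrait(values + 17.3, "b", "summary"), quantile_threshold=0.9)
    assert [s.member_nodes for s in a] == [s.member_nodes for s in b]


def test_spot_nodes_are_disjoint_and_profiles_recompute(som_model):
    summary = overexpression_summary_map(som_model)
    spots = detect_spots(summary, som_model, quantile_threshold=0.92)
    assert len(spots) >= 2
    seen = set()
    for s in spots:
        assert not (s.member_nodes & seen)
        seen |= s.member_nodes
        np.testing.assert_allclose(
            s.profile,
            som_model.prototypes[sorted(s.member_nodes)].mean(axis=0),
        )
        assert set(s.member_genes) == set(
            som_model.genes_in_nodes(s.member_nodes)
        )


def test_activation_table_definition():
    # sample 0 hot exactly on nodes {0,1}; sample 1 hot elsewhere
    rng = np.random.default_rng(9)
    proto = rng.normal(0.0, 0.01, size=(16, 2))  # tiny jitter avoids rank ties
    proto[[0, 1], 0] = 5.0
    proto[[10, 11], 1] = 5.0
    model = _toy_model(proto, (4, 4), gene_to_node=list(range(16)))
    summary = overexpression_summary_map(model)
    spots = detect_spots(summary, model, quantile_threshold=0.75, min_size=2)
    table = spot_activation_table(spots, model, top_fraction=0.2, member_fraction=0.5)
    assert set(table.to_numpy().ravel()) <= {0, 1}
    assert table.shape == (len(spots), 2)
    for s in spots:
        hot_sample = "s0" if 0 in s.member_nodes else "s1"
        assert table.loc[s.label, hot_sample] == 1
        other = "s1" if hot_sample == "s0" else "s0"
        assert table.loc[s.label, other] == 0


def test_planted_severe_module_active_in_severe_group(som_model, truth):
    summary = overexpression_summary_map(som_model)
    spots = detect_spots(summary, som_model, quantile_threshold=0.92)
    e_genes = set(truth.module_genes("E"))
    e_spot = max(spots, key=lambda s: len(set(s.member_genes) & e_genes))
    table = spot_activation_table(spots, som_model)
    cdh = truth.group_labels.index[truth.group_labels == "CD-H"]
    assert table.loc[e_spot.label, cdh].mean() >= 0.8


def test_cooccurrence_counts_and_implication():
    activation = pd.DataFrame(
        [[1, 1, 1, 0], [1, 1, 1, 0], [0, 1, 0, 0]],
        index=["A", "B", "C"],
        columns=list("wxyz"),
    )
    counts, implication = spot_cooccurrence(activation)
    assert counts.loc["A", "A"] == 3  # diagonal = frequency
    assert counts.equals(counts.T)
    # A and B always co-active -> implication 1.0 both directions
    assert implication.loc["A", "B"] == 1.0
    assert implication.loc["B", "A"] == 1.0
    assert implication.loc["C", "A"] == 1.0
    assert implication.loc["A", "C"] == pytest.approx(1 / 3)


def test_never_active_spot_implies_nothing():
    activation = pd.DataFrame(
        [[0, 0], [1, 1]], index=["A", "B"], columns=["x", "y"]
    )
    _, implication = spot_cooccurrence(activation)
    assert implication.loc["A", "B"] == 0.0


def test_gene_list_association_own_genes_accumulate(som_model):
    summary = overexpression_summary_map(som_model)
    spots = detect_spots(summary, som_model, quantile_threshold=0.92)
    target = spots.spots[0]
    report = gene_list_spot_association(
        spots, som_model, set(target.member_genes), som_model.gene_ids
    )
    assert report.loc[target.label, "call"] == "accumulated"
    assert report["p"].idxmin() == target.label


def test_gene_list_association_rejects_bad_input(som_model):
    summary = overexpression_summary_map(som_model)
    spots = detect_spots(summary, som_model, quantile_threshold=0.92)
    with pytest.raises(ValueError):
        gene_list_spot_association(spots, som_model, set(), som_model.gene_ids)
    with pytest.raises(ValueError):
        gene_list_spot_association(
            spots, som_model, {"NOT_A_GENE"}, som_model.gene_ids
        )


def test_large_disjoint_list_depletes(som_model):
    summary = overexpression_summary_map(som_model)
    spots = detect_spots(summary, som_model, quantile_threshold=0.92)
    spot_genes = set().union(*(s.member_genes for s in spots))
    gene_list = [g for g in som_model.gene_ids if g not in spot_genes][:3000]
    report = gene_list_spot_association(
        spots, som_model, gene_list, som_model.gene_ids
    )
    assert (report["call"] == "depleted").all()
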