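import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyview import (
    SpatialSample,
    build_celltype_views,
    build_intraview,
    build_juxtaview,
    build_paraview,
    delaunay_neighbors,
    juxta_cutoff,
    paraview_weight,
)

from conftest import make_sample


# --- intraview -------------------------------------------------------------


def test_intraview_is_expression_verbatim(small_sample):
    view = build_intraview(small_sample)
    np.testing.assert_array_equal(view.features, small_sample.expression)
    assert view.feature_names == small_sample.markers
    assert view.drop_target


# --- neighbor graph --------------------------------------------------------


UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])


def test_delaunay_unit_square_prunes_diagonal():
    graph = delaunay_neighbors(UNIT_SQUARE, cutoff=1.05)
    # four perimeter edges; the sqrt(2) diagonal is pruned
    assert graph.edges == {(0, 1), (0, 2), (1, 3), (2, 3)}


def test_delaunay_unit_square_keeps_one_diagonal():
    graph = delaunay_neighbors(UNIT_SQUARE, cutoff=2.0)
    # the triangulation contains exactly one of the two diagonals
    assert len(graph.edges) == 5
    assert len(graph.edges & {(0, 3), (1, 2)}) == 1


def test_delaunay_triangle():
    pts = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 1.5]])
    graph = delaunay_neighbors(pts, cutoff=np.inf)
    assert graph.edges == {(0, 1), (0, 2), (1, 2)}


def test_delaunay_collinear_falls_back_to_distance_graph():
    pts = np.column_stack([np.arange(4.0), np.zeros(4)])
    graph = delaunay_neighbors(pts, cutoff=1.5)
    assert graph.edges == {(0, 1), (1, 2), (2, 3)}


# --- juxta cutoff ----------------------------------------------------------


def test_pairwise_quantile_single_distance():
    s = SpatialSample(
        positions=[[0.0, 0.0], [4.0, 0.0]],
        expression=[[1.0, 2.0], [3.0, 4.0]],
        markers=["a", "b"],
    )
    assert juxta_cutoff([s], "pairwise_quantile", 0.25) == pytest.approx(4.0)


def test_neighbor_quantile_matches_edge_enumeration():
    # near-collinear chain of 4 points, spacing ~1: enumerate the Delaunay
    # edges by brute force and take the quantile directly
    pos = np.array([[0.0, 0.0], [1.0, 0.01], [2.0, 0.0], [3.0, 0.01]])
    s = SpatialSample(pos, np.ones((4, 2)), ["a", "b"])
    graph = delaunay_neighbors(pos, cutoff=np.inf)
    lengths = [np.linalg.norm(pos[i] - pos[j]) for i, j in graph.edges]
    expected = np.quantile(lengths, 0.75)
    assert juxta_cutoff([s], "neighbor_quantile", 0.75) == pytest.approx(expected)


# --- juxtaview -------------------------------------------------------------


def test_juxtaview_two_cell_case_and_isolated_unit():
    s = SpatialSample(
        positions=[[0.0, 0.0], [1.0, 0.0], [50.0, 50.0]],
        expression=[[1.0, 2.0], [3.0, 4.0], [9.0, 9.0]],
        markers=["a", "b"],
    )
    graph = delaunay_neighbors(s.positions, cutoff=2.0)
    view = build_juxtaview(s, graph)
    np.testing.assert_allclose(view.features[0], [3.0, 4.0])
    np.testing.assert_allclose(view.features[1], [1.0, 2.0])
    np.testing.assert_allclose(view.features[2], [0.0, 0.0])  # isolated


def test_juxtaview_matches_double_loop_oracle():
    s = make_sample(n_units=20, n_markers=3, seed=7)
    graph = delaunay_neighbors(s.positions, cutoff=4.0)
    view = build_juxtaview(s, graph)
    adj = graph.neighbors()
    expected = np.zeros_like(s.expression)
    for i in range(s.n_units):
        for j in adj[i]:
            expected[i] += s.expression[j]
    np.testing.assert_allclose(view.features, expected, atol=1e-10)


# --- paraview weights ------------------------------------------------------


def test_paraview_weight_closed_forms():
    assert paraview_weight(0.0, "gaussian", 2.0) == pytest.approx(1.0)
    assert paraview_weight(2.0, "gaussian", 2.0) == pytest.approx(np.exp(-1))
    assert paraview_weight(2.0, "exponential", 2.0) == pytest.approx(np.exp(-1))
    assert paraview_weight(1.5, "constant", 1.0) == 0.0
    assert paraview_weight(2.0, "linear", 1.0) == 0.0  # clamped, not negative
    assert paraview_weight(0.5, "linear", 1.0) == pytest.approx(0.5)


def test_zone_of_indifference_blanks_short_distances():
    for family in ("gaussian", "exponential", "linear", "constant"):
        assert paraview_weight(1.0, family, l=5.0, z=2.0) == 0.0
        assert paraview_weight(2.0, family, l=5.0, z=2.0) > 0.0  # boundary in


def test_paraview_weight_rejects_bad_scale():
    with pytest.raises(ValueError):
        paraview_weight(1.0, "gaussian", l=0.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    d1=st.floats(0.0, 50.0),
    step=st.floats(0.01, 10.0),
    l=st.floats(0.1, 20.0),
    family=st.sampled_from(["gaussian", "exponential", "linear", "constant"]),
)
def test_paraview_weight_nonincreasing_in_distance(d1, step, l, family):
    assert paraview_weight(d1, family, l) >= paraview_weight(d1 + step, family, l)


# --- paraview --------------------------------------------------------------


def test_paraview_three_collinear_constant_family():
    s = SpatialSample(
        positions=[[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]],
        expression=[[1.0, 10.0], [2.0, 20.0], [4.0, 40.0]],
        markers=["a", "b"],
    )
    view = build_paraview(s, family="constant", l=1.0, z=0.0)
    np.testing.assert_allclose(view.features[0], [2.0, 20.0])  # sees middle
    np.testing.assert_allclose(view.features[2], [2.0, 20.0])
    np.testing.assert_allclose(view.features[1], [5.0, 50.0])  # both ends


def test_paraview_matches_double_loop_oracle():
    s = make_sample(n_units=30, n_markers=3, seed=9)
    view = build_paraview(s, family="gaussian", l=10.0, z=1.0)
    expected = np.zeros_like(s.expression)
    for i in range(s.n_units):
        for j in range(s.n_units):
            if i == j:
                continue
            d = np.linalg.norm(s.positions[i] - s.positions[j])
            w = np.exp(-(d**2) / 100.0) if d >= 1.0 else 0.0
            expected[i] += w * s.expression[j]
    np.testing.assert_allclose(view.features, expected, atol=1e-10)


def test_paraview_excludes_own_row():
    s = SpatialSample(
        positions=[[0.0, 0.0]] * 1 + [[100.0, 100.0]],
        expression=[[5.0, 5.0], [1.0, 1.0]],
        markers=["a", "b"],
    )
    view = build_paraview(s, family="gaussian", l=1.0, z=0.0)
    # the far-away unit contributes a truncated-to-zero weight; the unit's
    # own expression never enters its paraview row
    np.testing.assert_allclose(view.features[0], [0.0, 0.0])


def test_views_are_linear_in_expression():
    s = make_sample(n_units=25, n_markers=3, seed=5)
    scaled = SpatialSample(
        s.positions, 3.0 * s.expression, list(s.markers)
    )
    graph = delaunay_neighbors(s.positions, cutoff=5.0)
    for builder in (
        lambda x: build_juxtaview(x, graph),
        lambda x: build_paraview(x, family="exponential", l=5.0),
    ):
        np.testing.assert_allclose(
            builder(scaled).features, 3.0 * builder(s).features, rtol=1e-10
        )


def test_zone_equal_to_cutoff_separates_juxta_and_para():
    # with z set to the juxta cutoff, no unit pair contributes to both views
    s = make_sample(n_units=40, n_markers=2, seed=11)
    cutoff = juxta_cutoff([s], "pairwise_quantile", 0.25)
    graph = delaunay_neighbors(s.positions, cutoff=cutoff)
    adj = graph.neighbors()
    for i in range(s.n_units):
        for j in range(s.n_units):
            if i == j:
                continue
            d = np.linalg.norm(s.positions[i] - s.positions[j])
            in_juxta = j in adj[i]
            in_para = paraview_weight(d, "gaussian", l=10.0, z=cutoff) > 0
            assert not (in_juxta and in_para)


# --- cell-type views -------------------------------------------------------


def test_celltype_views_onehot_and_neighbor_counts():
    s = SpatialSample(
        positions=[[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]],
        expression=np.ones((4, 2)),
        markers=["a", "b"],
        celltype=["ct1", "ct1", "ct3", "ct2"],
    )
    graph = delaunay_neighbors(s.positions, cutoff=1.05)  # perimeter edges
    intra, juxta = build_celltype_views(
        s, graph, types=["ct1", "ct2", "ct3", "ct4"]
    )
    np.testing.assert_array_equal(
        intra.features,
        [[1, 0, 0, 0], [1, 0, 0, 0], [0, 0, 1, 0], [0, 1, 0, 0]],
    )
    # unit 0 neighbors: 1 (ct1) and 2 (ct3)
    np.testing.assert_array_equal(juxta.features[0], [1, 0, 1, 0])
    # one-hot column sums equal per-type abundances
    np.testing.assert_array_equal(intra.features.sum(axis=0), [2, 1, 1, 0])
    assert not juxta.drop_target


def test_celltype_views_require_labels(small_sample):
    graph = delaunay_neighbors(small_sample.positions, cutoff=np.inf)
    with pytest.raises(ValueError, match="cell-type"):
        build_celltype_views(small_sample, graph)
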