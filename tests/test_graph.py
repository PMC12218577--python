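"""Graph core: topology building, strict interfaces, path composition,
gradients through composed paths, and fine-tuning with frozen edges."""

import numpy as np
import pytest

from modgraph import DataSpace, build_default_ad_graph, compose_path, path_gradient
from modgraph.autodiff import Tensor
from modgraph.default_graph import GraphConfig
from modgraph.graph import (AmbiguousEdgeError, ContractViolationError,
                            FunctionEdge, GraphConfigError, LinearMapEdge,
                            ModelGraph, PathError, SpaceMismatchError,
                            finetune_path)


def vec_space(name, n):
    return DataSpace(name, "feature_vector", (n,))


def linear_graph(matrices):
    """Chain n1 -> n2 -> ... with LinearMapEdges for the given matrices."""
    g = ModelGraph()
    dims = [matrices[0].shape[1]] + [m.shape[0] for m in matrices]
    for i, d in enumerate(dims):
        g.add_node(f"n{i + 1}", vec_space(f"s{i + 1}", d))
    for i, m in enumerate(matrices):
        g.add_edge(f"e{i + 1}", f"n{i + 1}", f"n{i + 2}",
                   LinearMapEdge(vec_space(f"s{i + 1}", m.shape[1]),
                                 vec_space(f"s{i + 2}", m.shape[0]), m))
    return g


class TestDefaultGraph:
    def test_default_topology_counts(self):
        g = build_default_ad_graph()
        assert g.n_nodes == 11
        assert g.n_edges == 14
        assert len(g.enumerate_paths()) == 11

    def test_missing_dimension_names_the_affected_nodes(self):
        with pytest.raises(GraphConfigError, match="roi"):
            build_default_ad_graph({"image_side": 16, "n_slices": 4})

    def test_seven_classifier_outputs_feed_the_fusion_input(self):
        g = build_default_ad_graph()
        feeders = g.feeder_edges["scores"]
        assert len(feeders) == 7
        for eid in feeders:
            assert g.edges[eid].target == "label"
            assert g.edges[eid].transform.output_space.kind == "probability_pair"

    def test_topology_yaml_roundtrip(self, tmp_path):
        g = build_default_ad_graph(GraphConfig(image_side=16, n_slices=4))
        path = tmp_path / "graph.yaml"
        g.to_yaml(path)

        def factory(edge_dict, src, tgt):
            return FunctionEdge(src, tgt, lambda x: x)

        # rebuilding uses only the document, not the original object
        g2 = ModelGraph.from_yaml(path, factory)
        assert g2.topology_dict()["nodes"] == g.topology_dict()["nodes"]
        assert {e["id"] for e in g2.topology_dict()["edges"]} == set(g.edges)
        assert g2.enumerate_paths() == g.enumerate_paths()


class TestInterfaceStrictness:
    def test_space_mismatch_raises_before_any_computation(self):
        g = ModelGraph()
        g.add_node("a", vec_space("a", 3))
        g.add_node("b", vec_space("b", 2))
        bad = LinearMapEdge(vec_space("a", 4), vec_space("b", 2), np.zeros((2, 4)))
        with pytest.raises(SpaceMismatchError):
            g.add_edge("e", "a", "b", bad)

    def test_kind_mismatch_rejected(self):
        g = ModelGraph()
        g.add_node("a", vec_space("a", 2))
        g.add_node("b", DataSpace("b", "probability_pair", (2,)))
        edge = LinearMapEdge(vec_space("a", 2), vec_space("b", 2), np.eye(2))
        with pytest.raises(SpaceMismatchError):
            g.add_edge("e", "a", "b", edge)

    def test_duplicate_ids_rejected(self):
        g = ModelGraph()
        g.add_node("a", vec_space("a", 2))
        with pytest.raises(GraphConfigError):
            g.add_node("a", vec_space("a", 2))


class TestComposePath:
    def test_single_node_path_is_identity(self):
        g = linear_graph([np.eye(2)])
        p = compose_path(g, ["n1"])
        x = np.array([0.3, -1.2])
        np.testing.assert_array_equal(p(x), x)

    def test_two_linear_edges_compose_to_matrix_product(self):
        # hand oracle: B @ (A @ x)
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        b = np.array([[0.5, -1.0], [2.0, 0.0]])
        g = linear_graph([a, b])
        p = compose_path(g, ["n1", "n2", "n3"])
        x = np.array([1.0, -2.0])
        np.testing.assert_allclose(p(x), b @ a @ x, atol=1e-12)

    def test_missing_edge_raises_path_error(self):
        g = linear_graph([np.eye(2), np.eye(2)])
        with pytest.raises(PathError, match="n1.*n3"):
            compose_path(g, ["n1", "n3"])

    def test_parallel_edges_require_disambiguation(self):
        g = linear_graph([np.eye(2)])
        g.add_edge("e_alt", "n1", "n2",
                   LinearMapEdge(vec_space("s1", 2), vec_space("s2", 2),
                                 2 * np.eye(2)))
        with pytest.raises(AmbiguousEdgeError):
            compose_path(g, ["n1", "n2"])
        p = compose_path(g, ["n1", "n2"], edge_ids=["e_alt"])
        np.testing.assert_allclose(p(np.array([1.0, 1.0])), [2.0, 2.0])

    def test_composition_associativity(self):
        rng = np.random.default_rng(0)
        mats = [rng.normal(size=(3, 4)), rng.normal(size=(2, 3))]
        g = linear_graph(mats)
        full = compose_path(g, ["n1", "n2", "n3"])
        first = compose_path(g, ["n1", "n2"])
        second = compose_path(g, ["n2", "n3"])
        x = rng.normal(size=4)
        np.testing.assert_allclose(full(x), second(first(x)), atol=1e-6)


class TestPathGradient:
    def test_linear_chain_gradient_is_column_sums(self):
        # d/dx sum(B A x) = (B A)^T 1 = column sums of B A
        a = np.array([[1.0, -2.0], [0.5, 3.0]])
        b = np.array([[2.0, 1.0], [-1.0, 4.0]])
        g = linear_graph([a, b])
        p = compose_path(g, ["n1", "n2", "n3"])
        grad = path_gradient(p, np.array([0.7, -0.3]), target_scalar="sum")
        np.testing.assert_allclose(grad, (b @ a).sum(axis=0), atol=1e-12)

    def test_constant_edge_gives_zero_gradient(self):
        g = ModelGraph()
        g.add_node("a", vec_space("a", 3))
        g.add_node("b", vec_space("b", 2))
        g.add_edge("const", "a", "b",
                   FunctionEdge(vec_space("a", 3), vec_space("b", 2),
                                lambda x: Tensor(np.ones(2)) * 1.0))
        p = compose_path(g, ["a", "b"])
        grad = path_gradient(p, np.array([1.0, 2.0, 3.0]), target_scalar="sum")
        np.testing.assert_array_equal(grad, np.zeros(3))

    def test_nondifferentiable_edge_refused(self):
        g = ModelGraph()
        g.add_node("a", vec_space("a", 2))
        g.add_node("b", vec_space("b", 2))
        g.add_edge("sampler", "a", "b",
                   FunctionEdge(vec_space("a", 2), vec_space("b", 2),
                                lambda x: x, differentiable=False))
        p = compose_path(g, ["a", "b"])
        with pytest.raises(ContractViolationError):
            path_gradient(p, np.zeros(2), target_scalar="sum")

    def test_gradient_matches_finite_differences_on_smooth_path(self):
        # nonlinear two-edge toy path vs central differences
        rng = np.random.default_rng(1)
        a = rng.normal(size=(3, 3))
        g = ModelGraph()
        g.add_node("a", vec_space("a", 3))
        g.add_node("b", vec_space("b", 3))
        g.add_node("c", vec_space("c", 3))
        g.add_edge("lin", "a", "b",
                   LinearMapEdge(vec_space("a", 3), vec_space("b", 3), a))
        g.add_edge("tanh", "b", "c",
                   FunctionEdge(vec_space("b", 3), vec_space("c", 3),
                                lambda x: x.tanh()))
        p = compose_path(g, ["a", "b", "c"])
        x = rng.normal(size=3)
        grad = path_gradient(p, x, target_scalar="sum")
        step = 1e-4
        for i in range(3):
            e = np.zeros(3)
            e[i] = step
            numeric = (p(x + e).sum() - p(x - e).sum()) / (2 * step)
            assert grad[i] == pytest.approx(numeric, rel=1e-4)


class TestFinetunePath:
    def _regression_graph(self, rng):
        a = rng.normal(size=(2, 2))
        return linear_graph([a])

    def test_freeze_all_is_warned_noop(self):
        rng = np.random.default_rng(0)
        g = self._regression_graph(rng)
        p = compose_path(g, ["n1", "n2"])
        before = g.edges["e1"].transform.matrix.data.copy()
        with pytest.warns(UserWarning):
            report = finetune_path(p, [(np.zeros(2), np.zeros(2))], frozen={"e1"})
        assert report["no_op"]
        np.testing.assert_array_equal(g.edges["e1"].transform.matrix.data, before)

    def test_single_linear_edge_reaches_least_squares_solution(self):
        # exact line target: y = W* x, loss must go to ~0
        rng = np.random.default_rng(3)
        w_star = np.array([[2.0, -1.0], [0.5, 1.5]])
        g = self._regression_graph(rng)
        p = compose_path(g, ["n1", "n2"])
        data = [(x, w_star @ x) for x in rng.normal(size=(16, 2))]
        report = finetune_path(p, data, loss="mse", epochs=400, lr=5e-2)
        assert report["losses"][-1] < 1e-4
        assert report["losses"][-1] <= report["losses"][0]

    def test_frozen_first_edge_unchanged_second_updated(self):
        rng = np.random.default_rng(5)
        g = linear_graph([rng.normal(size=(2, 2)), rng.normal(size=(2, 2))])
        p = compose_path(g, ["n1", "n2", "n3"])
        first_before = g.edges["e1"].transform.matrix.data.copy()
        second_before = g.edges["e2"].transform.matrix.data.copy()
        data = [(x, np.array([1.0, -1.0])) for x in rng.normal(size=(8, 2))]
        report = finetune_path(p, data, loss="mse", frozen={"e1"}, epochs=5)
        assert report["updated_edges"] == ["e2"]
        np.testing.assert_array_equal(g.edges["e1"].transform.matrix.data, first_before)
        assert not np.array_equal(g.edges["e2"].transform.matrix.data, second_before)
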