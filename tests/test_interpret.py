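"""Attribution: full-gradient completeness and closed forms, Shapley axioms
(efficiency, symmetry, null player), sampling agreement, and first-layer
weight importance arithmetic."""

import numpy as np
import pytest

from modgraph.autodiff import Tensor
from modgraph.autodiff import nn
from modgraph.cohort import MODALITIES
from modgraph.fusion import MASK_FILL, FusionMLP, ScoreVector
from modgraph.graph import (ContractViolationError, FunctionEdge,
                            LinearMapEdge, ModelGraph, compose_path)
from modgraph.interpret import (fullgrad_decomposition, fullgrad_saliency,
                                layer1_importance, shapley_modalities,
                                shapley_modalities_sampled)
from modgraph.spaces import DataSpace


def vec_space(name, n):
    return DataSpace(name, "feature_vector", (n,))


class TestFullGrad:
    def test_bias_free_linear_map_gives_w_times_x(self):
        w = np.array([[0.5, -2.0, 1.5]])
        g = ModelGraph()
        g.add_node("a", vec_space("a", 3))
        g.add_node("b", vec_space("b", 1))
        g.add_edge("lin", "a", "b",
                   LinearMapEdge(vec_space("a", 3), vec_space("b", 1), w))
        p = compose_path(g, ["a", "b"])
        x = np.array([2.0, 1.0, -1.0])
        amap = fullgrad_saliency(p, x, target_class=0)
        expected = np.abs(w[0] * x)
        expected = expected / expected.max()
        np.testing.assert_allclose(amap.values["a"], expected, atol=1e-12)

    def test_zero_input_and_zero_biases_give_zero_map(self):
        rng = np.random.default_rng(0)
        mlp = nn.Sequential(nn.Linear(4, 6, rng), nn.ReLU(),
                            nn.Linear(6, 2, rng))
        for layer in (mlp.layers[0], mlp.layers[2]):
            layer.bias.data[:] = 0.0
        g = ModelGraph()
        g.add_node("a", vec_space("a", 4))
        g.add_node("b", vec_space("b", 2))
        g.add_edge("net", "a", "b",
                   FunctionEdge(vec_space("a", 4), vec_space("b", 2),
                                lambda x: mlp(x.reshape(1, 4)).reshape(2)))
        p = compose_path(g, ["a", "b"])
        amap = fullgrad_saliency(p, np.zeros(4), target_class=1)
        np.testing.assert_array_equal(amap.values["a"], np.zeros(4))

    def test_raw_decomposition_complete_on_three_layer_relu_net(self):
        # f(x) = x . grad_x f + sum_b b . grad_b f must hold to 1e-5
        rng = np.random.default_rng(1)
        net = nn.Sequential(nn.Linear(6, 12, rng), nn.ReLU(),
                            nn.Linear(12, 8, rng), nn.ReLU(),
                            nn.Linear(8, 1, rng))
        for seed in range(5):
            x = np.random.default_rng(seed).normal(size=(1, 6))
            f_val, input_term, bias_terms = fullgrad_decomposition(
                lambda t: net(t), x)
            reconstruction = input_term + sum(bias_terms.values())
            assert reconstruction == pytest.approx(f_val, abs=1e-5)

    def test_sampling_edge_refused(self):
        g = ModelGraph()
        g.add_node("a", vec_space("a", 2))
        g.add_node("b", vec_space("b", 2))
        g.add_edge("sampler", "a", "b",
                   FunctionEdge(vec_space("a", 2), vec_space("b", 2),
                                lambda x: x, differentiable=False))
        p = compose_path(g, ["a", "b"])
        with pytest.raises(ContractViolationError):
            fullgrad_saliency(p, np.zeros(2))

    def test_map_rescaled_to_unit_interval(self):
        rng = np.random.default_rng(2)
        mlp = nn.Sequential(nn.Linear(5, 8, rng), nn.ReLU(), nn.Linear(8, 2, rng))
        g = ModelGraph()
        g.add_node("a", vec_space("a", 5))
        g.add_node("b", vec_space("b", 2))
        g.add_edge("net", "a", "b",
                   FunctionEdge(vec_space("a", 5), vec_space("b", 2),
                                lambda x: mlp(x.reshape(1, 5)).reshape(2)))
        p = compose_path(g, ["a", "b"])
        amap = fullgrad_saliency(p, rng.normal(size=5), target_class=0)
        vals = amap.values["a"]
        assert vals.min() >= 0.0 and vals.max() == pytest.approx(1.0)


class TestLayer1Importance:
    def test_uniform_weights_give_equal_importance(self, rng):
        mlp = FusionMLP(rng)
        mlp.fc1.weight.data = np.full_like(mlp.fc1.weight.data, 0.3)
        amap = layer1_importance(mlp)
        values = [float(v) for v in amap.values.values()]
        assert len(set(np.round(values, 12))) == 1

    def test_zeroed_group_columns_give_zero_importance(self, rng):
        mlp = FusionMLP(rng)
        before = layer1_importance(mlp)
        g = MODALITIES.index("gene")
        mlp.fc1.weight.data[2 * g:2 * g + 2, :] = 0.0
        after = layer1_importance(mlp)
        assert float(after.values["gene"]) == 0.0
        for m in MODALITIES:
            if m != "gene":
                assert float(after.values[m]) == pytest.approx(
                    float(before.values[m]))

    def test_hand_written_first_layer_matches_arithmetic(self, rng):
        mlp = FusionMLP(rng)
        w = np.zeros((14, 256))
        w[:, 0] = np.arange(14)  # only first hidden unit carries weight
        mlp.fc1.weight.data = w
        amap = layer1_importance(mlp)
        for g, m in enumerate(MODALITIES):
            expected = (abs(2 * g) + abs(2 * g + 1)) / (2 * 256)
            assert float(amap.values[m]) == pytest.approx(expected)


class TestShapley:
    @pytest.fixture()
    def trained_like_mlp(self, rng):
        # random weights suffice; the axioms hold for any fixed model
        return FusionMLP(rng)

    def _sv(self, seed=0):
        r = np.random.default_rng(seed)
        p = r.random(7)
        scores = np.stack([[1 - v, v] for v in p])
        return ScoreVector(scores=scores, available=np.ones(7, bool),
                           label="AD", subject="s")

    def test_efficiency_axiom(self, trained_like_mlp):
        for seed in range(10):
            sv = self._sv(seed)
            amap = shapley_modalities(trained_like_mlp, sv)
            full = trained_like_mlp.predict_proba(sv.flat())[0, 1]
            empty = trained_like_mlp.predict_proba(np.full(14, MASK_FILL))[0, 1]
            assert sum(float(v) for v in amap.values.values()) == \
                pytest.approx(full - empty, abs=1e-6)

    def test_symmetry_axiom_for_identical_groups(self, rng):
        mlp = FusionMLP(rng)
        # make the model treat mri and pet columns identically
        w = mlp.fc1.weight.data
        w[2:4, :] = w[0:2, :]
        scores = np.stack([[0.3, 0.7]] * 2 + [[0.5, 0.5]] * 5)
        sv = ScoreVector(scores=scores, available=np.ones(7, bool))
        amap = shapley_modalities(mlp, sv)
        assert float(amap.values["mri"]) == pytest.approx(
            float(amap.values["pet"]), abs=1e-9)

    def test_null_player_gets_zero(self, rng):
        mlp = FusionMLP(rng)
        g = MODALITIES.index("roi_surface")
        mlp.fc1.weight.data[2 * g:2 * g + 2, :] = 0.0
        amap = shapley_modalities(mlp, self._sv(3))
        assert float(amap.values["roi_surface"]) == pytest.approx(0.0, abs=1e-9)

    def test_linear_game_closed_form(self):
        # model linear in its 14 inputs: value_g = sum_j w_j (x_j - baseline_j)
        rng = np.random.default_rng(4)
        w = rng.normal(size=14)

        class LinearModel:
            def predict_proba(self, flat):
                flat = np.atleast_2d(flat)
                val = flat @ w
                return np.stack([1 - val, val], axis=1)

        sv = self._sv(5)
        amap = shapley_modalities(LinearModel(), sv)
        x = sv.flat()
        for g, m in enumerate(MODALITIES):
            expected = float(w[2 * g] * x[2 * g] + w[2 * g + 1] * x[2 * g + 1])
            assert float(amap.values[m]) == pytest.approx(expected, abs=1e-9)

    def test_sampled_shapley_agrees_with_enumeration(self, trained_like_mlp):
        sv = self._sv(6)
        exact = shapley_modalities(trained_like_mlp, sv)
        sampled = shapley_modalities_sampled(trained_like_mlp, sv,
                                             n_permutations=2000, seed=0)
        for m in MODALITIES:
            assert float(sampled.values[m]) == pytest.approx(
                float(exact.values[m]), abs=0.02)
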