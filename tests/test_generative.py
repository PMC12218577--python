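"""Generative edges: composite GAN loss closed forms, diffusion loss and
forward-noising consistency, sampling determinism, freezing contracts, and
the generated-image metrics."""

import numpy as np
import pytest

from modgraph.autodiff import Tensor
from modgraph.generative import (DiffusionBundle, DiffusionNet, GanBundle,
                                 GanLossConfig, NoiseSchedule,
                                 PatchDiscriminator, StyleTranslator,
                                 class_relevance_accuracy, diffusion_loss,
                                 frechet_distance, gan_generator_loss,
                                 sample_label2image, train_diffusion,
                                 train_img2img)
from modgraph.metrics import MetricError


# ---------------------------------------------------------------------------
# GAN loss closed forms
# ---------------------------------------------------------------------------
def _const_bundle(g_out, d_value, c_probs, phi=lambda x: x):
    return GanBundle(
        G=lambda c, z: Tensor(np.asarray(g_out, dtype=float)),
        D=lambda c, x: Tensor(np.full((len(c.data), 1, 1, 1), float(d_value))),
        C=lambda x: Tensor(np.asarray(c_probs, dtype=float)),
        phi=phi,
    )


class TestGanLoss:
    def test_default_weights_follow_reference_configuration(self):
        w = GanLossConfig()
        assert (w.lambda_l1, w.lambda_vgg, w.lambda_adv, w.lambda_c) == \
            (50.0, 100.0, 1.0, 50.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            GanLossConfig(lambda_c=-1.0)

    def test_oracle_inputs_give_zero_loss(self):
        # G reproduces x, D says real (1), C puts probability 1 on the label
        x = np.random.default_rng(0).random((2, 1, 4, 4))
        bundle = _const_bundle(x, 1.0, [[0.0, 1.0], [0.0, 1.0]])
        total, breakdown = gan_generator_loss(
            bundle, GanLossConfig(), (x, x, np.zeros((2, 2)), [1, 1]))
        assert total.data == pytest.approx(0.0, abs=1e-9)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in breakdown.values())

    def test_two_by_two_example_matches_hand_arithmetic(self):
        # x and G(c,z) chosen so per-pixel |diff| averages 0.25 exactly
        x = np.array([[[[0.0, 0.5], [1.0, 0.25]]]])
        g_out = np.array([[[[0.25, 0.5], [0.5, 0.5]]]])
        l1 = np.mean(np.abs(x - g_out))  # = (0.25+0+0.5+0.25)/4 = 0.25
        bundle = _const_bundle(g_out, 0.0, [[0.5, 0.5]], phi=lambda t: t)
        total, breakdown = gan_generator_loss(
            bundle, GanLossConfig(), (x, x, np.zeros((1, 2)), [1]))
        expected = 50 * l1 + 100 * l1 + 1 * 1.0 + 50 * np.log(2.0)
        assert total.data == pytest.approx(expected, rel=1e-9)
        assert breakdown["l1"] == pytest.approx(50 * 0.25)
        assert breakdown["perceptual"] == pytest.approx(100 * 0.25)
        assert breakdown["adversarial"] == pytest.approx(1.0)
        assert breakdown["classifier"] == pytest.approx(50 * np.log(2.0), rel=1e-9)

    def test_doubling_classifier_weight_scales_only_that_term(self):
        x = np.random.default_rng(1).random((2, 1, 4, 4))
        g_out = np.random.default_rng(2).random((2, 1, 4, 4))
        bundle = _const_bundle(g_out, 0.3, [[0.6, 0.4], [0.2, 0.8]])
        batch = (x, x, np.zeros((2, 2)), [0, 1])
        _, base = gan_generator_loss(bundle, GanLossConfig(), batch)
        _, doubled = gan_generator_loss(
            bundle, GanLossConfig(lambda_c=100.0), batch)
        assert doubled["classifier"] == pytest.approx(2 * base["classifier"])
        for key in ("l1", "perceptual", "adversarial"):
            assert doubled[key] == pytest.approx(base[key])

    def test_breakdown_terms_nonnegative_and_sum_to_total(self):
        x = np.random.default_rng(3).random((2, 1, 4, 4))
        g_out = np.random.default_rng(4).random((2, 1, 4, 4))
        bundle = _const_bundle(g_out, -0.7, [[0.9, 0.1], [0.4, 0.6]])
        total, breakdown = gan_generator_loss(
            bundle, GanLossConfig(), (x, x, np.zeros((2, 2)), [1, 0]))
        assert all(v >= 0 for v in breakdown.values())
        assert sum(breakdown.values()) == pytest.approx(float(total.data), abs=1e-6)


class TestGanTraining:
    @pytest.fixture()
    def tiny_pairs(self):
        rng = np.random.default_rng(0)
        cond = rng.random((12, 8, 8))
        target = np.clip(cond * 0.7 + 0.2, 0, 1)
        return [(c, t, int(i % 2)) for i, (c, t) in enumerate(zip(cond, target))]

    def test_fixed_seed_reproduces_loss_trajectory(self, tiny_pairs):
        def run():
            rng = np.random.default_rng(5)
            bundle = GanBundle(G=StyleTranslator(rng, z_dim=4),
                               D=PatchDiscriminator(rng),
                               C=lambda x: Tensor(np.full((len(x.data), 2), 0.5)),
                               phi=lambda x: x)
            report = train_img2img(bundle, tiny_pairs, epochs=1, seed=5,
                                   batch_size=6, track_frechet=False)
            return [h["g_total"] for h in report["history"]]

        assert run() == run()

    def test_l1_only_training_moves_toward_conditional_median(self):
        # one repeated condition with three targets; L1 regression pulls the
        # generator output toward the pixelwise median target
        rng = np.random.default_rng(7)
        cond = np.full((8, 8), 0.5)
        targets = [np.full((8, 8), v) for v in (0.2, 0.4, 0.9)] * 4
        pairs = [(cond, t, 0) for t in targets]
        bundle = GanBundle(G=StyleTranslator(rng, z_dim=4),
                           D=PatchDiscriminator(rng),
                           C=lambda x: Tensor(np.full((len(x.data), 2), 0.5)),
                           phi=lambda x: x)
        weights = GanLossConfig(lambda_l1=1.0, lambda_vgg=0.0, lambda_adv=0.0,
                                lambda_c=0.0)
        train_img2img(bundle, pairs, weights=weights, epochs=60, seed=7,
                      batch_size=12, lr=3e-3, track_frechet=False)
        out = bundle.G(Tensor(cond[None, None]), Tensor(np.zeros((1, 4)))).data
        median_err = abs(out.mean() - 0.4)
        mean_err = abs(out.mean() - 0.5)
        assert median_err < 0.1
        assert median_err < mean_err

    def test_classifier_and_phi_stay_frozen_during_training(self, tiny_pairs):
        rng = np.random.default_rng(9)
        from modgraph.classify import SliceClassifier
        from modgraph.generative import FrozenConvEmbedder

        clf = SliceClassifier(np.random.default_rng(1), n_slices_expected=4)
        phi = FrozenConvEmbedder(seed=2)
        c_before = {k: v.copy() for k, v in clf.state_dict().items()}
        phi_before = {k: v.copy() for k, v in phi.state_dict().items()}
        # classifier handle: softmax of the frozen model's logits
        bundle = GanBundle(
            G=StyleTranslator(rng, z_dim=4), D=PatchDiscriminator(rng),
            C=lambda imgs: _softmax_probs(clf, imgs), phi=phi)
        train_img2img(bundle, tiny_pairs, epochs=1, seed=9, batch_size=6,
                      track_frechet=False)
        for k, v in clf.state_dict().items():
            np.testing.assert_array_equal(v, c_before[k])
        for k, v in phi.state_dict().items():
            np.testing.assert_array_equal(v, phi_before[k])


def _softmax_probs(clf, images: Tensor) -> Tensor:
    from modgraph.autodiff import functional as F

    return F.softmax(clf(images), axis=-1)


# ---------------------------------------------------------------------------
# Diffusion
# ---------------------------------------------------------------------------
class TestDiffusion:
    def test_schedule_strictly_increasing_in_unit_interval(self):
        sched = NoiseSchedule(T=50)
        assert np.all(np.diff(sched.betas) > 0)
        assert sched.betas[0] > 0 and sched.betas[-1] < 1
        with pytest.raises(ValueError):
            NoiseSchedule(T=50, beta_start=0.02, beta_end=1e-4)

    def test_forward_noising_variance_matches_closed_form(self):
        # Var[x_t] = abar_t Var[x0] + (1 - abar_t) for unit-normal noise
        sched = NoiseSchedule(T=40)
        rng = np.random.default_rng(0)
        x0 = rng.standard_normal((20000, 1))
        for t in (1, 20, 40):
            eps = rng.standard_normal(x0.shape)
            x_t = sched.noisy(x0, np.full(len(x0), t), eps)
            expected = sched.alpha_bars[t - 1] * 1.0 + (1 - sched.alpha_bars[t - 1])
            assert np.var(x_t) == pytest.approx(expected, abs=1e-2 * 3)

    def test_oracle_noise_predictor_and_perfect_classifier_give_zero(self):
        rng = np.random.default_rng(1)
        x0 = rng.random((4, 1, 8, 8))
        eps = rng.standard_normal(x0.shape)

        class Oracle:
            def __call__(self, x_t, t, y, T):
                return Tensor(eps)

            def parameters(self):
                return []

        bundle = DiffusionBundle(
            eps_net=Oracle(), schedule=NoiseSchedule(T=10),
            C=lambda imgs: Tensor(np.eye(2)[np.ones(len(imgs.data), dtype=int)]))
        total, breakdown = diffusion_loss(bundle, (x0, np.ones(4, dtype=int)),
                                          np.full(4, 5), eps)
        assert total.data == pytest.approx(0.0, abs=1e-9)
        assert breakdown["mse"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_predictor_mse_equals_noise_second_moment(self):
        # Monte-Carlo check at n = 10^4 noise draws
        rng = np.random.default_rng(2)
        x0 = np.zeros((100, 1, 10, 10))
        eps = rng.standard_normal(x0.shape)  # 10^4 values

        class Zero:
            def __call__(self, x_t, t, y, T):
                return Tensor(np.zeros_like(x_t.data))

            def parameters(self):
                return []

        bundle = DiffusionBundle(eps_net=Zero(), schedule=NoiseSchedule(T=10))
        total, breakdown = diffusion_loss(bundle, (x0, np.zeros(100, dtype=int)),
                                          np.full(100, 3), eps,
                                          classifier_weight=0.0)
        assert breakdown["mse"] == pytest.approx(np.mean(eps ** 2), rel=1e-9)
        assert breakdown["mse"] == pytest.approx(1.0, abs=0.05)

    def test_uniform_classifier_contributes_exactly_ln2(self):
        rng = np.random.default_rng(3)
        x0 = rng.random((3, 1, 8, 8))
        eps = rng.standard_normal(x0.shape)

        class Oracle:
            def __call__(self, x_t, t, y, T):
                return Tensor(eps)

            def parameters(self):
                return []

        bundle = DiffusionBundle(
            eps_net=Oracle(), schedule=NoiseSchedule(T=10),
            C=lambda imgs: Tensor(np.full((len(imgs.data), 2), 0.5)))
        total, breakdown = diffusion_loss(bundle, (x0, np.array([0, 1, 0])),
                                          np.full(3, 2), eps)
        assert breakdown["classifier"] == pytest.approx(np.log(2.0), rel=1e-9)

    def test_out_of_range_step_rejected(self):
        bundle = DiffusionBundle(eps_net=DiffusionNet(np.random.default_rng(0)),
                                 schedule=NoiseSchedule(T=10))
        x0 = np.zeros((1, 1, 8, 8))
        with pytest.raises(ValueError, match="out of range"):
            diffusion_loss(bundle, (x0, np.zeros(1, dtype=int)), np.array([11]),
                           np.zeros_like(x0))

    def test_sampling_deterministic_per_seed_and_bounded(self):
        rng = np.random.default_rng(4)
        bundle = DiffusionBundle(eps_net=DiffusionNet(rng, base=4),
                                 schedule=NoiseSchedule(T=8))
        imgs = np.random.default_rng(5).random((12, 8, 8))
        train_diffusion(bundle, imgs, np.zeros(12, dtype=int), epochs=1, seed=4,
                        classifier_weight=0.0)
        a = sample_label2image(bundle, 1, 3, seed=11, side=8)
        b = sample_label2image(bundle, 1, 3, seed=11, side=8)
        np.testing.assert_array_equal(a, b)
        assert a.min() >= 0.0 and a.max() <= 1.0
        c = sample_label2image(bundle, 1, 3, seed=12, side=8)
        assert not np.array_equal(a, c)

    def test_untrained_bundle_refuses_to_sample(self):
        bundle = DiffusionBundle(eps_net=DiffusionNet(np.random.default_rng(0)),
                                 schedule=NoiseSchedule(T=8))
        with pytest.raises(RuntimeError, match="untrained"):
            sample_label2image(bundle, 0, 2, seed=0, side=8)


# ---------------------------------------------------------------------------
# Generated-image metrics
# ---------------------------------------------------------------------------
class TestClassRelevance:
    def test_oracle_generator_with_perfect_classifier_scores_one(self):
        bank = {0: np.zeros((5, 4, 4)), 1: np.ones((5, 4, 4))}
        gen = lambda label, n, seed: bank[label][:n]
        clf = lambda imgs: np.eye(2)[(imgs.mean(axis=(1, 2)) > 0.5).astype(int)]
        assert class_relevance_accuracy(gen, clf, n_per_label=5, seed=0) == 1.0

    def test_random_classifier_lands_near_half(self):
        rng = np.random.default_rng(0)
        gen = lambda label, n, seed: np.zeros((n, 4, 4))
        clf = lambda imgs: rng.dirichlet((1, 1), size=len(imgs))
        acc = class_relevance_accuracy(gen, clf, n_per_label=200, seed=0)
        # binomial 99.9% interval around 0.5 at n=400
        assert 0.5 - 3.3 * 0.025 <= acc <= 0.5 + 3.3 * 0.025

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            class_relevance_accuracy(lambda l, n, s: np.zeros((n, 2, 2)),
                                     lambda x: np.zeros((len(x), 2)),
                                     n_per_label=0)


class TestFrechet:
    def test_identical_sets_have_zero_distance(self):
        a = np.random.default_rng(0).normal(size=(40, 3))
        assert frechet_distance(a, a) == pytest.approx(0.0, abs=1e-6)

    def test_mean_offset_with_matched_covariance(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(500, 4))
        d = np.array([1.0, -2.0, 0.5, 0.0])
        b = a + d  # identical sample covariance, shifted mean
        assert frechet_distance(a, b) == pytest.approx(float(d @ d), abs=1e-8)

    def test_one_dimensional_gaussians_closed_form(self):
        # N(0,1) vs N(1,4): (0-1)^2 + (1 + 4 - 2*2) = 2, using embeddings
        # standardised to exact sample moments
        rng = np.random.default_rng(2)
        raw = rng.normal(size=(400, 1))
        a = (raw - raw.mean()) / raw.std(ddof=1)
        raw2 = rng.normal(size=(400, 1))
        b = (raw2 - raw2.mean()) / raw2.std(ddof=1) * 2.0 + 1.0
        assert frechet_distance(a, b) == pytest.approx(2.0, abs=1e-9)

    def test_too_few_vectors_rejected(self):
        with pytest.raises(MetricError):
            frechet_distance(np.zeros((3, 4)), np.zeros((10, 4)))
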