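"""Late fusion: score vectors, majority voting against a brute-force
oracle, masking semantics, fusion-MLP training and the missing-modality
protocols."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from modgraph.cohort import MODALITIES
from modgraph.fusion import (MASK_FILL, FusionMLP, MissingProtocol,
                             ProtocolError, ScoreVector, evaluate_missing,
                             frame_to_scores, majority_vote, mask_scores,
                             scores_to_frame, train_fusion)


def make_sv(p_ads, available=None, label="AD", subject="s0"):
    scores = np.stack([[1 - p, p] for p in p_ads])
    avail = np.ones(7, bool) if available is None else np.asarray(available, bool)
    scores[~avail] = MASK_FILL
    return ScoreVector(scores=scores, available=avail, label=label, subject=subject)


class TestScoreVector:
    def test_invalid_probability_pair_rejected(self):
        scores = np.zeros((7, 2))
        scores[:, 1] = 0.4  # pairs sum to 0.4+0.0, not 1
        with pytest.raises(ValueError, match="probability pair"):
            ScoreVector(scores=scores, available=np.ones(7, bool))

    def test_flat_has_width_fourteen_with_mask_fill(self):
        sv = make_sv([0.9] * 7, available=[True] * 6 + [False])
        flat = sv.flat()
        assert flat.shape == (14,)
        assert tuple(flat[-2:]) == (MASK_FILL, MASK_FILL)

    def test_csv_roundtrip_is_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        vectors = [make_sv(rng.random(7),
                           available=rng.random(7) > 0.3,
                           label=("AD" if i % 3 else "CN"), subject=f"s{i}")
                   for i in range(10)]
        frame = scores_to_frame(vectors)
        path = tmp_path / "scores.csv"
        frame.to_csv(path, index=False, float_format="%.17g")
        back = frame_to_scores(pd.read_csv(path, float_precision="round_trip"))
        for orig, re in zip(vectors, back):
            np.testing.assert_array_equal(orig.scores, re.scores)
            np.testing.assert_array_equal(orig.available, re.available)
            assert orig.label == re.label and orig.subject == re.subject


class TestMajorityVote:
    def test_plurality_wins(self):
        sv = make_sv([0.9, 0.8, 0.7, 0.6, 0.1, 0.2, 0.3])  # 4 AD vs 3 CN
        assert majority_vote(sv) == "AD"

    def test_mean_probability_rule_breaks_ties_softly(self):
        sv = make_sv([0.9, 0.3, 0, 0, 0, 0, 0],
                     available=[True, True] + [False] * 5)
        # one vote each way; mean p_AD = 0.6 > 0.5
        assert majority_vote(sv, tie_break="mean_probability") == "AD"

    def test_conservative_default_returns_cn_on_any_tie(self):
        sv = make_sv([0.9, 0.3, 0, 0, 0, 0, 0],
                     available=[True, True] + [False] * 5)
        assert majority_vote(sv) == "CN"

    def test_exact_residual_tie_returns_cn_under_both_rules(self):
        sv = make_sv([0.7, 0.3, 0, 0, 0, 0, 0],
                     available=[True, True] + [False] * 5)
        assert majority_vote(sv) == "CN"  # mean p_AD exactly 0.5
        assert majority_vote(sv, tie_break="mean_probability") == "CN"

    def test_no_available_modalities_rejected(self):
        sv = make_sv([0.5] * 7, available=[False] * 7)
        with pytest.raises(ValueError):
            majority_vote(sv)

    @pytest.mark.parametrize("tie_break", ["conservative", "mean_probability"])
    @pytest.mark.parametrize("n_voters", [3, 5, 7])
    def test_matches_bruteforce_oracle_on_exhaustive_vote_patterns(
            self, n_voters, tie_break):
        # every argmax pattern, checked against explicit vote counting
        for pattern in product([0, 1], repeat=n_voters):
            p_ads = [0.8 if v else 0.1 for v in pattern]
            avail = [True] * n_voters + [False] * (7 - n_voters)
            sv = make_sv(p_ads + [0] * (7 - n_voters), available=avail)
            n_ad = sum(pattern)
            n_cn = n_voters - n_ad
            if n_ad > n_cn:
                expected = "AD"
            elif n_cn > n_ad:
                expected = "CN"
            elif tie_break == "mean_probability":
                expected = "AD" if np.mean(p_ads) > 0.5 else "CN"
            else:
                expected = "CN"
            assert majority_vote(sv, tie_break=tie_break) == expected


class TestMaskScores:
    def test_empty_mask_is_identity(self):
        sv = make_sv([0.2, 0.9, 0.4, 0.6, 0.1, 0.8, 0.5])
        out = mask_scores(sv, [])
        np.testing.assert_array_equal(out.scores, sv.scores)
        np.testing.assert_array_equal(out.available, sv.available)

    def test_masking_all_seven_fills_everything(self):
        sv = make_sv([0.6] * 7)
        out = mask_scores(sv, list(MODALITIES))
        assert np.all(out.scores == MASK_FILL)
        assert not out.available.any()

    def test_sequential_masks_equal_union(self):
        sv = make_sv([0.2, 0.9, 0.4, 0.6, 0.1, 0.8, 0.5])
        seq = mask_scores(mask_scores(sv, ["pet"]), ["gene"])
        union = mask_scores(sv, ["pet", "gene"])
        np.testing.assert_array_equal(seq.scores, union.scores)
        np.testing.assert_array_equal(seq.available, union.available)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            mask_scores(make_sv([0.5] * 7), ["csf"])


def synthetic_frame(n=60, seed=0, informative=(0, 1, 6)):
    """Score table whose informative modalities track the label."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        label = "AD" if rng.random() < 0.4 else "CN"
        y = 1 if label == "AD" else 0
        p_ads = np.clip(rng.normal(0.5, 0.15, 7), 0.01, 0.99)
        for g in informative:
            p_ads[g] = np.clip(rng.normal(0.75 if y else 0.25, 0.1), 0.01, 0.99)
        rows.append(make_sv(p_ads, label=label, subject=f"s{i}").to_row())
    return pd.DataFrame(rows)


class TestFusionMLP:
    def test_outputs_are_probability_pairs_on_the_unit_cube(self, rng):
        mlp = FusionMLP(rng)
        x = np.random.default_rng(1).random((50, 14))
        probs = mlp.predict_proba(x)
        assert probs.min() >= 0
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_mask_range_equals_plain_training(self):
        frame = synthetic_frame()

        def run(mask_range):
            mlp = FusionMLP(np.random.default_rng(2))
            train_fusion(mlp, frame, mask_range=mask_range, epochs=5, seed=3)
            return mlp.state_dict()

        a, b = run((0, 0)), run((0, 0))
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_fixed_seed_reproduces_masked_training_exactly(self):
        frame = synthetic_frame()

        def run():
            mlp = FusionMLP(np.random.default_rng(4))
            train_fusion(mlp, frame, mask_range=(0, 5), epochs=5, seed=5)
            return mlp.state_dict()

        a, b = run(), run()
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_training_reduces_validation_loss(self):
        frame = synthetic_frame(n=80)
        mlp = FusionMLP(np.random.default_rng(6))
        report = train_fusion(mlp, frame, epochs=60, seed=6)
        assert report["val_loss_trained"] < report["val_loss_untrained"]

    def test_mask_range_must_leave_a_modality(self):
        mlp = FusionMLP(np.random.default_rng(0))
        with pytest.raises(ValueError, match="at least one"):
            train_fusion(mlp, synthetic_frame(), mask_range=(0, 7), epochs=1)


@pytest.fixture(scope="module")
def trained():
    frame = synthetic_frame(n=80, seed=1)
    mlp = FusionMLP(np.random.default_rng(7))
    train_fusion(mlp, frame, epochs=80, seed=7)
    return mlp, frame


class TestEvaluateMissing:
    def test_k0_protocol_has_zero_variance(self, trained):
        mlp, frame = trained
        proto = MissingProtocol(mode="random_k", k=0, repetitions=10)
        mean, se = evaluate_missing(mlp, frame, proto, seed=0)
        assert se == 0.0

    def test_single_removal_equals_singleton_subset(self, trained):
        mlp, frame = trained
        single = MissingProtocol(mode="single", features=("pet",))
        subset = MissingProtocol(mode="subset", features=("pet",))
        assert evaluate_missing(mlp, frame, single) == \
            evaluate_missing(mlp, frame, subset)

    def test_protocol_validation(self):
        with pytest.raises(ProtocolError):
            MissingProtocol(mode="random_k", k=6)
        with pytest.raises(ProtocolError):
            MissingProtocol(mode="subset", features=tuple(MODALITIES))
        with pytest.raises(ProtocolError):
            MissingProtocol(mode="single", features=("pet", "mri"))
        with pytest.raises(ProtocolError):
            MissingProtocol(mode="subset", features=("csf",))

    def test_masked_training_retains_accuracy_under_heavy_missingness(self, trained):
        mlp, frame = trained
        k5 = MissingProtocol(mode="random_k", k=5, repetitions=30)
        mlp_bac, _ = evaluate_missing(mlp, frame, k5, seed=1)
        assert mlp_bac > 0.6  # informative modalities survive masking on average
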