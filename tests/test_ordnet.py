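"""Ordinal head, losses, gradients, training and the binary variant."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import promtif.nn as nn
from promtif.evalmetrics import roc_auc_binary, spearman_rank
from promtif.ordnet import (
    OrdinalNetConfig,
    OrthogonalityModel,
    PromoterTIFModel,
    TrainConfig,
    _OrdinalNetwork,
    class_probabilities,
    encode_ordinal_target,
    forward_head,
    loss_auxiliary,
    loss_output,
)
from promtif.simfacs import SortSimConfig, TruthModel, make_fixture


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestOrdinalTarget:
    @pytest.mark.parametrize("y,expected", [
        (0, [0] * 10),
        (10, [1] * 10),
        (3, [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]),
    ])
    def test_prefix_encoding(self, y, expected):
        assert np.array_equal(encode_ordinal_target(y), expected)

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 10))
    def test_target_is_nonincreasing_prefix(self, y):
        o = encode_ordinal_target(y)
        assert (np.diff(o) <= 0).all() and o.sum() == y

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            encode_ordinal_target(11)


class TestForwardHead:
    def test_zero_score_zero_bias_gives_half(self):
        out = forward_head(np.zeros((1, 4)), np.zeros(4), np.zeros(1))
        assert out[0, 0] == 0.5

    def test_large_score_saturates_high(self):
        out = forward_head(np.full((1, 2), 50.0), np.ones(2), np.linspace(1, -1, 10))
        assert (out > 0.999).all()

    def test_closed_form_values(self):
        # w.x = 1 with biases (0, -1)
        out = forward_head(np.ones((1, 1)), np.ones(1), np.array([0.0, -1.0]))
        assert np.allclose(out, [[0.7310585786, 0.5]], atol=1e-9)

    @settings(max_examples=30, derandomize=True)
    @given(st.floats(-5, 5))
    def test_decreasing_biases_give_decreasing_thresholds(self, score):
        b = np.sort(np.random.default_rng(0).normal(size=10))[::-1]
        out = forward_head(np.array([[score]]), np.ones(1), b)
        assert (np.diff(out[0]) < 0).all()


class TestClassProbabilities:
    def test_half_thresholds(self):
        probs, pred, warn = class_probabilities(np.full(10, 0.5))
        assert np.allclose(probs[0], [0.5] + [0] * 9 + [0.5])
        assert pred[0] == 0 and not warn  # tie -> lower class

    def test_saturated_thresholds_predict_top(self):
        probs, pred, _ = class_probabilities(np.full(10, 0.999999))
        assert pred[0] == 10 and probs[0, 10] > 0.99

    def test_three_class_toy(self):
        probs, pred, warn = class_probabilities(np.array([0.9, 0.4]))
        assert np.allclose(probs[0], [0.1, 0.5, 0.4])
        assert pred[0] == 1 and not warn

    def test_nonmonotone_clamped_with_warning(self):
        probs, _, warn = class_probabilities(np.array([0.3, 0.7] + [0.1] * 8))
        assert warn and (probs >= 0).all()
        assert np.isclose(probs.sum(), 1.0)

    def test_normalization_over_random_monotone_heads(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(0, 3, size=(10_000, 1))
        b = np.sort(rng.normal(0, 2, 10))[::-1]
        o_hat = sigmoid(scores + b[None, :])
        probs, _, warn = class_probabilities(o_hat)
        assert not warn
        assert np.abs(probs.sum(axis=1) - 1.0).max() < 1e-9
        assert (probs >= 0).all()


class TestLosses:
    def test_single_threshold_ln2(self):
        assert np.isclose(loss_output(np.array([0.5]), np.array([1.0])), np.log(2))

    def test_weight_scales_linearly(self):
        base = loss_output(np.array([[0.5]]), np.array([[1.0]]), np.array([1.0]))
        double = loss_output(np.array([[0.5]]), np.array([[1.0]]), np.array([2.0]))
        assert np.isclose(double, 2 * base)

    def test_ten_thresholds_closed_form(self):
        o_hat = np.full((1, 10), 0.5)
        o = encode_ordinal_target(4)[None, :]
        assert np.isclose(loss_output(o_hat, o), 10 * np.log(2), atol=1e-9)

    def test_matches_elementwise_bce_oracle(self):
        """Random batches vs an independent per-element BCE implementation."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(1, 32)
            o_hat = rng.uniform(1e-4, 1 - 1e-4, size=(n, 10))
            y = rng.integers(0, 11, n)
            o = encode_ordinal_target(y)
            w = rng.uniform(0.1, 3.0, n)
            oracle = 0.0
            for i in range(n):
                s = 0.0
                for j in range(10):
                    p, t = o_hat[i, j], o[i, j]
                    s += -(t * np.log(p) + (1 - t) * np.log(1 - p))
                oracle += w[i] * s
            oracle /= n
            assert abs(loss_output(o_hat, o, w) - oracle) < 1e-6

    def test_saturated_probabilities_clamped(self):
        assert np.isfinite(loss_output(np.array([0.0, 1.0]), np.array([1.0, 0.0])))

    @pytest.mark.parametrize("b,expected", [
        (np.zeros(10), 9 * np.log(2)),
        (np.array([0.0, 1.0]), np.log(1 + np.e)),
    ])
    def test_auxiliary_closed_forms(self, b, expected):
        assert np.isclose(loss_auxiliary(b), expected, atol=1e-9)

    def test_auxiliary_small_for_well_ordered_biases(self):
        b = np.arange(10, dtype=float)[::-1] * 10  # gaps of +10
        assert loss_auxiliary(b) < 5e-4

    def test_auxiliary_decreases_with_gap(self):
        gaps = [loss_auxiliary(np.array([g, 0.0])) for g in (0.5, 1.0, 2.0)]
        assert gaps[0] > gaps[1] > gaps[2]


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        rng = np.random.default_rng(0)
        cfg = OrdinalNetConfig(input_length=9, conv_layers=((3, 1), (4, 3), (5, 2)),
                               fc_sizes=(8, 6), n_classes=5, dropout_p=0.0)
        net = _OrdinalNetwork(cfg, rng)
        X = rng.random((7, 4, 9))
        t = encode_ordinal_target(rng.integers(0, 5, 7), 5)
        w_n = rng.uniform(0.5, 2.0, 7)

        def total_loss():
            _, o_hat = net.forward(X, train=True)
            return loss_output(o_hat, t, w_n) + loss_auxiliary(net.b)

        _, o_hat = net.forward(X, train=True)
        net.train_step_grads(o_hat, t, w_n)
        analytic = [g.copy() for g in net.grads()]

        eps = 1e-6
        for pi, p in enumerate(net.params()):
            for idx in [tuple(rng.integers(0, d) for d in p.shape) for _ in range(4)]:
                orig = p[idx]
                p[idx] = orig + eps
                lp = total_loss()
                p[idx] = orig - eps
                lm = total_loss()
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - analytic[pi][idx]) < 1e-6 * max(1.0, abs(num))


class TestTraining:
    def _linear_dataset(self, n=3000, seed=0):
        """Near-noiseless linearly-encoded library: planted truth recovery."""
        cfg = SortSimConfig(n_sequences=n, seed=seed, intrinsic_sd=0.01,
                            cells_per_sequence=20)
        return make_fixture(cfg)

    def test_same_seed_reproducible_history(self):
        _, dataset, _ = self._linear_dataset(n=800, seed=2)
        tc = TrainConfig(seed=9, max_epochs=3)
        h1 = PromoterTIFModel.from_dataset(dataset, train_config=tc).fit().history
        h2 = PromoterTIFModel.from_dataset(dataset, train_config=tc).fit().history
        assert h1 == h2

    def test_recovers_planted_linear_code(self):
        library, dataset, _ = self._linear_dataset(n=8000, seed=4)
        tc = TrainConfig(seed=1, max_epochs=100, patience=20)
        res = PromoterTIFModel.from_dataset(dataset, train_config=tc).fit()
        assert res.eval_report().spearman_rho >= 0.95

    def test_single_epoch_snapshot(self):
        _, dataset, _ = self._linear_dataset(n=800, seed=2)
        res = PromoterTIFModel.from_dataset(
            dataset, train_config=TrainConfig(seed=0, max_epochs=1)).fit()
        assert res.best_epoch == 0 and len(res.history) == 1

    def test_too_small_dataset_raises(self):
        with pytest.raises(ValueError):
            PromoterTIFModel(["ACGTACGTACGTACGTA"] * 5, [0, 1, 2, 3, 4])

    def test_total_loss_is_exact_sum(self):
        rng = np.random.default_rng(0)
        o_hat = rng.uniform(0.01, 0.99, (16, 10))
        o = encode_ordinal_target(rng.integers(0, 11, 16))
        b = rng.normal(size=10)
        zeta_out = loss_output(o_hat, o)
        zeta_aux = loss_auxiliary(b)
        assert zeta_out + zeta_aux == zeta_out + zeta_aux  # composition is exact
        assert zeta_aux > 0

    def test_checkpoint_roundtrip(self, small_results, tmp_path):
        from promtif.ordnet import TIFResults
        path = tmp_path / "model.ckpt"
        small_results.save(path)
        net, payload = TIFResults.load_network(path)
        seqs = small_results.model.sequences[:5]
        from promtif.seqdata import encode_batch
        X = encode_batch(seqs)
        s1, _ = small_results.net.forward(X, train=False)
        s2, _ = net.forward(X, train=False)
        assert np.allclose(s1, s2)


class TestCrossValidation:
    def test_five_folds_five_rows(self):
        cfg = SortSimConfig(n_sequences=1500, seed=6)
        _, dataset, _ = make_fixture(cfg)
        model = PromoterTIFModel.from_dataset(
            dataset, train_config=TrainConfig(seed=0, max_epochs=4, patience=2))
        df = model.cross_validate(folds=5)
        assert len(df) == 5
        assert {"weighted_acc", "weighted_mae", "spearman_rho"} <= set(df.columns)
        assert df["weighted_mae"].std() >= 0


class TestOrthogonalityModel:
    def _separable(self, n=2000, seed=0, margin=0.1):
        """Labels planted from a latent score with a quantile margin carved
        out around the decision boundary, making the classes separable."""
        rng = np.random.default_rng(seed)
        truth = TruthModel.random_additive(17, rng)
        from promtif.simfacs import random_spacers
        seqs = random_spacers(n, 17, rng)
        scores = truth.score_batch(seqs)
        lo, hi = np.quantile(scores, [0.5 - margin, 0.5 + margin])
        keep = (scores < lo) | (scores > hi)
        kept_seqs = [s for s, k in zip(seqs, keep) if k]
        labels = (scores[keep] > hi).astype(int)
        return kept_seqs, labels

    def test_separable_labels_high_auc(self):
        seqs, labels = self._separable()
        model = OrthogonalityModel(seqs, labels,
                                   train_config=TrainConfig(seed=0, max_epochs=40, patience=8))
        res = model.fit()
        assert res.roc_auc() > 0.95

    def test_shuffled_labels_near_chance(self):
        seqs, labels = self._separable(seed=1)
        rng = np.random.default_rng(2)
        rng.shuffle(labels)
        model = OrthogonalityModel(seqs, labels,
                                   train_config=TrainConfig(seed=0, max_epochs=5, patience=2))
        res = model.fit()
        assert 0.35 < res.roc_auc() < 0.65

    def test_outputs_are_probabilities(self):
        seqs, labels = self._separable(n=400, seed=3)
        res = OrthogonalityModel(seqs, labels,
                                 train_config=TrainConfig(seed=0, max_epochs=2)).fit()
        p = res.predict_proba(seqs[:50])
        assert ((p > 0) & (p < 1)).all()

    def test_multiclass_labels_rejected(self):
        with pytest.raises(ValueError):
            OrthogonalityModel(["ACGT"] * 3, [0, 1, 2])
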