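"""The depthwise 1D-CNN ensemble: architecture contracts and training."""

import numpy as np
import pytest

from lcmsnet import (
    MemberConfig,
    build_member,
    count_parameters,
    default_cod_grid,
    load_ensemble,
    predict_proba,
    save_ensemble,
    train_ensemble,
)
from lcmsnet.model import EnsembleModel


def make_separable_images(rng, n_per_class=30, n_rt=60, n_mz=20, classes="abc"):
    """Noisy images where each class activates its own disjoint channel."""
    active = {c: 3 + 6 * i for i, c in enumerate(classes)}
    X = (rng.random((n_per_class * len(classes), n_rt, n_mz)) * 0.05).astype(np.float32)
    y = np.repeat(list(classes), n_per_class)
    for i, label in enumerate(y):
        t = 15 + (i % 12)
        X[i, t - 3 : t + 3, active[label]] = 1.0
    return X, y


@pytest.fixture(scope="module")
def trained_small():
    rng = np.random.default_rng(0)
    X, y = make_separable_images(rng)
    config = MemberConfig(kernel_len=5, pool_len=4, max_epochs=20, seed=1)
    model = train_ensemble(X, y, n_members=2, config=config)
    return model, X, y, config


class TestBuildMember:
    config = MemberConfig(kernel_len=3, pool_len=1, spatial_dropout_rate=0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            build_member(self.config, (20, 4), 1)

    def test_kernel_longer_than_rt_axis_rejected(self):
        with pytest.raises(ValueError):
            build_member(MemberConfig(kernel_len=30, pool_len=1), (20, 4), 2)

    def test_pool_longer_than_conv_output_rejected(self):
        with pytest.raises(ValueError):
            build_member(MemberConfig(kernel_len=3, pool_len=50), (20, 4), 2)

    def test_identity_kernel_reproduces_normalized_input(self, rng):
        member = build_member(self.config, (20, 4), 2, rng=rng)
        member.params["conv_w"] = np.array([[0.0] * 4, [1.0] * 4, [0.0] * 4], dtype=np.float32)
        member.params["conv_b"][:] = 0.0
        x = rng.random((3, 20, 4)).astype(np.float32)
        normalized = member._batchnorm(x, training=False, cache=None)
        features = member.features(x)
        # identity tap at offset 1 with pool window 1: features are the
        # normalized input rows 1..T-2
        np.testing.assert_allclose(features, normalized[:, 1:-1, :], rtol=1e-5, atol=1e-6)

    def test_channel_permutation_commutes_with_feature_map(self, rng):
        member = build_member(self.config, (20, 6), 2, rng=rng)
        x = rng.random((2, 20, 6)).astype(np.float32)
        base = member.features(x)
        perm = rng.permutation(6)
        member.params["conv_w"] = member.params["conv_w"][:, perm]
        member.params["conv_b"] = member.params["conv_b"][perm]
        member.params["bn_gamma"] = member.params["bn_gamma"][perm]
        member.params["bn_beta"] = member.params["bn_beta"][perm]
        member.running_mean = member.running_mean[perm]
        member.running_var = member.running_var[perm]
        permuted = member.features(x[:, :, perm])
        np.testing.assert_allclose(permuted, base[:, :, perm], rtol=1e-5, atol=1e-6)

    def test_zeroing_a_channel_only_changes_that_channels_features(self, rng):
        member = build_member(self.config, (20, 5), 2, rng=rng)
        x = rng.random((2, 20, 5)).astype(np.float32)
        base = member.features(x)
        x2 = x.copy()
        x2[:, :, 2] = 0.0
        other = member.features(x2)
        unchanged = [c for c in range(5) if c != 2]
        np.testing.assert_array_equal(other[:, :, unchanged], base[:, :, unchanged])
        assert not np.allclose(other[:, :, 2], base[:, :, 2])


class TestCountParameters:
    def test_hand_count_on_tiny_member(self):
        # 2 channels, kernel 3, conv output 18, pool 1 -> 36 features, 2 classes
        config = MemberConfig(kernel_len=3, pool_len=1)
        member = build_member(config, (20, 2), 2)
        model = EnsembleModel(members=[member], n_classes=2, input_shape=(20, 2),
                              class_order=("a", "b"))
        bn = 2 * 2            # gamma + beta per channel
        conv = 3 * 2 + 2      # taps per channel + bias
        dense = 36 * 2 + 2    # weights + bias
        assert count_parameters(model) == bn + conv + dense

    def test_larger_input_strictly_increases_count(self):
        config = MemberConfig(kernel_len=3, pool_len=1)
        small = EnsembleModel([build_member(config, (20, 2), 2)], 2, (20, 2), ("a", "b"))
        large = EnsembleModel([build_member(config, (40, 2), 2)], 2, (40, 2), ("a", "b"))
        assert count_parameters(large) > count_parameters(small)

    def test_default_cod_scale_ensemble_under_500k(self):
        grid = default_cod_grid()
        config = MemberConfig()
        members = [build_member(config, grid.shape, 5,
                                rng=np.random.default_rng(k)) for k in range(5)]
        model = EnsembleModel(members, 5, grid.shape, tuple("abcde"))
        total = count_parameters(model)
        per_member = count_parameters(model, per_member=True)
        assert total < 500_000
        assert sum(per_member) == total


class TestTrainingAndPrediction:
    def test_learns_separable_classes(self, trained_small):
        model, X, y, _ = trained_small
        probs = predict_proba(model, X)
        accuracy = (np.array(model.class_order)[probs.argmax(1)] == y).mean()
        assert accuracy >= 0.95

    def test_training_is_bit_identical_across_reruns(self, trained_small):
        model, X, y, config = trained_small
        again = train_ensemble(X, y, n_members=2, config=config)
        np.testing.assert_array_equal(predict_proba(model, X), predict_proba(again, X))

    def test_class_order_is_sorted_unique_labels(self, trained_small):
        model, _, y, _ = trained_small
        assert model.class_order == tuple(sorted(set(y)))

    def test_inference_is_deterministic(self, trained_small):
        model, X, _, _ = trained_small
        np.testing.assert_array_equal(predict_proba(model, X[:5]), predict_proba(model, X[:5]))

    def test_probabilities_sum_to_one(self, trained_small, rng):
        model, _, _, _ = trained_small
        X = rng.random((10, *model.input_shape)).astype(np.float32)
        probs = predict_proba(model, X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_ensemble_mean_equals_member_average(self, trained_small):
        model, X, _, _ = trained_small
        expected = np.mean([m.forward(X[:4].astype(np.float32)) for m in model.members], axis=0)
        np.testing.assert_allclose(predict_proba(model, X[:4]), expected, atol=1e-7)

    def test_single_member_ensemble_is_identity(self, trained_small):
        model, X, _, _ = trained_small
        solo = EnsembleModel([model.members[0]], model.n_classes,
                             model.input_shape, model.class_order)
        np.testing.assert_allclose(
            predict_proba(solo, X[:4]),
            model.members[0].forward(X[:4].astype(np.float32)),
        )

    def test_single_image_input_returns_vector(self, trained_small):
        model, X, _, _ = trained_small
        p = predict_proba(model, X[0])
        assert p.shape == (model.n_classes,)

    def test_shape_mismatch_rejected(self, trained_small, rng):
        model, _, _, _ = trained_small
        with pytest.raises(ValueError):
            predict_proba(model, rng.random((2, 10, 10)))

    def test_missing_second_class_rejected(self, rng):
        X = rng.random((10, 20, 4)).astype(np.float32)
        with pytest.raises(ValueError):
            train_ensemble(X, ["only"] * 10, n_members=1,
                           config=MemberConfig(kernel_len=3, pool_len=2))

    def test_ensemble_log_loss_no_worse_than_worst_member(self, trained_small):
        # Jensen: the log-loss of the averaged probabilities is bounded by
        # the largest member log-loss
        model, X, y, _ = trained_small
        y_idx = np.searchsorted(model.class_order, y)
        Xf = X.astype(np.float32)
        member_losses = [
            -np.mean(np.log(np.clip(m.forward(Xf)[np.arange(y.size), y_idx], 1e-12, None)))
            for m in model.members
        ]
        ens = predict_proba(model, X)
        ens_loss = -np.mean(np.log(np.clip(ens[np.arange(y.size), y_idx], 1e-12, None)))
        assert ens_loss <= max(member_losses) + 1e-9

    def test_save_load_round_trip(self, trained_small, tmp_path):
        model, X, _, _ = trained_small
        path = tmp_path / "model.npz"
        save_ensemble(model, path)
        back = load_ensemble(path)
        assert back.class_order == model.class_order
        np.testing.assert_array_equal(predict_proba(back, X[:6]), predict_proba(model, X[:6]))


class TestShiftTolerance:
    def test_augmented_training_tolerates_small_shifts_better_than_large(self):
        """Accuracy degrades less under shifts within the augmentation range
        than under shifts three times larger."""
        rng = np.random.default_rng(3)
        X, y = make_separable_images(rng, n_per_class=30, n_rt=80)
        config = MemberConfig(kernel_len=5, pool_len=4, max_epochs=15, seed=2)
        model = train_ensemble(X, y, n_members=1, config=config,
                               shift_bins_max=4, shift_copies=2)

        def accuracy_at_shift(shift):
            shifted = np.zeros_like(X)
            shifted[:, shift:, :] = X[:, :-shift, :]
            probs = predict_proba(model, shifted)
            return (np.array(model.class_order)[probs.argmax(1)] == y).mean()

        assert accuracy_at_shift(3) >= accuracy_at_shift(12)
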