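import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mbrainseg as mb
from mbrainseg.nn import (
    NetworkConfig,
    TrainConfig,
    build_model,
    inverse_frequency_weights,
    predict_mask,
    train,
    weighted_dice_loss,
)
from mbrainseg.nn import autodiff as ad
from mbrainseg.nn.training import Adam, grid_search


def tiny_dataset(n=3, shape=(16, 16, 8), seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        img = rng.normal(size=shape).astype(np.float32)
        c = np.asarray(shape) // 2
        idx = np.indices(shape)
        t = (((idx - c[:, None, None, None]) ** 2).sum(axis=0) < 16).astype(np.int64)
        img[t == 1] += 3.0
        out.append((img, t))
    return out


class TestArchitecture:
    def test_filter_widths_double_per_level(self):
        cfg = NetworkConfig(depth=5, base_filters=16)
        assert cfg.level_filters() == [16, 32, 64, 128, 256]

    def test_output_shape_and_probability_normalization(self):
        model = build_model(NetworkConfig(depth=3, base_filters=4, seed=0))
        probs = model.predict_probs(np.random.default_rng(0).normal(size=(16, 16, 8)).astype(np.float32))
        assert probs.shape == (2, 16, 16, 8)
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(
        depth=st.integers(2, 3),
        mx=st.integers(1, 3),
        my=st.integers(1, 3),
        mz=st.integers(1, 2),
    )
    def test_shape_preservation_property(self, depth, mx, my, mz):
        div = 2 ** (depth - 1)
        shape = (div * 2 * mx, div * 2 * my, div * 2 * mz)
        model = build_model(NetworkConfig(depth=depth, base_filters=2, seed=1))
        probs = model.predict_probs(np.zeros(shape, dtype=np.float32))
        assert probs.shape[1:] == shape

    def test_indivisible_dims_rejected(self):
        model = build_model(NetworkConfig(depth=3, base_filters=2))
        with pytest.raises(ValueError, match="divisible"):
            model.predict_probs(np.zeros((18, 16, 8), dtype=np.float32))

    def test_param_count_grows_with_depth_and_width(self):
        base = build_model(NetworkConfig(depth=3, base_filters=8)).param_count()
        deeper = build_model(NetworkConfig(depth=4, base_filters=8)).param_count()
        wider = build_model(NetworkConfig(depth=3, base_filters=16)).param_count()
        assert base < deeper and base < wider


class TestWeightedDiceLoss:
    def test_perfect_one_hot_prediction(self):
        t = (np.random.default_rng(0).random((8, 8, 4)) > 0.7).astype(np.int64)
        probs = np.stack([(t == 0), (t == 1)]).astype(np.float32)
        assert weighted_dice_loss(probs, t) <= 1e-4

    def test_uniform_half_probability_analytic_case(self):
        # half the voxels foreground, probabilities 0.5 everywhere, equal
        # weights: every per-class soft Dice term is 0.5, so loss = 0.5
        t = np.zeros((8, 8, 4), dtype=np.int64)
        t[:4] = 1
        probs = np.full((2, 8, 8, 4), 0.5, dtype=np.float32)
        assert weighted_dice_loss(probs, t, (0.5, 0.5)) == pytest.approx(0.5, abs=1e-3)

    def test_totally_wrong_prediction(self):
        t = np.zeros((6, 6, 2), dtype=np.int64)
        t[:3] = 1
        probs = np.stack([(t == 1), (t == 0)]).astype(np.float32)  # swapped
        assert weighted_dice_loss(probs, t) >= 1.0 - 1e-3

    def test_loss_bounded_and_monotone_in_overlap(self):
        # dilating the predicted set toward the target strictly decreases loss
        import scipy.ndimage as ndi

        idx = np.indices((16, 16, 16))
        t = ((((idx - 7.5) ** 2).sum(axis=0)) <= 25).astype(np.int64)
        seed_pred = np.zeros_like(t)
        seed_pred[7:9, 7:9, 7:9] = 1
        losses = []
        pred = seed_pred
        for _ in range(5):
            probs = np.stack([1 - pred, pred]).astype(np.float32)
            loss = weighted_dice_loss(probs, t, (0.5, 0.5))
            assert 0.0 <= loss <= 1.0
            losses.append(loss)
            pred = ndi.binary_dilation(pred) & (t > 0)
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_inverse_frequency_weights_counteract_imbalance(self):
        # 1:1000 imbalance: unweighted, the background term dominates the
        # loss gradient by ~2 orders of magnitude; inverse-frequency weights
        # bring the two class pulls to within one order of magnitude
        shape = (10, 10, 10)
        t = np.zeros(shape, dtype=np.int64)
        t[0, 0, 0] = 1  # single foreground voxel in 1000

        def pull_ratio(weights):
            probs = ad.parameter(np.full((2,) + shape, 0.5, dtype=np.float32))
            loss = weighted_dice_loss(probs, t, weights)
            loss.backward()
            g = probs.grad
            return np.abs(g[1]).sum() / np.abs(g[0]).sum()

        unweighted = pull_ratio((0.5, 0.5))
        weighted = pull_ratio(inverse_frequency_weights([t], 2))
        assert unweighted < 0.02  # background dominates 50x+
        assert 0.1 <= weighted <= 10.0  # weighting restores comparable pull

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            weighted_dice_loss(np.zeros((2, 4, 4, 4)), np.zeros((4, 4, 2), dtype=np.int64))


class TestTrainingProtocol:
    def test_lr_reduced_by_factor_after_plateau(self):
        # a vanishing learning rate freezes the model, so validation loss
        # cannot improve and the scheduler must fire after `lr_patience`
        data = tiny_dataset(n=2)
        model = build_model(NetworkConfig(depth=2, base_filters=2, seed=0))
        tcfg = TrainConfig(initial_lr=1e-30, lr_factor=0.7, lr_patience=2, max_epochs=4, seed=0)
        _, history = train(model, data, tcfg)
        assert history["lr"].iloc[0] == pytest.approx(1e-30)
        assert history["lr"].iloc[-1] == pytest.approx(1e-30 * 0.7)

    def test_seeded_determinism_of_first_epoch(self):
        data = tiny_dataset(n=2)
        losses = []
        for _ in range(2):
            model = build_model(NetworkConfig(depth=2, base_filters=2, dropout_rate=0.1, seed=3))
            _, history = train(model, data, TrainConfig(initial_lr=1e-3, max_epochs=1, seed=3))
            losses.append(history["train_loss"].iloc[0])
        assert losses[0] == pytest.approx(losses[1], abs=1e-6)

    def test_empty_dataset_rejected(self):
        model = build_model(NetworkConfig(depth=2, base_filters=2))
        with pytest.raises(ValueError, match="empty"):
            train(model, [], TrainConfig())

    def test_history_records_losses_and_lr(self):
        data = tiny_dataset(n=2)
        model = build_model(NetworkConfig(depth=2, base_filters=2, seed=0))
        _, history = train(model, data, TrainConfig(initial_lr=1e-3, max_epochs=3, seed=0))
        assert list(history.columns) == ["epoch", "train_loss", "val_loss", "lr"]
        assert len(history) <= 3 and np.isfinite(history[["train_loss", "val_loss"]]).all().all()


class TestPrediction:
    def test_untrained_model_outputs_valid_labels(self):
        model = build_model(NetworkConfig(depth=2, base_filters=2, n_classes=3, seed=5))
        vol = mb.Volume(np.random.default_rng(0).normal(size=(16, 16, 8)).astype(np.float32), (1, 1, 1))
        mask = predict_mask(model, vol)
        assert set(np.unique(mask.data)) <= {0, 1, 2}
        assert mask.shape == vol.shape and mask.spacing == vol.spacing

    def test_inference_is_deterministic(self):
        model = build_model(NetworkConfig(depth=2, base_filters=2, dropout_rate=0.3, seed=6))
        vol = mb.Volume(np.random.default_rng(1).normal(size=(16, 16, 8)).astype(np.float32), (1, 1, 1))
        m1 = predict_mask(model, vol)
        m2 = predict_mask(model, vol)
        np.testing.assert_array_equal(m1.data, m2.data)

    def test_model_save_load_round_trip(self, tmp_path):
        from mbrainseg.nn import load_model, save_model

        model = build_model(NetworkConfig(depth=2, base_filters=2, seed=7))
        save_model(model, tmp_path / "m", history=pd.DataFrame({"epoch": [0]}))
        back = load_model(tmp_path / "m")
        x = np.random.default_rng(2).normal(size=(16, 16, 8)).astype(np.float32)
        np.testing.assert_array_equal(model.predict_probs(x), back.predict_probs(x))


class TestGridSearch:
    def test_ranked_table_and_duplicate_determinism(self):
        data = tiny_dataset(n=3)
        cfgs = [
            (NetworkConfig(depth=2, base_filters=2, seed=0), TrainConfig(initial_lr=1e-3, seed=0)),
            (NetworkConfig(depth=2, base_filters=2, seed=0), TrainConfig(initial_lr=1e-3, seed=0)),
            (NetworkConfig(depth=2, base_filters=4, seed=0), TrainConfig(initial_lr=1e-3, seed=0)),
        ]
        table = grid_search(cfgs, data, budget_epochs=2)
        assert len(table) == 3 and list(table["rank"]) == [1, 2, 3]
        dup = table[table["base_filters"] == 2]["best_val_loss"]
        assert dup.iloc[0] == pytest.approx(dup.iloc[1], abs=1e-9)

    def test_capacity_ordering_on_phantom_task(self):
        # a 1-filter network underfits the sphere task relative to 8 filters
        data = tiny_dataset(n=4, seed=3)
        cfgs = [
            (NetworkConfig(depth=2, base_filters=1, seed=1), TrainConfig(initial_lr=2e-3, seed=1)),
            (NetworkConfig(depth=2, base_filters=8, seed=1), TrainConfig(initial_lr=2e-3, seed=1)),
        ]
        table = grid_search(cfgs, data, budget_epochs=6)
        assert table.iloc[0]["base_filters"] == 8
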