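"""Training loop determinism, schedule, prediction and checkpointing."""

import numpy as np
import pytest

from gcsaseg.exceptions import ShapeError
from gcsaseg.model import build_model
from gcsaseg.nn.functional import softmax_cross_entropy
from gcsaseg.nn.optim import AdamW, StepLR
from gcsaseg.nn.tensor import Tensor
from gcsaseg.synthetic import SynthSpec, make_memory_dataset
from gcsaseg.train import (TrainConfig, load_checkpoint, predict_patch,
                           predict_wsi, save_checkpoint, train)


@pytest.fixture(scope="module")
def tiny_pairs():
    spec = SynthSpec(seed=21, width=32, height=32, n_blobs=1,
                     blob_radius_range=(4, 9))
    pairs, _ = make_memory_dataset(spec, 16)
    return pairs


@pytest.fixture
def tiny_model(tiny_config):
    return build_model(tiny_config, seed=0)


class TestTrain:
    def test_zero_learning_rate_leaves_parameters_bitwise_unchanged(
            self, tiny_model, tiny_pairs):
        before = {k: v.copy() for k, v in tiny_model.state_dict().items()}
        cfg = TrainConfig(lr=0.0, epochs=1, batch=8, seed=0)
        model, _ = train(tiny_model, tiny_pairs[:8], [], cfg)
        after = model.state_dict()
        for k in before:
            if k.endswith("running_mean") or k.endswith("running_var"):
                continue  # running stats move in train mode by design
            np.testing.assert_array_equal(before[k], after[k], err_msg=k)

    def test_same_seed_reproduces_loss_trace_bitwise(self, tiny_config, tiny_pairs):
        cfg = TrainConfig(epochs=2, batch=4, seed=3)
        _, h1 = train(build_model(tiny_config, seed=1), tiny_pairs[:8],
                      tiny_pairs[8:10], cfg)
        _, h2 = train(build_model(tiny_config, seed=1), tiny_pairs[:8],
                      tiny_pairs[8:10], cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_miou == h2.val_miou

    def test_history_has_one_record_per_epoch_and_nonincreasing_lr(
            self, tiny_model, tiny_pairs):
        cfg = TrainConfig(epochs=5, batch=8, seed=0, lr_step=2, lr_factor=0.5)
        _, hist = train(tiny_model, tiny_pairs[:8], tiny_pairs[8:10], cfg)
        assert len(hist.train_loss) == len(hist.lr) == 5
        base = cfg.lr
        assert hist.lr == [base, base, base / 2, base / 2, base / 4]
        assert all(a >= b for a, b in zip(hist.lr, hist.lr[1:]))

    def test_mismatched_mask_size_fails_before_training(self, tiny_model, tiny_pairs):
        bad = [(tiny_pairs[0][0], tiny_pairs[0][1][:16, :])]
        with pytest.raises(ShapeError):
            train(tiny_model, bad, [], TrainConfig(epochs=1))

    def test_non_binary_mask_fails_before_training(self, tiny_model, tiny_pairs):
        bad_mask = tiny_pairs[0][1].copy()
        bad_mask[0, 0] = 7
        with pytest.raises(ValueError):
            train(tiny_model, [(tiny_pairs[0][0], bad_mask)], [], TrainConfig(epochs=1))

    def test_empty_train_set_raises(self, tiny_model):
        with pytest.raises(ValueError):
            train(tiny_model, [], [], TrainConfig(epochs=1))

    def test_loss_decreases_over_first_five_steps_on_one_batch(
            self, tiny_model, tiny_pairs):
        x = np.stack([im.transpose(2, 0, 1) / 255.0 for im, _ in tiny_pairs[:4]]
                     ).astype(np.float32)
        y = np.stack([(m == 255).astype(np.int64) for _, m in tiny_pairs[:4]])
        tiny_model.train()
        opt = AdamW(tiny_model.parameters(), lr=1e-4, weight_decay=0.02)
        losses = []
        for _ in range(5):
            opt.zero_grad()
            loss = softmax_cross_entropy(tiny_model(Tensor(x)), y)
            loss.backward()
            opt.step()
            losses.append(loss.item())
        assert all(a > b for a, b in zip(losses, losses[1:]))


class TestStepLR:
    def test_schedule_is_piecewise_constant_with_exact_factor(self):
        opt = AdamW([], lr=1.0)
        sched = StepLR(opt, step_size=3, factor=0.1)
        trace = []
        for _ in range(9):
            trace.append(opt.lr)
            sched.step()
        assert trace == [1.0] * 3 + [0.1] * 3 + [pytest.approx(0.01)] * 3


class _FixedLogitsModel:
    """Duck-typed stand-in returning constant logits (synthetic test double)."""

    def __init__(self, logits):
        self._logits = np.asarray(logits, dtype=np.float32)

    def eval(self):
        return self

    def __call__(self, _):
        return Tensor(self._logits)


class TestPredict:
    def test_patch_prediction_codomain_and_shape(self, tiny_model, tiny_pairs):
        mask = predict_patch(tiny_model, tiny_pairs[0][0])
        assert mask.shape == (32, 32) and mask.dtype == np.uint8
        assert set(np.unique(mask)) <= {0, 255}

    def test_argmax_matches_per_pixel_comparison(self):
        logits = np.zeros((1, 2, 2, 2), dtype=np.float32)
        logits[0, 0] = [[1.0, -1.0], [0.5, 2.0]]
        logits[0, 1] = [[0.0, 3.0], [0.4, 2.5]]
        model = _FixedLogitsModel(logits)
        out = predict_patch(model, np.zeros((2, 2, 3), dtype=np.uint8))
        np.testing.assert_array_equal(out, [[0, 255], [0, 255]])

    def test_wsi_equals_manual_tile_predict_stitch(self, tiny_model):
        from gcsaseg.tiling import stitch, tile_image
        img, _ = make_memory_dataset(SynthSpec(seed=8, width=80, height=50,
                                               n_blobs=1, blob_radius_range=(5, 10)),
                                     10)[0][0]
        auto = predict_wsi(tiny_model, img, patch=32)
        patches, grid = tile_image(img, patch=32)
        manual = stitch([predict_patch(tiny_model, p) for p in patches], grid)
        assert auto.shape == (50, 80)
        np.testing.assert_array_equal(auto, manual)

    def test_single_tile_wsi_equals_predict_patch(self, tiny_model, tiny_pairs):
        img = tiny_pairs[0][0]
        np.testing.assert_array_equal(predict_wsi(tiny_model, img, patch=32),
                                      predict_patch(tiny_model, img))

    def test_constant_slide_gives_identical_interior_tiles(self, tiny_model):
        img = np.full((64, 96, 3), 180, dtype=np.uint8)
        out = predict_wsi(tiny_model, img, patch=32)
        tiles = [out[r * 32:(r + 1) * 32, c * 32:(c + 1) * 32]
                 for r in range(2) for c in range(3)]
        for t in tiles[1:]:
            np.testing.assert_array_equal(t, tiles[0])


class TestCheckpoint:
    def test_roundtrip_restores_state_and_predictions(self, tiny_model, tiny_pairs,
                                                      tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_model, path)
        restored = load_checkpoint(path)
        assert restored.config == tiny_model.config
        for k, v in tiny_model.state_dict().items():
            np.testing.assert_array_equal(v, restored.state_dict()[k], err_msg=k)
        img = tiny_pairs[0][0]
        np.testing.assert_array_equal(predict_patch(tiny_model, img),
                                      predict_patch(restored, img))
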