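import math

import numpy as np
import pytest

from bucketaugment import (
    GaussianFeatureSegmenter,
    PhantomConfig,
    TrainConfig,
    VolumePatch,
    best_bucket,
    dice_ce_loss,
    dice_score,
    evaluate_dice,
    make_phantom,
    normalize_volume,
    patchify,
    train,
    unpatchify,
)


# --- preprocessing ----------------------------------------------------------


def test_minmax_normalization_closed_form():
    raw = np.zeros((4, 4, 4))
    raw[0, 0, 0], raw[1, 1, 1], raw[2, 2, 2] = -1000.0, 0.0, 1000.0
    out = normalize_volume(raw)
    assert out[0, 0, 0] == 0.0
    assert out[1, 1, 1] == 0.5
    assert out[2, 2, 2] == 1.0
    assert out.min() == 0.0 and out.max() == 1.0


def test_normalization_fixed_point_and_degenerate_input():
    img = np.linspace(0, 1, 64).reshape(4, 4, 4)
    np.testing.assert_allclose(normalize_volume(img), img)
    with pytest.raises(ValueError, match="dynamic range"):
        normalize_volume(np.full((4, 4, 4), 7.0))


@pytest.mark.parametrize("shape,patch,expected", [
    ((96, 96, 96), (96, 96, 96), 1),
    ((100, 100, 100), (96, 96, 96), 8),
    ((32, 32, 32), (16, 16, 16), 8),
    ((17, 16, 16), (16, 16, 16), 2),
])
def test_patch_counts_follow_ceiling_tiling(shape, patch, expected):
    vol = VolumePatch(np.random.default_rng(0).random(shape),
                      np.zeros(shape, dtype=np.int16))
    patches = patchify(vol, patch)
    assert len(patches) == expected
    assert all(p.image.shape == patch for p in patches)


def test_patchify_unpatchify_round_trip(phantom):
    patch_size = (16, 16, 16)
    patches = patchify(phantom, patch_size)
    restored = unpatchify(patches, phantom.image.shape, patch_size)
    np.testing.assert_array_equal(restored.image, phantom.image)
    np.testing.assert_array_equal(restored.label, phantom.label)


# --- metrics ----------------------------------------------------------------


def test_dice_score_closed_forms():
    a = np.zeros((4, 4, 4), dtype=bool)
    a[:2] = True
    assert dice_score(a, a) == 1.0
    assert dice_score(a, ~a) == 0.0
    assert dice_score(np.zeros_like(a), np.zeros_like(a)) == 1.0

    b = np.zeros_like(a)  # |A|=4, |B|=4, |A∩B|=2 -> 0.5
    a2 = np.zeros_like(a)
    a2.flat[:4] = True
    b.flat[2:6] = True
    assert dice_score(a2, b) == 0.5

    with pytest.raises(ValueError, match="mismatch"):
        dice_score(a, a[:2])


def test_dice_ce_loss_perfect_prediction_is_zero():
    truth = np.zeros((4, 4, 4), dtype=np.int16)
    truth[:2] = 1
    probs = np.stack([(truth == 0), (truth == 1)]).astype(float)
    assert dice_ce_loss(probs, truth) == pytest.approx(0.0, abs=1e-5)


def test_dice_ce_loss_uniform_prediction_ce_is_ln2():
    truth = np.zeros((4, 4, 4), dtype=np.int16)
    truth[0] = 1
    probs = np.full((2, 4, 4, 4), 0.5)
    # CE component is exactly ln 2; subtract the analytic soft-Dice part
    inter0, inter1 = 0.5 * (truth == 0).sum(), 0.5 * (truth == 1).sum()
    d0 = 2 * inter0 / (32 + (truth == 0).sum())
    d1 = 2 * inter1 / (32 + (truth == 1).sum())
    expected = (1 - (d0 + d1) / 2) + math.log(2)
    assert dice_ce_loss(probs, truth) == pytest.approx(expected)


def test_dice_ce_loss_rejects_unnormalized_probabilities():
    truth = np.zeros((4, 4, 4), dtype=np.int16)
    with pytest.raises(ValueError, match="sum to 1"):
        dice_ce_loss(np.full((2, 4, 4, 4), 0.7), truth)


def test_loss_falls_as_mass_moves_to_true_class():
    truth = np.array([0, 1], dtype=np.int16).reshape(1, 1, 2)
    losses = []
    for p in (0.5, 0.7, 0.9):
        probs = np.empty((2, 1, 1, 2))
        probs[0, 0, 0, 0], probs[1, 0, 0, 0] = p, 1 - p
        probs[0, 0, 0, 1], probs[1, 0, 0, 1] = 1 - p, p
        losses.append(dice_ce_loss(probs, truth))
    assert losses[0] > losses[1] > losses[2]


# --- evaluation -------------------------------------------------------------


class OracleTrainer:
    """Returns the ground truth it is asked about (keyed by image bytes)."""

    def __init__(self, patches):
        self._truth = {p.image.tobytes(): p.label for p in patches}

    def fit_step(self, batch):
        return 0.0

    def validate(self, val_set):
        return 0.0

    def predict(self, image):
        return self._truth[np.asarray(image, dtype=np.float64).tobytes()]


class BackgroundTrainer:
    def fit_step(self, batch):
        return 1.0

    def validate(self, val_set):
        return 1.0

    def predict(self, image):
        return np.zeros(np.asarray(image).shape, dtype=np.int16)


def test_evaluate_dice_oracle_and_background(phantom_factory):
    patches = [phantom_factory(s) for s in range(3)]
    perfect = evaluate_dice(OracleTrainer(patches), patches)
    assert set(perfect) == {1, 2}
    assert all(v == 1.0 for v in perfect.values())

    background = evaluate_dice(BackgroundTrainer(), patches)
    assert all(v == 0.0 for v in background.values())

    with pytest.raises(ValueError, match="empty"):
        evaluate_dice(BackgroundTrainer(), [])


def test_evaluate_dice_constant_half_overlap_predictor(phantom):
    class HalfPredictor:
        def fit_step(self, batch):
            return 0.0

        def validate(self, val_set):
            return 0.0

        def predict(self, image):
            # foreground mask with exactly half the class-1 voxels
            pred = np.zeros(image.shape, dtype=np.int16)
            idx = np.argwhere(phantom.label == 1)
            half = idx[: len(idx) // 2]
            pred[tuple(half.T)] = 1
            return pred

    n1 = int((phantom.label == 1).sum())
    expected = 2 * (n1 // 2) / (n1 // 2 + n1)
    result = evaluate_dice(HalfPredictor(), [phantom])
    assert result[1] == pytest.approx(expected)
    assert result[2] == 0.0


# --- training loop ----------------------------------------------------------


class ScriptedTrainer:
    """Deterministic mock: validation loss falls only while training data
    carries a designated intensity fingerprint, rises otherwise."""

    def __init__(self, good_mean, tol=1e-6):
        self.good_mean = good_mean
        self.tol = tol
        self.loss = 1.0
        self.last_mean = None

    def fit_step(self, batch):
        self.last_mean = float(np.mean([p.image.mean() for p in batch]))
        return self.loss

    def validate(self, val_set):
        if (self.last_mean is not None
                and abs(self.last_mean - self.good_mean) < self.tol):
            self.loss -= 0.01
        else:
            self.loss += 0.01
        return self.loss

    def predict(self, image):
        return np.zeros(np.asarray(image).shape, dtype=np.int16)


def _tiny_sets(n_train=2, n_val=1):
    train_set = [make_phantom(PhantomConfig(shape=(16, 16, 16), seed=s,
                                            noise_sigma=0.05))
                 for s in range(n_train)]
    val_set = [make_phantom(PhantomConfig(shape=(16, 16, 16), seed=100 + s,
                                          noise_sigma=0.05))
               for s in range(n_val)]
    return train_set, val_set


def test_validation_count_is_floor_epochs_over_k():
    train_set, val_set = _tiny_sets()
    cfg = TrainConfig(epochs=6, val_every_k_epochs=2, patch_size=(16, 16, 16),
                      n_buckets=3, n_ops=2, seed=0,
                      augmentation_mode="bucketaugment")
    model = GaussianFeatureSegmenter(n_classes=3, seed=0)
    _, controller, log = train(train_set, val_set, model, cfg)
    assert len(log) == 3
    assert len(controller.history) == 3
    assert sum(controller.q) == sum(r.reward for r in controller.history)


def test_mode_none_leaves_controller_untouched():
    train_set, val_set = _tiny_sets()
    cfg = TrainConfig(epochs=4, val_every_k_epochs=2, patch_size=(16, 16, 16),
                      seed=0, augmentation_mode="none")
    _, controller, log = train(train_set, val_set,
                               GaussianFeatureSegmenter(seed=0), cfg)
    assert controller.history == ()
    assert len(log) == 2


def test_training_is_deterministic_under_seed():
    def run():
        train_set, val_set = _tiny_sets()
        cfg = TrainConfig(epochs=4, val_every_k_epochs=1,
                          patch_size=(16, 16, 16), n_buckets=4, n_ops=2,
                          seed=5, augmentation_mode="bucketaugment")
        model = GaussianFeatureSegmenter(n_classes=3, seed=5)
        _, controller, log = train(train_set, val_set, model, cfg)
        return controller, log

    (c1, l1), (c2, l2) = run(), run()
    assert c1 == c2 and l1 == l2


def test_validation_set_is_never_augmented():
    train_set, val_set = _tiny_sets()
    before = [(p.image.copy(), p.label.copy()) for p in val_set]
    cfg = TrainConfig(epochs=3, val_every_k_epochs=1, patch_size=(16, 16, 16),
                      n_buckets=3, n_ops=2, seed=1,
                      augmentation_mode="bucketaugment")
    train(train_set, val_set, GaussianFeatureSegmenter(seed=1), cfg)
    for patch, (img, lab) in zip(val_set, before):
        np.testing.assert_array_equal(patch.image, img)
        np.testing.assert_array_equal(patch.label, lab)


def test_train_identifies_designated_good_bucket():
    """Each bucket is a pure intensity rescale with a distinct magnitude,
    so the augmented training data fingerprints the active bucket; the
    validation loss of the mock trainer falls only under bucket 2."""
    from bucketaugment import Bucket, SearchSpace, TransformSpec

    const = VolumePatch(np.full((8, 8, 8), 1.0),
                        np.zeros((8, 8, 8), dtype=np.int16))
    magnitudes = [0.1, 0.4, 0.7, 1.0]
    space = SearchSpace(
        buckets=tuple(
            Bucket(index=i, specs=(TransformSpec("intensity", 0, m),))
            for i, m in enumerate(magnitudes)
        ),
        n_buckets=4, n_ops=1, seed=0,
    )
    cfg = TrainConfig(epochs=40, val_every_k_epochs=1, patch_size=(8, 8, 8),
                      n_buckets=4, n_ops=1, seed=2, batch_size=1,
                      augmentation_mode="bucketaugment")
    trainer = ScriptedTrainer(good_mean=magnitudes[2])
    _, controller, _ = train([const], [const], trainer, cfg,
                             search_space=space)
    assert best_bucket(controller) == 2


def test_empty_sets_rejected():
    train_set, val_set = _tiny_sets()
    cfg = TrainConfig(epochs=1, patch_size=(16, 16, 16))
    with pytest.raises(ValueError, match="empty"):
        train([], val_set, GaussianFeatureSegmenter(), cfg)
    with pytest.raises(ValueError, match="empty"):
        train(train_set, [], GaussianFeatureSegmenter(), cfg)


def test_builtin_segmenter_learns_phantoms():
    train_set, val_set = _tiny_sets(n_train=4, n_val=2)
    cfg = TrainConfig(epochs=12, val_every_k_epochs=4, patch_size=(16, 16, 16),
                      batch_size=2, seed=0, augmentation_mode="none")
    model = GaussianFeatureSegmenter(n_classes=3, seed=0)
    _, _, log = train(train_set, val_set, model, cfg)
    dice = evaluate_dice(model, val_set)
    assert dice[1] > 0.8 and dice[2] > 0.8
    assert log[-1].val_loss < log[0].val_loss
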