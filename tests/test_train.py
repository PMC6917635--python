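"""Loss, optimizer, scheduler and the desk-scale training loop."""

import numpy as np
import pytest

from tinyseg.archspec import build_model
from tinyseg.data import SceneProfile, one_hot, synthesize_dataset
from tinyseg.nn import init_params
from tinyseg.train import (
    AdamState,
    PlateauScheduler,
    TrainConfig,
    adam_step,
    evaluate,
    train,
    weighted_cross_entropy,
)

# --- weighted cross-entropy ---------------------------------------------


def test_confident_correct_prediction_near_zero_loss():
    target = np.zeros((1, 2, 2, 3), np.float32)
    target[..., 1] = 1
    logits = 50.0 * target
    loss, _ = weighted_cross_entropy(logits, target)
    assert loss == pytest.approx(0.0, abs=1e-6)


def test_uniform_prediction_loss_is_log_c():
    rng = np.random.default_rng(0)
    for c in (2, 3, 5):
        labels = rng.integers(0, c, (1, 4, 4))
        target = np.eye(c, dtype=np.float32)[labels]
        loss, _ = weighted_cross_entropy(np.zeros((1, 4, 4, c)), target)
        assert loss == pytest.approx(np.log(c), rel=1e-6)


def test_loss_matches_per_pixel_loop_with_weights():
    rng = np.random.default_rng(1)
    logits = rng.standard_normal((2, 3, 3, 4))
    labels = rng.integers(0, 4, (2, 3, 3))
    target = np.eye(4)[labels]
    weights = np.array([0.1, 1.0, 2.5, 0.7])

    loss, _ = weighted_cross_entropy(logits, target, weights)

    total, total_w = 0.0, 0.0
    for n in range(2):
        for i in range(3):
            for j in range(3):
                z = logits[n, i, j]
                p = np.exp(z - z.max())
                p /= p.sum()
                c = labels[n, i, j]
                total += weights[c] * -np.log(p[c])
                total_w += weights[c]
    assert loss == pytest.approx(total / total_w, rel=1e-6)


def test_loss_gradient_matches_finite_differences():
    rng = np.random.default_rng(2)
    logits = rng.standard_normal((1, 2, 2, 3))
    target = np.eye(3)[rng.integers(0, 3, (1, 2, 2))]
    weights = np.array([0.5, 1.0, 2.0])
    _, grad = weighted_cross_entropy(logits, target, weights)
    eps = 1e-6
    for idx in np.ndindex(logits.shape):
        up, down = logits.copy(), logits.copy()
        up[idx] += eps
        down[idx] -= eps
        numeric = (
            weighted_cross_entropy(up, target, weights)[0]
            - weighted_cross_entropy(down, target, weights)[0]
        ) / (2 * eps)
        assert grad[idx] == pytest.approx(numeric, abs=1e-6)


def test_loss_validates_shapes_and_weights():
    with pytest.raises(ValueError):
        weighted_cross_entropy(np.zeros((1, 2, 2, 3)), np.zeros((1, 2, 2, 2)))
    with pytest.raises(ValueError):
        weighted_cross_entropy(
            np.zeros((1, 2, 2, 3)), np.zeros((1, 2, 2, 3)), np.ones(2)
        )


# --- optimizer / scheduler ----------------------------------------------


def test_adam_minimizes_quadratic():
    params = {"l": {"w": np.array([5.0, -3.0])}}
    state = AdamState.for_params(params)
    for _ in range(400):
        grads = {"l": {"w": 2.0 * params["l"]["w"]}}
        adam_step(params, grads, state, lr=0.05)
    np.testing.assert_allclose(params["l"]["w"], 0.0, atol=1e-3)


def test_plateau_scheduler_contract():
    sched = PlateauScheduler(1e-3, factor=0.1, patience=3, min_delta=1e-4)
    # constant validation loss -> drop after `patience` stale epochs
    lrs = [sched.step(1.0) for _ in range(8)]
    assert lrs[:3] == [1e-3, 1e-3, 1e-3]  # first call records the best
    assert lrs[3] == pytest.approx(1e-4)  # then 3 stale epochs -> drop
    assert lrs[6] == pytest.approx(1e-5)


def test_plateau_scheduler_resets_on_improvement():
    sched = PlateauScheduler(1e-3, factor=0.1, patience=2, min_delta=1e-4)
    assert sched.step(1.0) == 1e-3
    assert sched.step(0.5) == 1e-3   # improvement
    assert sched.step(0.5) == 1e-3   # stale 1 (below min_delta)
    assert sched.step(0.4) == 1e-3   # improvement resets counter
    assert sched.step(0.4) == 1e-3   # stale 1
    assert sched.step(0.4) == pytest.approx(1e-4)  # stale 2 -> drop


# --- training loop ------------------------------------------------------


def _dataset(n, classes, size, seed):
    scenes = synthesize_dataset(
        n, classes, height=size, width=size, seed=seed,
        profile=SceneProfile.easy(),
    )
    images = np.stack([s.image for s in scenes])
    labels = np.stack([s.mask for s in scenes])
    return images, labels, np.stack([one_hot(m, classes) for m in labels])


def test_training_reduces_loss_and_records_history(tmp_path):
    images, labels, hot = _dataset(10, 2, 32, seed=0)
    spec = build_model("fcn", tiny=True, n_classes=2, input_size=32)
    config = TrainConfig.desk_scale(epochs=5, seed=0)
    params, history = train(
        spec, (images[:8], hot[:8]), (images[8:], hot[8:]), config
    )
    assert history.train_loss[-1] < history.train_loss[0]
    assert len(history.train_loss) == len(history.val_loss) == 5
    assert 0 <= history.best_epoch < 5
    assert history.learning_rate == sorted(history.learning_rate, reverse=True)
    csv_path = tmp_path / "history.csv"
    history.to_csv(csv_path)
    lines = csv_path.read_text().splitlines()
    assert lines[0] == "epoch,train_loss,val_loss,learning_rate"
    assert len(lines) == 6


def test_training_deterministic_given_seed():
    images, labels, hot = _dataset(8, 2, 32, seed=3)
    spec = build_model("subpixel", tiny=True, n_classes=2, input_size=32)
    config = TrainConfig.desk_scale(epochs=2, seed=5)
    p1, h1 = train(spec, (images[:6], hot[:6]), (images[6:], hot[6:]), config)
    p2, h2 = train(spec, (images[:6], hot[:6]), (images[6:], hot[6:]), config)
    assert h1.train_loss == h2.train_loss
    for lname in p1:
        for key in p1[lname]:
            np.testing.assert_array_equal(p1[lname][key], p2[lname][key])


def test_train_rejects_class_mismatch_and_missing_class():
    images, labels, hot = _dataset(8, 2, 32, seed=1)
    spec3 = build_model("fcn", tiny=True, n_classes=3, input_size=32)
    with pytest.raises(ValueError):
        train(spec3, (images[:6], hot[:6]), (images[6:], hot[6:]),
              TrainConfig.desk_scale(epochs=1))
    spec2 = build_model("fcn", tiny=True, n_classes=2, input_size=32)
    empty = hot.copy()
    empty[..., 1] = 0.0
    empty[..., 0] = 1.0
    with pytest.raises(ValueError, match="never occurs"):
        train(spec2, (images[:6], empty[:6]), (images[6:], empty[6:]),
              TrainConfig.desk_scale(epochs=1))


def test_random_model_on_balanced_masks_scores_chance():
    # balanced 2-class masks: left half class 0, right half class 1.
    # An untrained model's prediction is label-independent, so accuracy
    # lands at chance level 0.5 (exactly, if it predicts one class).
    rng = np.random.default_rng(4)
    images = rng.uniform(0, 1, (6, 32, 32, 3)).astype(np.float32)
    labels = np.zeros((6, 32, 32), np.int64)
    labels[:, :, 16:] = 1
    spec = build_model("fcn", tiny=True, n_classes=2, input_size=32)
    report, _ = evaluate(spec, init_params(spec, rng=0), images, labels)
    assert report["pixel_accuracy"] == pytest.approx(0.5, abs=0.1)


def test_class_balancing_improves_minority_recall():
    # ~95/5 imbalanced 2-class scenes; average minority-class recall over
    # three seeds must be strictly higher with balancing than without.
    profile = SceneProfile(
        min_objects=1, max_objects=1, min_axis_frac=0.08, max_axis_frac=0.12,
        color_jitter=0.04, pixel_noise=0.02, background_noise=0.03,
    )
    scenes = synthesize_dataset(14, 2, height=32, width=32, seed=6,
                                profile=profile)
    images = np.stack([s.image for s in scenes])
    labels = np.stack([s.mask for s in scenes])
    hot = np.stack([one_hot(m, 2) for m in labels])
    freq = np.bincount(labels.ravel(), minlength=2) / labels.size
    assert freq[0] > 0.9  # confirm the imbalance premise

    spec = build_model("fcn", tiny=True, n_classes=2, input_size=32)
    recalls = {True: [], False: []}
    for seed in (0, 1, 2):
        for balanced in (True, False):
            config = TrainConfig.desk_scale(
                epochs=6, seed=seed, class_balancing=balanced
            )
            params, _ = train(
                spec, (images[:10], hot[:10]), (images[10:12], hot[10:12]),
                config,
            )
            _, cm = evaluate(spec, params, images[12:], labels[12:])
            row = cm.counts[1]
            recalls[balanced].append(row[1] / max(row.sum(), 1))
    assert np.mean(recalls[True]) > np.mean(recalls[False])
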