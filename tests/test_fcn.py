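"""FCN construction, training mechanics, prediction, gradient correctness."""

import numpy as np
import pytest

from musclemap import _layers as L
from musclemap.fcn import (
    FCNConfig,
    FCNNet,
    FCNSegmenter,
    TrainConfig,
    build_fcn,
    muscle_mask,
    predict,
    train,
)
from musclemap.phantom import generate_cohort
from musclemap.windowing import WindowConfig, hu_to_gray


def _tiny_pairs(spec, n, seed=0, window=WindowConfig(40, 400, 8)):
    cohort = generate_cohort({"s": (0.9, 1.1)}, n, seed, base_spec=spec)
    return [(hu_to_gray(s.image, window), s.labels) for s in cohort], cohort


@pytest.mark.parametrize("stride, n_fusions", [(32, 0), (16, 1), (8, 2), (4, 3), (2, 4)])
def test_fusion_count_and_output_shape(stride, n_fusions):
    cfg = FCNConfig(fusion_stride=stride, base_channels=4)
    assert cfg.n_fusions == n_fusions
    net = build_fcn(cfg)
    x = np.random.default_rng(0).normal(size=(1, 1, 64, 64))
    scores = net.forward(x)
    assert scores.shape == (1, 3, 64, 64)
    assert len(net.ups) == n_fusions and len(net.skips) == n_fusions


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="fusion_stride"):
        build_fcn(FCNConfig(fusion_stride=5))
    with pytest.raises(ValueError, match="n_classes"):
        build_fcn(FCNConfig(n_classes=1))
    with pytest.raises(NotImplementedError):
        build_fcn(FCNConfig(pretrained_backbone=True))


def test_input_must_be_divisible_by_32():
    net = build_fcn(FCNConfig(base_channels=4))
    with pytest.raises(ValueError, match="divisible by 32"):
        net.forward(np.zeros((1, 1, 50, 50)))


def test_prediction_codomain_and_tie_break(tiny_spec):
    pairs, _ = _tiny_pairs(tiny_spec, 2)
    net = build_fcn(FCNConfig(base_channels=4))
    lab = predict(net, pairs[0][0])
    assert set(np.unique(lab.classes)) <= {0, 1, 2}
    # all-zero score heads produce identically-zero scores -> class 0
    for layer in [net.score5, *net.skips, *net.ups, net.final_up]:
        for key in layer.params:
            layer.params[key][:] = 0.0
    lab0 = predict(net, pairs[0][0])
    assert np.all(lab0.classes == 0)


def test_training_is_deterministic(tiny_spec):
    pairs, _ = _tiny_pairs(tiny_spec, 4)
    histories = []
    for _ in range(2):
        net = build_fcn(FCNConfig(base_channels=4), seed=3)
        model = train(net, pairs, TrainConfig(epochs=2, seed=3, batch_size=2))
        histories.append(model.loss_history)
    assert histories[0] == histories[1]
    assert len(histories[0]) == 2


def test_training_reduces_loss(small_spec):
    pairs, _ = _tiny_pairs(small_spec, 8)
    net = build_fcn(FCNConfig(fusion_stride=2), seed=0)
    model = train(net, pairs, TrainConfig(epochs=8, seed=0))
    assert model.loss_history[-1] < model.loss_history[0]


def test_train_input_validation(tiny_spec):
    pairs, _ = _tiny_pairs(tiny_spec, 2)
    net = build_fcn(FCNConfig(base_channels=4))
    with pytest.raises(ValueError, match="empty"):
        train(net, [], TrainConfig())
    bad = [(pairs[0][0], np.full((32, 32), 7, dtype=np.uint8))]
    with pytest.raises(ValueError, match="label"):
        train(net, bad, TrainConfig())


def test_fullscale_preset_hyperparameters():
    cfg = TrainConfig.fullscale_preset()
    assert cfg.learning_rate == 1e-10
    assert cfg.weight_decay == 1e-12
    assert cfg.momentum == 0.9
    assert cfg.batch_size == 8
    assert cfg.epochs == 500
    assert cfg.loss_mode == "unnormalized"


def test_unnormalized_loss_is_pixel_sum():
    rng = np.random.default_rng(0)
    logits = rng.normal(size=(2, 3, 4, 4))
    labels = rng.integers(0, 3, size=(2, 4, 4))
    l_norm, _ = L.softmax_cross_entropy(logits, labels, "normalized")
    l_sum, _ = L.softmax_cross_entropy(logits, labels, "unnormalized")
    assert l_sum == pytest.approx(l_norm * 2 * 4 * 4)


def test_muscle_mask_extraction():
    lab = np.array([[0, 1], [2, 1]], dtype=np.uint8)
    np.testing.assert_array_equal(muscle_mask(lab).values, [[False, True], [False, True]])
    assert muscle_mask(np.full((2, 2), 2, np.uint8)).area_px == 0


def test_mirror_equivariance_smoke(small_spec):
    """Prediction quality should be nearly unchanged when segmenting the
    mirrored image and mirroring the result back (convolutional locality)."""
    from musclemap.metrics import dsc

    pairs, cohort = _tiny_pairs(small_spec, 9)
    net = build_fcn(FCNConfig(fusion_stride=2), seed=1)
    model = train(net, pairs[:8], TrainConfig(epochs=10, seed=1))
    gray, labels = pairs[8]
    gt = muscle_mask(labels)
    direct = dsc(gt, muscle_mask(predict(model, gray)))
    mirrored_gray = type(gray)(gray.values[:, ::-1].copy(), gray.window)
    back = muscle_mask(predict(model, mirrored_gray).classes[:, ::-1])
    assert abs(direct - dsc(gt, back)) < 0.05


def test_gradients_match_finite_differences():
    """Central-difference check through the full skip-fusion graph."""
    cfg = FCNConfig(fusion_stride=2, base_channels=4)
    net = FCNNet(cfg, seed=0, dtype=np.float64)
    rng = np.random.default_rng(1)
    x = rng.normal(0.0, 0.3, (1, 1, 32, 32))
    y = rng.integers(0, 3, (1, 32, 32))

    def loss():
        return L.softmax_cross_entropy(net.forward(x), y)[0]

    base_scores = net.forward(x)
    _, dscores = L.softmax_cross_entropy(base_scores, y)
    net.backward(dscores)
    eps = 1e-5
    for layer in net.layers():
        if not layer.params:
            continue
        for key, param in layer.params.items():
            flat, gflat = param.ravel(), layer.grads[key].ravel()
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                old = flat[idx]
                flat[idx] = old + eps
                lp = loss()
                flat[idx] = old - eps
                lm = loss()
                flat[idx] = old
                fd = (lp - lm) / (2 * eps)
                denom = max(abs(fd) + abs(gflat[idx]), 1e-8)
                assert abs(fd - gflat[idx]) / denom < 1e-4


def test_sklearn_estimator_interface(tiny_spec):
    pairs, cohort = _tiny_pairs(tiny_spec, 4)
    est = FCNSegmenter(fusion_stride=8, base_channels=4, epochs=2, random_state=1)
    X = [g for g, _ in pairs]
    y = [l.classes for _, l in pairs]
    est.fit(X, y)
    assert len(est.loss_history_) == 2
    preds = est.predict(X)
    assert preds.shape == (4, 32, 32)
    masks = est.predict_muscle_masks(X)
    assert masks.dtype == bool
    # get_params/set_params round-trip (sklearn contract)
    params = est.get_params()
    assert params["fusion_stride"] == 8
    est.set_params(epochs=3)
    assert est.epochs == 3
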