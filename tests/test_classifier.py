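"""CNN building blocks, training mechanics, evaluation, model choice."""

import numpy as np
import pytest

from grainsight import nn
from grainsight.classifier import (
    ArchitectureSpec,
    EvaluationReport,
    TrainConfig,
    build_model,
    compare_models,
    evaluate,
    predict,
    synthesize_labeled_crops,
    train,
    zero_residual_transform,
)
from grainsight.stacking import GrainCrop
from grainsight.synthetic_scenes import SceneSpec

TINY = ArchitectureSpec(name="vgg19_variant", vgg_widths=(4, 4, 8, 8, 8))


def _toy_crops(n, rng, labels=None):
    out = []
    for i in range(n):
        label = labels[i] if labels else ("perfect" if i % 2 == 0 else "imperfect")
        t = rng.integers(0, 256, (100, 100, 5)).astype(np.uint8)
        out.append(GrainCrop(t, "toy", i, label))
    return out


class TestArchitectures:
    def test_unknown_architecture(self):
        with pytest.raises(ValueError):
            build_model(ArchitectureSpec(name="alexnet"))

    def test_vgg_manifest_taxonomy(self):
        model = build_model(ArchitectureSpec(name="vgg19_variant"))
        kinds = [k for k, _ in model.layer_manifest()]
        assert kinds.count("conv") == 5
        assert kinds.count("batch_norm") == 5
        assert kinds.count("activation") == 5
        assert kinds.count("pool") == 5
        assert kinds.count("fully_connected") == 1
        assert model.total_layers() == 24

    def test_resnet_block_layout(self):
        model = build_model(ArchitectureSpec(name="resnet50"))
        kinds = [k for k, _ in model.layer_manifest()]
        assert kinds.count("residual_conv_block") == 4
        assert kinds.count("residual_id_block") == (3 - 1) + (4 - 1) + (6 - 1) + (3 - 1)
        assert model.count_convolutions() == 49
        assert model.count_fully_connected() == 1

    def test_forward_softmax_normalized(self):
        model = build_model(ArchitectureSpec(name="resnet50"), seed=0)
        probs = model.predict_proba(np.zeros((3, 5, 100, 100), dtype=np.float32))
        assert probs.shape == (3, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()


class TestResidualBlock:
    def test_identity_property_with_zeroed_transform(self):
        """With F-weights zeroed and batch norm bypassed, Y = x exactly for
        nonnegative inputs (residual formula with F = 0)."""
        rng = np.random.default_rng(0)
        block = nn.Bottleneck(16, 4, 16, rng)
        zero_residual_transform(block)
        x = np.abs(rng.normal(size=(2, 16, 9, 9))).astype(np.float32)
        assert np.array_equal(block.forward(x, train=False), x)

    def test_identity_shortcut_requires_matching_shapes(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            nn.Bottleneck(16, 4, 32, rng, projection=False)


def test_backprop_matches_finite_differences():
    """Analytic gradients of a conv->bn->relu->pool->fc net agree with
    central finite differences on a handful of parameters."""
    rng = np.random.default_rng(3)
    net = nn.Sequential([
        nn.Conv2d(2, 3, 3, rng),
        nn.BatchNorm2d(3),
        nn.ReLU(),
        nn.MaxPool2d(),
        nn.Flatten(),
        nn.Linear(3 * 4 * 4, 2, rng),
    ])
    x = rng.normal(size=(4, 2, 8, 8)).astype(np.float32)
    y = np.array([0, 1, 1, 0])

    def loss_of():
        logits = net.forward(x, train=True)
        return nn.cross_entropy(logits, y)[0]

    logits = net.forward(x, train=True)
    _, dlogits = nn.cross_entropy(logits, y)
    for p in net.params():
        p.g.fill(0.0)
    net.backward(dlogits)

    eps = 1e-2
    checked = 0
    for p in net.params():
        flat_v, flat_g = p.v.ravel(), p.g.ravel()
        for idx in range(0, flat_v.size, max(1, flat_v.size // 3)):
            orig = flat_v[idx]
            flat_v[idx] = orig + eps
            up = loss_of()
            flat_v[idx] = orig - eps
            dn = loss_of()
            flat_v[idx] = orig
            fd = (up - dn) / (2 * eps)
            assert abs(fd - flat_g[idx]) < 5e-2 * max(1.0, abs(fd))
            checked += 1
    assert checked >= 10


class TestTraining:
    def test_smoke_one_epoch_two_crops(self):
        rng = np.random.default_rng(0)
        crops = _toy_crops(2, rng)
        model = build_model(TINY, seed=0)
        hist = train(model, crops, TrainConfig(max_epochs=1, seed=0))
        assert len(hist.loss) == 1

    def test_same_seed_same_final_loss(self):
        rng = np.random.default_rng(1)
        crops = _toy_crops(12, rng)
        losses = []
        for _ in range(2):
            model = build_model(TINY, seed=5)
            hist = train(model, crops, TrainConfig(max_epochs=2, seed=5))
            losses.append(hist.loss[-1])
        assert losses[0] == losses[1]

    def test_single_class_rejected(self):
        rng = np.random.default_rng(2)
        crops = _toy_crops(4, rng, labels=["perfect"] * 4)
        model = build_model(TINY, seed=0)
        with pytest.raises(ValueError, match="both classes"):
            train(model, crops, TrainConfig(max_epochs=1))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(max_epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)


class TestPredict:
    def test_empty_crop_list(self):
        model = build_model(TINY, seed=0)
        labels, probs = predict(model, [])
        assert labels == [] and probs.shape == (0, 2)

    def test_probability_rows_and_order_invariance(self):
        rng = np.random.default_rng(3)
        crops = _toy_crops(6, rng)
        model = build_model(TINY, seed=1)
        labels, probs = predict(model, crops)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        perm = [3, 0, 5, 1, 4, 2]
        labels_p, probs_p = predict(model, [crops[i] for i in perm])
        assert np.allclose(probs_p, probs[perm], atol=1e-6)
        assert labels_p == [labels[i] for i in perm]


class TestEvaluate:
    def test_perfect_agreement(self):
        rep = evaluate(["perfect", "perfect", "imperfect", "imperfect"],
                       ["perfect", "perfect", "imperfect", "imperfect"])
        assert rep.overall_accuracy == 1.0
        assert rep.confusion_matrix.trace() == 4

    def test_total_disagreement(self):
        rep = evaluate(["imperfect", "perfect"], ["perfect", "imperfect"])
        assert rep.overall_accuracy == 0.0

    def test_mixed_validation_counts(self):
        """25 perfect all correct plus 21/25 imperfect -> 46/50 = 92%."""
        truth = ["perfect"] * 25 + ["imperfect"] * 25
        pred = ["perfect"] * 25 + ["imperfect"] * 21 + ["perfect"] * 4
        rep = evaluate(pred, truth)
        assert rep.overall_accuracy == pytest.approx(0.92)
        assert rep.per_class_accuracy[0] == 1.0
        assert rep.per_class_accuracy[1] == pytest.approx(21 / 25)
        assert rep.confusion_matrix.sum() == 50

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate(["perfect"], [])


class TestCompareModels:
    def _rep(self, acc):
        return EvaluationReport(np.zeros((2, 2), dtype=int), (acc, acc), acc)

    def test_higher_accuracy_wins(self):
        choice = compare_models(("vgg19_variant", self._rep(0.922), 10_000),
                                ("resnet50", self._rep(0.913), 20_000))
        assert choice == "vgg19_variant"

    def test_tie_goes_to_smaller_model(self):
        choice = compare_models(("big", self._rep(0.9), 1000),
                                ("small", self._rep(0.9), 10))
        assert choice == "small"

    def test_single_candidate(self):
        assert compare_models(("only", self._rep(0.5), 1)) == "only"


def test_nir_only_defect_signal_needs_five_channels():
    """When the defect contrast is placed exclusively in the NIR planes, a
    five-channel model beats the same architecture trained on RGB alone."""
    spec = SceneSpec(width=560, height=560, n_grains=48, adhesion_prob=0.0,
                     imperfect_frac=0.5, defect_mix=(1.0, 0.0, 0.0),
                     lesion_contrast_rgb=0.0, lesion_contrast_nir=45.0)
    tr = synthesize_labeled_crops(300, spec=spec, seed=5)
    te = synthesize_labeled_crops(120, spec=spec, seed=600005)
    truth = [c.label for c in te]
    widths = (8, 12, 16, 24, 32)
    cfg = TrainConfig(max_epochs=4, seed=3, early_stop_patience=10)

    m5 = build_model(ArchitectureSpec(name="vgg19_variant", vgg_widths=widths), seed=3)
    train(m5, tr, cfg)
    acc5 = evaluate(predict(m5, te)[0], truth).overall_accuracy

    m3 = build_model(ArchitectureSpec(name="vgg19_variant",
                                      input_shape=(100, 100, 3),
                                      vgg_widths=widths), seed=3)
    train(m3, tr, cfg, channels=[0, 1, 2])
    acc3 = evaluate(predict(m3, te, channels=[0, 1, 2])[0], truth).overall_accuracy

    assert acc5 > acc3
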