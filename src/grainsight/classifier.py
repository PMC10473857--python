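"""Perfect/imperfect grain classification with two CNN architectures.

Two networks are provided for five-channel 100 x 100 grain crops:

* ``vgg19_variant`` — a compact VGG-style stack of five
  (conv 3x3 -> batch-norm -> ReLU -> max-pool 2x2) stages followed by one
  fully-connected layer and a softmax.  Under the layer taxonomy used for
  grain inspection networks (input + conv + batch-norm + activation + pool
  + fully-connected + softmax + output) it totals 24 layers.
* ``resnet50`` — a 7x7 stem convolution, max pooling, four stages of
  bottleneck residual blocks with depths (3, 4, 6, 3) (the first block per
  stage a projection block, the rest identity blocks, three convolutions
  each), global average pooling and one fully-connected layer:
  1 + 3 x (3 + 4 + 6 + 3) = 49 convolution layers plus 1 fully-connected
  layer.  Shortcut projections are shape-matching maps and are not counted,
  following the conventional ResNet-50 accounting.

Both accept an arbitrary number of input channels (five-channel crops
preclude standard RGB-pretrained weights, so training is always from a
seeded random initialization).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import nn
from .stacking import CROP_SIZE, GrainCrop, crops_from_ground_truth
from .synthetic_scenes import SceneSpec, generate_scene, scene_seed

CLASS_NAMES = ("perfect", "imperfect")


@dataclass(frozen=True)
class ArchitectureSpec:
    """What to build: architecture family, input shape and widths."""

    name: str = "vgg19_variant"  # or 'resnet50'
    input_shape: tuple[int, int, int] = (CROP_SIZE, CROP_SIZE, 5)
    n_classes: int = 2
    # VGG stage widths; compact defaults sized for CPU training
    vgg_widths: tuple[int, ...] = (16, 32, 64, 128, 256)
    # ResNet bottleneck widths (stem, per-stage mid channels, expansion)
    resnet_stem: int = 16
    resnet_mids: tuple[int, int, int, int] = (8, 16, 32, 64)
    resnet_expansion: int = 4


@dataclass
class TrainConfig:
    """Training hyperparameters (Adam at lr 0.001, 100-epoch cap)."""

    max_epochs: int = 100
    learning_rate: float = 0.001
    batch_size: int = 32
    seed: int = 0
    optimizer: str = "adam"
    early_stop_patience: int = 10
    val_fraction: float = 0.15

    def __post_init__(self):
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class EvaluationReport:
    """2x2 confusion matrix (rows = true, cols = predicted) and accuracies."""

    confusion_matrix: np.ndarray
    per_class_accuracy: tuple[float, float]
    overall_accuracy: float


class GrainClassifier:
    """A built network plus its architecture manifest."""

    def __init__(self, spec: ArchitectureSpec, net: nn.Sequential,
                 manifest: list[tuple[str, dict]]):
        self.spec = spec
        self.net = net
        self._manifest = manifest

    def layer_manifest(self) -> list[tuple[str, dict]]:
        return list(self._manifest)

    def total_layers(self) -> int:
        return len(self._manifest)

    def count_convolutions(self) -> int:
        n = sum(1 for kind, _ in self._manifest if kind == "conv")
        n += 3 * sum(
            1 for kind, _ in self._manifest
            if kind in ("residual_id_block", "residual_conv_block")
        )
        return n

    def count_fully_connected(self) -> int:
        return sum(1 for kind, _ in self._manifest if kind == "fully_connected")

    def n_parameters(self) -> int:
        return int(sum(p.v.size for p in self.net.params()))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x.astype(np.float32), train)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(nn.softmax(self.forward(x[i:i + batch_size], train=False)))
        return np.concatenate(out) if out else np.empty((0, self.spec.n_classes))


def build_model(spec: ArchitectureSpec, seed: int = 0) -> GrainClassifier:
    """Build a seeded, randomly initialized network per ``spec``."""
    rng = np.random.default_rng(seed)
    h, w, in_ch = spec.input_shape
    if spec.name == "vgg19_variant":
        layers: list[nn.Layer] = []
        manifest: list[tuple[str, dict]] = [("input", {"shape": spec.input_shape})]
        prev = in_ch
        sh, sw = h, w
        for width in spec.vgg_widths:
            layers += [
                nn.Conv2d(prev, width, 3, rng),
                nn.BatchNorm2d(width),
                nn.ReLU(),
                nn.MaxPool2d(),
            ]
            manifest += [
                ("conv", {"kernel": 3, "out": width}),
                ("batch_norm", {"ch": width}),
                ("activation", {"kind": "relu"}),
                ("pool", {"kind": "max", "size": 2}),
            ]
            prev = width
            sh, sw = sh // 2, sw // 2
        layers += [nn.Flatten(), nn.Linear(prev * sh * sw, spec.n_classes, rng)]
        manifest += [
            ("fully_connected", {"out": spec.n_classes}),
            ("softmax", {}),
            ("output", {"classes": spec.n_classes}),
        ]
        return GrainClassifier(spec, nn.Sequential(layers), manifest)

    if spec.name == "resnet50":
        stem = spec.resnet_stem
        exp = spec.resnet_expansion
        layers = [
            nn.Conv2d(in_ch, stem, 7, rng, stride=2, pad=3),
            nn.BatchNorm2d(stem),
            nn.ReLU(),
            nn.MaxPool2d(),
        ]
        manifest = [
            ("input", {"shape": spec.input_shape}),
            ("conv", {"kernel": 7, "out": stem, "stride": 2}),
            ("batch_norm", {"ch": stem}),
            ("activation", {"kind": "relu"}),
            ("pool", {"kind": "max", "size": 2}),
        ]
        depths = (3, 4, 6, 3)
        prev = stem
        for si, (mid, depth) in enumerate(zip(spec.resnet_mids, depths)):
            out_ch = mid * exp
            stride = 1 if si == 0 else 2
            layers.append(nn.Bottleneck(prev, mid, out_ch, rng,
                                        stride=stride, projection=True))
            manifest.append(("residual_conv_block",
                             {"mid": mid, "out": out_ch, "stride": stride}))
            for _ in range(depth - 1):
                layers.append(nn.Bottleneck(out_ch, mid, out_ch, rng))
                manifest.append(("residual_id_block", {"mid": mid, "out": out_ch}))
            prev = out_ch
        layers += [nn.GlobalAvgPool(), nn.Linear(prev, spec.n_classes, rng)]
        manifest += [
            ("pool", {"kind": "avg", "global": True}),
            ("fully_connected", {"out": spec.n_classes}),
            ("softmax", {}),
            ("output", {"classes": spec.n_classes}),
        ]
        return GrainClassifier(spec, nn.Sequential(layers), manifest)

    raise ValueError(f"unknown architecture {spec.name!r}")


def zero_residual_transform(block: nn.Bottleneck) -> None:
    """Zero the F-path weights of a block and bypass its batch norms.

    Afterwards an identity block computes ``Y = relu(0 + x) = x`` exactly
    for nonnegative inputs — the residual identity property.
    """
    for layer in block.residual_layers():
        if isinstance(layer, nn.Conv2d):
            layer.W.v.fill(0.0)
            if layer.b is not None:
                layer.b.v.fill(0.0)
        elif isinstance(layer, nn.BatchNorm2d):
            layer.bypass = True


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def crops_to_arrays(
    crops: Sequence[GrainCrop], channels: Optional[Sequence[int]] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Crops -> (X, y): NCHW float32 in [-0.5, 0.5] and integer labels."""
    x = np.stack([c.tensor for c in crops]).astype(np.float32) / 255.0 - 0.5
    if channels is not None:
        x = x[..., list(channels)]
    x = np.moveaxis(x, -1, 1)
    y = np.array(
        [CLASS_NAMES.index(c.label) if c.label is not None else -1 for c in crops],
        dtype=np.int64,
    )
    return np.ascontiguousarray(x), y


def synthesize_labeled_crops(
    n_crops: int,
    spec: Optional[SceneSpec] = None,
    balanced: bool = True,
    seed: int = 0,
) -> list[GrainCrop]:
    """Generate labeled crops from synthetic scenes (training data helper).

    With ``balanced=True`` the output has an equal number of perfect and
    imperfect crops (generation continues until both classes are filled).
    """
    if spec is None:
        spec = SceneSpec(width=640, height=640, n_grains=60, adhesion_prob=0.0,
                         imperfect_frac=0.5 if balanced else 0.3)
    per_class = n_crops // 2
    buckets: dict[str, list[GrainCrop]] = {"perfect": [], "imperfect": []}
    out: list[GrainCrop] = []
    i = 0
    while True:
        if balanced:
            if all(len(b) >= per_class for b in buckets.values()):
                break
        elif len(out) >= n_crops:
            break
        if i > max(4, 4 * n_crops // max(spec.n_grains, 1)) + 64:
            raise RuntimeError("crop synthesis did not converge")
        sspec = replace(spec, seed=scene_seed(seed, 10_000 + i))
        image, gt = generate_scene(sspec)
        for crop in crops_from_ground_truth(image, gt, source_scene=f"synth_{i:03d}"):
            if balanced:
                buckets[crop.label].append(crop)
            else:
                out.append(crop)
        i += 1
    if balanced:
        out = buckets["perfect"][:per_class] + buckets["imperfect"][:per_class]
    return out[:n_crops]


# ---------------------------------------------------------------------------
# training / inference / evaluation
# ---------------------------------------------------------------------------

@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


def train(
    model: GrainClassifier,
    train_crops: Sequence[GrainCrop],
    config: TrainConfig,
    channels: Optional[Sequence[int]] = None,
) -> TrainHistory:
    """Minimize softmax cross-entropy with Adam; deterministic given seed.

    Early stopping monitors accuracy on an internal validation split
    (``config.val_fraction``) with ``config.early_stop_patience``; the best
    weights seen are NOT restored (the history records the trajectory).
    """
    x, y = crops_to_arrays(train_crops, channels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set must contain both classes")
    if config.optimizer != "adam":
        raise ValueError(f"unsupported optimizer {config.optimizer!r}")

    rng = np.random.default_rng(config.seed)
    n = len(x)
    order = rng.permutation(n)
    n_val = int(round(config.val_fraction * n)) if n > 10 else 0
    val_idx, tr_idx = order[:n_val], order[n_val:]
    xv, yv = x[val_idx], y[val_idx]
    xt, yt = x[tr_idx], y[tr_idx]

    opt = nn.Adam(model.net.params(), lr=config.learning_rate)
    history = TrainHistory()
    best_val, since_best = -1.0, 0
    for _epoch in range(config.max_epochs):
        perm = rng.permutation(len(xt))
        losses, correct = [], 0
        for i in range(0, len(xt), config.batch_size):
            idx = perm[i:i + config.batch_size]
            xb, yb = xt[idx], yt[idx]
            logits = model.net.forward(xb, train=True)
            loss, dlogits = nn.cross_entropy(logits, yb)
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"training aborted: non-finite loss at epoch {_epoch}"
                )
            opt.zero_grad()
            model.net.backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == yb).sum())
        history.loss.append(sum(losses) / len(xt))
        history.train_accuracy.append(correct / len(xt))
        if n_val:
            pv = model.predict_proba(xv).argmax(axis=1)
            acc = float((pv == yv).mean())
            history.val_accuracy.append(acc)
            if acc > best_val + 1e-12:
                best_val, since_best = acc, 0
            else:
                since_best += 1
                if since_best >= config.early_stop_patience:
                    break
    return history


def predict(
    model: GrainClassifier,
    crops: Sequence[GrainCrop],
    channels: Optional[Sequence[int]] = None,
) -> tuple[list[str], np.ndarray]:
    """Class names and softmax probabilities for each crop."""
    if not crops:
        return [], np.empty((0, 2))
    x, _ = crops_to_arrays(crops, channels)
    probs = model.predict_proba(x)
    labels = [CLASS_NAMES[int(i)] for i in probs.argmax(axis=1)]
    return labels, probs


def evaluate(predictions: Sequence[str], truth: Sequence[str]) -> EvaluationReport:
    """Confusion matrix (rows = true, cols = predicted) and accuracies."""
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth must have equal length")
    cm = np.zeros((2, 2), dtype=np.int64)
    for p, t in zip(predictions, truth):
        cm[CLASS_NAMES.index(t), CLASS_NAMES.index(p)] += 1
    with np.errstate(invalid="ignore"):
        per_class = cm.diagonal() / np.maximum(cm.sum(axis=1), 1)
    overall = float(cm.trace() / cm.sum()) if cm.sum() else float("nan")
    return EvaluationReport(cm, (float(per_class[0]), float(per_class[1])), overall)


def compare_models(
    *candidates: tuple[str, EvaluationReport, int]
) -> str:
    """Pick the model with the higher overall accuracy; ties go to the
    smaller model (fewer parameters).  Each candidate is
    ``(name, report, n_parameters)``; a single candidate is returned as is.
    """
    if not candidates:
        raise ValueError("no candidates")
    best = candidates[0]
    for cand in candidates[1:]:
        if cand[1].overall_accuracy > best[1].overall_accuracy:
            best = cand
        elif cand[1].overall_accuracy == best[1].overall_accuracy and cand[2] < best[2]:
            best = cand
    return best[0]
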