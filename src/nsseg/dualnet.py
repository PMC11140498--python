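"""Small dual-branch patch model: classification + segmentation heads.

The model follows the patch-based fully convolutional contract: it takes a
patch of an image and returns an image-level lesion probability (the
classification branch) and a per-pixel probability map of the same shape
(the segmentation branch).  Patch-level class labels are derived from the
pixel labels by checking whether the patch contains any positive pixel.
Pixel targets may be tri-state (negative / positive / ignore); ignore
pixels generate no loss, which is how ranked pseudo-labels express
uncertainty.

The network is deliberately small — a two-level fully convolutional
encoder–decoder with a skip connection, a global-average-pooled linear
classification head and a 1x1-conv sigmoid pixel head — and is implemented
directly on numpy arrays with hand-written backpropagation and Adam, so
training a model on the desk-scale phantom corpus takes seconds on one
CPU.  All training and inference is driven by explicit
``numpy.random.Generator`` seeds and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

__all__ = [
    "NEG",
    "POS",
    "IGNORE",
    "TriStateMask",
    "TrainConfig",
    "TrainingSample",
    "ExamPrediction",
    "PatchNet",
    "patch_label",
    "extract_patches",
    "forward",
    "masked_pixel_loss",
    "classification_loss",
    "train",
    "predict_exam",
]

# tri-state pixel label encoding
NEG, POS, IGNORE = 0, 1, 2

_EPS = 1e-7


@dataclass
class TriStateMask:
    """Per-pixel label grid over {NEG, POS, IGNORE}.

    Reference (ground-truth) masks never contain IGNORE; pseudo-label
    masks may.  ``grid`` is an int8 array.
    """

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int8)
        if not np.isin(self.grid, (NEG, POS, IGNORE)).all():
            raise ValueError("mask contains states outside {NEG, POS, IGNORE}")

    @classmethod
    def from_binary(cls, mask: np.ndarray) -> "TriStateMask":
        return cls(np.asarray(mask, dtype=np.int8))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.grid.shape


def _as_grid(mask) -> np.ndarray:
    return mask.grid if isinstance(mask, TriStateMask) else np.asarray(mask)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for one training run.

    ``mixing_ratio`` is the labeled fraction of each minibatch when a
    pseudo-labeled pool is present (0.6 mirrors the 0.6:0.4 mixing of
    labeled to pseudo-labeled data).  ``steps_per_epoch`` is the number of
    minibatch steps per epoch.  ``lambda_cls`` weighs the classification
    loss against the pixel loss in the combined objective.
    """

    epochs: int = 8
    batch_size: int = 16
    crop_size: int = 32
    steps_per_epoch: int = 30
    mixing_ratio: float = 0.6
    learning_rate: float = 0.01
    lambda_cls: float = 1.0
    channels: tuple[int, int] = (8, 16)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mixing_ratio <= 1.0:
            raise ValueError("mixing_ratio must be in [0, 1]")
        if self.crop_size % 2:
            raise ValueError("crop_size must be even (one 2x pooling level)")
        for name in ("epochs", "batch_size", "crop_size", "steps_per_epoch"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class TrainingSample:
    """One unit of the training pool.

    ``mask`` is a tri-state grid ({0,1} for reference data).  When
    ``pixel_loss`` is false the segmentation branch is not supervised on
    this sample (image-label Oracle mode) and ``label_override`` supplies
    the classification target; ``whole_image`` makes the full image the
    patch instead of a random crop.
    """

    image: np.ndarray
    mask: np.ndarray
    source: str = "labeled"
    pixel_loss: bool = True
    whole_image: bool = False
    label_override: int | None = None


@dataclass
class ExamPrediction:
    """Model outputs for one examination."""

    exam_id: str
    image_probs: list[float]
    prob_maps: list[np.ndarray]
    exam_score: float


# ---------------------------------------------------------------------------
# numpy conv-net primitives (NCHW layout, stride-1 same-padding 3x3 convs)
# ---------------------------------------------------------------------------


def _conv3(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
    return np.einsum("nchwij,fcij->nfhw", win, W, optimize=True) + b[:, None, None]


def _conv3_backward(x: np.ndarray, W: np.ndarray, dout: np.ndarray):
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))
    dW = np.einsum("nchwij,nfhw->fcij", win, dout, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    dop = np.pad(dout, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dwin = sliding_window_view(dop, (3, 3), axis=(2, 3))
    Wf = W[:, :, ::-1, ::-1]
    dx = np.einsum("nfhwij,fcij->nchw", dwin, Wf, optimize=True)
    return dW, db, dx


def _pool2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _unpool2(d: np.ndarray) -> np.ndarray:
    return d.repeat(2, axis=2).repeat(2, axis=3)


def _sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


_HIGHPASS_SIGMA = 4.0


def _stack_channels(images: np.ndarray) -> np.ndarray:
    """(N,H,W) -> (N,2,H,W): raw intensity + high-pass residual.

    The second channel subtracts a local Gaussian mean, giving the tiny
    network a brightness-normalized view so lesion contrast survives
    global gamma/brightness shifts that its small receptive field could
    not otherwise factor out.
    """
    blur = ndimage.gaussian_filter(images, sigma=(0, _HIGHPASS_SIGMA, _HIGHPASS_SIGMA))
    return np.stack([images, images - blur], axis=1)


_LEAK = 0.1  # leaky-ReLU slope: keeps narrow channels from dying


def _lrelu(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, z, _LEAK * z)


def _dlrelu(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, 1.0, _LEAK)


class PatchNet:
    """Two-level fully convolutional network with two output branches.

    conv(1->8) -> avgpool/2 -> conv(8->16) -> nearest-upsample x2, skip
    concat with the first feature map, 1x1 conv to the pixel logit map;
    classification logit from a linear head on the globally averaged
    bottleneck features.  The final layers of both branches start at zero,
    so an untrained model outputs probability 0.5 everywhere.
    """

    PARAM_NAMES = ("W1", "b1", "W2", "b2", "w3", "b3", "w4", "b4")

    def __init__(self, params: dict[str, np.ndarray]):
        # copy: training must never mutate a caller's weight dict in place
        self.params = {k: np.array(v, dtype=np.float64) for k, v in params.items()}

    @classmethod
    def init(cls, rng: np.random.Generator, c1: int = 8, c2: int = 16) -> "PatchNet":
        params = {
            "W1": rng.normal(0, math.sqrt(2.0 / 18), size=(c1, 2, 3, 3)),
            "b1": np.zeros(c1),
            "W2": rng.normal(0, math.sqrt(2.0 / (9 * c1)), size=(c2, c1, 3, 3)),
            "b2": np.zeros(c2),
            "w3": np.zeros(c1 + c2),
            "b3": np.zeros(()),
            "w4": np.zeros(c2),
            "b4": np.zeros(()),
        }
        return cls(params)

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    @classmethod
    def from_state(cls, state: dict[str, np.ndarray]) -> "PatchNet":
        return cls({k: state[k] for k in cls.PARAM_NAMES})

    # -- forward / backward -------------------------------------------------

    def _forward(self, x: np.ndarray):
        """x: (N,1,H,W) with H, W even.  Returns logits and a cache."""
        p = self.params
        z1 = _conv3(x, p["W1"], p["b1"])
        a1 = _lrelu(z1)
        pl = _pool2(a1)
        z2 = _conv3(pl, p["W2"], p["b2"])
        a2 = _lrelu(z2)
        up = _unpool2(a2)
        cat = np.concatenate([a1, up], axis=1)
        logit_map = np.einsum("nchw,c->nhw", cat, p["w3"], optimize=True) + p["b3"]
        g = a2.mean(axis=(2, 3))
        logit_cls = g @ p["w4"] + p["b4"]
        cache = (x, z1, a1, pl, z2, a2, cat, g)
        return logit_cls, logit_map, cache

    def _backward(self, cache, dlogit_cls: np.ndarray, dlogit_map: np.ndarray):
        p = self.params
        x, z1, a1, pl, z2, a2, cat, g = cache
        c1 = a1.shape[1]
        h2, w2 = a2.shape[2], a2.shape[3]

        grads = {}
        grads["w4"] = g.T @ dlogit_cls
        grads["b4"] = np.asarray(dlogit_cls.sum())
        dg = np.outer(dlogit_cls, p["w4"])

        grads["w3"] = np.einsum("nhw,nchw->c", dlogit_map, cat, optimize=True)
        grads["b3"] = np.asarray(dlogit_map.sum())
        dcat = dlogit_map[:, None, :, :] * p["w3"][None, :, None, None]

        da1 = dcat[:, :c1]
        dup = dcat[:, c1:]
        da2 = dup.reshape(*dup.shape[:2], h2, 2, w2, 2).sum(axis=(3, 5))
        da2 += dg[:, :, None, None] / (h2 * w2)
        dz2 = da2 * _dlrelu(z2)

        grads["W2"], grads["b2"], dpl = _conv3_backward(pl, p["W2"], dz2)
        da1 = da1 + _unpool2(dpl) / 4.0
        dz1 = da1 * _dlrelu(z1)
        grads["W1"], grads["b1"], _ = _conv3_backward(x, p["W1"], dz1)
        return grads

    def predict_patch(self, patch: np.ndarray) -> tuple[float, np.ndarray]:
        x = _stack_channels(patch.astype(np.float64)[None])
        logit_cls, logit_map, _ = self._forward(x)
        return float(_sigmoid(logit_cls[0])), np.asarray(_sigmoid(logit_map[0]))


def forward(model: PatchNet, image_patch: np.ndarray) -> tuple[float, np.ndarray]:
    """Evaluate the model on one 2D patch -> (class_prob, prob_map)."""
    patch = np.asarray(image_patch, dtype=np.float64)
    if patch.ndim != 2 or patch.shape[0] % 2 or patch.shape[1] % 2:
        raise ValueError(f"expected a 2D patch with even sides, got shape {patch.shape}")
    return model.predict_patch(patch)


# ---------------------------------------------------------------------------
# labels, patches, losses
# ---------------------------------------------------------------------------


def patch_label(mask_patch) -> int:
    """1 iff the patch contains any positive pixel; IGNORE never counts."""
    return int((_as_grid(mask_patch) == POS).any())


def extract_patches(
    image: np.ndarray,
    mask,
    crop_size: int,
    sampler: str = "grid",
    rng: np.random.Generator | None = None,
    n_patches: int = 1,
):
    """Cut (image_patch, mask_patch, patch_label) triples from one image.

    ``sampler="grid"`` tiles a deterministic grid with stride ``crop_size``
    (plus a tail tile flush with each edge so the whole image is covered);
    ``sampler="random"`` draws ``n_patches`` uniform random crops.
    """
    grid = _as_grid(mask)
    h, w = image.shape
    if crop_size > h or crop_size > w:
        raise ValueError("crop_size exceeds image dimensions")
    if sampler == "grid":
        ys = sorted(set(list(range(0, h - crop_size + 1, crop_size)) + [h - crop_size]))
        xs = sorted(set(list(range(0, w - crop_size + 1, crop_size)) + [w - crop_size]))
        positions = [(y, x) for y in ys for x in xs]
    elif sampler == "random":
        if rng is None:
            raise ValueError("random sampler requires rng")
        positions = [
            (int(rng.integers(0, h - crop_size + 1)), int(rng.integers(0, w - crop_size + 1)))
            for _ in range(n_patches)
        ]
    else:
        raise ValueError(f"unknown sampler {sampler!r}")
    out = []
    for y, x in positions:
        ip = image[y : y + crop_size, x : x + crop_size]
        mp = grid[y : y + crop_size, x : x + crop_size]
        out.append((ip, mp, patch_label(mp)))
    return out


def masked_pixel_loss(prob_map: np.ndarray, tri_mask) -> float:
    """Mean binary cross-entropy over non-IGNORE pixels (0 if all ignored)."""
    grid = _as_grid(tri_mask)
    if prob_map.shape != grid.shape:
        raise ValueError("prob_map / mask shape mismatch")
    keep = grid != IGNORE
    if not keep.any():
        return 0.0
    p = np.clip(prob_map[keep], _EPS, 1 - _EPS)
    t = (grid[keep] == POS).astype(np.float64)
    return float(-(t * np.log(p) + (1 - t) * np.log(1 - p)).mean())


def classification_loss(class_prob: float, label: int) -> float:
    """Binary cross-entropy of the classification branch."""
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    p = min(max(float(class_prob), _EPS), 1 - _EPS)
    return float(-(label * math.log(p) + (1 - label) * math.log(1 - p)))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


_CLIP_NORM = 5.0  # global gradient-norm ceiling


def _clip_grads(grads: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    norm = math.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if norm > _CLIP_NORM:
        scale = _CLIP_NORM / norm
        grads = {k: g * scale for k, g in grads.items()}
    return grads


def _prepare_patch(sample: TrainingSample, config: TrainConfig, augment_config, rng):
    """Crop (and optionally noise) one training sample into a patch."""
    image, grid = sample.image, _as_grid(sample.mask)
    if augment_config is not None:
        from .augment import augment_sample  # deferred: avoid module cycle

        image, grid = augment_sample(image, grid, augment_config, rng)
    if sample.whole_image:
        ip, mp = image, grid
    else:
        c = config.crop_size
        y = int(rng.integers(0, image.shape[0] - c + 1))
        x = int(rng.integers(0, image.shape[1] - c + 1))
        ip, mp = image[y : y + c, x : x + c], grid[y : y + c, x : x + c]
    label = sample.label_override if sample.label_override is not None else patch_label(mp)
    return ip, mp, int(label), sample


def _batch_objective(model: PatchNet, prepared, lambda_cls: float):
    """Forward+backward over one minibatch; groups by patch shape.

    Objective = mean over samples of (per-sample masked pixel BCE)
    + lambda_cls * mean over samples of (classification BCE).
    Returns (loss, grads, counters).
    """
    n_total = len(prepared)
    grads = {k: np.zeros_like(v) for k, v in model.params.items()}
    loss = 0.0
    counters = {"pixel_terms": {}, "drawn": {}}

    groups: dict[tuple[int, int], list] = {}
    for item in prepared:
        groups.setdefault(item[0].shape, []).append(item)

    for shape, items in groups.items():
        x = _stack_channels(np.stack([ip for ip, _, _, _ in items]).astype(np.float64))
        logit_cls, logit_map, cache = model._forward(x)
        p_cls = _sigmoid(logit_cls)
        p_map = _sigmoid(logit_map)

        labels = np.array([lab for _, _, lab, _ in items], dtype=np.float64)
        dl_cls = lambda_cls * (p_cls - labels) / n_total
        loss += lambda_cls * sum(
            classification_loss(p, int(l)) for p, l in zip(p_cls, labels)
        ) / n_total

        dl_map = np.zeros_like(logit_map)
        for i, (_, mp, _, sample) in enumerate(items):
            src = sample.source
            counters["drawn"][src] = counters["drawn"].get(src, 0) + 1
            if not sample.pixel_loss:
                continue
            keep = mp != IGNORE
            n_keep = int(keep.sum())
            counters["pixel_terms"][src] = counters["pixel_terms"].get(src, 0) + n_keep
            if n_keep == 0:
                continue
            t = (mp == POS).astype(np.float64)
            dl_map[i] = (p_map[i] - t) * keep / (n_keep * n_total)
            loss += masked_pixel_loss(p_map[i], mp) / n_total

        g = model._backward(cache, dl_cls, dl_map)
        for k in grads:
            grads[k] += g[k]
    return loss, grads, counters


def train(
    init_weights: dict[str, np.ndarray] | None,
    labeled_source: Sequence[TrainingSample],
    pseudo_source: Sequence[TrainingSample] | None,
    config: TrainConfig,
    augment_config=None,
    rng: np.random.Generator | None = None,
    history: dict | None = None,
) -> dict[str, np.ndarray]:
    """Gradient training of the dual-branch model; returns final weights.

    The teacher/baseline trains from scratch on the labeled pool alone;
    the student passes the teacher's weights as ``init_weights`` and adds
    a pseudo-labeled pool, mixed per minibatch at ``config.mixing_ratio``
    labeled to pseudo.  When ``augment_config`` is given every drawn
    sample is noised before cropping.  ``history``, if provided, collects
    per-epoch losses and sampling/loss counters for auditing.
    """
    from .selftrain import mixed_minibatch  # deferred: avoid module cycle

    if not labeled_source:
        raise ValueError("labeled_source must be non-empty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if init_weights is None:
        model = PatchNet.init(rng, c1=config.channels[0], c2=config.channels[1])
    else:
        model = PatchNet.from_state(init_weights)
    opt = _Adam(model.params, config.learning_rate)
    if history is None:
        history = {}
    history.setdefault("epoch_loss", [])
    history.setdefault("drawn", {})
    history.setdefault("pixel_terms", {})

    use_pseudo = bool(pseudo_source) and config.mixing_ratio < 1.0
    total_steps = config.epochs * config.steps_per_epoch
    step_no = 0
    for _epoch in range(config.epochs):
        losses = []
        for _step in range(config.steps_per_epoch):
            if use_pseudo:
                batch = mixed_minibatch(
                    labeled_source, pseudo_source, config.mixing_ratio, config.batch_size, rng
                )
            else:
                idx = rng.integers(0, len(labeled_source), size=config.batch_size)
                batch = [labeled_source[i] for i in idx]
            prepared = [_prepare_patch(s, config, augment_config, rng) for s in batch]
            loss, grads, counters = _batch_objective(model, prepared, config.lambda_cls)
            # cosine decay to lr/10 with gradient clipping: stabilizes the
            # tiny net against dead units and late-training oscillation
            frac = step_no / max(total_steps - 1, 1)
            lr_t = config.learning_rate * (0.55 + 0.45 * math.cos(math.pi * frac))
            opt.step(model.params, _clip_grads(grads), lr=lr_t)
            step_no += 1
            losses.append(loss)
            for key in ("drawn", "pixel_terms"):
                for src, cnt in counters[key].items():
                    history[key][src] = history[key].get(src, 0) + cnt
        history["epoch_loss"].append(float(np.mean(losses)))
    return model.state()


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def predict_image(
    model: PatchNet, image: np.ndarray, crop_size: int, rule: str = "max_both"
) -> tuple[float, np.ndarray]:
    """Tile one image with a deterministic grid, stitch the probability
    map (overlaps averaged) and aggregate an image-level probability."""
    acc = np.zeros(image.shape)
    cnt = np.zeros(image.shape)
    class_probs = []
    h, w = image.shape
    ys = sorted(set(list(range(0, h - crop_size + 1, crop_size)) + [h - crop_size]))
    xs = sorted(set(list(range(0, w - crop_size + 1, crop_size)) + [w - crop_size]))
    for y in ys:
        for x in xs:
            cp, pm = model.predict_patch(image[y : y + crop_size, x : x + crop_size])
            acc[y : y + crop_size, x : x + crop_size] += pm
            cnt[y : y + crop_size, x : x + crop_size] += 1
            class_probs.append(cp)
    prob_map = acc / cnt
    if rule == "max_both":
        image_prob = max(max(class_probs), float(prob_map.max()))
    elif rule == "class":
        image_prob = max(class_probs)
    elif rule == "pixel":
        image_prob = float(prob_map.max())
    else:
        raise ValueError(f"unknown aggregation rule {rule!r}")
    return image_prob, prob_map


def predict_exam(
    model: PatchNet, exam, crop_size: int = 32, rule: str = "max_both"
) -> ExamPrediction:
    """Per-image probability maps and the exam score (max over images)."""
    image_probs, prob_maps = [], []
    for image in exam.images:
        p, pm = predict_image(model, image, crop_size, rule)
        image_probs.append(p)
        prob_maps.append(pm)
    return ExamPrediction(
        exam_id=exam.exam_id,
        image_probs=image_probs,
        prob_maps=prob_maps,
        exam_score=float(max(image_probs)),
    )
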