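"""Crop/weed ANN classifier, post-filters and the end-to-end pipeline.

A small feed-forward network — 5 inputs, hidden layers of 5 and 1 neurons
(tanh), one sigmoid output — maps the five normalized shape features to a
crop score in [0, 1] (crop = 1, weed = 0; ties at 0.5 go to crop).  Inputs
are min-max scaled to [0, 1] with statistics learned on the training set.
Training is full-batch gradient descent with momentum on binary
cross-entropy, fully deterministic given a seed.

Two post-filters clean up the raw network decisions:

* regions touching the image border carry truncated morphology and are
  excluded from identification altogether;
* a weed call on a region larger than a maximum weed size (default 300 px)
  is overridden to crop — early-season broadleaf weeds simply do not get
  that large.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import color_transform, regions, segmentation
from .regions import PlantRegion

CROP, WEED, EXCLUDED = "crop", "weed", "excluded"


@dataclass
class ANNHyperparams:
    hidden_sizes: tuple[int, int] = (5, 1)
    learning_rate: float = 0.3
    momentum: float = 0.9
    epochs: int = 4000
    init_scale: float = 0.5
    accuracy_floor: float = 0.9


@dataclass
class ANNModel:
    """Trained feed-forward network with its feature-scaling statistics."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    feat_min: np.ndarray
    feat_max: np.ndarray
    seed: int
    hyperparams: ANNHyperparams
    train_accuracy: float = float("nan")

    @property
    def architecture(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "architecture": self.architecture,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "feat_min": self.feat_min.tolist(),
            "feat_max": self.feat_max.tolist(),
            "seed": self.seed,
            "train_accuracy": self.train_accuracy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ANNModel":
        return cls(
            weights=[np.asarray(w, dtype=np.float64) for w in d["weights"]],
            biases=[np.asarray(b, dtype=np.float64) for b in d["biases"]],
            feat_min=np.asarray(d["feat_min"], dtype=np.float64),
            feat_max=np.asarray(d["feat_max"], dtype=np.float64),
            seed=int(d.get("seed", 0)),
            hyperparams=ANNHyperparams(),
            train_accuracy=float(d.get("train_accuracy", float("nan"))),
        )


@dataclass
class Detection:
    """Classification outcome for one plant region."""

    region: PlantRegion
    features: np.ndarray
    ann_score: float
    ann_class: str
    final_class: str
    filter_applied: str = "none"  # none | edge_excluded | size_override


def _scale(X: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = np.where(hi > lo, hi - lo, 1.0)
    return (X - lo) / span


def _forward(model_w, model_b, X: np.ndarray) -> np.ndarray:
    a = X
    for w, b in zip(model_w[:-1], model_b[:-1]):
        a = np.tanh(a @ w + b)
    z = a @ model_w[-1] + model_b[-1]
    return 1.0 / (1.0 + np.exp(-z))


def train_ann(
    features: np.ndarray,
    labels: Sequence[str] | np.ndarray,
    seed: int = 0,
    hyperparams: ANNHyperparams | None = None,
) -> ANNModel:
    """Train the crop/weed network.

    Parameters
    ----------
    features : (n, 5) array of normalized shape features.
    labels : length-n sequence of 'crop'/'weed' (or 1/0).
    seed : controls weight initialization; identical data + seed +
        hyperparameters give bit-identical models.
    """
    hp = hyperparams or ANNHyperparams()
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D array")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    y = np.asarray(
        [1.0 if lab in (CROP, 1, 1.0, "1") else 0.0 for lab in labels],
        dtype=np.float64,
    )
    if len(y) != len(X):
        raise ValueError("features and labels differ in length")
    if y.min() == y.max():
        raise ValueError("training set must contain both classes")
    for cls in (0.0, 1.0):
        if np.count_nonzero(y == cls) < 2:
            raise ValueError("need at least 2 examples per class")

    lo, hi = X.min(axis=0), X.max(axis=0)
    Xs = _scale(X, lo, hi)
    yv = y[:, None]

    sizes = [X.shape[1], *hp.hidden_sizes, 1]
    rng = np.random.default_rng(seed)
    W = [
        rng.uniform(-hp.init_scale, hp.init_scale, (a, b)) / np.sqrt(a)
        for a, b in zip(sizes[:-1], sizes[1:])
    ]
    B = [np.zeros(b) for b in sizes[1:]]
    vW = [np.zeros_like(w) for w in W]
    vB = [np.zeros_like(b) for b in B]
    n = len(Xs)

    for _ in range(hp.epochs):
        # forward, caching activations
        acts = [Xs]
        for w, b in zip(W[:-1], B[:-1]):
            acts.append(np.tanh(acts[-1] @ w + b))
        out = 1.0 / (1.0 + np.exp(-(acts[-1] @ W[-1] + B[-1])))
        # backward: BCE + sigmoid gives delta = out - y
        delta = (out - yv) / n
        grads_w, grads_b = [], []
        for layer in range(len(W) - 1, -1, -1):
            grads_w.append(acts[layer].T @ delta)
            grads_b.append(delta.sum(axis=0))
            if layer > 0:
                delta = (delta @ W[layer].T) * (1.0 - acts[layer] ** 2)
        grads_w.reverse()
        grads_b.reverse()
        for i in range(len(W)):
            vW[i] = hp.momentum * vW[i] - hp.learning_rate * grads_w[i]
            vB[i] = hp.momentum * vB[i] - hp.learning_rate * grads_b[i]
            W[i] += vW[i]
            B[i] += vB[i]

    preds = (_forward(W, B, Xs) >= 0.5).astype(float)
    acc = float((preds[:, 0] == y).mean())
    model = ANNModel(
        weights=W, biases=B, feat_min=lo, feat_max=hi,
        seed=seed, hyperparams=hp, train_accuracy=acc,
    )
    return model


def predict(model: ANNModel, fv: np.ndarray) -> tuple[float, str] | list[tuple[float, str]]:
    """Score feature vector(s); class is crop iff score >= 0.5."""
    X = np.asarray(fv, dtype=np.float64)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    Xs = _scale(X, model.feat_min, model.feat_max)
    scores = _forward(model.weights, model.biases, Xs)[:, 0]
    out = [(float(s), CROP if s >= 0.5 else WEED) for s in scores]
    return out[0] if single else out


def post_filter(
    detections: list[Detection],
    max_weed_size: int = 300,
    *,
    size_rule: str = "override_weed",
) -> list[Detection]:
    """Apply the edge-exclusion and maximum-weed-size criteria in place.

    ``size_rule='override_weed'`` (default) vetoes only weed calls on
    regions above ``max_weed_size``; ``'force_crop'`` pre-classifies every
    oversize region as crop regardless of the network output.
    """
    for d in detections:
        if d.region.touches_edge:
            d.final_class = EXCLUDED
            d.filter_applied = "edge_excluded"
        elif d.region.area > max_weed_size and (
            d.ann_class == WEED or size_rule == "force_crop"
        ):
            d.final_class = CROP
            d.filter_applied = "size_override"
        else:
            d.final_class = d.ann_class
            d.filter_applied = "none"
    return detections


def process_image(
    image: np.ndarray,
    model: ANNModel,
    seg_config: segmentation.SegmentationConfig | None = None,
    *,
    max_weed_size: int = 300,
    min_area: int = 5,
    extent_mode: str = "bbox",
    neg_coeff: float = color_transform.NEG_GREEN_COEFF,
) -> tuple[list[Detection], segmentation.SegmentationResult]:
    """Run the full detection pipeline on one RGB image.

    Chain: chromaticity normalization -> NEG -> 8-bit scaling -> adaptive
    segmentation -> 3x3 median filter -> component labeling -> per-region
    measurement and feature normalization -> ANN prediction -> post-filters.
    Returns the detections and the segmentation result (for reporting the
    threshold-adjustment trace).

    ``min_area`` defaults to 5 px at the pipeline level: a binary median
    filter can leave isolated 1-3 px artifacts where a dense noise window
    bordered a sparse one, and at this working resolution (~2 mm/pixel) no
    real seedling is smaller than a few dozen pixels.
    """
    gray = color_transform.rgb_to_gray_neg(image, coeff=neg_coeff)
    seg = segmentation.adaptive_segment(gray, seg_config)
    filtered = segmentation.median_filter_3x3(seg.mask)
    labeled = regions.label_components(filtered, min_area=min_area)
    dets: list[Detection] = []
    for reg in regions.measure_all(labeled, extent_mode=extent_mode):
        fv = regions.normalized_features(reg)
        score, cls = predict(model, fv)
        dets.append(Detection(
            region=reg, features=fv, ann_score=score,
            ann_class=cls, final_class=cls,
        ))
    post_filter(dets, max_weed_size=max_weed_size)
    return dets, seg


@dataclass
class EvalMetrics:
    """Detection-vs-truth metrics for one or more scenes."""

    n_truth_plants: int = 0
    n_detected: int = 0
    n_missed: int = 0
    n_spurious: int = 0
    n_crop_truth: int = 0          # non-excluded detections of true crops
    n_crop_correct: int = 0
    confusion: dict = field(default_factory=lambda: {
        (CROP, CROP): 0, (CROP, WEED): 0, (WEED, CROP): 0, (WEED, WEED): 0,
    })

    @property
    def plant_error_pct(self) -> float:
        if self.n_truth_plants == 0:
            return 0.0
        return 100.0 * (self.n_missed + self.n_spurious) / self.n_truth_plants

    @property
    def crop_identification_pct(self) -> float:
        if self.n_crop_truth == 0:
            return float("nan")
        return 100.0 * self.n_crop_correct / self.n_crop_truth


def evaluate(
    detections: list[Detection],
    truth_labels: np.ndarray,
    truth_classes: dict[int, str],
    shape: tuple[int, int],
    metrics: EvalMetrics | None = None,
) -> EvalMetrics:
    """Match detections to ground-truth plants by maximum mask overlap.

    A truth plant with no detection overlapping it is a miss; a detection
    overlapping no truth plant is spurious; the plant-identification error
    is (misses + spurious) over total truth plants.  The crop
    identification rate is measured among non-excluded detections whose
    best-overlap truth plant is a crop.  Metrics accumulate across calls
    when an existing ``EvalMetrics`` is passed in.
    """
    m = metrics or EvalMetrics()
    truth_labels = np.asarray(truth_labels)
    n_truth = int(truth_labels.max())
    m.n_truth_plants += n_truth

    matched_truth: set[int] = set()
    for d in detections:
        px = d.region.pixels
        overlap = truth_labels[px[:, 0], px[:, 1]]
        vals, counts = np.unique(overlap[overlap > 0], return_counts=True)
        if len(vals) == 0:
            m.n_spurious += 1
            continue
        best = int(vals[np.argmax(counts)])
        matched_truth.add(best)
        true_cls = truth_classes[best]
        if d.final_class != EXCLUDED:
            m.confusion[(true_cls, d.final_class)] = (
                m.confusion.get((true_cls, d.final_class), 0) + 1
            )
            if true_cls == CROP:
                m.n_crop_truth += 1
                if d.final_class == CROP:
                    m.n_crop_correct += 1
    m.n_detected += len(matched_truth)
    m.n_missed += n_truth - len(matched_truth)
    return m
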