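"""Seeded synthetic field-scene and feature-dataset generation.

Emulates the imaging conditions the pipeline was designed for: a brownish
soil background with pixel noise, a shade band from the robot's solar-panel
roof crossing part of the frame (multiplicative, channel-uniform
attenuation — exactly the disturbance the chromaticity normalization
cancels), optional saturated white highlight patches where all color
information is lost, and green plants of two morphologies: long thin corn
blades (emergence to first-leaf stage) and compact lobed broadleaf-weed
blobs.  Every generator is deterministic given its seed, and each scene
carries its ground-truth mask and per-plant class labels.

Feature datasets for classifier training are produced by drawing shapes
from these generators and measuring them through the real region-
measurement path, so classifier tests exercise measurement and
classification jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import regions as regions_mod
from .classifier import CROP, WEED


@dataclass
class SceneParams:
    """Knobs of the synthetic field scene.

    Defaults keep total plant cover well under 20% of the frame, matching
    the row-crop density the segmentation limits were designed for.
    """

    height: int = 240
    width: int = 320
    soil_mean: tuple[float, float, float] = (115.0, 95.0, 70.0)
    soil_sd: float = 6.0
    shade_enabled: bool = True
    shade_fraction: float = 0.4      # fraction of columns under shade
    shade_attenuation: float = 0.45  # multiplicative, channel-uniform
    shade_color_shift: float = 0.0   # optional bluish cast for stress tests
    n_saturated_patches: int = 2
    saturated_patch_radius: tuple[int, int] = (5, 12)
    n_corn: int = 3
    n_weed: int = 4
    plant_color_mean: tuple[float, float, float] = (55.0, 140.0, 50.0)
    plant_color_sd: float = 8.0
    corn_length: tuple[int, int] = (26, 46)
    corn_blade_width: tuple[int, int] = (3, 6)
    corn_curve_max: float = 2.0
    weed_core_radius: tuple[int, int] = (4, 6)
    weed_n_lobes: tuple[int, int] = (3, 5)
    weed_lobe_radius: tuple[int, int] = (2, 3)
    occlusion_allowed: bool = False
    edge_allowed: bool = False
    noise_sd: float = 3.0
    seed: int = 0


@dataclass
class SyntheticScene:
    """Generated RGB scene with its ground truth."""

    image: np.ndarray        # (H, W, 3) uint8
    truth_mask: np.ndarray   # (H, W) uint8, 1 = plant
    truth_labels: np.ndarray  # (H, W) int32, 0 = background
    truth_classes: dict[int, str]  # label -> 'crop' | 'weed'
    params: SceneParams


def _disk(radius: int) -> np.ndarray:
    d = 2 * radius + 1
    y, x = np.ogrid[-radius:radius + 1, -radius:radius + 1]
    return (x * x + y * y <= radius * radius).astype(np.uint8)


def generate_corn_shape(params: SceneParams, seed: int) -> np.ndarray:
    """One elongated corn blade as a tight binary array.

    A horizontally oriented elliptical blade with a slight quadratic bend;
    bounding-box aspect (long/short) >= ~3 by default.  Degenerate
    length/width ranges (blade as wide as long) are allowed but warned
    about, since the shape then loses the corn-vs-weed signal.
    """
    rng = np.random.default_rng(seed)
    length = int(rng.integers(params.corn_length[0], params.corn_length[1] + 1))
    bw = int(rng.integers(params.corn_blade_width[0], params.corn_blade_width[1] + 1))
    if length < 3 * bw:
        warnings.warn("corn blade length/width ranges overlap; shape is not elongated")
    curve = rng.uniform(0, params.corn_curve_max)
    h = bw + int(np.ceil(curve)) + 1
    canvas = np.zeros((h, length), dtype=np.uint8)
    for x in range(length):
        u = 2.0 * x / (length - 1) - 1.0  # -1..1 along the blade
        half = 0.5 * bw * np.sqrt(max(1.0 - u * u, 0.0))
        center = 0.5 * bw + curve * (x / (length - 1)) ** 2
        lo = int(np.floor(center - half))
        hi = int(np.ceil(center + half))
        canvas[max(lo, 0):min(hi, h) + 1, x] = 1
    canvas = _trim(canvas)
    if rng.random() < 0.5:  # vertical rows look the same to the features
        canvas = canvas.T
    return canvas


def generate_weed_shape(params: SceneParams, seed: int) -> np.ndarray:
    """One compact lobed broadleaf-weed blob as a tight binary array.

    A central disk with lobes at roughly even angles; by default the area
    stays below 300 px (the early-season weed size prior) and the
    bounding-box aspect is near 1.
    """
    rng = np.random.default_rng(seed)
    r0 = int(rng.integers(params.weed_core_radius[0], params.weed_core_radius[1] + 1))
    n_lobes = int(rng.integers(params.weed_n_lobes[0], params.weed_n_lobes[1] + 1))
    pad = r0 + 2 * params.weed_lobe_radius[1] + 2
    size = 2 * pad + 1
    canvas = np.zeros((size, size), dtype=np.uint8)
    core = _disk(r0)
    _paste(canvas, core, pad - r0, pad - r0)
    base = rng.uniform(0, 2 * np.pi)
    for k in range(n_lobes):
        ang = base + 2 * np.pi * k / n_lobes + rng.normal(0, 0.25)
        rl = int(rng.integers(params.weed_lobe_radius[0], params.weed_lobe_radius[1] + 1))
        cy = int(round(pad + r0 * np.sin(ang)))
        cx = int(round(pad + r0 * np.cos(ang)))
        _paste(canvas, _disk(rl), cy - rl, cx - rl)
    canvas = _trim(canvas)
    # keep within the early-season weed size prior
    if canvas.sum() > 300 and r0 > 2:
        smaller = replace(params, weed_core_radius=(r0 - 1, r0 - 1),
                          weed_lobe_radius=(params.weed_lobe_radius[0],) * 2)
        return generate_weed_shape(smaller, seed)
    return canvas


def _paste(canvas: np.ndarray, patch: np.ndarray, top: int, left: int) -> None:
    h, w = patch.shape
    H, W = canvas.shape
    t0, l0 = max(top, 0), max(left, 0)
    t1, l1 = min(top + h, H), min(left + w, W)
    if t1 <= t0 or l1 <= l0:
        return
    canvas[t0:t1, l0:l1] |= patch[t0 - top:t1 - top, l0 - left:l1 - left]


def _trim(mask: np.ndarray) -> np.ndarray:
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    return mask[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]


def _place_shapes(params: SceneParams, rng: np.random.Generator,
                  shapes: list[tuple[np.ndarray, str]]):
    """Drop shapes onto the frame, rejecting overlap/adjacency as configured."""
    H, W = params.height, params.width
    total_area = sum(int(s.sum()) for s, _ in shapes)
    if total_area > 0.5 * H * W:
        raise ValueError("requested plant area exceeds the frame capacity")
    labels = np.zeros((H, W), dtype=np.int32)
    occupied = np.zeros((H, W), dtype=bool)  # dilated, for adjacency tests
    classes: dict[int, str] = {}
    margin = 2
    for idx, (shape, cls) in enumerate(shapes, start=1):
        h, w = shape.shape
        placed = False
        for _ in range(200):
            if params.edge_allowed:
                top = int(rng.integers(-h + 1, H))
                left = int(rng.integers(-w + 1, W))
            else:
                if h + 2 * margin >= H or w + 2 * margin >= W:
                    raise ValueError("shape larger than frame interior")
                top = int(rng.integers(margin, H - h - margin))
                left = int(rng.integers(margin, W - w - margin))
            t0, l0 = max(top, 0), max(left, 0)
            t1, l1 = min(top + h, H), min(left + w, W)
            sub = shape[t0 - top:t1 - top, l0 - left:l1 - left]
            if sub.sum() == 0:
                continue
            if not params.occlusion_allowed:
                # check the dilated footprint so plants are not even adjacent
                pt0, pl0 = max(t0 - 1, 0), max(l0 - 1, 0)
                pt1, pl1 = min(t1 + 1, H), min(l1 + 1, W)
                if occupied[pt0:pt1, pl0:pl1].any():
                    continue
            labels[t0:t1, l0:l1][sub > 0] = idx
            ys, xs = np.nonzero(sub)
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    yy = np.clip(ys + (t0 + dy), 0, H - 1)
                    xx = np.clip(xs + (l0 + dx), 0, W - 1)
                    occupied[yy, xx] = True
            classes[idx] = cls
            placed = True
            break
        if not placed:
            raise ValueError("could not place plant without overlap; frame too full")
    return labels, classes


def generate_scene(params: SceneParams | None = None) -> SyntheticScene:
    """Render one synthetic field scene with ground truth.

    Composition order: soil + plants in floating point, pixel noise, then
    the multiplicative shade band and white saturated patches, finally
    8-bit quantisation.  Because shade multiplies all channels equally
    before quantisation, the chromaticity-normalized image of a shaded
    pixel equals its unshaded value up to quantisation error — the
    property the NEG normalization relies on.
    """
    p = params or SceneParams()
    rng = np.random.default_rng(p.seed)
    H, W = p.height, p.width

    shapes: list[tuple[np.ndarray, str]] = []
    for i in range(p.n_corn):
        shapes.append((generate_corn_shape(p, int(rng.integers(2**31))), CROP))
    for i in range(p.n_weed):
        shapes.append((generate_weed_shape(p, int(rng.integers(2**31))), WEED))
    shapes = [shapes[i] for i in rng.permutation(len(shapes))]
    labels, classes = _place_shapes(p, rng, shapes)
    mask = (labels > 0).astype(np.uint8)

    img = np.empty((H, W, 3), dtype=np.float64)
    for ch in range(3):
        img[..., ch] = p.soil_mean[ch] + rng.normal(0, p.soil_sd, (H, W))
    plant = mask > 0
    n_plant = int(plant.sum())
    for ch in range(3):
        img[..., ch][plant] = (
            p.plant_color_mean[ch] + rng.normal(0, p.plant_color_sd, n_plant)
        )
    img += rng.normal(0, p.noise_sd, img.shape)
    img = np.clip(img, 0, 254)  # leave 255 to the saturated patches

    if p.shade_enabled and p.shade_fraction > 0:
        n_shade = int(round(p.shade_fraction * W))
        slope = rng.uniform(-0.15, 0.15)
        cols = np.arange(W)[None, :]
        edge = n_shade + slope * np.arange(H)[:, None]
        shade = cols < edge
        att = np.array([
            p.shade_attenuation * (1.0 - p.shade_color_shift),
            p.shade_attenuation,
            p.shade_attenuation * (1.0 + p.shade_color_shift),
        ])
        img[shade] = img[shade] * att

    for _ in range(p.n_saturated_patches):
        r = int(rng.integers(*p.saturated_patch_radius))
        for _ in range(50):
            cy = int(rng.integers(r, H - r))
            cx = int(rng.integers(r, W - r))
            if not plant[max(cy - r, 0):cy + r + 1, max(cx - r, 0):cx + r + 1].any():
                break
        else:
            continue
        d = _disk(r).astype(bool)
        img[cy - r:cy + r + 1, cx - r:cx + r + 1][d] = 255.0

    return SyntheticScene(
        image=np.clip(np.round(img), 0, 255).astype(np.uint8),
        truth_mask=mask,
        truth_labels=labels,
        truth_classes=classes,
        params=p,
    )


def _measure_shape(shape: np.ndarray, extent_mode: str = "bbox") -> np.ndarray:
    """Five normalized features of a lone shape via the real measurement path."""
    pad = np.pad(shape, 2)
    labeled = regions_mod.label_components(pad)
    reg = regions_mod.measure_region(labeled, 1, extent_mode=extent_mode)
    return regions_mod.normalized_features(reg)


def generate_feature_dataset(
    n_corn: int = 54,
    n_weed: int = 65,
    overlap: float = 0.0,
    seed: int = 0,
    params: SceneParams | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Labeled shape-feature dataset for classifier training.

    Shapes come from the two shape generators and are measured with the
    region-measurement pipeline, not sampled in feature space.  ``overlap``
    in [0, 1] morphs corn blades toward weed blobs: at 0 the classes are
    cleanly separable on the aspect ratio alone; at 1 corn shapes are drawn
    from the weed generator itself, so the class distributions coincide and
    no classifier can beat chance.  Default sizes 54 + 65 mirror a typical
    training split for this problem.
    """
    if n_corn < 1 or n_weed < 1:
        raise ValueError("need at least one example per class")
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must be in [0, 1]")
    p = params or SceneParams()
    rng = np.random.default_rng(seed)
    feats, labels = [], []
    for _ in range(n_corn):
        s = int(rng.integers(2**31))
        if overlap >= 1.0:
            shape = generate_weed_shape(p, s)
        elif overlap <= 0.0:
            shape = generate_corn_shape(p, s)
        else:
            # morph: shrink blade length toward weed-like compactness
            lo = max(int(round(p.corn_length[0] * (1 - overlap) + 9 * overlap)), 4)
            hi = max(int(round(p.corn_length[1] * (1 - overlap) + 13 * overlap)), lo + 1)
            bw_hi = int(round(p.corn_blade_width[1] * (1 - overlap) + 9 * overlap))
            pm = replace(p, corn_length=(lo, hi),
                         corn_blade_width=(p.corn_blade_width[0], max(bw_hi, 3)))
            if rng.random() < overlap:
                shape = generate_weed_shape(pm, s)
            else:
                shape = generate_corn_shape(pm, s)
        feats.append(_measure_shape(shape))
        labels.append(CROP)
    for _ in range(n_weed):
        s = int(rng.integers(2**31))
        feats.append(_measure_shape(generate_weed_shape(p, s)))
        labels.append(WEED)
    return np.array(feats), labels
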