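"""Individual plant labeling and morphological measurement.

Plants are the 8-connected components of the filtered binary mask.  Four
pixel-unit measurements are taken per plant — perimeter (PRI), area, width
and height — and converted to five size-normalized shape ratios

    f1 = height/width   f2 = height/PRI   f3 = PRI/area
    f4 = width/area     f5 = height/area

with the convention width >= height (the longer vs shorter extent), so f1
is in (0, 1]: low for elongated corn blades, near 1 for compact broadleaf
weeds.  PRI counts region pixels with at least one 4-neighbor outside the
region (the image border counts as outside).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull

EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass
class PlantRegion:
    """One connected plant component and its pixel-unit measurements."""

    label: int
    pixels: np.ndarray  # (n, 2) array of (row, col) coordinates
    area: int
    perimeter: int  # PRI
    width: int      # longer bounding-box side (or max Feret, by config)
    height: int     # shorter side
    bbox: tuple[int, int, int, int]  # (row_min, col_min, row_max, col_max) inclusive
    centroid: tuple[float, float]
    touches_edge: bool


def label_components(mask: np.ndarray, min_area: int = 1) -> np.ndarray:
    """Label 8-connected foreground components 1..n.

    Labels are assigned in raster-scan order of each component's first
    pixel.  Components smaller than ``min_area`` are dropped (default 1,
    i.e. nothing is dropped) and the remaining labels renumbered to stay
    contiguous.
    """
    mask = np.asarray(mask) != 0
    labeled, n = ndimage.label(mask, structure=EIGHT_CONNECTED)
    if n == 0:
        return labeled.astype(np.int32)
    if min_area > 1:
        counts = np.bincount(labeled.ravel(), minlength=n + 1)
        keep = counts >= min_area
        keep[0] = False
        remap = np.zeros(n + 1, dtype=np.int32)
        remap[keep] = np.arange(1, int(keep.sum()) + 1)
        labeled = remap[labeled]
        n = int(keep.sum())
    # enforce raster order of first occurrence
    flat = labeled.ravel()
    fg = np.nonzero(flat)[0]
    order = flat[fg[np.sort(np.unique(flat[fg], return_index=True)[1])]]
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[order] = np.arange(1, n + 1)
    return remap[labeled].astype(np.int32)


def _feret_extents(pixels: np.ndarray) -> tuple[float, float]:
    """Max and min Feret diameters of a pixel set (pixel-square corners)."""
    # represent each pixel by its 4 unit-square corners so single pixels
    # and lines get physically sensible extents
    r, c = pixels[:, 0].astype(float), pixels[:, 1].astype(float)
    pts = np.concatenate([
        np.stack([r, c], 1), np.stack([r + 1, c], 1),
        np.stack([r, c + 1], 1), np.stack([r + 1, c + 1], 1),
    ])
    pts = np.unique(pts, axis=0)
    if len(pts) <= 2 or np.ptp(pts[:, 0]) == 0 or np.ptp(pts[:, 1]) == 0:
        return float(max(np.ptp(pts[:, 0]), np.ptp(pts[:, 1]), 1.0)), 1.0
    hull = pts[ConvexHull(pts).vertices]
    d = hull[:, None, :] - hull[None, :, :]
    max_feret = float(np.sqrt((d ** 2).sum(-1)).max())
    # min Feret: smallest width over hull-edge directions
    edges = np.roll(hull, -1, axis=0) - hull
    norms = np.linalg.norm(edges, axis=1)
    dirs = edges[norms > 0] / norms[norms > 0, None]
    normals = np.stack([-dirs[:, 1], dirs[:, 0]], 1)
    proj = hull @ normals.T
    min_feret = float((proj.max(0) - proj.min(0)).min())
    return max_feret, min_feret


def measure_region(
    labeled: np.ndarray, label: int, *, extent_mode: str = "bbox"
) -> PlantRegion:
    """Measure one labeled component.

    ``extent_mode='bbox'`` (default) takes width/height as the longer and
    shorter side of the axis-aligned bounding box (side = max - min + 1);
    ``'feret'`` uses the max/min Feret diameters rounded to whole pixels.
    """
    labeled = np.asarray(labeled)
    inside = labeled == label
    n = int(np.count_nonzero(inside))
    if n == 0:
        raise ValueError(f"label {label} has no pixels")
    rows, cols = np.nonzero(inside)
    r0, r1 = int(rows.min()), int(rows.max())
    c0, c1 = int(cols.min()), int(cols.max())

    # PRI: pixels with >=1 four-neighbor outside the region (border = outside)
    interior = ndimage.binary_erosion(
        inside, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    pri = n - int(np.count_nonzero(interior))

    if extent_mode == "bbox":
        side_a, side_b = r1 - r0 + 1, c1 - c0 + 1
    elif extent_mode == "feret":
        fmax, fmin = _feret_extents(np.stack([rows, cols], 1))
        side_a, side_b = int(round(fmax)), int(round(fmin))
    else:
        raise ValueError(f"unknown extent_mode {extent_mode!r}")
    width, height = max(side_a, side_b), min(side_a, side_b)

    h, w = labeled.shape
    touches = r0 == 0 or c0 == 0 or r1 == h - 1 or c1 == w - 1
    return PlantRegion(
        label=int(label),
        pixels=np.stack([rows, cols], axis=1),
        area=n,
        perimeter=pri,
        width=int(width),
        height=int(height),
        bbox=(r0, c0, r1, c1),
        centroid=(float(rows.mean()), float(cols.mean())),
        touches_edge=bool(touches),
    )


def measure_all(labeled: np.ndarray, *, extent_mode: str = "bbox") -> list[PlantRegion]:
    """Measure every labeled component, in label order."""
    n = int(labeled.max())
    return [measure_region(labeled, k, extent_mode=extent_mode) for k in range(1, n + 1)]


def normalized_features(region: PlantRegion) -> np.ndarray:
    """The five size-normalized shape ratios of a region.

    Returns ``[height/width, height/PRI, PRI/area, width/area, height/area]``.
    """
    if region.perimeter <= 0 or region.area <= 0 or region.width <= 0:
        raise ValueError("region measurements must be positive")
    h, w, p, a = region.height, region.width, region.perimeter, region.area
    return np.array([h / w, h / p, p / a, w / a, h / a], dtype=np.float64)


def labeled_to_gray(labeled: np.ndarray) -> np.ndarray:
    """Visualization image: each plant a distinct intensity in [50, 255]."""
    labeled = np.asarray(labeled)
    n = int(labeled.max())
    out = np.zeros(labeled.shape, dtype=np.uint8)
    if n == 0:
        return out
    levels = np.linspace(50, 255, n).astype(np.uint8)
    for k in range(1, n + 1):
        out[labeled == k] = levels[k - 1]
    return out
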