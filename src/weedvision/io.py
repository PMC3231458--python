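"""Image and result I/O.

Masks and labeled images round-trip losslessly through PNG; detection
tables go to CSV and run reports (thresholds, rate traces) to JSON, all
byte-stable for identical inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .classifier import Detection
from .config import SCHEMA_VERSION
from .regions import labeled_to_gray
from .segmentation import SegmentationResult

DETECTION_COLUMNS = [
    "label", "centroid_row", "centroid_col", "area", "perimeter",
    "width", "height", "f1", "f2", "f3", "f4", "f5",
    "ann_score", "ann_class", "final_class", "filter_applied", "touches_edge",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit 3-channel RGB image (PNG/TIFF/BMP/JPEG)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface decoder failures uniformly
        raise ValueError(f"could not decode image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]  # drop alpha
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"{path}: expected a 3-channel RGB image, got shape {arr.shape}"
        )
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit channels, got {arr.dtype}")
    return arr


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG (0/255)."""
    iio.imwrite(Path(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)


def write_labeled(labeled: np.ndarray, path: str | Path) -> None:
    """Write a labeled image with distinct per-plant intensities."""
    iio.imwrite(Path(path), labeled_to_gray(labeled))


def write_overlay(image: np.ndarray, detections: list[Detection],
                  path: str | Path) -> None:
    """Overlay detections on the RGB image: crops green, weeds purple."""
    out = np.asarray(image).copy()
    tints = {"crop": (0, 255, 0), "weed": (200, 0, 200), "excluded": (128, 128, 128)}
    for d in detections:
        px = d.region.pixels
        tint = np.array(tints[d.final_class], dtype=np.float64)
        out[px[:, 0], px[:, 1]] = (
            0.5 * out[px[:, 0], px[:, 1]].astype(np.float64) + 0.5 * tint
        ).astype(np.uint8)
    iio.imwrite(Path(path), out)


def detections_to_frame(detections: list[Detection]) -> pd.DataFrame:
    rows = []
    for d in detections:
        r = d.region
        rows.append({
            "label": r.label,
            "centroid_row": round(r.centroid[0], 3),
            "centroid_col": round(r.centroid[1], 3),
            "area": r.area, "perimeter": r.perimeter,
            "width": r.width, "height": r.height,
            **{f"f{i+1}": round(float(v), 6) for i, v in enumerate(d.features)},
            "ann_score": round(d.ann_score, 6),
            "ann_class": d.ann_class,
            "final_class": d.final_class,
            "filter_applied": d.filter_applied,
            "touches_edge": r.touches_edge,
        })
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def write_outputs(
    detections: list[Detection],
    seg: SegmentationResult,
    out_dir: str | Path,
    stem: str = "image",
    image: np.ndarray | None = None,
    labeled: np.ndarray | None = None,
) -> dict[str, Path]:
    """Write the full per-image output set; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["mask"] = out_dir / f"{stem}_mask.png"
    write_mask(seg.mask, paths["mask"])
    if labeled is not None:
        paths["labeled"] = out_dir / f"{stem}_labeled.png"
        write_labeled(labeled, paths["labeled"])
    if image is not None:
        paths["overlay"] = out_dir / f"{stem}_overlay.png"
        write_overlay(image, detections, paths["overlay"])

    paths["detections"] = out_dir / f"{stem}_detections.csv"
    detections_to_frame(detections).to_csv(paths["detections"], index=False)

    report = {
        "schema_version": SCHEMA_VERSION,
        "initial_threshold": seg.initial_threshold,
        "final_threshold": seg.threshold,
        "n_adjustments": seg.n_adjustments,
        "rate_trace_pct": [round(r, 4) for r in seg.rate_trace],
        "capped": seg.capped,
        "degenerate": seg.degenerate,
        "active_lower_fraction": seg.active_lower_fraction,
        "n_detections": len(detections),
    }
    paths["report"] = out_dir / f"{stem}_report.json"
    paths["report"].write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return paths
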