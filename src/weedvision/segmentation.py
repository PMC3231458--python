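"""Adaptive plant/soil segmentation of the gray NEG image.

The threshold is first estimated on the 256-bin histogram by minimizing the
within-group variance sum (the Otsu criterion), then adjusted iteratively
until the segmented-pixel rate falls between configured limits:

* upper limit: 20% of the frame (row-crop scenes are designed so plants
  cover less than a fifth of the image);
* lower limit: 0.5%; if even the *initial* segmentation falls below 0.5%,
  the active lower bound for the image switches to 5%.

Each adjustment step is ``Round((R_C - R_L)/R_L * 20)`` where ``R_C`` is the
current segmented rate (%) and ``R_L`` the violated limit — large when far
from the limit, small near it, which avoids overshoot.  The loop is capped
at 30 adjustments.  A 3x3 median filter removes residual salt noise from
the binary mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class SegmentationConfig:
    """Limits and step parameters of the adaptive threshold loop.

    Fractions are of total image pixels; on a 320x240 frame the defaults
    correspond to 15,360 px (upper), 384 px (lower) and 3,840 px
    (alternate lower).
    """

    upper_limit_fraction: float = 0.20
    lower_limit_fraction: float = 0.005
    alt_lower_limit_fraction: float = 0.05
    max_adjustments: int = 30
    step_scale: float = 20.0
    threshold_min: int = 1
    threshold_max: int = 255
    #: Otsu criterion variant: pixel-count-weighted within-class variance
    #: sum (standard) or the unweighted sum of the two variances.
    weighted_variance: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.lower_limit_fraction
                < self.alt_lower_limit_fraction
                < self.upper_limit_fraction < 1.0):
            raise ValueError(
                "limit fractions must satisfy 0 < lower < alt_lower < upper < 1"
            )
        if self.max_adjustments < 1:
            raise ValueError("max_adjustments must be >= 1")
        if not (0 < self.threshold_min <= self.threshold_max <= 255):
            raise ValueError("threshold bounds must satisfy 0 < min <= max <= 255")

    def limits_in_pixels(self, shape: tuple[int, int]) -> dict[str, int]:
        """Pixel counts the limit fractions correspond to for a frame shape."""
        total = int(shape[0]) * int(shape[1])
        return {
            "upper": int(round(self.upper_limit_fraction * total)),
            "lower": int(round(self.lower_limit_fraction * total)),
            "alt_lower": int(round(self.alt_lower_limit_fraction * total)),
        }


@dataclass
class SegmentationResult:
    """Binary plant mask with the threshold-adjustment trace."""

    mask: np.ndarray
    threshold: int
    initial_threshold: int
    n_adjustments: int
    rate_trace: list[float] = field(default_factory=list)
    capped: bool = False
    degenerate: bool = False
    active_lower_fraction: float = 0.005


def _histogram(gray: np.ndarray) -> np.ndarray:
    gray = np.asarray(gray)
    if gray.size == 0:
        raise ValueError("empty image")
    if gray.min() < 0 or gray.max() > 255:
        raise ValueError("gray NEG values must lie in [0, 255]")
    return np.bincount(gray.ravel().astype(np.int64), minlength=256).astype(np.float64)


def estimate_threshold(
    gray: np.ndarray,
    *,
    weighted: bool = True,
    t_min: int = 1,
    t_max: int = 255,
) -> int:
    """Histogram threshold minimizing the two groups' variance sum.

    Candidate thresholds t in [t_min, t_max] split pixels into
    {value <= t} and {value > t}; the returned t minimizes
    ``n0*var0 + n1*var1`` (population variances; pixel-count weighted by
    default) with ties broken toward the smallest t.  A constant image
    returns its own value (clipped into the candidate range).
    """
    hist = _histogram(gray)
    nonzero = np.nonzero(hist)[0]
    if len(nonzero) == 1:  # constant image: no split exists
        return int(np.clip(nonzero[0], t_min, t_max))

    values = np.arange(256, dtype=np.float64)
    # cumulative pixel counts / sums / sums of squares up to and including v
    cnt = np.cumsum(hist)
    s1 = np.cumsum(hist * values)
    s2 = np.cumsum(hist * values**2)
    total_cnt, total_s1, total_s2 = cnt[-1], s1[-1], s2[-1]

    ts = np.arange(t_min, t_max + 1)
    n0 = cnt[ts]
    n1 = total_cnt - n0
    # group variances via E[x^2] - E[x]^2; empty group contributes zero
    with np.errstate(invalid="ignore", divide="ignore"):
        var0 = np.where(n0 > 0, s2[ts] / n0 - (s1[ts] / n0) ** 2, 0.0)
        var1 = np.where(
            n1 > 0,
            (total_s2 - s2[ts]) / n1 - ((total_s1 - s1[ts]) / n1) ** 2,
            0.0,
        )
    var0 = np.maximum(var0, 0.0)  # guard tiny negative round-off
    var1 = np.maximum(var1, 0.0)
    if weighted:
        crit = n0 * var0 + n1 * var1
    else:
        crit = var0 + var1
    return int(ts[int(np.argmin(crit))])


def is_degenerate(gray: np.ndarray) -> bool:
    """True when the histogram has a single nonempty bin (constant image)."""
    return len(np.nonzero(_histogram(gray))[0]) == 1


def apply_threshold(gray: np.ndarray, t: int) -> np.ndarray:
    """Binary mask: 1 where ``gray > t`` (strict), else 0."""
    if not (1 <= t <= 255):
        raise ValueError(f"threshold {t} outside [1, 255]")
    return (np.asarray(gray) > t).astype(np.uint8)


def segmented_rate(mask: np.ndarray) -> float:
    """Foreground pixels as a percentage of total pixels."""
    mask = np.asarray(mask)
    if mask.size == 0:
        return 0.0
    return 100.0 * float(np.count_nonzero(mask)) / mask.size


def compute_increment(
    rate_current: float, rate_limit: float, step_scale: float = 20.0
) -> int:
    """Threshold adjustment step ``Round((R_C - R_L)/R_L * step_scale)``.

    Positive when the current rate exceeds the limit (raising the threshold
    shrinks the foreground); negative below the limit.  Rounding is
    half-away-from-zero.
    """
    if rate_limit <= 0:
        raise ValueError("rate_limit must be positive")
    x = (rate_current - rate_limit) / rate_limit * step_scale
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def adaptive_segment(
    gray: np.ndarray, config: SegmentationConfig | None = None
) -> SegmentationResult:
    """Segment a gray NEG image with adaptive threshold adjustment.

    The initial threshold comes from :func:`estimate_threshold`.  If the
    initial segmented rate is below the lower limit, the active lower bound
    for this image becomes the alternate (5%) limit, both as stopping bound
    and inside the increment formula.  The threshold is then stepped by
    :func:`compute_increment` against the currently violated limit, clamped
    to [threshold_min, threshold_max], until the rate is inside the limits
    or ``max_adjustments`` steps were taken.  A step that rounds to zero
    while still outside the limits is forced to +/-1 in the corrective
    direction so the loop cannot stall.
    """
    cfg = config or SegmentationConfig()
    gray = np.asarray(gray)

    t = estimate_threshold(
        gray,
        weighted=cfg.weighted_variance,
        t_min=cfg.threshold_min,
        t_max=cfg.threshold_max,
    )
    if is_degenerate(gray):
        warnings.warn(
            "constant NEG image: no plant/soil contrast, returning empty mask",
            stacklevel=2,
        )
        return SegmentationResult(
            mask=np.zeros_like(gray, dtype=np.uint8),
            threshold=t,
            initial_threshold=t,
            n_adjustments=0,
            rate_trace=[0.0],
            capped=False,
            degenerate=True,
            active_lower_fraction=cfg.lower_limit_fraction,
        )

    upper = 100.0 * cfg.upper_limit_fraction
    lower = 100.0 * cfg.lower_limit_fraction
    alt_lower = 100.0 * cfg.alt_lower_limit_fraction

    mask = apply_threshold(gray, t)
    rate = segmented_rate(mask)
    trace = [rate]
    initial_t = t

    # the alternate lower bound is triggered by the *initial* rate only
    active_lower = alt_lower if rate < lower else lower

    n_adj = 0
    while (rate > upper or rate < active_lower) and n_adj < cfg.max_adjustments:
        limit = upper if rate > upper else active_lower
        inc = compute_increment(rate, limit, cfg.step_scale)
        if inc == 0:
            inc = 1 if rate > upper else -1
        t = int(np.clip(t + inc, cfg.threshold_min, cfg.threshold_max))
        mask = apply_threshold(gray, t)
        rate = segmented_rate(mask)
        trace.append(rate)
        n_adj += 1

    capped = rate > upper or rate < active_lower
    return SegmentationResult(
        mask=mask,
        threshold=t,
        initial_threshold=initial_t,
        n_adjustments=n_adj,
        rate_trace=trace,
        capped=capped,
        degenerate=False,
        active_lower_fraction=active_lower / 100.0,
    )


def median_filter_3x3(mask: np.ndarray) -> np.ndarray:
    """3x3 median filter on a binary mask; borders by edge replication."""
    mask = np.asarray(mask).astype(np.uint8)
    return ndimage.median_filter(mask, size=3, mode="nearest").astype(np.uint8)
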