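"""Normalized excess-green (NEG) color transform.

Converts an 8-bit RGB field image to chromaticity-normalized channels,

    R = r/(r+g+b),  G = g/(r+g+b),  B = b/(r+g+b),

then to the normalized excess-green index

    NEG = 2.8*G - R - B,

a vegetation index that is high for green plant material and low for soil,
and invariant to multiplicative changes of illumination intensity (shade)
because the chromaticity normalization cancels any common channel factor.
For histogram-based thresholding the NEG image is scaled by 100, rounded,
and clamped into 8-bit range.
"""

from __future__ import annotations

import numpy as np

#: Default green-channel weight of the excess-green index.
NEG_GREEN_COEFF = 2.8


class DegenerateImageError(ValueError):
    """Raised when an image is empty or otherwise unusable."""


def _as_rgb_array(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"expected an (H, W, 3) RGB array, got shape {arr.shape}"
        )
    if arr.size == 0:
        raise DegenerateImageError("empty image")
    if np.issubdtype(arr.dtype, np.floating):
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("RGB values must lie in [0, 255]")
    return arr


def normalize_rgb(image: np.ndarray) -> np.ndarray:
    """Chromaticity-normalize an RGB image.

    Each pixel (r, g, b) maps to (r, g, b) / (r + g + b).  Black pixels
    (channel sum zero) map to (0, 0, 0): they carry no chromaticity and
    cannot be vegetation, and the convention avoids a division by zero.

    Parameters
    ----------
    image : ndarray, shape (H, W, 3)
        8-bit RGB image (any integer or float dtype with values in
        [0, 255]).

    Returns
    -------
    ndarray, shape (H, W, 3), float64
        Normalized channels; non-black pixels sum to 1 across channels.
    """
    arr = _as_rgb_array(image).astype(np.float64)
    total = arr.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(total > 0, arr / total, 0.0)
    return norm


def compute_neg(norm: np.ndarray, coeff: float = NEG_GREEN_COEFF) -> np.ndarray:
    """Compute the normalized excess-green index ``coeff*G - R - B``.

    With the default coefficient 2.8 and chromaticity-normalized input the
    result lies in [-1.0, 2.8] (pure green attains the maximum, any
    green-free pixel the minimum).

    Parameters
    ----------
    norm : ndarray, shape (H, W, 3)
        Output of :func:`normalize_rgb`.
    coeff : float
        Green-channel weight (default 2.8).
    """
    norm = np.asarray(norm, dtype=np.float64)
    if norm.ndim != 3 or norm.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) normalized RGB array")
    r, g, b = norm[..., 0], norm[..., 1], norm[..., 2]
    return coeff * g - r - b


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # MATLAB-style rounding: halves go away from zero, not to even.
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def neg_to_gray(neg: np.ndarray) -> np.ndarray:
    """Scale a NEG image by 100 into an 8-bit gray image.

    Values are rounded half-away-from-zero and clamped to [0, 255].
    Negative NEG never indicates vegetation, so clamping to 0 is lossless
    for segmentation; NEG*100 above 255 is maximally green.
    """
    neg = np.asarray(neg, dtype=np.float64)
    gray = np.clip(_round_half_away(neg * 100.0), 0, 255)
    return gray.astype(np.uint8)


def rgb_to_gray_neg(image: np.ndarray, coeff: float = NEG_GREEN_COEFF) -> np.ndarray:
    """Convenience chain: RGB -> normalized RGB -> NEG -> 8-bit gray."""
    return neg_to_gray(compute_neg(normalize_rgb(image), coeff=coeff))
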