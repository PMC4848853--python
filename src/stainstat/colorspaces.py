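"""Colour-space transforms and histogram quantization.

All stain-detection models in this package operate on chromaticity
coordinates derived from 8-bit RGB pixels.  Four spaces are supported:

``rgb``
    The raw 3D colour cube (luminance and chromaticity mixed).
``normalized_rgb``
    Intensity-normalised fractions r = R/(R+G+B) etc.; because the three
    fractions sum to one the space is effectively 2D and is binned over
    (r, g).
``opponent``
    Red–green and blue–yellow opponent signals rg = r − g,
    by = (r + g)/2 − b computed from the normalised fractions.
``cbcr``
    The chroma plane of YCbCr with the luma channel discarded:
    Cb = −0.1687 R − 0.3313 G + 0.5 B and
    Cr = 0.5 R − 0.4187 G − 0.0813 B, kept *signed* (the usual +128
    digital offset is applied only at quantization time).

Every transform is vectorised over arrays whose last axis holds the
three RGB channels, so an H×W×3 image or an N×3 pixel list both work.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "SPACES",
    "space_ndim",
    "rgb_to_normalized",
    "rgb_to_opponent",
    "rgb_to_cbcr",
    "rgb_to_cmyk",
    "transform",
    "quantize",
    "quantize_rgb",
]

#: Supported colour-space tags and the dimensionality of their binned
#: representation.
SPACES: dict[str, int] = {
    "rgb": 3,
    "normalized_rgb": 2,
    "opponent": 2,
    "cbcr": 2,
}

# Documented coordinate ranges [(lo, hi), ...] per binned axis.  Uniform
# bins are laid over these fixed ranges (never data-driven) so that
# models trained on different images share bin geometry.
_RANGES: dict[str, tuple[tuple[float, float], ...]] = {
    "rgb": (((0.0, 256.0),) * 3),
    "normalized_rgb": ((0.0, 1.0), (0.0, 1.0)),
    "opponent": ((-1.0, 1.0), (-1.0, 0.5)),
    "cbcr": ((-128.0, 128.0), (-128.0, 128.0)),
}

# ITU-R BT.601 chroma coefficients as printed to 4 decimals.
_CB_COEF = np.array([-0.1687, -0.3313, 0.5])
_CR_COEF = np.array([0.5, -0.4187, -0.0813])


def space_ndim(space: str) -> int:
    """Number of binned axes of *space* (2 for chromaticity planes, 3 for rgb)."""
    try:
        return SPACES[space]
    except KeyError:
        raise ValueError(f"unknown colour space {space!r}; expected one of {sorted(SPACES)}") from None


def _as_float_rgb(pixels) -> np.ndarray:
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.shape[-1] != 3:
        raise ValueError("expected RGB data with a trailing axis of length 3")
    return arr


def rgb_to_normalized(pixels) -> np.ndarray:
    """Map RGB to intensity-normalised fractions (r, g, b) summing to 1.

    The black pixel (0, 0, 0) has no defined hue; it is assigned the grey
    limit (1/3, 1/3, 1/3) so the transform is total and black sits with
    the achromatic colours.
    """
    arr = _as_float_rgb(pixels)
    total = arr.sum(axis=-1, keepdims=True)
    out = np.where(total > 0, arr / np.where(total > 0, total, 1.0), 1.0 / 3.0)
    return out


def rgb_to_opponent(pixels) -> np.ndarray:
    """Opponent chromaticity (rg, by): rg = r − g, by = (r + g)/2 − b."""
    n = rgb_to_normalized(pixels)
    rg = n[..., 0] - n[..., 1]
    by = (n[..., 0] + n[..., 1]) / 2.0 - n[..., 2]
    return np.stack([rg, by], axis=-1)


def rgb_to_cbcr(pixels) -> np.ndarray:
    """Signed (Cb, Cr) chroma coordinates of the raw 8-bit RGB values.

    No +128 offset is applied here; grey pixels map exactly to (0, 0)
    because each coefficient triple sums to zero.
    """
    arr = _as_float_rgb(pixels)
    cb = arr @ _CB_COEF
    cr = arr @ _CR_COEF
    return np.stack([cb, cr], axis=-1)


def rgb_to_cmyk(pixels, ucr: bool = True) -> np.ndarray:
    """Convert RGB to CMYK in [0, 1] with a trailing axis of length 4.

    With ``ucr=True`` (default) the undercolour-removal convention is
    used: K = min(C', M', Y') is subtracted from each primary, matching
    the ImageJ-style RGB→CMYK conversion.  ``ucr=False`` gives the naive
    variant C = 1 − R/255 etc. with K = 0.
    """
    arr = _as_float_rgb(pixels)
    prim = 1.0 - arr / 255.0
    if not ucr:
        k = np.zeros(arr.shape[:-1])
        return np.concatenate([prim, k[..., None]], axis=-1)
    k = prim.min(axis=-1)
    cmy = prim - k[..., None]
    return np.concatenate([cmy, k[..., None]], axis=-1)


def transform(pixels, space: str) -> np.ndarray:
    """Apply the coordinate transform for *space* (identity for rgb)."""
    if space == "rgb":
        return _as_float_rgb(pixels)
    if space == "normalized_rgb":
        return rgb_to_normalized(pixels)[..., :2]
    if space == "opponent":
        return rgb_to_opponent(pixels)
    if space == "cbcr":
        return rgb_to_cbcr(pixels)
    space_ndim(space)  # raises with the standard message
    raise AssertionError("unreachable")


def quantize(coords, space: str, bins_per_channel: int) -> np.ndarray:
    """Bin transformed coordinates into integer indices.

    Uniform bins are laid over the space's documented range; values at
    the upper range boundary clamp into the last bin.  Returns an
    integer array with trailing axis of length 2 (3 for rgb), each index
    in ``[0, bins_per_channel)``.

    Raises ``ValueError`` for coordinates outside the documented range
    of the space or an unsupported bin count.
    """
    if not (2 <= bins_per_channel <= 256):
        raise ValueError("bins_per_channel must be in [2, 256]")
    ndim = space_ndim(space)
    arr = np.asarray(coords, dtype=np.float64)
    if arr.shape[-1] != ndim:
        raise ValueError(f"space {space!r} expects {ndim} coordinates, got {arr.shape[-1]}")
    ranges = _RANGES[space]
    out = np.empty(arr.shape, dtype=np.int64)
    eps = 1e-9
    for ax, (lo, hi) in enumerate(ranges):
        x = arr[..., ax]
        if np.any(x < lo - eps) or np.any(x > hi + eps):
            raise ValueError(
                f"coordinate {ax} out of range [{lo}, {hi}] for colour space {space!r}"
            )
        idx = np.floor((x - lo) * (bins_per_channel / (hi - lo))).astype(np.int64)
        out[..., ax] = np.clip(idx, 0, bins_per_channel - 1)
    return out


def quantize_rgb(pixels, space: str, bins_per_channel: int) -> np.ndarray:
    """Transform RGB pixels into *space* and quantize in one step."""
    return quantize(transform(pixels, space), space, bins_per_channel)
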