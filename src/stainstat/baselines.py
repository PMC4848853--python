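"""Comparison detectors: colour deconvolution and the CMYK Y-channel.

Colour deconvolution (Ruifrok–Johnston style) models each stain as a
unit vector of optical-density absorbances per RGB channel; co-localised
stains add in OD space (Beer–Lambert), so per-pixel stain amounts are
recovered by inverting the 3×3 stain matrix.  The CMYK detector simply
thresholds one channel of an RGB→CMYK conversion (historically the Y
channel for brown DAB stain); it fails on dark saturated stain, where
the K channel swallows the pigment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .colorspaces import rgb_to_cmyk
from .errors import DegenerateMatrixError, TrainingError
from .statmodel import DetectionResult

__all__ = [
    "StainVector",
    "StainMatrix",
    "od_transform",
    "od_to_rgb",
    "complete_stain_matrix",
    "deconvolve",
    "remix",
    "estimate_vector_from_roi",
    "cd_detect",
    "cmyk_detect",
    "PRESETS",
    "get_preset",
]

# Printed built-in H-DAB brown (DAB) absorbance vector.
DAB_OD = (0.26814753, 0.57031375, 0.77642715)
# Best-performing pink (Picro-Sirius Red) absorbance vector.
PSR_PINK_OD = (0.12670784, 0.76997238, 0.62432366)
# Standard Landini H-DAB haematoxylin triple; an external constant, the
# companion vector is not printed alongside the DAB one.
HEMATOXYLIN_OD = (0.650, 0.704, 0.286)


@dataclass(frozen=True)
class StainVector:
    """A named unit optical-density absorbance vector (R, G, B order).

    Physical stains absorb, so components must be non-negative; the
    auto-completed residual of a two-stain system is the one exception
    (``allow_negative=True``) — it keeps its signed components so the
    completed matrix stays orthogonal and well-conditioned.
    """

    name: str
    od: tuple
    allow_negative: bool = False

    def __post_init__(self):
        od = np.asarray(self.od, dtype=np.float64)
        if od.shape != (3,):
            raise ValueError("a stain vector has exactly three OD components")
        if not self.allow_negative and np.any(od < 0):
            raise ValueError("OD components must be >= 0")
        norm = float(np.linalg.norm(od))
        if norm == 0:
            raise ValueError("zero stain vector")
        object.__setattr__(self, "od", tuple(od / norm))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.od)


@dataclass(frozen=True)
class StainMatrix:
    """Three stain vectors; rows of the OD mixing matrix."""

    stains: tuple  # (StainVector, StainVector, StainVector)

    def __post_init__(self):
        if len(self.stains) != 3:
            raise ValueError("a stain matrix holds exactly 3 stain vectors")
        m = self.matrix
        if np.linalg.matrix_rank(m) < 3:
            raise DegenerateMatrixError("stain matrix is singular")
        if self.condition_number > 1e3:
            warnings.warn(
                f"stain matrix is ill-conditioned (cond = {self.condition_number:.3g})",
                stacklevel=2,
            )

    @property
    def matrix(self) -> np.ndarray:
        return np.stack([s.array for s in self.stains])

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    def stain_names(self) -> list[str]:
        return [s.name for s in self.stains]


def od_transform(image, I0: float = 255.0) -> np.ndarray:
    """Per-channel optical density of an 8-bit RGB image.

    OD_c = −log10((I_c + 1) / (I0 + 1)); the +1 guard keeps intensity 0
    finite.  White (255) maps to OD 0 exactly.
    """
    arr = np.asarray(image, dtype=np.float64)
    return -np.log10((arr + 1.0) / (I0 + 1.0))


def od_to_rgb(od, I0: float = 255.0) -> np.ndarray:
    """Invert :func:`od_transform` and round back to 8-bit intensities."""
    arr = np.asarray(od, dtype=np.float64)
    inten = (I0 + 1.0) * np.power(10.0, -arr) - 1.0
    return np.clip(np.rint(inten), 0, 255).astype(np.uint8)


def complete_stain_matrix(v1: StainVector, v2: StainVector) -> StainMatrix:
    """Complete a two-stain system with an orthogonal residual vector.

    The third row is the normalized cross product of the first two; it
    is exactly orthogonal to both stains, so any absorbance outside the
    two-stain plane lands in the residual channel and the matrix is
    always invertible.  Its components may be signed (it is a residual
    direction, not a physical stain).
    """
    cross = np.cross(v1.array, v2.array)
    norm = np.linalg.norm(cross)
    if norm < 1e-6:
        raise DegenerateMatrixError("stain vectors are collinear; cannot complete matrix")
    third = cross / norm
    if third.sum() < 0:  # orient the residual toward positive absorbance
        third = -third
    return StainMatrix(stains=(v1, v2, StainVector("residual", tuple(third), allow_negative=True)))


def deconvolve(od, m: StainMatrix) -> np.ndarray:
    """Unmix OD maps into per-stain concentration maps.

    *od* has a trailing RGB axis; the result has a trailing stain axis
    ordered as ``m.stains``.  Re-mixing (``remix``) reproduces the OD
    input to numerical precision.
    """
    arr = np.asarray(od, dtype=np.float64)
    return arr @ m.inverse


def remix(concentrations, m: StainMatrix) -> np.ndarray:
    """Forward Beer–Lambert mixing: concentrations → OD maps."""
    return np.asarray(concentrations, dtype=np.float64) @ m.matrix


def estimate_vector_from_roi(image, mask, name: str = "trained", I0: float = 255.0) -> StainVector:
    """Train a stain vector as the unit-normalized mean OD over a ROI.

    Requires at least 10 selected pixels with non-negligible mean OD
    (a white ROI cannot be normalized).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 10:
        raise TrainingError("ROI must select at least 10 pixels")
    od = od_transform(image, I0=I0)[mask]
    mean = od.mean(axis=0)
    norm = float(np.linalg.norm(mean))
    if norm < 1e-6:
        raise TrainingError("ROI mean optical density is ~0 (unstained ROI); cannot normalize")
    return StainVector(name, tuple(np.clip(mean / norm, 0.0, None)))


def cd_detect(image, m: StainMatrix, stain_index: int, threshold: float) -> DetectionResult:
    """Colour-deconvolution detector: threshold one stain's concentration."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    conc = deconvolve(od_transform(image), m)[..., stain_index]
    return DetectionResult(score_map=conc, mask=conc >= threshold, theta_used=float(threshold))


def cmyk_detect(image, channel: str = "Y", threshold: float = 0.5, ucr: bool = True) -> DetectionResult:
    """CMYK-channel detector: threshold one channel of the conversion."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    chan = {"C": 0, "M": 1, "Y": 2, "K": 3}
    if channel not in chan:
        raise ValueError(f"channel must be one of C, M, Y, K; got {channel!r}")
    score = rgb_to_cmyk(image, ucr=ucr)[..., chan[channel]]
    return DetectionResult(score_map=score, mask=score >= threshold, theta_used=float(threshold))


def _make_presets() -> dict:
    h = StainVector("haematoxylin", HEMATOXYLIN_OD)
    dab = StainVector("dab", DAB_OD)
    pink = StainVector("psr-pink", PSR_PINK_OD)
    # Picric-yellow companion: absorbance of a representative pale-yellow
    # PSR background colour (a package-chosen constant; no companion is
    # printed alongside the pink vector).
    yellow_od = od_transform(np.array([250.0, 240.0, 140.0]))
    yellow = StainVector("picric-yellow", tuple(yellow_od / np.linalg.norm(yellow_od)))
    return {
        "h-dab": complete_stain_matrix(h, dab),
        "psr": complete_stain_matrix(yellow, pink),
    }


#: Named stain-matrix presets; in each, index 1 is the target stain
#: (DAB brown for ``h-dab``, PSR pink for ``psr``).
PRESETS: dict[str, StainMatrix] = _make_presets()

#: Index of the target (positively stained) stain within each preset.
PRESET_TARGET_INDEX: dict[str, int] = {"h-dab": 1, "psr": 1}


def get_preset(name: str) -> StainMatrix:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown stain preset {name!r}; available: {sorted(PRESETS)}") from None
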