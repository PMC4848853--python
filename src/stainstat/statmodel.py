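"""The statistical colour model: histogram training and ML-ratio detection.

The model is a pair of class-conditional colour histograms.  Labelled
training pixels (positive = stained, negative = background) are quantized
into colour bins in a chosen chromaticity space and tallied.  The
class-conditional probability of a bin is its count divided by the class
total,

    P(bin | S) = #S[bin] / N_S        P(bin | S̄) = #S̄[bin] / N_S̄,

and a pixel is called positively stained when the maximum-likelihood
ratio meets a threshold θ:

    P(bin | S) / P(bin | S̄) ≥ θ,     0 ≤ θ ≤ 1.

Two conventions close the gaps the ratio leaves open: a bin seen in
neither class has ratio 0 (an unseen colour is not called stain), and a
bin with positive evidence but no negative evidence has ratio +inf (the
inequality holds at every finite θ).  Optional additive smoothing
(``smoothing_alpha`` > 0) replaces counts by (count + α) / (N + α·B);
the default α = 0 reproduces the raw-histogram model.

Training is incremental: histograms from successive labelled samples
accumulate, and the model derived from the accumulated counts is
identical to one trained on the concatenated pixels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import colorspaces as cs
from .errors import (
    ConfigurationError,
    ModelFormatError,
    ModelStateError,
    TrainingError,
)

__all__ = [
    "MODEL_FORMAT_VERSION",
    "DEFAULT_SPACE",
    "DEFAULT_BINS",
    "LabelledPixelSet",
    "TrainingAccumulator",
    "ColourModel",
    "DetectionResult",
    "accumulate",
    "finalize",
    "likelihood_ratio",
    "classify_image",
    "filter_background",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = "1"

#: CbCr with 128 bins per channel: the best-performing chromaticity
#: space and the optimal bin count in the step-one comparison.
DEFAULT_SPACE = "cbcr"
DEFAULT_BINS = 128

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass
class LabelledPixelSet:
    """A non-empty collection of RGB training pixels with one class label."""

    pixels: np.ndarray  # (N, 3) uint8
    label: str  # "positive" or "negative"
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.uint8).reshape(-1, 3)
        if self.pixels.shape[0] == 0:
            raise TrainingError("a labelled pixel set must be non-empty")
        if self.label not in (POSITIVE, NEGATIVE):
            raise ConfigurationError(f"label must be 'positive' or 'negative', got {self.label!r}")

    def __len__(self) -> int:
        return self.pixels.shape[0]


def _empty_counts(space: str, bins: int) -> np.ndarray:
    return np.zeros((bins,) * cs.space_ndim(space), dtype=np.int64)


@dataclass
class TrainingAccumulator:
    """Running per-class histogram counts over one bin geometry."""

    space: str = DEFAULT_SPACE
    bins: int = DEFAULT_BINS
    pos_counts: np.ndarray = None  # type: ignore[assignment]
    neg_counts: np.ndarray = None  # type: ignore[assignment]
    n_pos: int = 0
    n_neg: int = 0
    sample_log: list = field(default_factory=list)

    def __post_init__(self):
        cs.space_ndim(self.space)
        if self.pos_counts is None:
            self.pos_counts = _empty_counts(self.space, self.bins)
        if self.neg_counts is None:
            self.neg_counts = _empty_counts(self.space, self.bins)


def _histogram_pixels(pixels: np.ndarray, space: str, bins: int) -> np.ndarray:
    idx = cs.quantize_rgb(pixels, space, bins)
    ndim = cs.space_ndim(space)
    flat = np.zeros(bins**ndim, dtype=np.int64)
    # row-major flat index: i*B + j (i*B² + j*B + k for 3D)
    lin = idx[..., 0]
    for ax in range(1, ndim):
        lin = lin * bins + idx[..., ax]
    np.add.at(flat, lin.ravel(), 1)
    return flat.reshape((bins,) * ndim)


def accumulate(acc: TrainingAccumulator, sample: LabelledPixelSet) -> TrainingAccumulator:
    """Add one labelled sample's per-bin tallies to the accumulator.

    Mutates and returns *acc*.  Accumulation commutes: samples may be
    added in any order.
    """
    hist = _histogram_pixels(sample.pixels, acc.space, acc.bins)
    if sample.label == POSITIVE:
        acc.pos_counts += hist
        acc.n_pos += len(sample)
    else:
        acc.neg_counts += hist
        acc.n_neg += len(sample)
    acc.sample_log.append(sample.source_id)
    return acc


@dataclass
class ColourModel:
    """A finalized two-class histogram colour model."""

    space: str
    bins: int
    pos_counts: np.ndarray
    neg_counts: np.ndarray
    n_pos: int
    n_neg: int
    theta_default: float = 1.0
    smoothing_alpha: float = 0.0
    sample_log: list = field(default_factory=list)
    format_version: str = MODEL_FORMAT_VERSION

    @property
    def n_bins_total(self) -> int:
        return self.bins ** cs.space_ndim(self.space)

    def prob_pos(self) -> np.ndarray:
        """P(bin | S) over all bins, with additive smoothing if set."""
        a = self.smoothing_alpha
        return (self.pos_counts + a) / (self.n_pos + a * self.n_bins_total)

    def prob_neg(self) -> np.ndarray:
        a = self.smoothing_alpha
        return (self.neg_counts + a) / (self.n_neg + a * self.n_bins_total)

    def ratio_table(self) -> np.ndarray:
        """Per-bin likelihood ratio P(bin|S)/P(bin|S̄).

        With α = 0: bins with positive evidence only are +inf, bins seen
        in neither class are 0.
        """
        p = self.prob_pos()
        q = self.prob_neg()
        with np.errstate(divide="ignore", invalid="ignore"):
            r = p / q
        r[(q == 0) & (p > 0)] = np.inf
        r[(q == 0) & (p == 0)] = 0.0
        return r


def finalize(
    acc: TrainingAccumulator,
    theta_default: float = 1.0,
    smoothing_alpha: float = 0.0,
) -> ColourModel:
    """Derive a usable model from accumulated counts.

    Requires at least one pixel in each class; raises ``TrainingError``
    naming the missing class otherwise.
    """
    if acc.n_pos <= 0:
        raise TrainingError("cannot finalize: no pixels in the positive class")
    if acc.n_neg <= 0:
        raise TrainingError("cannot finalize: no pixels in the negative class")
    if smoothing_alpha < 0:
        raise ConfigurationError("smoothing_alpha must be >= 0")
    if not (0.0 <= theta_default <= 1.0):
        raise ConfigurationError("theta_default must be in [0, 1]")
    return ColourModel(
        space=acc.space,
        bins=acc.bins,
        pos_counts=acc.pos_counts.copy(),
        neg_counts=acc.neg_counts.copy(),
        n_pos=acc.n_pos,
        n_neg=acc.n_neg,
        theta_default=theta_default,
        smoothing_alpha=smoothing_alpha,
        sample_log=list(acc.sample_log),
    )


def _bin_index_tuple(model: ColourModel, pixels) -> tuple:
    idx = cs.quantize_rgb(pixels, model.space, model.bins)
    return tuple(idx[..., ax] for ax in range(idx.shape[-1]))


def likelihood_ratio(model: ColourModel, pixels) -> np.ndarray:
    """Likelihood ratio of each pixel's colour bin (vectorised)."""
    if not isinstance(model, ColourModel):
        raise ModelStateError("likelihood_ratio requires a finalized ColourModel")
    table = model.ratio_table()
    return table[_bin_index_tuple(model, pixels)]


@dataclass
class DetectionResult:
    """Per-pixel scores and the thresholded detection mask for one image."""

    score_map: np.ndarray  # float, same H×W as the image
    mask: np.ndarray  # bool
    theta_used: float

    @property
    def positive_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0


def classify_image(model: ColourModel, image, theta: float | None = None) -> DetectionResult:
    """Classify every pixel of an 8-bit RGB image by the ML-ratio rule.

    ``mask`` is True exactly where the likelihood ratio ≥ θ.  θ defaults
    to the model's stored default; values above 1 are accepted (with a
    warning) so ROC sweeps can explore the full ratio range.
    """
    if not isinstance(model, ColourModel):
        raise ModelStateError("classify_image requires a finalized ColourModel")
    if theta is None:
        theta = model.theta_default
    if theta < 0:
        raise ConfigurationError("theta must be >= 0")
    if theta > 1:
        warnings.warn("theta > 1 is outside the decision rule's stated range; "
                      "accepted for ROC sweeps", stacklevel=2)
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ConfigurationError("expected an H×W×3 RGB image")
    scores = likelihood_ratio(model, img)
    mask = scores >= theta
    return DetectionResult(score_map=scores, mask=mask, theta_used=float(theta))


def filter_background(
    pixels,
    provisional: ColourModel | np.ndarray,
    slider: float,
    space: str = DEFAULT_SPACE,
    bins: int = DEFAULT_BINS,
) -> np.ndarray:
    """Drop candidate training pixels from low-mass histogram bins.

    Headless equivalent of the interactive sliding-bar background
    filter: a pixel is retained when its bin's share of the provisional
    positive histogram is at least ``slider`` times the modal bin's
    share.  ``slider = 0`` retains everything; ``slider = 1`` retains
    only occupants of the modal bin.

    *provisional* is either a finalized ``ColourModel`` (its positive
    histogram is used, and its geometry overrides *space*/*bins*) or a
    raw positive count array laid out as by the accumulator.
    """
    if not (0.0 <= slider <= 1.0):
        raise ConfigurationError("slider must be in [0, 1]")
    if isinstance(provisional, ColourModel):
        counts = provisional.pos_counts
        space, bins = provisional.space, provisional.bins
    else:
        counts = np.asarray(provisional)
        if counts.shape != (bins,) * cs.space_ndim(space):
            raise ConfigurationError("provisional histogram shape does not match space/bins")
    total = counts.sum()
    if total <= 0:
        raise TrainingError("provisional positive histogram is empty")
    mass = counts / total
    cutoff = slider * mass.max()
    px = np.asarray(pixels, dtype=np.uint8).reshape(-1, 3)
    idx = cs.quantize_rgb(px, space, bins)
    pixel_mass = mass[tuple(idx[:, ax] for ax in range(idx.shape[-1]))]
    return px[pixel_mass >= cutoff]


# ---------------------------------------------------------------------------
# Persistence: JSON with sparse count maps {flat_index: count}.

def _counts_to_sparse(counts: np.ndarray) -> dict[str, int]:
    flat = counts.ravel()
    nz = np.flatnonzero(flat)
    return {str(int(i)): int(flat[i]) for i in nz}


def _sparse_to_counts(sparse: dict, shape: tuple, what: str) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=np.int64)
    for key, val in sparse.items():
        i = int(key)
        v = int(val)
        if v < 0:
            raise ModelFormatError(f"negative count in {what}")
        if not (0 <= i < flat.size):
            raise ModelFormatError(f"flat index {i} out of range in {what}")
        flat[i] = v
    return flat.reshape(shape)


def save_model(model: ColourModel, path) -> None:
    """Serialize a model to UTF-8 JSON (sparse per-class count maps)."""
    doc = {
        "format_version": model.format_version,
        "space_tag": model.space,
        "bins_per_channel": model.bins,
        "smoothing_alpha": model.smoothing_alpha,
        "theta_default": model.theta_default,
        "N_S": model.n_pos,
        "N_Sbar": model.n_neg,
        "pos_counts": _counts_to_sparse(model.pos_counts),
        "neg_counts": _counts_to_sparse(model.neg_counts),
        "sample_log": list(model.sample_log),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True)


def load_model(path) -> ColourModel:
    """Load and validate a model file; raises ``ModelFormatError`` on defects."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    try:
        version = doc["format_version"]
        space = doc["space_tag"]
        bins = int(doc["bins_per_channel"])
        n_pos = int(doc["N_S"])
        n_neg = int(doc["N_Sbar"])
        shape = (bins,) * cs.space_ndim(space)
        pos = _sparse_to_counts(doc["pos_counts"], shape, "pos_counts")
        neg = _sparse_to_counts(doc["neg_counts"], shape, "neg_counts")
        model = ColourModel(
            space=space,
            bins=bins,
            pos_counts=pos,
            neg_counts=neg,
            n_pos=n_pos,
            n_neg=n_neg,
            theta_default=float(doc["theta_default"]),
            smoothing_alpha=float(doc["smoothing_alpha"]),
            sample_log=list(doc.get("sample_log", [])),
            format_version=version,
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ModelFormatError(f"malformed model file {path}: {exc}") from exc
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model format version {version!r} (expected {MODEL_FORMAT_VERSION})"
        )
    if int(model.pos_counts.sum()) != n_pos:
        raise ModelFormatError("sum(pos_counts) does not equal N_S")
    if int(model.neg_counts.sum()) != n_neg:
        raise ModelFormatError("sum(neg_counts) does not equal N_Sbar")
    return model
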