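"""Seeded synthetic stained-slide phantoms with pixel-level ground truth.

Phantoms emulate brightfield histology under the Beer–Lambert law: each
stain contributes ``density × od_vector`` to the per-pixel optical
density, and transmitted intensity is ``255 · 10^(−OD)`` plus additive
Gaussian sensor noise, rounded to 8 bits.  Because mixing is exactly the
linear-absorbance model colour deconvolution assumes, the deconvolution
baseline is bias-free on noise-free phantoms and its characteristic
failure on very dark stain emerges only from 8-bit clipping — the
saturated-DAB regime is reproduced by rendering a fraction of target
objects at three times the top nominal density.

Two stock conditions mirror the common assays: DAB-brown targets on a
haematoxylin-blue background (``dab_params``) and Picro-Sirius-Red pink
fibres on a pale-yellow background (``psr_params``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import disk, ellipse

from .baselines import StainMatrix, get_preset
from .errors import SamplingError
from .statmodel import LabelledPixelSet

__all__ = [
    "GROUND_TRUTH_EPSILON",
    "PhantomParams",
    "SyntheticSlide",
    "dab_params",
    "psr_params",
    "render_slide",
    "sample_training_pixels",
    "make_benchmark",
]

#: Minimum target-stain OD density for a pixel to count as ground-truth
#: positive.  Fixed, and recorded in benchmark manifests.
GROUND_TRUTH_EPSILON = 0.05


@dataclass(frozen=True)
class PhantomParams:
    """Full description of one phantom; identical params + seed give a
    bit-identical rendering."""

    width: int = 256
    height: int = 256
    stain_matrix: StainMatrix = field(default_factory=lambda: get_preset("h-dab"))
    target_stain_index: int = 1
    counter_stain_index: int = 0
    n_objects: int = 40
    object_shape: str = "ellipse"  # "ellipse" (nuclei) or "fibre" (strips)
    size_range: tuple = (6.0, 18.0)
    target_density_range: tuple = (0.4, 1.0)
    counter_density_range: tuple = (0.3, 0.8)
    target_object_fraction: float = 0.5
    dark_fraction: float = 0.0
    dark_multiplier: float = 9.0
    noise_sd: float = 2.0
    background_rgb: tuple = (228, 230, 244)
    seed: int = 0

    def __post_init__(self):
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")
        if not (0.0 <= self.dark_fraction <= 1.0):
            raise ValueError("dark_fraction must be in [0, 1]")
        if self.dark_multiplier < 3.0:
            raise ValueError("dark objects are rendered at >= 3x the top target density")
        if min(self.target_density_range) < 0 or min(self.counter_density_range) < 0:
            raise ValueError("stain densities must be >= 0")
        if self.object_shape not in ("ellipse", "fibre"):
            raise ValueError("object_shape must be 'ellipse' or 'fibre'")


def dab_params(**overrides) -> PhantomParams:
    """DAB-brown nuclei and haematoxylin-blue counter-objects on a pale
    haematoxylin-washed (faint blue) field."""
    return dataclasses.replace(PhantomParams(), **overrides)


def psr_params(**overrides) -> PhantomParams:
    """PSR-pink collagen fibres on a pale-yellow background."""
    base = PhantomParams(
        stain_matrix=get_preset("psr"),
        object_shape="fibre",
        background_rgb=(250, 240, 140),
        counter_density_range=(0.1, 0.3),
    )
    return dataclasses.replace(base, **overrides)


@dataclass
class SyntheticSlide:
    """A rendered phantom with its ground truth."""

    image: np.ndarray  # (H, W, 3) uint8
    truth_mask: np.ndarray  # (H, W) bool: target density > epsilon
    target_density: np.ndarray  # (H, W) float OD-scale
    counter_density: np.ndarray  # (H, W) float OD-scale
    params: PhantomParams

    @property
    def true_fraction(self) -> float:
        return float(self.truth_mask.mean())


def _stamp_ellipse(dens, rng, size_lo, size_hi, value, shape):
    a = rng.uniform(size_lo, size_hi)
    b = rng.uniform(size_lo, size_hi)
    r0 = rng.uniform(0, shape[0])
    c0 = rng.uniform(0, shape[1])
    rot = rng.uniform(0, np.pi)
    rr, cc = ellipse(r0, c0, a, b, shape=shape, rotation=rot)
    dens[rr, cc] += value


def _stamp_fibre(dens, rng, size_lo, size_hi, value, shape):
    # curvilinear strip: disks stamped along a quadratic Bézier curve
    size = rng.uniform(size_lo, size_hi)
    thickness = max(1.0, size / 4.0)
    length = 4.0 * size
    p0 = rng.uniform([0, 0], shape)
    angle = rng.uniform(0, 2 * np.pi)
    p2 = p0 + length * np.array([np.sin(angle), np.cos(angle)])
    mid = (p0 + p2) / 2.0
    p1 = mid + rng.normal(0, length / 4.0, size=2)
    painted = np.zeros(shape, dtype=bool)
    for t in np.linspace(0.0, 1.0, max(8, int(2 * length))):
        pt = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2
        rr, cc = disk(tuple(pt), thickness, shape=shape)
        painted[rr, cc] = True
    dens[painted] += value


def render_slide(params: PhantomParams) -> SyntheticSlide:
    """Render a phantom: seeded object placement, Beer–Lambert mixing,
    8-bit quantization and additive Gaussian noise."""
    rng = np.random.default_rng(params.seed)
    shape = (params.height, params.width)
    target_dens = np.zeros(shape)
    counter_dens = np.zeros(shape)
    lo, hi = params.size_range
    t_lo, t_hi = params.target_density_range
    c_lo, c_hi = params.counter_density_range
    stamp = _stamp_ellipse if params.object_shape == "ellipse" else _stamp_fibre
    for _ in range(params.n_objects):
        is_target = rng.random() < params.target_object_fraction
        if is_target:
            if rng.random() < params.dark_fraction:
                # saturated dark-stain mimic: deep enough into the 8-bit
                # floor that the darkest stain is close to neutral black
                value = params.dark_multiplier * t_hi
            else:
                value = rng.uniform(t_lo, t_hi)
            stamp(target_dens, rng, lo, hi, value, shape)
        else:
            stamp(counter_dens, rng, lo, hi, rng.uniform(c_lo, c_hi), shape)

    m = params.stain_matrix.matrix
    bg = np.asarray(params.background_rgb, dtype=np.float64)
    bg_od = -np.log10((bg + 1.0) / 256.0)
    od = (
        bg_od[None, None, :]
        + target_dens[..., None] * m[params.target_stain_index]
        + counter_dens[..., None] * m[params.counter_stain_index]
    )
    # transmission law chosen as the exact inverse of od_transform's
    # guarded formula, so unmixing error is pure 8-bit rounding
    inten = np.rint(256.0 * np.power(10.0, -od) - 1.0)
    if params.noise_sd > 0:
        inten = inten + rng.normal(0.0, params.noise_sd, size=inten.shape)
    image = np.clip(np.rint(inten), 0, 255).astype(np.uint8)
    truth = target_dens > GROUND_TRUTH_EPSILON
    return SyntheticSlide(
        image=image,
        truth_mask=truth,
        target_density=target_dens,
        counter_density=counter_dens,
        params=params,
    )


def sample_training_pixels(
    slide: SyntheticSlide, n_pos: int, n_neg: int, seed: int
) -> tuple[LabelledPixelSet, LabelledPixelSet]:
    """Draw labelled training pixels from a phantom, without replacement
    within each class (labels come from the ground-truth mask)."""
    rng = np.random.default_rng(seed)
    flat_img = slide.image.reshape(-1, 3)
    truth = slide.truth_mask.ravel()
    pos_idx = np.flatnonzero(truth)
    neg_idx = np.flatnonzero(~truth)
    if len(pos_idx) < n_pos:
        raise SamplingError(f"phantom has only {len(pos_idx)} positive pixels, need {n_pos}")
    if len(neg_idx) < n_neg:
        raise SamplingError(f"phantom has only {len(neg_idx)} negative pixels, need {n_neg}")
    take_pos = rng.choice(pos_idx, size=n_pos, replace=False)
    take_neg = rng.choice(neg_idx, size=n_neg, replace=False)
    sid = f"phantom-seed{slide.params.seed}"
    return (
        LabelledPixelSet(flat_img[take_pos], "positive", source_id=sid + ":pos"),
        LabelledPixelSet(flat_img[take_neg], "negative", source_id=sid + ":neg"),
    )


def make_benchmark(
    n_slides: int,
    params_template: PhantomParams,
    base_seed: int,
    out_dir,
    train_fraction: float = 0.5,
) -> pd.DataFrame:
    """Render a deterministic benchmark set and write it to *out_dir*.

    Produces one PNG image and one 0/255 mask PNG per slide plus a
    ``manifest.csv`` with columns ``file,mask,seed,true_fraction,split``.
    The first ``ceil(train_fraction · n)`` slides form the train split.
    """
    import imageio.v3 as iio

    if n_slides < 2:
        raise ValueError("a benchmark needs at least 2 slides")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_train = int(np.ceil(train_fraction * n_slides))
    rows = []
    for i in range(n_slides):
        params = dataclasses.replace(params_template, seed=base_seed + i)
        slide = render_slide(params)
        img_name = f"slide_{i:03d}.png"
        mask_name = f"slide_{i:03d}_mask.png"
        iio.imwrite(out / img_name, slide.image)
        iio.imwrite(out / mask_name, (slide.truth_mask * np.uint8(255)))
        rows.append(
            {
                "file": img_name,
                "mask": mask_name,
                "seed": params.seed,
                "true_fraction": slide.true_fraction,
                "split": "train" if i < n_train else "test",
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
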