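import numpy as np
import pytest

from stainstat import statmodel as sm
from stainstat import synthdata as sd


def gaussian_cbcr_pixels(mean_cb, mean_cr, sd, n, rng):
    """RGB pixels whose CbCr chromaticity is Gaussian around a mean.

    Luma is drawn uniformly in a range that keeps all channels inside
    [0, 255] for means within about 35 units of the grey axis, so
    clipping does not distort the chromaticity distribution.
    """
    cb = rng.normal(mean_cb, sd, n)
    cr = rng.normal(mean_cr, sd, n)
    y = rng.uniform(90, 160, n)
    r = y + 1.402 * cr
    g = y - 0.344136 * cb - 0.714136 * cr
    b = y + 1.772 * cb
    return np.clip(np.rint(np.stack([r, g, b], axis=-1)), 0, 255).astype(np.uint8)


def train_two_class(pos_px, neg_px, space="cbcr", bins=128, **finalize_kw):
    acc = sm.TrainingAccumulator(space=space, bins=bins)
    sm.accumulate(acc, sm.LabelledPixelSet(pos_px, "positive", "pos"))
    sm.accumulate(acc, sm.LabelledPixelSet(neg_px, "negative", "neg"))
    return sm.finalize(acc, **finalize_kw)


@pytest.fixture(scope="session")
def dab_slide():
    return sd.render_slide(sd.dab_params(seed=11))


@pytest.fixture(scope="session")
def dab_model(dab_slide):
    pos, neg = sd.sample_training_pixels(dab_slide, 4000, 4000, seed=7)
    return train_two_class(pos.pixels, neg.pixels)


@pytest.fixture(scope="session")
def toy_counts():
    """A 16-colour toy problem on a 4-bin CbCr grid with hand-set counts.

    Returns (colours, pos_counts, neg_counts) where the counts index the
    4x4 bin grid of each colour's quantized chromaticity.
    """
    rng = np.random.default_rng(42)
    colours = rng.integers(0, 256, size=(16, 3), dtype=np.uint8)
    pos = np.zeros((4, 4), dtype=np.int64)
    neg = np.zeros((4, 4), dtype=np.int64)
    from stainstat import colorspaces as cs

    idx = cs.quantize_rgb(colours, "cbcr", 4)
    for k, (i, j) in enumerate(idx):
        # deterministic, asymmetric tallies; some colours in one class only
        if k % 3 == 0:
            pos[i, j] += 5 + k
        elif k % 3 == 1:
            neg[i, j] += 3 + k
        else:
            pos[i, j] += k
            neg[i, j] += 2 * k + 1
    return colours, pos, neg


@pytest.fixture(scope="session")
def toy_model(toy_counts):
    _, pos, neg = toy_counts
    return sm.ColourModel(
        space="cbcr",
        bins=4,
        pos_counts=pos,
        neg_counts=neg,
        n_pos=int(pos.sum()),
        n_neg=int(neg.sum()),
    )
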