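# Methods

## The statistical colour model

The detector is a two-class non-parametric colour model. Labelled
training pixels are transformed to a colour space, quantized into a
uniform histogram, and tallied per class; the likelihood ratio of a
pixel's bin against a threshold θ ∈ [0, 1] gives the decision. Four
spaces are supported:

| space | dims | coordinates | binning range |
|---|---|---|---|
| `rgb` | 3 | raw R, G, B | [0, 256) per channel |
| `normalized_rgb` | 2 | r = R/(R+G+B), g = G/(R+G+B) | [0, 1] each |
| `opponent` | 2 | rg = r − g, by = (r+g)/2 − b | [−1, 1] × [−1, 0.5] |
| `cbcr` | 2 | Cb = −0.1687R − 0.3313G + 0.5B, Cr = 0.5R − 0.4187G − 0.0813B | [−128, 128) each |

`cbcr` with 128 bins per channel is the default: discarding luminance
makes the model robust to staining intensity and illumination, halves
the memory of a 3D histogram, and 128 bins per channel balances
resolution against sparsity. "Bins" always means bins **per channel**
(a 2D model has 128² cells). The normalized-RGB space is binned over
(r, g) only, since b = 1 − r − g carries no extra information. Bin
edges are fixed over each space's full representable range — never
data-driven — so models trained on different images share geometry and
histograms can be accumulated across samples. CbCr values are kept
signed (as the linear form produces them); the +128 offset enters only
at quantization. The upper range boundary clamps into the last bin.

Degenerate colours are made total by convention: black normalizes to
the grey limit (1/3, 1/3, 1/3), a bin seen in neither class has ratio 0
(an unseen colour is never called stain), and a bin with positive but
no negative evidence has ratio +inf (positive at every finite θ).
Optional additive smoothing α replaces counts with
(count + α)/(N + α·B); the default α = 0 is the plain
relative-frequency model, and α is stored in the model file so a saved
model classifies reproducibly.

θ defaults to 1, the canonical maximum-likelihood boundary; no other
fixed value is privileged, and ROC sweeps explore the full range
(values above 1 are accepted with a warning).

The headless *background filter* replaces the interactive
sliding-bar step of ROI-based training tools: a candidate training
pixel is kept when its bin's share of the provisional positive
histogram is at least `slider` times the modal bin's share. What the
original interactive bar thresholds is not documented; relative
histogram mass is this package's explicit, deterministic stand-in.

Model files are UTF-8 JSON with sparse per-class count maps
(`{flat_index: count}`, row-major flat index i·B + j). Loading
validates counts against the class totals, so a corrupted file fails
loudly rather than classifying subtly wrong.

## Baselines

**Colour deconvolution.** Stains are unit optical-density vectors;
absorbances add (Beer–Lambert), so per-pixel stain amounts come from
inverting the 3×3 stain matrix applied to
OD_c = −log10((I_c + 1)/(I0 + 1)). The +1 guard keeps black pixels
finite at the cost of a small bias at very low intensity. Presets ship
the published built-in H-DAB DAB vector (0.26814753, 0.57031375,
0.77642715) and the best PSR pink vector (0.12670784, 0.76997238,
0.62432366). Companion vectors are external or package-chosen
constants: the standard haematoxylin triple (0.650, 0.704, 0.286), and
a picric-yellow vector derived from a representative pale-yellow
background colour. A two-stain matrix is completed with the normalized
cross product of the stain pair; the residual row is exactly orthogonal
to both stains (its components may be signed — it is a residual
direction, not a physical stain), which keeps the matrix invertible and
routes off-plane absorbance into the residual channel. ROI-based vector
"training" is the unit-normalized mean OD of the ROI, the simplest
defensible estimator.

**CMYK.** The Y channel of the undercolour-removal RGB→CMYK conversion
(K = min(C′, M′, Y′) subtracted from each primary; a naive no-UCR
variant is available). Under UCR, Y = (R − B)/255 whenever R is the
brightest channel, so the channel responds to brown but collapses to
≈ 0 for dark, nearly neutral pixels — the documented undercounting of
saturated DAB.

## Evaluation protocol

Detections are ranked into integer confidence levels 1..L_max
(L_max = 255; level 0 = not detected), and cumulative TPR/FPR sums run
from the most confident level downward for sweep steps i = 1..I_max
(default 200). Pixels sharing a level enter atomically — no
intra-level interpolation — and pooling images before ranking is
identical to evaluating the concatenated pixels. Two level modes
exist: `intensity` (level = 255 − luminance of the detected pixel, the
detected-image convention, darker = more confident) and `ratio` (a
monotone map of the log likelihood-ratio onto [2, 254], with 1 reserved
for zero ratios and 255 for +inf, preserving score order). AUC is
trapezoidal over the polyline closed through (0, 0) and (1, 1); the
partial AUC at an FPR cap (10 % by convention) is reported both
normalized by the cap (default; a perfect detector scores 1 at any
cap) and truncated, since the convention in published tables is
ambiguous. Agreement between detected and reference positive fractions
is the squared Pearson correlation (equivalently OLS R² with
intercept). Pooling across images is the default; per-image averaging
is available behind a flag.

## Synthetic phantoms

The generator renders seeded stained-tissue phantoms with exact ground
truth. Elliptical objects (nuclei) or curvilinear strips (fibres) are
placed uniformly at random; each object deposits a constant stain
density, densities adding where objects overlap. Per pixel,
OD = background OD + Σ density_s · v_s, and transmitted intensity is
I = round(256·10^(−OD) − 1) plus additive Gaussian sensor noise
(sd 2 intensity units), clipped to 8 bits. This transmission law is the
exact inverse of the package's guarded OD transform, so on noise-free
phantoms the deconvolution baseline's only error source is 8-bit
rounding: recovered densities are within the analytic rounding bound
everywhere, and within 0.01 OD in the single-stain regime at nominal
densities ≤ 1.0. (At co-stained overlaps the information limit of 8
bits exceeds 0.01 OD — one intensity step at OD 1.2 is ≈ 0.012 OD —
so no unmixing method can do better there.)

Stock conditions: `dab_params` renders DAB-brown targets and
haematoxylin-blue counter-objects on a pale haematoxylin-washed field
(228, 230, 244) — slide background is rarely pure white once a
counterstain has been applied; `psr_params` renders pink fibres on a
pale picric-yellow field. Defaults: 256×256 px, 40 objects, object
sizes 6–18 px, target densities 0.4–1.0 OD, counterstain 0.3–0.8 OD.
Ground truth is target density > ε = 0.05 OD (fixed, recorded in
benchmark manifests).

A `dark_fraction` of target objects is rendered at `dark_multiplier`
(default 9, minimum 3) times the top nominal density. The default
drives all channels to the 8-bit floor, producing the nearly neutral
black of saturated chromogen. This regime is what separates the
methods: against a chromatic (blue-washed) background, the histogram
model learns near-black as a positive colour, while the CMYK Y channel
of a neutral pixel is ≈ 0 — tied with the background — and linear
unmixing misestimates clipped pixels. At only 3× the darkest
Beer–Lambert pixel is still strongly chromatic (R ≈ 40, B ≈ 0) and the
failure mode never appears.

What the phantoms do **not** emulate: tissue texture and spatially
correlated stain variation, scanner colour profiles and chromatic
aberration, out-of-focus blur, true chemical saturation (deviation
from Beer–Lambert below the clipping point), and annotation noise in
the ground truth. Passing tests therefore demonstrate correctness of
the algorithms and the direction of the method differences under the
stated physics — not field performance on patient material.

## Numerical and design notes

- Histogram accumulation commutes and is exactly equivalent to
  training on concatenated pixels; tests assert this bit-exactly.
- Classification uses a per-bin lookup table, so an image classifies in
  O(pixels) independent of θ.
- The ROC oracle equivalence (naive per-threshold recount) and the
  likelihood-ratio oracle equivalence (per-pixel brute force on a
  16-colour toy model at 100 θ values) are exact, not approximate.
- Problem sizes in tests and the acceptance script (256² phantoms,
  10-slide benchmarks, 10⁵ training pixels per class) were chosen so
  the full pipeline exercises every code path in seconds while keeping
  all measured quantities stable to well under a percentage point
  across seeds.
- No pretrained stain model ships with the package: the published
  tool's default model was trained on unavailable data, so fixtures are
  always trained at run time from the synthetic generator.

## Known limitations

- A chromaticity-only model cannot separate colours that differ only in
  luminance (e.g. neutral black stain on a pure-white background); the
  stock phantoms avoid this degeneracy the same way real slides do,
  via a tinted background.
- Raw (α = 0) 128² histograms are sparse for small training sets;
  unseen colours default to negative. Use more training pixels or
  α > 0.
- The CMYK conversion formula of the original comparison is not fully
  documented; both UCR and naive variants are provided.
- Partial-AUC tables in the literature may use either the truncated or
  the normalized convention; both are reported.
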