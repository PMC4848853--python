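"""Pixel-level ROC evaluation and positive-fraction quantification.

Detections are ranked into integer confidence *levels* 1..L_max
(level 0 = not detected).  The ROC is built cumulatively over levels,
from the most confident downward: with T_j the true positives and D_j
all detections entering at sweep step j,

    TPR_i = Σ_{j=1..i} T_j / G_S      FPR_i = Σ_{j=1..i} (D_j − T_j) / G_S̄

for i = 1..I_max (default 200), where G_S and G_S̄ are the ground-truth
positive and negative pixel totals.  Pixels sharing a level enter the
sums atomically — no intra-level interpolation — and pooling detections
over several images before ranking is identical to evaluating their
concatenated pixels.

Areas under the curve are trapezoidal; the partial area at an FPR cap
(10 % by convention) is reported either normalized by the cap, so a
perfect detector scores 1 at any cap, or truncated (raw area).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EvaluationError
from .statmodel import DetectionResult

__all__ = [
    "GroundTruth",
    "LevelledScores",
    "ROCCurve",
    "QuantComparison",
    "scores_to_levels",
    "pool_levels",
    "roc_curve",
    "auc",
    "positive_fraction_series",
]

DEFAULT_L_MAX = 255
DEFAULT_I_MAX = 200

# BT.601 luma weights used for the intensity-mode confidence level.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class GroundTruth:
    """A boolean truth mask with its class totals."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def g_pos(self) -> int:
        return int(self.mask.sum())

    @property
    def g_neg(self) -> int:
        return int(self.mask.size - self.mask.sum())


@dataclass
class LevelledScores:
    """Integer confidence levels per pixel: 0 = undetected, L_max = most confident."""

    levels: np.ndarray  # int array, any shape
    l_max: int = DEFAULT_L_MAX

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=np.int64)
        if self.levels.size and (self.levels.min() < 0 or self.levels.max() > self.l_max):
            raise EvaluationError("levels must lie in [0, l_max]")


@dataclass
class ROCCurve:
    """Cumulative TPR/FPR arrays over sweep steps i = 1..I_max."""

    tpr: np.ndarray
    fpr: np.ndarray

    @property
    def i_max(self) -> int:
        return len(self.tpr)


def scores_to_levels(
    result: DetectionResult,
    mode: str = "intensity",
    image=None,
    l_max: int = DEFAULT_L_MAX,
) -> LevelledScores:
    """Rank a detection result's pixels into confidence levels.

    ``mode="intensity"`` (the detected-image convention): a detected
    pixel's level is ``l_max − round(luminance)`` of the *original
    image* pixel, clamped to at least 1, so darker detected stain ranks
    more confident; undetected pixels are level 0.  Requires *image*.

    ``mode="ratio"``: a monotone map of the log likelihood-ratio onto
    [1, l_max]; +inf scores rank at l_max, zero scores at 1 (finite
    positive scores occupy [2, l_max − 1] so the order of the score
    classes is preserved), and equal scores share a level.
    """
    mask = result.mask
    levels = np.zeros(mask.shape, dtype=np.int64)
    if mode == "intensity":
        if image is None:
            raise ValueError("mode='intensity' requires the original RGB image")
        lum = np.rint(np.asarray(image, dtype=np.float64) @ _LUMA)
        lv = l_max - lum
        levels[mask] = np.clip(lv[mask], 1, l_max).astype(np.int64)
    elif mode == "ratio":
        scores = np.asarray(result.score_map, dtype=np.float64)
        sel = mask & np.isfinite(scores) & (scores > 0)
        levels[mask & np.isinf(scores)] = l_max
        levels[mask & (scores == 0)] = 1
        if np.any(sel):
            logs = np.log(scores[sel])
            lo, hi = logs.min(), logs.max()
            if hi > lo:
                scaled = 2 + (logs - lo) * (l_max - 3) / (hi - lo)
            else:
                scaled = np.full(logs.shape, (1 + l_max) / 2.0)
            levels[sel] = np.clip(np.rint(scaled), 2, l_max - 1).astype(np.int64)
    else:
        raise ValueError("mode must be 'intensity' or 'ratio'")
    return LevelledScores(levels=levels, l_max=l_max)


def pool_levels(parts: list[LevelledScores]) -> LevelledScores:
    """Concatenate per-image levels into one pooled instance."""
    if not parts:
        raise EvaluationError("nothing to pool")
    l_max = parts[0].l_max
    if any(p.l_max != l_max for p in parts):
        raise EvaluationError("cannot pool levels with different l_max")
    return LevelledScores(np.concatenate([p.levels.ravel() for p in parts]), l_max=l_max)


def roc_curve(
    levels: LevelledScores,
    gt: GroundTruth,
    i_max: int = DEFAULT_I_MAX,
) -> ROCCurve:
    """Cumulative ROC over confidence levels, most confident first.

    Sweep step i covers levels l_max down to l_max − i + 1; level-0
    (undetected) pixels never enter the sums.  Requires both truth
    classes to be non-empty.
    """
    if gt.g_pos == 0 or gt.g_neg == 0:
        raise EvaluationError("ROC requires both positive and negative ground-truth pixels")
    lv = levels.levels.ravel()
    truth = gt.mask.ravel()
    if lv.shape != truth.shape:
        raise EvaluationError("levels and ground truth have different sizes")
    l_max = levels.l_max
    # D_j, T_j indexed by sweep rank j = l_max + 1 − level, for levels >= 1
    det = lv >= 1
    rank_det = l_max + 1 - lv[det]
    d_j = np.bincount(rank_det, minlength=l_max + 1)[1 : i_max + 1].astype(np.float64)
    rank_tp = l_max + 1 - lv[det & truth]
    t_j = np.bincount(rank_tp, minlength=l_max + 1)[1 : i_max + 1].astype(np.float64)
    if len(d_j) < i_max:  # i_max beyond l_max: pad with empty levels
        pad = i_max - len(d_j)
        d_j = np.pad(d_j, (0, pad))
        t_j = np.pad(t_j, (0, pad))
    tpr = np.cumsum(t_j) / gt.g_pos
    fpr = np.cumsum(d_j - t_j) / gt.g_neg
    return ROCCurve(tpr=tpr, fpr=fpr)


def _curve_points(curve: ROCCurve) -> tuple[np.ndarray, np.ndarray]:
    """Integration polyline: (0,0), the sweep points, then (1,1)."""
    fpr = np.concatenate([[0.0], curve.fpr, [1.0]])
    tpr = np.concatenate([[0.0], curve.tpr, [1.0]])
    return fpr, tpr


def auc(curve: ROCCurve, fpr_cap: float = 1.0, normalized: bool = True) -> float:
    """Trapezoidal area under the ROC restricted to FPR ≤ *fpr_cap*.

    The polyline is closed through (0, 0) and (1, 1).  With
    ``normalized=True`` the partial area is divided by the cap so a
    perfect detector scores 1 at any cap; ``fpr_cap=1`` is the standard
    full AUC either way.
    """
    if not (0.0 < fpr_cap <= 1.0):
        raise ValueError("fpr_cap must be in (0, 1]")
    fpr, tpr = _curve_points(curve)
    if fpr_cap < 1.0:
        tpr_cap = float(np.interp(fpr_cap, fpr, tpr))
        keep = fpr < fpr_cap
        fpr = np.concatenate([fpr[keep], [fpr_cap]])
        tpr = np.concatenate([tpr[keep], [tpr_cap]])
    area = float(np.trapezoid(tpr, fpr))
    return area / fpr_cap if normalized else area


@dataclass
class QuantComparison:
    """Paired detected vs manual positive fractions and their R²."""

    detected: np.ndarray
    manual: np.ndarray
    r_squared: float


def positive_fraction_series(detected, manual) -> QuantComparison:
    """R² (squared Pearson correlation) of detected vs manual fractions.

    *detected* may be a list of :class:`DetectionResult` or of floats.
    Requires at least 3 pairs and non-zero variance in both series.
    """
    det = np.array(
        [d.positive_fraction if isinstance(d, DetectionResult) else float(d) for d in detected],
        dtype=np.float64,
    )
    man = np.asarray(manual, dtype=np.float64)
    if det.shape != man.shape or det.size < 3:
        raise EvaluationError("need >= 3 equal-length paired fractions")
    if np.ptp(det) == 0 or np.ptp(man) == 0:
        raise EvaluationError("zero-variance series: R² undefined")
    r = float(np.corrcoef(det, man)[0, 1])
    return QuantComparison(detected=det, manual=man, r_squared=r * r)
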