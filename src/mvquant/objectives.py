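"""Multiclass segmentation objectives and evaluation metrics.

Implements, independent of any network, the training objectives and metrics
used for scallop-level mitral valve segmentation:

* generalized Dice loss, averaged over the set C' of classes *present* in
  the ground truth:

      L_Dice = 1 - (1/|C'|) sum_{c in C'}
               (2 sum_i p_ic g_ic + eps) / (sum_i p_ic + sum_i g_ic + eps)

* focal loss with focusing parameter gamma (default 2), summed over *all*
  classes C:

      L_Focal = -(1/N) sum_i sum_{c in C} (1 - p_ic)^gamma g_ic log p_ic

* the combined objective  L = (L_Dice + L_Focal) / 2

* deep supervision: L_total = L(final, G) + sum_k L(psi_k, G_k), where each
  auxiliary ground truth G_k is the nearest-neighbour downsampling of G so
  the discrete class labels are preserved at every scale.

* evaluation: Dice, precision, recall and false-positive rate per class.

Arrays are plain numpy ``(C, H, W)`` tensors: probability maps sum to one
over the class axis, ground truth is one-hot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "MV_CLASS_LEGEND",
    "LossConfig",
    "one_hot",
    "generalized_dice_loss",
    "focal_loss",
    "combined_loss",
    "downsample_gt",
    "deep_supervision_loss",
    "dice_score",
    "class_metrics",
    "ClassMetrics",
]

#: The 11-channel legend: six leaflet scallops, chordae, annulus, the two
#: papillary muscles and background.
MV_CLASS_LEGEND: tuple[str, ...] = (
    "background",
    "a_1",
    "a_2",
    "a_3",
    "p_1",
    "p_2",
    "p_3",
    "chordae",
    "annulus",
    "papillary_anterior",
    "papillary_posterior",
)


@dataclass(frozen=True)
class LossConfig:
    """Numerical knobs of the objectives.

    epsilon stabilizes the Dice ratio; prob_clip bounds probabilities away
    from 0 before the focal log; gamma is the focal focusing parameter.
    deep_supervision_scales are the downsampling factors of the auxiliary
    decoder outputs (a 256 input with factors 2/4/8 gives the 128/64/32
    pyramid).
    """

    epsilon: float = 1e-6
    gamma: float = 2.0
    prob_clip: float = 1e-7
    deep_supervision_scales: tuple[int, ...] = (2, 4, 8)

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")


_DEFAULT_CFG = LossConfig()


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Convert an integer label map (H, W) to a one-hot (C, H, W) mask."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("label values outside [0, n_classes)")
    out = np.zeros((n_classes, *labels.shape), dtype=np.uint8)
    np.put_along_axis(out, labels[None], 1, axis=0)
    return out


def _check_pair(p: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    g = np.asarray(g, dtype=float)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: prediction {p.shape} vs ground truth {g.shape}")
    if p.ndim < 2:
        raise ValueError("expected (C, ...) arrays")
    return p, g


def generalized_dice_loss(
    p: np.ndarray, g: np.ndarray, cfg: LossConfig = _DEFAULT_CFG
) -> float:
    """Generalized Dice loss averaged over classes present in the image."""
    p, g = _check_pair(p, g)
    C = p.shape[0]
    pf = p.reshape(C, -1)
    gf = g.reshape(C, -1)
    present = gf.sum(axis=1) > 0
    if not np.any(present):
        raise ValueError("degenerate target: no class present in ground truth")
    eps = cfg.epsilon
    num = 2.0 * (pf * gf).sum(axis=1) + eps
    den = pf.sum(axis=1) + gf.sum(axis=1) + eps
    return float(1.0 - (num[present] / den[present]).mean())


def focal_loss(p: np.ndarray, g: np.ndarray, cfg: LossConfig = _DEFAULT_CFG) -> float:
    """Focal loss over all classes; reduces to mean cross-entropy at gamma=0."""
    p, g = _check_pair(p, g)
    C = p.shape[0]
    n_pixels = p.size // C
    pc = np.clip(p, cfg.prob_clip, 1.0)
    term = (1.0 - pc) ** cfg.gamma * g * np.log(pc)
    return float(-term.sum() / n_pixels)


def combined_loss(p: np.ndarray, g: np.ndarray, cfg: LossConfig = _DEFAULT_CFG) -> float:
    """Simple average of the generalized Dice and focal losses."""
    return (generalized_dice_loss(p, g, cfg) + focal_loss(p, g, cfg)) / 2.0


def downsample_gt(
    g: np.ndarray,
    factor: int | None = None,
    out_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Nearest-neighbour downsampling of a one-hot mask.

    Each output pixel takes the label of the source pixel at
    ``floor(output_index * source_size / output_size)``, so the result stays
    strictly one-hot at every scale.
    """
    g = np.asarray(g)
    if g.ndim != 3:
        raise ValueError("expected a (C, H, W) one-hot mask")
    C, H, W = g.shape
    if out_shape is None:
        if factor is None or factor <= 0:
            raise ValueError("need a positive factor or an explicit out_shape")
        if H % factor or W % factor:
            raise ValueError(f"factor {factor} does not divide {(H, W)}")
        out_shape = (H // factor, W // factor)
    Hk, Wk = out_shape
    rows = (np.arange(Hk) * H // Hk).astype(int)
    cols = (np.arange(Wk) * W // Wk).astype(int)
    return g[:, rows[:, None], cols[None, :]]


def deep_supervision_loss(
    final: np.ndarray,
    intermediates: Sequence[np.ndarray],
    g: np.ndarray,
    cfg: LossConfig = _DEFAULT_CFG,
) -> float:
    """Combined loss at the output scale plus every auxiliary scale.

    Each intermediate prediction is compared against the nearest-neighbour
    downsampled ground truth of matching size; terms are summed unweighted.
    """
    total = combined_loss(final, g, cfg)
    for psi in intermediates:
        psi = np.asarray(psi)
        if psi.ndim != 3 or psi.shape[0] != g.shape[0]:
            raise ValueError("intermediate output has incompatible class axis")
        gk = downsample_gt(g, out_shape=psi.shape[1:])
        total += combined_loss(psi, gk, cfg)
    return float(total)


def dice_score(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A&B| / (|A| + |B|); two empty masks score 1."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


class ClassMetrics(NamedTuple):
    dice: float
    precision: float
    recall: float
    fpr: float
    undefined: frozenset


def class_metrics(pred: np.ndarray, gt: np.ndarray, class_id: int) -> ClassMetrics:
    """Per-class Dice, precision, recall and false-positive rate.

    Undefined ratios (empty denominator) are reported as 0 and recorded in
    ``undefined`` so aggregation code can treat them explicitly.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError("label map shapes differ")
    if class_id not in np.union1d(np.unique(pred), np.unique(gt)) and class_id != 0:
        warnings.warn(f"class {class_id} absent from both maps", stacklevel=2)
    a = pred == class_id
    b = gt == class_id
    tp = int(np.logical_and(a, b).sum())
    fp = int(np.logical_and(a, ~b).sum())
    fn = int(np.logical_and(~a, b).sum())
    tn = int(np.logical_and(~a, ~b).sum())
    undefined: set[str] = set()
    dice = 1.0 if (2 * tp + fp + fn) == 0 else 2.0 * tp / (2 * tp + fp + fn)
    precision = recall = fpr = 0.0
    if tp + fp:
        precision = tp / (tp + fp)
    else:
        undefined.add("precision")
    if tp + fn:
        recall = tp / (tp + fn)
    else:
        undefined.add("recall")
    if fp + tn:
        fpr = fp / (fp + tn)
    else:
        undefined.add("fpr")
    return ClassMetrics(float(dice), float(precision), float(recall), float(fpr), frozenset(undefined))
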