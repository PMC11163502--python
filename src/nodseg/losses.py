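"""Segmentation metrics, training losses, and the fold-level t-test.

Metrics operate on binary masks; losses operate on probability maps.  The
compound training objective mixes soft Dice loss and weighted binary
cross-entropy:

    L = a * L_dice + (1 - a) * L_bce,        a in [0, 1]

with L_dice = 1 - 2|P.G| / (|P| + |G|) (soft, epsilon-smoothed) and L_bce
the voxel-mean negative log-likelihood with positive-class weight w_p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .nn import autodiff as ad

__all__ = [
    "LossConfig", "ConfusionCounts", "StatsResult", "confusion", "dsc", "oe",
    "dice_loss", "bce_loss", "bcedice_loss", "bcedice_loss_graph",
    "t_test_compare",
]

DICE_EPS = 1e-5
PROB_CLIP = 1e-7


@dataclass(frozen=True)
class LossConfig:
    """Mixing weight `a` of the Dice term and BCE positive-class weight."""

    a: float = 0.5
    wp: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"mixing weight a must lie in [0,1], got {self.a}")
        if self.wp <= 0:
            raise ValueError(f"positive-class weight wp must be > 0, got {self.wp}")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int


@dataclass(frozen=True)
class StatsResult:
    t: float
    p: float
    df: float
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int


def _check_pair(pred, gt):
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    return pred.astype(bool), gt.astype(bool)


def confusion(pred_mask, gt_mask) -> ConfusionCounts:
    p, g = _check_pair(pred_mask, gt_mask)
    return ConfusionCounts(int(np.sum(p & g)), int(np.sum(p & ~g)),
                           int(np.sum(~p & g)))


def dsc(pred_mask, gt_mask) -> float:
    """Dice similarity 2TP/(2TP+FP+FN); 1.0 when both masks are empty."""
    c = confusion(pred_mask, gt_mask)
    denom = 2 * c.TP + c.FP + c.FN
    return 1.0 if denom == 0 else 2.0 * c.TP / denom


def oe(pred_mask, gt_mask) -> float:
    """Overlapping error 1 - TP/(TP+FP+FN); 0.0 when both masks are empty."""
    c = confusion(pred_mask, gt_mask)
    denom = c.TP + c.FP + c.FN
    return 0.0 if denom == 0 else 1.0 - c.TP / denom


def _check_probs(pred):
    pred = np.asarray(pred, dtype=np.float64)
    if pred.min() < 0.0 or pred.max() > 1.0:
        raise ValueError("predicted probabilities must lie in [0, 1]")
    return pred


def dice_loss(pred_probs, gt_mask, eps: float = DICE_EPS) -> float:
    """1 minus the epsilon-smoothed soft Dice overlap."""
    p = _check_probs(pred_probs)
    g = np.asarray(gt_mask, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shapes differ: {p.shape} vs {g.shape}")
    inter = float((p * g).sum())
    return 1.0 - (2.0 * inter + eps) / (p.sum() + g.sum() + eps)


def bce_loss(pred_probs, gt_mask, cfg: LossConfig = LossConfig()) -> float:
    """Voxel-mean weighted binary cross-entropy."""
    p = np.clip(_check_probs(pred_probs), PROB_CLIP, 1.0 - PROB_CLIP)
    g = np.asarray(gt_mask, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shapes differ: {p.shape} vs {g.shape}")
    return float(-np.mean(cfg.wp * g * np.log(p) + (1.0 - g) * np.log1p(-p)))


def bcedice_loss(pred_probs, gt_mask, cfg: LossConfig = LossConfig()) -> float:
    """Convex combination a*Dice + (1-a)*BCE of the two losses."""
    return (cfg.a * dice_loss(pred_probs, gt_mask)
            + (1.0 - cfg.a) * bce_loss(pred_probs, gt_mask, cfg))


def bcedice_loss_graph(pred: "ad.Tensor", gt_mask, cfg: LossConfig = LossConfig()):
    """Differentiable BCEDice on an autodiff probability tensor (training path)."""
    g = ad.Tensor(np.asarray(gt_mask, dtype=np.float32))
    p = ad.clip(pred, PROB_CLIP, 1.0 - PROB_CLIP)
    inter = ad.sum_all(ad.mul(p, g))
    soft = (2.0 * inter + DICE_EPS) / (ad.sum_all(p) + ad.sum_all(g) + DICE_EPS)
    dice = 1.0 - soft
    ll = ad.mul(g, ad.log(p)) * cfg.wp + ad.mul(1.0 - g, ad.log(1.0 - p))
    bce = 0.0 - ad.mean_all(ll)
    return dice * cfg.a + bce * (1.0 - cfg.a)


def t_test_compare(folds_a, folds_b) -> StatsResult:
    """Two-sided pooled-variance two-sample t-test on per-fold mean scores."""
    a = np.asarray(folds_a, dtype=np.float64)
    b = np.asarray(folds_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two folds per group for a t-test")
    res = stats.ttest_ind(a, b, equal_var=True)
    return StatsResult(
        t=float(res.statistic), p=float(res.pvalue), df=float(a.size + b.size - 2),
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=int(a.size),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=int(b.size))
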