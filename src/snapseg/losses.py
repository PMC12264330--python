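"""Training losses: multi-class Dice, weighted cross-entropy, and their sum.

All losses act on arrays whose last axis is the 3-class channel axis
(lumen, wall, background).  Predictions are simplex-valued probability maps;
targets may be hard one-hot masks or soft surrogate labels.  Alongside each
loss value the analytic gradient with respect to the predicted probabilities
is available, for use by the training engine's hand-derived backprop.
"""

from __future__ import annotations

import numpy as np

#: smoothing added to numerator and denominator of the Dice ratio, defining
#: the empty-empty case as a perfect match (loss 0)
DICE_SMOOTH = 1e-5

#: probabilities are clamped to this floor inside logarithms
LOG_EPS = 1e-7

#: class weights (lumen, wall, background) of the adversarial-branch CE loss
DEFAULT_CLASS_WEIGHTS = (2.0, 2.0, 1.0)


def binary_dice_loss(x: np.ndarray, x_hat: np.ndarray) -> float:
    """``1 - 2*sum(x*x_hat) / (sum(x) + sum(x_hat))`` with smoothing."""
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    num = 2.0 * float((x * x_hat).sum()) + DICE_SMOOTH
    den = float(x.sum()) + float(x_hat.sum()) + DICE_SMOOTH
    return 1.0 - num / den


def multiclass_dice_loss(p: np.ndarray, y: np.ndarray) -> float:
    """Mean of the binary Dice losses of the lumen and vessel-wall channels.

    Background is excluded: the loss targets the two structures of interest and
    their Dice already reflects background errors implicitly.
    """
    p, y = _check_pair(p, y)
    return 0.5 * (binary_dice_loss(y[..., 0], p[..., 0])
                  + binary_dice_loss(y[..., 1], p[..., 1]))


def multiclass_dice_grad(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    """d(multiclass_dice_loss)/dp, same shape as ``p`` (background channel 0)."""
    p, y = _check_pair(p, y)
    grad = np.zeros_like(p)
    for c in (0, 1):
        num = 2.0 * (p[..., c] * y[..., c]).sum() + DICE_SMOOTH
        den = p[..., c].sum() + y[..., c].sum() + DICE_SMOOTH
        # d/dp_k [1 - num/den] = -(2*y_k*den - num) / den^2, averaged over 2 classes
        grad[..., c] = -0.5 * (2.0 * y[..., c] * den - num) / den ** 2
    return grad


def weighted_ce_loss(p_adv: np.ndarray, y_target: np.ndarray,
                     w: tuple[float, float, float] = DEFAULT_CLASS_WEIGHTS) -> float:
    """Class-weighted soft-target cross-entropy, averaged over voxels.

    ``mean_k sum_j -w[j] * y[k,j] * log p[k,j]`` — the per-voxel weighted CE is
    summed over channels and averaged over all voxels (not over the weight
    mass), so the background weight of 1 still dilutes foreground terms.
    """
    p_adv, y_target = _check_pair(p_adv, y_target)
    w_arr = np.asarray(w, dtype=np.float64)
    logp = np.log(np.clip(p_adv, LOG_EPS, 1.0))
    per_voxel = -(w_arr * y_target * logp).sum(axis=-1)
    return float(per_voxel.mean())


def weighted_ce_grad(p_adv: np.ndarray, y_target: np.ndarray,
                     w: tuple[float, float, float] = DEFAULT_CLASS_WEIGHTS) -> np.ndarray:
    """d(weighted_ce_loss)/dp, honouring the log clamp (zero grad when clamped)."""
    p_adv, y_target = _check_pair(p_adv, y_target)
    w_arr = np.asarray(w, dtype=np.float64)
    n_vox = int(np.prod(p_adv.shape[:-1]))
    grad = -(w_arr * y_target) / np.clip(p_adv, LOG_EPS, 1.0) / n_vox
    grad[p_adv < LOG_EPS] = 0.0
    return grad


def total_finetune_loss(p_stu: np.ndarray, y: np.ndarray,
                        p_adv: np.ndarray, y_target: np.ndarray,
                        w: tuple[float, float, float] = DEFAULT_CLASS_WEIGHTS) -> float:
    """Joint fine-tuning loss: supervised Dice branch + adversarial CE branch."""
    return multiclass_dice_loss(p_stu, y) + weighted_ce_loss(p_adv, y_target, w)


def _check_pair(p: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    if p.shape[-1] != 3:
        raise ValueError("last axis must hold the 3 class channels")
    return p, y
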