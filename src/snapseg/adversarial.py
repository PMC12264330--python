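"""FGSM input perturbations for the adversarial training branch.

The fast gradient sign method approximates the worst-case bounded perturbation
of an input image in one step: ``r_adv = epsilon * sign(grad_i CE(p(i), y~))``
where the gradient is taken with respect to the image and CE is the plain
(unweighted) voxel-mean cross-entropy against the current fitting target.
Intensities are in normalized units, so ``epsilon`` is measured in standard
deviations; the perturbed image is used as-is, without clipping or
re-normalization.
"""

from __future__ import annotations

import numpy as np

from .losses import LOG_EPS


def ce_grad_wrt_probs(p: np.ndarray, y_target: np.ndarray) -> np.ndarray:
    """Gradient of unweighted voxel-mean soft-target CE w.r.t. probabilities."""
    p = np.asarray(p, dtype=np.float64)
    y_target = np.asarray(y_target, dtype=np.float64)
    n_vox = int(np.prod(p.shape[:-1]))
    grad = -y_target / np.clip(p, LOG_EPS, 1.0) / n_vox
    grad[p < LOG_EPS] = 0.0
    return grad


def unweighted_ce(p: np.ndarray, y_target: np.ndarray) -> float:
    """Plain voxel-mean soft-target cross-entropy (the FGSM attack loss)."""
    logp = np.log(np.clip(np.asarray(p, dtype=np.float64), LOG_EPS, 1.0))
    return float(-(np.asarray(y_target) * logp).sum(axis=-1).mean())


def fgsm_perturbation(model, window: np.ndarray, y_target: np.ndarray,
                      epsilon: float) -> np.ndarray:
    """Single-step sign attack on an image window.

    Runs one forward/backward pass of ``model`` to obtain the gradient of the
    unweighted CE loss with respect to the input, and returns
    ``epsilon * sign(gradient)``; entries are exactly in {-epsilon, 0,
    +epsilon} (``sign(0) = 0``).  Model parameters are left untouched: any
    parameter gradients accumulated during the pass are cleared before return.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    probs, tape = model.forward_window(window, need_cache=True)
    if probs.shape != np.asarray(y_target).shape:
        raise ValueError(f"target shape {np.asarray(y_target).shape} does not "
                         f"match prediction {probs.shape}")
    grad_in = model.backward_window(ce_grad_wrt_probs(probs, y_target), tape)
    model.zero_grad()  # the attack must not contribute to the training step
    return (epsilon * np.sign(grad_in)).astype(np.float32)


def perturb_image(window: np.ndarray, r_adv: np.ndarray) -> np.ndarray:
    """Elementwise ``window + r_adv``; no clipping or re-normalization."""
    window = np.asarray(window)
    r_adv = np.asarray(r_adv)
    if window.shape != r_adv.shape:
        raise ValueError(f"shape mismatch: {window.shape} vs {r_adv.shape}")
    return (window + r_adv).astype(window.dtype)
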