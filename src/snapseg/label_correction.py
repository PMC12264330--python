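"""Surrogate ground truth for misaligned labels.

For a volume whose manual segmentation is flagged as misaligned, the fitting
target of the adversarial branch is not the manual label itself but a convex
combination of it with a selectively hardened ensemble of the student and
mean-teacher predictions: voxels where both models confidently agree are
snapped to one-hot, everywhere else the two predictions are averaged, and the
result is blended with the manual label with weight ``beta`` on the label.

The surrogate is a *target*: it is built from detached prediction arrays and
no gradient ever flows through it.
"""

from __future__ import annotations

import numpy as np

from .volume_io import LabelMask, Quality


def selective_harden(p_tea: np.ndarray, p_stu: np.ndarray, tau: float,
                     enabled: bool = True) -> np.ndarray:
    """Selectively hardened ensemble of teacher and student probability maps.

    A voxel is hardened to the one-hot vector of class ``u`` when the teacher
    and student argmax classes coincide (``u == v``) and both of their maximum
    probabilities strictly exceed ``tau``; otherwise the voxel keeps the
    elementwise mean of the two predictions.  Argmax ties count as
    disagreement.  With ``enabled=False`` hardening is skipped entirely and
    the plain mean is returned (the ablation without selective hardening);
    ``tau=1`` likewise hardens nothing, since probabilities cannot exceed 1.
    """
    p_tea = np.asarray(p_tea, dtype=np.float64)
    p_stu = np.asarray(p_stu, dtype=np.float64)
    if p_tea.shape != p_stu.shape:
        raise ValueError(f"shape mismatch: {p_tea.shape} vs {p_stu.shape}")
    mean = 0.5 * (p_tea + p_stu)
    if not enabled:
        return mean
    u = p_tea.argmax(axis=-1)
    v = p_stu.argmax(axis=-1)
    max_tea = p_tea.max(axis=-1)
    max_stu = p_stu.max(axis=-1)
    # an argmax tie (two channels sharing the max) is treated as disagreement
    tie_tea = (p_tea == max_tea[..., None]).sum(axis=-1) > 1
    tie_stu = (p_stu == max_stu[..., None]).sum(axis=-1) > 1
    harden = (u == v) & (max_tea > tau) & (max_stu > tau) & ~tie_tea & ~tie_stu
    out = mean
    onehot = np.eye(p_tea.shape[-1])[u[harden]]
    out[harden] = onehot
    return out


def surrogate_label(y: np.ndarray | LabelMask, p_sel: np.ndarray,
                    beta: float) -> np.ndarray:
    """Convex combination ``beta * y + (1 - beta) * p_sel`` of manual label
    and hardened pseudo-label; simplex-valued whenever both inputs are."""
    if isinstance(y, LabelMask):
        y = y.onehot
    y = np.asarray(y, dtype=np.float64)
    p_sel = np.asarray(p_sel, dtype=np.float64)
    if y.shape != p_sel.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {p_sel.shape}")
    if not (0.0 <= beta <= 1.0):
        raise ValueError("beta must be in [0, 1]")
    return beta * y + (1.0 - beta) * p_sel


def fitting_target(label: LabelMask, p_tea: np.ndarray, p_stu: np.ndarray,
                   tau: float = 0.99, beta: float = 0.5,
                   selective: bool = True) -> np.ndarray:
    """Adversarial-branch target: the manual label for well-registered
    volumes, the surrogate label for misaligned ones."""
    if label.quality == Quality.WELL_REGISTERED:
        return label.onehot.astype(np.float64)
    p_sel = selective_harden(p_tea, p_stu, tau, enabled=selective)
    return surrogate_label(label, p_sel, beta)
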