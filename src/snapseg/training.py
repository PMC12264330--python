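"""Two-stage training: Dice warm-up on clean labels, adversarial fine-tuning on all.

Stage 1 (warm-up) trains the student on well-registered volumes only, driven by
the multi-class Dice loss; the teacher tracks it by EMA without ever seeing a
gradient.  Stage 2 (fine-tuning) adds the adversarial branch: per window the
student predicts the augmented image (Path 1), the teacher predicts it without
gradients (Path 3), the two predictions build the fitting target for misaligned
labels, an FGSM perturbation against that target produces the adversarial image,
and the student is supervised by Dice (Path 1) plus weighted CE on the perturbed
prediction (Path 2).

One augmentation draw applies the same geometric transform to every slice of a
window and to its label, preserving longitudinal continuity.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import losses
from .adversarial import ce_grad_wrt_probs, perturb_image
from .backbone import ModelPair, TrainingConfig, build_model
from .inference import predict_volume
from .label_correction import fitting_target
from .metrics import evaluate_volume
from .volume_io import (
    ImageVolume,
    LabelMask,
    Quality,
    SliceWindow,
    WINDOW_LEN,
    read_manifest,
    read_volume,
)


@dataclass
class AugmentationPolicy:
    """Slice-consistent augmentation: one draw per window, applied to all slices."""

    rotation_quarters: tuple[int, ...] = (0, 1, 2, 3)
    contrast_range: tuple[float, float] = (0.8, 1.2)
    gamma_range: tuple[float, float] = (0.8, 1.2)
    hflip_prob: float = 0.5
    enabled: bool = True


def sample_training_window(vol: ImageVolume, label: LabelMask,
                           rng: np.random.Generator) -> SliceWindow:
    """Crop a uniformly random run of 8 consecutive slices (image and label)."""
    n = vol.n_slices
    if n < WINDOW_LEN:
        raise ValueError(f"volume has {n} < {WINDOW_LEN} slices")
    start = int(rng.integers(0, n - WINDOW_LEN + 1))
    return SliceWindow(start, vol.data[start:start + WINDOW_LEN],
                       label.onehot[start:start + WINDOW_LEN], label.quality)


def _apply_gamma(img: np.ndarray, gamma: float) -> np.ndarray:
    """Per-channel gamma correction on min-max rescaled intensities."""
    lo = img.min(axis=(0, 1, 2), keepdims=True)
    hi = img.max(axis=(0, 1, 2), keepdims=True)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    unit = (img - lo) / span
    return (unit ** gamma) * span + lo


def augment(window: SliceWindow, policy: AugmentationPolicy,
            rng: np.random.Generator) -> SliceWindow:
    """Rotation -> horizontal flip -> contrast -> gamma, identical per slice.

    Geometric transforms hit image and label alike; intensity transforms hit
    the image channels only.  90/270-degree rotations require square slices.
    """
    img = window.data
    lab = window.label
    if not policy.enabled:
        return window
    k = int(rng.choice(policy.rotation_quarters))
    do_flip = rng.random() < policy.hflip_prob
    contrast = rng.uniform(*policy.contrast_range)
    gamma = rng.uniform(*policy.gamma_range)

    if k % 2 == 1 and img.shape[1] != img.shape[2]:
        raise ValueError("90/270-degree rotation needs square in-plane dims")
    if k:
        img = np.rot90(img, k, axes=(1, 2))
        lab = np.rot90(lab, k, axes=(1, 2)) if lab is not None else None
    if do_flip:
        img = img[:, :, ::-1]
        lab = lab[:, :, ::-1] if lab is not None else None
    img = np.ascontiguousarray(img, dtype=np.float32) * np.float32(contrast)
    img = _apply_gamma(img, gamma).astype(np.float32)
    lab = np.ascontiguousarray(lab) if lab is not None else None
    return SliceWindow(window.start_index, img, lab, window.quality)


# ---------------------------------------------------------------------------
# Optimization steps
# ---------------------------------------------------------------------------

def warmup_step(pair: ModelPair, optimizer, batch: list[SliceWindow],
                cfg: TrainingConfig) -> float:
    """One Dice-loss step on well-registered windows; teacher EMA follows."""
    for win in batch:
        if win.quality != Quality.WELL_REGISTERED:
            raise ValueError("warm-up batch must contain only well-registered labels")
    total = 0.0
    inv_b = 1.0 / len(batch)
    for win in batch:
        y = win.label.astype(np.float64)
        p_stu, tape = pair.student.forward_window(win.data)
        total += losses.multiclass_dice_loss(p_stu, y)
        pair.student.backward_window(losses.multiclass_dice_grad(p_stu, y) * inv_b,
                                     tape)
    optimizer.step()
    optimizer.zero_grad()
    pair.ema_step(cfg.alpha)
    return total * inv_b


def finetune_step(pair: ModelPair, optimizer, batch: list[SliceWindow],
                  cfg: TrainingConfig) -> tuple[float, float]:
    """One joint Dice + adversarial-CE step; returns (dice_part, ce_part).

    The fitting target is built from detached prediction arrays, so no
    gradient flows through the teacher or the surrogate.  The FGSM input
    gradient is computed against the unweighted CE before any parameter
    gradient is accumulated for the actual update.
    """
    dice_total, ce_total = 0.0, 0.0
    inv_b = 1.0 / len(batch)
    for win in batch:
        y = win.label.astype(np.float64)
        p_stu, tape_clean = pair.student.forward_window(win.data)

        if cfg.adversarial:
            if cfg.surrogate and win.quality == Quality.MISALIGNED:
                p_tea = pair.teacher.predict_window(win.data).astype(np.float64)
                label = LabelMask(win.label, Quality.MISALIGNED)
                y_tilde = fitting_target(label, p_tea, p_stu.astype(np.float64),
                                         cfg.tau, cfg.beta, cfg.selective_hardening)
            else:
                y_tilde = y
            # FGSM: input gradient of the unweighted CE, before the real step
            grad_in = pair.student.backward_window(
                ce_grad_wrt_probs(p_stu, y_tilde), tape_clean)
            pair.student.zero_grad()
            r_adv = (cfg.epsilon * np.sign(grad_in)).astype(np.float32)
            p_adv, tape_adv = pair.student.forward_window(
                perturb_image(win.data, r_adv))
            ce_total += losses.weighted_ce_loss(p_adv, y_tilde, cfg.class_weights)
            pair.student.backward_window(
                losses.weighted_ce_grad(p_adv, y_tilde, cfg.class_weights) * inv_b,
                tape_adv)

        dice_total += losses.multiclass_dice_loss(p_stu, y)
        pair.student.backward_window(losses.multiclass_dice_grad(p_stu, y) * inv_b,
                                     tape_clean)
    optimizer.step()
    optimizer.zero_grad()
    pair.ema_step(cfg.alpha)
    return dice_total * inv_b, ce_total * inv_b


# ---------------------------------------------------------------------------
# Dataset containers and the full schedule
# ---------------------------------------------------------------------------

@dataclass
class TrainingResult:
    pair: ModelPair                     # best checkpoint by validation DSCavg
    final_pair: ModelPair               # state at the last iteration
    log: pd.DataFrame
    best_val_dsc_avg: float


def load_split(manifest_path, split: str) -> list[tuple[ImageVolume, LabelMask]]:
    """Load all volumes of one manifest split into memory."""
    df = read_manifest(manifest_path)
    out = []
    for _, row in df[df["split"] == split].iterrows():
        vol, label = read_volume(row["image_path"], row["label_path"],
                                 row["quality"], row["volume_id"])
        out.append((vol, label))
    return out


def _validate(pair: ModelPair, val_set, cfg: TrainingConfig) -> float:
    scores = []
    for vol, label in val_set:
        res = predict_volume(pair, vol, use_teacher=cfg.teacher_fusion)
        rec = evaluate_volume(res.class_map, label, vol.voxel_spacing, vol.volume_id)
        scores.append(rec.dsc_avg)
    return float(np.mean(scores))


def run_two_stage(train_set: list[tuple[ImageVolume, LabelMask]],
                  val_set: list[tuple[ImageVolume, LabelMask]],
                  cfg: TrainingConfig,
                  policy: AugmentationPolicy | None = None,
                  exclude_misaligned: bool = False) -> TrainingResult:
    """Run warm-up then fine-tuning and return the best validated model.

    Warm-up draws batches from the well-registered training volumes only;
    fine-tuning draws from all of them (or again only the clean ones when
    ``exclude_misaligned`` is set — the data-exclusion control experiment).
    Validation DSCavg is computed every ``cfg.val_interval`` fine-tuning
    iterations with the same fused inference used at test time, and the
    checkpoint with the highest value is returned.
    """
    cfg.validate()
    if not train_set or not val_set:
        raise ValueError("empty training or validation split")
    policy = policy or AugmentationPolicy()
    clean = [tv for tv in train_set if tv[1].quality == Quality.WELL_REGISTERED]
    if not clean:
        raise ValueError("warm-up needs at least one well-registered volume")
    finetune_pool = clean if exclude_misaligned else list(train_set)

    ss = np.random.SeedSequence(cfg.seed).spawn(3)
    init_seed = int(ss[0].generate_state(1)[0] % (2 ** 31))
    rng_data = np.random.default_rng(ss[1])
    rng_aug = np.random.default_rng(ss[2])

    from .nn import Adam  # local import to keep module load light

    pair = ModelPair(build_model(cfg.depth, cfg.base_channels, seed=init_seed))
    optimizer = Adam(pair.student.parameters(), lr=cfg.lr,
                     weight_decay=cfg.weight_decay)

    records = []
    best_state = None
    best_val = -np.inf

    def draw_batch(pool):
        idx = rng_data.integers(0, len(pool), size=cfg.batch_size)
        batch = []
        for i in idx:
            vol, label = pool[i]
            win = sample_training_window(vol, label, rng_data)
            batch.append(augment(win, policy, rng_aug))
        return batch

    total_iters = cfg.iters_warmup + cfg.iters_finetune
    for it in range(total_iters):
        optimizer.lr = cfg.learning_rate(it)
        if it < cfg.iters_warmup:
            loss = warmup_step(pair, optimizer, draw_batch(clean), cfg)
            records.append({"iter": it, "stage": "warmup", "lr": optimizer.lr,
                            "dice_part": loss, "ce_part": 0.0,
                            "val_dsc_avg": np.nan})
        else:
            dice_part, ce_part = finetune_step(pair, optimizer,
                                               draw_batch(finetune_pool), cfg)
            ft_iter = it - cfg.iters_warmup
            val = np.nan
            if (ft_iter + 1) % cfg.val_interval == 0 or it == total_iters - 1:
                val = _validate(pair, val_set, cfg)
                if val > best_val:
                    best_val = val
                    best_state = (pair.student.state_dict(),
                                  pair.teacher.state_dict())
            records.append({"iter": it, "stage": "finetune", "lr": optimizer.lr,
                            "dice_part": dice_part, "ce_part": ce_part,
                            "val_dsc_avg": val})

    final_pair = copy.deepcopy(pair)
    if best_state is not None:
        pair.student.load_state_dict(best_state[0])
        pair.teacher.load_state_dict(best_state[1])
    else:  # no validation ran (tiny schedules): keep the final state
        best_val = _validate(pair, val_set, cfg)
    return TrainingResult(pair, final_pair, pd.DataFrame(records), float(best_val))


#: Ablation ladder: which components each named variant enables.
ABLATION_VARIANTS = {
    "baseline": dict(adversarial=False, teacher_fusion=False,
                     surrogate=False, selective_hardening=False),
    "model1": dict(adversarial=True, teacher_fusion=False,
                   surrogate=False, selective_hardening=False),
    "model2": dict(adversarial=True, teacher_fusion=True,
                   surrogate=False, selective_hardening=False),
    "model3": dict(adversarial=True, teacher_fusion=True,
                   surrogate=True, selective_hardening=False),
    "full": dict(adversarial=True, teacher_fusion=True,
                 surrogate=True, selective_hardening=True),
}


def ablation_config(name: str, base: TrainingConfig) -> TrainingConfig:
    """Copy ``base`` with one ablation variant's switches applied."""
    if name not in ABLATION_VARIANTS:
        raise ValueError(f"unknown variant {name!r}; options: {sorted(ABLATION_VARIANTS)}")
    cfg = copy.deepcopy(base)
    for k, v in ABLATION_VARIANTS[name].items():
        setattr(cfg, k, v)
    return cfg
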