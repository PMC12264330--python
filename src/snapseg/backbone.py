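"""Student/teacher segmentation backbone: a configurable 3D U-Net.

The network maps an 8-slice, 7-channel window to a 3-class probability map.
Each resolution level applies two conv–GroupNorm–ReLU blocks; levels are
linked by 2x down/upsampling with skip concatenation, and the head is a 1x1x1
convolution followed by a channel softmax.  Depth and width are configurable:
the clinical-scale default is depth 4 / 16 base channels on 8x224x224 windows,
while tests run a desk-scale depth 2 / 8 channels on small windows.

The teacher network is never trained by gradient descent; it tracks the
student as an exponential moving average (EMA) of its parameters.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn


@dataclass
class TrainingConfig:
    """Hyperparameters of the two-stage framework.

    ``alpha`` is the EMA smoothing coefficient, ``beta`` the manual-label
    weight of the surrogate label, ``tau`` the selective-hardening confidence
    threshold and ``epsilon`` the FGSM strength in units of the normalized
    (unit-variance) intensities.  Defaults follow the tuned operating point
    alpha=0.99, beta=0.5, tau=0.99, epsilon=4.
    """

    alpha: float = 0.99
    beta: float = 0.5
    tau: float = 0.99
    epsilon: float = 4.0
    class_weights: tuple[float, float, float] = (2.0, 2.0, 1.0)
    iters_warmup: int = 4000
    iters_finetune: int = 4000
    batch_size: int = 4
    lr: float = 2e-4
    lr_decay_start: int = 4000
    lr_decay_every: int = 500
    lr_decay_factor: float = 0.9
    weight_decay: float = 5e-4
    val_interval: int = 100
    depth: int = 4
    base_channels: int = 16
    seed: int = 0
    # ablation switches (all on = full framework)
    adversarial: bool = True
    teacher_fusion: bool = True
    surrogate: bool = True
    selective_hardening: bool = True

    def validate(self) -> None:
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError("alpha must be in [0, 1)")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must be in [0, 1]")
        if not (1.0 / 3.0 <= self.tau <= 1.0):
            raise ValueError("tau must be in [1/3, 1]")
        for name in ("iters_warmup", "iters_finetune", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def learning_rate(self, iteration: int) -> float:
        """Schedule: fixed lr before ``lr_decay_start``, then x factor every
        ``lr_decay_every`` iterations (first decay one interval after start)."""
        if iteration < self.lr_decay_start:
            return self.lr
        n = (iteration - self.lr_decay_start) // self.lr_decay_every
        return self.lr * self.lr_decay_factor ** n


class _Block:
    """Two conv–GroupNorm–ReLU units."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.layers = [
            nn.Conv3d(in_ch, out_ch, rng), nn.GroupNorm(out_ch), nn.ReLU(),
            nn.Conv3d(out_ch, out_ch, rng), nn.GroupNorm(out_ch), nn.ReLU(),
        ]

    def forward(self, x, need_cache=True):
        caches = []
        for lay in self.layers:
            x, c = lay.forward(x, need_cache)
            caches.append(c)
        return x, caches

    def backward(self, gy, caches):
        for lay, c in zip(reversed(self.layers), reversed(caches)):
            gy = lay.backward(gy, c)
        return gy

    def params(self):
        out = []
        for i, lay in enumerate(self.layers):
            out += [(f"{i}.{n}", p, g) for n, p, g in lay.params()]
        return out


class UNet3D:
    """Encoder–decoder segmenter; activations are channels-first (C, D, H, W)."""

    def __init__(self, depth: int = 2, base_channels: int = 8,
                 in_channels: int = 7, n_classes: int = 3, seed: int = 0):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        if base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        self.config = dict(depth=depth, base_channels=base_channels,
                           in_channels=in_channels, n_classes=n_classes, seed=seed)
        rng = np.random.default_rng(seed)
        chans = [base_channels * 2 ** i for i in range(depth)]
        self.enc = []
        prev = in_channels
        for c in chans[:-1]:
            self.enc.append(_Block(prev, c, rng))
            prev = c
        self.bottleneck = _Block(prev, chans[-1], rng)
        self.pool = nn.AvgPool3d()
        self.up = nn.UpsampleNearest()
        self.dec = []
        up_ch = chans[-1]
        for c in reversed(chans[:-1]):
            self.dec.append(_Block(up_ch + c, c, rng))
            up_ch = c
        self.head = nn.Conv3d(up_ch, n_classes, rng, k=1)
        self.depth = depth

    # -- parameter plumbing --------------------------------------------------
    def parameters(self):
        out = []
        for i, b in enumerate(self.enc):
            out += [(f"enc{i}.{n}", p, g) for n, p, g in b.params()]
        out += [(f"bottom.{n}", p, g) for n, p, g in self.bottleneck.params()]
        for i, b in enumerate(self.dec):
            out += [(f"dec{i}.{n}", p, g) for n, p, g in b.params()]
        out += [(f"head.{n}", p, g) for n, p, g in self.head.params()]
        return out

    def zero_grad(self):
        for _, _, g in self.parameters():
            g[...] = 0.0

    def state_arrays(self) -> list[np.ndarray]:
        return [p for _, p, _ in self.parameters()]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: p.copy() for n, p, _ in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n, p, _ in self.parameters():
            p[...] = state[n]

    def check_input_size(self, h: int, w: int) -> None:
        f = 2 ** (self.depth - 1)
        if h % f or w % f or 8 % f:
            raise ValueError(f"spatial dims must be divisible by {f} at depth {self.depth}")
        if min(8, h, w) // f < 1:
            raise ValueError("spatial dims collapse below 1 after downsampling")

    # -- forward / backward --------------------------------------------------
    def forward_window(self, window: np.ndarray, need_cache: bool = True):
        """(8, H, W, 7) image window -> ((8, H, W, 3) probability map, tape)."""
        x = np.ascontiguousarray(np.moveaxis(window, 3, 0), dtype=nn.DTYPE)
        self.check_input_size(x.shape[2], x.shape[3])
        tape = {"enc": [], "skips_shape": []}
        skips = []
        h = x
        for b in self.enc:
            h, c = b.forward(h, need_cache)
            skips.append(h)
            tape["enc"].append(c)
            h, _ = self.pool.forward(h, need_cache)
        h, tape["bottom"] = self.bottleneck.forward(h, need_cache)
        tape["dec"] = []
        for b, skip in zip(self.dec, reversed(skips)):
            h, _ = self.up.forward(h, need_cache)
            h = np.concatenate([skip, h], axis=0)
            tape["skips_shape"].append(skip.shape[0])
            h, c = b.forward(h, need_cache)
            tape["dec"].append(c)
        z, tape["head"] = self.head.forward(h, need_cache)
        p = nn.softmax_channels(z)
        if need_cache:
            tape["probs"] = p
        return np.moveaxis(p, 0, 3), tape

    def backward_window(self, grad_probs: np.ndarray, tape) -> np.ndarray:
        """Backpropagate d(loss)/d(probs); returns d(loss)/d(input window).

        Parameter gradients accumulate on the layers; the returned array has
        the window layout (8, H, W, 7).
        """
        gp = np.ascontiguousarray(np.moveaxis(grad_probs, 3, 0), dtype=nn.DTYPE)
        gz = nn.softmax_backward(tape["probs"], gp)
        gh = self.head.backward(gz, tape["head"])
        gskips = []
        for b, c, sc in zip(reversed(self.dec), reversed(tape["dec"]),
                            reversed(tape["skips_shape"])):
            gh = b.backward(gh, c)
            gskips.append(gh[:sc])
            gh = self.up.backward(gh[sc:], None)
        gh = self.bottleneck.backward(gh, tape["bottom"])
        for b, c, gskip in zip(reversed(self.enc), reversed(tape["enc"]), gskips):
            gh = self.pool.backward(gh, None)
            gh = b.backward(gh + gskip, c)
        return np.moveaxis(gh, 0, 3)

    def predict_window(self, window: np.ndarray) -> np.ndarray:
        """Inference-only forward pass; no caches, no gradients."""
        p, _ = self.forward_window(window, need_cache=False)
        return p


def build_model(depth: int = 2, base_channels: int = 8, seed: int = 0) -> UNet3D:
    """Construct a segmenter; two builds with the same seed are identical."""
    return UNet3D(depth=depth, base_channels=base_channels, seed=seed)


def ema_update(theta_t: list[np.ndarray], theta_s: list[np.ndarray],
               alpha: float) -> None:
    """In-place EMA: theta_t <- alpha*theta_t + (1-alpha)*theta_s, elementwise."""
    if len(theta_t) != len(theta_s):
        raise ValueError("parameter lists differ in length")
    for pt, ps in zip(theta_t, theta_s):
        if pt.shape != ps.shape:
            raise ValueError(f"shape mismatch {pt.shape} vs {ps.shape}")
        pt *= alpha
        pt += (1.0 - alpha) * ps


class ModelPair:
    """Student (gradient-trained) and mean-teacher (EMA-tracked) networks.

    The teacher starts as an exact copy of the student and is only ever touched
    by :meth:`ema_step`.
    """

    def __init__(self, student: UNet3D):
        self.student = student
        self.teacher = copy.deepcopy(student)

    def ema_step(self, alpha: float) -> None:
        ema_update(self.teacher.state_arrays(), self.student.state_arrays(), alpha)

    def save(self, path: str | Path, extra: dict | None = None) -> None:
        path = Path(path)
        blobs = {f"student/{n}": p for n, p in self.student.state_dict().items()}
        blobs |= {f"teacher/{n}": p for n, p in self.teacher.state_dict().items()}
        meta = {"config": self.student.config, "extra": extra or {}}
        blobs["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez_compressed(path, **blobs)

    @classmethod
    def load(cls, path: str | Path) -> tuple["ModelPair", dict]:
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            cfg = meta["config"]
            pair = cls(UNet3D(depth=cfg["depth"], base_channels=cfg["base_channels"],
                              in_channels=cfg["in_channels"],
                              n_classes=cfg["n_classes"], seed=cfg["seed"]))
            pair.student.load_state_dict(
                {n: z[f"student/{n}"] for n, _, _ in pair.student.parameters()})
            pair.teacher.load_state_dict(
                {n: z[f"teacher/{n}"] for n, _, _ in pair.teacher.parameters()})
        return pair, meta["extra"]
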