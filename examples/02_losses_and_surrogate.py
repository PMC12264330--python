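"""Worked numbers for the three losses and the surrogate-label generator.

Evaluates the multi-class Dice loss, the class-weighted cross-entropy and the
selective-hardening / surrogate-label rules on tiny hand-checkable inputs.
"""

import math

import numpy as np

from snapseg import losses
from snapseg.label_correction import selective_harden, surrogate_label

# binary Dice: prediction (0.5, 0.5) against mask (1, 0)
d = losses.binary_dice_loss(np.array([1.0, 0.0]), np.array([0.5, 0.5]))
print(f"binary Dice loss            : {d:.4f}   (1 - 2*0.5/(1+1) = 0.5)")

# weighted CE at one voxel: true lumen, predicted probability 0.5, weight 2
y = np.zeros((1, 1, 1, 3)); y[..., 0] = 1
p = np.array([0.5, 0.25, 0.25]).reshape(1, 1, 1, 3)
ce = losses.weighted_ce_loss(p, y)
print(f"weighted CE (one voxel)     : {ce:.4f}   (-2*ln 0.5 = {-2*math.log(0.5):.4f})")

# selective hardening: confident agreement above tau=0.99 snaps to one-hot
pt = np.array([0.995, 0.003, 0.002]).reshape(1, 1, 1, 3)
ps = np.array([0.992, 0.005, 0.003]).reshape(1, 1, 1, 3)
print("hardened voxel              :", selective_harden(pt, ps, tau=0.99)[0, 0, 0])

# below threshold: the two predictions are averaged instead
pl = np.array([0.8, 0.1, 0.1]).reshape(1, 1, 1, 3)
print("low-confidence voxel        :", selective_harden(pl, pl, tau=0.99)[0, 0, 0])

# surrogate: models confidently say lumen where the manual label says wall
manual = np.array([0.0, 1.0, 0.0]).reshape(1, 1, 1, 3)
hardened = np.array([1.0, 0.0, 0.0]).reshape(1, 1, 1, 3)
sur = surrogate_label(manual, hardened, beta=0.5)
print("surrogate (beta=0.5)        :", sur[0, 0, 0])
# The 0.5/0.5 split encodes honest uncertainty between the (possibly
# misaligned) manual contour and the models' consensus.
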