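"""FGSM perturbations against the segmentation backbone.

Computes the one-step sign attack on a phantom window and shows that the
perturbation is +/- epsilon (in normalized-intensity units) and that it
increases the cross-entropy of the prediction against its target.
"""

import numpy as np

from snapseg.adversarial import fgsm_perturbation, perturb_image, unweighted_ce
from snapseg.backbone import build_model
from snapseg.phantom import PhantomConfig, generate_phantom

vol, label = generate_phantom(PhantomConfig(N=8, H=32, W=32, lumen_radius=4,
                                            wall_radius=7,
                                            centerline_amplitude=2, seed=1))
model = build_model(depth=2, base_channels=8, seed=0)
y = label.onehot.astype(float)

eps = 0.5
r = fgsm_perturbation(model, vol.data, y, epsilon=eps)
print(f"perturbation values: {sorted(set(np.unique(r)))} (epsilon = {eps})")

ce_before = unweighted_ce(model.predict_window(vol.data), y)
ce_after = unweighted_ce(model.predict_window(perturb_image(vol.data, r)), y)
print(f"CE before attack: {ce_before:.4f}   after: {ce_after:.4f}")
# The attack raises the loss: training on these worst-case inputs (Path 2)
# regularizes the student against small input perturbations.
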