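"""Grad-CAM saliency maps for the dual-branch classifier.

For each branch the map is the ReLU of the gradient-weighted sum of the
branch's final convolutional activation channels, where the channel weights
are the spatial averages of the gradients of the target-class *logit*
(pre-softmax, the standard convention — post-softmax gradients saturate).
Branch maps are bilinearly upsampled to the input resolution and
max-normalized; the combined map weights each branch by its additive share
of the class logit.

The final dense head decomposes exactly over the two halves of the refined
feature vector F: logit_c = w_c[:D] . F[:D] + w_c[D:] . F[D:] + b_c, the two
dot products being each branch's contribution.  The combination weight is
w_branch = |s_branch| / (|s_A| + |s_B|), falling back to 0.5/0.5 when both
shares vanish.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage.transform import resize

from .model import ForwardResult, HybridModel, forward

logger = logging.getLogger(__name__)

BRANCHES = ("a", "b")


def _normalize_map(cam: np.ndarray) -> np.ndarray:
    m = cam.max()
    return cam / m if m > 0 else cam


def _branch_cam(res: ForwardResult, image_shape, branch_id: str) -> np.ndarray:
    act = res.branch_activations[branch_id]
    a, g = act.data[0], act.grad[0]           # (C, h, w)
    weights = g.mean(axis=(1, 2))             # spatially averaged gradients
    cam = np.maximum((weights[:, None, None] * a).sum(axis=0), 0.0)
    cam = resize(cam, image_shape, order=1, mode="edge", anti_aliasing=False)
    return _normalize_map(cam)


def _run_with_grads(model: HybridModel, image: np.ndarray, target_class: int) -> ForwardResult:
    image = np.asarray(image, dtype=float)
    if image.ndim != 3:
        raise ValueError("branch_gradcam expects a single (H, W, 3) image")
    res = forward(model, image)
    seed = np.zeros_like(res.logits.data)
    seed[0, target_class] = 1.0
    res.logits.backward(seed)
    return res


def branch_gradcam(model: HybridModel, image: np.ndarray, target_class: int,
                   branch_id: str) -> np.ndarray:
    """Saliency map (H, W) in [0, 1] for one branch; all-zero when the
    target score does not depend on the branch activations."""
    if branch_id not in BRANCHES:
        raise ValueError(f"branch_id must be one of {BRANCHES}")
    res = _run_with_grads(model, image, target_class)
    return _branch_cam(res, np.asarray(image).shape[:2], branch_id)


def branch_contributions(model: HybridModel, res: ForwardResult,
                         target_class: int) -> dict[str, float]:
    """Each branch's normalized absolute share of the target-class logit."""
    d_a = model.backbone_a.embedding_dim
    w = model.head_w.data[:, target_class]
    f = res.refined.data[0]
    s_a = abs(float(w[:d_a] @ f[:d_a]))
    s_b = abs(float(w[d_a:] @ f[d_a:]))
    total = s_a + s_b
    if total == 0:
        return {"a": 0.5, "b": 0.5}
    return {"a": s_a / total, "b": s_b / total}


def combined_gradcam(model: HybridModel, image: np.ndarray, target_class: int,
                     return_weights: bool = False):
    """Contribution-weighted sum of the two branch maps, max-normalized."""
    res = _run_with_grads(model, image, target_class)
    shape = np.asarray(image).shape[:2]
    maps = {b: _branch_cam(res, shape, b) for b in BRANCHES}
    w = branch_contributions(model, res, target_class)
    combined = w["a"] * maps["a"] + w["b"] * maps["b"]
    if combined.max() == 0:
        logger.warning("both branch Grad-CAM maps are zero; returning an all-zero map")
    combined = _normalize_map(combined)
    return (combined, w) if return_weights else combined
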