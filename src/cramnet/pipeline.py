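"""End-to-end helpers: train on a split, explain a batch, score agreement.

These functions wire the pieces together the way the command-line interface
and the worked examples use them: images stay in raw [0, 1] space for
masking and visualization, while every model evaluation goes through the
training-set channel standardization stored on the model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import gradcam, metrics, model as model_mod, saliency, shapley, synth


def model_logit_fn(model, target_class: int = synth.MALIGNANT):
    """Batch callable (N, H, W, 3) raw images -> target-class logits,
    applying the model's stored standardization."""
    stats = getattr(model, "norm_stats", None)

    def fn(images: np.ndarray) -> np.ndarray:
        px = np.asarray(images, dtype=float)
        if stats is not None:
            px, _ = synth.normalize(px, stats)
        return model_mod.forward(model, px).logits.data[:, target_class]

    return fn


def _standardized(model, image: np.ndarray) -> np.ndarray:
    stats = getattr(model, "norm_stats", None)
    if stats is None:
        return np.asarray(image, dtype=float)
    px, _ = synth.normalize(np.asarray(image, dtype=float)[None], stats)
    return px[0]


def gradcam_map(model, image: np.ndarray, target_class: int = synth.MALIGNANT) -> np.ndarray:
    """Combined Grad-CAM on a raw image (standardized internally)."""
    return gradcam.combined_gradcam(model, _standardized(model, image), target_class)


def gradcam_metrics(model, images: list[synth.LabeledImage],
                    frac: float = 0.30,
                    target_class: int = synth.MALIGNANT) -> pd.DataFrame:
    """Per-image saliency-agreement rows: iou, dice, pointing, overlap.

    Pointing game and overlap are NaN for images with empty annotations
    (benign), matching the class-stratified reporting convention.
    """
    rows = []
    for i, im in enumerate(images):
        cam = gradcam_map(model, im.pixels, target_class)
        binmap = saliency.binarize_saliency(cam, frac)
        row = {"index": i, "label": im.label,
               "iou": saliency.iou(binmap, im.gt_mask),
               "dice": saliency.dice(binmap, im.gt_mask),
               "pointing": np.nan, "normalized_overlap": np.nan}
        if im.gt_mask.any():
            row["pointing"] = saliency.pointing_game(cam, im.gt_mask)
            if cam.max() > 0:
                row["normalized_overlap"] = saliency.normalized_overlap(cam, im.gt_mask)
        rows.append(row)
    return pd.DataFrame(rows)


def shap_mask_alignment(model, images: list[synth.LabeledImage],
                        k_target: int = 50, n_samples: int = 2048,
                        seed: int = 0) -> pd.DataFrame:
    """SHAP agreement with the planted region, per malignant image.

    For each image: segment, run Kernel SHAP on the malignant logit, and sum
    the attributions of superpixels that intersect the ground-truth mask.
    A positive sum means the annotated region pushes the prediction toward
    malignant.
    """
    fn = model_logit_fn(model)
    rows = []
    for i, im in enumerate(images):
        seg = shapley.segment_superpixels(im.pixels, k_target, seed=seed)
        sv = shapley.kernel_shap(fn, im.pixels, seg, n_samples=n_samples, seed=seed + i)
        k = int(seg.max()) + 1
        intersecting = np.unique(seg[im.gt_mask]) if im.gt_mask.any() else np.array([], dtype=int)
        mask_sum = float(sv.phi[intersecting].sum()) if intersecting.size else np.nan
        rows.append({"index": i, "label": im.label, "k": k,
                     "mask_phi_sum": mask_sum,
                     "total_phi_sum": float(sv.phi.sum()),
                     "efficiency_residual": sv.efficiency_residual})
    return pd.DataFrame(rows)


def evaluate_split(model, images: list[synth.LabeledImage], threshold: float = 0.5) -> dict:
    """Confusion counts, headline percentages and AUC on a list of images."""
    scores = model_mod.evaluate_scores(model, images)
    true = synth.labels_of(images)
    pred = (scores >= threshold).astype(int)
    counts = metrics.confusion(pred, true)
    summary = metrics.summary_metrics(counts)
    roc = metrics.roc_auc(scores, true)
    return {"counts": counts, "summary": summary, "auc": roc.auc,
            "scores": scores, "pred": pred, "true": true}
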