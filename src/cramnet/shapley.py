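"""Superpixel-level Shapley attribution for image classifiers.

An image is oversegmented into ~K compact superpixels (SLIC); each
superpixel is a player that is either "present" (original pixels) or
"absent" (replaced by the image's global per-channel mean color).  The value
v(S) of a coalition S is the model output on the correspondingly masked
image.  Two estimators are provided:

* :func:`exact_shapley` — brute-force enumeration of all 2^K coalitions
  (guarded to K <= 12), the verification oracle.
* :func:`kernel_shap` — the weighted-least-squares estimator with the
  Shapley kernel, constrained so the efficiency identity
  base + sum(phi) = v(full) holds exactly.  When the sample budget covers
  every proper coalition the estimator enumerates them with their analytic
  kernel weights and reproduces the exact values.

``model_fn`` is any callable mapping a batch of images (N, H, W, 3) to N
scalar scores; attributing the malignant-class logit (rather than the
probability) keeps the values well conditioned under the additive head.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, factorial

import numpy as np
from skimage.segmentation import slic

EXACT_K_LIMIT = 12


@dataclass
class ShapValues:
    phi: np.ndarray        # (K,) signed attributions
    base_value: float      # model output on the fully masked image
    full_value: float      # model output on the unmasked image

    @property
    def efficiency_residual(self) -> float:
        return float(self.base_value + self.phi.sum() - self.full_value)


def segment_superpixels(image: np.ndarray, k_target: int = 50, seed: int = 0) -> np.ndarray:
    """SLIC-style oversegmentation into roughly ``k_target`` compact regions.

    Returns an (H, W) int label map with consecutive labels 0..K-1.  The
    achieved K typically lands within [k_target/2, 2*k_target].  The
    procedure is deterministic (``seed`` is accepted for interface symmetry
    with the sampling estimator).
    """
    image = np.asarray(image, dtype=float)
    if k_target < 2:
        raise ValueError("k_target must be >= 2")
    if image.shape[0] * image.shape[1] < k_target:
        raise ValueError("image has fewer pixels than requested superpixels")
    labels = slic(image, n_segments=k_target, compactness=10.0, start_label=0,
                  channel_axis=-1, enforce_connectivity=True)
    # relabel to consecutive 0..K-1
    uniq, labels = np.unique(labels, return_inverse=True)
    return labels.reshape(image.shape[:2])


def mask_superpixels(image: np.ndarray, seg: np.ndarray, coalition,
                     baseline_color: np.ndarray | None = None) -> np.ndarray:
    """Replace every superpixel *not* in ``coalition`` with the image's
    global per-channel mean color (or an explicit baseline color)."""
    image = np.asarray(image, dtype=float)
    k = int(seg.max()) + 1
    coalition = np.asarray(sorted({int(c) for c in coalition}), dtype=int)
    if coalition.size and (coalition.min() < 0 or coalition.max() >= k):
        raise ValueError(f"coalition indices must lie in 0..{k - 1}")
    if baseline_color is None:
        baseline_color = image.mean(axis=(0, 1))
    present = np.zeros(k, dtype=bool)
    present[coalition] = True
    out = np.where(present[seg][..., None], image, baseline_color[None, None, :])
    return out


def _coalition_values(model_fn, image, seg, subsets: np.ndarray,
                      batch_size: int = 256) -> np.ndarray:
    """Evaluate v(S) for each row of the boolean subset matrix (n, K)."""
    baseline = np.asarray(image, dtype=float).mean(axis=(0, 1))
    vals = np.empty(len(subsets))
    for start in range(0, len(subsets), batch_size):
        chunk = subsets[start:start + batch_size]
        masked = np.stack([
            np.where(row[seg][..., None], image, baseline[None, None, :])
            for row in chunk])
        vals[start:start + len(chunk)] = np.asarray(model_fn(masked)).reshape(-1)
    return vals


def exact_shapley(model_fn, image: np.ndarray, seg: np.ndarray,
                  batch_size: int = 256) -> ShapValues:
    """Exact Shapley values by full coalition enumeration (K <= 12)."""
    k = int(seg.max()) + 1
    if k > EXACT_K_LIMIT:
        raise ValueError(
            f"exact enumeration needs 2^{k} model evaluations; use kernel_shap for K > {EXACT_K_LIMIT}")
    n = 1 << k
    subsets = ((np.arange(n)[:, None] >> np.arange(k)) & 1).astype(bool)
    v = _coalition_values(model_fn, image, seg, subsets, batch_size)
    sizes = subsets.sum(axis=1)
    weights = np.array([factorial(s) * factorial(k - s - 1) / factorial(k) for s in range(k)])
    phi = np.zeros(k)
    for s_idx in range(n):
        s_size = sizes[s_idx]
        for i in range(k):
            if not subsets[s_idx, i]:
                phi[i] += weights[s_size] * (v[s_idx | (1 << i)] - v[s_idx])
    return ShapValues(phi=phi, base_value=float(v[0]), full_value=float(v[n - 1]))


def _kernel_weight(k: int, s: int) -> float:
    return (k - 1) / (comb(k, s) * s * (k - s))


def kernel_shap(model_fn, image: np.ndarray, seg: np.ndarray,
                n_samples: int = 2048, seed: int = 0,
                batch_size: int = 256) -> ShapValues:
    """Kernel SHAP: Shapley-kernel weighted least squares over coalitions,
    with the efficiency constraint enforced exactly.

    Deterministic per seed.  If ``n_samples`` covers all 2^K - 2 proper
    coalitions they are enumerated instead of sampled, which makes the
    estimate identical to :func:`exact_shapley`.
    """
    k = int(seg.max()) + 1
    if k < 2:
        raise ValueError("need at least 2 superpixels")
    if n_samples < k + 2:
        raise ValueError(f"n_samples must be at least K+2 = {k + 2}")

    n_proper = (1 << k) - 2
    if n_samples >= n_proper:
        idx = np.arange(1, (1 << k) - 1)
        z = ((idx[:, None] >> np.arange(k)) & 1).astype(bool)
        w = np.array([_kernel_weight(k, int(s)) for s in z.sum(axis=1)])
    else:
        rng = np.random.default_rng(seed)
        sizes = np.arange(1, k)
        size_p = np.array([_kernel_weight(k, int(s)) * comb(k, int(s)) for s in sizes])
        size_p = size_p / size_p.sum()
        # antithetic pairs: each draw contributes a coalition and its complement
        half = n_samples // 2
        z = np.zeros((2 * half, k), dtype=bool)
        for row in range(half):
            s = int(rng.choice(sizes, p=size_p))
            members = rng.choice(k, size=s, replace=False)
            z[2 * row, members] = True
            z[2 * row + 1] = ~z[2 * row]
        w = np.ones(len(z))

    v = _coalition_values(model_fn, image, seg, z, batch_size)
    v0 = float(np.asarray(model_fn(mask_superpixels(image, seg, [])[None])).reshape(-1)[0])
    v_full = float(np.asarray(model_fn(np.asarray(image, dtype=float)[None])).reshape(-1)[0])
    delta = v_full - v0

    # eliminate the efficiency constraint: phi_{K-1} = delta - sum_{j<K-1} phi_j
    zf = z.astype(float)
    a = zf[:, :-1] - zf[:, -1:]
    y = v - v0 - zf[:, -1] * delta
    aw = a * w[:, None]
    g = a.T @ aw
    if np.linalg.matrix_rank(g) < k - 1:
        raise np.linalg.LinAlgError(
            "singular Kernel SHAP regression system; increase n_samples")
    phi_head = np.linalg.solve(g, aw.T @ y)
    phi = np.append(phi_head, delta - phi_head.sum())
    return ShapValues(phi=phi, base_value=v0, full_value=v_full)


def shap_overlay(image: np.ndarray, seg: np.ndarray, phi: np.ndarray,
                 alpha: float = 1.0) -> np.ndarray:
    """Diverging red/blue rendering of per-superpixel attributions.

    Red marks regions pushing toward the attributed (malignant) class, blue
    regions pushing away, white neutral; the color scale is symmetric at
    +/- max|phi|.  ``alpha`` < 1 blends the colors over the image.
    """
    image = np.asarray(image, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if int(seg.max()) + 1 != phi.size:
        raise ValueError("phi length does not match the number of superpixels")
    scale = np.abs(phi).max()
    t = phi / scale if scale > 0 else np.zeros_like(phi)
    colors = np.ones((phi.size, 3))
    pos, neg = t >= 0, t < 0
    colors[pos, 1] = colors[pos, 2] = 1.0 - t[pos]     # toward red
    colors[neg, 0] = colors[neg, 1] = 1.0 + t[neg]     # toward blue
    rendered = colors[seg]
    if alpha < 1.0:
        rendered = alpha * rendered + (1.0 - alpha) * image
    return rendered
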