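"""Dual-branch convolutional classifier with gated attention fusion.

Two backbone feature extractors run in parallel on the same image; their
globally pooled embeddings are concatenated and refined by the gated
recurrent channel attention module (:mod:`cramnet.cram`) before a 2-way
softmax head.  The built-in :class:`TinyBackbone` (three stride-2 conv
blocks + global average pooling) trains from scratch in seconds on small
synthetic patches; any object satisfying the same contract (``forward``
returning an embedding and the final convolutional activation, ``tensors``
listing parameters) can stand in for a larger pretrained network.

The training loop follows the usual fine-tuning recipe for this kind of
model: Adam on softmax cross-entropy, L2 weight decay on the head and
attention parameters, a triangular cyclic learning rate, optional
progressive unfreezing of the backbones, online augmentation of training
batches only, and early stopping on validation loss with best-weight
restoration.  Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import synth
from .autodiff import (Tensor, add, concat, conv2d, global_avg_pool, matmul,
                       relu, softmax, softmax_cross_entropy)
from .cram import CramParams, CramResult, cram_forward, init_cram


class TinyBackbone:
    """Three stride-2 3x3 conv blocks with ReLU, then global average pooling.

    For a 64x64 input the final convolutional activation is
    ``widths[-1]`` x 8 x 8; that map is what Grad-CAM inspects.
    """

    def __init__(self, in_channels: int = 3, widths=(8, 16, 32), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.widths = tuple(widths)
        self.embedding_dim = widths[-1]
        self.blocks = []
        prev = in_channels
        for w in widths:
            fan_in = prev * 9
            kernel = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(w, prev, 3, 3))
            self.blocks.append((Tensor(kernel, requires_grad=True),
                                Tensor(np.zeros(w), requires_grad=True)))
            prev = w

    def forward(self, x: Tensor):
        """x: (N, 3, H, W) -> (embedding (N, D), last conv activation Tensor)."""
        cur = x
        for kernel, bias in self.blocks:
            cur = relu(conv2d(cur, kernel, bias, stride=2, pad=1))
        return global_avg_pool(cur), cur

    def tensors(self):
        return [t for kb in self.blocks for t in kb]

    def last_block_tensors(self):
        return list(self.blocks[-1])


ATTENTION_MODES = ("cram", "single_step", "none")


@dataclass
class HybridModel:
    backbone_a: TinyBackbone
    backbone_b: TinyBackbone
    cram: CramParams | None         # None when attention_mode == "none"
    head_w: Tensor                  # (2D, 2)
    head_b: Tensor                  # (2,)
    attention_mode: str = "cram"
    residual: bool = True
    dropout_p: float | None = None

    @property
    def fused_dim(self) -> int:
        return self.backbone_a.embedding_dim + self.backbone_b.embedding_dim

    def tensors(self):
        ts = self.backbone_a.tensors() + self.backbone_b.tensors()
        if self.cram is not None:
            ts += self.cram.tensors()
        return ts + [self.head_w, self.head_b]

    def fusion_tensors(self):
        """Head + attention parameters (the L2-regularized subset)."""
        ts = [] if self.cram is None else self.cram.tensors()
        return ts + [self.head_w, self.head_b]


@dataclass
class ForwardResult:
    probs: np.ndarray               # (N, 2)
    logits: Tensor                  # (N, 2)
    fused: Tensor                   # (N, 2D) = f_concat
    refined: Tensor                 # (N, 2D) = F
    masks: list[Tensor]             # attention masks (empty for mode "none")
    branch_activations: dict        # {"a": Tensor, "b": Tensor} final conv maps


def build_model(backbone_a=None, backbone_b=None, attention_mode: str = "cram",
                residual: bool = True, hidden_width: int | None = None,
                dropout_p: float | None = None, seed: int = 0) -> HybridModel:
    """Assemble the dual-branch classifier.

    ``attention_mode``: "cram" (two gated passes), "single_step" (one pass,
    squeeze-and-excitation-like), "none" (concatenation straight to head).
    """
    if attention_mode not in ATTENTION_MODES:
        raise ValueError(f"attention_mode must be one of {ATTENTION_MODES}")
    rng = np.random.default_rng(seed)
    backbone_a = backbone_a or TinyBackbone(seed=int(rng.integers(2**31)))
    backbone_b = backbone_b or TinyBackbone(seed=int(rng.integers(2**31)))
    fused_dim = backbone_a.embedding_dim + backbone_b.embedding_dim
    if attention_mode == "none":
        cram = None
    else:
        n_steps = 2 if attention_mode == "cram" else 1
        cram = init_cram(fused_dim, hidden_width or min(fused_dim, 256),
                         seed=int(rng.integers(2**31)), n_steps=n_steps)
    head_w = Tensor(rng.normal(0.0, np.sqrt(2.0 / fused_dim), size=(fused_dim, 2)),
                    requires_grad=True)
    head_b = Tensor(np.zeros(2), requires_grad=True)
    return HybridModel(backbone_a=backbone_a, backbone_b=backbone_b, cram=cram,
                       head_w=head_w, head_b=head_b, attention_mode=attention_mode,
                       residual=residual, dropout_p=dropout_p)


def _to_nchw(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=float)
    if images.ndim == 3:
        images = images[None]
    if images.shape[-1] != 3:
        raise ValueError(f"expected 3-channel images (H, W, 3); got shape {images.shape}")
    return np.transpose(images, (0, 3, 1, 2))


def forward(model: HybridModel, images: np.ndarray, rng=None,
            train_mode: bool = False) -> ForwardResult:
    """Full forward pass exposing every intermediate the explainers need.

    ``images``: (N, H, W, 3) or a single (H, W, 3) array.  Deterministic in
    evaluation mode (dropout only fires with ``train_mode=True``).
    """
    x = Tensor(_to_nchw(images))
    emb_a, act_a = model.backbone_a.forward(x)
    emb_b, act_b = model.backbone_b.forward(x)
    fused = concat([emb_a, emb_b], axis=-1)
    if model.cram is not None:
        res = cram_forward(fused, model.cram, residual=model.residual)
        refined, masks = res.refined, res.masks
    else:
        refined, masks = fused, []
    feat = refined
    if train_mode and model.dropout_p:
        rng = rng or np.random.default_rng(0)
        keep = (rng.random(feat.data.shape) >= model.dropout_p) / (1.0 - model.dropout_p)
        feat = feat * Tensor(keep)
    logits = add(matmul(feat, model.head_w), model.head_b)
    return ForwardResult(probs=softmax(logits.data), logits=logits, fused=fused,
                         refined=refined, masks=masks,
                         branch_activations={"a": act_a, "b": act_b})


def predict(model: HybridModel, images, batch_size: int = 64) -> np.ndarray:
    """Per-image malignant probability in [0, 1]."""
    images = np.asarray(images, dtype=float)
    single = images.ndim == 3
    if single:
        images = images[None]
    out = np.concatenate([
        forward(model, images[i:i + batch_size]).probs[:, synth.MALIGNANT]
        for i in range(0, len(images), batch_size)])
    return out[0] if single else out


def predict_labels(model: HybridModel, images, threshold: float = 0.5) -> np.ndarray:
    """Threshold malignant probability; ties at the threshold go malignant
    (the sensitivity-favoring convention)."""
    return (np.atleast_1d(predict(model, images)) >= threshold).astype(int)


# --- training -------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training hyperparameters.

    The learning-rate pair, batch size, patience, weight decay and epoch cap
    default to the fine-tuning recipe for the full-size pretrained model
    (lr cycling 1e-4 <-> 1e-5, batch 16, patience 5, L2 1e-5, <=50 epochs).
    Small from-scratch backbones need a proportionally larger rate — see
    :func:`desk_scale_config`.
    """

    lr_high: float = 1e-4
    lr_low: float = 1e-5
    batch_size: int = 16
    max_epochs: int = 50
    patience: int = 5
    l2: float = 1e-5
    cycle_period: int = 4           # epochs per triangular LR cycle
    freeze_schedule: list | None = None  # [(epoch, scope)] scope in {"fusion", "fusion+last", "all"}
    augment: synth.AugmentConfig | None = field(default_factory=synth.AugmentConfig)
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.lr_low <= self.lr_high):
            raise ValueError("need 0 < lr_low <= lr_high")
        if self.patience < 1 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("patience, batch_size and max_epochs must be >= 1")


def desk_scale_config(seed: int = 0, **overrides) -> TrainConfig:
    """Config for training the tiny backbones from scratch on synthetic
    patches: same schedule shape, learning rate scaled up for random init."""
    kw = dict(lr_high=3e-3, lr_low=3e-4, seed=seed)
    kw.update(overrides)
    return TrainConfig(**kw)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    stopping_epoch: int = 0
    best_epoch: int = 0

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"epoch": np.arange(1, len(self.train_loss) + 1),
                             "train_loss": self.train_loss, "train_acc": self.train_acc,
                             "val_loss": self.val_loss, "val_acc": self.val_acc})


def cyclic_lr(epoch: int, cfg: TrainConfig) -> float:
    """Triangular wave: lr_high at the cycle ends, lr_low at mid-cycle."""
    half = cfg.cycle_period / 2.0
    t = epoch % cfg.cycle_period
    return cfg.lr_low + (cfg.lr_high - cfg.lr_low) * abs(1.0 - t / half)


class _Adam:
    def __init__(self, params: list[Tensor], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.b1, self.b2, self.eps, self.t = beta1, beta2, eps, 0

    def step(self, lr: float):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if not p.trainable or p.grad is None:
                continue
            g = p.grad
            m *= self.b1; m += (1 - self.b1) * g
            v *= self.b2; v += (1 - self.b2) * g * g
            mh = m / (1 - self.b1 ** self.t)
            vh = v / (1 - self.b2 ** self.t)
            p.data -= lr * mh / (np.sqrt(vh) + self.eps)


def _apply_freeze(model: HybridModel, scope: str):
    for t in model.tensors():
        t.trainable = False
    for t in model.fusion_tensors():
        t.trainable = True
    if scope in ("fusion+last", "all"):
        for bb in (model.backbone_a, model.backbone_b):
            for t in bb.last_block_tensors():
                t.trainable = True
    if scope == "all":
        for t in model.tensors():
            t.trainable = True


def train(model: HybridModel, data: synth.DatasetSplit,
          cfg: TrainConfig | None = None) -> tuple[HybridModel, TrainHistory]:
    """Train in place and return ``(model, history)``.

    Training images are standardized with training-set channel statistics
    (also applied to validation), augmented online per batch, and the
    best-validation-loss weights are restored at the end.
    """
    cfg = cfg or TrainConfig()
    if not data.train or not data.val:
        raise ValueError("train and val partitions must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    stats = synth.channel_stats(synth.stack_pixels(data.train))
    val_px, _ = synth.normalize(synth.stack_pixels(data.val), stats)
    val_y = synth.labels_of(data.val)

    params = model.tensors()
    opt = _Adam(params)
    history = TrainHistory()
    best_loss, best_state, since_best = np.inf, None, 0
    n = len(data.train)

    for epoch in range(1, cfg.max_epochs + 1):
        if cfg.freeze_schedule:
            for ep, scope in cfg.freeze_schedule:
                if ep == epoch - 1:
                    _apply_freeze(model, scope)
        lr = cyclic_lr(epoch - 1, cfg)
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = []
            for j in idx:
                im = data.train[j]
                if cfg.augment is not None:
                    im = synth.augment(im, seed=int(rng.integers(2**31)), config=cfg.augment)
                batch.append(im.pixels)
            bx, _ = synth.normalize(np.stack(batch), stats)
            by = np.array([data.train[j].label for j in idx])
            res = forward(model, bx, rng=rng, train_mode=True)
            loss = softmax_cross_entropy(res.logits, by)
            loss.backward()
            # L2 penalty on fusion (head + attention) parameters only
            if cfg.l2:
                for p in model.fusion_tensors():
                    p.grad += cfg.l2 * p.data
            opt.step(lr)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            ep_loss += float(loss.data) * len(idx)
            ep_correct += int((res.probs.argmax(axis=1) == by).sum())
        history.train_loss.append(ep_loss / n)
        history.train_acc.append(ep_correct / n)

        vres = forward(model, val_px)
        vloss = float(softmax_cross_entropy(vres.logits, val_y).data)
        vacc = float((vres.probs.argmax(axis=1) == val_y).mean())
        history.val_loss.append(vloss)
        history.val_acc.append(vacc)
        history.stopping_epoch = epoch

        if vloss < best_loss - 1e-12:
            best_loss, since_best = vloss, 0
            history.best_epoch = epoch
            best_state = [p.data.copy() for p in params]
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break

    if best_state is not None:
        for p, s in zip(params, best_state):
            p.data[...] = s
    model.norm_stats = stats  # evaluation-time standardization
    return model, history


def evaluate_scores(model: HybridModel, images: list[synth.LabeledImage]) -> np.ndarray:
    """Malignant probabilities for LabeledImages, using the training-set
    standardization stored on the model by :func:`train`."""
    px = synth.stack_pixels(images)
    stats = getattr(model, "norm_stats", None)
    if stats is not None:
        px, _ = synth.normalize(px, stats)
    return predict(model, px)


# --- checkpointing --------------------------------------------------------

def save_model(model: HybridModel, path: str):
    arrays, meta = {}, {
        "attention_mode": model.attention_mode,
        "residual": int(model.residual),
        "dropout_p": -1.0 if model.dropout_p is None else model.dropout_p,
        "widths_a": list(model.backbone_a.widths),
        "widths_b": list(model.backbone_b.widths),
        "hidden_width": 0 if model.cram is None else model.cram.hidden_width,
        "n_steps": 0 if model.cram is None else len(model.cram.steps),
    }
    for i, t in enumerate(model.tensors()):
        arrays[f"p{i}"] = t.data
    stats = getattr(model, "norm_stats", None)
    if stats is not None:
        arrays["norm_mean"], arrays["norm_std"] = stats.mean, stats.std
    import json
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str) -> HybridModel:
    import json
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        model = build_model(
            backbone_a=TinyBackbone(widths=meta["widths_a"]),
            backbone_b=TinyBackbone(widths=meta["widths_b"]),
            attention_mode=meta["attention_mode"],
            residual=bool(meta["residual"]),
            hidden_width=meta["hidden_width"] or None,
            dropout_p=None if meta["dropout_p"] < 0 else meta["dropout_p"])
        for i, t in enumerate(model.tensors()):
            t.data[...] = z[f"p{i}"]
        if "norm_mean" in z:
            model.norm_stats = synth.ChannelStats(mean=z["norm_mean"], std=z["norm_std"])
    return model
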