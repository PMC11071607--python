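"""Training loss terms.

Three terms drive the two training phases:

* a supervised **generalized Dice** data term, with per-class weights
  inversely proportional to the squared class volume, so small structures
  (muscle patches) are not drowned out by large ones (fat compartments);
* a **cross-decoder consistency** term — symmetric mean squared difference
  between the two decoders' probability maps of the same input;
* a **prediction confidence** term — mean per-pixel Shannon entropy,
  normalized by ln C, pushing the model toward committed (low-entropy)
  predictions on weakly labeled data.

All functions accept channel-last probability maps, either a single
``(H, W, C)`` map or a batch ``(N, H, W, C)``; label maps drop the channel
axis. Each loss has an analytic-gradient twin used by the trainer; values
are always reduced to a scalar float.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossWeights",
    "generalized_dice_loss",
    "generalized_dice_grad",
    "consistency_loss",
    "consistency_grad",
    "confidence_loss",
    "confidence_grad",
    "combine",
]

_EPS = 1e-8


@dataclass(frozen=True)
class LossWeights:
    """Non-negative weights of the three loss terms."""

    w_sup: float = 1.0
    w_cons: float = 0.1
    w_conf: float = 0.1

    def __post_init__(self) -> None:
        for name in ("w_sup", "w_cons", "w_conf"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


def _as_batch(pred: np.ndarray) -> np.ndarray:
    pred = np.asarray(pred, dtype=np.float64)
    if pred.ndim == 3:
        pred = pred[None]
    if pred.ndim != 4:
        raise ValueError(f"probability map must be (H,W,C) or (N,H,W,C), got {pred.shape}")
    return pred


def _one_hot(target: np.ndarray, classes: int) -> np.ndarray:
    target = np.asarray(target)
    if target.ndim == 2:
        target = target[None]
    if target.min() < 0 or target.max() >= classes:
        raise ValueError("target contains invalid class indices")
    return np.eye(classes, dtype=np.float64)[target]  # (N, H, W, C)


def generalized_dice_grad(pred, target, classes: int | None = None):
    """Generalized Dice loss and its gradient with respect to ``pred``.

    Per sample: ``1 - 2 (Σ_c w_c Σ_i p g) / (Σ_c w_c Σ_i (p + g))`` with
    ``w_c = 1 / (Σ_i g_ci)^2``; a class absent from the target gets weight
    0, which keeps the loss finite on slices missing a class. Batches are
    averaged per-sample.
    """
    pred = _as_batch(pred)
    if classes is None:
        classes = pred.shape[-1]
    g = _one_hot(target, classes)
    if g.shape != pred.shape:
        raise ValueError(f"pred shape {pred.shape} does not match target {g.shape}")
    n = pred.shape[0]
    vol = g.sum(axis=(1, 2))  # (N, C)
    w = np.where(vol > 0, 1.0 / np.maximum(vol, 1.0) ** 2, 0.0)  # (N, C)
    inter = (pred * g).sum(axis=(1, 2))  # (N, C)
    total = (pred + g).sum(axis=(1, 2))
    num = (w * inter).sum(axis=1)  # (N,)
    den = (w * total).sum(axis=1)
    loss = float(np.mean(1.0 - 2.0 * num / den))
    # dL_k/dp_ci = -2 (w_c g_ci den_k - num_k w_c) / den_k^2, averaged over k
    coef = w / den[:, None] ** 2  # (N, C)
    grad = -2.0 * (coef[:, None, None, :] * (g * den[:, None, None, None]
                                             - num[:, None, None, None])) / n
    return loss, grad


def generalized_dice_loss(pred, target, classes: int | None = None) -> float:
    """Generalized Dice overlap loss in [0, 1]; 0 iff prediction is the
    exact one-hot encoding of the target."""
    return generalized_dice_grad(pred, target, classes)[0]


def consistency_grad(strong, weak):
    """Symmetric MSE between two probability maps and its two gradients."""
    a = _as_batch(strong)
    b = _as_batch(weak)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    diff = a - b
    loss = float(np.mean(diff**2))
    g = 2.0 * diff / diff.size
    return loss, g, -g


def consistency_loss(strong, weak) -> float:
    """Mean squared difference over pixels and channels; 0 iff the branches
    agree exactly; symmetric in its arguments."""
    return consistency_grad(strong, weak)[0]


def confidence_grad(pred):
    """Normalized mean per-pixel entropy and its gradient."""
    p = _as_batch(pred)
    classes = p.shape[-1]
    n_pix = p.shape[0] * p.shape[1] * p.shape[2]
    pc = np.clip(p, _EPS, 1.0)
    log_p = np.log(pc)
    loss = float(-(pc * log_p).sum() / (n_pix * np.log(classes)))
    grad = -(log_p + 1.0) / (n_pix * np.log(classes))
    grad = np.where(p < _EPS, 0.0, grad)
    return loss, grad


def confidence_loss(pred) -> float:
    """Mean Shannon entropy of the per-pixel class distribution, divided by
    ln C: 0 iff every pixel is one-hot, 1 iff every pixel is uniform."""
    return confidence_grad(pred)[0]


def combine(sup: float, cons: float, conf: float, weights: LossWeights) -> float:
    """Weighted sum of the three loss terms."""
    terms = (sup, cons, conf)
    if not all(np.isfinite(t) for t in terms):
        raise ValueError(f"loss terms must be finite, got {terms}")
    return weights.w_sup * sup + weights.w_cons * cons + weights.w_conf * conf
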