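"""Two-phase label-refinement training.

Phase 1 (self-supervised warm-up): the dual-branch network is trained on
the weak labels alone, with only the supervised generalized-Dice term, to
give the shared encoder a usable feature representation.

Phase 2 (encoder-frozen fine-tuning): the encoder is frozen and the two
decoders are fine-tuned jointly — the strong decoder on the small trusted
set, the weak decoder on the large weak set — with the consistency and
confidence terms switched on. Every ``replace_interval`` epochs the weak
label maps are replaced by the strong decoder's argmax predictions
(pseudo-labels), so the weak set improves as training proceeds.

Ground truth, when supplied, is used only by evaluation callbacks that log
per-class DSC of the current weak revision; it never influences training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import SliceSample, as_sample_list
from .losses import (
    LossWeights,
    confidence_grad,
    consistency_grad,
    generalized_dice_grad,
)
from .metrics import MetricsReport, evaluate_set
from .model import DualBranchModel, freeze_encoder, parameter_checksum
from .nn import Adam, Tensor, softmax_channels
from .nn.tensor import no_grad

__all__ = [
    "TrainConfig",
    "RefinementRun",
    "pretrain",
    "finetune",
    "replace_weak_labels",
    "run_pipeline",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the two-phase schedule.

    ``loss_weights`` apply in phase 2 only; phase 1 uses the supervised
    term alone. ``ramp_epochs`` linearly ramps the consistency and
    confidence weights from 0 to their configured values over the first
    fine-tune epochs, which avoids early confirmation bias from an
    untrained strong decoder.
    """

    pretrain_epochs: int = 100
    finetune_epochs: int = 100
    replace_interval: int = 1
    batch_size: int = 4
    learning_rate: float = 1e-3
    loss_weights: LossWeights = field(default_factory=LossWeights)
    ramp_epochs: int = 10
    seed: int = 0
    replace_during_pretrain: bool = False
    pretrain_both_decoders: bool = True
    confidence_branch: str = "strong"

    def __post_init__(self) -> None:
        if self.pretrain_epochs < 0 or self.finetune_epochs < 0:
            raise ValueError("epoch counts must be >= 0")
        if self.replace_interval < 1:
            raise ValueError("replace_interval must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.confidence_branch not in ("strong", "weak", "both"):
            raise ValueError("confidence_branch must be strong | weak | both")


@dataclass
class RefinementRun:
    """Everything a refinement run produces."""

    model: DualBranchModel
    strong_set: list[SliceSample]
    weak_set: list[SliceSample]  # final weak revisions
    initial_weak: list[SliceSample]
    history: pd.DataFrame
    metrics: MetricsReport | None = None


# ---------------------------------------------------------------------------
# helpers

def _stack_images(samples: Sequence[SliceSample]) -> np.ndarray:
    return np.stack([s.image for s in samples])


def _stack_labels(samples: Sequence[SliceSample]) -> np.ndarray:
    return np.stack([s.labels for s in samples])


def _hwc(t: Tensor) -> np.ndarray:
    """Channel-last (N, H, W, C) tensor data as float64 for the losses."""
    return t.data.astype(np.float64)


def _seed_grad(t: Tensor, grad_hwc: np.ndarray) -> None:
    t.backward(grad_hwc)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


class _StrongCycler:
    """Endless seeded stream of strong-sample index batches."""

    def __init__(self, n: int, batch_size: int, rng: np.random.Generator) -> None:
        self.n, self.bs, self.rng = n, min(batch_size, n), rng
        self._queue: list[int] = []

    def next(self) -> np.ndarray:
        while len(self._queue) < self.bs:
            self._queue.extend(self.rng.permutation(self.n).tolist())
        out, self._queue = self._queue[: self.bs], self._queue[self.bs :]
        return np.asarray(out)


# ---------------------------------------------------------------------------
# phase 1

def pretrain(model: DualBranchModel, weak_set: Sequence[SliceSample],
             cfg: TrainConfig) -> DualBranchModel:
    """Self-supervised warm-up on weak labels only.

    Trains encoder + both decoders (by default) with the generalized-Dice
    data term; consistency and confidence are off in this phase. With
    ``pretrain_epochs = 0`` the model is returned untouched.
    """
    weak = as_sample_list(weak_set)
    if model.frozen_encoder:
        raise ValueError("pretrain requires an unfrozen encoder")
    if cfg.pretrain_epochs == 0:
        return model
    _phase1(model, list(weak), cfg, history=None)
    return model


def _phase1(model: DualBranchModel, weak: list[SliceSample], cfg: TrainConfig,
            history: list[dict] | None,
            truth: Sequence[SliceSample] | None = None) -> list[SliceSample]:
    images = _stack_images(weak)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n = len(weak)
    for epoch in range(cfg.pretrain_epochs):
        labels = _stack_labels(weak)
        epoch_losses = []
        for idx in _batches(n, cfg.batch_size, rng):
            strong_t, weak_t = model.forward_batch(images[idx])
            opt.zero_grad()
            lw, gw = generalized_dice_grad(_hwc(weak_t), labels[idx])
            _seed_grad(weak_t, gw)
            if cfg.pretrain_both_decoders:
                ls, gs = generalized_dice_grad(_hwc(strong_t), labels[idx])
                _seed_grad(strong_t, gs)
            else:
                ls = float("nan")
            opt.step()
            epoch_losses.append((ls, lw))
        replaced = False
        if cfg.replace_during_pretrain and (epoch + 1) % cfg.replace_interval == 0:
            weak = replace_weak_labels(model, weak)
            replaced = True
        if history is not None:
            row = _history_row("pretrain", epoch, epoch_losses, 0.0, 0.0, replaced)
            if truth is not None:
                row.update(_dsc_row(weak, truth))
            history.append(row)
    return weak


# ---------------------------------------------------------------------------
# phase 2

def finetune(model: DualBranchModel, strong_set: Sequence[SliceSample],
             weak_set: Sequence[SliceSample], cfg: TrainConfig,
             truth: Sequence[SliceSample] | None = None) -> RefinementRun:
    """Encoder-frozen mixed-supervision fine-tuning with iterative
    pseudo-label replacement.

    The encoder is frozen first and its checksum is asserted after every
    epoch. Because the frozen encoder maps each image to a constant
    feature tensor, encoder features are computed once and cached for the
    whole phase.
    """
    strong = as_sample_list(strong_set)
    weak = as_sample_list(weak_set)
    initial_weak = list(weak)
    freeze_encoder(model)
    enc_digest = parameter_checksum(model.encoder_parameters())

    dtype = model.dtype
    with no_grad():
        fw, sw = model.encode(Tensor(_stack_images(weak)[..., None].astype(dtype)))
        fs, ss = model.encode(Tensor(_stack_images(strong)[..., None].astype(dtype)))
    feat_weak, skips_weak = fw.data, tuple(t.data for t in sw)
    feat_strong, skips_strong = fs.data, tuple(t.data for t in ss)

    def _slice(skips: tuple[np.ndarray, ...], idx) -> tuple[Tensor, ...]:
        return tuple(Tensor(s[idx]) for s in skips)

    strong_labels = _stack_labels(strong)
    opt = Adam(model.decoder_parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    cycler = _StrongCycler(len(strong), cfg.batch_size, rng)
    w = cfg.loss_weights
    history: list[dict] = []

    for epoch in range(cfg.finetune_epochs):
        ramp = 1.0 if cfg.ramp_epochs <= 0 else min(1.0, (epoch + 1) / cfg.ramp_epochs)
        w_cons = w.w_cons * ramp
        w_conf = w.w_conf * ramp
        weak_labels = _stack_labels(weak)
        epoch_losses = []
        cons_vals, conf_vals = [], []
        for idx in _batches(len(weak), cfg.batch_size, rng):
            opt.zero_grad()
            # strong stream: trusted labels supervise the strong decoder
            sidx = cycler.next()
            s_probs = softmax_channels(
                model.strong_decoder(Tensor(feat_strong[sidx]), _slice(skips_strong, sidx))
            )
            ls, gs = generalized_dice_grad(_hwc(s_probs), strong_labels[sidx])
            _seed_grad(s_probs, w.w_sup * gs)
            # weak stream: weak labels supervise the weak decoder; the two
            # branches are tied by consistency; confidence sharpens the
            # strong branch on weakly labeled inputs
            feat = Tensor(feat_weak[idx])
            skips = _slice(skips_weak, idx)
            ws_probs = softmax_channels(model.strong_decoder(feat, skips))
            ww_probs = softmax_channels(model.weak_decoder(feat, skips))
            ws_hwc, ww_hwc = _hwc(ws_probs), _hwc(ww_probs)
            lw, gw = generalized_dice_grad(ww_hwc, weak_labels[idx])
            lcons, ga, gb = consistency_grad(ws_hwc, ww_hwc)
            g_ws = w_cons * ga
            g_ww = w.w_sup * gw + w_cons * gb
            lconf = 0.0
            if w.w_conf > 0:
                if cfg.confidence_branch in ("strong", "both"):
                    c, gc = confidence_grad(ws_hwc)
                    lconf += c
                    g_ws = g_ws + w_conf * gc
                if cfg.confidence_branch in ("weak", "both"):
                    c, gc = confidence_grad(ww_hwc)
                    lconf += c
                    g_ww = g_ww + w_conf * gc
            _seed_grad(ws_probs, g_ws)
            _seed_grad(ww_probs, g_ww)
            opt.step()
            epoch_losses.append((ls, lw))
            cons_vals.append(lcons)
            conf_vals.append(lconf)

        replaced = False
        if (epoch + 1) % cfg.replace_interval == 0:
            weak = _replace_from_features(model, weak, feat_weak, skips_weak)
            replaced = True
        if parameter_checksum(model.encoder_parameters()) != enc_digest:
            raise AssertionError("frozen encoder changed during fine-tuning")
        row = _history_row("finetune", epoch, epoch_losses,
                           float(np.mean(cons_vals)), float(np.mean(conf_vals)),
                           replaced)
        if truth is not None:
            row.update(_dsc_row(weak, truth))
        history.append(row)

    metrics = None
    if truth is not None:
        metrics = evaluate_set(weak, list(truth), weak[0].scheme)
    return RefinementRun(model=model, strong_set=strong, weak_set=weak,
                         initial_weak=initial_weak,
                         history=pd.DataFrame(history), metrics=metrics)


def _history_row(phase: str, epoch: int, sup_losses, cons: float, conf: float,
                 replaced: bool) -> dict:
    arr = np.asarray(sup_losses, dtype=np.float64)
    return dict(phase=phase, epoch=epoch,
                sup_strong=float(np.nanmean(arr[:, 0])),
                sup_weak=float(np.mean(arr[:, 1])),
                cons=cons, conf=conf, replaced=replaced)


def _dsc_row(weak: Sequence[SliceSample], truth: Sequence[SliceSample]) -> dict:
    report = evaluate_set(list(weak), list(truth), weak[0].scheme)
    return {f"dsc_{name}": stats.dsc_mean for name, stats in report.per_class.items()}


# ---------------------------------------------------------------------------
# pseudo-label replacement

def _argmax_labels(probs_nhwc: np.ndarray) -> np.ndarray:
    # np.argmax returns the first (lowest-index) maximum: deterministic ties
    return np.argmax(probs_nhwc, axis=-1).astype(np.int64)


def _replace_from_features(model: DualBranchModel, weak: list[SliceSample],
                           feat_weak: np.ndarray,
                           skips_weak: tuple[np.ndarray, ...] = ()) -> list[SliceSample]:
    with no_grad():
        skips = tuple(Tensor(s) for s in skips_weak)
        probs = softmax_channels(model.strong_decoder(Tensor(feat_weak), skips)).data
    labels = _argmax_labels(probs)
    return [s.with_labels(lab) for s, lab in zip(weak, labels)]


def replace_weak_labels(model: DualBranchModel,
                        weak_set: Sequence[SliceSample]) -> list[SliceSample]:
    """Replace every weak label map by the strong decoder's argmax.

    Provenance stays weak and images are untouched; the input revision is
    not mutated. Idempotent for a fixed model.
    """
    weak = as_sample_list(weak_set)
    out = []
    for s in weak:
        strong_probs, _ = model.forward(s.image)
        labels = np.argmax(strong_probs, axis=-1).astype(np.int64)
        out.append(s.with_labels(labels))
    return out


# ---------------------------------------------------------------------------
# end-to-end

def run_pipeline(raw_weak: Sequence[SliceSample], strong: Sequence[SliceSample],
                 cfg: TrainConfig, model: DualBranchModel | None = None,
                 truth: Sequence[SliceSample] | None = None) -> RefinementRun:
    """Warm-up, freeze, fine-tune: the full label-refinement pipeline.

    ``model`` defaults to a desk-scale dual-branch network seeded from the
    config. When ``truth`` is given the run's history carries per-epoch
    DSC of the weak revisions and the final report compares the refined
    labels against it.
    """
    from .model import build_model  # local import to avoid cycle at module load

    weak = as_sample_list(raw_weak)
    strong = as_sample_list(strong)
    if model is None:
        h, w = weak[0].shape
        model = build_model(channels=1, classes=weak[0].scheme.count,
                            width=8, depth=2, seed=cfg.seed)
    pre_history: list[dict] = []
    if cfg.pretrain_epochs > 0:
        weak = _phase1(model, weak, cfg, history=pre_history, truth=truth)
    run = finetune(model, strong, weak, cfg, truth=truth)
    run.initial_weak = list(raw_weak)
    if pre_history:
        run.history = pd.concat([pd.DataFrame(pre_history), run.history],
                                ignore_index=True)
    return run
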