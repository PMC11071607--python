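"""Per-class overlap metrics and set-level aggregation.

Three standard segmentation accuracy measures, reported as percentages:

* IoU  = |P ∩ T| / |P ∪ T|
* DSC  = 2 |P ∩ T| / (|P| + |T|)
* RVD  = | |P| − |T| | / |T|

Conventions for empty classes: if both prediction and truth lack the class
the slice is counted as perfect (100, 100, 0); if the truth lacks it but
the prediction does not, IoU and DSC are 0 and RVD is undefined (reported
as NaN and excluded from aggregation). Aggregation is per-slice mean ± SD
(sample SD, ddof=1) for each foreground class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ClassScheme, SliceSample

__all__ = ["ClassStats", "MetricsReport", "class_overlap", "evaluate_set"]


def class_overlap(pred: np.ndarray, truth: np.ndarray, class_index: int):
    """IoU, DSC and RVD (each in %) for one foreground class."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if class_index < 1:
        raise ValueError("class_index must be a foreground class (>= 1)")
    p = pred == class_index
    t = truth == class_index
    np_, nt = int(p.sum()), int(t.sum())
    if nt == 0:
        if np_ == 0:
            return 100.0, 100.0, 0.0
        return 0.0, 0.0, float("nan")
    inter = int((p & t).sum())
    union = np_ + nt - inter
    iou = 100.0 * inter / union
    dsc = 100.0 * 2.0 * inter / (np_ + nt)
    rvd = 100.0 * abs(np_ - nt) / nt
    return iou, dsc, rvd


@dataclass(frozen=True)
class ClassStats:
    """Mean ± SD of one metric triple over a sample set."""

    iou_mean: float
    iou_sd: float
    dsc_mean: float
    dsc_sd: float
    rvd_mean: float
    rvd_sd: float


@dataclass(frozen=True)
class MetricsReport:
    """Per-foreground-class aggregate metrics over matched sample pairs."""

    scheme: ClassScheme
    per_class: dict[str, ClassStats]
    per_sample: pd.DataFrame  # columns: sample_id, class, iou, dsc, rvd
    n_samples: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, s in self.per_class.items():
            rows.append(
                dict(class_name=name, iou_mean=s.iou_mean, iou_sd=s.iou_sd,
                     dsc_mean=s.dsc_mean, dsc_sd=s.dsc_sd,
                     rvd_mean=s.rvd_mean, rvd_sd=s.rvd_sd)
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "per_class": {
                name: dict(iou=[s.iou_mean, s.iou_sd], dsc=[s.dsc_mean, s.dsc_sd],
                           rvd=[s.rvd_mean, s.rvd_sd])
                for name, s in self.per_class.items()
            },
        }

    def dsc(self, class_name: str) -> float:
        return self.per_class[class_name].dsc_mean


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if values.size > 1 else 0.0


def evaluate_set(
    preds: Sequence[SliceSample],
    truths: Sequence[SliceSample],
    scheme: ClassScheme,
) -> MetricsReport:
    """Per-sample metrics, then mean ± SD per foreground class.

    Samples are matched by ``sample_id`` prefix-insensitively: a prediction
    whose id extends a truth id (e.g. revision suffixes) matches it. Counts
    must agree and every prediction must match exactly one truth.
    """
    if len(preds) != len(truths):
        raise ValueError(f"count mismatch: {len(preds)} predictions vs {len(truths)} truths")
    truth_by_id = {t.sample_id: t for t in truths}

    def match(p: SliceSample) -> SliceSample:
        if p.sample_id in truth_by_id:
            return truth_by_id[p.sample_id]
        hits = [t for tid, t in truth_by_id.items() if p.sample_id.startswith(tid)]
        if len(hits) != 1:
            raise ValueError(f"unmatched sample_id {p.sample_id!r} "
                             f"(truth ids: {sorted(truth_by_id)})")
        return hits[0]

    rows = []
    for p in preds:
        t = match(p)
        if p.labels.shape != t.labels.shape:
            raise ValueError(f"shape mismatch for sample {p.sample_id!r}")
        for cls in scheme.foreground:
            iou, dsc, rvd = class_overlap(p.labels, t.labels, cls)
            rows.append(dict(sample_id=p.sample_id, class_name=scheme.names[cls],
                             iou=iou, dsc=dsc, rvd=rvd))
    frame = pd.DataFrame(rows)
    per_class: dict[str, ClassStats] = {}
    for cls in scheme.foreground:
        name = scheme.names[cls]
        sub = frame[frame["class_name"] == name]
        rvd = sub["rvd"].dropna().to_numpy()
        per_class[name] = ClassStats(
            iou_mean=float(sub["iou"].mean()), iou_sd=_sd(sub["iou"].to_numpy()),
            dsc_mean=float(sub["dsc"].mean()), dsc_sd=_sd(sub["dsc"].to_numpy()),
            rvd_mean=float(rvd.mean()) if rvd.size else float("nan"),
            rvd_sd=_sd(rvd),
        )
    return MetricsReport(scheme=scheme, per_class=per_class,
                         per_sample=frame, n_samples=len(preds))
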