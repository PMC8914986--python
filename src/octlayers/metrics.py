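"""Evaluation protocol: Dice, boundary errors, pixel metrics, run aggregation.

The evaluation mirrors the study protocol for full-width B-scans: a fixed
number of columns is excluded at the left edge (poor tissue contrast, 100 px
by default) and at the right edge (optic nerve head, 300 px by default), so a
1534-wide image is scored over exactly 1134 columns.  Per-layer Dice overlap
is complemented by the clinically more relevant boundary errors: the
per-column difference between predicted and true boundary row (signed,
positive = predicted deeper in the image) and its absolute value, averaged
over evaluable columns.  Pixel accuracy, precision, recall and specificity
are computed one-vs-rest per class.  Repeated runs are summarized by their
mean and sample standard deviation.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phantom import BoundarySet
from .profiles import Profile, get_profile

__all__ = [
    "EvalConfig",
    "DiceReport",
    "BoundaryError",
    "BoundaryErrorReport",
    "ClassMetrics",
    "PixelMetricsReport",
    "RunAggregate",
    "EvaluationReport",
    "dice",
    "dice_report",
    "boundary_errors",
    "confusion_metrics",
    "aggregate_runs",
    "evaluate_report",
]


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation margins and run count.

    The defaults are tied to the nominal 1534 px width; use :meth:`scaled`
    to shrink them proportionally for other geometries.
    """

    exclude_left: int = 100
    exclude_right: int = 300
    runs: int = 4

    def __post_init__(self) -> None:
        if self.exclude_left < 0 or self.exclude_right < 0:
            raise ValueError("exclusion margins must be non-negative")
        if self.runs < 1:
            raise ValueError("runs must be positive")

    def columns(self, width: int) -> slice:
        if self.exclude_left + self.exclude_right >= width:
            raise ValueError(
                f"margins ({self.exclude_left}+{self.exclude_right}) leave no "
                f"columns of a {width}-wide image"
            )
        return slice(self.exclude_left, width - self.exclude_right)

    def n_columns(self, width: int) -> int:
        s = self.columns(width)
        return s.stop - s.start

    @classmethod
    def scaled(cls, width: int, reference_width: int = 1534, runs: int = 4) -> "EvalConfig":
        """Margins scaled proportionally from the nominal geometry."""
        f = width / reference_width
        return cls(
            exclude_left=int(round(100 * f)),
            exclude_right=int(round(300 * f)),
            runs=runs,
        )


def dice(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """Dice overlap 100 * 2|P∩G| / (|P|+|G|), in percent.

    Two empty masks score 100 (perfect agreement on absence) — a vanished
    foveal layer must not spuriously zero the score.
    """
    p = np.asarray(pred_mask, dtype=bool)
    g = np.asarray(gt_mask, dtype=bool)
    if p.shape != g.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {g.shape}")
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 100.0
    return 200.0 * int(np.logical_and(p, g).sum()) / denom


@dataclass
class DiceReport:
    """Per-layer Dice (%) plus two overall readings.

    ``overall`` is the Dice of the union of all layer classes (predicted
    union vs ground-truth union); ``per_layer_mean`` is the plain mean of the
    per-layer values.  Both are reported because an "overall" column admits
    either reading.
    """

    per_layer: dict[str, float]
    overall: float
    per_layer_mean: float


def dice_report(
    pred_labels: np.ndarray,
    gt_labels: np.ndarray,
    profile: str | Profile,
    cfg: EvalConfig | None = None,
) -> DiceReport:
    pred_labels = np.asarray(pred_labels)
    gt_labels = np.asarray(gt_labels)
    if pred_labels.shape != gt_labels.shape:
        raise ValueError("label map shapes differ")
    p = get_profile(profile)
    if cfg is not None:
        sl = cfg.columns(pred_labels.shape[1])
        pred_labels = pred_labels[:, sl]
        gt_labels = gt_labels[:, sl]
    per_layer = {
        name: dice(pred_labels == k + 1, gt_labels == k + 1)
        for k, name in enumerate(p.layer_names)
    }
    overall = dice(pred_labels > 0, gt_labels > 0)
    return DiceReport(
        per_layer=per_layer,
        overall=overall,
        per_layer_mean=float(np.mean(list(per_layer.values()))),
    )


@dataclass
class BoundaryError:
    signed: float
    absolute: float
    n_columns: int


@dataclass
class BoundaryErrorReport:
    """Mean signed/absolute boundary error (px) per boundary and averaged.

    Sign convention: predicted − ground truth; positive means the prediction
    sits deeper (larger row).  Columns where either trace is undefined are
    excluded, with the evaluable count reported per boundary; boundaries with
    no evaluable column carry NaN and are excluded from the averages.
    """

    per_boundary: dict[str, BoundaryError]
    mean_signed: float
    mean_absolute: float
    evaluated_columns: int


def boundary_errors(
    pred: BoundarySet, gt: BoundarySet, cfg: EvalConfig | None = None
) -> BoundaryErrorReport:
    if pred.profile != gt.profile:
        raise ValueError(f"profile mismatch: {pred.profile} vs {gt.profile}")
    if pred.width != gt.width:
        raise ValueError("boundary sets have different widths")
    cfg = cfg if cfg is not None else EvalConfig()
    sl = cfg.columns(pred.width)
    per_boundary: dict[str, BoundaryError] = {}
    signed_means, abs_means = [], []
    for j, name in enumerate(gt.boundary_names):
        diff = pred.traces[j, sl] - gt.traces[j, sl]
        valid = np.isfinite(diff)
        n = int(valid.sum())
        if n == 0:
            per_boundary[name] = BoundaryError(math.nan, math.nan, 0)
            continue
        signed = float(diff[valid].mean())
        absolute = float(np.abs(diff[valid]).mean())
        per_boundary[name] = BoundaryError(signed, absolute, n)
        signed_means.append(signed)
        abs_means.append(absolute)
    if not signed_means:
        raise ValueError("no boundary has any evaluable column")
    return BoundaryErrorReport(
        per_boundary=per_boundary,
        mean_signed=float(np.mean(signed_means)),
        mean_absolute=float(np.mean(abs_means)),
        evaluated_columns=cfg.n_columns(pred.width),
    )


@dataclass
class ClassMetrics:
    """One-vs-rest confusion metrics (%) for one class; None = undefined."""

    accuracy: float | None
    precision: float | None
    recall: float | None
    specificity: float | None
    tp: int
    fp: int
    fn: int
    tn: int


@dataclass
class PixelMetricsReport:
    per_class: dict[str, ClassMetrics]
    macro: dict[str, float]
    micro: dict[str, float]


def _safe_pct(num: int, den: int) -> float | None:
    return 100.0 * num / den if den > 0 else None


def confusion_metrics(
    pred_labels: np.ndarray,
    gt_labels: np.ndarray,
    cfg: EvalConfig | None = None,
    profile: str | Profile = "retinal7",
) -> PixelMetricsReport:
    """Pixel accuracy, precision, recall and specificity per class.

    Each layer class is scored one-vs-rest over the evaluated columns;
    ``macro`` averages the per-class percentages (undefined entries
    excluded), ``micro`` pools the confusion counts across classes first.
    TP+FP+FN+TN equals the evaluated pixel count for every class.
    """
    pred_labels = np.asarray(pred_labels)
    gt_labels = np.asarray(gt_labels)
    if pred_labels.shape != gt_labels.shape:
        raise ValueError("label map shapes differ")
    p = get_profile(profile)
    if cfg is not None:
        sl = cfg.columns(pred_labels.shape[1])
        pred_labels = pred_labels[:, sl]
        gt_labels = gt_labels[:, sl]
    per_class: dict[str, ClassMetrics] = {}
    totals = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    for k, name in enumerate(p.layer_names):
        pk = pred_labels == k + 1
        gk = gt_labels == k + 1
        tp = int(np.sum(pk & gk))
        fp = int(np.sum(pk & ~gk))
        fn = int(np.sum(~pk & gk))
        tn = int(np.sum(~pk & ~gk))
        per_class[name] = ClassMetrics(
            accuracy=_safe_pct(tp + tn, tp + fp + fn + tn),
            precision=_safe_pct(tp, tp + fp),
            recall=_safe_pct(tp, tp + fn),
            specificity=_safe_pct(tn, tn + fp),
            tp=tp,
            fp=fp,
            fn=fn,
            tn=tn,
        )
        for key, v in zip(("tp", "fp", "fn", "tn"), (tp, fp, fn, tn)):
            totals[key] += v
    macro = {}
    for metric in ("accuracy", "precision", "recall", "specificity"):
        vals = [
            getattr(m, metric) for m in per_class.values() if getattr(m, metric) is not None
        ]
        macro[metric] = float(np.mean(vals)) if vals else math.nan
    tp, fp, fn, tn = (totals[k] for k in ("tp", "fp", "fn", "tn"))

    def _or_nan(v: float | None) -> float:
        return v if v is not None else math.nan

    micro = {
        "accuracy": _or_nan(_safe_pct(tp + tn, tp + fp + fn + tn)),
        "precision": _or_nan(_safe_pct(tp, tp + fp)),
        "recall": _or_nan(_safe_pct(tp, tp + fn)),
        "specificity": _or_nan(_safe_pct(tn, tn + fp)),
    }
    return PixelMetricsReport(per_class=per_class, macro=macro, micro=micro)


@dataclass
class RunAggregate:
    """Mean and sample (n−1) standard deviation over independent runs."""

    mean: float
    sd: float
    n: int


def aggregate_runs(values: Sequence[float]) -> RunAggregate:
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("at least two runs are required to estimate a spread")
    return RunAggregate(
        mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=int(arr.size)
    )


# ---------------------------------------------------------------------------
# Combined per-image / aggregated reporting


@dataclass
class ImageEvaluation:
    image_id: str
    dice: DiceReport
    boundary: BoundaryErrorReport
    pixels: PixelMetricsReport


@dataclass
class EvaluationReport:
    per_image: dict[str, ImageEvaluation]
    aggregate: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for image_id, ev in self.per_image.items():
            row: dict = {"image_id": image_id, "dice_overall": ev.dice.overall}
            for name, v in ev.dice.per_layer.items():
                row[f"dice_{name}"] = v
            row["boundary_mean_signed"] = ev.boundary.mean_signed
            row["boundary_mean_absolute"] = ev.boundary.mean_absolute
            for name, be in ev.boundary.per_boundary.items():
                row[f"signed_{name}"] = be.signed
                row[f"absolute_{name}"] = be.absolute
            for metric, v in ev.pixels.macro.items():
                row[f"macro_{metric}"] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "aggregate": self.aggregate,
            "per_image": {
                k: self.to_frame().set_index("image_id").loc[k].to_dict()
                for k in self.per_image
            },
        }
        path.write_text(json.dumps(payload, indent=2, default=float))
        return path


def evaluate_report(
    predictions: Mapping[str, tuple[np.ndarray, BoundarySet]],
    ground_truth: Mapping[str, tuple[np.ndarray, BoundarySet]],
    profile: str | Profile,
    cfg: EvalConfig | None = None,
) -> EvaluationReport:
    """Evaluate predicted (label map, boundaries) against ground truth per image.

    Both mappings are keyed by image id and must cover the same ids; the
    offenders are listed otherwise.  The aggregate block averages the main
    scalar metrics over images.
    """
    cfg = cfg if cfg is not None else EvalConfig()
    missing = sorted(set(ground_truth) ^ set(predictions))
    if missing:
        raise ValueError(f"image id mismatch between bundles: {missing}")
    per_image: dict[str, ImageEvaluation] = {}
    for image_id in sorted(ground_truth):
        pred_labels, pred_bounds = predictions[image_id]
        gt_labels, gt_bounds = ground_truth[image_id]
        per_image[image_id] = ImageEvaluation(
            image_id=image_id,
            dice=dice_report(pred_labels, gt_labels, profile, cfg),
            boundary=boundary_errors(pred_bounds, gt_bounds, cfg),
            pixels=confusion_metrics(pred_labels, gt_labels, cfg, profile),
        )
    aggregate = {
        "dice_overall": float(np.mean([e.dice.overall for e in per_image.values()])),
        "dice_per_layer_mean": float(
            np.mean([e.dice.per_layer_mean for e in per_image.values()])
        ),
        "boundary_mean_signed": float(
            np.mean([e.boundary.mean_signed for e in per_image.values()])
        ),
        "boundary_mean_absolute": float(
            np.mean([e.boundary.mean_absolute for e in per_image.values()])
        ),
        "macro_recall": float(
            np.mean([e.pixels.macro["recall"] for e in per_image.values()])
        ),
        "macro_precision": float(
            np.mean([e.pixels.macro["precision"] for e in per_image.values()])
        ),
        "n_images": len(per_image),
    }
    return EvaluationReport(per_image=per_image, aggregate=aggregate)
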