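"""Pixel-wise and instance-level segmentation evaluation.

Pixel metrics (Dice similarity coefficient, sensitivity, precision) are
derived from a multiclass confusion matrix; instance metrics use
same-class matching at an intersection-over-union criterion of 0.5 and
the panoptic quality trio: recognition quality RQ = TP/(TP + FP/2 +
FN/2) (the harmonic mean of precision and recall), segmentation quality
SQ = mean IoU over matched pairs, and PQ = SQ * RQ.

Confusion matrices and match counts are summed globally across all
images before any ratio is computed, so every particle counts equally
whether it sits in a dense or a sparse micrograph; global aggregation
is deliberately not the mean of per-image scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

__all__ = [
    "ConfusionMatrix",
    "MatchResult",
    "MetricsReport",
    "pixel_confusion",
    "pixel_scores",
    "instance_components",
    "match_instances",
    "match_label_maps",
    "panoptic_scores",
    "evaluate_dataset",
]

N_CLASSES = 6  # foreground classes; label 0 is background


@dataclass
class ConfusionMatrix:
    """(K+1)x(K+1) joint label counts; rows = truth, columns = prediction."""

    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((N_CLASSES + 1, N_CLASSES + 1), np.int64))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, np.int64)
        expect = (N_CLASSES + 1, N_CLASSES + 1)
        if self.counts.shape != expect:
            raise ValueError(f"confusion matrix must be {expect}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())


def pixel_confusion(gt: np.ndarray, pred: np.ndarray,
                    mask: np.ndarray | None = None) -> ConfusionMatrix:
    """Joint (truth, prediction) label counts, optionally under a mask."""
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
    if mask is not None:
        gt, pred = gt[mask], pred[mask]
    for name, arr in (("gt", gt), ("pred", pred)):
        if arr.size and (arr.min() < 0 or arr.max() > N_CLASSES):
            raise ValueError(f"{name} labels must lie in 0..{N_CLASSES}")
    k = N_CLASSES + 1
    joint = np.bincount(gt.ravel().astype(np.int64) * k + pred.ravel(),
                        minlength=k * k)[:k * k]
    return ConfusionMatrix(joint.reshape(k, k))


def pixel_scores(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class DSC, sensitivity and precision from a confusion matrix.

    A class absent from both truth and prediction has no defined score
    (0/0): its row carries NaN and is excluded from macro means.
    """
    c = cm.counts
    rows = []
    for k in range(1, N_CLASSES + 1):
        tp = c[k, k]
        fn = c[k, :].sum() - tp
        fp = c[:, k].sum() - tp
        rows.append({
            "class": k,
            "dsc": 2 * tp / (2 * tp + fp + fn) if tp + fp + fn else np.nan,
            "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
            "precision": tp / (tp + fp) if tp + fp else np.nan,
        })
    return pd.DataFrame(rows).set_index("class")


def instance_components(labels: np.ndarray, connectivity: int = 8
                        ) -> tuple[np.ndarray, dict[int, int]]:
    """Approximate instances as foreground connected components.

    Returns an instance-id raster (0 = background) and a map from
    instance id to its (majority) class.
    """
    labels = np.asarray(labels)
    comps, n = cc_label(labels > 0, connectivity=1 if connectivity == 4 else 2,
                        return_num=True)
    id2class: dict[int, int] = {}
    for cid in range(1, n + 1):
        vals = labels[comps == cid]
        counts = np.bincount(vals, minlength=N_CLASSES + 1)
        counts[0] = 0
        id2class[cid] = int(np.argmax(counts))
    return comps, id2class


@dataclass
class MatchResult:
    """Globally summable instance-matching outcome, per class."""

    tp: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES + 1, np.int64))
    fp: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES + 1, np.int64))
    fn: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES + 1, np.int64))
    iou_sum: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES + 1))
    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    unmatched_gt: list[int] = field(default_factory=list)
    unmatched_pred: list[int] = field(default_factory=list)

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(self.tp + other.tp, self.fp + other.fp,
                           self.fn + other.fn, self.iou_sum + other.iou_sum)


def match_instances(gt_inst: np.ndarray, gt_classes: dict[int, int],
                    pred_inst: np.ndarray, pred_classes: dict[int, int],
                    iou_threshold: float = 0.5) -> MatchResult:
    """Match same-class instances with IoU strictly above the threshold.

    For thresholds of at least 0.5 each instance can overlap at most one
    counterpart that strongly, so the matching is unique without any
    assignment search.  Unmatched ground-truth instances are false
    negatives, unmatched predictions false positives.
    """
    gt_inst = np.asarray(gt_inst)
    pred_inst = np.asarray(pred_inst)
    if gt_inst.shape != pred_inst.shape:
        raise ValueError("instance rasters must share a shape")
    gt_areas = np.bincount(gt_inst.ravel())
    pred_areas = np.bincount(pred_inst.ravel())
    both = (gt_inst > 0) & (pred_inst > 0)
    n_pred = pred_inst.max() + 1
    codes = gt_inst[both].astype(np.int64) * n_pred + pred_inst[both]
    pair_codes, inter = np.unique(codes, return_counts=True)

    result = MatchResult()
    matched_gt: set[int] = set()
    matched_pred: set[int] = set()
    for code, i in zip(pair_codes, inter):
        g, p = int(code // n_pred), int(code % n_pred)
        if gt_classes.get(g) != pred_classes.get(p):
            continue
        union = gt_areas[g] + pred_areas[p] - i
        iou = i / union
        if iou > iou_threshold:
            cls = gt_classes[g]
            result.tp[cls] += 1
            result.iou_sum[cls] += iou
            result.pairs.append((g, p, float(iou)))
            matched_gt.add(g)
            matched_pred.add(p)
    for g, cls in gt_classes.items():
        if g not in matched_gt:
            result.fn[cls] += 1
            result.unmatched_gt.append(g)
    for p, cls in pred_classes.items():
        if p not in matched_pred:
            result.fp[cls] += 1
            result.unmatched_pred.append(p)
    return result


def match_label_maps(gt_labels: np.ndarray, pred_labels: np.ndarray,
                     iou_threshold: float = 0.5) -> MatchResult:
    """Convenience: derive instances from two semantic maps and match them."""
    gi, gc = instance_components(gt_labels)
    pi, pc = instance_components(pred_labels)
    return match_instances(gi, gc, pi, pc, iou_threshold)


def panoptic_scores(match: MatchResult) -> pd.DataFrame:
    """Per-class PQ, SQ and RQ from globally summed TP/FP/FN.

    SQ is the mean IoU over matched pairs only; classes with no
    instances at all (TP=FP=FN=0) carry NaN and are excluded from
    macro means.  PQ = SQ * RQ holds exactly wherever TP > 0.
    """
    rows = []
    for k in range(1, N_CLASSES + 1):
        tp, fp, fn = int(match.tp[k]), int(match.fp[k]), int(match.fn[k])
        if tp + fp + fn == 0:
            rq = sq = pq = np.nan
        else:
            rq = tp / (tp + 0.5 * fp + 0.5 * fn)
            sq = match.iou_sum[k] / tp if tp else 0.0
            pq = sq * rq
        rows.append({"class": k, "pq": pq, "sq": sq, "rq": rq,
                     "tp": tp, "fp": fp, "fn": fn})
    return pd.DataFrame(rows).set_index("class")


@dataclass
class MetricsReport:
    """Aggregated evaluation of a gt/pred dataset."""

    pixel: pd.DataFrame
    panoptic: pd.DataFrame
    confusion: ConfusionMatrix
    match: MatchResult
    n_images: int
    provenance: dict = field(default_factory=dict)

    @property
    def mean_dsc(self) -> float:
        return float(self.pixel["dsc"].mean())

    @property
    def mean_rq(self) -> float:
        return float(self.panoptic["rq"].mean())

    def summary(self) -> dict:
        return {
            "n_images": self.n_images,
            "mean_dsc": _nan_none(self.pixel["dsc"].mean()),
            "mean_sensitivity": _nan_none(self.pixel["sensitivity"].mean()),
            "mean_precision": _nan_none(self.pixel["precision"].mean()),
            "mean_pq": _nan_none(self.panoptic["pq"].mean()),
            "mean_sq": _nan_none(self.panoptic["sq"].mean()),
            "mean_rq": _nan_none(self.panoptic["rq"].mean()),
            "per_class": {
                str(k): {
                    **{m: _nan_none(self.pixel.loc[k, m])
                       for m in ("dsc", "sensitivity", "precision")},
                    **{m: _nan_none(self.panoptic.loc[k, m])
                       for m in ("pq", "sq", "rq")},
                    **{m: int(self.panoptic.loc[k, m])
                       for m in ("tp", "fp", "fn")},
                }
                for k in self.pixel.index
            },
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2,
                                         sort_keys=True) + "\n")

    def to_csv(self, path: str | Path) -> None:
        table = self.pixel.join(self.panoptic)
        table.to_csv(path, float_format="%.6f")


def _nan_none(x):
    x = float(x)
    return None if np.isnan(x) else x


def evaluate_dataset(gt_items, pred_items, iou_threshold: float = 0.5,
                     masks=None, provenance: dict | None = None) -> MetricsReport:
    """Globally aggregated pixel and panoptic metrics over paired rasters.

    ``gt_items`` and ``pred_items`` are equally long sequences of label
    rasters (arrays) or paths readable by :func:`emcaps.io.read_labels`.
    Confusions and match counts are summed over all pairs before any
    metric is computed.
    """
    from . import io as eio

    gt_items = list(gt_items)
    pred_items = list(pred_items)
    if len(gt_items) != len(pred_items):
        raise ValueError(
            f"unpaired files: {len(gt_items)} ground-truth vs "
            f"{len(pred_items)} prediction items")
    if masks is None:
        masks = [None] * len(gt_items)

    def load(x):
        return eio.read_labels(x) if isinstance(x, (str, Path)) else np.asarray(x)

    cm = ConfusionMatrix()
    match = MatchResult()
    for gt, pred, mask in zip(gt_items, pred_items, masks):
        gt, pred = load(gt), load(pred)
        cm = cm + pixel_confusion(gt, pred, mask)
        match = match + match_label_maps(gt, pred, iou_threshold)
    return MetricsReport(pixel=pixel_scores(cm), panoptic=panoptic_scores(match),
                         confusion=cm, match=match, n_images=len(gt_items),
                         provenance=provenance or {})
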