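"""Semantic segmentation: probability stacks, argmax maps and postprocessing.

The reference engine is a deterministic matched filter: each barcode
class is detected by normalized cross-correlation with its rotationally
symmetric contrast template, detections are resolved into per-class
probability channels, and the standard multistep postprocessing is then
applied to the argmax label map:

1. binarize the class channels into a foreground mask,
2. connected-component analysis on the binarized mask,
3. remove components with fewer than 42 pixels,
4. conditional majority voting per component (area below 500 px,
   circularity above 0.2, no tie),
5. fill background holes completely surrounded by a single class.

An optional trainable per-pixel engine with the same predict contract
lives in :mod:`emcaps.train`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import match_template, peak_local_max
from skimage.measure import label as cc_label

from .core import (
    BACKGROUND_LABEL,
    PATTERN_LABEL,
    BarcodeClass,
    ContrastTemplate,
    Micrograph,
    PixelScale,
    class_templates,
)

__all__ = [
    "PostprocessParams",
    "MatchedFilterEngine",
    "normalize_percentile",
    "matched_filter_predict",
    "sliding_window_predict",
    "argmax_map",
    "postprocess",
]

N_CHANNELS = 8  # background + 6 classes + pattern

_QT_CLASSES = (BarcodeClass.QT_1M, BarcodeClass.QT_2M, BarcodeClass.QT_3M)
_TM_CLASSES = (BarcodeClass.TM_1M,)


def _paint_disk(channel: np.ndarray, pr: int, pc: int, r_px: float,
                value: float) -> None:
    """Max-composite a constant disk of ``value`` into a channel in place."""
    h, w = channel.shape
    r0, r1 = max(0, int(pr - r_px) - 1), min(h, int(pr + r_px) + 2)
    c0, c1 = max(0, int(pc - r_px) - 1), min(w, int(pc + r_px) + 2)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - pr
    cc = np.arange(c0, c1)[None, :] - pc
    m = (rr * rr + cc * cc) <= r_px * r_px
    sub = channel[r0:r1, c0:c1]
    np.maximum(sub, np.where(m, value, 0.0), out=sub)


def normalize_percentile(raster: np.ndarray, lo_pct: float = 0.5,
                         hi_pct: float = 99.5) -> np.ndarray:
    """Percentile normalization: clip to [P_lo, P_hi] and map to [0, 1].

    Constant rasters map to all zeros.
    """
    raster = np.asarray(raster, float)
    if raster.size == 0:
        raise ValueError("empty raster")
    if lo_pct >= hi_pct:
        raise ValueError(f"lo percentile must be < hi ({lo_pct} >= {hi_pct})")
    lo, hi = np.percentile(raster, [lo_pct, hi_pct])
    if hi <= lo:
        return np.zeros_like(raster)
    return (np.clip(raster, lo, hi) - lo) / (hi - lo)


@dataclass(frozen=True)
class PostprocessParams:
    """Thresholds of the multistep label-map refinement."""

    min_component_px: int = 42
    majority_max_px: int = 500
    majority_min_circularity: float = 0.2
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.min_component_px < 1:
            raise ValueError("min_component_px must be >= 1")
        if not 0.0 <= self.majority_min_circularity <= 1.0:
            raise ValueError("circularity threshold must lie in [0, 1]")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def skimage_connectivity(self) -> int:
        return 1 if self.connectivity == 4 else 2


class MatchedFilterEngine:
    """Deterministic reference engine based on template matching.

    For each class the (percentile-normalized) raster is cross-correlated
    with a 2D rotation of the class contrast template.  Candidate
    particle centers are local maxima of the best per-class correlation;
    each accepted center paints a soft disk of its winning class's outer
    radius into that class channel.  The background channel is the
    complement of the strongest class evidence, and the pattern channel
    marks local co-occurrence of Qt and Tm responses within
    ``pattern_radius_nm``.  Channels are normalized to sum to one.
    """

    def __init__(self,
                 templates: dict[BarcodeClass, ContrastTemplate] | None = None,
                 scale: PixelScale | None = None,
                 peak_threshold: float = 0.35,
                 pattern_radius_nm: float = 80.0):
        self.scale = scale or PixelScale()
        self.templates = templates or class_templates(self.scale)
        if set(self.templates) != set(BarcodeClass):
            raise ValueError("templates must cover all six classes")
        self.peak_threshold = peak_threshold
        self.pattern_radius_nm = pattern_radius_nm
        self._kernels = {cls: t.kernel(self.scale)
                         for cls, t in self.templates.items()}

    def outer_radius_px(self, cls: BarcodeClass) -> float:
        return self.templates[cls].outer_radius_nm / self.scale.nm_per_pixel

    def predict(self, raster: np.ndarray | Micrograph) -> np.ndarray:
        if isinstance(raster, Micrograph):
            raster = raster.pixels
        raster = np.asarray(raster, float)
        img = normalize_percentile(raster)
        h, w = img.shape
        for k in self._kernels.values():
            if k.shape[0] > h or k.shape[1] > w:
                raise ValueError("template kernel larger than raster")
        ncc = np.zeros((6, h, w))
        for cls, kern in self._kernels.items():
            with np.errstate(invalid="ignore", divide="ignore"):
                r = match_template(img, kern, pad_input=True)
            ncc[int(cls) - 1] = np.nan_to_num(r)

        best = ncc.max(axis=0)
        min_r = min(self.outer_radius_px(c) for c in BarcodeClass)
        peaks = peak_local_max(best, min_distance=max(1, int(min_r)),
                               threshold_abs=self.peak_threshold,
                               exclude_border=False)
        stack = np.zeros((N_CHANNELS, h, w))
        detections: list[tuple[BarcodeClass, int, int, float]] = []
        for pr, pc in peaks:
            scores = ncc[:, pr, pc]
            k = int(np.argmax(scores))
            cls = BarcodeClass(k + 1)
            s = float(np.clip(scores[k], 0.0, 1.0))
            detections.append((cls, int(pr), int(pc), s))
            _paint_disk(stack[k + 1], pr, pc, self.outer_radius_px(cls), s)

        class_max = stack[1:7].max(axis=0)
        stack[BACKGROUND_LABEL] = np.clip(1.0 - class_max, 0.0, 1.0)
        stack[PATTERN_LABEL] = self._pattern_channel((h, w), detections)
        stack /= stack.sum(axis=0, keepdims=True)
        return stack

    def _pattern_channel(self, shape: tuple[int, int],
                         detections) -> np.ndarray:
        """Co-occurrence of Qt and Tm detections within the pattern radius."""
        r_px = self.pattern_radius_nm / self.scale.nm_per_pixel
        qt = np.zeros(shape)
        tm = np.zeros(shape)
        for cls, pr, pc, s in detections:
            if cls in _QT_CLASSES:
                _paint_disk(qt, pr, pc, r_px, s)
            elif cls in _TM_CLASSES:
                _paint_disk(tm, pr, pc, r_px, s)
        return np.minimum(qt, tm)


def matched_filter_predict(
    raster: np.ndarray | Micrograph,
    templates: dict[BarcodeClass, ContrastTemplate] | None = None,
    scale: PixelScale | None = None,
    **engine_kwargs,
) -> np.ndarray:
    """One-shot matched-filter prediction; see :class:`MatchedFilterEngine`."""
    if isinstance(raster, Micrograph) and scale is None:
        scale = raster.scale
    return MatchedFilterEngine(templates, scale, **engine_kwargs).predict(raster)


def sliding_window_predict(
    engine,
    raster: np.ndarray | Micrograph,
    window_px: int = 512,
    overlap: float = 0.5,
    batch_size: int = 32,
    tta: bool = False,
    tta_noise_sigma: float = 0.01,
    seed: int = 0,
) -> np.ndarray:
    """Tiled inference with uniform blending of overlapping windows.

    Test-time augmentation averages the probability stacks of the four
    flip variants plus one Gaussian-noise-perturbed pass (sigma given as
    a fraction of the raster's dynamic range, seeded).  ``batch_size``
    is accepted for interface parity; the reference engine is not
    batched.
    """
    del batch_size
    if isinstance(raster, Micrograph):
        raster = raster.pixels
    raster = np.asarray(raster, float)
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must lie in [0, 1), got {overlap}")
    h, w = raster.shape

    def run(img: np.ndarray) -> np.ndarray:
        ph, pw = max(0, window_px - img.shape[0]), max(0, window_px - img.shape[1])
        padded = np.pad(img, ((0, ph), (0, pw)), mode="reflect") if ph or pw else img
        hh, ww = padded.shape
        stride = max(1, int(round(window_px * (1.0 - overlap))))
        acc = np.zeros((N_CHANNELS, hh, ww))
        weight = np.zeros((hh, ww))
        rows = _tile_starts(hh, window_px, stride)
        cols = _tile_starts(ww, window_px, stride)
        for r0 in rows:
            for c0 in cols:
                tile = padded[r0:r0 + window_px, c0:c0 + window_px]
                acc[:, r0:r0 + window_px, c0:c0 + window_px] += engine.predict(tile)
                weight[r0:r0 + window_px, c0:c0 + window_px] += 1.0
        acc /= weight
        return acc[:, :img.shape[0], :img.shape[1]]

    if not tta:
        return run(raster)

    stacks = []
    for flip_r, flip_c in ((False, False), (True, False), (False, True), (True, True)):
        img = raster[::-1] if flip_r else raster
        img = img[:, ::-1] if flip_c else img
        s = run(np.ascontiguousarray(img))
        s = s[:, ::-1] if flip_r else s
        s = s[:, :, ::-1] if flip_c else s
        stacks.append(s)
    rng = np.random.default_rng(seed)
    dyn = float(raster.max() - raster.min()) or 1.0
    noisy = raster + rng.normal(0.0, tta_noise_sigma * dyn, raster.shape)
    stacks.append(run(noisy))
    return np.mean(stacks, axis=0)


def _tile_starts(size: int, window: int, stride: int) -> list[int]:
    starts = list(range(0, max(size - window, 0) + 1, stride))
    if starts[-1] != size - window:
        starts.append(size - window)
    return starts


def argmax_map(stack: np.ndarray, mode: str = "six") -> np.ndarray:
    """Label raster from a probability stack.

    ``mode='six'``: per-pixel argmax over the six class channels, with
    the background label assigned wherever the background channel is at
    least as large as every class channel (ties resolve to background;
    class ties resolve to the lowest channel index).  ``mode='eight'``
    takes the argmax over background plus the six class channels
    directly.  The pattern channel never participates and remains
    available as ``stack[7]``.
    """
    if stack.ndim != 3 or stack.shape[0] != N_CHANNELS:
        raise ValueError(f"expected stack of {N_CHANNELS} channels")
    if mode == "six":
        cls = np.argmax(stack[1:7], axis=0).astype(np.uint8) + 1
        cls_max = stack[1:7].max(axis=0)
        cls[stack[BACKGROUND_LABEL] >= cls_max] = BACKGROUND_LABEL
        return cls
    if mode == "eight":
        return np.argmax(stack[:7], axis=0).astype(np.uint8)
    raise ValueError(f"unknown argmax mode {mode!r}")


def postprocess(labels: np.ndarray, params: PostprocessParams | None = None) -> np.ndarray:
    """Multistep conservative refinement of a multiclass label map.

    Executes, in order: foreground binarization, connected-component
    analysis, removal of components below ``min_component_px``,
    conditional per-component majority voting (component area strictly
    below ``majority_max_px``, circularity strictly above
    ``majority_min_circularity`` and a unique majority class), and
    single-class hole filling.  Idempotent, and never introduces a class
    absent from the component it modifies.
    """
    from .instances import circularity  # shared perimeter estimator

    params = params or PostprocessParams()
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("label raster must be 2D")
    if labels.min() < 0 or labels.max() > 6:
        raise ValueError("labels must lie in 0..6")
    out = labels.astype(np.uint8).copy()

    # (1)-(2) binarize and run connected components
    fg = out > 0
    comps, n = cc_label(fg, connectivity=params.skimage_connectivity,
                        return_num=True)
    if n == 0:
        return out
    areas = np.bincount(comps.ravel())

    # (3) remove small particles
    small = np.flatnonzero(areas < params.min_component_px)
    small = small[small > 0]
    if len(small):
        kill = np.isin(comps, small)
        out[kill] = 0
        comps[kill] = 0

    # (4) conditional majority voting
    objects = ndimage.find_objects(comps)
    for cid, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        area = areas[cid]
        if area < params.min_component_px or area >= params.majority_max_px:
            continue
        mask = comps[sl] == cid
        counts = np.bincount(out[sl][mask], minlength=7)
        counts[0] = 0
        top = counts.max()
        if top == area and np.count_nonzero(counts == top) == 1:
            continue  # already single-class
        if np.count_nonzero(counts == top) != 1:
            continue  # tie: refrain from voting
        if circularity(mask) <= params.majority_min_circularity:
            continue
        out[sl][mask] = int(np.argmax(counts))

    # (5) fill holes fully surrounded by one class
    bg = out == 0
    # complement connectivity: 8-connected foreground implies 4-connected holes
    hole_conn = 1 if params.connectivity == 8 else 2
    holes, nh = cc_label(bg, connectivity=hole_conn, return_num=True)
    if nh:
        border = np.zeros_like(bg)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        open_ids = set(np.unique(holes[border & bg]).tolist())
        footprint = np.ones((3, 3), bool)
        hole_objs = ndimage.find_objects(holes)
        for hid, sl in enumerate(hole_objs, start=1):
            if sl is None or hid in open_ids:
                continue
            sl = tuple(slice(max(0, s.start - 1), s.stop + 1) for s in sl)
            hmask = holes[sl] == hid
            ring = ndimage.binary_dilation(hmask, footprint) & ~hmask
            ring_labels = np.unique(out[sl][ring])
            ring_labels = ring_labels[ring_labels > 0]
            if len(ring_labels) == 1 and not np.any(out[sl][ring] == 0):
                out[sl][hmask] = int(ring_labels[0])
    return out
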