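"""Fluorescent-frame segmentation and automated-vs-reference validation.

A transparent, deterministic replacement for an interactive segmentation
pipeline: Gaussian smoothing, global thresholding (Otsu or fixed), hole
filling, small-object removal, optional border clearing, and connected-
component labelling. Touching-cell declumping is deliberately absent: the
imaging design keeps labelled cells sparse, so merged objects are simply
large objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation as sk_seg

from .synthetic import FrameImage

__all__ = ["SegmentationConfig", "LabelMask", "segment_frame",
           "validate_segmentation", "ValidationResult"]


@dataclass(frozen=True)
class SegmentationConfig:
    smooth_sigma_px: float = 1.0
    threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float = 0.0    # used when threshold_method == "fixed"
    min_area_px: int = 50
    clear_border: bool = False
    connectivity: int = 8           # 4 or 8

    def __post_init__(self):
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if self.smooth_sigma_px < 0:
            raise ValueError("smooth_sigma_px must be >= 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class LabelMask:
    """Labelled objects of one frame (0 = background, 1..n = objects)."""

    labels: np.ndarray
    frame_ref: str = ""
    connectivity: int = 8
    warning: str | None = None  # e.g. constant image under Otsu

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


def segment_frame(image: FrameImage | np.ndarray,
                  config: SegmentationConfig = SegmentationConfig(),
                  frame_ref: str = "") -> LabelMask:
    """Segment one single-channel frame into a :class:`LabelMask`.

    A constant image under Otsu thresholding yields an empty mask with a
    warning flag rather than an exception.
    """
    pixels = image.pixels if isinstance(image, FrameImage) else np.asarray(image, float)
    if pixels.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if np.any(pixels < 0):
        raise ValueError("intensities must be non-negative")
    smoothed = (ndimage.gaussian_filter(pixels, config.smooth_sigma_px)
                if config.smooth_sigma_px > 0 else pixels)
    warning = None
    if config.threshold_method == "otsu":
        if np.ptp(smoothed) == 0:
            return LabelMask(np.zeros(pixels.shape, np.int32), frame_ref,
                             config.connectivity, warning="constant image: no threshold")
        thr = filters.threshold_otsu(smoothed)
    else:
        thr = config.fixed_threshold
    fg = smoothed > thr
    fg = ndimage.binary_fill_holes(fg)
    conn = 1 if config.connectivity == 4 else 2
    # keep objects of at least min_area_px pixels
    fg = morphology.remove_small_objects(fg, max_size=config.min_area_px - 1,
                                         connectivity=conn)
    if config.clear_border:
        fg = sk_seg.clear_border(fg)
    labels = measure.label(fg, connectivity=conn).astype(np.int32)
    return LabelMask(labels, frame_ref, config.connectivity, warning)


@dataclass
class ValidationResult:
    """Object-level agreement between a predicted and a reference mask."""

    matches: pd.DataFrame          # columns: predicted_label, truth_label, iou
    unmatched_predicted: list[int]
    unmatched_truth: list[int]
    count_difference: int          # n_predicted - n_truth

    @property
    def mean_iou(self) -> float:
        return float(self.matches["iou"].mean()) if len(self.matches) else float("nan")


def validate_segmentation(predicted: LabelMask | np.ndarray,
                          truth: LabelMask | np.ndarray) -> ValidationResult:
    """Match predicted to reference objects and score intersection-over-union.

    Objects are matched greedily by decreasing pixel overlap, one-to-one;
    the result is invariant to label renumbering of either mask.
    """
    pred = predicted.labels if isinstance(predicted, LabelMask) else np.asarray(predicted)
    tru = truth.labels if isinstance(truth, LabelMask) else np.asarray(truth)
    if pred.shape != tru.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {tru.shape}")
    p_labels = [int(v) for v in np.unique(pred) if v != 0]
    t_labels = [int(v) for v in np.unique(tru) if v != 0]
    p_sizes = {l: int(np.sum(pred == l)) for l in p_labels}
    t_sizes = {l: int(np.sum(tru == l)) for l in t_labels}
    both = (pred != 0) & (tru != 0)
    overlaps: dict[tuple[int, int], int] = {}
    if both.any():
        pairs, counts = np.unique(
            np.stack([pred[both], tru[both]]), axis=1, return_counts=True)
        overlaps = {(int(p), int(t)): int(c)
                    for (p, t), c in zip(pairs.T, counts)}
    rows = []
    used_p: set[int] = set()
    used_t: set[int] = set()
    for (pl, tl), ov in sorted(overlaps.items(), key=lambda kv: -kv[1]):
        if pl in used_p or tl in used_t:
            continue
        union = p_sizes[pl] + t_sizes[tl] - ov
        rows.append({"predicted_label": pl, "truth_label": tl,
                     "iou": ov / union})
        used_p.add(pl)
        used_t.add(tl)
    matches = pd.DataFrame(rows, columns=["predicted_label", "truth_label", "iou"])
    return ValidationResult(
        matches=matches,
        unmatched_predicted=[l for l in p_labels if l not in used_p],
        unmatched_truth=[l for l in t_labels if l not in used_t],
        count_difference=len(p_labels) - len(t_labels),
    )
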