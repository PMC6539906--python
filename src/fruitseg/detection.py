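"""Applying a learned model to new images.

Detection mirrors the training geometry: the image is split into
illumination-homogeneous regions, each region's light level selects — by
linear interpolation between the two nearest group anchors — three
per-dimension thresholds, and each region is binarized per dimension.
The region masks are stitched into whole-image masks, the seven candidate
combinations are formed, and the model's chosen combination is cleaned
morphologically (opening with an 11x11 square to delete speckle, then
closing with a 5x5 square to bridge small gaps) to give the final mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import closing as _closing
from skimage.morphology import opening as _opening

from .colorspace import ColorImage, convert, to_gray
from .metrics import Direction, f_score, fpr, tpr
from .regions import LightGroup, Region, split_recursive
from .training import COMBINATIONS, ThresholdModel, combination_label


@dataclass
class DetectionReport:
    """Everything the detector produced for one image."""

    final_mask: np.ndarray
    raw_mask: np.ndarray  # chosen combination before morphology
    per_dimension_masks: np.ndarray  # (H, W, 3) uint8 stack
    per_combination_masks: dict[tuple[int, ...], np.ndarray]
    regions: list[Region]
    metrics: dict | None = None  # tpr/fpr/f of final_mask vs truth
    raw_metrics: dict | None = None  # same, before morphology


def interpolate_thresholds(
    model: ThresholdModel, level: float, mode: str = "standard"
) -> np.ndarray:
    """Per-dimension thresholds for a region at light ``level``.

    Standard linear interpolation between the two group anchors bracketing
    the level:

        T = (T_lo * (LL_hi - level) + T_hi * (level - LL_lo)) / (LL_hi - LL_lo)

    which is exact at the anchors and continuous in between.  Levels
    outside the anchor span clamp to the nearest group's thresholds.
    ``mode="literal"`` applies the reversed weight ordering
    ``T_lo * (level - LL_lo) + T_hi * (LL_hi - level)`` instead; the two
    agree at the midpoint between anchors but the literal form flips the
    endpoints, so the standard form is the default.
    """
    anchors = np.asarray(model.group_levels)
    table = np.asarray(model.thresholds)
    if level <= anchors[0]:
        return table[0].copy()
    if level >= anchors[-1]:
        return table[-1].copy()
    i = int(np.searchsorted(anchors, level, side="right")) - 1
    lo, hi = anchors[i], anchors[i + 1]
    t_lo, t_hi = table[i], table[i + 1]
    if mode == "standard":
        return (t_lo * (hi - level) + t_hi * (level - lo)) / (hi - lo)
    if mode == "literal":
        return (t_lo * (level - lo) + t_hi * (hi - level)) / (hi - lo)
    raise ValueError(f"unknown interpolation mode {mode!r}")


def binarize(
    pixels: np.ndarray, thresholds, directions: list[Direction]
) -> np.ndarray:
    """Threshold a (H, W, 3) block per dimension into a (H, W, 3) 0/1 stack.

    Classification is strict: fruit is ``value > T`` for direction GT and
    ``value < T`` for LT.
    """
    out = np.empty(pixels.shape, dtype=np.uint8)
    for d in range(3):
        ch = pixels[..., d]
        if directions[d] is Direction.GT:
            out[..., d] = ch > thresholds[d]
        else:
            out[..., d] = ch < thresholds[d]
    return out


def combine(per_dimension_masks: np.ndarray, combination: tuple[int, ...]) -> np.ndarray:
    """Elementwise AND of the masks named by ``combination``."""
    combination = tuple(combination)
    if combination not in COMBINATIONS:
        raise ValueError(f"unknown combination {combination!r}")
    mask = per_dimension_masks[..., combination[0]].astype(bool)
    for d in combination[1:]:
        mask = mask & per_dimension_masks[..., d].astype(bool)
    return mask.astype(np.uint8)


def morphological_cleanup(
    mask: np.ndarray, opening_size: int = 11, closing_size: int = 5
) -> np.ndarray:
    """Opening (erosion then dilation) with an 11x11 square to remove small
    false-positive clusters, then closing (dilation then erosion) with a
    5x5 square to reconnect fruit split across clusters.  Square elements
    are used since fruit orientation is unknown a priori."""
    m = np.asarray(mask).astype(bool)
    m = _opening(m, np.ones((opening_size, opening_size), dtype=bool))
    m = _closing(m, np.ones((closing_size, closing_size), dtype=bool))
    return m.astype(np.uint8)


def dimension_masks(
    rgb: ColorImage, model: ThresholdModel, interp_mode: str = "standard"
) -> tuple[np.ndarray, list[Region]]:
    """Split, interpolate, and binarize; stitch region masks per dimension.

    Returns the whole-image (H, W, 3) stack and the region partition.
    OVEREXPOSED regions emit background (all zeros) in every dimension.
    """
    gray = to_gray(rgb)
    regions = split_recursive(gray, model.split_config)
    conv = convert(rgb, model.space)
    stack = np.zeros(conv.pixels.shape, dtype=np.uint8)
    for region in regions:
        if region.group is LightGroup.OVEREXPOSED:
            continue
        thr = interpolate_thresholds(model, region.light_level, mode=interp_mode)
        sl = region.slice()
        stack[sl] = binarize(conv.pixels[sl], thr, model.directions)
    return stack, regions


def detect(
    rgb: ColorImage,
    model: ThresholdModel,
    truth: np.ndarray | None = None,
    interp_mode: str = "standard",
) -> DetectionReport:
    """Run the full detector on one RGB image.

    When ``truth`` is supplied, pixel metrics are computed for the final
    mask and for the chosen combination before morphology.
    """
    if truth is not None:
        truth = np.asarray(truth).astype(bool)
        if truth.shape != rgb.shape:
            raise ValueError(
                f"truth shape {truth.shape} does not match image {rgb.shape}"
            )
    stack, regions = dimension_masks(rgb, model, interp_mode=interp_mode)
    per_combination = {c: combine(stack, c) for c in COMBINATIONS}
    raw = per_combination[model.combination]
    final = morphological_cleanup(raw)

    def _measure(mask):
        t = tpr(mask, truth)
        f = fpr(mask, truth)
        return {"tpr": t, "fpr": f, "f": f_score(t, f)}

    report = DetectionReport(
        final_mask=final,
        raw_mask=raw,
        per_dimension_masks=stack,
        per_combination_masks=per_combination,
        regions=regions,
    )
    if truth is not None:
        report.metrics = _measure(final)
        report.raw_metrics = _measure(raw)
    return report


def report_to_dict(report: DetectionReport) -> dict:
    """JSON-friendly summary (masks summarized by pixel counts)."""
    return {
        "n_regions": len(report.regions),
        "detected_pixels": int(report.final_mask.sum()),
        "detected_pixels_raw": int(report.raw_mask.sum()),
        "per_combination_pixels": {
            combination_label(c): int(m.sum())
            for c, m in report.per_combination_masks.items()
        },
        "metrics": report.metrics,
        "raw_metrics": report.raw_metrics,
    }
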