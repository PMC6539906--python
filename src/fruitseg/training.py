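"""Learning the detection model from labeled images.

Training pools pixel values per (illumination group, color dimension)
bucket by splitting every training image into homogeneous regions,
categorizing each region's light level, and separating fruit from
background with the ground-truth mask.  One threshold per bucket — nine in
total — is then selected by sweeping an ROC and maximizing either the
F-score (default) or a weighted TPR/(1-FPR) trade-off.  Finally the best
of the seven candidate mask combinations (three single dimensions and the
four intersections) is chosen on the training set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .colorspace import CHANNEL_RANGES, ColorImage, convert, to_gray
from .metrics import Direction, UndefinedMetricError, f_score, fpr, roc_curve, tpr
from .regions import TRAINABLE_GROUPS, LightGroup, SplitConfig, split_recursive
from .tuning import TuningResult, learn_direction

#: The seven candidate combinations: dimensions are 0-based indices.
COMBINATIONS: tuple[tuple[int, ...], ...] = (
    (0,),
    (1,),
    (2,),
    (0, 1),
    (0, 2),
    (1, 2),
    (0, 1, 2),
)


def combination_label(combo: tuple[int, ...]) -> str:
    return "∩".join(str(d + 1) for d in combo)


@dataclass
class LabeledImage:
    """An RGB image with an optional aligned binary ground-truth mask."""

    rgb: ColorImage
    truth: np.ndarray | None = None
    id: str = ""

    def __post_init__(self) -> None:
        if self.truth is not None:
            self.truth = np.asarray(self.truth).astype(bool)
            if self.truth.shape != self.rgb.shape:
                raise ValueError(
                    f"mask shape {self.truth.shape} does not match "
                    f"image shape {self.rgb.shape}"
                )


@dataclass
class TrainingPools:
    """Pixel values pooled per (light group, color dimension) bucket."""

    values: dict[tuple[LightGroup, int], tuple[np.ndarray, np.ndarray]]
    region_levels: dict[LightGroup, np.ndarray]


@dataclass
class ThresholdModel:
    """The complete learned detector.

    ``thresholds[g][d]`` is the cutoff for illumination group ``g`` (LOW,
    MEDIUM, HIGH) and color dimension ``d``; ``group_levels`` holds the
    anchor light level of each group used for interpolation at test time.
    ``combination`` names the dimensions whose masks are intersected to
    form the final detection.
    """

    space: str
    group_levels: list[float]
    thresholds: list[list[float]]
    directions: list[Direction]
    combination: tuple[int, ...]
    split_config: SplitConfig
    combination_scores: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.combination = tuple(self.combination)
        if len(self.group_levels) != 3 or len(self.thresholds) != 3:
            raise ValueError("model needs three illumination groups")
        if any(len(row) != 3 for row in self.thresholds):
            raise ValueError("model needs three thresholds per group")
        if not all(a < b for a, b in zip(self.group_levels, self.group_levels[1:])):
            raise ValueError("group anchor levels must be strictly increasing")

    def to_dict(self) -> dict:
        from . import __version__

        return {
            "space": self.space,
            "group_levels": list(self.group_levels),
            "thresholds": [list(row) for row in self.thresholds],
            "directions": [d.value for d in self.directions],
            "combination": list(self.combination),
            "split_config": self.split_config.to_dict(),
            "combination_scores": self.combination_scores,
            "version": __version__,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdModel":
        return cls(
            space=d["space"],
            group_levels=[float(v) for v in d["group_levels"]],
            thresholds=[[float(v) for v in row] for row in d["thresholds"]],
            directions=[Direction(v) for v in d["directions"]],
            combination=tuple(d["combination"]),
            split_config=SplitConfig.from_dict(d["split_config"]),
            combination_scores=d.get("combination_scores"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "ThresholdModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def collect_training_pixels(
    images: list[LabeledImage], cfg: SplitConfig, space: str
) -> TrainingPools:
    """Pool fruit/background channel values per (group, dimension).

    Every image is split on its grayscale view, each region is assigned a
    light group, and the region's converted-space pixels are separated by
    the ground-truth mask into the group's fruit and background buckets.
    OVEREXPOSED regions are discarded and contribute to no bucket.
    """
    if not images:
        raise ValueError("need at least one labeled image")
    fruit_acc: dict = {(g, d): [] for g in TRAINABLE_GROUPS for d in range(3)}
    bg_acc: dict = {(g, d): [] for g in TRAINABLE_GROUPS for d in range(3)}
    levels: dict = {g: [] for g in TRAINABLE_GROUPS}
    for im in images:
        if im.truth is None:
            raise ValueError(f"image {im.id!r} has no ground truth")
        gray = to_gray(im.rgb)
        conv = convert(im.rgb, space)
        for region in split_recursive(gray, cfg):
            if region.group is LightGroup.OVEREXPOSED:
                continue
            sl = region.slice()
            t = im.truth[sl]
            px = conv.pixels[sl]
            levels[region.group].append(region.light_level)
            for d in range(3):
                ch = px[..., d]
                fruit_acc[(region.group, d)].append(ch[t])
                bg_acc[(region.group, d)].append(ch[~t])
    values = {
        key: (
            np.concatenate(fruit_acc[key]) if fruit_acc[key] else np.empty(0),
            np.concatenate(bg_acc[key]) if bg_acc[key] else np.empty(0),
        )
        for key in fruit_acc
    }
    region_levels = {g: np.asarray(v) for g, v in levels.items()}
    return TrainingPools(values=values, region_levels=region_levels)


def select_threshold(
    fruit_values,
    bg_values,
    direction: Direction,
    objective_weight: float | None = None,
    n_levels: int = 256,
    value_range: tuple[float, float] | None = None,
) -> tuple[float, float, float]:
    """Pick the ROC sweep point maximizing the detection objective.

    By default the objective is the F-score of each (TPR, FPR) point; an
    explicit ``objective_weight`` w switches to the linear trade-off
    ``w * TPR + (1 - w) * (1 - FPR)``, which lets a caller bias the
    detector toward recall or precision at train time.  When several
    candidates tie at the optimum, the middle one is returned: on
    separable data the optimal plateau spans the gap between the class
    supports, and a mid-gap cutoff leaves margin on both sides so that
    thresholds interpolated between illumination groups stay clear of
    either class.  Returns ``(threshold, tpr, fpr)`` at the optimum.
    """
    points = roc_curve(
        fruit_values, bg_values, direction, n_levels=n_levels, value_range=value_range
    )
    if objective_weight is None:
        scores = np.array([f_score(p.tpr, p.fpr) for p in points])
    else:
        w = objective_weight
        scores = np.array([w * p.tpr + (1 - w) * (1 - p.fpr) for p in points])
    ties = np.flatnonzero(scores == scores.max())
    p = points[int(ties[len(ties) // 2])]
    return p.threshold, p.tpr, p.fpr


def select_combination(
    masks_per_image: list[np.ndarray], truths: list[np.ndarray]
) -> tuple[tuple[int, ...], dict[str, float]]:
    """Evaluate the seven candidate combinations and return the argmax.

    ``masks_per_image[i]`` is the (H, W, 3) stack of per-dimension binary
    masks for training image ``i``.  Mean F over the images decides; ties
    prefer fewer intersected dimensions (then lower dimension indices).
    Images whose truth is single-class are skipped.
    """
    scores: dict[tuple[int, ...], list[float]] = {c: [] for c in COMBINATIONS}
    for stack, truth in zip(masks_per_image, truths):
        truth = np.asarray(truth).astype(bool)
        if not truth.any() or truth.all():
            continue
        for combo in COMBINATIONS:
            mask = np.logical_and.reduce([stack[..., d] for d in combo])
            scores[combo].append(f_score(tpr(mask, truth), fpr(mask, truth)))
    mean_scores = {
        combo: (float(np.mean(v)) if v else 0.0) for combo, v in scores.items()
    }
    best = max(
        COMBINATIONS,
        key=lambda c: (mean_scores[c], -len(c), tuple(-d for d in c)),
    )
    return best, {combination_label(c): s for c, s in mean_scores.items()}


def _fallback_order(gi: int) -> list[int]:
    """Group indices by distance from ``gi`` (nearest populated wins)."""
    return sorted(range(3), key=lambda j: (abs(j - gi), j))


def fit(
    images: list[LabeledImage],
    tuning: TuningResult,
    space: str,
    objective_weight: float | None = None,
    n_levels: int = 256,
    min_side: int = 16,
) -> ThresholdModel:
    """Learn a complete ThresholdModel from labeled training images.

    Builds the per-(group, dimension) pixel pools, learns the three
    classification-rule directions, selects the nine thresholds, anchors
    each group at the mean light level of its training regions, and picks
    the best mask combination on the training set.  A group with no
    two-class data inherits the nearest populated group's thresholds (with
    a warning) and is anchored at the midpoint of its light interval.
    """
    if not images:
        raise ValueError("need at least one labeled image")
    cfg = SplitConfig(
        std_stop=tuning.std_stop,
        t1=tuning.t1,
        t2=tuning.t2,
        t_over=tuning.t_over,
        min_side=min_side,
    )
    converted = [convert(im.rgb, space) for im in images]
    if tuning.directions is not None:
        directions = list(tuning.directions)
    else:
        directions = [learn_direction(converted, d) for d in range(3)]

    pools = collect_training_pixels(images, cfg, space)
    learned: dict[tuple[int, int], float] = {}
    for gi, group in enumerate(TRAINABLE_GROUPS):
        for d in range(3):
            fruit, bg = pools.values[(group, d)]
            if fruit.size and bg.size:
                learned[(gi, d)], _, _ = select_threshold(
                    fruit,
                    bg,
                    directions[d],
                    objective_weight=objective_weight,
                    n_levels=n_levels,
                )

    thresholds = [[0.0] * 3 for _ in range(3)]
    for d in range(3):
        populated = [gi for gi in range(3) if (gi, d) in learned]
        if not populated:
            raise UndefinedMetricError(
                f"no illumination group has both classes for dimension {d}"
            )
        for gi in range(3):
            if (gi, d) in learned:
                thresholds[gi][d] = learned[(gi, d)]
            else:
                src = next(j for j in _fallback_order(gi) if (j, d) in learned)
                warnings.warn(
                    f"group {TRAINABLE_GROUPS[gi].value!r} has no two-class "
                    f"pixels for dimension {d}; borrowing thresholds from "
                    f"{TRAINABLE_GROUPS[src].value!r}",
                    stacklevel=2,
                )
                thresholds[gi][d] = learned[(src, d)]

    interval_mid = [
        (0.0 + cfg.t1) / 2.0,
        (cfg.t1 + cfg.t2) / 2.0,
        (cfg.t2 + cfg.t_over) / 2.0,
    ]
    group_levels = []
    for gi, group in enumerate(TRAINABLE_GROUPS):
        lv = pools.region_levels[group]
        group_levels.append(float(lv.mean()) if lv.size else interval_mid[gi])

    model = ThresholdModel(
        space=space,
        group_levels=group_levels,
        thresholds=thresholds,
        directions=directions,
        combination=(0,),
        split_config=cfg,
    )

    from .detection import dimension_masks  # local import: avoids a cycle

    stacks = [dimension_masks(im.rgb, model)[0] for im in images]
    combo, combo_scores = select_combination(stacks, [im.truth for im in images])
    model.combination = combo
    model.combination_scores = combo_scores
    return model
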