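"""Automatic parameter tuning.

Three parameter families are tuned from a labeled image set before
training:

* the light-level cutoffs T1/T2, chosen so that 15% of sampled sub-image
  light levels fall in the LOW group, 70% in MEDIUM, and 15% in HIGH;
* the recursive-split stop value (the grayscale STD below which a region
  counts as homogeneous), chosen by grid search maximizing the mean
  F-score over repeated random train/test cycles;
* the per-dimension classification-rule direction, learned with a
  majority heuristic that assumes background dominates the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .colorspace import CHANNEL_RANGES, ColorImage, to_gray
from .metrics import Direction
from .regions import grid_tiles


class DegenerateDistributionError(ValueError):
    """The sampled light levels carry no spread to place cutoffs in."""


@dataclass
class LightStats:
    """Descriptive statistics of a light-level sample.

    ``std`` uses the sample (n-1) convention; skewness and excess kurtosis
    use the plain moment estimators.  For a constant sample the shape
    statistics are reported as 0 with ``degenerate=True``.
    """

    mean: float
    std: float
    skewness: float
    kurtosis: float
    median: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "std": self.std,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
            "median": self.median,
            "degenerate": self.degenerate,
        }


@dataclass
class TuningResult:
    """Tuned parameters handed from the tuning stage to training."""

    t1: float
    t2: float
    std_stop: float
    t_over: float = 250.0
    directions: list[Direction] | None = None
    light_stats: LightStats | None = None

    def to_dict(self) -> dict:
        return {
            "t1": self.t1,
            "t2": self.t2,
            "std_stop": self.std_stop,
            "t_over": self.t_over,
            "directions": None
            if self.directions is None
            else [d.value for d in self.directions],
            "light_stats": None
            if self.light_stats is None
            else self.light_stats.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TuningResult":
        directions = d.get("directions")
        if directions is not None:
            directions = [Direction(v) for v in directions]
        ls = d.get("light_stats")
        if ls is not None:
            ls = LightStats(**ls)
        return cls(
            t1=d["t1"],
            t2=d["t2"],
            std_stop=d["std_stop"],
            t_over=d.get("t_over", 250.0),
            directions=directions,
            light_stats=ls,
        )

    def save(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "TuningResult":
        import json

        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def tune_light_thresholds(
    levels, low_fraction: float = 0.15, high_fraction: float = 0.15
) -> tuple[float, float]:
    """Percentile rule for the light-group cutoffs.

    T1 is the ``low_fraction`` quantile and T2 the ``1 - high_fraction``
    quantile of the empirical light-level distribution (linear
    interpolation between order statistics), so the defaults leave 15% of
    sub-images LOW, 70% MEDIUM, and 15% HIGH.
    """
    arr = np.asarray(levels, dtype=np.float64).ravel()
    if arr.size < 2 or np.unique(arr).size < 2:
        raise DegenerateDistributionError(
            "need at least two distinct light levels to place cutoffs"
        )
    t1, t2 = np.percentile(arr, [100 * low_fraction, 100 * (1 - high_fraction)])
    if t2 <= t1:  # heavy ties; nudge apart inside the valid range
        t2 = np.nextafter(t1, np.inf)
    return float(t1), float(t2)


def light_statistics(levels) -> LightStats:
    """Mean, std, skewness, excess kurtosis, and median of a sample."""
    arr = np.asarray(levels, dtype=np.float64).ravel()
    if arr.size < 2:
        raise ValueError("need at least two values")
    degenerate = bool(arr.std() == 0)
    return LightStats(
        mean=float(arr.mean()),
        std=float(arr.std(ddof=1)),
        skewness=0.0 if degenerate else float(_stats.skew(arr)),
        kurtosis=0.0 if degenerate else float(_stats.kurtosis(arr)),
        median=float(np.median(arr)),
        degenerate=degenerate,
    )


def sample_light_levels(images, fraction: float = 0.01) -> np.ndarray:
    """Light levels of square tiles covering ~``fraction`` of each image.

    The per-tile mean grayscale values pooled over ``images`` form the
    empirical distribution that :func:`tune_light_thresholds` cuts.
    """
    levels: list[float] = []
    for img in images:
        gray = to_gray(img)
        levels.extend(t.light_level for t in grid_tiles(gray, fraction))
    return np.asarray(levels)


def learn_direction(
    images: list[ColorImage],
    dimension: int,
    threshold: float | None = None,
    background_fraction: float = 0.70,
) -> Direction:
    """Majority heuristic for the classification-rule direction.

    Apply ``value > threshold`` over the pooled training pixels of one
    color dimension (the probe threshold defaults to the midpoint of the
    channel's range).  If the pixels left below the threshold — presumed
    background — are less than 70% of the pool, the direction is reversed
    to ``value < threshold``.  Assumes images contain more background than
    fruit; order of ``images`` does not matter.
    """
    if not images:
        raise ValueError("need at least one image")
    space = images[0].space
    if threshold is None:
        lo, hi = CHANNEL_RANGES[space][dimension]
        threshold = (lo + hi) / 2.0
    below = 0
    total = 0
    for img in images:
        if img.space != space:
            raise ValueError("images must share one color space")
        ch = img.pixels[..., dimension]
        below += int((ch <= threshold).sum())
        total += ch.size
    return Direction.GT if below / total >= background_fraction else Direction.LT


def tune_std_stop(
    dataset,
    grid,
    space: str,
    sample_fraction: float = 0.30,
    repeats: int = 5,
    seed: int = 0,
    train_fraction: float = 0.70,
    t_over: float = 250.0,
    tile_fraction: float = 0.01,
) -> tuple[float, dict[float, float]]:
    """Choose the split stop value by F-score maximization.

    For every candidate STD in ``grid``, run ``repeats`` cycles of: sample
    ``sample_fraction`` of the labeled images, split them 70/30 into
    train/test, tune T1/T2 and fit a model on the training fold, and score
    the mean F on the test fold.  The same sampled splits are reused for
    every candidate (a paired comparison), making the search reproducible
    for a fixed ``seed``.  Returns the winning candidate (ties broken
    toward the larger value — fewer splits) and the per-candidate mean F.
    """
    from .detection import detect  # local import: avoids a module cycle
    from .training import fit

    dataset = list(dataset)
    if len(dataset) < 2:
        raise ValueError("need at least two labeled images")
    if any(im.truth is None for im in dataset):
        raise ValueError("every image needs a ground-truth mask")
    grid = [float(g) for g in grid]
    if not grid:
        raise ValueError("empty candidate grid")

    rng = np.random.default_rng(seed)
    n = len(dataset)
    splits = []
    for _ in range(repeats):
        k = max(2, int(round(sample_fraction * n)))
        idx = rng.permutation(n)[:k]
        n_train = min(k - 1, max(1, int(round(train_fraction * k))))
        splits.append((idx[:n_train], idx[n_train:]))

    scores: dict[float, float] = {}
    for cand in grid:
        fs = []
        for train_idx, test_idx in splits:
            train = [dataset[i] for i in train_idx]
            test = [dataset[i] for i in test_idx]
            levels = sample_light_levels((im.rgb for im in train), tile_fraction)
            t1, t2 = tune_light_thresholds(levels)
            tuning = TuningResult(t1=t1, t2=t2, std_stop=cand, t_over=t_over)
            model = fit(train, tuning, space)
            for im in test:
                fs.append(detect(im.rgb, model, im.truth).metrics["f"])
        scores[cand] = float(np.mean(fs))

    best = max(grid, key=lambda c: (scores[c], c))
    return best, scores
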