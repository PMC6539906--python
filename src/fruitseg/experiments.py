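"""Evaluation protocols: cross-validation and sensitivity analyses.

The reference protocol is repeated random sub-sampling: 70% of the images
train the detector, 30% test it, five times with different random splits,
and the reported rates are averages over the test folds.  Sensitivity
protocols perturb the pipeline around the trained operating point: image
noise, scaled thresholds, scaled split stop value, training-fraction
sweeps, and a morphology ablation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .colorspace import ColorImage
from .detection import detect, morphological_cleanup
from .metrics import f_score
from .training import LabeledImage, ThresholdModel, fit
from .tuning import TuningResult, sample_light_levels, tune_light_thresholds


@dataclass
class ExperimentConfig:
    """Protocol settings; defaults mirror the reference evaluation."""

    train_fraction: float = 0.70
    repeats: int = 5
    seed: int = 0
    noise_percents: tuple[float, ...] = (0.05, 0.10, 0.20, 0.30)
    threshold_deltas: tuple[float, ...] = (-0.15, -0.10, -0.05, 0.05, 0.10, 0.15)
    std_deltas: tuple[float, ...] = (0.05, 0.10)
    std_stop: float = 10.0
    t_over: float = 250.0
    tile_fraction: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class RepeatResult:
    """Mean test-fold rates for one train/test split."""

    tpr: float
    fpr: float
    f: float  # mean of per-image F (final masks)
    raw_tpr: float
    raw_fpr: float
    raw_f: float  # before morphology
    model: ThresholdModel | None = None


@dataclass
class CrossValResult:
    repeats: list[RepeatResult]

    def _mean(self, attr: str) -> float:
        return float(np.mean([getattr(r, attr) for r in self.repeats]))

    @property
    def mean_tpr(self) -> float:
        return self._mean("tpr")

    @property
    def mean_fpr(self) -> float:
        return self._mean("fpr")

    @property
    def mean_f(self) -> float:
        """Average of per-split F-scores."""
        return self._mean("f")

    @property
    def mean_raw_f(self) -> float:
        return self._mean("raw_f")

    @property
    def f_of_mean_rates(self) -> float:
        """F recomputed from the averaged TPR/FPR (the alternative report)."""
        return f_score(self.mean_tpr, self.mean_fpr)


def _split_indices(n: int, train_fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(n)
    n_train = min(n - 1, max(1, int(round(train_fraction * n))))
    return perm[:n_train], perm[n_train:]


def _tune_and_fit(
    train: list[LabeledImage], cfg: ExperimentConfig, space: str
) -> ThresholdModel:
    levels = sample_light_levels((im.rgb for im in train), cfg.tile_fraction)
    t1, t2 = tune_light_thresholds(levels)
    tuning = TuningResult(t1=t1, t2=t2, std_stop=cfg.std_stop, t_over=cfg.t_over)
    return fit(train, tuning, space)


def cross_validate(
    images: list[LabeledImage],
    cfg: ExperimentConfig,
    space: str,
    noise_percent: float = 0.0,
    noise_on_train: bool = False,
    keep_models: bool = False,
) -> CrossValResult:
    """Repeated random train/test evaluation of the full pipeline.

    Each repeat re-runs the tuning stage (light cutoffs, directions) on the
    training fold only, fits a model, and averages the pixel metrics over
    the test fold.  ``noise_percent`` optionally corrupts the test images
    (and the training images too with ``noise_on_train``) to probe
    robustness to sensor noise.
    """
    images = list(images)
    if len(images) < 2:
        raise ValueError("need at least two labeled images")
    results: list[RepeatResult] = []
    for rep in range(cfg.repeats):
        rng = np.random.default_rng([cfg.seed, rep])
        train_idx, test_idx = _split_indices(len(images), cfg.train_fraction, rng)
        train = [images[i] for i in train_idx]
        test = [images[i] for i in test_idx]
        if noise_percent and noise_on_train:
            train = [
                LabeledImage(
                    add_noise(im.rgb, noise_percent, seed=int(rng.integers(2**31))),
                    im.truth,
                    im.id,
                )
                for im in train
            ]
        model = _tune_and_fit(train, cfg, space)
        rows = []
        for im in test:
            rgb = im.rgb
            if noise_percent:
                rgb = add_noise(rgb, noise_percent, seed=int(rng.integers(2**31)))
            rep_out = detect(rgb, model, im.truth)
            rows.append(
                (
                    rep_out.metrics["tpr"],
                    rep_out.metrics["fpr"],
                    rep_out.metrics["f"],
                    rep_out.raw_metrics["tpr"],
                    rep_out.raw_metrics["fpr"],
                    rep_out.raw_metrics["f"],
                )
            )
        means = np.mean(rows, axis=0)
        results.append(
            RepeatResult(*map(float, means), model=model if keep_models else None)
        )
    return CrossValResult(results)


def add_noise(rgb: ColorImage, percent: float, seed: int = 0) -> ColorImage:
    """Additive zero-mean Gaussian sensor noise, sigma = percent of 255.

    Noise is drawn independently per pixel and channel and the result is
    clipped to the valid [0, 255] range.  ``percent=0`` is the identity.
    """
    if not 0 <= percent <= 0.5:
        raise ValueError("percent must be in [0, 0.5]")
    if percent == 0:
        return rgb
    rng = np.random.default_rng(seed)
    noisy = rgb.pixels + rng.normal(0.0, percent * 255.0, rgb.pixels.shape)
    return ColorImage(np.clip(noisy, 0.0, 255.0), rgb.space)


def perturb_thresholds(model: ThresholdModel, delta: float) -> ThresholdModel:
    """Scale every learned threshold by ``(1 + delta)``.

    Thresholds are clipped back to their channel's declared range.  Used to
    probe how sensitive the detector is to errors in the learned cutoffs.
    """
    if abs(delta) >= 1:
        raise ValueError("|delta| must be < 1")
    from .colorspace import CHANNEL_RANGES

    ranges = CHANNEL_RANGES[model.space]
    new = [
        [
            float(np.clip(t * (1.0 + delta), ranges[d][0], ranges[d][1]))
            for d, t in enumerate(row)
        ]
        for row in model.thresholds
    ]
    out = dataclasses.replace(model, thresholds=new)
    return out


def perturb_std_stop(model: ThresholdModel, delta: float) -> ThresholdModel:
    """Scale the split stop value by ``(1 + delta)``."""
    cfg = dataclasses.replace(
        model.split_config, std_stop=model.split_config.std_stop * (1.0 + delta)
    )
    return dataclasses.replace(model, split_config=cfg)


def ablate_morphology(
    images: list[LabeledImage], model: ThresholdModel
) -> tuple[float, float]:
    """Mean F with and without the morphological cleanup stage."""
    with_f, without_f = [], []
    for im in images:
        if im.truth is None:
            raise ValueError("ablation requires ground truth")
        report = detect(im.rgb, model, im.truth)
        with_f.append(report.metrics["f"])
        without_f.append(report.raw_metrics["f"])
    return float(np.mean(with_f)), float(np.mean(without_f))


def threshold_sensitivity(
    images: list[LabeledImage], cfg: ExperimentConfig, space: str
) -> "pd.DataFrame":
    """TPR/FPR of the detector as the learned thresholds are scaled.

    Fits one model per repeat, then re-evaluates the test fold with every
    threshold delta (including the unperturbed 0).  Returns a tidy frame
    with columns delta, tpr, fpr, f.
    """
    import pandas as pd

    deltas = sorted(set(cfg.threshold_deltas) | {0.0})
    rows = []
    for rep in range(cfg.repeats):
        rng = np.random.default_rng([cfg.seed, rep])
        train_idx, test_idx = _split_indices(len(images), cfg.train_fraction, rng)
        model = _tune_and_fit([images[i] for i in train_idx], cfg, space)
        for delta in deltas:
            perturbed = perturb_thresholds(model, delta)
            for i in test_idx:
                im = images[i]
                m = detect(im.rgb, perturbed, im.truth).metrics
                rows.append(
                    {"repeat": rep, "delta": delta, "tpr": m["tpr"],
                     "fpr": m["fpr"], "f": m["f"]}
                )
    frame = pd.DataFrame(rows)
    return frame.groupby("delta", as_index=False)[["tpr", "fpr", "f"]].mean()
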