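import warnings

import numpy as np
import pytest

from fruitseg.colorspace import ColorImage
from fruitseg.detection import detect
from fruitseg.metrics import Direction, UndefinedMetricError, f_score, fpr, tpr
from fruitseg.regions import LightGroup, SplitConfig, TRAINABLE_GROUPS
from fruitseg.training import (
    LabeledImage,
    ThresholdModel,
    collect_training_pixels,
    fit,
    select_combination,
    select_threshold,
)
from fruitseg.tuning import TuningResult

from conftest import quick_fit


def brute_force_best(fruit, bg, direction, thresholds):
    best = -1.0
    for t in thresholds:
        if direction is Direction.GT:
            tp = np.mean(fruit > t)
            fp = np.mean(bg > t)
        else:
            tp = np.mean(fruit < t)
            fp = np.mean(bg < t)
        best = max(best, f_score(tp, fp))
    return best


def test_select_threshold_separable():
    thr, tp, fp = select_threshold([0.8, 0.9], [0.1, 0.2], Direction.GT)
    assert 0.2 < thr < 0.8
    assert tp == 1.0 and fp == 0.0


def test_select_threshold_uninformative_classes():
    vals = np.linspace(0, 1, 50)
    _, tp, fp = select_threshold(vals, vals, Direction.GT, objective_weight=0.5)
    score = 0.5 * tp + 0.5 * (1 - fp)
    assert score == pytest.approx(0.5, abs=0.02)


@pytest.mark.parametrize("direction", [Direction.GT, Direction.LT])
@pytest.mark.parametrize("trial", range(5))
def test_select_threshold_equals_exhaustive_search(direction, trial):
    rng = np.random.default_rng(trial)
    fruit = rng.normal(0.6, 0.25, 20)
    bg = rng.normal(0.4, 0.25, 20)
    thr, tp, fp = select_threshold(fruit, bg, direction)
    lo = min(fruit.min(), bg.min())
    hi = max(fruit.max(), bg.max())
    oracle = brute_force_best(fruit, bg, direction, np.linspace(lo, hi, 256))
    assert f_score(tp, fp) == pytest.approx(oracle, abs=1e-12)
    # the reported rates are what the threshold actually achieves
    if direction is Direction.GT:
        assert tp == pytest.approx(np.mean(fruit > thr))
    else:
        assert tp == pytest.approx(np.mean(fruit < thr))


def test_select_threshold_objective_weight_biases_recall():
    rng = np.random.default_rng(9)
    fruit = rng.normal(0.6, 0.2, 200)
    bg = rng.normal(0.4, 0.2, 200)
    _, tp_recall, _ = select_threshold(fruit, bg, Direction.GT, objective_weight=0.95)
    _, tp_precision, _ = select_threshold(fruit, bg, Direction.GT, objective_weight=0.05)
    assert tp_recall >= tp_precision


def make_labeled(pixels, truth):
    return LabeledImage(ColorImage(np.asarray(pixels, float), "rgb"), truth)


def test_collect_pools_uniform_image_single_group():
    # mid-gray image: every region is MEDIUM; truth splits the buckets
    pixels = np.full((32, 32, 3), 128.0)
    truth = np.zeros((32, 32), bool)
    truth[:8, :8] = True
    cfg = SplitConfig(std_stop=10.0, t1=84.0, t2=140.0)
    pools = collect_training_pixels([make_labeled(pixels, truth)], cfg, "rgb")
    for g in (LightGroup.LOW, LightGroup.HIGH):
        for d in range(3):
            fruit, bg = pools.values[(g, d)]
            assert fruit.size == 0 and bg.size == 0
    fruit, bg = pools.values[(LightGroup.MEDIUM, 0)]
    assert fruit.size == 64 and bg.size == 32 * 32 - 64


def test_collect_pools_empty_truth_gives_empty_fruit():
    pixels = np.full((32, 32, 3), 128.0)
    cfg = SplitConfig(std_stop=10.0, t1=84.0, t2=140.0)
    pools = collect_training_pixels(
        [make_labeled(pixels, np.zeros((32, 32), bool))], cfg, "rgb"
    )
    assert all(v[0].size == 0 for v in pools.values.values())


def test_collect_pools_conserve_pixels(gradient_dataset):
    im = gradient_dataset[0]
    cfg = SplitConfig(std_stop=10.0, t1=40.0, t2=120.0)
    pools = collect_training_pixels([im], cfg, "ndi")
    total = sum(
        pools.values[(g, 0)][0].size + pools.values[(g, 0)][1].size
        for g in TRAINABLE_GROUPS
    )
    assert total == im.rgb.pixels[..., 0].size  # nothing overexposed here
    # all three illumination groups are populated under the 3-zone gradient
    assert all(pools.region_levels[g].size > 0 for g in TRAINABLE_GROUPS)


def test_fit_separable_scene_reaches_perfect_training_f(flat_dataset):
    model = quick_fit(flat_dataset, "ndi")
    for im in flat_dataset:
        report = detect(im.rgb, model, im.truth)
        assert report.raw_metrics["f"] == 1.0


def test_fit_learned_threshold_between_class_supports(flat_dataset):
    # dimension 1 of the NDI space separates red fruit from green background
    model = quick_fit(flat_dataset, "ndi")
    assert model.directions[0] is Direction.GT
    for row in model.thresholds:
        assert -0.5 < row[0] < 0.65


def test_fit_empty_group_falls_back_with_warning():
    # a single mid-gray-level image populates only the MEDIUM group; LOW
    # and HIGH must borrow its thresholds and warn
    pixels = np.full((32, 32, 3), 120.0)
    pixels[8:16, 8:16] = (200.0, 30.0, 30.0)
    truth = np.zeros((32, 32), bool)
    truth[8:16, 8:16] = True
    tuning = TuningResult(t1=84.0, t2=200.0, std_stop=100.0)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = fit([make_labeled(pixels, truth)], tuning, "ndi")
    assert any("borrowing thresholds" in str(w.message) for w in caught)
    assert model.thresholds[0] == model.thresholds[1] == model.thresholds[2]


def test_fit_rejects_empty_input():
    with pytest.raises(ValueError):
        fit([], TuningResult(t1=84, t2=140, std_stop=10), "ndi")


def test_fit_deterministic(flat_dataset):
    a = quick_fit(flat_dataset, "ndi")
    b = quick_fit(flat_dataset, "ndi")
    assert a.thresholds == b.thresholds
    assert a.combination == b.combination
    assert a.group_levels == b.group_levels


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def test_select_combination_prefers_perfect_single_dimension(rng):
    truth = disk_mask((40, 40), (20, 20), 8)
    stack = np.zeros((40, 40, 3), np.uint8)
    stack[..., 0] = truth
    stack[..., 1] = rng.integers(0, 2, (40, 40))
    stack[..., 2] = rng.integers(0, 2, (40, 40))
    combo, scores = select_combination([stack], [truth])
    assert combo == (0,)
    assert scores["1"] == 1.0


def test_select_combination_intersection_cleans_independent_noise():
    truth = disk_mask((60, 60), (30, 30), 10)
    noise_a = disk_mask((60, 60), (5, 5), 4)
    noise_b = disk_mask((60, 60), (55, 55), 4)
    stack = np.zeros((60, 60, 3), np.uint8)
    stack[..., 0] = truth | noise_a
    stack[..., 1] = truth | noise_b
    stack[..., 2] = np.random.default_rng(0).integers(0, 2, (60, 60))
    combo, scores = select_combination([stack], [truth])
    assert combo == (0, 1)
    assert scores["1∩2"] == 1.0


def test_select_combination_tie_prefers_fewer_dimensions():
    truth = disk_mask((30, 30), (15, 15), 6)
    stack = np.stack([truth, truth, truth], axis=-1).astype(np.uint8)
    combo, _ = select_combination([stack], [truth])
    assert combo == (0,)


def test_intersection_dominance(rng):
    # AND can only remove detections: both rates bounded by each operand's
    truth = rng.integers(0, 2, (16, 16))
    truth[0, 0] = 1
    truth[0, 1] = 0
    for _ in range(10):
        a = rng.integers(0, 2, (16, 16))
        b = rng.integers(0, 2, (16, 16))
        both = a & b
        assert tpr(both, truth) <= min(tpr(a, truth), tpr(b, truth))
        assert fpr(both, truth) <= min(fpr(a, truth), fpr(b, truth))


def test_model_json_round_trip(tmp_path, flat_model_rgb):
    path = tmp_path / "model.json"
    flat_model_rgb.save(path)
    back = ThresholdModel.load(path)
    assert back.space == flat_model_rgb.space
    assert back.thresholds == flat_model_rgb.thresholds
    assert back.directions == flat_model_rgb.directions
    assert back.combination == flat_model_rgb.combination
    assert back.group_levels == flat_model_rgb.group_levels
    assert back.split_config == flat_model_rgb.split_config


def test_model_validates_anchor_order():
    with pytest.raises(ValueError):
        ThresholdModel(
            space="ndi",
            group_levels=[50.0, 40.0, 120.0],
            thresholds=[[0.0] * 3] * 3,
            directions=[Direction.GT] * 3,
            combination=(0,),
            split_config=SplitConfig(std_stop=10, t1=84, t2=140),
        )
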