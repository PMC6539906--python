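import numpy as np
import pytest

from fruitseg.colorspace import ColorImage
from fruitseg.detection import (
    binarize,
    combine,
    detect,
    dimension_masks,
    interpolate_thresholds,
    morphological_cleanup,
    report_to_dict,
)
from fruitseg.metrics import Direction
from fruitseg.regions import SplitConfig
from fruitseg.training import ThresholdModel


def toy_model(thresholds, group_levels=(10.0, 70.0, 130.0), space="ndi"):
    return ThresholdModel(
        space=space,
        group_levels=list(group_levels),
        thresholds=[list(row) for row in thresholds],
        directions=[Direction.GT] * 3,
        combination=(0,),
        split_config=SplitConfig(std_stop=10.0, t1=40.0, t2=110.0),
    )


THREE_LEVELS = toy_model([[0.2] * 3, [0.4] * 3, [0.6] * 3])


def test_interpolation_exact_at_anchors():
    for level, row in zip(THREE_LEVELS.group_levels, THREE_LEVELS.thresholds):
        np.testing.assert_allclose(
            interpolate_thresholds(THREE_LEVELS, level), row
        )


def test_interpolation_worked_example():
    # anchors 10/70 with thresholds 0.2/0.4: level 40 is the midpoint
    np.testing.assert_allclose(
        interpolate_thresholds(THREE_LEVELS, 40.0), [0.3] * 3
    )


def test_interpolation_clamps_outside_anchor_span():
    np.testing.assert_allclose(interpolate_thresholds(THREE_LEVELS, 0.0), [0.2] * 3)
    np.testing.assert_allclose(interpolate_thresholds(THREE_LEVELS, 200.0), [0.6] * 3)


def test_interpolation_continuous_in_level():
    levels = np.linspace(5, 140, 300)
    values = np.array([interpolate_thresholds(THREE_LEVELS, lv)[0] for lv in levels])
    assert np.abs(np.diff(values)).max() < 0.01


def test_interpolation_random_models_exact_at_anchors(rng):
    for _ in range(10):
        anchors = np.sort(rng.uniform(0, 255, 3))
        if np.diff(anchors).min() < 1:
            continue
        table = rng.uniform(-1, 1, (3, 3))
        model = toy_model(table.tolist(), group_levels=anchors.tolist())
        for level, row in zip(anchors, table):
            np.testing.assert_allclose(
                interpolate_thresholds(model, level), row, atol=1e-12
            )


def test_literal_mode_agrees_at_midpoint_but_flips_anchors():
    mid = interpolate_thresholds(THREE_LEVELS, 40.0, mode="literal")
    np.testing.assert_allclose(mid, [0.3] * 3)
    # the printed weight ordering hands the lower anchor the *upper*
    # threshold, which is why the standard ordering is the default
    near_low = interpolate_thresholds(THREE_LEVELS, 10.0 + 1e-9, mode="literal")
    np.testing.assert_allclose(near_low, [0.4] * 3, atol=1e-6)
    with pytest.raises(ValueError):
        interpolate_thresholds(THREE_LEVELS, 40.0, mode="bogus")


def test_binarize_directions():
    pixels = np.full((4, 4, 3), 0.8)
    ones = binarize(pixels, [0.5] * 3, [Direction.GT] * 3)
    assert (ones == 1).all()
    zeros = binarize(pixels, [0.5] * 3, [Direction.LT] * 3)
    assert (zeros == 0).all()


def test_binarize_checkerboard():
    board = np.indices((4, 4)).sum(axis=0) % 2
    pixels = np.stack([board.astype(float)] * 3, axis=-1)
    out = binarize(pixels, [0.5] * 3, [Direction.GT] * 3)
    np.testing.assert_array_equal(out[..., 0], board)


def test_combine_matches_per_pixel_conjunction(rng):
    stack = rng.integers(0, 2, (8, 8, 3)).astype(np.uint8)
    for combo in [(0,), (0, 1), (1, 2), (0, 1, 2)]:
        got = combine(stack, combo)
        expected = np.ones((8, 8), bool)
        for d in combo:
            expected &= stack[..., d].astype(bool)
        np.testing.assert_array_equal(got.astype(bool), expected)
    assert (combine(np.stack([np.ones((4, 4)), stack[:4, :4, 0], stack[:4, :4, 1]], -1), (0, 1))
            == stack[:4, :4, 0]).all()
    with pytest.raises(ValueError):
        combine(stack, (2, 0))


def test_morphology_removes_small_blob_keeps_large():
    empty = np.zeros((40, 40), np.uint8)
    assert morphological_cleanup(empty).sum() == 0
    small = empty.copy()
    small[10:15, 10:15] = 1  # 5x5 blob cannot contain an 11x11 element
    assert morphological_cleanup(small).sum() == 0
    large = np.zeros((80, 80), np.uint8)
    large[10:60, 10:60] = 1
    cleaned = morphological_cleanup(large)
    assert cleaned.sum() >= 0.95 * 50 * 50
    assert (cleaned[10:60, 10:60] | (1 - large[10:60, 10:60])).all()


def test_detect_overexposed_image_is_all_background():
    white = ColorImage(np.full((64, 64, 3), 255.0), "rgb")
    report = detect(white, THREE_LEVELS)
    assert report.final_mask.sum() == 0
    assert report.per_dimension_masks.sum() == 0


def test_detect_intersection_subset_property(gradient_dataset, gradient_model_rgb):
    import dataclasses

    model = dataclasses.replace(gradient_model_rgb, combination=(0, 1))
    im = gradient_dataset[0]
    report = detect(im.rgb, model)
    raw = report.raw_mask.astype(bool)
    assert (raw <= report.per_dimension_masks[..., 0].astype(bool)).all()
    assert (raw <= report.per_dimension_masks[..., 1].astype(bool)).all()


def test_detect_deterministic(flat_dataset, flat_model_rgb):
    im = flat_dataset[0]
    a = detect(im.rgb, flat_model_rgb, im.truth)
    b = detect(im.rgb, flat_model_rgb, im.truth)
    np.testing.assert_array_equal(a.final_mask, b.final_mask)
    assert a.metrics == b.metrics


def test_detect_stitches_regions_exactly_once(gradient_dataset, gradient_model_rgb):
    im = gradient_dataset[1]
    report = detect(im.rgb, gradient_model_rgb)
    cov = np.zeros(im.rgb.shape, dtype=int)
    for region in report.regions:
        cov[region.slice()] += 1
    assert (cov == 1).all()


def test_detect_shape_mismatch_rejected(flat_dataset, flat_model_rgb):
    with pytest.raises(ValueError):
        detect(flat_dataset[0].rgb, flat_model_rgb, np.zeros((4, 4), bool))


def test_report_summary_is_json_friendly(flat_dataset, flat_model_rgb):
    import json

    im = flat_dataset[0]
    summary = report_to_dict(detect(im.rgb, flat_model_rgb, im.truth))
    encoded = json.loads(json.dumps(summary))
    assert encoded["metrics"]["f"] > 0.9
    assert encoded["n_regions"] == len(
        detect(im.rgb, flat_model_rgb).regions
    )
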