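"""Ganglion scoring: substack projection rule, ROI measurement,
normalization conventions, mixture thresholding and combination tables."""

import numpy as np
import pandas as pd
import pytest

from gustaquant import ganglion, synthetic
from gustaquant.datatypes import ROISet
from gustaquant.ganglion import (
    determine_threshold,
    measure_cells,
    normalize_intensities,
    project_substacks,
    score_cells,
)

from conftest import make_stack


# --------------------------------------------------------------------------
# substack projection


def test_thirty_slices_make_three_even_substacks():
    vol = np.arange(30 * 4 * 4).reshape(1, 30, 4, 4) % 251
    stack = make_stack(vol.astype(np.uint8), voxel_size=(1, 1, 1))
    projs = project_substacks(stack, thickness_um=10)
    assert len(projs) == 3
    for i, proj in enumerate(projs):
        np.testing.assert_array_equal(
            proj.voxels[0, 0], vol[0, 10 * i : 10 * (i + 1)].max(axis=0)
        )


@pytest.mark.parametrize("nz", range(21, 31))
def test_trailing_remainder_rule(nz):
    """Remainder >= half thickness becomes its own substack, else merges
    into the previous one; verified by enumerating 21-30 slice stacks."""
    rng = np.random.default_rng(nz)
    vol = rng.integers(0, 255, (1, nz, 3, 3)).astype(np.uint8)
    projs = project_substacks(make_stack(vol, voxel_size=(1, 1, 1)), 10)
    expected = [10] * (nz // 10)
    rem = nz % 10
    if rem:
        if rem >= 5:
            expected.append(rem)
        else:
            expected[-1] += rem
    assert len(projs) == len(expected)
    start = 0
    for size, proj in zip(expected, projs):
        np.testing.assert_array_equal(
            proj.voxels[0, 0], vol[0, start : start + size].max(axis=0)
        )
        start += size


def test_substack_thinner_than_slice_rejected():
    stack = make_stack(np.zeros((1, 5, 3, 3), np.uint8), voxel_size=(1, 1, 2))
    with pytest.raises(ValueError, match="at least one slice"):
        project_substacks(stack, thickness_um=1.0)


# --------------------------------------------------------------------------
# measurement and normalization


def _cells_projection():
    img = np.full((1, 20, 20), 20.0)
    labels = np.zeros((1, 20, 20), np.int32)
    img[0, 2:7, 2:7] = 100.0
    labels[0, 2:7, 2:7] = 1
    img[0, 10:15, 10:15] = 180.0
    labels[0, 10:15, 10:15] = 2
    stack = make_stack(img.astype(np.uint8), channel_names=("GFP",))
    rois = ROISet(labels, {1: "cell_1", 2: "cell_2"}, kind="cell")
    return stack, rois


def test_roi_mean_of_uniform_region():
    stack, rois = _cells_projection()
    table = measure_cells(stack, rois)
    assert table.loc[table["label"] == 1, "mean_GFP"].iloc[0] == 100.0
    assert table.loc[table["label"] == 2, "mean_GFP"].iloc[0] == 180.0


def test_roi_mean_matches_bruteforce_average():
    rng = np.random.default_rng(12)
    img = rng.integers(0, 255, (1, 12, 12)).astype(np.uint8)
    labels = np.zeros((1, 12, 12), np.int32)
    labels[0, 3:8, 4:9] = 1
    table = measure_cells(
        make_stack(img, channel_names=("GFP",)), ROISet(labels, {1: "c"}, "cell")
    )
    acc = [
        img[0, y, x]
        for y in range(12)
        for x in range(12)
        if labels[0, y, x] == 1
    ]
    assert table["mean_GFP"].iloc[0] == pytest.approx(np.mean(acc))


def test_normalization_arithmetic_with_max_scaling():
    stack, rois = _cells_projection()
    table = measure_cells(stack, rois)
    out = normalize_intensities(table, stack, rois, percentile=100)
    # background median 20; shifted means 80 and 160; scale = 160
    assert out.loc[out["label"] == 1, "norm_GFP"].iloc[0] == pytest.approx(0.5)
    assert out.loc[out["label"] == 2, "norm_GFP"].iloc[0] == pytest.approx(1.0)
    consts = out.attrs["normalization"]["GFP"]
    assert consts["background"] == 20.0
    assert consts["scale"] == 160.0


def test_normalization_invariant_to_intensity_rescaling():
    stack, rois = _cells_projection()
    table = normalize_intensities(measure_cells(stack, rois), stack, rois)
    bright = make_stack(
        stack.voxels.astype(np.uint16) * 3, channel_names=("GFP",), bit_depth=16
    )
    table3 = normalize_intensities(measure_cells(bright, rois), bright, rois)
    np.testing.assert_allclose(table["norm_GFP"], table3["norm_GFP"])


def test_blank_channel_rejected():
    img = np.full((1, 10, 10), 20, dtype=np.uint8)
    labels = np.zeros((1, 10, 10), np.int32)
    labels[0, 2:5, 2:5] = 1
    stack = make_stack(img, channel_names=("GFP",))
    rois = ROISet(labels, {1: "c"}, "cell")
    with pytest.raises(ValueError, match="blank"):
        normalize_intensities(measure_cells(stack, rois), stack, rois)


# --------------------------------------------------------------------------
# threshold determination


def test_bimodal_threshold_two_sd_above_lower_median(ganglion_values):
    vals = ganglion_values["value_GFP"].to_numpy()
    model = determine_threshold(vals, "GFP", seed=0)
    assert model.modality == "bimodal"
    assert 0.27 <= model.threshold <= 0.33
    # oracle: statistics of the true lower-component draws
    lower = vals[~ganglion_values["true_pos_GFP"].to_numpy()]
    oracle_t = np.median(lower) + 2 * np.std(lower, ddof=1)
    assert model.threshold == pytest.approx(oracle_t, abs=0.02)
    # the defining identity holds exactly
    assert model.threshold - model.lower_median == pytest.approx(
        2 * model.lower_sd, abs=1e-12
    )


def test_threshold_order_invariant(ganglion_values):
    vals = ganglion_values["value_GFP"].to_numpy()
    rng = np.random.default_rng(0)
    shuffled = vals.copy()
    rng.shuffle(shuffled)
    t1 = determine_threshold(vals, "GFP", seed=0).threshold
    t2 = determine_threshold(shuffled, "GFP", seed=0).threshold
    assert t1 == pytest.approx(t2, abs=1e-9)


def test_identical_values_degenerate_unimodal():
    model = determine_threshold(np.full(30, 0.4), "GFP")
    assert model.modality == "unimodal"
    assert model.threshold == 0.4
    table = pd.DataFrame({"norm_GFP": np.full(30, 0.4)})
    scored, _ = score_cells(table, {"GFP": model})
    assert not scored["pos_GFP"].any()  # strict inequality at the threshold


def test_too_few_values_rejected():
    with pytest.raises(ValueError, match="20"):
        determine_threshold(np.linspace(0, 1, 10), "GFP")


def test_unimodal_threshold_flagged_extrapolated():
    rng = np.random.default_rng(21)
    vals = rng.normal(0.5, 0.05, 400)
    model = determine_threshold(vals, "GFP", seed=0)
    assert model.modality == "unimodal"
    assert model.extrapolated
    assert model.threshold == pytest.approx(vals.mean() + 2 * vals.std(), rel=0.2)


# --------------------------------------------------------------------------
# scoring


def test_cell_exactly_at_threshold_is_negative(ganglion_values):
    model = determine_threshold(
        ganglion_values["value_GFP"].to_numpy(), "GFP", seed=0
    )
    table = pd.DataFrame({"norm_GFP": [model.threshold, model.threshold + 1e-9]})
    scored, _ = score_cells(table, {"GFP": model})
    assert list(scored["pos_GFP"]) == [False, True]


def test_combination_percentages_partition(ganglion_values):
    vals = ganglion_values.rename(
        columns={"value_GFP": "norm_GFP", "value_P2X3": "norm_P2X3"}
    )
    models = {
        ch: determine_threshold(vals[f"norm_{ch}"].to_numpy(), ch, seed=0)
        for ch in ("GFP", "P2X3")
    }
    _, summary = score_cells(vals, models, channels=["GFP", "P2X3"])
    combos = summary.dropna(subset=["combination"])
    assert combos["pct_of_cells"].sum() == pytest.approx(100.0)


def test_scoring_invariant_under_affine_rescaling(ganglion_values):
    vals = ganglion_values["value_GFP"].to_numpy()
    model = determine_threshold(vals, "GFP", seed=0)
    flags = vals > model.threshold
    rescaled = 3.0 * vals + 1.0
    model2 = determine_threshold(rescaled, "GFP", seed=0)
    flags2 = rescaled > model2.threshold
    np.testing.assert_array_equal(flags, flags2)


def test_missing_channel_model_rejected(ganglion_values):
    table = ganglion_values.rename(columns={"value_GFP": "norm_GFP"})
    with pytest.raises(ValueError, match="GFP"):
        score_cells(table[["norm_GFP"]], {}, channels=["GFP"])


def test_full_scoring_recovers_positive_fraction_on_rendered_field():
    """Imaging, projection, normalization and thresholding round trip."""
    params = synthetic.GanglionSimParams(n_cells=250, seed=31)
    field, truth, roi_sets = synthetic.generate_ganglion_field(params)
    projs = project_substacks(field, params.substack_thickness_um)
    tables = []
    for proj, rois in zip(projs, roi_sets):
        t = measure_cells(proj, rois)
        t = normalize_intensities(t, proj, rois)
        tables.append(t)
    pooled = pd.concat(tables, ignore_index=True)
    model = determine_threshold(pooled["norm_GFP"].to_numpy(), "GFP", seed=0)
    scored, _ = score_cells(pooled, {"GFP": model}, channels=["GFP"])
    merged = scored.merge(
        truth[["cell_id", "true_pos_GFP"]], left_on="label", right_on="cell_id"
    )
    true_frac = merged["true_pos_GFP"].mean()
    est_frac = merged["pos_GFP"].mean()
    assert abs(est_frac - true_frac) <= 0.03
    assert (merged["pos_GFP"] != merged["true_pos_GFP"]).mean() < 0.02
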