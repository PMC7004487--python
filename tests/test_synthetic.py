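"""Generator contracts: determinism, stored-truth self-consistency, and
the closed-form cases each simulated modality must reproduce."""

import numpy as np
import pytest

from gustaquant import synthetic
from gustaquant.synthetic import (
    BudSimParams,
    GanglionSimParams,
    TraceSimParams,
    generate_atp_plate,
    generate_bud_stack,
    generate_calcium_trace,
    generate_ganglion_field,
    generate_nerve_trace,
)

TINY_BUD = dict(
    stack_shape=(12, 72, 72),
    n_buds=1,
    bud_semiaxes_um=(5.0, 6.0, 6.0),
    cells_per_bud={"type_ii": 2, "type_iii": 2},
)


# --------------------------------------------------------------------------
# taste-bud stacks


def test_bud_stack_deterministic_given_seed():
    a, _ = generate_bud_stack(BudSimParams(seed=5, **TINY_BUD))
    b, _ = generate_bud_stack(BudSimParams(seed=5, **TINY_BUD))
    np.testing.assert_array_equal(a.voxels, b.voxels)


def test_bud_stack_seed_changes_output():
    a, _ = generate_bud_stack(BudSimParams(seed=5, **TINY_BUD))
    b, _ = generate_bud_stack(BudSimParams(seed=6, **TINY_BUD))
    assert not np.array_equal(a.voxels, b.voxels)


def test_true_fraction_hits_target_within_one_voxel():
    params = BudSimParams(seed=1, noise_sd=0.0, poisson_gain=0.0,
                          fiber_density=0.20, **TINY_BUD)
    _, truth = generate_bud_stack(params)
    roi_vox = int(truth.rois.mask_for(1).sum())
    frac = truth.innervation.query("channel == 'P2X3'")["fraction"].iloc[0]
    assert abs(frac - 0.20) <= 1.0 / roi_vox


def test_full_overlap_makes_fiber_channels_identical():
    params = BudSimParams(seed=2, channel_overlap_fraction=1.0, **TINY_BUD)
    _, truth = generate_bud_stack(params)
    np.testing.assert_array_equal(
        truth.fiber_masks["GFP"], truth.fiber_masks["P2X3"]
    )


def test_zero_overlap_makes_fiber_channels_disjoint():
    params = BudSimParams(seed=3, channel_overlap_fraction=0.0, **TINY_BUD)
    _, truth = generate_bud_stack(params)
    assert not (truth.fiber_masks["GFP"] & truth.fiber_masks["P2X3"]).any()
    assert truth.fiber_masks["GFP"].any()  # GFP still has its own fibers


def test_stored_truth_matches_recount_from_masks():
    params = BudSimParams(seed=4, **TINY_BUD)
    _, truth = generate_bud_stack(params)
    roi = truth.rois.mask_for(1)
    b = truth.fiber_masks["P2X3"] & roi
    a = truth.fiber_masks["GFP"] & roi
    stored_b = truth.innervation.query("channel == 'P2X3'")["fraction"].iloc[0]
    stored_f = truth.overlap["fraction"].iloc[0]
    assert stored_b == b.sum() / roi.sum()
    assert stored_f == (a & b).sum() / b.sum()


def test_cell_centroids_inside_their_bud():
    params = BudSimParams(seed=6, **TINY_BUD)
    _, truth = generate_bud_stack(params)
    roi = truth.rois.mask_for(1)
    for _, cell in truth.cells.iterrows():
        z, y, x = (int(round(cell[c])) for c in ("z", "y", "x"))
        assert roi[z, y, x]


def test_infeasible_fiber_density_raises():
    with pytest.raises(ValueError, match="infeasible"):
        BudSimParams(fiber_density=0.9, **TINY_BUD).validate()


def test_overlap_exceeding_gfp_density_raises():
    with pytest.raises(ValueError, match="overlap"):
        BudSimParams(
            fiber_density={"P2X3": 0.4, "GFP": 0.1},
            channel_overlap_fraction=0.9,
            **TINY_BUD,
        ).validate()


# --------------------------------------------------------------------------
# ganglion fields


def test_ganglion_zero_positive_fraction_all_negative():
    params = GanglionSimParams(
        n_cells=50, positive_fraction={"GFP": 0.0}, seed=1
    )
    truth = synthetic.draw_cell_intensities(params)
    assert not truth["true_pos_GFP"].any()
    # all values from the lower component, so well under the upper mean
    assert truth["value_GFP"].max() < 0.5


def test_ganglion_truth_count_is_self_consistent():
    params = GanglionSimParams(n_cells=100, positive_fraction={"GFP": 0.4}, seed=2)
    truth = synthetic.draw_cell_intensities(params)
    n_pos = int(truth["true_pos_GFP"].sum())
    # the stored flags are the same Bernoulli draws the values came from
    assert n_pos == (truth["value_GFP"] > 0.5).sum()


def test_ganglion_class_means_match_components_within_3se():
    params = GanglionSimParams(n_cells=1000, positive_fraction={"GFP": 0.5}, seed=3)
    truth = synthetic.draw_cell_intensities(params)
    for flag, mean in ((True, 0.8), (False, 0.2)):
        vals = truth.loc[truth["true_pos_GFP"] == flag, "value_GFP"]
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - mean) < 3 * se


def test_ganglion_empty_field_is_valid():
    params = GanglionSimParams(n_cells=0, seed=4, field_shape_yx=(64, 64))
    stack, truth, roi_sets = generate_ganglion_field(params)
    assert len(truth) == 0
    assert stack.voxels.shape[0] == len(params.channels)
    assert all(len(r.names) == 0 for r in roi_sets)


def test_ganglion_field_deterministic():
    params = dict(n_cells=40, seed=9, field_shape_yx=(128, 128))
    a, ta, _ = generate_ganglion_field(GanglionSimParams(**params))
    b, tb, _ = generate_ganglion_field(GanglionSimParams(**params))
    np.testing.assert_array_equal(a.voxels, b.voxels)
    assert ta.equals(tb)


def test_ganglion_unordered_means_rejected():
    with pytest.raises(ValueError, match="ordered"):
        GanglionSimParams(lower_mean=0.8, upper_mean=0.2).validate()


# --------------------------------------------------------------------------
# traces


def test_nerve_plateau_equals_baseline_plus_amplitude():
    params = TraceSimParams(
        baseline_level=1.0, amplitudes={"stim": 0.5}, rise_tau_s=0.0, noise_sd=0.0
    )
    trace, amps = generate_nerve_trace(params)
    stim = trace.stimuli[0]
    window = trace.values[
        int(stim.onset * params.sampling_rate) : int(stim.offset * params.sampling_rate)
    ]
    np.testing.assert_allclose(window, 1.5)
    assert amps["stim"] == 0.5


def test_nerve_zero_amplitude_is_baseline_plus_drift():
    params = TraceSimParams(
        baseline_level=2.0, drift_slope=0.01, amplitudes={"stim": 0.0}, noise_sd=0.0
    )
    trace, _ = generate_nerve_trace(params)
    np.testing.assert_allclose(trace.values, 2.0 + 0.01 * trace.times)


def test_drift_window_mean_matches_line_integral():
    slope = 0.02
    params = TraceSimParams(
        baseline_level=1.0, drift_slope=slope, amplitudes={"stim": 0.0},
        noise_sd=0.0, sampling_rate=10.0,
    )
    trace, _ = generate_nerve_trace(params)
    onset = trace.stimuli[0].onset
    sl = slice(int((onset - 10) * 10), int(onset * 10))
    # mean of sampled line over [onset-10, onset) = value at sample midpoint
    t_mid = np.mean(trace.times[sl])
    np.testing.assert_allclose(np.mean(trace.values[sl]), 1.0 + slope * t_mid)


def test_negative_baseline_rejected():
    with pytest.raises(ValueError, match="baseline"):
        generate_nerve_trace(TraceSimParams(baseline_level=-1.0))


def test_calcium_schedule_needs_15s_baseline():
    schedule = (synthetic.Stimulus("ATP", 10.0, 30.0),)
    with pytest.raises(ValueError, match="15 s"):
        generate_calcium_trace(TraceSimParams(schedule=schedule))


def test_calcium_true_delta_r_stored():
    params = TraceSimParams(
        sampling_rate=1.0, baseline_level=1.0, amplitudes={"ATP": 0.5},
        rise_tau_s=0.0, noise_sd=0.0,
    )
    trace, amps = generate_calcium_trace(params)
    assert amps["ATP"] == 0.5
    assert trace.kind == "calcium"
    assert trace.values.max() == pytest.approx(1.5)


def test_trace_deterministic_given_seed():
    params = TraceSimParams(noise_sd=0.05, seed=3)
    a, _ = generate_nerve_trace(params)
    b, _ = generate_nerve_trace(TraceSimParams(noise_sd=0.05, seed=3))
    np.testing.assert_array_equal(a.values, b.values)


def test_default_schedule_30s_on_40s_rinse_never_overlaps():
    sched = synthetic.default_schedule(["a", "b", "c"])
    for s0, s1 in zip(sched, sched[1:]):
        assert s1.onset - s0.offset == pytest.approx(40.0)
        assert s0.duration == 30.0


# --------------------------------------------------------------------------
# ATP plates


def test_plate_linear_noiseless():
    plate = generate_atp_plate(2.0, 100.0, {"NaCl 500 mM": [50.0]}, noise_sd=0.0)
    row = plate.loc[plate["condition"] == "NaCl 500 mM"].iloc[0]
    assert row["rlu"] == 200.0


def test_plate_zero_concentration_reads_intercept():
    plate = generate_atp_plate(3.0, 77.0, {"artificial saliva": [0.0]}, noise_sd=0.0)
    row = plate.loc[plate["condition"] == "artificial saliva"].iloc[0]
    assert row["rlu"] == 77.0


def test_plate_negative_concentration_rejected():
    with pytest.raises(ValueError, match="negative|non-negative"):
        generate_atp_plate(2.0, 100.0, {"NaCl 500 mM": [-1.0]})


def test_plate_deterministic_given_seed():
    a = generate_atp_plate(2.0, 100.0, {"c": [10, 20]}, noise_sd=5.0, seed=7)
    b = generate_atp_plate(2.0, 100.0, {"c": [10, 20]}, noise_sd=5.0, seed=7)
    assert a.equals(b)
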