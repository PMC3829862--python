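"""Generator: timebase protocol, field placement, transients, rendering."""

import numpy as np
import pytest

import fretscreen as fs
from fretscreen.simulate import _transient_shape

from conftest import archetype_cell


class TestTimebase:
    def test_default_protocol_has_13_frames_spanning_the_23p5s_windows(self):
        tb = fs.default_timebase()
        assert tb.n_frames == 13
        assert tb.n_pre == 3
        assert tb.dispense_index == 3
        # 5 s baseline at 2.5 s + 5 s at 1 s + 12.5 s at 2.5 s
        assert np.allclose(tb.times[:3], [0.0, 2.5, 5.0])
        assert np.allclose(np.diff(tb.times[3:8]), 1.0)
        assert np.allclose(np.diff(tb.times[7:]), 2.5)
        assert tb.times[-1] == pytest.approx(22.5)

    def test_times_strictly_increasing(self):
        tb = fs.default_timebase()
        assert np.all(np.diff(tb.times) > 0)

    def test_rejects_bad_dispense_index(self):
        with pytest.raises(ValueError):
            fs.Timebase(times=np.arange(5.0), dispense_index=0)
        with pytest.raises(ValueError):
            fs.Timebase(times=np.arange(5.0), dispense_index=5)

    def test_rejects_non_increasing_times(self):
        with pytest.raises(ValueError):
            fs.Timebase(times=np.array([0.0, 1.0, 1.0]), dispense_index=1)


class TestSimulateField:
    def test_zero_cells_gives_empty_list(self):
        params = fs.SimParams()
        assert fs.simulate_field(0, (64, 64), params, rng=0) == []

    def test_all_responders_when_fraction_is_one(self):
        params = fs.SimParams(responder_fraction=1.0)
        cells = fs.simulate_field(40, (512, 512), params, rng=0)
        assert all(c.is_responder for c in cells)
        assert all(c.peak_scale > 0 for c in cells)

    def test_min_center_distance_enforced(self):
        params = fs.SimParams()
        cells = fs.simulate_field(60, (512, 512), params, rng=3)
        centers = np.array([c.nucleus_center for c in cells])
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        d[np.diag_indices(len(cells))] = np.inf
        assert d.min() >= params.min_center_distance

    def test_impossible_packing_fails_explicitly(self):
        params = fs.SimParams()
        with pytest.raises(RuntimeError, match="reduce density"):
            fs.simulate_field(100, (64, 64), params, rng=0, max_attempts_per_cell=50)

    def test_responder_fraction_recovered_across_seeds(self):
        """Planted responder fraction averages to the parameter (within 3
        percentage points over >= 50 seeds at n=100)."""
        params = fs.SimParams.wild_type(n_cells=100)
        fractions = [
            np.mean([c.is_responder for c in fs.simulate_field(100, (512, 512), params, rng=s)])
            for s in range(50)
        ]
        assert abs(np.mean(fractions) - 0.29) < 0.03

    def test_deterministic_per_seed(self):
        params = fs.SimParams()
        a = fs.simulate_field(20, (256, 256), params, rng=42)
        b = fs.simulate_field(20, (256, 256), params, rng=42)
        assert a == b


class TestCalciumSeries:
    def test_non_responder_is_constant_baseline(self, timebase):
        params = fs.SimParams()
        cell = archetype_cell(params, responder=False)
        series = fs.calcium_series(cell, timebase)
        assert np.allclose(series, params.baseline_calcium)

    def test_full_suppression_equals_non_responder(self, timebase):
        params = fs.SimParams()
        responder = archetype_cell(params, responder=True)
        series = fs.calcium_series(responder, timebase, suppression=1.0)
        assert np.allclose(series, params.baseline_calcium)

    def test_genotype_amplitude_scales_evoked_component_threefold(self, timebase):
        params = fs.SimParams()
        cell = archetype_cell(params)
        wt = fs.calcium_series(cell, timebase, genotype_amplitude=1.0)
        fad = fs.calcium_series(cell, timebase, genotype_amplitude=3.0)
        evoked_wt = wt - params.baseline_calcium
        evoked_fad = fad - params.baseline_calcium
        post = timebase.dispense_index
        assert np.allclose(evoked_fad[post:], 3.0 * evoked_wt[post:])

    def test_baseline_flat_and_peak_after_dispense(self, timebase):
        params = fs.SimParams()
        cell = archetype_cell(params)
        series = fs.calcium_series(cell, timebase)
        assert np.allclose(series[: timebase.n_pre], params.baseline_calcium)
        assert np.argmax(series) >= timebase.dispense_index

    def test_suppression_monotonically_reduces_peak(self, timebase):
        params = fs.SimParams()
        cell = archetype_cell(params)
        peaks = [
            fs.calcium_series(cell, timebase, suppression=s).max()
            for s in np.linspace(0, 1, 6)
        ]
        assert np.all(np.diff(peaks) < 0)

    def test_negative_taus_rejected(self, timebase):
        with pytest.raises(ValueError):
            _transient_shape(np.array([1.0]), rise=-1.0, decay=6.0)
        with pytest.raises(ValueError):
            _transient_shape(np.array([1.0]), rise=0.8, decay=-6.0)

    def test_out_of_range_suppression_rejected(self, timebase):
        params = fs.SimParams()
        cell = archetype_cell(params)
        with pytest.raises(ValueError):
            fs.calcium_series(cell, timebase, suppression=1.5)


class TestSensorMap:
    def test_ratio_increases_with_calcium(self):
        sensor = fs.SensorMap()
        c = np.linspace(0, 10, 50)
        assert np.all(np.diff(sensor.ratio(c)) > 0)

    def test_saturation_compresses_a_doubling(self):
        # near saturation, doubling calcium raises the ratio by less than 2x
        sensor = fs.SensorMap()
        lift = lambda c: sensor.ratio(c) - sensor.ratio(0.0)
        assert lift(80.0) < 2 * lift(40.0)
        # well below half-saturation the response is nearly proportional
        assert lift(0.2) == pytest.approx(2 * lift(0.1), rel=0.01)


class TestRenderStack:
    def test_zero_cells_gives_background_only(self, timebase):
        params = fs.SimParams(photon_noise_scale=0.0, field_shape=(64, 64))
        stack = fs.render_stack([], np.zeros((0, timebase.n_frames)), timebase, params, rng=0)
        assert np.all(stack.channel("nuclear") == params.background["nuclear"])
        assert np.all(stack.channel("donor") == params.background["donor"])

    def test_constant_calcium_gives_constant_ratio(self, timebase):
        params = fs.SimParams(field_shape=(96, 96)).noiseless()
        cell = archetype_cell(params, responder=False)
        calcium = np.full((1, timebase.n_frames), 0.5)
        stack = fs.render_stack([cell], calcium, timebase, params, rng=0)
        nuclei, cyto = fs.ground_truth_labels([cell], params.field_shape)
        mask = cyto == 1
        donor = stack.channel("donor")[:, mask].mean(axis=1) - params.background["donor"]
        acceptor = stack.channel("acceptor")[:, mask].mean(axis=1) - params.background["acceptor"]
        ratio = acceptor / donor
        assert np.allclose(ratio, ratio[0])
        assert ratio[0] == pytest.approx(params.sensor.ratio(0.5))

    def test_mismatched_series_length_rejected(self, timebase):
        params = fs.SimParams(field_shape=(64, 64))
        cell = archetype_cell(params)
        with pytest.raises(ValueError, match="shape"):
            fs.render_stack([cell], np.zeros((1, 5)), timebase, params, rng=0)

    def test_deterministic_per_seed(self, timebase):
        params = fs.SimParams.wild_type(n_cells=10, field_shape=(128, 128))
        a = fs.simulate_well(params, 5)
        b = fs.simulate_well(params, 5)
        assert np.array_equal(a.stack.frames, b.stack.frames)
        assert a.cells == b.cells


class TestSimulatePlate:
    def test_dmso_only_layout_has_zero_suppression(self):
        layout = fs.PlateLayout()
        for i in range(4):
            layout.add(fs.Well(f"A{i+1:02d}", "DMSO", replicate=i + 1))
        layout.add(fs.Well("B01", "TP"))  # validate() needs one TP well
        params = fs.SimParams(n_cells=5, field_shape=(96, 96))
        plate = fs.simulate_plate(layout, params, seed=1)
        for wid in ("A01", "A02", "A03", "A04"):
            assert plate.wells[wid].suppression == 0.0
        assert plate.wells["B01"].suppression == params.control_suppression

    def test_positive_control_normalized_amplitude_below_0p35(self):
        """TP-like wells are planted at <= 0.35 of the DMSO evoked response."""
        params = fs.SimParams()
        norm = fs.expected_normalized_response(params.control_suppression, params)
        assert norm <= 0.35

    def test_stack_count_and_frame_count(self):
        layout = fs.make_layout(["C1"], n_replicates=2, n_dmso=1, n_tp=1,
                                n_cpa=0, n_tmb8=0, n_untreated=0)
        params = fs.SimParams(n_cells=4, field_shape=(96, 96))
        plate = fs.simulate_plate(layout, params, seed=2)
        assert len(plate.wells) == 4
        for sim in plate.wells.values():
            assert sim.stack.frames.shape[0] == 13

    def test_ground_truth_masks_cover_every_cell(self, small_noiseless_well):
        sim, params = small_noiseless_well
        labels = set(np.unique(sim.cell_labels)) - {0}
        assert labels == {c.cell_id for c in sim.cells}


def test_suppression_inversion_round_trip():
    params = fs.SimParams(responder_fraction=1.0).noiseless()
    for target in (0.3, 0.89, 0.9, 0.95):
        s = fs.suppression_for_normalized_response(target, params)
        assert fs.expected_normalized_response(s, params) == pytest.approx(target, abs=1e-9)
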