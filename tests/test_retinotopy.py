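import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import ks_2samp

from oracles import ks_d_by_pooled_evaluation
from tectoquant.retinotopy import (
    CalciumMovie,
    StimulusProtocol,
    apply_inclusion_criteria,
    compute_dff,
    estimate_receptive_fields,
    grid_map,
    ks_two_sample,
    make_bar_protocol,
    optimal_stimulus_position,
    position_response_table,
    receptive_field_sharpness,
    RFEstimate,
)
from tectoquant.synthetic import CellRF, generate_calcium_movie, make_roi_grid


def _tiny_protocol():
    # 5 positions presented once, 2-frame stimuli, explicit baseline
    pres = [(p, 10 + 4 * (p - 1), 12 + 4 * (p - 1)) for p in range(1, 6)]
    return StimulusProtocol(pres, np.arange(0, 10))


class TestDff:
    def test_constant_movie_is_zero(self):
        movie = CalciumMovie(np.full((30, 4, 4), 100.0), frame_rate_hz=10.0)
        dff, valid = compute_dff(movie, _tiny_protocol())
        assert valid.all()
        assert np.allclose(dff, 0.0)

    def test_three_fold_rise_is_two(self):
        frames = np.full((30, 2, 2), 100.0)
        frames[12:14] = 300.0
        dff, _ = compute_dff(CalciumMovie(frames, 10.0), _tiny_protocol())
        assert np.allclose(dff[12:14], 2.0)
        assert np.allclose(dff[:10], 0.0)

    def test_matches_per_pixel_hand_computation(self):
        frames = np.array(
            [[[10.0, 20.0], [40.0, 8.0]],
             [[30.0, 10.0], [40.0, 4.0]],
             [[50.0, 60.0], [40.0, 0.0]]]
        )
        protocol = StimulusProtocol(
            [(p, 1, 2) for p in range(1, 6)], np.array([0, 1])
        )
        dff, valid = compute_dff(CalciumMovie(frames, 1.0), protocol)
        f0 = np.array([[20.0, 15.0], [40.0, 6.0]])
        assert np.allclose(dff, (frames - f0) / f0)
        assert valid.all()

    def test_zero_baseline_pixels_flagged(self):
        frames = np.full((30, 2, 2), 50.0)
        frames[:, 0, 0] = 0.0
        dff, valid = compute_dff(CalciumMovie(frames, 10.0), _tiny_protocol())
        assert not valid[0, 0] and valid[1, 1]
        assert np.isnan(dff[:, 0, 0]).all()

    def test_all_zero_baseline_rejected(self):
        movie = CalciumMovie(np.zeros((30, 2, 2)), 10.0)
        with pytest.raises(ValueError):
            compute_dff(movie, _tiny_protocol())


class TestResponseTable:
    def test_repeat_presentations_average(self):
        # same position shown twice with responses 1.0 and 3.0
        pres = [(1, 10, 12), (1, 20, 22)] + [(p, 24 + 2 * p, 26 + 2 * p) for p in range(2, 6)]
        protocol = StimulusProtocol(pres, np.arange(0, 10))
        frames = np.full((40, 3, 3), 100.0)
        frames[10:12] = 200.0
        frames[20:22] = 400.0
        dff, _ = compute_dff(CalciumMovie(frames, 1.0), protocol)
        table = position_response_table(
            dff, protocol, [np.ones((3, 3), bool)], 1.0, decay_allowance_s=0.0
        )
        assert table.responses[0, 0] == pytest.approx(2.0)

    def test_constant_roi_gives_zero_vector(self):
        frames = np.full((40, 4, 4), 80.0)
        protocol = _tiny_protocol()
        dff, _ = compute_dff(CalciumMovie(frames, 10.0), protocol)
        table = position_response_table(dff, protocol, [np.ones((4, 4), bool)], 10.0)
        assert np.allclose(table.responses, 0.0)

    def test_empty_roi_rejected(self):
        frames = np.full((40, 4, 4), 80.0)
        protocol = _tiny_protocol()
        dff, _ = compute_dff(CalciumMovie(frames, 10.0), protocol)
        with pytest.raises(ValueError):
            position_response_table(dff, protocol, [np.zeros((4, 4), bool)], 10.0)


class TestOptimalPosition:
    @pytest.mark.parametrize(
        "responses, expected",
        [
            ((0, 0, 5, 0, 0), 3.0),
            ((2, 2, 2, 2, 2), 3.0),
            ((1, 2, 6, 2, 1), 3.0),
            ((0, 0, 0, 4, 4), 4.5),
        ],
    )
    def test_weighted_average_examples(self, responses, expected):
        assert optimal_stimulus_position(responses) == pytest.approx(expected, abs=1e-12)

    def test_negatives_rectified_before_weighting(self):
        assert optimal_stimulus_position((-5, 0, 4, 0, -5)) == pytest.approx(3.0)

    def test_all_nonpositive_is_undefined(self):
        assert np.isnan(optimal_stimulus_position((-1, 0, -2, 0, -0.5)))


class TestSharpness:
    def test_uniform_responses_give_unity(self):
        assert receptive_field_sharpness((3, 3, 3, 3, 3), 3.0) == pytest.approx(1.0)

    def test_peaked_example(self):
        # closest two to 3.0 are {3, 2} (tie to lower index): mean 4;
        # periphery {1, 4, 5}: mean 4/3 -> ratio 3
        assert receptive_field_sharpness((1, 2, 6, 2, 1), 3.0) == pytest.approx(3.0)

    def test_sparse_example(self):
        assert receptive_field_sharpness((0, 1, 4, 1, 0), 3.0) == pytest.approx(7.5)

    def test_nonpositive_periphery_is_undefined(self):
        assert np.isnan(receptive_field_sharpness((0, 1, 4, 0, 0), 3.0))

    def test_undefined_optimum_propagates(self):
        assert np.isnan(receptive_field_sharpness((1, 2, 6, 2, 1), float("nan")))


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    responses=st.lists(
        st.floats(min_value=0.0, max_value=50.0, allow_nan=False), min_size=5, max_size=5
    ).filter(lambda r: sum(r) > 1e-6 and sorted(r)[2] > 1e-9),
    scale=st.floats(min_value=0.01, max_value=100.0),
)
def test_rf_statistics_invariant_to_positive_scaling(responses, scale):
    r = np.array(responses)
    opt = optimal_stimulus_position(r)
    assert optimal_stimulus_position(r * scale) == pytest.approx(opt)
    sharp = receptive_field_sharpness(r, opt)
    scaled = receptive_field_sharpness(r * scale, optimal_stimulus_position(r * scale))
    if np.isfinite(sharp):
        assert scaled == pytest.approx(sharp)


class TestInclusionCriteria:
    @staticmethod
    def _estimate(roi_id=0, opt=3.0, sharp=2.0, peak=3.5, size=40, animal="a"):
        return RFEstimate(roi_id, opt, sharp, peak, size, animal)

    def test_weak_response_excluded_at_published_cutoff(self):
        ests, log = apply_inclusion_criteria(
            [self._estimate(peak=1.9)], min_cells_per_animal=1
        )
        assert not ests[0].included and ests[0].exclusion_reason == "weak_response"
        assert log == [(0, "weak_response")]

    def test_peripheral_optimum_excluded(self):
        ests, _ = apply_inclusion_criteria(
            [self._estimate(opt=4.3)], min_cells_per_animal=1
        )
        assert ests[0].exclusion_reason == "peripheral_optimum"

    def test_central_interval_is_inclusive(self):
        ests, _ = apply_inclusion_criteria(
            [self._estimate(opt=2.0), self._estimate(roi_id=1, opt=4.0)],
            min_cells_per_animal=1,
        )
        assert all(e.included for e in ests)

    def test_small_roi_excluded(self):
        ests, _ = apply_inclusion_criteria(
            [self._estimate(size=29)], min_cells_per_animal=1
        )
        assert ests[0].exclusion_reason == "small_roi"

    def test_undefined_sharpness_logged(self):
        ests, _ = apply_inclusion_criteria(
            [self._estimate(sharp=float("nan"))], min_cells_per_animal=1
        )
        assert ests[0].exclusion_reason == "undefined_sharpness"

    def test_animal_below_thirty_cells_dropped_entirely(self):
        animal_a = [self._estimate(roi_id=i, animal="a") for i in range(29)]
        animal_b = [self._estimate(roi_id=100 + i, animal="b") for i in range(30)]
        ests, _ = apply_inclusion_criteria(animal_a + animal_b)
        a_flags = [e.included for e in ests if e.animal_id == "a"]
        b_flags = [e.included for e in ests if e.animal_id == "b"]
        assert not any(a_flags) and all(b_flags)
        reasons = {e.exclusion_reason for e in ests if e.animal_id == "a"}
        assert reasons == {"animal_below_min_cells"}


class TestPipelineRecovery:
    def test_on_grid_center_recovered_and_deterministic(self):
        protocol = make_bar_protocol(
            n_repeats=2, stim_frames=5, gap_frames=100, pre_frames=50, rng=1
        )
        masks = make_roi_grid((32, 32), 1)
        cell = CellRF(0.0, 15.0, 4.0, masks[0])  # centre = middle position
        movie, rois = generate_calcium_movie(
            0, protocol, [cell], frame_rate_hz=10.0, decay_tau_s=0.5
        )
        dff, _ = compute_dff(movie, protocol)
        table = position_response_table(dff, protocol, rois, 10.0)
        est = estimate_receptive_fields(table)[0]
        assert est.optimal_position == pytest.approx(3.0, abs=1e-3)
        table2 = position_response_table(dff, protocol, rois, 10.0)
        assert np.array_equal(table.responses, table2.responses)

    def test_estimate_monotone_in_true_center(self):
        protocol = make_bar_protocol(
            n_repeats=2, stim_frames=5, gap_frames=80, pre_frames=40, rng=5
        )
        masks = make_roi_grid((32, 32), 1)
        estimates = []
        for center in np.linspace(-27.0, 27.0, 7):
            cell = CellRF(center, 12.0, 4.0, masks[0])
            movie, rois = generate_calcium_movie(
                1, protocol, [cell], frame_rate_hz=10.0, decay_tau_s=0.5
            )
            dff, _ = compute_dff(movie, protocol)
            table = position_response_table(dff, protocol, rois, 10.0)
            estimates.append(estimate_receptive_fields(table)[0].optimal_position)
        assert np.all(np.diff(estimates) > 0)

    def test_null_cell_leaves_movie_at_baseline(self):
        protocol = make_bar_protocol(rng=0)
        masks = make_roi_grid((16, 16), 1)
        movie, _ = generate_calcium_movie(
            0, protocol, [CellRF(0.0, 15.0, 0.0, masks[0])], f0=80.0
        )
        assert np.allclose(movie.frames, 80.0)


class TestGridMap:
    def _two_cell_setup(self):
        protocol = make_bar_protocol(
            n_repeats=2, stim_frames=5, gap_frames=80, pre_frames=40, rng=2
        )
        masks = make_roi_grid((24, 24), 2, roi_size=6, stride=12)
        deg = protocol.position_degrees
        # narrow fields: tails two positions away are ~1e-8, so the weighted
        # average sits on the true grid position to numerical precision
        cells = [CellRF(deg[1], 6.0, 4.0, masks[0]), CellRF(deg[3], 6.0, 4.0, masks[1])]
        movie, rois = generate_calcium_movie(
            0, protocol, cells, frame_rate_hz=10.0, decay_tau_s=0.5
        )
        dff, _ = compute_dff(movie, protocol)
        return dff, protocol, rois

    def test_two_cells_map_to_their_positions(self):
        dff, protocol, rois = self._two_cell_setup()
        pixel_map = grid_map(dff, protocol, 10.0)
        assert np.nanmean(pixel_map[rois[0]]) == pytest.approx(2.0, abs=1e-3)
        assert np.nanmean(pixel_map[rois[1]]) == pytest.approx(4.0, abs=1e-3)

    def test_unresponsive_pixels_flagged_nan(self):
        dff, protocol, rois = self._two_cell_setup()
        pixel_map = grid_map(dff, protocol, 10.0)
        background = ~(rois[0] | rois[1])
        assert np.isnan(pixel_map[background]).all()

    def test_invariant_to_positive_scaling_of_dff(self):
        dff, protocol, rois = self._two_cell_setup()
        a = grid_map(dff, protocol, 10.0)
        b = grid_map(dff * 3.0, protocol, 10.0)
        both = np.isfinite(a) & np.isfinite(b)
        assert np.array_equal(np.isfinite(a), np.isfinite(b))
        assert np.allclose(a[both], b[both])


class TestKS:
    def test_identical_samples_have_zero_distance(self):
        d, p = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports_have_distance_one(self):
        d, _ = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert d == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pooled_ecdf_oracle_and_scipy(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=50)
        b = rng.normal(0.4, 1.3, size=40)
        d, p = ks_two_sample(a, b)
        assert d == pytest.approx(ks_d_by_pooled_evaluation(a, b), abs=1e-12)
        ref = ks_2samp(a, b, method="asymp")
        assert d == pytest.approx(ref.statistic, abs=1e-12)
        assert 0.0 <= p <= 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])
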