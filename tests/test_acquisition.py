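import dataclasses

import numpy as np
import pytest

from arrcine import (
    AcquisitionParams,
    DegenerateCycleError,
    InfeasibleWindowError,
    InsufficientDataError,
    KSpacePlan,
    RRSeries,
    cs_reconstruct,
    plan_segmented,
    realtime_frame_count,
    simulate_realtime,
    simulate_segmented,
    temporal_interpolate,
    truth_stack,
)
from arrcine.acquisition import _fft2c, _sampling_mask


@pytest.fixture(scope="module")
def ref_params():
    return AcquisitionParams.reference()


class TestPlanSegmented:
    def test_constant_rr_no_phase_mixing(self, ref_params):
        rr = RRSeries(np.full(16, 824.0))
        plan = plan_segmented(ref_params, rr, n_lines=168)
        for frame in plan.entries:
            phases = {p for _, _, p in frame}
            assert len(phases) == 1

    def test_variable_rr_mixes_phases(self):
        # frame 10 of 20 at 40 ms: 400 ms into each beat
        params = AcquisitionParams(
            n_phases=20, temporal_resolution=40.0, views_per_frame=84
        )
        rr = RRSeries([800.0, 1000.0])
        plan = plan_segmented(params, rr, n_lines=168)
        phases = sorted(p for _, _, p in plan.entries[10])
        assert phases == pytest.approx([0.4, 0.5])

    def test_heartbeat_count_is_ceiling(self, ref_params):
        rr = RRSeries(np.full(32, 900.0))
        plan = plan_segmented(ref_params, rr, n_lines=168)
        beats = {h for frame in plan.entries for h, _, _ in frame}
        assert len(beats) == 13  # ceil(168 / 13)

    def test_lines_cover_kspace(self, ref_params):
        rr = RRSeries(np.full(16, 824.0))
        plan = plan_segmented(ref_params, rr, n_lines=168)
        covered = sorted(
            int(i) for _, lines, _ in plan.entries[0] for i in lines
        )
        assert covered == list(range(168))

    def test_window_clamped_to_shortest_rr(self, ref_params):
        rr = RRSeries(np.full(16, 500.0))
        plan = plan_segmented(ref_params, rr, n_lines=168)
        assert plan.n_frames == int(500.0 // 41.2)

    def test_infeasible_window(self, ref_params):
        with pytest.raises(InfeasibleWindowError):
            plan_segmented(ref_params, RRSeries([30.0, 30.0]), n_lines=168)

    def test_json_round_trip(self, ref_params, tmp_path):
        rr = RRSeries(np.full(16, 824.0))
        plan = plan_segmented(ref_params, rr, n_lines=64)
        path = tmp_path / "plan.json"
        plan.to_json(path)
        back = KSpacePlan.from_json(path)
        assert back.n_frames == plan.n_frames
        for fa, fb in zip(plan.entries, back.entries):
            for (ha, la, pa), (hb, lb, pb) in zip(fa, fb):
                assert ha == hb and pa == pytest.approx(pb)
                np.testing.assert_array_equal(np.asarray(la), lb)


class TestSimulateSegmented:
    def test_regular_rhythm_reproduces_truth(self, small_phantom):
        params = AcquisitionParams.reference(temporal_resolution=41.2)
        rr = RRSeries(np.full(16, 824.0))  # exactly 20 frames of 41.2 ms
        seg = simulate_segmented(small_phantom, params, rr)
        truth = truth_stack(small_phantom, 20)
        vrange = truth.frames.max() - truth.frames.min()
        rmse = np.sqrt(np.mean((seg.frames - truth.frames) ** 2))
        assert rmse < 1e-6 * vrange

    def test_irregular_rhythm_degrades_frames(self, small_phantom):
        from arrcine import ArrhythmiaSpec, generate_rr

        params = AcquisitionParams.reference()
        truth = truth_stack(small_phantom, 20)
        rr_reg = RRSeries(np.full(64, 824.0))
        rr_arr = generate_rr(ArrhythmiaSpec(824, "afib", 25.0, 64, seed=4))
        seg_reg = simulate_segmented(small_phantom, params, rr_reg)
        seg_arr = simulate_segmented(small_phantom, params, rr_arr)
        n = seg_arr.n_frames
        rmse_reg = np.sqrt(np.mean((seg_reg.frames[:n] - truth.frames[:n]) ** 2))
        rmse_arr = np.sqrt(np.mean((seg_arr.frames - truth.frames[:n]) ** 2))
        assert rmse_arr > rmse_reg


class TestSamplingMask:
    def test_center_always_sampled(self):
        params = AcquisitionParams.realtime(seed=0)
        rng = np.random.default_rng(0)
        mask = _sampling_mask(rng, 168, params)
        c0 = 168 // 2 - params.center_lines // 2
        assert mask[c0 : c0 + params.center_lines].all()

    def test_acceleration_controls_line_count(self):
        params = AcquisitionParams.realtime(seed=0)
        rng = np.random.default_rng(0)
        mask = _sampling_mask(rng, 168, params)
        assert mask.sum() == max(12, round(168 / 11))

    def test_full_sampling_at_unit_acceleration(self):
        params = AcquisitionParams.realtime(acceleration=1.0, seed=0)
        rng = np.random.default_rng(0)
        assert _sampling_mask(rng, 168, params).all()


class TestCsReconstruct:
    def test_full_sampling_is_exact(self, small_phantom):
        truth = truth_stack(small_phantom, 8)
        ksp = np.stack([_fft2c(f) for f in truth.frames])
        masks = np.ones((8, small_phantom.grid), dtype=bool)
        params = AcquisitionParams.realtime(acceleration=1.0, n_iterations=3)
        recon = np.abs(cs_reconstruct(ksp, masks, params))
        np.testing.assert_allclose(recon, truth.frames, atol=1e-10)

    def test_zero_threshold_returns_zero_filled(self, small_phantom):
        truth = truth_stack(small_phantom, 8)
        params = AcquisitionParams.realtime(threshold_weight=0.0, seed=1)
        rng = np.random.default_rng(1)
        masks = np.stack(
            [_sampling_mask(rng, small_phantom.grid, params) for _ in range(8)]
        )
        ksp = np.stack(
            [
                np.where(masks[t][:, None], _fft2c(truth.frames[t]), 0)
                for t in range(8)
            ]
        )
        recon = cs_reconstruct(ksp, masks, params)
        zf = np.stack(
            [
                np.fft.ifft2(np.fft.ifftshift(ksp[t], axes=0))
                for t in range(8)
            ]
        )
        np.testing.assert_allclose(recon, zf)

    def test_cs_beats_zero_filled_on_static_series(self):
        from arrcine import PhantomSpec

        static = PhantomSpec(grid=96, endo_radius_d=16, epi_radius_d=24,
                             contraction_fraction=0.0)
        truth = truth_stack(static, 12)
        params = AcquisitionParams.realtime(seed=3)
        rng = np.random.default_rng(3)
        masks = np.stack([_sampling_mask(rng, 96, params) for _ in range(12)])
        ksp = np.stack(
            [np.where(masks[t][:, None], _fft2c(truth.frames[t]), 0) for t in range(12)]
        )
        cs = np.abs(cs_reconstruct(ksp, masks, params))
        zf = np.abs(
            np.stack(
                [np.fft.ifft2(np.fft.ifftshift(ksp[t], axes=0)) for t in range(12)]
            )
        )
        rmse_cs = np.sqrt(np.mean((cs - truth.frames) ** 2))
        rmse_zf = np.sqrt(np.mean((zf - truth.frames) ** 2))
        assert rmse_cs < rmse_zf

    def test_residuals_non_increasing(self, small_phantom):
        truth = truth_stack(small_phantom, 10)
        params = AcquisitionParams.realtime(seed=7)
        rng = np.random.default_rng(7)
        masks = np.stack(
            [_sampling_mask(rng, small_phantom.grid, params) for _ in range(10)]
        )
        ksp = np.stack(
            [np.where(masks[t][:, None], _fft2c(truth.frames[t]), 0) for t in range(10)]
        )
        _, residuals = cs_reconstruct(ksp, masks, params, return_residuals=True)
        assert np.all(np.diff(residuals) <= 1e-9 * residuals[0])

    def test_empty_input_rejected(self):
        params = AcquisitionParams.realtime()
        with pytest.raises(InsufficientDataError):
            cs_reconstruct(np.zeros((0, 8, 8)), np.zeros((0, 8)), params)


class TestSimulateRealtime:
    def test_frame_count_is_floor_of_rr_over_tr(self):
        assert realtime_frame_count(833, 49) == 17
        assert realtime_frame_count(800, 49) == 16

    def test_fewer_than_16_frames_only_above_75_bpm(self):
        # 75 bpm <-> RR 800 ms: exactly 16 frames at 49 ms
        for rr in [800, 820, 900, 1100]:  # HR <= 75 bpm
            assert realtime_frame_count(rr, 49) >= 16
        for rr in [500, 700, 780]:
            if realtime_frame_count(rr, 49) < 16:
                assert 60000 / rr > 75

    def test_unit_acceleration_no_iterations_is_truth(self, small_phantom):
        from arrcine.phantom import render_phase

        params = AcquisitionParams.realtime(
            acceleration=1.0, n_iterations=0, seed=2
        )
        rr = RRSeries(np.full(3, 824.0))
        rt = simulate_realtime(small_phantom, params, rr)
        for t, p in enumerate(rt.phases):
            np.testing.assert_allclose(
                rt.frames[t], render_phase(small_phantom, float(p)), atol=1e-10
            )

    def test_degenerate_cycle(self, small_phantom):
        params = AcquisitionParams.realtime()
        with pytest.raises(DegenerateCycleError):
            simulate_realtime(small_phantom, params, RRSeries([40.0, 40.0]))

    def test_seeded_masks_are_deterministic(self, small_phantom):
        params = AcquisitionParams.realtime(seed=11)
        rr = RRSeries(np.full(2, 824.0))
        a = simulate_realtime(small_phantom, params, rr)
        b = simulate_realtime(small_phantom, params, rr)
        np.testing.assert_array_equal(a.frames, b.frames)


class TestTemporalInterpolate:
    def test_matching_grid_is_identity(self, small_phantom):
        truth = truth_stack(small_phantom, 20)
        out = temporal_interpolate(truth, 20)
        np.testing.assert_allclose(out.frames, truth.frames)

    def test_17_frames_to_20(self, small_phantom):
        params = AcquisitionParams.realtime(seed=1)
        rt = simulate_realtime(small_phantom, params, RRSeries(np.full(2, 833.0)))
        assert rt.n_frames == 17
        out = temporal_interpolate(rt, 20)
        assert out.n_frames == 20
        np.testing.assert_allclose(out.phases, np.arange(20) / 20)

    def test_constant_frames_interpolate_to_constant(self):
        from arrcine import CineStack

        frames = np.ones((2, 8, 8)) * 3.5
        stack = CineStack(frames=frames, phases=np.array([0.0, 0.5]))
        out = temporal_interpolate(stack, 10)
        np.testing.assert_allclose(out.frames, 3.5)

    def test_single_frame_rejected(self):
        from arrcine import CineStack

        stack = CineStack(frames=np.ones((1, 8, 8)), phases=np.array([0.0]))
        with pytest.raises(InsufficientDataError):
            temporal_interpolate(stack, 20)


def test_params_json_round_trip(tmp_path):
    params = AcquisitionParams.realtime(seed=9)
    path = tmp_path / "params.json"
    params.to_json(path)
    assert AcquisitionParams.from_json(path) == params
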