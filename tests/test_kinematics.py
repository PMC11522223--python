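"""Period estimation, drift removal and angle assignment."""

import numpy as np
import pytest

import wormhull as wh
from wormhull import imaging, kinematics
from wormhull.kinematics import PeriodEstimationError
from wormhull.pipeline import _mask_roi
from wormhull.protocols import battery_render_spec, battery_spec


@pytest.fixture(scope="module")
def small_spec():
    return battery_spec(2)


def _render(spec, period, n_frames, noise=0.0, seed=2, **kw):
    rs = wh.auto_render_spec(spec, 2.0, n_frames, period, seed=seed,
                             noise_sigma=noise, **kw)
    ph = wh.build_phantom(spec, voxel_um=1.0)
    return wh.render_stack(ph, rs)


def _estimate(render, **kw):
    enh = imaging.enhance(render.stack)
    sils = imaging.segment(enh)
    return kinematics.estimate_period(enh, roi=_mask_roi(sils), **kw)


class TestEstimatePeriod:
    def test_integer_period_recovered(self, small_spec):
        res = _render(small_spec, 40.0, 68)
        est = _estimate(res)
        assert abs(est.period_frames - 40.0) <= 0.5

    def test_non_integer_period_parabolic_refinement(self, small_spec):
        """A 48.5-frame period is resolved to better than half a frame."""
        res = _render(small_spec, 48.5, 82, noise=0.02)
        est = _estimate(res)
        assert abs(est.period_frames - 48.5) <= 0.5

    def test_identical_frames_rejected(self):
        frames = np.tile(np.random.default_rng(0).random((1, 32, 48)), (24, 1, 1))
        stack = wh.ImageStack(frames=frames.astype(np.float32), pixel_size_um=1.0)
        with pytest.raises(PeriodEstimationError):
            kinematics.estimate_period(stack)

    def test_rotation_symmetric_specimen_rejected(self):
        """A sphere looks the same at every angle: no reliable rotation."""
        ph = wh.build_phantom(wh.PhantomSpec(kind="sphere", max_radius_um=20.0), 1.0)
        rs = wh.RenderSpec(n_frames=40, period_frames=16.0, pixel_size_um=1.0,
                           shape=(64, 64), noise_sigma=0.0)
        res = wh.render_stack(ph, rs)
        with pytest.raises(PeriodEstimationError):
            kinematics.estimate_period(imaging.enhance(res.stack))

    def test_invariant_to_gain_and_offset(self, small_spec):
        """NCC is unchanged by global intensity scaling and offsets."""
        res = _render(small_spec, 40.0, 68)
        enh = imaging.enhance(res.stack, upsample_factor=1, denoise_weight=0.0)
        est1 = kinematics.estimate_period(enh)
        scaled = wh.ImageStack(frames=0.5 * enh.frames + 0.2,
                               pixel_size_um=enh.pixel_size_um)
        est2 = kinematics.estimate_period(scaled)
        np.testing.assert_allclose(est2.similarity, est1.similarity, atol=1e-5)
        assert est2.period_frames == pytest.approx(est1.period_frames, abs=1e-3)

    def test_lag_bounds_validated(self, small_spec):
        res = _render(small_spec, 40.0, 68)
        with pytest.raises(ValueError):
            kinematics.estimate_period(res.stack, min_lag=2, max_lag=60)
        with pytest.raises(ValueError):
            kinematics.estimate_period(res.stack, min_lag=10, max_lag=200)


class TestAlign:
    def _sils(self, spec, drift_mode="none", drift=(0.0, 0.0), seed=2):
        rs = wh.auto_render_spec(spec, 2.0, 68, 40.0, seed=seed, noise_sigma=0.0,
                                 drift_mode=drift_mode, drift_px=drift)
        ph = wh.build_phantom(spec, voxel_um=1.0)
        res = wh.render_stack(ph, rs)
        sils = imaging.segment(imaging.enhance(res.stack))
        return res, sils

    def test_zero_drift_offsets_near_zero(self, small_spec):
        _, sils = self._sils(small_spec)
        aligned = kinematics.align_frames(sils, period_frames=40.0)
        assert np.abs(aligned.offsets_px).max() <= 1  # integer shifts of <=1 px

    def test_constant_drift_recovered(self, small_spec):
        res, sils = self._sils(small_spec, drift_mode="constant", drift=(0.15, 0.1))
        aligned = kinematics.align_frames(sils, period_frames=40.0)
        # applied offsets undo the linear drift trace (drift is specified in
        # native pixels; the masks live on the upsampled raster)
        scale = res.stack.pixel_size_um / sils.pixel_size_um
        for axis in (0, 1):
            expect = -res.drift_px[:, axis] * scale
            err = aligned.offsets_px[:, axis] - expect
            assert np.abs(err - err.mean()).max() <= 1.0

    def test_alignment_is_fixed_point(self, small_spec):
        _, sils = self._sils(small_spec)
        once = kinematics.align_frames(sils, period_frames=40.0)
        twice = kinematics.align_frames(once, period_frames=40.0)
        assert np.abs(twice.offsets_px).max() <= 1


class TestAssignAngles:
    @staticmethod
    def _fake_est(period, T):
        return kinematics.RotationEstimate(
            period_frames=period,
            angles_rad=2 * np.pi * np.arange(T) / period,
            lags=np.arange(2), similarity=np.ones(2), peak_score=1.0,
        )

    @staticmethod
    def _fake_sils(T, rows=32, cols=48):
        masks = np.zeros((T, rows, cols), bool)
        masks[:, 10:20, 5:40] = True
        return wh.SilhouetteStack(
            masks=masks, pixel_size_um=1.0,
            confidence=np.ones((T, cols), np.float32),
            extents=np.tile([5, 40], (T, 1)),
            centroids=np.tile([14.5, 22.0], (T, 1)),
            failed=np.zeros(T, bool), axis_row=14.5,
        )

    def test_quarter_turn_bookkeeping(self):
        sils = self._fake_sils(80)
        win = kinematics.assign_angles(self._fake_est(64.0, 80), sils)
        assert len(win) == 64
        assert win.angles_rad[16] == pytest.approx(np.pi / 2)

    def test_non_integer_period_window(self):
        sils = self._fake_sils(60)
        win = kinematics.assign_angles(self._fake_est(48.5, 60), sils)
        assert len(win) == 49  # frame 48 has angle 2*pi*48/48.5 < 2*pi
        assert win.angles_rad[48] == pytest.approx(2 * np.pi * 48 / 48.5)
        assert win.angles_rad[-1] < 2 * np.pi

    def test_window_must_fit(self):
        sils = self._fake_sils(40)
        with pytest.raises(ValueError):
            kinematics.assign_angles(self._fake_est(48.0, 40), sils)

    def test_too_few_usable_frames_aborts(self):
        sils = self._fake_sils(20)
        sils.failed[:10] = True
        sils.masks[:10] = False
        with pytest.raises(kinematics.AlignmentError):
            kinematics.assign_angles(self._fake_est(16.0, 20), sils, n_min=12)

    def test_assigned_angles_match_generator(self, small_spec):
        res = _render(small_spec, 40.0, 68)
        enh = imaging.enhance(res.stack)
        sils = imaging.segment(enh)
        est = kinematics.estimate_period(enh, roi=_mask_roi(sils))
        win = kinematics.assign_angles(est, kinematics.align_frames(sils, est.period_frames))
        true = res.angles_rad[: len(win)]
        tol = 2 * np.pi * 0.5 / 40.0
        assert np.abs(win.angles_rad - true).max() <= tol
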