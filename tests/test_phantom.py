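"""Phantom generator: spec validation, analytic ground truth, rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wormhull as wh
from wormhull.phantom import PhantomError, RenderError, ground_truth_metrics


class TestSpecValidation:
    def test_zero_radius_rejected(self):
        with pytest.raises(PhantomError):
            wh.PhantomSpec(kind="worm", length_um=100.0, max_radius_um=0.0)

    def test_fat_worm_rejected(self):
        with pytest.raises(PhantomError):
            wh.PhantomSpec(kind="worm", length_um=40.0, max_radius_um=25.0)

    def test_negative_semi_axis_rejected(self):
        with pytest.raises(PhantomError):
            wh.PhantomSpec(kind="embryo", semi_axes_um=(25.0, -1.0, 15.0))

    @given(
        L=st.floats(200, 1500),
        r=st.floats(10, 30),
        taper=st.floats(0, 0.5),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_radius_profile_bounded_and_capped(self, L, r, taper):
        spec = wh.PhantomSpec(kind="worm", length_um=L, max_radius_um=r, taper=taper)
        u = np.linspace(0, 1, 201)
        prof = spec.radius_profile(u)
        assert np.all(prof >= 0)
        assert np.all(prof <= r + 1e-9)
        assert prof[0] == 0 and prof[-1] == 0  # caps close the body


class TestGroundTruth:
    def test_sphere_closed_form(self):
        spec = wh.PhantomSpec(kind="sphere", max_radius_um=25.0)
        m = ground_truth_metrics(spec)
        assert m["volume_um3"] == pytest.approx(4 / 3 * np.pi * 25**3)
        assert m["surface_area_um2"] == pytest.approx(4 * np.pi * 25**2)
        assert m["ratio"] == pytest.approx(1.0)

    def test_embryo_ellipsoid_closed_form(self):
        spec = wh.PhantomSpec(kind="embryo", semi_axes_um=(25.0, 15.0, 15.0))
        m = ground_truth_metrics(spec)
        # ~50 um long x ~30 um diameter ovoid
        assert m["volume_um3"] == pytest.approx(4 / 3 * np.pi * 25 * 15 * 15)
        assert m["length_um"] == pytest.approx(50.0)
        assert m["max_width_um"] == pytest.approx(30.0)

    def test_quadrature_matches_closed_forms_on_smooth_ellipsoid(self):
        bumpy = wh.PhantomSpec(kind="embryo", semi_axes_um=(25.0, 15.0, 15.0),
                               bump_amplitude_um=1e-9)
        m = ground_truth_metrics(bumpy)  # forces the quadrature path
        assert m["volume_um3"] == pytest.approx(4 / 3 * np.pi * 25 * 15 * 15, rel=1e-3)

    def test_worm_volume_quadrature_vs_fine_grid(self):
        """The continuous quadrature volume agrees with a fine-grid count
        and the count converges as the voxel is halved."""
        spec = wh.PhantomSpec(kind="worm", length_um=200.0, max_radius_um=18.0,
                              bend_amplitude_um=10.0, bend_wavelength_um=150.0)
        truth = ground_truth_metrics(spec)["volume_um3"]
        v_coarse = wh.build_phantom(spec, voxel_um=2.0).grid_bool.sum() * 2.0**3
        v_fine = wh.build_phantom(spec, voxel_um=1.0).grid_bool.sum() * 1.0**3
        assert v_fine == pytest.approx(truth, rel=0.01)
        assert abs(v_fine - v_coarse) / truth < 0.01

    def test_ratio_invariant(self):
        spec = wh.PhantomSpec(kind="worm", length_um=400.0, max_radius_um=20.0)
        m = ground_truth_metrics(spec)
        assert m["ratio"] == pytest.approx(m["length_um"] / m["max_width_um"], rel=1e-12)


class TestBuild:
    def test_grid_single_component_and_sampling_guard(self):
        spec = wh.PhantomSpec(kind="worm", length_um=300.0, max_radius_um=16.0)
        with pytest.raises(PhantomError):
            wh.build_phantom(spec, voxel_um=8.0)  # coarser than r/4
        ph = wh.build_phantom(spec, voxel_um=2.0)
        import scipy.ndimage as ndi

        _, n = ndi.label(ph.grid_bool, structure=ndi.generate_binary_structure(3, 1))
        assert n == 1

    def test_yaml_round_trip(self, tmp_path):
        spec = wh.sample_adult_spec(7)
        spec.to_yaml(tmp_path / "spec.yaml")
        back = wh.PhantomSpec.from_yaml(tmp_path / "spec.yaml")
        assert back == spec

    def test_yaml_unknown_key_rejected(self, tmp_path):
        (tmp_path / "bad.yaml").write_text("kind: worm\nwingspan_um: 3\n")
        with pytest.raises(PhantomError):
            wh.PhantomSpec.from_yaml(tmp_path / "bad.yaml")


@pytest.fixture(scope="module")
def small():
    spec = wh.PhantomSpec(kind="worm", length_um=200.0, max_radius_um=15.0,
                          bend_amplitude_um=12.0, bend_wavelength_um=160.0,
                          n_landmarks=2, rng_seed=0)
    return wh.build_phantom(spec, voxel_um=1.0)


class TestRender:

    def test_integer_period_frames_identical(self, small):
        rs = wh.RenderSpec(n_frames=40, period_frames=16.0, pixel_size_um=2.0,
                           shape=(48, 140), noise_sigma=0.0)
        res = wh.render_stack(small, rs)
        np.testing.assert_array_equal(res.stack.frames[0], res.stack.frames[16])
        np.testing.assert_array_equal(res.stack.frames[3], res.stack.frames[19])

    def test_sphere_silhouettes_identical_at_all_angles(self):
        ph = wh.build_phantom(wh.PhantomSpec(kind="sphere", max_radius_um=20.0), 1.0)
        rs = wh.RenderSpec(n_frames=24, period_frames=12.0, pixel_size_um=1.0,
                           shape=(64, 64), noise_sigma=0.0)
        res = wh.render_stack(ph, rs)
        # identical up to boundary-pixel rasterisation jitter
        area = res.true_silhouettes[0].sum()
        for s in res.true_silhouettes[1:]:
            assert (s ^ res.true_silhouettes[0]).sum() <= 0.01 * area

    def test_bent_worm_silhouette_area_trace_periodic(self, small):
        """The silhouette area of a bent worm oscillates and the rotation
        period is a period of the trace: its autocorrelation at the
        generator period matches the global maximum.  (The *fundamental*
        area period is half a turn -- a silhouette and its mirror image
        share an area -- which is why the period estimator correlates
        full images rather than area traces.)"""
        P = 16
        rs = wh.RenderSpec(n_frames=64, period_frames=float(P), pixel_size_um=2.0,
                           shape=(48, 140), noise_sigma=0.0)
        res = wh.render_stack(small, rs)
        area = res.true_silhouettes.reshape(len(res.stack), -1).sum(axis=1).astype(float)
        assert area.std() > 0  # it does vary
        area -= area.mean()
        ac = np.array([np.dot(area[: -k or None], area[k:]) / (64 - k)
                       for k in range(1, 33)])
        assert ac[P - 1] >= 0.95 * ac.max()

    def test_identical_seeds_bit_identical(self, small):
        rs = wh.RenderSpec(n_frames=12, period_frames=12.0, pixel_size_um=2.0,
                           shape=(48, 140), noise_sigma=0.03, rng_seed=42)
        a = wh.render_stack(small, rs)
        b = wh.render_stack(small, rs)
        np.testing.assert_array_equal(a.stack.frames, b.stack.frames)

    def test_specimen_too_large_for_frame(self, small):
        rs = wh.RenderSpec(n_frames=12, period_frames=12.0, pixel_size_um=2.0,
                           shape=(48, 40), noise_sigma=0.0)
        with pytest.raises(RenderError):
            wh.render_stack(small, rs)

    def test_tail_fade_darkens_intensity_only(self, small):
        """Fading reduces tail contrast but leaves true geometry untouched."""
        base = wh.RenderSpec(n_frames=8, period_frames=8.0, pixel_size_um=2.0,
                             shape=(48, 140), noise_sigma=0.0)
        faded = wh.RenderSpec(n_frames=8, period_frames=8.0, pixel_size_um=2.0,
                              shape=(48, 140), noise_sigma=0.0,
                              tail_fade_frac=0.3, tail_fade_floor=0.05)
        a = wh.render_stack(small, base)
        b = wh.render_stack(small, faded)
        np.testing.assert_array_equal(a.true_silhouettes, b.true_silhouettes)
        # worst-orientation frame 0: tail-side columns are brighter when faded
        tail_cols = slice(95, 115)
        assert b.clean_frames[0][:, tail_cols].min() > a.clean_frames[0][:, tail_cols].min()
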