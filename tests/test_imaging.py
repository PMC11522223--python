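"""Enhancement and segmentation: calibration bookkeeping, accuracy
against the generator's true silhouettes, and confidence gating."""

import numpy as np
import pytest

import wormhull as wh
from wormhull import imaging
from wormhull.imaging import SegmentationError


@pytest.fixture(scope="module")
def noisy_render():
    spec = wh.PhantomSpec(kind="worm", length_um=200.0, max_radius_um=15.0,
                          bend_amplitude_um=10.0, bend_wavelength_um=170.0,
                          n_landmarks=2, rng_seed=5)
    ph = wh.build_phantom(spec, voxel_um=1.0)
    rs = wh.RenderSpec(n_frames=12, period_frames=12.0, pixel_size_um=2.0,
                       shape=(48, 140), noise_sigma=0.05, rng_seed=5)
    return ph, wh.render_stack(ph, rs)


class TestEnhance:
    def test_constant_image_stays_constant(self):
        stack = wh.ImageStack(frames=np.full((2, 32, 32), 0.6, np.float32),
                              pixel_size_um=1.0)
        out = imaging.enhance(stack, upsample_factor=1, denoise_weight=0.0)
        np.testing.assert_allclose(out.frames, 0.6, atol=1e-5)

    def test_upsample_calibration_bookkeeping(self):
        stack = wh.ImageStack(frames=np.zeros((1, 100, 200), np.float32),
                              pixel_size_um=4.0)
        out = imaging.enhance(stack, upsample_factor=2)
        assert out.frames.shape == (1, 200, 400)
        assert out.pixel_size_um == 2.0
        with pytest.raises(ValueError):
            imaging.enhance(stack, upsample_factor=3)

    def test_denoising_reduces_error_to_clean_render(self, noisy_render):
        """Enhancement brings a noisy stack strictly closer to what the
        same enhancement yields on the noiseless render."""
        ph, res = noisy_render
        clean = wh.ImageStack(frames=np.clip(res.clean_frames, 0, 1),
                              pixel_size_um=res.stack.pixel_size_um)
        enh_noisy = imaging.enhance(res.stack, upsample_factor=1)
        enh_clean = imaging.enhance(clean, upsample_factor=1)
        mae_raw = np.abs(res.stack.frames - clean.frames).mean()
        mae_enh = np.abs(enh_noisy.frames - enh_clean.frames).mean()
        assert mae_enh < mae_raw

    def test_deterministic(self, noisy_render):
        _, res = noisy_render
        a = imaging.enhance(res.stack).frames
        b = imaging.enhance(res.stack).frames
        np.testing.assert_array_equal(a, b)


class TestSegment:
    def test_noiseless_convex_render_high_iou(self):
        """Masks of a noiseless sphere render overlap the generator's true
        silhouettes with IoU >= 0.98."""
        ph = wh.build_phantom(wh.PhantomSpec(kind="sphere", max_radius_um=25.0), 1.0)
        rs = wh.RenderSpec(n_frames=8, period_frames=8.0, pixel_size_um=0.5,
                           shape=(160, 160), noise_sigma=0.0)
        res = wh.render_stack(ph, rs)
        sils = imaging.segment(imaging.enhance(res.stack, upsample_factor=1))
        for i in range(4):
            t = res.true_silhouettes[i]
            m = sils.masks[i]
            iou = (t & m).sum() / (t | m).sum()
            assert iou >= 0.98

    def test_blank_frames_flagged_or_fatal(self):
        rng = np.random.default_rng(0)
        blank = (0.7 + 0.01 * rng.normal(size=(3, 64, 64))).astype(np.float32)
        with pytest.raises(SegmentationError):
            imaging.segment(wh.ImageStack(frames=blank, pixel_size_um=1.0))

    def test_single_blank_frame_flagged_not_zero_filled(self, noisy_render):
        _, res = noisy_render
        frames = res.stack.frames.copy()
        frames[3] = 0.7  # background only
        sils = imaging.segment(wh.ImageStack(frames=frames, pixel_size_um=2.0))
        assert sils.failed[3]
        assert not sils.masks[3].any()
        assert sils.ok.sum() == len(sils) - 1

    def test_masks_single_component(self, noisy_render):
        import scipy.ndimage as ndi

        _, res = noisy_render
        sils = imaging.segment(imaging.enhance(res.stack))
        for i in np.nonzero(sils.ok)[0]:
            _, n = ndi.label(sils.masks[i])
            assert n == 1

    def test_idempotent_on_own_output(self, noisy_render):
        """Segmenting the (inverted) mask image reproduces the mask."""
        _, res = noisy_render
        sils = imaging.segment(imaging.enhance(res.stack))
        img = (1.0 - sils.masks[0].astype(np.float32)) * 0.8
        again = imaging.segment(wh.ImageStack(frames=img[None], pixel_size_um=1.0))
        np.testing.assert_array_equal(again.masks[0], sils.masks[0])


class TestConfidentExtent:
    @staticmethod
    def _faded_run(fade_frac):
        spec = wh.PhantomSpec(kind="worm", length_um=300.0, max_radius_um=16.0,
                              bend_amplitude_um=10.0, bend_wavelength_um=260.0,
                              n_landmarks=2, rng_seed=6)
        ph = wh.build_phantom(spec, voxel_um=1.0)
        rs = wh.RenderSpec(n_frames=16, period_frames=16.0, pixel_size_um=2.0,
                           shape=(48, 190), noise_sigma=0.0,
                           tail_fade_frac=fade_frac, tail_fade_floor=0.03)
        res = wh.render_stack(ph, rs)
        sils = imaging.segment(imaging.enhance(res.stack))
        return res, sils

    def test_extent_excludes_faded_tail_columns(self):
        """At the worst orientation (frame 0) the confident extent stops
        before the faded tail, while bright body columns stay included."""
        res, sils = self._faded_run(0.3)
        t0 = np.kron(res.true_silhouettes[0], np.ones((2, 2), bool))
        cols = np.nonzero(t0.any(axis=0))[0]
        lo, hi = sils.extents[0]
        body_len = cols.max() - cols.min() + 1
        assert hi < cols.max() - 0.15 * body_len  # tail excluded
        assert lo < cols.min() + 0.1 * body_len  # body included from the head

    def test_less_fading_never_shortens_extent(self):
        _, strong = self._faded_run(0.35)
        _, weak = self._faded_run(0.15)
        width_strong = strong.extents[0, 1] - strong.extents[0, 0]
        width_weak = weak.extents[0, 1] - weak.extents[0, 0]
        assert width_weak >= width_strong


class TestIO:
    def test_tiff_round_trip(self, tmp_path, noisy_render):
        _, res = noisy_render
        path = tmp_path / "stack.tif"
        res.stack.write_tiff(path)
        back = imaging.read_stack(path, pixel_size_um=res.stack.pixel_size_um)
        assert back.frames.shape == res.stack.frames.shape
        np.testing.assert_allclose(back.frames, res.stack.frames, atol=1.1 / 65535)
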