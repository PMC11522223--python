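"""Carving: analytic strip-intersection laws, slicewise/bruteforce
equivalence, superset property, meshing."""

import numpy as np
import pytest

import wormhull as wh
from wormhull import hull, imaging, kinematics
from wormhull.hull import ReconstructionError, carve_bruteforce, carve_slicewise, extract_mesh
from wormhull.protocols import battery_render_spec, battery_spec

from conftest import angle_stamped_window


def rectangle_stack(n_angles, half_height_px, rows=128, cols=24, span=(4, 20),
                    half_turn=True):
    """Identical rectangle silhouettes at uniform angles; the analytic
    visual-hull cross-section is then the regular 2N-gon of apothem r."""
    masks = np.zeros((n_angles, rows, cols), bool)
    axis = (rows - 1) / 2
    r = half_height_px
    lo, hi = int(np.ceil(axis - r + 0.5)), int(np.floor(axis + r - 0.5))
    masks[:, lo: hi + 1, span[0]: span[1]] = True
    angles = (np.pi if half_turn else 2 * np.pi) * np.arange(n_angles) / n_angles
    return wh.SilhouetteStack(
        masks=masks,
        pixel_size_um=1.0,
        confidence=np.ones((n_angles, cols), np.float32),
        extents=np.tile([span[0], span[1]], (n_angles, 1)),
        centroids=np.tile([axis, (span[0] + span[1]) / 2], (n_angles, 1)),
        failed=np.zeros(n_angles, bool),
        axis_row=axis,
        angles_rad=angles,
        residuals_px=np.zeros((n_angles, 2)),
    )


class TestStripIntersectionLaw:
    @pytest.mark.parametrize("n_angles", [4, 8, 90])
    def test_cross_section_area_matches_2n_gon(self, n_angles):
        """N strips of half-width r at uniform angles intersect in the
        regular 2N-gon with area 2N r^2 tan(pi/2N)."""
        r = 50.0
        sils = rectangle_stack(n_angles, half_height_px=r)
        vol = carve_slicewise(sils, voxel_um=0.5)
        mid = vol.grid.shape[0] // 2
        area = vol.grid[mid].sum() * vol.voxel_um**2
        expected = 2 * n_angles * r**2 * np.tan(np.pi / (2 * n_angles))
        assert area == pytest.approx(expected, rel=0.02)

    def test_many_angles_approach_circle(self):
        r = 50.0
        vol = carve_slicewise(rectangle_stack(90, half_height_px=r), voxel_um=0.5)
        mid = vol.grid.shape[0] // 2
        assert vol.grid[mid].sum() * 0.25 == pytest.approx(np.pi * r**2, rel=0.02)

    def test_volume_decreases_as_frames_are_added(self):
        r = 40.0
        vols = []
        for n in (2, 4, 8, 16):
            v = carve_slicewise(rectangle_stack(n, half_height_px=r), voxel_um=1.0)
            vols.append(v.volume_um3)
        assert all(a >= b for a, b in zip(vols, vols[1:]))


class TestOracleEquivalence:
    @staticmethod
    def _phantom_window(kind, seed):
        if kind == "worm":
            spec = battery_spec(seed)
            rs = battery_render_spec(spec, seed)
            vox = 1.0
        elif kind == "worm_faded":
            spec = battery_spec(seed)
            rs = battery_render_spec(spec, seed)
            rs.tail_fade_frac, rs.tail_fade_floor = 0.25, 0.03
            vox = 1.0
        elif kind == "embryo":
            spec = wh.embryo_spec(seed=seed)
            rs = wh.embryo_render_spec(seed=seed, noise_sigma=0.0)
            vox = 0.3
        elif kind == "cylinder":
            spec = wh.PhantomSpec(kind="cylinder", length_um=120.0, max_radius_um=20.0,
                                  bump_amplitude_um=0.8, n_landmarks=2, rng_seed=seed)
            rs = wh.auto_render_spec(spec, 1.0, 24, 24.0, seed=seed, noise_sigma=0.0)
            vox = 0.5
        ph = wh.build_phantom(spec, voxel_um=vox)
        res = wh.render_stack(ph, rs)
        return angle_stamped_window(res)

    @pytest.mark.parametrize("kind,seed", [
        ("worm", 1), ("worm", 2), ("worm_faded", 3), ("embryo", 4), ("cylinder", 5),
    ])
    def test_slicewise_equals_bruteforce(self, kind, seed):
        win = self._phantom_window(kind, seed)
        a = carve_slicewise(win)
        b = carve_bruteforce(win)
        np.testing.assert_array_equal(a.grid, b.grid)

    def test_single_frame_extrudes_silhouette(self):
        sils = rectangle_stack(1, half_height_px=20.0, rows=64)
        vol = carve_slicewise(sils, voxel_um=1.0)
        from wormhull.validate import reproject

        np.testing.assert_array_equal(reproject(vol, 0.0), sils.masks[0])

    def test_zero_usable_frames_error(self):
        sils = rectangle_stack(4, half_height_px=20.0, rows=64)
        sils.failed[:] = True
        with pytest.raises(ReconstructionError):
            carve_slicewise(sils)


class TestSupersetProperty:
    def test_hull_projection_covers_true_silhouette(self, small_worm):
        """The visual hull is a superset of the body, so its projection
        must cover the generator's true silhouette (up to the one-voxel
        boundary tolerance that rasterisation allows)."""
        from wormhull.validate import reproject

        phantom, render = small_worm
        win = angle_stamped_window(render)
        vol = carve_slicewise(win)
        import scipy.ndimage as ndi

        for frame in (0, len(win) // 3):
            angle = float(np.rad2deg(win.angles_rad[frame]))
            proj = reproject(vol, angle)
            truth = np.kron(render.true_silhouettes[frame], np.ones((2, 2), bool))
            interior = ndi.binary_erosion(truth, iterations=2)  # 1 native px
            covered = (interior & proj).sum() / interior.sum()
            assert covered > 0.995

    def test_empty_volume_reports_diagnostics(self):
        sils = rectangle_stack(4, half_height_px=20.0, rows=64)
        # disjoint extents leave every slice unconstrained -> empty volume
        sils.extents[:] = [0, 0]
        with pytest.raises(ReconstructionError):
            carve_slicewise(sils)


@pytest.fixture(scope="module")
def sphere_vol():
    n = 101
    c = (n - 1) / 2
    x, y, z = np.mgrid[0:n, 0:n, 0:n]
    grid = ((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2) <= (25.0 / 0.6) ** 2
    return hull.VoxelVolume(grid=grid, voxel_um=0.6)


class TestMesh:

    def test_sphere_area_and_volume_closed_form(self, sphere_vol):
        mesh = extract_mesh(sphere_vol, smooth_iters=10)
        assert mesh.watertight
        assert mesh.area_um2 == pytest.approx(4 * np.pi * 25**2, rel=0.03)
        assert mesh.volume_um3 == pytest.approx(4 / 3 * np.pi * 25**3, rel=0.03)

    def test_mesh_volume_consistent_with_voxel_count(self, sphere_vol):
        mesh = extract_mesh(sphere_vol, smooth_iters=10)
        assert mesh.volume_um3 == pytest.approx(sphere_vol.volume_um3, rel=0.02)

    def test_smoothing_preserves_volume(self, sphere_vol):
        v0 = extract_mesh(sphere_vol, smooth_iters=0).volume_um3
        v10 = extract_mesh(sphere_vol, smooth_iters=10).volume_um3
        assert abs(v10 - v0) / v0 < 0.01

    def test_empty_volume_rejected(self):
        empty = hull.VoxelVolume(grid=np.zeros((4, 5, 5), bool), voxel_um=1.0)
        with pytest.raises(ReconstructionError):
            extract_mesh(empty)
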