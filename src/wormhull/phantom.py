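"""Parametric specimen phantoms and brightfield rotation-stack rendering.

This module stands in for the robotic rotation rig: it builds analytic
3-D solids that mimic C. elegans adults (rod-like, ~1 mm long, ~50 um
maximum diameter), embryos (ovoids ~50 x 30 um) and calibration shapes
(sphere, cylinder, ellipsoid), and renders the image stack a camera
would record while the specimen rolls uniformly about the horizontal
image axis.

Every phantom is a swept solid: cross-sections perpendicular to the
body axis x, each a (possibly bumpy) circle or ellipse whose centre may
be displaced in the co-rotating plane (the centreline bend).  Ground
truth for the five morphometric readouts (surface area, volume, length,
maximum width, length/width ratio) is evaluated by dense quadrature of
the continuous parametric definition, with closed forms substituted
where they exist (sphere, bump-free ellipsoid, cylinder).

Brightfield contrast is modelled as a saturating function of projected
material thickness, so silhouette edges are sharp while the interior
carries texture from internal "landmark" inclusions (the transparent /
opaque organelles that real recordings show and that the period
estimator keys on).  Landmarks and the low-contrast tail fade modulate
intensity only -- the geometric ground truth is unaffected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import scipy.ndimage as ndi
import yaml

from .imaging import ImageStack

__all__ = [
    "PhantomSpec",
    "RenderSpec",
    "GroundTruth",
    "Phantom",
    "RenderResult",
    "PhantomError",
    "RenderError",
    "build_phantom",
    "render_stack",
    "adult_spec",
    "embryo_spec",
    "adult_render_spec",
    "auto_render_spec",
    "embryo_render_spec",
    "sample_adult_spec",
    "sample_embryo_spec",
]

Kind = Literal["worm", "embryo", "cylinder", "sphere", "ellipsoid"]


class PhantomError(ValueError):
    """Raised for degenerate or inconsistent phantom specifications."""


class RenderError(ValueError):
    """Raised when a stack cannot be rendered (e.g. specimen exceeds frame)."""


@dataclass
class PhantomSpec:
    """Parametric description of one specimen.

    Lengths are in micrometres.  ``kind='worm'`` is a tapered tube of
    length ``length_um`` and maximum radius ``max_radius_um`` with
    head/tail caps, an in-plane sinusoidal centreline bend, and an
    optional helical surface corrugation.  ``kind='embryo'`` (alias
    ``ellipsoid``) is an ellipsoid with semi-axes ``semi_axes_um`` and
    the same corrugation model.  ``sphere`` and ``cylinder`` are
    calibration shapes with closed-form metrics.
    """

    kind: Kind = "worm"
    length_um: float = 1000.0
    max_radius_um: float = 25.0
    # radius profile: r(u) = r_max * (1 - taper*(2u-1)^2) * caps(u)
    taper: float = 0.2
    cap_frac_head: float = 0.08
    cap_frac_tail: float = 0.15
    cap_shape_head: float = 1.0
    cap_shape_tail: float = 1.3
    # centreline bend in the co-rotating plane
    bend_amplitude_um: float = 0.0
    bend_wavelength_um: float = 900.0
    bend_phase: float = 0.0
    # embryo / ellipsoid semi-axes (a = half length along x)
    semi_axes_um: tuple[float, float, float] = (25.0, 15.0, 15.0)
    # helical surface corrugation (amplitude is absolute at max radius);
    # bump_asymmetry adds a one-lobed component so the surface has no
    # residual m-fold rotational symmetry (real specimens are lumpy and
    # asymmetric, and a perfectly m-fold symmetric surface would make
    # the rotation period ambiguous at 1/m of a turn)
    bump_amplitude_um: float = 0.0
    bump_frequency: int = 5
    bump_pitch_um: float = 0.0  # 0 -> half the axial length
    bump_asymmetry: float = 0.6
    # internal intensity landmarks (geometry is untouched)
    n_landmarks: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("worm", "embryo", "cylinder", "sphere", "ellipsoid"):
            raise PhantomError(f"unknown phantom kind {self.kind!r}")
        if self.kind in ("worm", "cylinder"):
            if self.length_um <= 0 or self.max_radius_um <= 0:
                raise PhantomError("length_um and max_radius_um must be positive")
            if self.kind == "worm" and 2 * self.max_radius_um > self.length_um:
                raise PhantomError("worm requires 2*max_radius_um <= length_um")
        if self.kind == "sphere" and self.max_radius_um <= 0:
            raise PhantomError("sphere radius must be positive")
        if self.kind in ("embryo", "ellipsoid") and min(self.semi_axes_um) <= 0:
            raise PhantomError("all semi-axes must be positive")
        if not 0 <= self.taper < 1:
            raise PhantomError("taper must lie in [0, 1)")
        if abs(self.bump_amplitude_um) * (1 + abs(self.bump_asymmetry)) >= (
            0.5 * self.reference_radius_um
        ):
            raise PhantomError("bump amplitude too large for a star-convex section")

    # -- derived geometry ------------------------------------------------
    @property
    def axial_length_um(self) -> float:
        """Extent of the body along the rotation axis x."""
        if self.kind in ("worm", "cylinder"):
            return self.length_um
        if self.kind == "sphere":
            return 2.0 * self.max_radius_um
        return 2.0 * self.semi_axes_um[0]

    @property
    def reference_radius_um(self) -> float:
        """Radius scale used to normalise the relative bump amplitude."""
        if self.kind in ("worm", "cylinder", "sphere"):
            return self.max_radius_um
        return min(self.semi_axes_um[1], self.semi_axes_um[2])

    def radius_profile(self, u: np.ndarray) -> np.ndarray:
        """Worm tube radius at normalised arc position u in [0, 1]."""
        u = np.asarray(u, dtype=float)
        body = 1.0 - self.taper * (2.0 * u - 1.0) ** 2
        caps = np.ones_like(u)
        ch, ct = self.cap_frac_head, self.cap_frac_tail
        if ch > 0:
            m = u < ch
            caps[m] = np.sin(0.5 * np.pi * u[m] / ch) ** self.cap_shape_head
        if ct > 0:
            m = u > 1.0 - ct
            caps[m] = np.sin(0.5 * np.pi * (1.0 - u[m]) / ct) ** self.cap_shape_tail
        return self.max_radius_um * body * caps

    def _section_arrays(self, xs: np.ndarray):
        """Per-station (off, ry, rz, bump_rel, bump_phase) along the axis."""
        L = self.axial_length_um
        u = np.clip(xs / L, 0.0, 1.0)
        if self.kind in ("worm", "cylinder"):
            if self.kind == "worm":
                r = self.radius_profile(u)
            else:
                r = np.full_like(u, self.max_radius_um)
                r[(u <= 0) | (u >= 1)] = 0.0
            ry = rz = r
            off = self.bend_amplitude_um * np.sin(
                2.0 * np.pi * xs / self.bend_wavelength_um + self.bend_phase
            ) if self.kind == "worm" and self.bend_amplitude_um else np.zeros_like(u)
        else:
            if self.kind == "sphere":
                a = b = c = self.max_radius_um
            else:
                a, b, c = self.semi_axes_um
            s = np.sqrt(np.clip(1.0 - ((xs - a) / a) ** 2, 0.0, None))
            ry, rz = b * s, c * s
            off = np.zeros_like(u)
        if self.bump_amplitude_um:
            rel = self.bump_amplitude_um / self.reference_radius_um
            pitch = self.bump_pitch_um or 0.5 * L
            phase = 2.0 * np.pi * xs / pitch
        else:
            rel, phase = 0.0, np.zeros_like(u)
        return off, ry, rz, rel, phase

    def bend_offset(self, xs: np.ndarray) -> np.ndarray:
        return self._section_arrays(np.asarray(xs, dtype=float))[0]

    def bump_eps(self, phi: np.ndarray, phase) -> np.ndarray | float:
        """Relative radial corrugation at section angle phi / helical phase."""
        if not self.bump_amplitude_um:
            return 0.0
        rel = self.bump_amplitude_um / self.reference_radius_um
        return rel * (
            np.cos(self.bump_frequency * phi + phase)
            + self.bump_asymmetry * np.cos(phi + 0.61 * phase + 1.3)
        )

    # -- (de)serialisation ----------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["semi_axes_um"] = list(d["semi_axes_um"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        d = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise PhantomError(f"unknown PhantomSpec keys: {sorted(unknown)}")
        if "semi_axes_um" in d:
            d["semi_axes_um"] = tuple(d["semi_axes_um"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Oracle geometry for one phantom.

    Metrics come from quadrature of the continuous definition (or closed
    forms); the occupancy grid and mesh are at the build resolution.
    Angles/drift are filled in by :func:`render_stack`.
    """

    metrics: dict[str, float]
    occupancy: np.ndarray  # bool (nx, ny, nz)
    voxel_um: float
    mesh: "object | None" = None
    angles_rad: np.ndarray | None = None
    drift_px: np.ndarray | None = None

    def save_json(self, path: str | Path) -> None:
        out = {"voxel_um": self.voxel_um, "metrics": self.metrics}
        if self.angles_rad is not None:
            out["angles_rad"] = np.asarray(self.angles_rad).tolist()
        Path(path).write_text(json.dumps(out, indent=2))


@dataclass
class Phantom:
    """A built phantom: fractional occupancy + landmark field + truth."""

    spec: PhantomSpec
    voxel_um: float
    occupancy: np.ndarray  # float32 fractional coverage (nx, ny, nz)
    landmark_field: np.ndarray | None
    ground_truth: GroundTruth
    x0_um: float  # physical x of voxel index 0 centre (body head at x=0)

    @property
    def grid_bool(self) -> np.ndarray:
        return self.occupancy >= 0.5

    def centroid_um(self) -> np.ndarray:
        """Occupancy-weighted centroid in grid coordinates (um)."""
        w = self.occupancy
        idx = np.array(np.nonzero(w > 0))
        ww = w[w > 0]
        com = (idx * ww).sum(axis=1) / ww.sum()
        return com * self.voxel_um


# ----------------------------------------------------------------------
# ground-truth quadrature
# ----------------------------------------------------------------------

_N_STATIONS = 2001
_N_PHI = 512


def _boundary_grid(spec: PhantomSpec, n_x: int = _N_STATIONS, n_phi: int = _N_PHI):
    """Dense (x, phi) sampling of the body surface. Cosine-spaced stations
    cluster samples at the caps where the surface slope diverges."""
    L = spec.axial_length_um
    xs = 0.5 * L * (1.0 - np.cos(np.linspace(0.0, np.pi, n_x)))
    phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    off, ry, rz, rel, phase = spec._section_arrays(xs)
    eps = spec.bump_eps(phi[None, :], phase[:, None]) if rel else np.zeros((xs.size, phi.size))
    Y = off[:, None] + ry[:, None] * (1.0 + eps) * np.cos(phi)[None, :]
    Z = rz[:, None] * (1.0 + eps) * np.sin(phi)[None, :]
    return xs, phi, Y, Z, off


def ground_truth_metrics(spec: PhantomSpec) -> dict[str, float]:
    """Five morphometric readouts from the continuous parametric body."""
    xs, phi, Y, Z, off = _boundary_grid(spec)
    L = spec.axial_length_um

    # volume: shoelace area per station, trapezoid along x
    Yc = np.concatenate([Y, Y[:, :1]], axis=1)
    Zc = np.concatenate([Z, Z[:, :1]], axis=1)
    area = 0.5 * np.abs(
        np.sum(Yc[:, :-1] * np.diff(Zc, axis=1) - Zc[:, :-1] * np.diff(Yc, axis=1), axis=1)
    )
    volume = float(np.trapezoid(area, xs))

    # surface: |p_x x p_phi| over the parametric surface
    X = np.broadcast_to(xs[:, None], Y.shape)
    dX_x = np.gradient(X, xs, axis=0)
    dY_x = np.gradient(Y, xs, axis=0)
    dZ_x = np.gradient(Z, xs, axis=0)
    dphi = phi[1] - phi[0]
    dY_p = np.gradient(np.concatenate([Y[:, -1:], Y, Y[:, :1]], axis=1), dphi, axis=1)[:, 1:-1]
    dZ_p = np.gradient(np.concatenate([Z[:, -1:], Z, Z[:, :1]], axis=1), dphi, axis=1)[:, 1:-1]
    cx = dY_x * dZ_p - dZ_x * dY_p
    cy = -(dX_x * dZ_p)
    cz = dX_x * dY_p
    integrand = np.sqrt(cx**2 + cy**2 + cz**2)
    surface = float(np.trapezoid(np.sum(integrand, axis=1) * dphi, xs))

    # length: centreline arc length (straight shapes: axial extent)
    if spec.kind == "worm" and spec.bend_amplitude_um:
        doff = np.gradient(off, xs)
        length = float(np.trapezoid(np.sqrt(1.0 + doff**2), xs))
    else:
        length = float(L)

    # max width: largest antipodal chord of any cross-section
    half = Y.shape[1] // 2
    chord = np.hypot(Y - np.roll(Y, half, axis=1), Z - np.roll(Z, half, axis=1))
    max_width = float(chord.max())

    # closed forms where exact
    if spec.kind == "sphere":
        r = spec.max_radius_um
        volume, surface = 4.0 / 3.0 * np.pi * r**3, 4.0 * np.pi * r**2
        length, max_width = 2.0 * r, 2.0 * r
    elif spec.kind in ("embryo", "ellipsoid") and spec.bump_amplitude_um == 0:
        a, b, c = spec.semi_axes_um
        volume = 4.0 / 3.0 * np.pi * a * b * c
        length, max_width = 2.0 * a, 2.0 * max(b, c)
    elif spec.kind == "cylinder":
        r, Lc = spec.max_radius_um, spec.length_um
        volume, surface = np.pi * r**2 * Lc, 2 * np.pi * r * Lc + 2 * np.pi * r**2
        length, max_width = Lc, 2.0 * r

    return {
        "surface_area_um2": surface,
        "volume_um3": volume,
        "length_um": length,
        "max_width_um": max_width,
        "ratio": length / max_width,
    }


# ----------------------------------------------------------------------
# voxelisation
# ----------------------------------------------------------------------

def build_phantom(
    spec: PhantomSpec,
    voxel_um: float,
    margin_voxels: int = 2,
    with_mesh: bool = False,
) -> Phantom:
    """Voxelise a phantom on an isotropic grid with anti-aliased edges.

    The grid has odd (ny, nz) so the body axis sits on a voxel centre.
    Fractional edge coverage is estimated from the signed radial distance
    to the parametric boundary, which keeps the rendered silhouette edge
    accurate to well below one voxel.
    """
    if voxel_um <= 0:
        raise PhantomError("voxel_um must be positive")
    if voxel_um > spec.reference_radius_um / 4.0:
        raise PhantomError(
            f"voxel_um={voxel_um} too coarse: need <= {spec.reference_radius_um / 4.0:.3f}"
        )
    L = spec.axial_length_um
    nx = int(np.ceil(L / voxel_um)) + 2 * margin_voxels
    x0 = -(margin_voxels - 0.5) * voxel_um  # physical x of slice 0 centre
    xs = x0 + np.arange(nx) * voxel_um

    off_all, ry_all, rz_all, rel, phase_all = spec._section_arrays(np.clip(xs, 0, L))
    inside = (xs >= 0) & (xs <= L)
    bump_max = abs(rel) * (1 + abs(spec.bump_asymmetry))
    half = float(np.max(np.abs(off_all) + np.maximum(ry_all, rz_all) * (1 + bump_max)))
    hn = int(np.ceil(half / voxel_um)) + margin_voxels
    ny = nz = 2 * hn + 1
    yy = (np.arange(ny) - hn)[:, None] * voxel_um
    zz = (np.arange(nz) - hn)[None, :] * voxel_um

    occ = np.zeros((nx, ny, nz), dtype=np.float32)
    m = spec.bump_frequency
    for i in range(nx):
        if not inside[i] or (ry_all[i] <= 0 and rz_all[i] <= 0):
            continue
        ry, rz = max(ry_all[i], 1e-9), max(rz_all[i], 1e-9)
        yr = yy - off_all[i]
        n = np.hypot(yr / ry, zz / rz)
        if rel:
            phi = np.arctan2(zz / rz, yr / ry)
            e = 1.0 + spec.bump_eps(phi, phase_all[i])
        else:
            e = 1.0
        R = np.hypot(yr, zz)
        with np.errstate(divide="ignore", invalid="ignore"):
            dist = np.where(n > 1e-6, (e - n) * (R / np.maximum(n, 1e-6)), voxel_um)
        occ[i] = np.clip(0.5 + dist / voxel_um, 0.0, 1.0)

    grid = occ >= 0.5
    if not grid.any():
        raise PhantomError("phantom voxelisation produced an empty grid")
    lab, nlab = ndi.label(grid, structure=ndi.generate_binary_structure(3, 1))
    if nlab != 1:
        sizes = ndi.sum_labels(grid, lab, index=np.arange(1, nlab + 1))
        if sizes.max() / sizes.sum() < 0.99:
            raise PhantomError("phantom occupancy is not a single connected component")
        grid = lab == (1 + int(np.argmax(sizes)))
        occ *= grid.astype(np.float32)

    lm = _landmark_field(spec, xs, yy, zz, occ) if spec.n_landmarks else None

    gt = GroundTruth(metrics=ground_truth_metrics(spec), occupancy=grid, voxel_um=voxel_um)
    if with_mesh:
        from .hull import VoxelVolume, extract_mesh

        vol = VoxelVolume(grid=grid, voxel_um=voxel_um)
        gt.mesh = extract_mesh(vol, smooth_iters=10).trimesh
    return Phantom(
        spec=spec, voxel_um=voxel_um, occupancy=occ, landmark_field=lm,
        ground_truth=gt, x0_um=x0,
    )


def _landmark_field(spec, xs, yy, zz, occ) -> np.ndarray:
    """Seeded internal inclusions: transparent (<0) and opaque (>0) blobs."""
    rng = np.random.default_rng(spec.rng_seed + 911)
    L = spec.axial_length_um
    lm = np.zeros_like(occ)
    off_all, ry_all, rz_all, _, _ = spec._section_arrays(np.clip(xs, 0, L))
    for k in range(spec.n_landmarks):
        ux = rng.uniform(0.2, 0.8)
        i0 = int(np.argmin(np.abs(xs - ux * L)))
        ry, rz = ry_all[i0], rz_all[i0]
        if min(ry, rz) <= 0:
            continue
        # strictly interior (blob edge <= 0.65 of the local radius) so the
        # silhouette rim keeps its clean contrast in every orientation
        fr, alpha = rng.uniform(0.0, 0.30), rng.uniform(0, 2 * np.pi)
        cy = off_all[i0] + fr * ry * np.cos(alpha)
        cz = fr * rz * np.sin(alpha)
        sx = rng.uniform(0.05, 0.12) * L
        sr = rng.uniform(0.20, 0.35) * min(ry, rz)
        w = -0.7 if k % 2 == 0 else 0.9
        d2 = (
            ((xs - ux * L) / sx)[:, None, None] ** 2
            + ((yy - cy) / sr)[None, :, :] ** 2
            + ((zz - cz) / sr)[None, :, :] ** 2
        )
        lm += w * np.clip(1.5 * (1.0 - d2), 0.0, 1.0).astype(np.float32)
    return lm * occ


# ----------------------------------------------------------------------
# rendering
# ----------------------------------------------------------------------

@dataclass
class RenderSpec:
    """Acquisition model for one rotation recording.

    ``period_frames`` may be non-integer; frame i sees the phantom
    rotated by 2*pi*i/period about the image-horizontal axis through its
    centroid (counter-clockwise viewed from +x; frame 0 is 0 rad).
    """

    n_frames: int = 104
    period_frames: float = 64.0
    pixel_size_um: float = 4.0
    shape: tuple[int, int] = (48, 288)  # rows, cols
    frame_interval_s: float = 0.25
    drift_mode: Literal["none", "constant", "walk"] = "none"
    drift_px: tuple[float, float] = (0.0, 0.0)  # per-frame (dx, dy) or walk sd
    psf_sigma_px: float = 1.0
    noise_sigma: float = 0.0  # fraction of dynamic range
    bg_level: float = 0.75
    bg_gradient: float = 0.06
    contrast: float = 0.55
    t_sat_um: float = 4.0  # thickness giving full silhouette contrast
    lm_contrast: float = 0.18
    lm_scale_um: float = 8.0
    tail_fade_frac: float = 0.0  # worm only; fraction of length that fades
    tail_fade_floor: float = 0.06
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_frames >= self.period_frames >= 8):
            raise RenderError("need n_frames >= period_frames >= 8")
        if self.pixel_size_um <= 0:
            raise RenderError("pixel_size_um must be positive")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["shape"] = list(d["shape"])
        d["drift_px"] = list(d["drift_px"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RenderSpec":
        d = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise RenderError(f"unknown RenderSpec keys: {sorted(unknown)}")
        for key in ("shape", "drift_px"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class RenderResult:
    """Rendered stack plus the oracle traces tests compare against."""

    stack: ImageStack
    angles_rad: np.ndarray
    drift_px: np.ndarray  # (n_frames, 2) applied (dx, dy)
    clean_frames: np.ndarray  # noise-free renders
    true_silhouettes: np.ndarray  # bool (T, rows, cols), discretised truth
    tail_visibility: np.ndarray | None = None  # per-frame fade depth in [0,1]


def _drift_trace(spec: RenderSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_frames
    if spec.drift_mode == "none":
        return np.zeros((n, 2))
    if spec.drift_mode == "constant":
        steps = np.tile(np.asarray(spec.drift_px, dtype=float), (n, 1))
        steps[0] = 0.0
        return np.cumsum(steps, axis=0)
    sd = np.asarray(spec.drift_px, dtype=float)
    steps = rng.normal(0.0, 1.0, size=(n, 2)) * sd
    steps[0] = 0.0
    return np.cumsum(steps, axis=0)


def render_stack(phantom: Phantom, spec: RenderSpec) -> RenderResult:
    """Render the rotation sequence of a phantom.

    Each frame is the orthographic projection along the optical axis z of
    the phantom rotated by theta_i about the x axis through its occupancy
    centroid, translated by the drift trace, shaded, blurred and noised.
    Projection is computed per frame as two small matrix products
    (cross-section scatter onto image rows, then axial scatter onto
    columns), which is exact mass-conserving linear-interpolation
    splatting and far cheaper than resampling the 3-D grid.
    """
    occ = phantom.occupancy
    if not (occ > 0).any():
        raise RenderError("empty phantom grid")
    vox = phantom.voxel_um
    px = spec.pixel_size_um
    rows, cols = spec.shape
    nx, ny, nz = occ.shape
    rng = np.random.default_rng(spec.rng_seed)

    com = phantom.centroid_um() / vox  # in voxel units
    ybar, zbar = com[1], com[2]
    yy = (np.arange(ny) - ybar)[:, None] * vox
    zz = (np.arange(nz) - zbar)[None, :] * vox
    flat = occ.reshape(nx, ny * nz).astype(np.float32)
    lm_flat = (
        phantom.landmark_field.reshape(nx, ny * nz).astype(np.float32)
        if phantom.landmark_field is not None
        else None
    )
    ind_flat = (occ >= 0.5).reshape(nx, ny * nz).astype(np.float32)

    drift = _drift_trace(spec, rng)
    angles = 2.0 * np.pi * np.arange(spec.n_frames) / spec.period_frames

    # static column scatter (x -> image columns); drift dx added per frame
    xc_body = (com[0]) * vox  # centroid x in grid um
    col_centre = (cols - 1) / 2.0
    row_centre = (rows - 1) / 2.0
    xs_um = np.arange(nx) * vox

    # tail fade ramp along grid x (worm only): contrast decays over the
    # tail fraction and reaches the floor well before the tip (the deep
    # tail is essentially invisible at the worst orientation)
    fade_ramp = None
    if spec.tail_fade_frac > 0 and phantom.spec.kind == "worm":
        occ_x = flat.sum(axis=1) > 0
        xi = np.nonzero(occ_x)[0]
        x_lo, x_hi = xi[0], xi[-1]
        span = (x_hi - x_lo + 1) * spec.tail_fade_frac
        ramp = (np.arange(nx) - (x_hi - span)) / max(0.6 * span, 1e-9)
        fade_ramp = np.clip(ramp, 0.0, 1.0).astype(np.float32)

    # physical extent check (worst case: full diagonal + drift)
    max_r = max(
        abs(yy).max() + abs(zz).max(),
        0.0,
    )
    if (nx * vox / px + np.abs(drift[:, 0]).max()) > cols or (
        2 * max_r / px + 2 * np.abs(drift[:, 1]).max()
    ) > 2 * rows:
        raise RenderError("image too small for the rotated, drifted specimen")

    frames = np.empty((spec.n_frames, rows, cols), dtype=np.float32)
    clean = np.empty_like(frames)
    sils = np.empty((spec.n_frames, rows, cols), dtype=bool)
    cgrid = (np.arange(cols) - col_centre) / cols
    bg_field = (spec.bg_level * (1.0 + spec.bg_gradient * cgrid))[None, :].astype(np.float32)
    bg_field = np.broadcast_to(bg_field, (rows, cols))
    fades = np.empty(spec.n_frames, dtype=np.float32)

    scale = vox * vox / px  # projected mass -> thickness in um per row bin

    for i, theta in enumerate(angles):
        dx, dy = drift[i]
        s = (yy * np.cos(theta) - zz * np.sin(theta)) / px + row_centre + dy
        W = _scatter_matrix(s.ravel(), rows)
        cx = (xs_um - xc_body) / px + col_centre + dx
        # thickness is intensive along x: average (not sum) the x voxels
        # that land in each image column
        Xw = _scatter_matrix(cx, cols)
        colsum = Xw.sum(axis=0, keepdims=True)
        Xw = Xw / np.maximum(colsum, 1e-12)

        T = (flat @ W) * scale  # (nx, rows) thickness um
        F = np.clip(T / spec.t_sat_um, 0.0, 1.0)
        d_theta = 0.5 * (1.0 + np.cos(theta))
        fades[i] = d_theta
        if fade_ramp is not None:
            depth = (1.0 - spec.tail_fade_floor) * d_theta
            F *= (1.0 - depth * fade_ramp)[:, None]
        signal = spec.contrast * (F.T @ Xw)  # (rows, cols)
        if lm_flat is not None:
            LM = ((lm_flat @ W) * scale).T @ Xw
            signal = signal + spec.lm_contrast * np.clip(LM / spec.lm_scale_um, -1.0, 1.0)
        img = bg_field - np.clip(signal, -0.2, 1.0)
        if spec.psf_sigma_px > 0:
            img = ndi.gaussian_filter(img, spec.psf_sigma_px, mode="nearest")
        clean[i] = img
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
        frames[i] = np.clip(img, 0.0, 1.0)

        dens = ((ind_flat @ W) * (vox / px)).T @ Xw  # area-coverage fraction
        sils[i] = dens > 0.5

    stack = ImageStack(
        frames=frames,
        pixel_size_um=px,
        frame_interval_s=spec.frame_interval_s,
        provenance=f"wormhull.phantom kind={phantom.spec.kind} seed={spec.rng_seed}",
    )
    return RenderResult(
        stack=stack,
        angles_rad=angles,
        drift_px=drift,
        clean_frames=clean,
        true_silhouettes=sils,
        tail_visibility=1.0 - fades if fade_ramp is not None else None,
    )


def _scatter_matrix(pos: np.ndarray, nbins: int) -> np.ndarray:
    """Dense linear-interpolation scatter matrix (len(pos), nbins)."""
    W = np.zeros((pos.size, nbins), dtype=np.float32)
    f = np.floor(pos).astype(int)
    w1 = (pos - f).astype(np.float32)
    idx = np.arange(pos.size)
    ok0 = (f >= 0) & (f < nbins)
    ok1 = (f + 1 >= 0) & (f + 1 < nbins)
    W[idx[ok0], f[ok0]] = 1.0 - w1[ok0]
    W[idx[ok1], f[ok1] + 1] = w1[ok1]
    return W


# ----------------------------------------------------------------------
# standard study specimens
# ----------------------------------------------------------------------

def adult_spec(seed: int = 0, bend_um: float = 30.0, tail_fade: bool = False) -> PhantomSpec:
    """The standard adult phantom: ~1 mm long, ~50 um maximum diameter."""
    del tail_fade  # fading is a render-time property; kept for clarity at call sites
    return PhantomSpec(
        kind="worm",
        length_um=1000.0,
        max_radius_um=25.0,
        taper=0.2,
        bend_amplitude_um=bend_um,
        bend_wavelength_um=900.0,
        bend_phase=0.4,
        bump_amplitude_um=1.0,
        bump_frequency=5,
        n_landmarks=4,
        rng_seed=seed,
    )


def embryo_spec(seed: int = 0) -> PhantomSpec:
    """The standard embryo phantom: ~50 x 30 um ovoid with 5% surface bumps."""
    return PhantomSpec(
        kind="embryo",
        semi_axes_um=(25.0, 15.0, 15.0),
        bump_amplitude_um=0.75,
        bump_frequency=5,
        bump_pitch_um=40.0,
        n_landmarks=3,
        rng_seed=seed,
    )


def adult_render_spec(seed: int = 0, noise_sigma: float = 0.02, **kw) -> RenderSpec:
    """Acquisition defaults for adults (4x objective scale: 4 um/px)."""
    defaults = dict(
        n_frames=104,
        period_frames=64.0,
        pixel_size_um=4.0,
        shape=(48, 288),
        noise_sigma=noise_sigma,
        rng_seed=seed,
    )
    defaults.update(kw)
    return RenderSpec(**defaults)


def embryo_render_spec(seed: int = 0, noise_sigma: float = 0.02, **kw) -> RenderSpec:
    """Acquisition defaults for embryos (20x objective scale: 0.6 um/px)."""
    defaults = dict(
        n_frames=80,
        period_frames=48.0,
        pixel_size_um=0.6,
        shape=(72, 112),
        noise_sigma=noise_sigma,
        rng_seed=seed,
    )
    defaults.update(kw)
    return RenderSpec(**defaults)


def auto_render_spec(
    spec: PhantomSpec,
    pixel_size_um: float,
    n_frames: int,
    period_frames: float,
    seed: int = 0,
    noise_sigma: float = 0.02,
    margin_um: float = 30.0,
    **kw,
) -> RenderSpec:
    """Size the frame to the specimen: used for cohorts whose phantoms
    vary in length and bend amplitude."""
    L = spec.axial_length_um
    reach = spec.bend_amplitude_um + spec.reference_radius_um
    if spec.kind in ("embryo", "ellipsoid"):
        reach = max(spec.semi_axes_um[1], spec.semi_axes_um[2])
    reach += abs(spec.bump_amplitude_um) * (1 + abs(spec.bump_asymmetry))
    rows = 2 * int(np.ceil((reach + margin_um) / pixel_size_um)) + 1
    rows += rows % 2  # even row count keeps the axis mid-frame
    cols = int(np.ceil(L / pixel_size_um)) + 2 * int(np.ceil(margin_um / pixel_size_um))
    return RenderSpec(
        n_frames=n_frames,
        period_frames=period_frames,
        pixel_size_um=pixel_size_um,
        shape=(rows, cols),
        noise_sigma=noise_sigma,
        rng_seed=seed,
        **kw,
    )


def sample_adult_spec(seed: int) -> PhantomSpec:
    """Cohort draw: adult with randomised bend, taper and size."""
    rng = np.random.default_rng(seed)
    return PhantomSpec(
        kind="worm",
        length_um=float(rng.uniform(850, 1150)),
        max_radius_um=float(rng.uniform(21, 28)),
        taper=float(rng.uniform(0.1, 0.3)),
        bend_amplitude_um=float(rng.uniform(10, 45)),
        bend_wavelength_um=float(rng.uniform(700, 1200)),
        bend_phase=float(rng.uniform(0, 2 * np.pi)),
        bump_amplitude_um=float(rng.uniform(0.6, 1.4)),
        bump_frequency=int(rng.choice([3, 5, 7])),
        n_landmarks=4,
        rng_seed=seed,
    )


def sample_embryo_spec(seed: int) -> PhantomSpec:
    """Cohort draw: embryo with randomised semi-axes and surface bumps."""
    rng = np.random.default_rng(seed)
    return PhantomSpec(
        kind="embryo",
        semi_axes_um=(
            float(rng.uniform(22, 28)),
            float(rng.uniform(13.5, 16.5)),
            float(rng.uniform(13.5, 16.5)),
        ),
        bump_amplitude_um=float(rng.uniform(0.8, 1.5)),
        bump_frequency=int(rng.choice([3, 5])),
        bump_pitch_um=float(rng.uniform(30, 60)),
        n_landmarks=3,
        rng_seed=seed,
    )
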