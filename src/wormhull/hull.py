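"""Customised shape-from-silhouette carving and surface extraction.

The reconstruction volume lives in the specimen's co-rotating frame:
grid axis x is the rotation axis (image columns), and the (y, z) plane
is the cross-section plane, with the axis at the plane's centre voxel.
Because the rotation axis is parallel to the image rows, each axial
slice x can be carved independently: frame i at angle theta constrains
the slice to the strip

    lo_i(x) <= y*cos(theta) - z*sin(theta) < hi_i(x)

where [lo_i, hi_i) is the silhouette's row interval in column x
(relative to the rotation-axis row).  The visual hull of the slice is
the intersection of the strips of every *contributing* frame.

A frame contributes to slice x only when x lies inside its confident
column extent.  This gating is the feature-completion rule: a faint
tail that a given orientation failed to detect imposes no constraint
there, so the tail is reconstructed from the orientations that did see
it instead of being carved away.

``carve_bruteforce`` re-derives the same hull by projecting every voxel
into every contributing frame; it exists as an independent oracle for
tests and matches ``carve_slicewise`` voxel for voxel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi
import trimesh
import trimesh.smoothing
from skimage.measure import marching_cubes

from .imaging import SilhouetteStack

__all__ = [
    "VoxelVolume",
    "SurfaceMesh",
    "ReconstructionError",
    "carve_slicewise",
    "carve_bruteforce",
    "extract_mesh",
]


class ReconstructionError(RuntimeError):
    pass


@dataclass
class VoxelVolume:
    """Carved occupancy grid in the co-rotating specimen frame."""

    grid: np.ndarray  # bool (nx, ny, nz)
    voxel_um: float
    x0_col: int = 0  # image column of slice 0
    axis_row: float = 0.0  # rotation-axis row in the mask raster
    raster_shape: tuple[int, int] | None = None  # (rows, cols) of the masks
    n_contributing: np.ndarray | None = None  # frames contributing per slice
    sub: int = 1  # fine voxels per mask pixel

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-D")

    @property
    def volume_um3(self) -> float:
        return float(self.grid.sum()) * self.voxel_um**3

    @property
    def centre_yz(self) -> tuple[int, int]:
        return (self.grid.shape[1] - 1) // 2, (self.grid.shape[2] - 1) // 2

    def coords_um(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates of voxel centres (x from slice 0, y/z from axis)."""
        cy, cz = self.centre_yz
        nx, ny, nz = self.grid.shape
        return (
            np.arange(nx) * self.voxel_um,
            (np.arange(ny) - cy) * self.voxel_um,
            (np.arange(nz) - cz) * self.voxel_um,
        )


@dataclass
class SurfaceMesh:
    """Triangle mesh of the reconstructed surface, in micrometres."""

    vertices: np.ndarray
    faces: np.ndarray
    watertight: bool

    @property
    def trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @property
    def area_um2(self) -> float:
        return float(self.trimesh.area)

    @property
    def volume_um3(self) -> float:
        return float(self.trimesh.volume)

    def save(self, path: str | Path) -> None:
        """Write PLY (binary little-endian) or STL by extension."""
        self.trimesh.export(str(path))


# ----------------------------------------------------------------------
# carving
# ----------------------------------------------------------------------

def _column_spans(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column [row_min, row_max] of the silhouette (-1 where empty).

    Columns with several disjoint runs (bent bodies seen edge-on) use
    the full min..max span: runs cannot be matched across angles, and
    the conservative span keeps the hull a superset of the body.
    """
    rows = np.arange(mask.shape[0])[:, None]
    any_fg = mask.any(axis=0)
    r_lo = np.where(any_fg, np.where(mask, rows, mask.shape[0]).min(axis=0), -1)
    r_hi = np.where(any_fg, np.where(mask, rows, -1).max(axis=0), -1)
    return r_lo, r_hi


def _carve_geometry(sils: SilhouetteStack, voxel_um: float, margin: int = 2):
    """Common grid layout + per-frame strip bounds for both carvers.

    The grid may be finer than the mask raster (``voxel_um`` an integer
    divisor of the pixel size); ``sub`` fine slices then share each image
    column's strip bounds, and (y, z) voxels are spaced ``voxel_um``.
    """
    if sils.angles_rad is None:
        raise ReconstructionError("silhouettes carry no assigned angles")
    if sils.axis_row is None:
        raise ReconstructionError("silhouettes are not aligned (no axis row)")
    px = sils.pixel_size_um
    sub = px / voxel_um
    if abs(sub - round(sub)) > 1e-9 or sub < 1:
        raise ReconstructionError(
            f"voxel_um must be the mask pixel size ({px} um) divided by an integer"
        )
    sub = int(round(sub))
    ok = sils.ok
    if int(ok.sum()) < 1:
        raise ReconstructionError("no usable frames")
    rows, cols = sils.masks.shape[1:]
    ext = sils.extents[ok]
    x_lo = max(int(ext[:, 0].min()) - margin, 0)
    x_hi = min(int(ext[:, 1].max()) + margin, cols)
    n_cols = x_hi - x_lo
    if n_cols <= 0:
        raise ReconstructionError("confident extents are empty")
    nx = n_cols * sub

    axis = float(sils.axis_row)
    half = 0.0
    for i in np.nonzero(ok)[0]:
        r, _ = np.nonzero(sils.masks[i])
        if r.size:
            half = max(half, float(np.abs(r - axis).max()))
    hn = int(np.ceil((half + margin) * sub))
    ny = nz = 2 * hn + 1

    frames = []
    res = sils.residuals_px if sils.residuals_px is not None else np.zeros((len(sils), 2))
    for i in np.nonzero(ok)[0]:
        r_lo, r_hi = _column_spans(sils.masks[i])
        lo = np.full(n_cols, np.nan)
        hi = np.full(n_cols, np.nan)
        e0, e1 = sils.extents[i]
        c = np.arange(x_lo, x_hi)
        inside = (c >= e0) & (c < e1)
        has = r_lo[c] >= 0
        # confident but empty columns carve the slice empty (the frame
        # confidently saw nothing there); columns outside the extent are NaN
        lo[inside] = np.where(has[inside], r_lo[c][inside] - 0.5, np.inf)
        hi[inside] = np.where(has[inside], r_hi[c][inside] + 0.5, -np.inf)
        frames.append(
            dict(
                angle=float(sils.angles_rad[i]),
                lo=np.repeat(lo, sub),
                hi=np.repeat(hi, sub),
                res_y=float(res[i, 1]),
                spans=(r_lo, r_hi),
                col_range=(x_lo, x_hi),
            )
        )
    geom = dict(
        nx=nx, ny=ny, nz=nz, hn=hn, x0=x_lo, axis=axis, sub=sub,
        rows=rows, cols=cols, voxel=voxel_um,
    )
    return geom, frames


def _finalize(occ, contrib, geom, sils) -> VoxelVolume:
    occ[contrib == 0] = False
    if not occ.any():
        raise ReconstructionError(
            "carving produced an empty volume; per-slice contributing frames: "
            f"{contrib.tolist()}"
        )
    lab, n = ndi.label(occ, structure=ndi.generate_binary_structure(3, 1))
    if n > 1:
        sizes = ndi.sum_labels(occ, lab, index=np.arange(1, n + 1))
        occ = lab == (1 + int(np.argmax(sizes)))
    return VoxelVolume(
        grid=occ,
        voxel_um=geom["voxel"],
        x0_col=geom["x0"],
        axis_row=geom["axis"],
        raster_shape=(geom["rows"], geom["cols"]),
        n_contributing=contrib,
        sub=geom["sub"],
    )


def carve_slicewise(
    sils: SilhouetteStack,
    voxel_um: float | None = None,
    feature_completion: bool = True,
) -> VoxelVolume:
    """Carve the visual hull slice by slice from angle-stamped silhouettes.

    ``feature_completion=False`` disables the confident-extent gating
    (every frame then constrains every slice, including the columns its
    segmentation could not see), which truncates low-contrast regions --
    kept as an ablation switch.
    """
    voxel = voxel_um if voxel_um is not None else 0.5 * sils.pixel_size_um
    geom, frames = _carve_geometry(sils, voxel)
    nx, ny, nz, hn, axis = geom["nx"], geom["ny"], geom["nz"], geom["hn"], geom["axis"]
    scale = 1.0 / geom["sub"]  # rows per fine voxel
    jj = (np.arange(ny) - hn)[:, None] * scale
    kk = (np.arange(nz) - hn)[None, :] * scale

    occ = np.ones((nx, ny, nz), dtype=bool)
    contrib = np.zeros(nx, dtype=int)
    for fr in frames:
        lo, hi = fr["lo"].copy(), fr["hi"].copy()
        if not feature_completion:
            r_lo, r_hi = fr["spans"]
            x0, x1 = fr["col_range"]
            c = np.arange(x0, x1)
            has = r_lo[c] >= 0
            lo = np.repeat(np.where(has, r_lo[c] - 0.5, np.inf), geom["sub"])
            hi = np.repeat(np.where(has, r_hi[c] + 0.5, -np.inf), geom["sub"])
        active = ~np.isnan(lo)
        if not active.any():
            continue
        contrib += active
        th = fr["angle"]
        # row coordinate of each (y, z) voxel as seen by this frame
        v = jj * np.cos(th) - kk * np.sin(th) + axis - fr["res_y"]
        keep = (v[None, :, :] >= lo[:, None, None]) & (v[None, :, :] < hi[:, None, None])
        keep[~active] = True
        occ &= keep
    return _finalize(occ, contrib, geom, sils)


def carve_bruteforce(
    sils: SilhouetteStack,
    voxel_um: float | None = None,
    feature_completion: bool = True,
) -> VoxelVolume:
    """Independent full-3-D carver: a voxel survives iff its projection
    lands inside every contributing frame's (column-convexified) mask.

    Used as the oracle in tests; agrees with :func:`carve_slicewise`
    voxel for voxel because both use the same half-open row intervals.
    """
    voxel = voxel_um if voxel_um is not None else 0.5 * sils.pixel_size_um
    geom, frames = _carve_geometry(sils, voxel)
    nx, ny, nz, hn, axis = geom["nx"], geom["ny"], geom["nz"], geom["hn"], geom["axis"]
    rows, sub = geom["rows"], geom["sub"]
    scale = 1.0 / sub
    jj = (np.arange(ny) - hn)[:, None] * scale
    kk = (np.arange(nz) - hn)[None, :] * scale

    occ = np.ones((nx, ny, nz), dtype=bool)
    contrib = np.zeros(nx, dtype=int)
    for fr in frames:
        r_lo, r_hi = fr["spans"]
        conv = np.zeros((rows, geom["cols"]), dtype=bool)
        for c in np.nonzero(r_lo >= 0)[0]:
            conv[r_lo[c]: r_hi[c] + 1, c] = True
        th = fr["angle"]
        v = jj * np.cos(th) - kk * np.sin(th) + axis - fr["res_y"]
        row_idx = np.floor(v + 0.5).astype(int)
        in_rows = (row_idx >= 0) & (row_idx < rows)
        row_safe = np.clip(row_idx, 0, rows - 1)
        x0, x1 = fr["col_range"]
        active = ~np.isnan(fr["lo"]) if feature_completion else np.ones(nx, bool)
        contrib += active
        for sl in np.nonzero(active)[0]:
            col = x0 + sl // sub
            keep = conv[row_safe, col] & in_rows
            occ[sl] &= keep
    return _finalize(occ, contrib, geom, sils)


# ----------------------------------------------------------------------
# meshing
# ----------------------------------------------------------------------

def extract_mesh(
    vol: VoxelVolume,
    smooth_iters: int = 10,
    gaussian_sigma: float | None = None,
) -> SurfaceMesh:
    """Marching-cubes surface of the carved volume, gently smoothed.

    The occupancy field is Gaussian-smoothed before marching cubes at
    iso-level 0.5, which removes voxel staircase bias; the default sigma
    is one *mask pixel* (``vol.sub`` voxels) -- the grid may be carved
    finer than the silhouettes, but the surface information lives at the
    pixel scale.  Taubin smoothing (a volume-preserving low-pass) is
    then applied ``smooth_iters`` times.  Output vertices are in
    micrometres, x along the rotation axis from slice 0, (y, z) relative
    to the axis.
    """
    if not vol.grid.any():
        raise ReconstructionError("cannot mesh an empty volume")
    if gaussian_sigma is None:
        gaussian_sigma = float(vol.sub)
    vox = vol.voxel_um
    # crop to the occupied bounding box; marching cubes on empty margin is wasted
    prof = [np.nonzero(vol.grid.any(axis=tuple(a for a in range(3) if a != ax)))[0]
            for ax in range(3)]
    o = [int(p[0]) for p in prof]
    grid = vol.grid[o[0]: prof[0][-1] + 1, o[1]: prof[1][-1] + 1, o[2]: prof[2][-1] + 1]
    f = grid.astype(np.float32)
    if gaussian_sigma > 0:
        f = ndi.gaussian_filter(f, gaussian_sigma)
        # keep the iso-surface crossing anchored at the binary boundary
        f = np.maximum(f, grid * 0.501)
    f = np.pad(f, 1)
    verts, faces, _, _ = marching_cubes(f, level=0.5, spacing=(vox, vox, vox))
    cy, cz = vol.centre_yz
    verts = verts + (np.array(o) - 1) * vox - np.array([0.0, cy * vox, cz * vox])
    mesh = trimesh.Trimesh(verts, faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    if smooth_iters > 0:
        trimesh.smoothing.filter_taubin(mesh, lamb=0.5, nu=0.53, iterations=smooth_iters)
    watertight = bool(mesh.is_watertight)
    if not watertight:
        trimesh.repair.fill_holes(mesh)
        watertight = bool(mesh.is_watertight)
        if not watertight:
            raise ReconstructionError("mesh is not watertight after repair")
    return SurfaceMesh(
        vertices=np.asarray(mesh.vertices), faces=np.asarray(mesh.faces),
        watertight=watertight,
    )
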