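"""Reprojection-IoU validation of a reconstructed model.

The reconstruction is scored by re-projecting the carved volume at the
viewpoints 0..180 deg in 30-deg steps and comparing each projection
with the segmented silhouette whose assigned angle is nearest -- the
intersection-over-union between "projected worm" and "segmented worm"
at corresponding orientations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hull import VoxelVolume
from .imaging import SilhouetteStack

__all__ = ["IoUReport", "IoUError", "reproject", "iou", "validate_reconstruction"]

DEFAULT_VIEWPOINTS_DEG = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0)


class IoUError(ValueError):
    pass


@dataclass
class IoUReport:
    viewpoints_deg: list[float]
    ious: list[float]
    matched_angles_deg: list[float]
    skipped: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.ious)

    @property
    def mean(self) -> float:
        return float(np.mean(self.ious))

    @property
    def sd(self) -> float:
        return float(np.std(self.ious, ddof=1)) if self.n > 1 else 0.0

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {
                "viewpoints_deg": self.viewpoints_deg,
                "iou": self.ious,
                "matched_angles_deg": self.matched_angles_deg,
                "skipped_viewpoints_deg": self.skipped,
                "mean": self.mean,
                "sd": self.sd,
                "n": self.n,
            },
            indent=2,
        ))

    def save_csv(self, path: str | Path) -> None:
        np.savetxt(
            Path(path),
            np.column_stack([self.viewpoints_deg, self.matched_angles_deg, self.ious]),
            delimiter=",",
            header="viewpoint_deg,matched_angle_deg,iou",
            comments="",
        )


def reproject(vol: VoxelVolume, angle_deg: float) -> np.ndarray:
    """Orthographic silhouette of the volume at a rotation angle.

    Rotates the co-rotating grid to the requested orientation and
    projects along the optical axis, on the same raster geometry as the
    aligned masks (so the result is directly comparable to a segmented
    frame).  Uses the same nearest-row splatting convention as the
    carver, making the single-frame round trip exact.
    """
    if not vol.grid.any():
        raise IoUError("cannot reproject an empty volume")
    if vol.raster_shape is None:
        raise IoUError("volume carries no raster geometry")
    rows, cols = vol.raster_shape
    nx, ny, nz = vol.grid.shape
    cy, cz = vol.centre_yz
    sub = vol.sub
    th = np.deg2rad(angle_deg)
    jj = (np.arange(ny) - cy)[:, None] / sub
    kk = (np.arange(nz) - cz)[None, :] / sub
    v = jj * np.cos(th) - kk * np.sin(th) + vol.axis_row
    # splat voxel centres onto a raster of `sub` fine bins per image row;
    # a row is foreground when at least half of its fine bins are occupied
    fine = np.floor((v + 0.5) * sub).astype(int)
    in_range = (fine >= 0) & (fine < rows * sub)
    occ_fine = np.zeros((cols, rows * sub), dtype=bool)
    for i in range(nx):
        col = vol.x0_col + i // sub
        if col < 0 or col >= cols:
            continue
        sel = vol.grid[i] & in_range
        if sel.any():
            occ_fine[col, fine[sel]] = True
    frac = occ_fine.reshape(cols, rows, sub).sum(axis=2)
    return (frac.T * 2 >= sub)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two same-shape binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise IoUError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise IoUError("IoU undefined: both masks are empty")
    return float(np.logical_and(a, b).sum() / union)


def validate_reconstruction(
    vol: VoxelVolume,
    sils: SilhouetteStack,
    viewpoints_deg: tuple[float, ...] = DEFAULT_VIEWPOINTS_DEG,
) -> IoUReport:
    """Score reprojection IoU at the requested viewpoints.

    Each viewpoint is paired with the usable frame whose assigned angle
    is nearest (no interpolation); the projection is rendered at that
    frame's actual angle so model and silhouette are compared at truly
    corresponding orientations.  A viewpoint with no frame within half
    an inter-frame step is skipped with a warning and reduces n.
    """
    if sils.angles_rad is None:
        raise IoUError("silhouettes carry no assigned angles")
    ok = sils.ok
    ang = np.rad2deg(sils.angles_rad)
    step = float(np.median(np.diff(np.sort(ang[ok])))) if ok.sum() > 1 else 360.0

    views, scores, matched, skipped = [], [], [], []
    for vp in viewpoints_deg:
        diffs = np.abs(ang - vp)
        diffs[~ok] = np.inf
        i = int(np.argmin(diffs))
        if diffs[i] > 0.5 * step + 1e-9:
            warnings.warn(f"no frame within half a step of viewpoint {vp} deg; skipped")
            skipped.append(float(vp))
            continue
        proj = reproject(vol, float(ang[i]))
        views.append(float(vp))
        matched.append(float(ang[i]))
        scores.append(iou(proj, sils.masks[i]))
    if not scores:
        raise IoUError("every viewpoint was skipped")
    return IoUReport(
        viewpoints_deg=views, ious=scores, matched_angles_deg=matched, skipped=skipped,
    )
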