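"""Frame-stack containers, enhancement and silhouette segmentation.

The original recordings were enhanced and segmented by trained networks;
this module provides deterministic classical operators with the same
contract: clean single-component binary silhouettes per frame, plus a
per-column confidence and the "confident extent" of columns where the
specimen is detected with sufficient contrast.  Columns outside that
extent (the faint adult tail) impose no constraints downstream, which is
what lets the carver reconstruct the tail from the orientations that do
see it.

Coordinates are 0-based (row, col), row 0 at top; extents are half-open
``[x_lo, x_hi)`` column intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi
import tifffile
from skimage import filters, morphology, restoration, transform

__all__ = [
    "ImageStack",
    "SilhouetteStack",
    "SegmentationError",
    "enhance",
    "segment",
    "read_stack",
]


class SegmentationError(RuntimeError):
    pass


@dataclass
class ImageStack:
    """A grayscale frame sequence with physical calibration.

    ``frames`` is float32 in [0, 1], shape (T, rows, cols).
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be (T, rows, cols) with T >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def write_tiff(self, path: str | Path) -> None:
        """16-bit multi-page TIFF with resolution metadata."""
        data = np.clip(self.frames, 0.0, 1.0)
        tifffile.imwrite(
            Path(path),
            (data * 65535).astype(np.uint16),
            resolution=(1e4 / self.pixel_size_um, 1e4 / self.pixel_size_um),
            metadata={"pixel_size_um": self.pixel_size_um,
                      "frame_interval_s": self.frame_interval_s},
        )


def read_stack(
    path: str | Path | list[str | Path],
    pixel_size_um: float,
    frame_interval_s: float = 1.0,
) -> ImageStack:
    """Read a multi-page TIFF (or a glob/list of PNG/TIFF frames)."""
    if isinstance(path, (list, tuple)):
        import imageio.v3 as iio

        frames = np.stack([np.asarray(iio.imread(p), dtype=np.float32) for p in path])
    else:
        p = Path(path)
        if any(ch in p.name for ch in "*?["):
            return read_stack(sorted(p.parent.glob(p.name)), pixel_size_um, frame_interval_s)
        frames = tifffile.imread(p).astype(np.float32)
        if frames.ndim == 2:
            frames = frames[None]
    peak = frames.max()
    if peak > 1.0:
        frames /= 65535.0 if peak > 255 else 255.0
    return ImageStack(frames=frames, pixel_size_um=pixel_size_um,
                      frame_interval_s=frame_interval_s, provenance=str(path))


@dataclass
class SilhouetteStack:
    """Per-frame binary silhouettes with confidences and (later) angles.

    ``masks`` is bool (T, rows, cols).  ``confidence`` holds the
    per-column contrast score in [0, 1]; ``extents`` the half-open
    confident column interval per frame.  ``offsets_px`` and
    ``angles_rad`` are filled by the kinematics stage.  Frames whose
    segmentation failed are flagged in ``failed`` and carry empty masks.
    """

    masks: np.ndarray
    pixel_size_um: float
    confidence: np.ndarray  # (T, cols) float
    extents: np.ndarray  # (T, 2) int, half-open [lo, hi)
    centroids: np.ndarray  # (T, 2) float (row, col)
    failed: np.ndarray  # (T,) bool
    offsets_px: np.ndarray | None = None  # (T, 2) applied integer (dx, dy)
    residuals_px: np.ndarray | None = None  # (T, 2) sub-pixel remainder
    axis_row: float | None = None  # estimated rotation-axis image row
    angles_rad: np.ndarray | None = None
    frame_indices: np.ndarray | None = None  # indices into the source stack

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        lo, hi = self.extents[:, 0], self.extents[:, 1]
        cols = self.masks.shape[2]
        if ((lo < 0) | (hi > cols) | (lo > hi)).any():
            raise ValueError("extents must satisfy 0 <= lo <= hi <= cols")

    def __len__(self) -> int:
        return self.masks.shape[0]

    @property
    def ok(self) -> np.ndarray:
        return ~self.failed

    def select(self, idx: np.ndarray) -> "SilhouetteStack":
        def take(a):
            return None if a is None else a[idx]

        return replace(
            self,
            masks=self.masks[idx],
            confidence=self.confidence[idx],
            extents=self.extents[idx],
            centroids=self.centroids[idx],
            failed=self.failed[idx],
            offsets_px=take(self.offsets_px),
            residuals_px=take(self.residuals_px),
            angles_rad=take(self.angles_rad),
            frame_indices=(np.asarray(idx) if self.frame_indices is None
                           else self.frame_indices[idx]),
        )

    def write_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(Path(path), self.masks.astype(np.uint8) * 255)


# ----------------------------------------------------------------------
# enhancement
# ----------------------------------------------------------------------

def flatten_background(frame: np.ndarray, sigma_frac: float = 0.25) -> np.ndarray:
    """Remove smooth shading: subtract a large-kernel Gaussian estimate,
    restore the median level."""
    sigma = sigma_frac * min(frame.shape)
    bg = ndi.gaussian_filter(frame, sigma, mode="nearest")
    return frame - bg + float(np.median(bg))


def enhance(
    stack: ImageStack,
    upsample_factor: int = 2,
    denoise_weight: float = 0.08,
    unsharp_amount: float = 0.5,
    bg_sigma_frac: float = 0.25,
) -> ImageStack:
    """Classical enhancement: background flattening, edge-preserving
    total-variation denoising, bicubic upsampling and unsharp masking.

    The output pixel size is ``pixel_size_um / upsample_factor``.  The
    pipeline is fully deterministic; with ``upsample_factor=1`` and
    ``denoise_weight=0`` it reduces to background flattening only.
    """
    if upsample_factor not in (1, 2, 4):
        raise ValueError("upsample_factor must be 1, 2 or 4")
    out = []
    for frame in stack.frames:
        f = flatten_background(frame, bg_sigma_frac)
        if denoise_weight > 0:
            f = restoration.denoise_tv_chambolle(f, weight=denoise_weight)
        if upsample_factor > 1:
            f = transform.rescale(f, upsample_factor, order=3, anti_aliasing=False)
            if unsharp_amount > 0:
                f = filters.unsharp_mask(f, radius=1.0, amount=unsharp_amount)
        out.append(f.astype(np.float32))
    return ImageStack(
        frames=np.stack(out),
        pixel_size_um=stack.pixel_size_um / upsample_factor,
        frame_interval_s=stack.frame_interval_s,
        provenance=stack.provenance + f" | enhanced x{upsample_factor}",
    )


# ----------------------------------------------------------------------
# segmentation
# ----------------------------------------------------------------------

def _segment_frame(frame, dark_specimen, closing_radius, min_area):
    work = flatten_background(frame)
    thr = filters.threshold_otsu(work)
    fg = work < thr if dark_specimen else work > thr
    if closing_radius > 0:
        fg = morphology.closing(fg, morphology.disk(closing_radius))
    fg = ndi.binary_fill_holes(fg)
    lab, n = ndi.label(fg)
    if n == 0:
        return None, work
    if n > 1:
        sizes = ndi.sum_labels(fg, lab, index=np.arange(1, n + 1))
        fg = lab == (1 + int(np.argmax(sizes)))
    if fg.sum() < min_area or fg.sum() > 0.9 * fg.size:
        return None, work
    # background-only frames: Otsu happily splits pure noise, so demand
    # real foreground contrast well above the background noise floor
    bgv, fgv = work[~fg], work[fg]
    if dark_specimen:
        depth = float(np.median(bgv) - np.percentile(fgv, 10))
    else:
        depth = float(np.percentile(fgv, 90) - np.median(bgv))
    if depth < max(4.0 * float(np.std(bgv)), 0.02):
        return None, work
    return fg, work


def _column_confidence(work, mask, dark_specimen):
    """Normalised foreground/background contrast per column."""
    bg = work[~mask]
    bg_level = float(np.median(bg)) if bg.size else float(np.median(work))
    fg_vals = work[mask]
    if dark_specimen:
        fg_ref = float(np.percentile(fg_vals, 10))
        depth_full = bg_level - fg_ref
        col_depth = bg_level - np.min(np.where(mask, work, np.inf), axis=0)
    else:
        fg_ref = float(np.percentile(fg_vals, 90))
        depth_full = fg_ref - bg_level
        col_depth = np.max(np.where(mask, work, -np.inf), axis=0) - bg_level
    col_depth = np.where(np.isfinite(col_depth), col_depth, 0.0)
    if depth_full <= 0:
        return np.zeros(work.shape[1])
    return np.clip(col_depth / depth_full, 0.0, 1.0)


def _confident_run(conf, c_min):
    """Longest run of columns with confidence >= c_min, half-open."""
    good = conf >= c_min
    if not good.any():
        return 0, 0
    edges = np.diff(np.concatenate([[0], good.astype(int), [0]]))
    starts, ends = np.nonzero(edges == 1)[0], np.nonzero(edges == -1)[0]
    k = int(np.argmax(ends - starts))
    return int(starts[k]), int(ends[k])


def segment(
    stack: ImageStack,
    dark_specimen: bool = True,
    closing_radius: int = 2,
    min_area_px: int = 64,
    c_min: float = 0.3,
) -> SilhouetteStack:
    """Threshold-based silhouette extraction with confidence gating.

    Per frame: Otsu threshold on the background-flattened image,
    morphological closing, hole filling, largest connected component.
    The per-column confidence is the column's foreground/background
    contrast normalised by the frame's robust contrast range; the
    confident extent is the longest column run with confidence >=
    ``c_min``.  Frames with an empty foreground are flagged as failed
    (their masks stay empty and they are excluded downstream).
    """
    T = len(stack)
    rows, cols = stack.shape
    masks = np.zeros((T, rows, cols), dtype=bool)
    conf = np.zeros((T, cols), dtype=np.float32)
    extents = np.zeros((T, 2), dtype=int)
    cents = np.full((T, 2), np.nan)
    failed = np.zeros(T, dtype=bool)

    for i, frame in enumerate(stack.frames):
        fg, work = _segment_frame(frame, dark_specimen, closing_radius, min_area_px)
        if fg is None:
            failed[i] = True
            continue
        masks[i] = fg
        conf[i] = _column_confidence(work, fg, dark_specimen)
        extents[i] = _confident_run(conf[i], c_min)
        r, c = np.nonzero(fg)
        cents[i] = (r.mean(), c.mean())

    if failed.all():
        raise SegmentationError("segmentation failed on every frame")
    return SilhouetteStack(
        masks=masks,
        pixel_size_um=stack.pixel_size_um,
        confidence=conf,
        extents=extents,
        centroids=cents,
        failed=failed,
    )
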