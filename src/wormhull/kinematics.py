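"""Rotation-period estimation, drift removal and angle assignment.

The specimen rolls uniformly about the image-horizontal axis, so the
frame sequence is periodic: frame i and frame i + P show the same
orientation.  The period P (in frames, possibly non-integer) is found by
template matching -- the mean normalised cross-correlation (NCC) between
frame pairs at each candidate lag -- refined by parabolic interpolation
and by averaging over every full period the stack contains.  NCC is
computed on intensity frames rather than masks because internal
landmarks (gonad, intestinal granules, the embryo's transparent
inclusion) break the near-symmetries that silhouettes alone cannot.

Uniform angular velocity within the carving window is assumed; angle
assignment is then just theta_i = 2*pi*(i - ref)/P.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .imaging import ImageStack, SilhouetteStack

__all__ = [
    "RotationEstimate",
    "PeriodEstimationError",
    "AlignmentError",
    "estimate_period",
    "align_frames",
    "assign_angles",
]


class PeriodEstimationError(RuntimeError):
    """No reliable rotation detected."""


class AlignmentError(RuntimeError):
    pass


@dataclass
class RotationEstimate:
    period_frames: float
    angles_rad: np.ndarray  # 2*pi*i/P for every frame of the analysed stack
    lags: np.ndarray
    similarity: np.ndarray  # mean NCC vs lag
    peak_score: float
    reference_frame: int = 0

    def save_csv(self, path: str | Path) -> None:
        np.savetxt(
            Path(path),
            np.column_stack([self.lags, self.similarity]),
            delimiter=",",
            header="lag_frames,mean_ncc",
            comments="",
        )


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 1.0  # two constant frames are indistinguishable
    return float((a * b).sum() / (na * nb))


def similarity_curve(
    frames: np.ndarray,
    min_lag: int,
    max_lag: int,
    max_pairs: int = 16,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean NCC between frames i and i+lag for each lag in [min_lag, max_lag]."""
    T = frames.shape[0]
    lags = np.arange(min_lag, max_lag + 1)
    sim = np.empty(lags.size)
    flat = frames.reshape(T, -1).astype(np.float32)
    flat = flat - flat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(flat, axis=1)
    for k, lag in enumerate(lags):
        idx = np.arange(0, T - lag)
        if idx.size > max_pairs:
            idx = idx[np.linspace(0, idx.size - 1, max_pairs).astype(int)]
        num = np.einsum("ij,ij->i", flat[idx], flat[idx + lag])
        den = norms[idx] * norms[idx + lag]
        good = den > 0
        sim[k] = float(np.mean(num[good] / den[good])) if good.any() else 1.0
    return lags, sim


def _parabolic_peak(lags: np.ndarray, sim: np.ndarray, k: int) -> tuple[float, float]:
    """Refine integer-lag peak k by 3-point parabola; returns (lag, height)."""
    if k <= 0 or k >= sim.size - 1:
        return float(lags[k]), float(sim[k])
    y0, y1, y2 = sim[k - 1], sim[k], sim[k + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return float(lags[k]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    height = y1 - 0.25 * (y0 - y2) * delta
    return float(lags[k] + delta), float(height)


def estimate_period(
    stack: ImageStack | SilhouetteStack,
    min_lag: int = 8,
    max_lag: int | None = None,
    roi: tuple[int, int, int, int] | None = None,
    s_min: float = 0.6,
    flat_tol: float = 5e-3,
) -> RotationEstimate:
    """Estimate the rotation period by template matching.

    ``roi`` (r0, r1, c0, c1) restricts NCC to a crop (typically the
    union bounding box of the silhouettes) so that static background
    does not dilute the periodic signal.  Candidate periods are the
    local maxima of the similarity curve; the fundamental is chosen by
    a harmonic-comb score -- the worst similarity at the candidate's
    integer multiples minus the best similarity at its half-integer
    multiples.  The true period scores high on both counts, whereas
    harmonics (2P) and the subharmonic peaks of specimens with residual
    rotational near-symmetry (bumpy surfaces repeat at 1/m turn, mirror
    symmetry at 1/2 turn) each leave a high half-multiple and are
    rejected.  The chosen period is then refined by a 3-point parabola
    at every visible multiple and the per-multiple estimates averaged.

    Raises :class:`PeriodEstimationError` when the curve is flat (static
    or rotation-symmetric specimen) or its peak is weaker than ``s_min``.
    """
    if isinstance(stack, SilhouetteStack):
        frames = stack.masks.astype(np.float32)
    else:
        frames = stack.frames
    T = frames.shape[0]
    if max_lag is None:
        max_lag = T - 8
    if not (T > max_lag > min_lag >= 4):
        raise ValueError("need T > max_lag > min_lag >= 4")
    if roi is not None:
        r0, r1, c0, c1 = roi
        frames = frames[:, r0:r1, c0:c1]

    lags, sim = similarity_curve(frames, min_lag, max_lag)
    baseline = float(np.percentile(sim, 10))
    span = float(sim.max() - sim.min())
    if span < flat_tol:
        raise PeriodEstimationError(
            "no reliable rotation detected: similarity curve is flat "
            f"(range {span:.2e})"
        )

    # local maxima (strict neighbours)
    interior = np.arange(1, sim.size - 1)
    is_peak = (sim[interior] >= sim[interior - 1]) & (sim[interior] >= sim[interior + 1])
    peak_idx = interior[is_peak]
    if peak_idx.size == 0:
        raise PeriodEstimationError("no reliable rotation detected: no similarity peak")
    best = peak_idx[np.argmax(sim[peak_idx])]
    h_best = float(sim[best])
    if h_best < s_min:
        raise PeriodEstimationError(
            f"no reliable rotation detected: peak score {h_best:.3f} < s_min={s_min}"
        )

    def sim_at(lag: float) -> float:
        return float(np.interp(lag, lags, sim))

    # harmonic-comb score per candidate peak
    best_score, fund = -np.inf, None
    for k in peak_idx:
        p_k, _ = _parabolic_peak(lags, sim, int(k))
        mults = [m * p_k for m in range(1, 64) if m * p_k <= lags[-1] + 0.25]
        halves = [
            (m + 0.5) * p_k for m in range(0, 64)
            if lags[0] <= (m + 0.5) * p_k <= lags[-1]
        ]
        worst_mult = min(sim_at(m) for m in mults)
        ref = max((sim_at(h) for h in halves), default=baseline)
        score = worst_mult - ref
        if score > best_score + 1e-12:
            best_score, fund = score, int(k)
    p0, _ = _parabolic_peak(lags, sim, fund)

    # average over every visible multiple of the fundamental
    estimates, weights = [], []
    k = 1
    while k * p0 <= lags[-1] + 0.5:
        target = k * p0
        j = int(np.argmin(np.abs(lags - target)))
        if abs(lags[j] - target) <= max(2.0, 0.05 * target):
            loc = j
            for jj in (j - 1, j, j + 1):
                if 0 <= jj < sim.size and sim[jj] > sim[loc]:
                    loc = jj
            pk, _ = _parabolic_peak(lags, sim, loc)
            estimates.append(pk / k)
            weights.append(k)  # longer lags give finer fractional resolution
        k += 1
    period = float(np.average(estimates, weights=weights))
    angles = 2.0 * np.pi * np.arange(T) / period
    return RotationEstimate(
        period_frames=period,
        angles_rad=angles,
        lags=lags,
        similarity=sim,
        peak_score=h_best,
    )


# ----------------------------------------------------------------------
# alignment
# ----------------------------------------------------------------------

def _rolling_mean(trace: np.ndarray, window: int) -> np.ndarray:
    """Drift-tracking smoother: a least-squares line (steady drift passes
    through unchanged) plus a period-length centred rolling mean of the
    residual with periodic padding (rotation-induced oscillation, which
    repeats every window, averages to zero without edge artifacts)."""
    window = max(1, min(int(window), trace.size) | 1)
    i = np.arange(trace.size)
    slope, intercept = np.polyfit(i, trace, 1)
    line = intercept + slope * i
    resid = trace - line
    pad = window // 2
    padded = np.pad(resid, pad, mode="wrap")
    kernel = np.ones(window) / window
    return line + np.convolve(padded, kernel, mode="valid")


def _shift_mask(mask: np.ndarray, dy: int, dx: int) -> np.ndarray:
    out = np.zeros_like(mask)
    rows, cols = mask.shape
    src_r = slice(max(0, -dy), min(rows, rows - dy))
    src_c = slice(max(0, -dx), min(cols, cols - dx))
    dst_r = slice(max(0, dy), min(rows, rows + dy))
    dst_c = slice(max(0, dx), min(cols, cols + dx))
    out[dst_r, dst_c] = mask[src_r, src_c]
    return out


def align_frames(
    sils: SilhouetteStack,
    period_frames: float | None = None,
) -> SilhouetteStack:
    """Remove in-plane drift while preserving rotation-induced wobble.

    The drift estimate for both axes is the period-length centred
    rolling mean of the silhouette-centroid traces (the periodic
    oscillation a bent body imprints on its centroid averages out over
    one period, so only genuine drift survives the smoothing).  The
    rotation-axis row is the mean smoothed y-centroid.  Masks are
    shifted by integer pixels; the sub-pixel residual is stored and
    applied later by the carver as a real-valued strip-bound shift.
    """
    ok = sils.ok
    if not ok.any():
        raise AlignmentError("all frames failed segmentation; nothing to align")
    T = len(sils)
    window = int(round(period_frames)) if period_frames else int(ok.sum())

    yc = sils.centroids[:, 0].copy()
    xc = sils.centroids[:, 1].copy()
    # interpolate over failed frames so smoothing stays well defined
    if (~ok).any():
        idx = np.arange(T)
        yc[~ok] = np.interp(idx[~ok], idx[ok], yc[ok])
        xc[~ok] = np.interp(idx[~ok], idx[ok], xc[ok])

    y_smooth = _rolling_mean(yc, window)
    x_smooth = _rolling_mean(xc, window)
    axis_row = float(np.mean(y_smooth[ok]))
    x_target = float(np.median(x_smooth[ok]))

    dy = axis_row - y_smooth  # shift that removes the drift
    dx = x_target - x_smooth
    dyi = np.rint(dy).astype(int)
    dxi = np.rint(dx).astype(int)

    masks = np.stack([
        _shift_mask(sils.masks[i], dyi[i], dxi[i]) if ok[i] else sils.masks[i]
        for i in range(T)
    ])
    extents = sils.extents.copy()
    extents[ok, 0] = np.clip(extents[ok, 0] + dxi[ok], 0, masks.shape[2])
    extents[ok, 1] = np.clip(extents[ok, 1] + dxi[ok], 0, masks.shape[2])
    conf = np.stack([
        np.roll(sils.confidence[i], dxi[i]) if ok[i] else sils.confidence[i]
        for i in range(T)
    ])
    cents = sils.centroids + np.column_stack([dyi, dxi])

    return replace(
        sils,
        masks=masks,
        confidence=conf,
        extents=extents,
        centroids=cents,
        offsets_px=np.column_stack([dxi, dyi]),
        residuals_px=np.column_stack([dx - dxi, dy - dyi]),
        axis_row=axis_row,
    )


def assign_angles(
    est: RotationEstimate,
    sils: SilhouetteStack,
    reference_frame: int = 0,
    n_min: int = 12,
) -> SilhouetteStack:
    """Select one full period of frames and stamp each with its angle.

    Frames ``reference_frame <= i < reference_frame + P`` are kept (the
    count is ceil(P), so a non-integer period keeps the frame whose
    angle falls just short of 2*pi) and frame i receives
    ``2*pi*(i - reference_frame)/P``.
    """
    P = est.period_frames
    n_window = int(np.ceil(P - 1e-9))
    if reference_frame + n_window > len(sils):
        raise ValueError(
            f"window [{reference_frame}, {reference_frame + n_window}) exceeds stack "
            f"length {len(sils)}"
        )
    idx = np.arange(reference_frame, reference_frame + n_window)
    usable = sils.ok[idx]
    if int(usable.sum()) < n_min:
        raise AlignmentError(
            f"only {int(usable.sum())} usable frames in the rotation window "
            f"(need >= {n_min}); hull would be too coarse"
        )
    out = sils.select(idx)
    out.angles_rad = 2.0 * np.pi * (idx - reference_frame) / P
    return out
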