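"""Shared fixtures: the expensive reference reconstructions are built
once per session and reused by the unit and validation tests."""

from __future__ import annotations

import numpy as np
import pytest

import wormhull as wh
from wormhull import protocols


@pytest.fixture(scope="session")
def adult_run() -> protocols.StudyRun:
    """Standard adult phantom reconstruction (seed 1, 2% noise)."""
    return protocols.run_adult(seed=1, noise_sigma=0.02, phenotype=True)


@pytest.fixture(scope="session")
def embryo_run() -> protocols.StudyRun:
    """Standard embryo phantom reconstruction (seed 1, 2% noise)."""
    return protocols.run_embryo(seed=1, noise_sigma=0.02, phenotype=True)


@pytest.fixture(scope="session")
def battery_runs() -> list[dict]:
    """Twenty noiseless recovery-battery worms through the full pipeline,
    reduced to the comparisons the tests need (full runs would hold ~50 MB
    of grids each)."""
    out = []
    for seed in range(1, 21):
        run = protocols.run_battery_specimen(seed)
        out.append({
            "seed": seed,
            "truth": dict(run.phantom.ground_truth.metrics),
            "record": run.result.record,
            "period_frames": run.result.estimate.period_frames,
            "mean_iou": run.result.iou_report.mean,
        })
    return out


@pytest.fixture(scope="session")
def small_worm():
    """A small bent worm phantom + noiseless render, for cheap unit tests."""
    spec = protocols.battery_spec(3)
    phantom = wh.build_phantom(spec, voxel_um=1.0)
    render = wh.render_stack(phantom, protocols.battery_render_spec(spec, 3))
    return phantom, render


def angle_stamped_window(render, enhance_factor: int = 2):
    """Segment + align + angle-stamp a rendered stack without estimating
    the period (uses the generator's true period); shared test helper."""
    from wormhull import imaging, kinematics

    enh = imaging.enhance(render.stack, upsample_factor=enhance_factor)
    sils = imaging.segment(enh)
    P = 2 * np.pi / (render.angles_rad[1] - render.angles_rad[0])
    est = kinematics.RotationEstimate(
        period_frames=P,
        angles_rad=2 * np.pi * np.arange(len(sils)) / P,
        lags=np.arange(2),
        similarity=np.ones(2),
        peak_score=1.0,
    )
    aligned = kinematics.align_frames(sils, period_frames=P)
    return kinematics.assign_angles(est, aligned)
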