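"""Reference simulation protocols.

These functions bundle the standard study conditions -- phantom
geometry, acquisition settings and reconstruction configuration -- used
throughout the examples and the validation suite, so that every entry
point reproduces the same experiment:

* adults: ~1 mm x ~50 um worms imaged at 4 um/px (4x objective scale),
  64 frames per rotation, 104-frame recordings, 2% additive noise;
* embryos: ~50 x 30 um ovoids at 0.6 um/px (20x scale), 48 frames per
  rotation, 80-frame recordings, 2% noise;
* recovery battery: down-scaled worms (300-480 um) at 2 um/px with
  randomised bend, taper and size, 40 frames per rotation, used for
  parameter-recovery checks against the analytic ground truth.

All randomness is derived from the integer seed passed in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import (
    Phantom,
    PhantomSpec,
    RenderResult,
    RenderSpec,
    adult_render_spec,
    adult_spec,
    auto_render_spec,
    build_phantom,
    embryo_render_spec,
    embryo_spec,
    render_stack,
    sample_adult_spec,
    sample_embryo_spec,
)
from .pipeline import PipelineResult, RunConfig, run_pipeline

__all__ = [
    "StudyRun",
    "run_adult",
    "run_embryo",
    "battery_spec",
    "battery_render_spec",
    "run_battery_specimen",
]

ADULT_PIXEL_UM = 4.0
ADULT_PERIOD = 64.0
ADULT_FRAMES = 104
EMBRYO_PIXEL_UM = 0.6
EMBRYO_PERIOD = 48.0
EMBRYO_FRAMES = 80
BATTERY_PIXEL_UM = 2.0
BATTERY_PERIOD = 40.0
BATTERY_FRAMES = 68


@dataclass
class StudyRun:
    phantom: Phantom
    render: RenderResult
    result: PipelineResult


def _config(phenotype: bool) -> RunConfig:
    cfg = RunConfig()
    cfg.phenotype.enabled = phenotype
    return cfg


def run_adult(
    seed: int = 1,
    noise_sigma: float = 0.02,
    cohort: bool = False,
    phenotype: bool = False,
    tail_fade: bool = False,
    noise_seed: int | None = None,
) -> StudyRun:
    """Standard adult experiment: build, render and reconstruct.

    ``cohort=True`` draws the randomised cohort geometry for this seed
    instead of the fixed standard worm.  ``tail_fade`` switches on the
    orientation-dependent low-contrast tail (fading over the last 25% of
    the body down to a 3% contrast floor at the worst orientation).
    """
    spec = sample_adult_spec(seed) if cohort else adult_spec(seed=seed)
    fade = dict(tail_fade_frac=0.25, tail_fade_floor=0.03) if tail_fade else {}
    rs = auto_render_spec(
        spec, ADULT_PIXEL_UM, ADULT_FRAMES, ADULT_PERIOD,
        seed=noise_seed if noise_seed is not None else seed,
        noise_sigma=noise_sigma, **fade,
    ) if cohort or tail_fade else adult_render_spec(
        seed=noise_seed if noise_seed is not None else seed,
        noise_sigma=noise_sigma, **fade,
    )
    phantom = build_phantom(spec, voxel_um=ADULT_PIXEL_UM / 2)
    render = render_stack(phantom, rs)
    result = run_pipeline(render.stack, _config(phenotype))
    return StudyRun(phantom, render, result)


def run_embryo(
    seed: int = 1,
    noise_sigma: float = 0.02,
    cohort: bool = False,
    phenotype: bool = False,
    noise_seed: int | None = None,
) -> StudyRun:
    """Standard embryo experiment: build, render and reconstruct."""
    spec = sample_embryo_spec(seed) if cohort else embryo_spec(seed=seed)
    rs = auto_render_spec(
        spec, EMBRYO_PIXEL_UM, EMBRYO_FRAMES, EMBRYO_PERIOD,
        seed=noise_seed if noise_seed is not None else seed,
        noise_sigma=noise_sigma,
    ) if cohort else embryo_render_spec(
        seed=noise_seed if noise_seed is not None else seed,
        noise_sigma=noise_sigma,
    )
    phantom = build_phantom(spec, voxel_um=EMBRYO_PIXEL_UM / 2)
    render = render_stack(phantom, rs)
    result = run_pipeline(render.stack, _config(phenotype))
    return StudyRun(phantom, render, result)


def battery_spec(seed: int) -> PhantomSpec:
    """Recovery-battery worm: randomised bend, taper and size."""
    rng = np.random.default_rng(seed + 500)
    return PhantomSpec(
        kind="worm",
        length_um=float(rng.uniform(300, 480)),
        max_radius_um=float(rng.uniform(15, 22)),
        taper=float(rng.uniform(0.1, 0.3)),
        bend_amplitude_um=float(rng.uniform(8, 35)),
        bend_wavelength_um=float(rng.uniform(260, 520)),
        bend_phase=float(rng.uniform(0, 2 * np.pi)),
        bump_amplitude_um=float(rng.uniform(0.4, 0.9)),
        bump_frequency=int(rng.choice([3, 5, 7])),
        n_landmarks=3,
        rng_seed=seed,
    )


def battery_render_spec(spec: PhantomSpec, seed: int, noise_sigma: float = 0.0) -> RenderSpec:
    return auto_render_spec(
        spec, BATTERY_PIXEL_UM, BATTERY_FRAMES, BATTERY_PERIOD,
        seed=seed, noise_sigma=noise_sigma,
    )


def run_battery_specimen(seed: int, noise_sigma: float = 0.0) -> StudyRun:
    """One recovery-battery worm through the full pipeline (with metrics)."""
    spec = battery_spec(seed)
    phantom = build_phantom(spec, voxel_um=BATTERY_PIXEL_UM / 2)
    render = render_stack(phantom, battery_render_spec(spec, seed, noise_sigma))
    result = run_pipeline(render.stack, _config(phenotype=True))
    return StudyRun(phantom, render, result)
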