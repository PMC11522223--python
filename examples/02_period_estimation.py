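"""Estimate the rotation period of a recording by template matching.

Renders a short worm recording with a deliberately non-integer period
(48.5 frames per turn), then scans the frame-to-frame normalised
cross-correlation over candidate lags.  The similarity curve peaks each
time the specimen returns to the same orientation; parabolic refinement
around the peaks resolves the period to a fraction of a frame.
"""

import numpy as np

import wormhull as wh
from wormhull import imaging, kinematics
from wormhull.pipeline import _mask_roi
from wormhull.protocols import battery_spec

TRUE_PERIOD = 48.5

spec = battery_spec(2)
phantom = wh.build_phantom(spec, voxel_um=1.0)
render = wh.render_stack(
    phantom,
    wh.auto_render_spec(spec, 2.0, 82, TRUE_PERIOD, seed=2, noise_sigma=0.02),
)

enhanced = imaging.enhance(render.stack)
sils = imaging.segment(enhanced)
est = kinematics.estimate_period(enhanced, roi=_mask_roi(sils))

print(f"true period     : {TRUE_PERIOD} frames")
print(f"estimated period: {est.period_frames:.3f} frames "
      f"(error {est.period_frames - TRUE_PERIOD:+.3f})")
print(f"peak similarity : {est.peak_score:.4f}")
k = int(np.argmax(est.similarity))
print(f"similarity curve peaks near lag {est.lags[k]} "
      f"(top NCC {est.similarity[k]:.4f} of {est.lags.size} lags scanned)")
# Sub-frame accuracy matters: a half-frame period error tilts every
# assigned angle and smears the carved hull.
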