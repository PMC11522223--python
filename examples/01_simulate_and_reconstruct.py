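"""Render a rotating adult worm phantom and reconstruct its 3-D model.

Builds the standard ~1 mm adult phantom, renders 104 brightfield frames
of its rotation (64 frames per turn, 2% noise), runs the full pipeline
and prints the estimated rotation period, the per-viewpoint reprojection
IoU, and the five morphometric readouts next to the analytic truth.
"""

import numpy as np

from wormhull import protocols

run = protocols.run_adult(seed=1, noise_sigma=0.02, phenotype=True)

est = run.result.estimate
print(f"rotation period : {est.period_frames:.3f} frames "
      f"(generator: {protocols.ADULT_PERIOD})")

rep = run.result.iou_report
print("reprojection IoU by viewpoint (deg -> %):")
for vp, v in zip(rep.viewpoints_deg, rep.ious):
    print(f"  {vp:5.0f}  {100 * v:6.2f}")
print(f"mean {100 * rep.mean:.2f}%  sd {100 * rep.sd:.2f}%  (n = {rep.n})")

truth = run.phantom.ground_truth.metrics
rec = run.result.record.as_dict()
print("\nmorphometrics (measured vs analytic truth):")
for key in truth:
    print(f"  {key:20s} {rec[key]:12.1f} vs {truth[key]:12.1f} "
          f"({100 * (rec[key] / truth[key] - 1):+.2f}%)")
# An IoU above 95% at every viewpoint means the projected model overlaps
# the segmented silhouettes almost perfectly; metric errors of a few
# percent reflect the raster resolution and the visual-hull bound.
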