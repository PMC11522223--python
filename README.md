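# wormhull

3-D reconstruction and morphometric phenotyping of rotating
*Caenorhabditis elegans* from brightfield silhouettes.

## The problem

A nematode rolling uniformly about its long axis shows the camera a
different silhouette every frame.  One full rotation therefore contains
enough information to recover a dense 3-D model of the animal with
nothing more than a widefield microscope: intersect the back-projected
silhouettes of all orientations (the *visual hull*) and the body
emerges.  From the model, five morphometric phenotypes — surface area
*S*, volume *V*, length *L*, maximum width *W* and the ratio *L/W* —
can be read out per animal and compared across strains.

`wormhull` implements this pipeline for image stacks of one specimen
rotating about the image-horizontal axis:

1. **enhance** — background flattening, edge-preserving denoising,
   bicubic upsampling (classical stand-ins for learned enhancement);
2. **segment** — Otsu threshold + morphology → one clean silhouette per
   frame, with a per-column confidence and a *confident extent*;
3. **period** — template matching: the mean normalised cross-correlation
   between frames *i* and *i + lag* peaks when the specimen returns to
   the same orientation; harmonic-comb scoring picks the fundamental and
   parabolic interpolation resolves it below one frame;
4. **align** — in-plane drift removal that preserves the rotation-induced
   centroid wobble of bent bodies;
5. **carve** — per axial slice *x*, the cross-section is
   `⋂ᵢ { p : loᵢ(x) ≤ p·u(θᵢ) < hiᵢ(x) }` over the frames whose
   confident extent covers *x* — the gating is what reconstructs the
   low-contrast tail from the orientations that saw it;
6. **mesh** — marching cubes + volume-preserving Taubin smoothing;
7. **validate** — reprojection IoU against the segmented frames at
   viewpoints 0°–180° in 30° steps;
8. **phenotype** — *V* from the voxel count, *S* from the watertight
   mesh, *L* as the arc length of the skeleton-geodesic centreline
   extended to the tips, *W* as the largest Feret diameter of the
   cross-sections normal to the centreline;
9. **stats** — two-tailed Student's *t* tests per metric and PCA +
   logistic-regression/SVM strain classification.

A parametric **phantom generator** stands in for the robotic rotation
rig: worms (~1 mm × ~50 µm, bent, tapered, corrugated), embryos
(~50 × 30 µm lumpy ovoids), spheres and cylinders, each with analytic
ground truth, internal intensity landmarks, drift, blur, noise and an
orientation-dependent low-contrast tail.

## Worked example

```bash
python examples/01_simulate_and_reconstruct.py
```

prints (standard adult phantom, 64 frames/turn, 2% noise):

```
rotation period : 63.998 frames (generator: 64.0)
reprojection IoU by viewpoint (deg -> %):
      0   98.07
     30   98.99
     60   98.39
     90   98.31
    120   97.96
    150   98.75
    180   98.09
mean 98.37%  sd 0.38%  (n = 7)

morphometrics (measured vs analytic truth):
  surface_area_um2         138432.0 vs     137141.4 (+0.94%)
  volume_um3              1557932.0 vs    1553505.7 (+0.28%)
  length_um                   983.7 vs       1011.0 (-2.69%)
  max_width_um                 51.0 vs         50.0 (+2.00%)
  ratio                        19.3 vs         20.2 (-4.60%)
```

The period is recovered to three thousandths of a frame; every
viewpoint's reprojection overlaps its silhouette by more than 95%; and
the five phenotypes land within a few percent of the analytic truth
(length is biased slightly short because the faintest tip columns fall
below the segmentation confidence floor).

Other examples: `02_period_estimation.py` (non-integer periods),
`03_tail_completion.py` (confidence gating vs ablation),
`04_phenotype_and_stats.py` (t tests + PCA/SVM strain separation),
`05_cli_workflow.py` (file-based workflow; the `wormhull` console
script exposes the same stages as subcommands).

## Library usage

```python
import wormhull as wh
stack = wh.read_stack("recording.tif", pixel_size_um=4.0)
result = wh.run_pipeline(stack)
result.mesh.save("worm.ply")
print(result.iou_report.mean, result.record.volume_um3)
```

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
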