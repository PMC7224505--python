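# fasc3d

Automatic three-dimensional reconstruction of peripheral-nerve **fascicles**
(bundles of nerve fibers wrapped in perineurium) from ordered stacks of 2D
histological cross-sections.

Computational models of peripheral nerves used to design neural interfaces
usually simplify the internal anatomy — a single cross-section extruded along
the nerve, or circular fascicles — even though fascicular branching is known to
change simulated recordings and stimulation selectivity. `fasc3d` is for
researchers who have serial nerve sections (hematoxylin & eosin or
anti-neurofilament IHC stains, typically 5 μm sections cut every 250 μm) and
want a labeled 3D fascicle model with no manual tracing.

## The pipeline

Four stages, each usable on its own:

1. **Registration** — consecutive slices are aligned by intensity-based
   (mean-squares) registration under stochastic gradient descent, in four
   passes of nested transform families at increasing resolution: translation
   at 25%, rigid at 50%, similarity at 75% (H&E) or 100% (IHC), full affine at
   100%. Pairwise transforms are chained to the block reference frame and each
   slice is resampled exactly once. Quality is reported as before/after MSE
   (0–255 intensity scale) and SSIM.
2. **Detection** (H&E only) — per-slice fascicle bounding boxes. The built-in
   detector is the phase-coded circle Hough transform (a single complex
   accumulator whose phase encodes radius on a log scale); a trained neural
   detector can be plugged in through a boxes-JSON interface. Detections are
   scored by precision/recall/F1 with greedy IOU ≥ 0.5 matching.
3. **Segmentation** — H&E: detection boxes become inflated ellipses, the
   exterior is masked to the background estimate, and a Chan–Vese active
   contour (smooth factor 0.6, contraction bias 0.5) shrinks outside-in onto
   the fascicle boundary. IHC: Otsu threshold + morphological closing + hole
   filling. Otsu and K-means whole-slice comparators are included.
4. **Reconstruction** — per-pixel hole fixing along z (re-inserting fascicle
   evidence missing from intermediate slices), watershed splitting of merged
   fascicles (distance-transform watershed, erosion + second watershed for
   large merges, labels dilated back so support is preserved exactly), then
   shape-based interpolation between slices: intermediate layers threshold the
   linear blend of signed Euclidean distance maps `(1−t)·d_a + t·d_b < 0`,
   which morphs cross-sections into each other and never bridges shapes with
   no x-y overlap. 3D connected components assign fascicle identities through
   branches. An extrusion baseline (first slice replicated along z) is
   provided for comparison.

An evaluation harness rebuilds the standard comparison matrix against a gold
standard (manual registration + manual segmentation): fully automatic, MRAS
(manual registration/automatic segmentation), ARMS (automatic
registration/manual segmentation), and EX (extrusion), each with and without
hole fixing, reporting 3D IOU and a per-z-layer IOU profile.

Because real annotated histology cannot ship with a package, `fasc3d` includes
a synthetic **phantom generator**: blocks of roughly elliptical fascicle tubes
with smooth centerline wander, branch events, IHC-like (dark-on-light) or
H&E-like (low-contrast textured RGB) rendering, per-slice misalignment with
recorded true transforms, and slice-level fascicle dropout — with full ground
truth (masks, boxes, transforms, dense labeled volume) for every stage.

## Worked example

```python
import numpy as np
from fasc3d import (PhantomSpec, generate_phantom, register_stack, segment_ihc,
                    ReconstructionParams, reconstruct_block, compare_models)

spec = PhantomSpec(n_slices=12, image_size=512, n_fascicles=5,
                   fascicle_radii=(12, 28), misalignment=(15, 5, 0),
                   branch_events=[(6, 0)], noise_sd=0.02, seed=11)
stack, truth = generate_phantom(spec)

aligned, transforms, quality = register_stack(stack)
print(f"mean MSE  {np.mean([q.mse_before for q in quality]):7.1f} -> "
      f"{np.mean([q.mse_after for q in quality]):6.1f}")
print(f"mean SSIM {np.mean([q.ssim_before for q in quality]):7.3f} -> "
      f"{np.mean([q.ssim_after for q in quality]):6.3f}")

masks = [segment_ihc(s.gray()) for s in aligned.slices]
params = ReconstructionParams()  # hole fixing on, 4 layers between sections
model = reconstruct_block(masks, params, stack.pixel_size, stack.slice_spacing)
print(f"model: {model.n_labels} fascicles, grid {model.voxels.shape}, "
      f"voxel size {tuple(round(v, 1) for v in model.voxel_size)} um")

iou, _ = compare_models(model, truth.volume(params.n_intermediate, params.downscale))
print(f"3D IOU vs ground truth: {iou:.3f}")
```

Output:

```
mean MSE    823.6 ->   96.9
mean SSIM   0.513 ->  0.617
model: 5 fascicles, grid (56, 128, 128), voxel size (20.0, 20.0, 50.0) um
3D IOU vs ground truth: 0.870
```

The registration collapses the misalignment-driven MSE by ~8× and raises SSIM;
segmentation + reconstruction recover the branching five-fascicle anatomy
(including the slice-6 bifurcation, which an extrusion cannot represent) at
0.87 overlap with the analytic ground truth.

## Command line

```bash
fasc3d simulate  --spec phantom.yaml --out-dir block01/
fasc3d register  --stack block01/images.tiff --stain IHC --out aligned.tiff \
                 --transforms transforms.json --metrics reg_quality.csv
fasc3d detect    --aligned aligned.tiff --method hough --out boxes.json
fasc3d segment   --aligned aligned.tiff --stain IHC --out masks.tiff
fasc3d reconstruct --masks masks.tiff --spacing 250 --thickness 5 --out model.nrrd
fasc3d evaluate  --config matrix.yaml --out results.csv
fasc3d pipeline  --config pipeline.yaml --out-dir run01/   # all of the above
```

`pipeline.yaml` takes a `seed`, a `phantom:` block (PhantomSpec fields) or a
`stack:` path, and optional `preprocess:`, `detector:` and `reconstruction:`
blocks mirroring the dataclass fields. IHC blocks skip the detection stage —
thresholding needs no boxes. Every output is reproducible from config + seed.

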