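# myoseg

Semi-automated segmentation and morphometry of skeletal-muscle fibers in
fluorescence micrographs.

Muscle fiber size — quantified as cross-sectional area (CSA, µm²) or,
preferably, the **minimum Feret diameter** (the smallest caliper width over
all orientations, which is least distorted by oblique sectioning) — is a
primary readout in studies of atrophy, hypertrophy, nerve injury and
myopathy. Fiber boundaries are visualized by membrane/matrix stains
(collagen V, laminin, dystrophin), but automated segmentation tools often
fail under weak or regionally uneven staining. `myoseg` implements a
pipeline built around *line* detection of the stained extracellular
membrane rather than edge detection of fiber interiors, which tolerates
low-contrast images:

1. **Intensity leveling** — the image is divided by a median-filter
   background estimate (45×45 µm kernel), normalizing fiber interiors to
   ≈ 1.0 and leaving boundary stain > 1.
2. **Contrast enhancement** — Perona–Malik anisotropic diffusion
   (conductance threshold `k = σ²/resolution²`, σ = 3 µm by default)
   followed by raising pixel values to the 4th power.
3. **Ridge detection** — Steger's Hessian-based curvilinear-structure
   detector at scale `σ_px = (w/resolution)/(2√3) + 0.5` for a target
   boundary width w (default 6 µm), yielding a 1-px skeleton of boundary
   centerlines.
4. **Seed generation** — disk dilation (6 µm) of the skeleton, Gaussian
   blur, and a threshold (default 70 on the 0–255 scale): connected
   sub-threshold regions become watershed markers.
5. **Marker-based watershed** on the blurred ridge image, followed by
   per-fiber CSA and min/max Feret measurement (exact rotating calipers on
   the convex hull of pixel corners), exclusion of fibers outside
   200–10,000 µm² or touching the ROI edge, and summary statistics.

All physical parameters are given in µm and scaled by the image resolution
(µm/pixel), so one configuration serves images from different microscopes.

The package also provides:

- a **staining-contrast mapping tool**: the leveled image sampled at ridge
  centerlines, averaged in 27×27 µm windows, gives a map of the
  boundary-to-interior stain ratio; regions above ≈ 2.25 segment reliably;
- a **synthetic phantom generator** (hexagonal or Voronoi fiber mosaics
  with known ground truth, controllable staining contrast, illumination
  gradients and noise) and **evaluation metrics** (mean-Feret error, count
  error, Bland–Altman agreement) used to validate the pipeline end to end.

## Worked example

Generate a phantom that mimics a collagen-stained section (45 µm fibers,
6 µm boundaries, staining ratio 2.5, a 30% illumination gradient, 5%
noise) and segment it:

```python
import myoseg as ms

spec = ms.PhantomSpec(width_px=1000, height_px=1000, resolution=0.462,
                      layout="hexagonal", hex_pitch_um=51.0,
                      boundary_width_um=6.0, contrast_ratio=2.5,
                      illumination=0.3, noise_sd=0.05, rng_seed=1)
img, truth = ms.generate_phantom(spec)

labels, table, summary = ms.run_pipeline(img)
print(summary["n_kept"], round(summary["mean_min_feret_um"], 2))

truth_kept = ms.filter_fibers(truth.records)
print(round(ms.mean_feret_error(table, truth_kept), 2),
      round(ms.count_error(table, truth_kept), 2))
```

Output:

```
72 45.07
0.19 0.0
```

72 fibers are kept (those inside the CSA window and not touching the image
edge), with an estimated mean minimum Feret diameter of 45.07 µm against a
ground truth of 45.0 µm — a 0.19% mean-diameter error and 0.0% fiber-count
error.

The same pipeline is available from the shell:

```sh
myoseg segment section.tif --resolution 0.462 --out results/
myoseg contrast section.tif --resolution 0.462 --out results/
myoseg phantom --spec spec.json --seed 1 --out phantom/
myoseg evaluate --pred results/fibers.csv --truth phantom/truth_fibers.csv --out report.json
```

`segment` writes the label image (TIFF), a boundary overlay (PNG), the
per-fiber table (CSV: id, CSA, min/max Feret, centroid, edge flag,
exclusion reason), a min-Feret histogram (CSV) and a summary JSON with the
configuration echo and excluded-fiber bookkeeping.

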