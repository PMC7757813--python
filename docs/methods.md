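# Methods

## Pipeline model and assumptions

`myoseg` assumes a single-channel fluorescence image of a transverse
muscle section in which the extracellular membrane/matrix is stained
*brighter* than the fiber interiors, forming a connected network of
curvilinear lines of roughly constant physical width (micrometres). The
method detects those lines and floods the enclosed basins; it therefore
places segmentation boundaries along the membrane centerline — halfway
between neighbouring fibers — rather than at the fiber's interior edge.
All stages are deterministic; only the phantom generator consumes a random
seed.

### Stage 1 — intensity leveling

Background := median filter of the raw image with a square kernel of side
`round(45 µm / resolution)` px, forced odd. The image is divided by the
background, normalizing interiors to ≈ 1.0. Two numerical choices:

- **Separable median.** The 2-D median is computed as a row pass followed
  by a column pass (O(k) per pixel instead of O(k²)). On the smooth,
  slowly-varying fields this stage estimates, the separable result is
  indistinguishable from the exact 2-D median; `exact=True` restores the
  exact filter (used in unit tests with small kernels). At the default
  97-px kernel the exact filter costs minutes per megapixel, the separable
  one ~3 s.
- **Axis detrending.** The gross illumination trend is first estimated per
  axis (median of each column, then of each row of the detrended image),
  smoothed with a 1-D median of the kernel width, with the border
  half-windows replaced by a straight-line fit to the adjacent interior
  (a running median is biased where its window is folded at the border).
  The local median runs on the detrended image and the trend is re-applied.
  This makes leveling *exactly* invariant to separable multiplicative
  shading — a plain windowed median leaves two residual biases under a
  gradient (the in-window quantile shift caused by the bright-stripe
  fraction, and the border fold), both of which scale with gradient ×
  kernel size.
- Division guard: background floored at 1e-6 of the image maximum. Border
  policy for the median itself: reflection.

### Stage 2 — contrast enhancement

Perona–Malik diffusion, explicit scheme with 4-neighbour fluxes and
no-flux boundaries, conductance `g(∇) = exp(−(∇/k)²)` (or the rational
variant `1/(1+(∇/k)²)`). The conductance threshold follows
`k = σ²/resolution²` with σ the filter width in µm (default 3). The
explicit flux form conserves the image mean exactly and obeys the discrete
maximum principle for time steps ≤ 0.25 (2-D stability bound); defaults
are 15 iterations at Δt = 0.2, chosen to suppress pixel noise at the
µm scales involved while leaving membrane contrast intact — both exposed
in the configuration, as noise levels vary between acquisitions. After
diffusion, pixel values are raised to the 4th power (interiors ≈ 1 stay
put, boundary stain is amplified) and mapped linearly to 0–255 for the
ridge stage; the mapping is recorded in the run summary.

### Stage 3 — ridge detection

Steger's method: Gaussian partial derivatives at scale
`σ_px = (w/resolution)/(2√3) + 0.5`, where w is the physical boundary
width (default 6 µm). For a plateau bar of width w the centre response
|g″_σ * bar| is maximized at exactly σ = w/(2√3); the +0.5 px offsets
discretization at small widths. Per pixel, the Hessian eigenvector of the
largest-magnitude eigenvalue gives the line normal; the eigenvector is
taken from whichever of the two row equations of (H − λI)v = 0 is better
conditioned, which remains correct for exactly axis-aligned lines (where
the mixed derivative vanishes identically). A line point is accepted where
the directional derivative along the normal vanishes within the pixel and
the second directional derivative is negative (bright line). The nominal
in-pixel criterion |t·n| ≤ 0.5 is widened to 0.55: when a line runs
exactly midway between two pixel rows, the discrete profile makes the
solved offset overshoot to ≈ 0.505 on *both* flanking pixels, and the
strict test would reject the entire centerline.

Salience = |second directional derivative|. Hysteresis linking uses
thresholds high = 0.5 × (99.5th percentile of candidate salience) and
low = high/3 by default. On a usable stain the candidate set is dominated
by true boundary pixels whose saliences form a tight high mode well
separated from interior noise (two orders of magnitude on reference
phantoms), so thresholds anchored to the top of the distribution retain
the whole centerline; percentile-rank thresholds do not (any fixed rank
below the boundary-pixel fraction truncates the centerline itself).
Accepted points are thinned to a 1-px skeleton; sub-pixel positions are
kept for diagnostics. Full line-width estimation and bias correction are
out of scope — the pipeline needs only centerlines.

### Stage 4 — seeding

The skeleton is dilated with a Euclidean disk (radius 6 µm, implemented
via the exact distance transform), blurred with a Gaussian (σ default
3 µm — half the line width: enough to smooth dilation blockiness without
bridging adjacent fibers), and thresholded at 70 on the 0–255 scale of the
blurred binary image. Connected components (8-connectivity) of the strict
sublevel set with at least `min_seed_px` pixels (default: a quarter of the
200 µm² minimum-fiber area) become markers. Zero markers raises a
dedicated error advising a higher threshold.

### Stage 5 — watershed and membrane exclusion

Marker-based watershed on the blurred ridge topography, 4-connectivity
(prevents diagonal leakage across 1-px divide chains), with 1-px divide
lines labelled 0. An optional binary mask excludes regions (e.g.
connective tissue) from flooding; fibers adjacent to masked-out areas are
flagged as edge fibers. Because the divide traces the membrane
*centerline*, each basin still contains half the membrane on each side;
pixels within `line_width/2` (µm) of the divide are then set to 0 so that
reported CSA and Feret describe the fiber proper. Without this the mean
diameter is overestimated by a full membrane width (≈ 13% for 45 µm
fibers with 6 µm membranes). The divide set used for the distance
computation is the watershed's own zero line; a thickened boundary set
would double-count and strip ≈ 1 px/side too much (a measurable −2%
diameter bias).

### Morphometry

CSA = pixel count × resolution². Feret diameters are computed on the
convex hull of pixel *corner* points (so a 1-px-wide object has width
1 px): the minimum Feret is the smallest over hull edges of the farthest
vertex distance to the edge line (the rotating-calipers minimum is always
attained perpendicular to a hull edge), the maximum is the hull diameter.
A brute-force 0.1° rotation sweep exists only as a test oracle. Fibers
with CSA outside [200, 10,000] µm² (the biological range of the target
tissue; segments above it are fused fibers, below it artifacts) or
touching the ROI edge are excluded; fractions excluded below/above are
reported over all detected fibers. Summary statistics use the n−1 SD and
a 5 µm histogram bin by default.

## Contrast mapping

The leveled image value *at* a boundary centerline is the
boundary-to-interior stain ratio (interiors level to 1). The map samples
the leveled image at skeleton pixels and averages over sampled pixels
within an odd square window of 27 µm — over sampled pixels only, not the
full window, so the value is a pure stain ratio independent of fiber
size. Windows with no skeleton pixel map to 0 (documented fallback);
sample presence is decided against half of one sample's window weight to
avoid float-rounding phantom samples. Rendered output clips to the
display range [1.0, 3.0]; the data file keeps raw values. A ratio ≥ 2.25
marks regions expected to segment reliably.

## Phantom generator

Phantoms emulate the staining properties the pipeline targets: convex
polygonal fibers, bright boundary stripes of constant physical width
(default 6 µm), boundary/interior intensity ratio in the 1–3 range
(scalar or a left-to-right ramp), a multiplicative linear illumination
gradient, and additive Gaussian noise (clipped at 0, quantized to 16-bit
with interior base 1000 counts). Additive Gaussian noise (not Poisson)
keeps the contrast ratio exact in expectation and matches the visually
dominant camera noise.

Geometry: seed points (triangular lattice for hexagonal cells; dart-throwing
Poisson-disk sampling for Voronoi mosaics, with the cell pitch equal to
the requested fiber diameter plus the boundary width and the rejection
radius shrinking with the requested size dispersion). Pixels whose
bisector distance between the two nearest seeds is below half the
boundary width form the stripes; ground-truth labels are the cells eroded
by half the boundary width — i.e. truth fibers, like measured fibers,
exclude the shared membrane, and for hexagonal layouts every interior
fiber has min Feret = pitch − boundary width analytically. The hexagonal
lattice is offset by (pitch/3, row/3) from the image origin so that no
membrane stripe runs exactly along the image frame — a degenerate
alignment that real crops do not exhibit and that would make basins flood
through a half-stripe at the border.

What the phantoms do *not* model: interior texture and organelles,
non-specific staining blobs, connective-tissue bands, freezing/sectioning
artifacts, or fiber-type intensity differences. Passing phantom tests
therefore demonstrates the geometric and photometric correctness of the
chain, not robustness to histological artifacts; on real tissue the
interactive parameters (seed threshold, line width, mask) remain
necessary, which is why every stage parameter is exposed.

## Validation conditions and problem sizes

- Reference recovery: 1000×1000 px hexagonal phantom at 0.462 µm/px,
  51 µm pitch (true min Feret 45 µm), contrast 2.5, 30% illumination
  gradient, 5% noise. The pipeline recovers the mean min-Feret to ≈ 0.2%
  and the kept-fiber count exactly; the whole run takes ~5 s.
- Contrast adequacy: the low- vs high-contrast comparison (ratios 1.5 and
  3.0, 700×700 px) uses 20% noise. The noise level is set by signal
  reasoning, not tuning: weak staining means the boundary amplitude is
  comparable to the noise, and at 20% the ratio-1.5 boundary sits at
  SNR 2.5 (marginal) while ratio 3.0 sits at SNR 10 (robust), so the
  sweep actually spans the adequacy threshold. At gentle noise both
  conditions segment near-perfectly and the comparison degenerates to a
  seed-level tie.
- Small crops: in a 600-px crop a sizable fraction of fibers borders the
  frame, where truth and prediction can legitimately disagree about the
  edge-exclusion flag (a frame-clipped cell too small to seed is annexed
  by its neighbour's basin, and the neighbour is then conservatively
  excluded). Count agreement is therefore asserted tightly only at the
  reference size.

## Evaluation metrics

Image-level comparison, matching how segmentation methods are validated
against manual tracing: absolute (and signed) percent difference of the
mean minimum Feret over kept fibers, signed percent fiber-count
difference (positive = over-segmentation), and Bland–Altman agreement
(per-pair mean m and difference d; OLS of d on m for proportional bias;
mean difference ± 1.96 SD as limits of agreement). Fiber-to-fiber
(IoU-style) matching is deliberately out of scope.

## Known limitations

- Line detection cannot reject broad connective-tissue areas; these
  should be masked out (the `--mask` input) as in practice.
- The separable median and the axis-trend model assume background
  variation is smooth at the kernel scale; pathological high-frequency
  shading would leak into the leveled image.
- Images whose fiber boundaries are darker than interiors require
  `detect_dark_lines`, which is exposed on the detector but untested
  against real dark-line stains.
- Raw intensities are never rescaled on input; leveling is
  scale-invariant by construction, so 10-, 12- and 16-bit data need no
  special handling.
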