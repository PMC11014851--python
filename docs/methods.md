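# Methods

## The measurement problem

A quantitative phase image (QPI) measures the optical path difference (OPD)
of light through a cell. Because the refractive-index excess of cellular
material is proportional to its dry-mass concentration, OPD divides directly
into areal dry-mass density,

    sigma = OPD / alpha        [pg/um^2],

with alpha the specific refractive increment, 0.18 um^3/pg for typical
cellular dry material. A time-lapse QPI movie therefore tracks the dry-mass
distribution of a single cell.

Local mass change mixes two effects. In a fixed (Eulerian) pixel,

    d(sigma)/dt + div(sigma v) = r,

where v is the intracellular mass-transport velocity and r the net local
biomass production (positive) or degradation (negative). The quantity of
biological interest is r. This package estimates r by eliminating the
transport term geometrically rather than numerically: small control volumes
(default 0.7 um^2) are advected with the measured velocity field, so that in
the co-moving (Lagrangian) frame the mass of each deforming volume changes
only through r. The ordinary-least-squares slope of a volume's mass versus
time over an analysis window is its net growth rate in pg/h; rasterizing the
rates onto the volumes' window-start footprints yields a growth map.
Explicitly differentiating the noisy field to form div(sigma v) is never
done — tracking absorbs the advection term exactly, which is the point of
the Lagrangian formulation.

## Pipeline stages and the choices behind them

### Mass imaging

* **Background**: a least-squares plane is fitted to the off-cell region and
  subtracted everywhere, then the residual background median is removed.
  A plane is the simplest model consistent with slowly varying illumination
  and is exactly testable (a planar ramp must vanish to numerical noise).
* **Segmentation**: Gaussian pre-smoothing (sigma 1 px), a fixed density
  threshold (default 0.05 pg/um^2, config key
  `segmentation_threshold_pg_per_um2`), largest connected component, holes
  filled. Deterministic given the frame and threshold. Real pipelines may
  substitute any mask; masks are first-class inputs.
* **Grid convention**: arrays are row-major; the center of pixel (i, j) is
  at x = (j + 0.5) px, y = (i + 0.5) px, with y down rows. Every module uses
  this convention; velocimetry/advection interop depends on it.

### Velocimetry

Between consecutive mass frames, interrogation windows on a regular node
grid are compared by zero-mean normalized cross-correlation: the central
template of the first window (inset by the search radius) is matched against
the second window (FFT numerator, spatial-domain normalization), giving a
true NCC map with no periodic wrap-around. Defaults: window 32 px, overlap
0.75 (nodes every 8 px), search radius 4 px. These were chosen by
measurement, not convention: with a 16 px window the 8 x 8 template carries
too few independent texture features and subpixel errors reach ~0.11 px RMS
on realistic granular phase texture, whereas the 24 x 24 template of the
default configuration measures ~0.01 px. Per-frame intracellular
displacements are of order 1 px by acquisition design (1 min intervals for
~0.2 um/min transport at ~0.25 um sampling), so a 4 px search is ample; a
Nyquist guard warns when the 95th-percentile displacement exceeds half the
diffraction-limited resolution (0.48 um).

Subpixel refinement is two-stage. A 3-point Gaussian peak fit initializes;
a gradient-based (Lucas-Kanade-style) iteration then re-estimates the
fractional displacement by linearizing `b(x) ~ gain * a(x - f) + offset`
over the integer-aligned overlap. The gain and offset absorb uniform growth
and background drift. This matters quantitatively: peak-interpolation
estimators carry a texture-locked bias of ~0.01-0.04 px which, being frozen
in time, integrates into a secular drift of every tracked volume; the
gradient stage reduces the bias to ~0.001 px.

Vector validation follows standard practice: windows below a mean density
floor or with an ambiguous correlation (ratio of the primary peak to the
highest secondary *local maximum* below 1.2 — smooth phase texture produces
one broad peak, so the max-of-remainder rule would reject everything) are
invalid; a 3 x 3 local-median test with threshold `outlier_zmax` MADs
removes outliers; invalid nodes are infilled by iterated neighbour medians.
Finally the field is smoothed with a Gaussian of 1 node
(`smooth_sigma_nodes`). Smoothing is not cosmetic: the per-node correlation
noise is frozen in time, and advecting volumes through a static compressible
perturbation makes them cluster at its convergence zones and spuriously
contract (~15% area over an hour in early experiments); smoothing over the
node spacing suppresses exactly this mode while leaving locally linear
transport fields intact.

### Lagrangian tracking

Volumes are axis-aligned squares of side sqrt(cv_area) tiled over the mask's
bounding box, kept when their center lies in the mask, with deterministic
row-major ids. Two tracking modes exist:

* **Per-pair advection** (`anchored=False`): each corner moves by the
  bilinear interpolation of the pair field, explicit Euler (`rk2` optional).
  Simple, but any persistent velocity bias integrates linearly over frames.
* **Anchored tracking** (`anchored=True`, default): for each frame k the
  cumulative displacement of material from the *window-start* frame is
  re-measured directly, by correlating reference-frame windows against
  frame k with the window offset by the integer part of the time-integrated
  pair field. The position error of a track is then bounded by a single
  correlation's accuracy instead of growing with k. On the fixed-cell
  control this is the difference between ~10% and ~100% of volumes testing
  consistent with zero growth. Nodes whose anchored correlation fails
  (texture decorrelation, window leaving the image) fall back to the
  integrated guess.

Mass inside a deformed volume is the exact integral of the piecewise-
constant density over the polygon: per-pixel Sutherland-Hodgman clipping
with a convex fully-inside/fully-outside pre-classification (~0.3 ms per
volume). An s x s supersampled estimate is available as a cross-check and
converges to the exact path as ~1/s (about 1e-3 pg at s = 64 on granular
texture). Volumes whose polygon leaves the image or self-intersects are
flagged and excluded from fitting from that frame on; they are never
re-seeded mid-window, which would mix material identities.

### Growth fitting and maps

Rates are OLS slopes of mass (pg) against time (h) over the in-bounds
frames of a window; `rate_se` is the standard OLS slope error; fewer than
3 usable frames marks the estimate invalid. Growth maps assign each pixel
the rate of the volume whose window-start polygon covers it (nearest seed
center on overlap); uncovered pixels are NaN. Sliding windows (default
30 min maps; 120 min with 60 min step for cell-cycle-style series) re-seed
on the current mask at each window start. Windows in which whole-cell mass
or area jumps by more than 20% in one frame are excluded with a warning:
division-like events break the material identity the Lagrangian frame
relies on.

### Regions and puncta

A region's total rate is the sum over volumes whose seed center lies in the
region mask; its specific growth rate is that total divided by the region's
dry mass at window start (1/h). Totals are exactly additive over masks that
partition the cell. Puncta are connected components of the growth map above
+threshold (growth) or below -threshold (degradation), with components
smaller than `puncta_min_area_um2` (default 0.5 um^2) discarded and
deterministic centroid ordering. The default threshold is 2 x 1.4826 x MAD
of the map's defined pixels — an explicit, reproducible operationalization
of a quantity that is usually described only qualitatively. On very quiet
synthetic maps this robust scale can be orders of magnitude below any
meaningful rate, so the absolute threshold is exposed
(`puncta_threshold_pg_per_h`); the validation scenario for focal sources
sets it to 30% of the designed peak per-volume response.

## The synthetic-data generator

Scenes prescribe a velocity field (zero, uniform, solid-body rotation,
shear, or custom), a source term (zero, uniform specific rate g, or
localized cosine-bump sources that co-move with the material), and a
cell-like texture: a smooth disk (default plateau 1.5 pg/um^2, cosine edge
taper 1 um) multiplied by band-limited granular contrast (default feature
diameter 0.75 um, relative amplitude 0.35). The granularity is essential,
not decorative: correlation velocimetry is blind on featureless disks, and
real cytoplasm carries mass-density granularity at about this scale.
Rendered OPD adds independent Gaussian read noise per frame (default
0.5 nm, small against the ~100 nm cellular signal) and is clipped at zero.
Identical scenes (including seed) render byte-identical movies.

Evolution is exact where an exact solution exists: for zero/uniform
velocity the state is spectrally translated and the source applied
analytically (sigma * e^(gt), or sigma0 + t * r0 in the co-moving frame), so
ground truth carries no scheme error. General fields use semi-Lagrangian
advection (bicubic sampling at backtraced departure points) with an exact
rotational departure map — a single-step backtrace has an O((w dt)^2) chord
error that visibly violates conservation — and a midpoint backtrace for
custom fields. Measured conservation: < 0.25% over 60 frames for rotations
up to 0.8 px/frame.

What the generator does *not* emulate: diffraction and the microscope's
transfer function, halo and shade-off artifacts, phase noise correlated
across pixels, out-of-plane (3-D) motion, organelle-scale refractive
heterogeneity, and cell division. Passing the validation suite therefore
demonstrates correctness of the mass-balance machinery under realistic
texture, motion and read noise — not robustness to every optical artifact
of a real instrument.

## Validation scenarios (the built-in controls)

* **Fixed-cell drift control**: a frozen textured cell rigidly drifted
  0.2 px/frame over 31 frames with 0.5 nm noise, 10 realizations. True
  growth is identically zero; >= 95% of volumes must test |rate| < 3 se and
  each whole-cell slope must be consistent with zero.
* **Whole-cell consistency**: summed volume rates vs. the OLS slope of
  segmented total mass, within 5% on growing movies.
* **Uniform source**: g = 0.05/h over 120 one-minute frames, 5 seeds;
  whole-cell specific rate and mass-weighted per-volume specific rate within
  10% of g. (Mass weighting is the natural per-volume average: it equals the
  specific growth rate of the tracked material and does not blow up on
  near-empty edge volumes.)
* **Focal sources**: one growth and one degradation bump (peak
  0.5 pg/um^2/h, radius 1.5 um) on a translating cell; exactly one positive
  and one negative punctum within 1 um of the true centers; each blob's
  summed rate within 15% of the prescribed total.
* **Velocimetry**: integer shifts exact; 0.3 px shifts within 0.05 px RMS;
  rotation field within 10% at 0.5-2 px displacements.
* **Conservation**: divergence-free rotation, volumes tracked through the
  prescribed field; summed tracked mass within 2% over 30 frames; exact
  tiling additivity of seeded volumes.
* **Determinism**: identical config + seed give byte-identical output trees.

Scenario problem sizes (128 px images, ~10 um cells, 31-120 frames) were
chosen so every scenario runs in minutes on a single CPU while keeping
>= 400 control volumes per cell.

## Known limitations

* Local sources violate the brightness-constancy assumption of the
  correlator; strong blobs induce weak apparent-motion "ghosts" (of order
  10% of the blob's rate amplitude) in adjacent volumes. The focal-source
  scenario thresholds above this level; real analyses should too.
* Anchored tracking needs the window-start texture to remain recognizable
  across the window; it degrades gracefully (falls back to integrated
  per-pair fields) under strong remodeling, but windows much longer than
  the texture decorrelation time lose its benefit.
* Rates are 2-D projections: out-of-plane transport is assumed slow, and
  the areal densities are axial integrals.
* `rate_se` is the white-noise OLS error and does not propagate velocimetry
  uncertainty; serially correlated tracking error is suppressed by design
  (anchoring) rather than modelled.
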