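# Methods

This note documents the models and procedures implemented in `endoquant`,
the parameter choices that matter, what the synthetic generators do and do
not emulate, and the numerical decisions taken where the underlying
workflow left the choice open.

## Image processing primitives

**Projections.** Z-stacks are reduced per pixel by mean, max, sum or
median. All downstream quantifications operate on projected 2-D images.

**Rolling-ball background subtraction.** The background is the grayscale
opening of the intensity surface with a spherical-cap structuring element
of the stated pixel radius — the textbook definition of "rolling a ball
under the surface". ImageJ's shrink/paraboloid accelerations are *not*
reproduced, so values can differ slightly from Fiji on real data. Edges
use replicate padding; the subtraction is clipped at zero (intensities are
photon counts). The implementation (scipy grey erosion/dilation with a
non-flat structure) is validated against a naive per-pixel min/max oracle
to machine precision. Complexity is O(pixels × radius²): the defaults
(300/80/25 px) are meant for full-resolution micrographs; analyses of the
256-px synthetic fields use a radius of 50 px, scaled to the synthetic
cell size.

**Automatic threshold.** The "Default" automatic threshold is the
intermeans (isodata) iteration t ← (mean below t + mean above t)/2 run to
its fixed point on a 256-bin histogram spanning the image's min–max range
(mirroring 8-bit behaviour for float images). Pixels strictly above the
threshold are foreground; the threshold is recorded in the mask metadata.
A constant image has no defined threshold and yields an empty mask with a
warning. The iteration is cross-checked against an independently coded
brute-force fixed-point search on 1000 random histograms.

**Sharpen / blur.** Sharpening is the 3×3 kernel (centre 12, ring −1)/4
with replicate padding and zero clipping; blurring is an isotropic
Gaussian. Both leave constant images unchanged.

**Temporal median subtraction.** For time-lapse stacks, the per-pixel
median over time is subtracted from every frame (clipped at zero),
removing stationary background while transient signal survives.

## Junction quantification

The AJ mask pipeline is average-projection → rolling-ball → isodata
threshold on the VE-Cadherin channel; because isodata is invariant to
positive rescaling, the mask does not depend on overall staining
intensity. No morphological cleanup is applied by default (none is part
of the reference workflow).

The junctional intensity ratio divides the mean processed co-channel
intensity inside the AJ mask by the mean outside it. "Background" is
deliberately the in-field complement of the AJ mask — the only background
available in a confluent monolayer field. The same processing (average
projection, rolling-ball at the channel's radius) is applied before both
means. Note one consequence of morphological background removal: a
perfectly flat cytoplasmic signal would be subtracted away entirely, so
the ratio is meaningful for the granular/punctate intracellular signal
distributions real stainings show (and which the generator emulates).

The junctional YAP fraction thresholds the max-projected,
background-subtracted YAP channel at a fixed, batch-constant value (a
required configuration input — it is an instrument/staining-dependent
constant, not something the package can guess) and reports the area of
the thresholded signal inside the AJ mask relative to the AJ-mask area.

Junction shape descriptors are computed on manually outlined polygons:
perimeter (closed polyline length, via shapely), area (shoelace), Feret's
diameter (maximum pairwise vertex distance). Because "normalized by the
longest distance" admits two readings, both P/F and A/F² are reported.
A/F² respects the isodiametric bound π/4.

## Orientation analysis and the mismatch score

Gradients are evaluated by cubic-B-spline interpolation (spline prefilter
followed by the exact derivative of the interpolant at pixel centres).
The structure tensor components J_xx, J_xy, J_yy are the Gaussian-smoothed
gradient products with window σ = 4 px; the dominant axial orientation is
θ = ½·atan2(2·J_xy, J_yy − J_xx), an angle in [−90°, 90°) measured
counterclockwise from the +x axis with y up. The tensor trace is the
orientation energy; pixels whose energy is at the numerical floor (flat
regions) have undefined orientation and are excluded from histograms.

Histograms use 18 ten-degree bins and are normalized to the contributing
pixel count (uniform weighting — each pixel one angle — by default;
energy weighting is available but off). The mismatch score between the
actin and VE-Cadherin histograms of one junction ROI is their L1 distance,
bounded in [0, 2], 0 iff identical. The ROI bounding box is enlarged by a
3-µm margin on each side (converted by the pixel size) before analysis;
the actin patch is sharpened and the VE-Cadherin patch blurred at σ = 2 px
first. Orientation recovery on noisy stripe patterns is accurate to
better than ±2° down to SNR ≈ 10; with uniform weighting, sparse fiber
images dominated by background noise pixels flatten the histograms, which
is why validation patches are dense or noise-free and why energy
weighting exists as an option.

## Nucleus-based quantifications

Nucleus segmentation (no recipe is prescribed upstream, so this is this
package's choice): Gaussian smoothing at σ = 1 px, isodata threshold,
hole filling, distance-transform watershed seeded at distance peaks at
least 4 µm apart, then an area filter (20–500 µm² by default). The small
smoothing sigma matters: heavier smoothing inflates the segmented
boundary on unbalanced histograms and biases the nuclear/perinuclear
ratio toward 1. Border-clipped nuclei legitimately fall below the size
filter; whole in-field nuclei are recovered at ≥ 95 % on the synthetic
fields.

The nuclear/perinuclear ratio divides the mean signal inside each nucleus
by the mean in a ring obtained by dilating the nucleus by the ring width
(2 µm default, a first-class parameter since the expansion distance used
by upstream analyses is unpublished and results depend on it). Ring
pixels inside any nucleus, or claimed by two nuclei's rings, are excluded
from both — no double attribution in confluent monolayers. Nuclei whose
ring is empty after exclusions report a missing ratio; border-touching
nuclei are flagged. The ratio is invariant to positive rescaling of the
signal.

Marker positivity is thresholded on the per-nucleus mean intensity with a
configurable scalar; on real data an Otsu split of the nucleus means is a
reasonable way to choose it. The leak-area fraction is the fraction of
field pixels above threshold in the streptavidin channel; a batch-constant
fixed threshold is the comparable-across-conditions mode, isodata is
offered for exploration.

## Motility

Track metrics use every recorded time step (a stride parameter exists for
sensitivity analysis): path length is the sum of Euclidean step lengths,
net displacement the start-to-end distance, and the directionality index
DI their quotient — exactly 1 for straight motion, ≥ 1 always (triangle
inequality). Tracks returning exactly to their start have undefined DI
(reported missing, never infinite). The x axis is the wound-closure
direction and y the wound-parallel direction; inputs should be rotated to
this frame upstream.

Wound segmentation (the upstream workflow documents only the
median-projection background removal; the segmentation recipe is this
module's choice, and parameterized): after temporal-median subtraction,
each frame's local *variance* (3-px window, then σ = 2 px Gaussian
smoothing of the variance map) separates textured monolayer from the
smooth cell-free wound. Variance rather than standard deviation is used
because the variance profile crosses its midpoint at the true boundary,
keeping edge localization unbiased; the symmetric smoothing suppresses
speckle without shifting that crossing. One isodata threshold is computed
from the pooled texture histogram of all frames — a movie-constant
threshold that stays well-defined even when the wound has become small —
and the wound is the largest connected low-texture region per frame, with
a contrast guard (candidate mean texture must be below half the
monolayer's) so confluent fields report zero area. The closure rate is
the least-squares slope of area versus time.

## Synthetic data

Each generator is a pure function of its parameters including the seed;
one seed is split into independent per-channel streams (adding a channel
never perturbs the others), and every sample records the *realized*
ground truth (actual leak fraction after patch placement, realized
enrichment, per-nucleus positivity, drawn fiber angles, per-frame wound
areas) — recovery is always assessed against realized, not nominal,
values.

The monolayer is a Voronoi tessellation of blue-noise (dart-throwing)
centres, evaluated on coordinates warped by a smooth random displacement
field whose RMS amplitude is the junction "jaggedness" in µm. The
junction band is the set of pixels whose two nearest-centre distances
differ by less than the junction width. Defaults: 256-px field at
0.5 µm/px, 60 cells, 1.5-µm junctions, nuclei 7×5 µm — roughly one
confluent HUVEC field at moderate magnification. VE-Cadherin marks the
band (intensity 100); N-Cadherin is a *punctate* cytoplasmic pool
(granules with true zero gaps, mean 40) plus the enriched junction band —
punctate because morphological background removal flattens any smooth
plateau to zero, which would make the junctional ratio unbounded, and
because a granular vesicular pool is what cytoplasmic cadherin staining
looks like. YAP partitions between nucleus and cytoplasm at the set
ratio; a seeded subset of nuclei is marker-bright (10 vs 100); leak
patches are 1.5-µm disks seeded on junction pixels without overlap until
the target area fraction is met (realized fraction within 0.5 percentage
points of nominal). Noise is optional Poisson shot noise plus additive
Gaussian read noise (σ = 2 by default, SNR ≥ 20 for the main structures).

Fiber patches draw straight line segments with axial (period-180°) von
Mises orientations; κ = 0 is isotropic and κ ≥ 10⁴ degenerate (all fibers
exactly at the mean). A 1-px PSF blur is applied — without it the raster
stair-steps of drawn lines alias into spurious orientations. The
analytic binned density is returned for oracle comparisons. Stripe
patches are smooth sinusoids at a known angle.

Tracks are correlated random walks: fixed step length speed × interval
(default 0.5 µm/min × 10 min), headings evolving by wrapped-normal turns
with σ = π(1 − persistence), so persistence 0 is an effectively isotropic
walk (E|R|² ≈ n·ℓ²) and persistence ≥ 1 exactly straight.

The wound series is a vertical smooth band whose half-width shrinks
linearly, embedded in a monolayer with per-frame speckle texture on a
static baseline; wound and monolayer share the same mean brightfield
level and differ only in temporal texture, as in real phase/brightfield
wound assays. True areas come from the continuous geometry.

What the generators do **not** emulate: optical PSF anisotropy and
z-blur, illumination gradients, staining variability between cells,
nuclear texture, cell shape change over time, tracking errors (missed or
swapped detections), or any mechanics/signalling — they reproduce image
*statistics* only. Passing recovery tests therefore demonstrates
correctness of the measurement code under controlled conditions, not
robustness to every real-data artefact.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: 36 stripe angles at
SNR 10 on 128-px patches (orientation); 1000 random histograms (isodata);
64-px images at radii 5/15/50 (rolling ball vs naive oracle); 4 YAP
ratios × ~57 nuclei; 3 enrichment levels on 256-px fields; 1000 random
polygons (Feret); 20 000 random walks of 100 steps against a vectorized
resimulation oracle (the ensemble is large because DI = path/net has a
heavy 1/|R| right tail, so means of small ensembles fluctuate several
percent); 20-frame wound movies on 128×512 fields closing from 50 % to
10 % of the field width; and 5 monolayer fields for nucleus-count
recovery. These sizes keep the whole validation under a minute on one
CPU while leaving each comparison statistically meaningful.

## Known limitations

* Rolling-ball values are not bit-identical to Fiji (no shrink/paraboloid
  approximation, different edge handling), though they agree with the
  mathematical definition to machine precision.
* The exact windowing of the reference orientation plugin is not public;
  the Gaussian tensor window σ = 4 px follows its documented
  interpretation, so absolute histogram values may differ slightly while
  the mismatch statistic's behaviour is preserved.
* Whether upstream orientation histograms were energy-weighted is
  unknown; uniform weighting ("total number of angles measured") is the
  default and energy weighting an option.
* The junctional ratio's "background" is the in-field AJ-mask complement;
  if a different background definition was used upstream, absolute ratios
  shift while orderings are preserved.
* Wound segmentation after median subtraction is this package's recipe
  (documented above); upstream publications do not specify one.
* Nucleus segmentation is classical (threshold + watershed); densely
  overlapping nuclei beyond a watershed's ability to split are out of
  scope, as are whole-cell segmentation and 3-D analyses.
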