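# Methods

This note documents the models, parameter choices and numerical
conventions behind `gaquant`, and what the synthetic phantom does and
does not establish about real data.

## Signal model and pipeline

The pipeline assumes a macular SS-OCT cube in which the RPE complex is
the brightest posterior band, Bruch's membrane (BM) survives atrophy,
and geographic atrophy (GA) manifests as loss of the RPE band plus
sub-RPE hypertransmission. The detection statistic is the integrated
attenuation ratio: per A-scan, the mean intensity of an RPE-complex slab
`[OS/RPE, BM + 10 µm]` divided by the mean of a choroid–scleral slab
`[BM + 20 µm, BM + 220 µm]`. Slab statistics use the **mean**, not the
sum, so the ratio does not depend on how much of a slab survives
truncation at the volume bottom. The slab offsets are configurable
defaults; they are stated in micrometres below the named surface.

Before slab averaging the volume is quantised to a canonical
max-normalised 16-bit scale. Device exports are integer-valued anyway,
and this makes the ratio map *bit-identical* under any positive global
gain — the map measures tissue, not scanner brightness.

### Layer segmentation

Initial detection runs per B-scan: a minimal-cost left-to-right path
through the negated smoothed intensity (per-step axial jump bounded at
±2 px) tracks the brightest band; its inner/outer edges come from the
extrema of the axial gradient within ±12 px of the path, refined to
sub-pixel by parabolic interpolation; the ILM is the topmost crossing of
a robust fractional threshold (25 % of the way from the vitreous level
to the column's 95th-percentile brightness), which stays anchored on the
inner-retinal rise even where atrophy disrupts the posterior bands.
Surfaces are regularised laterally with a small median filter and the
ordering `ILM ≤ OS/RPE ≤ BM` is enforced by clipping. The band search is
restricted to depths leaving at least 120 µm of tissue below, so the
background slab needed later is always measurable; A-scans with no
detectable signal are flagged invalid rather than guessed.

Refinement classifies each A-scan by band contrast — mean intensity in
`[OS/RPE, BM]` over the mean of `[BM + 20 µm, BM + 120 µm]` — and where
contrast falls below 1.5 (configurable; 0 disables refinement entirely)
BM is re-estimated by a least-squares quadratic per B-scan over the
flanking strong-contrast A-scans, with a global 2-D quadratic fallback
for B-scans that lack flanking support. OS/RPE collapses onto BM there:
inside atrophy the outer segments and RPE are gone, so the OS/RPE
boundary has no independent existence. The phantom records its
ground-truth OS/RPE with the same convention (and additionally exposes
the healthy band top for tests that need the uncollapsed geometry).

A consequence worth stating: with the collapsed convention the
numerator slab inside GA sits in hypertransmissive tissue, so the
hypertransmission gain cancels between numerator and denominator and
the in-lesion ratio saturates near 1 (against ≈ 2.8 outside at the
default profile) instead of scaling as `residual/gain`. Contrast remains
ample for detection; the gain-monotonicity of the map itself is tested
with the numerator anchored at the residual band top.

### Thresholding and refinement

Otsu's threshold on the valid-pixel histogram of the enhanced ratio map
is the default, with a `fixed:<v>` escape hatch (candidate = ratio
strictly below the threshold, which makes fixed-threshold masks nested
in the threshold). One isodata step — moving the threshold to the
midpoint of the two class means — follows Otsu: on nearly noise-free
maps the histogram collapses to spikes, Otsu's 256-bin grid lumps both
atrophic modes into one bin, and the raw bin-centre threshold can land
on the lower mode instead of inside the gap. The refinement is a no-op
on well-mixed histograms and centres the cut on spiky ones.

Morphological refinement is closing then opening with a 2-px disk and
hole filling; components with equivalent diameter below 175 µm are
discarded — the definitional minimum size of a GA lesion, the one size
constant the problem supplies. Components are 8-connected everywhere
(extraction and measurement use the same structuring element).
Confirmation retains a component only if its mean sub-RPE intensity is
at least `k = 1.3` times the non-GA background mean; boundary
adjustment beyond accept/reject is deliberately not performed, so
postprocessing can only shrink the mask.

### Measurement

Area is pixel count × pixel area. Perimeter is the length of the
marching-squares 0.5-level contour of the *lightly smoothed* (Gaussian,
σ = 1 px) component indicator: contouring the raw mask follows the
half-pixel staircase and overestimates a disk's circumference by ≈ 5 %,
while the smoothed level set tracks it to ≈ 0.4 %; boundary-pixel
counting would be worse still (up to 4/π) and would poison the
circularity. Tiny components that smoothing erases fall back to the raw
contour. Circularity is `4πA/P²` clipped to 1; the lesion set is
"regular" when the area-weighted mean circularity is ≥ 0.60 (reported in
the output so users can audit the rule), and "single" exactly when one
component exists. An empty mask has no defined morphology: both labels
are explicit nulls.

## Agreement statistics

Lin's CCC uses population (1/n) moment estimators; the O(1/n) difference
from n−1 moments is documented rather than configurable. Its 95 % CI is
the Fisher-z interval with Lin's variance for the transformed estimate.
Two-way ICCs come from the subjects × raters ANOVA decomposition:
the *random-effects* model maps to the absolute-agreement form
(interchangeable raters; Shrout–Fleiss 2,1 / 2,k) and the
*mixed-effects* model to the consistency form (fixed raters; 3,1 / 3,k),
with CIs from the standard F-distribution bounds; average-of-k forms are
the report default because validation designs correlate averages of
three measures, and single-measure forms remain exposed. Degenerate
inputs are handled explicitly: identical columns give ICC 1, zero
between-subject variance gives ICC 0 with a warning, and a CCC of two
equal constants is an error rather than 1.

Agreement categories follow the conventional limits with boundary values
assigned upward: poor < 0.90 ≤ moderate < 0.95 ≤ substantial < 0.99 ≤
almost perfect.

Mann–Whitney U uses the exact null distribution when both samples are
small (min(n) ≤ 10) and tie-free, otherwise the tie-corrected normal
approximation with continuity correction.

The validation report runs the grid overall and per stratum (regular /
irregular, single / multiple): CCC between mean-manual and
mean-software, interobserver ICC (random) across manual raters,
intrasoftware ICC (mixed) across replicates, and a descriptive summary
with the Mann–Whitney comparison. Strata with fewer than 3 eyes are
reported as not estimable.

## The phantom

The phantom renders a 7 × 7 mm cube (default 256 × 256 A-scans,
320 axial samples at 2.6 µm — a plausible grid, since device voxel
geometry is not standardised) from a layer stack
(vitreous 150 µm/0.02, inner retina 200/0.35, outer retina 120/0.20,
RPE 30/0.90, choroid 200/0.25, sclera 110/0.40, reflectivities on
[0, 1]) bowed by a parabolic posterior curvature (20 µm at the corners —
exactly quadratic, so the per-B-scan quadratic BM interpolation is
unbiased by design, a deliberate simplification). Inside GA the RPE band
keeps 10 % of its reflectivity and everything below BM is multiplied by
a hypertransmission gain of 2. Speckle is multiplicative gamma noise
with mean 1 and shape 4 (a standard multi-look surrogate; shape → ∞ or
`None` disables it). Lesions are radially perturbed circles
`r(θ) = R(1 + Σ aₖ cos k(θ − φ))`; continuous truth (shoelace area,
polyline perimeter at 4096 boundary samples) is computed from the
polygon, not the raster, and overlapping lesion specs are rejected so
per-lesion truth stays unambiguous. Harmonic amplitude doubles as an
objective shape rule for fixtures: total amplitude ≤ 0.1 plays
"regular", ≥ 0.3 "irregular".

The study simulator draws a latent true area per eye from a truncated
normal and adds rater bias plus independent Gaussian error per manual
rater and per software replicate. Defaults emulate a 46-eye,
three-rater, three-replicate design with areas 5.6 ± 4.7 mm² (truncated
at 0.4), observer SD 1.2 mm² and software SD 0.65 mm² — error magnitudes
chosen so interobserver and intrasoftware reliability sit near 0.94 and
0.98, the regime such validation studies report. Measurements are
floored at 0.01 mm² to keep every cell positive.

**What the phantom does not model:** optics (no PSF, depth roll-off,
vessel or drusen shadowing beyond the single hypertransmission term), no
drusen or neovascular phenotypes, no eye motion, and speckle without
spatial correlation. Passing tests therefore demonstrate correctness of
the algorithmic chain under the stated signal model, not clinical
performance; real scans add confounders (media opacity, irregular
atrophy borders, foveal sparing) that the phantom deliberately omits.

## Problem sizes and numerics

The validation suite and `scripts/acceptance.py` use cohorts of 20 and
10 seeded single-lesion phantoms respectively per noise condition at the
full default geometry, 500-eye simulated studies for variance-ratio
recovery, and 1000 replicates for Mann–Whitney type-I calibration —
sizes at which the Monte-Carlo error is comfortably below the asserted
tolerances. Unit tests run on a reduced 96 × 224 × 96 grid (4 µm axial)
for speed. Rank-filter order statistics use index `round(rank·(n−1))`
over the valid samples of each window (invalid neighbours are excluded,
never zero-filled, which would bias ratios at borders). All en-face
pixel coordinates place pixel centres at `(i + 0.5) · Δ`; axial surface
positions are fractional pixels with voxel k centred at `(k + 0.5) · Δz`.

## Known limitations

- The segmentation is a functional stand-in for whatever a commercial
  module does; it is robust for layered phantoms but untested on
  pathology beyond GA.
- Boundary-adjustment of confirmed regions (geodesic growth to the
  hypertransmission edge) is not implemented; confirmation is
  accept/reject only.
- The CCC confidence interval is asymptotic; for very small n a
  bootstrap would be preferable.
- Perimeter values depend mildly on the smoothing scale of the contour
  extraction (σ = 1 px); comparisons across software should fix this
  convention.
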