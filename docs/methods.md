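# Methods

## Scope and design

`ermorph` implements the image-analysis and scoring computations of a
high-content yeast ER-expansion screen: mid-section morphometry, cortical
tubule/sheet classification, and plate-normalized Z-scoring, together with
a synthetic-microscopy generator that provides ground truth for validation.
The image stages are organised as function pipelines over numpy arrays;
the screen-scoring stage, being a statistical fit to tabular data, is a
model/results pair (`ERExpansionScreen(...).fit() → ScreenResults`).

## Synthetic microscopy generator

The generator emulates the geometry of diploid budding yeast imaged at
60× on an sCMOS camera (default pixel size 0.108 µm/px, overridable).
Cells are non-overlapping ellipses with axis ratio ≤ 1.5 and semi-major
radii 16–24 px (≈ 3.5–5 µm diameter), placed by bounded rejection sampling.
Fields are z-stacks of `n_slices` (default 5) optical slices spaced 1 µm;
slice *i* receives Gaussian blur of `psf_sigma + 1.2·|i − focus|·spacing`
pixels, so the designated focus slice has strictly maximal intensity SD —
the property the focus-selection step relies on.  Read noise is Gaussian
with SD 5% of the signal amplitude by default; Poisson shot noise is
optional.  Intensities are arbitrary units rescaled to [0, 1]; all
downstream thresholds are Otsu-relative, so absolute amplitudes carry no
information.  All randomness flows from one seed per field through
deterministically spawned per-cell substreams; identical specs reproduce
byte-identical pixels.

**Mid sections.**  The cytosolic BFP fills cell interiors; both ER markers
form a band along the cell border covering a target fraction `c` of the
periphery, interrupted by `g` equally spaced gaps at a random phase.  The
rendered band is 6 px deep — slightly deeper than the 5-px measuring band —
so the peripheral-ER-size metric reads the *angular* coverage `c` rather
than a radial thickness ratio.  A coverage below 1 with zero gaps is
rejected as geometrically impossible (the complement of a partial band has
at least one component); gaps narrower than ~2 px of arc are likewise
rejected as unrasterizable.

**Cortical sections.**  Per cell, sheet patches (smoothed elliptical blobs,
radii ~4–8 px) are placed first; a tubule network is then grown as dilated
self-avoiding random-walk strands (width 2 px) threading the remaining
cortex until the realized non-sheet tubule area matches its target within
~5% of the cell area.  The general marker labels tubules ∪ sheets; the
curvature marker labels tubules, a 2-px sheet rim (sheet minus its 2-px
erosion) and — when requested — "tubular cluster" patches, which are
sheet-sized regions filled in *both* channels and counted with the tubule
class in the truth masks.  Tubule and sheet truth masks are disjoint by
construction and lie inside the cell labels.

**Screen tables.**  One row per (plate, well, field):

    value = global mean + plate offset + smooth covariate trends
          + planted effect + well-level noise + field-level noise

Per-metric base means/SDs are realistic magnitudes (peripheral ER size
0.45 ± 0.04, profile size 0.08 ± 0.012, gaps 0.35 ± 0.08 /µm, intensity
1000 ± 60 a.u.); `residual_sd` scales all of them and denotes the *total*
per-field residual SD, split into a well-level component shared by the two
fields of a well and a field-level component (fraction 0.2 of the SD) —
the two fields image the same culture, so most residual variation is
shared.  Metric residuals are correlated across metrics (0.4 between the
two size metrics, −0.3/−0.2 with the gap count), as the same cell
population links them.  Covariate trends are smooth sinusoid-plus-slope
functions of standardized cell area, cell count and well order with
amplitudes of 0.15–0.2 residual SDs; plate offsets default to 0.5 residual
SDs.  Planted effects are expressed in residual-SD units and shift both
fields of the mutant's well.

## Mid-section pipeline

Best focus is the slice of maximal intensity SD (ties → lowest index),
re-assessed per cell on the curvature-marker crop.  Cell borders are
enhanced by an annular Fourier bandpass retaining 2–40 px wavelengths
(soft Gaussian-tapered edges to limit ringing) followed by Frangi
vesselness at scales {1, 1.5, 2} px and Otsu binarization; the 1–2 px
vesselness ridge is dilated by 1 px before a radius-1 opening and a
minimum-size filter (25% of the minimum cell area) so speckle and
vacuole-sized rings are removed without erasing the border.  Interiors
enclosed by the border mask become cell objects; objects touching the
image edge, or outside plausible area bounds, are discarded; objects
dimmer than median − 2·MAD of the object brightness distribution are
discarded; touching objects are split by watershed seeded from local
maxima of the interior distance transform.

Per cell, the ER is segmented in both marker channels by Sato tubeness
(scale 1 px) gated by minimal intensity support (half the Otsu level),
OR-ed with a direct Otsu intensity threshold — the tubeness ridge clips
the radial extent of a profile and would bridge short interruptions, while
the intensity threshold recovers the full profile width; speckle below
8 px is dropped.  The cell border is the minimum-volume enclosing ellipse
(Khachiyan's algorithm, see below) of the combined ER mask together with
the cell object expanded to the apparent border (bounded by neighbouring
cells and shrunk 1 px so that detected ER sets the outer contour where
present); without this anchor the minimal ellipse collapses across large
ER gaps.  The periphery band is the 5-px-wide band inside the ellipse
(ellipse minus the ellipse with both semi-axes reduced by 5).

Metrics: peripheral ER size = band-ER area over band area; ER profile
size = mean 8-connected component area of band-ER over band area; gaps =
8-connected components of band minus ER, counted per µm of periphery
(Crofton perimeter of the band's mid-ellipse × pixel size).  Two counting
guards suppress discretization artefacts: a gap must cover ≥ 5 px and must
penetrate at least 2 px (40% of the band width) below the fitted border —
otherwise slivers where the fitted ellipse locally overshoots the true
border register as spurious gaps.  Cells whose ER mask is empty are
dropped with a logged reason.  Finally, the population filter keeps cells
whose every measurement (area, intensities, roundness, three metrics) lies
within 2.5 SD of the population mean, in a single pass.

## Minimum-volume enclosing ellipse

Khachiyan's barycentric coordinate-ascent algorithm, iterated to a
configurable tolerance (default 10⁻³ for pipeline use, 10⁻⁷ in tests),
with the convex hull taken first so the cost is independent of mask size.
Degenerate inputs (< 3 points, collinear sets) raise.  The test oracle is
an independent SLSQP optimisation of −log det A under containment
constraints from multiple starts; on random 5-point sets the two agree in
area to within 1%, and the rectangle/circle closed forms are recovered.

## Cortical classifier

Channels are rolling-ball background subtracted (radius 50 px; the ball's
intensity semi-axis scales with the image's intensity range so the step is
scale-equivariant) and percentile-stretched to [0, 1] (0.1–99.9%).  Each
channel is segmented twice with ring kernels — a normalized annulus
spanning Euclidean radii [r, r+1], widened by 0.5 px if it would hold
fewer than 8 pixels: a pixel is kept when its 3×3-median-filtered value
exceeds the ring mean by more than the pass's *strength* and exceeds
Otsu × the channel's background multiplier.  The small pass (radius 2,
strength 0.02) finds tubules; the large pass (radius 10, strength 0.01)
finds sheets: a sheet-interior pixel sees its ring partly outside the
sheet, hence a positive contrast, for sheets up to roughly the ring
radius — the default radius 10 covers the largest patches the generator
renders.  The pass union is the channel's total-ER mask.

Classification: regions of the general-marker mask surviving an opening
with a disk of radius = trimming factor (default 3) are provisional
sheets; the remainder are tubules.  Sheet-like regions of the
curvature-marker mask overlapping the general mask are tubular clusters,
subtracted from sheets and added to tubules.  A reconstruction of the
opened mask back to full connected components is deliberately *not*
applied: the cortical ER is usually one connected network, and
reconstruction would label the entire network sheet-like as soon as any
patch survived the opening; the opening itself already returns surviving
features at near-full extent.  The final tubule and sheet masks partition
the general-marker total mask exactly, and clusters are a subset of
tubules — both properties hold by construction on every input.

ER masks are computed on whole images and assigned to cells by an integer
label mask — externally produced (the screen's workflow) or from the
built-in fallback segmenter (bright-field → Gaussian σ2 → 0.5× downscale →
tubeness σ1 → upscale → Otsu → watershed).  Population summaries are
medians over all cells.

## Screen scoring

Local regression is LOWESS (tricube-weighted local linear fit, span 0.3,
2 robustness iterations) applied twice — the second pass refits the
residuals, removing most of the attenuation bias a single local-linear
smooth leaves on curved trends.  The correction order follows the
measurement logic: plate-mean centering of intensity, LOWESS vs cell area,
then vs cell count; per-plate background population = rows within 1.5 SD
of the plate's mean corrected intensity (≥ 3 members required, SD > 0);
per-field Z per metric from that plate's BP moments; LOWESS of Z vs well
order, then vs cell count; aggregation per sample keeps the field Z of
maximal absolute value with its sign, so underexpansion (negative) hits
are not masked; hits are strains with Z < −2 on peripheral ER size and/or
profile size and/or Z > +2 on gaps in at least two of the three metrics
(strict inequalities).  Wells with fewer than 25 cells are dropped before
scoring.  BP moments are computed before the well-order/count corrections,
i.e. the corrections are applied to the Z scores, matching the order in
which the steps are stated above.

Aggregating the signed maximum magnitude over two correlated fields
inflates the null Z SD to √(1 + (2/π)√(1−ρ²)) for within-well correlation
ρ; with the generator's field-noise fraction 0.2 (ρ ≈ 0.96) the null SD is
≈ 1.08 and the one-sided exceedance beyond |2| is ≈ 2.7%, against 2.3%
nominal.  The same aggregation acting on a −3 SD planted effect yields a
per-metric detection probability of Φ(≈1) ≈ 0.84, so the two-metric hit
rule recovers roughly 55–70% of such mutants at these thresholds — weaker
effects than about −3.6 SD cannot be detected with high sensitivity at a
−2 cutoff when the null SD is ≈ 1, which is an intrinsic property of the
thresholding scheme, not of the implementation.

## Problem sizes and numerical choices

Validation studies use 360×360 px fields with 8 cells (mid and cortical
recovery), 128×128 px 2-cell fields for bulk invariant checks, and screens
of 16 plates × 300 wells × 2 fields; these sizes give stable statistics
(≈ 100 cells per recovery study, ≈ 4,800 samples per screen) at desk-scale
runtimes.  Ties in focus selection resolve to the lowest slice index;
connectivity for profiles and gaps is 8-connected; constant images yield
empty masks with a warning rather than exceptions; Otsu on a constant
image is treated as undefined (empty mask).  LOWESS uses a delta of 1% of
the covariate range for speed; with fewer than 10 points it degrades to
identity with a warning.

## What the synthetic data does and does not show

The generator reproduces the *geometry* the pipeline measures (band
coverage and gaps, tubule/sheet area fractions, curvature-marker rim
behaviour, plate/covariate/noise structure of screen tables) but not the
optics or biology of real images: no 3D PSF, no chromatic aberration, no
nuclear envelope, no uneven illumination, no autofluorescence, and marker
intensity distributions are free parameters.  Passing the recovery tests
therefore shows the computations are correct and self-consistent on known
ground truth — it does not certify accuracy on real micrographs, where
parameter tuning (the classifier's per-image strengths and backgrounds,
as in the original semi-automated workflow) remains the user's
responsibility.  Classifier defaults here were calibrated once against
the generator; real images with different tubule widths or sheet scales
will need different radii and strengths.

## Known limitations

* The mid-section border fit assumes roughly elliptical cells; strongly
  non-elliptical or overlapping cells violate the model.
* Gap counting suppresses components < 5 px or shallower than 2 px, so
  gaps narrower than ~2 px of arc are not resolved.
* The large-feature ring test cannot see the interior of uniform sheets
  much larger than the sheet radius; such interiors rely on the
  intensity/background gate and may be under-segmented.
* The screen model treats wells as independent; spatial plate effects
  beyond well order (row/column gradients) are not modelled or corrected.
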