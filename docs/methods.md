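# Methods

`protonrad` re-implements the computational core of an image-guided
small-animal proton irradiation workflow: proton radiographs are formed on a
flat-panel detector, corrected and quality-scored; a 2D treatment plan is
projected from a planning volume; plan and beam are registered through
manually placed landmarks and a collimator radiograph; and the biological
outcome is read out as a tile-wise DNA-damage map correlated with dose.  This
note records the models, the parameters that matter, and the choices made
where the design was genuinely open.

## Radiograph formation and correction

Raw frames are modelled as `gain * beam_profile * transmission + dark`.  Two
background fields are estimated from dedicated calibration stacks: the
detector dark signal `I_dark` (pixelwise mean of dark frames) and the
beam-fluence background `I_beam` (pixelwise mean of beam-only frames *after*
removing `I_dark`, so the two corrections are independent; the order is a
package convention).  Every object frame is corrected as
`raw - I_dark - I_beam` and frames are combined by a per-pixel median (even
counts: mean of the two central order statistics).  The median tolerates up to
`floor((n-1)/2)` impulse-corrupted values per pixel with bit-identical
output, which is the reason it is preferred over the mean for detectors that
see direct proton hits.

Quality metrics use the population (divide-by-N) standard deviation:
`SNR = S/sigma` on one ROI, and `CNR = (S_a - S_b)/sigma_b`, with the noise
taken from the low-contrast (background) ROI — the formula's sigma is not
assigned to a region in the usual presentation, so the assignment is fixed
and documented here.  A zero-noise ROI yields a signed-infinity sentinel, not
an exception.

Spatial resolution is characterised two ways:

* **Edge response.** Scattering redistributes fluence at a material edge
  (valley inside the dense material, excess just outside).  Profile lines
  perpendicular to the edge are averaged; the far-field plateau is the median
  of the outer 20% of samples on each side, and the enhancement peak's full
  width at half its excess over the plateau is measured with linear
  subpixel interpolation.  A peak must clear the plateau by 3x the far-field
  noise, otherwise a "no edge enhancement" error is raised (a perfectly
  sharp step has no peak).  On synthetic Gaussian enhancements of
  sigma 2-10 px the estimator recovers `2.3548 sigma` within 2%.
* **Line pairs.** Per bar group, the image is averaged along the bars and the
  Michelson contrast `(max-min)/(max+min)` of the profile is computed; a
  group is resolved when its contrast exceeds 0.1 *and* 3x the contrast of a
  flat background region.  The resolvability threshold is a convention (the
  source workflow reports outcomes only).

Acquisition time is `n_frames / frame_rate` (8.4 Hz default) and imaging dose
is strictly linear in time with a geometry-specific calibration constant
(mGy/s) from the configuration registry — the two reference geometries
(grid phantom: 1.98 mGy/s; mouse position: 2.875 mGy/s) are not mutually
derivable, so the dose rate is never hard-coded.  Feature detectability uses
the Rose criterion, |CNR| > 4.

## Synthetic data generation

All inputs are generated with known ground truth; every generator is a pure
function of (parameters, seed) and emits a serializable record sufficient to
score the downstream estimates.

* **Phantoms.**  A hole-grid plate (hole groups of 1.0 down to 0.3 mm
  diameter; layout is a generator convention recorded in the spec metadata)
  and a line-pair grid spanning 0.6-6.0 lp/mm with bar width `1/(2f)`.
  Primitives are rasterised at 4x supersampling and block-averaged to the
  0.05 mm detector grid.
* **Image formation.**  Base transmission is `exp(-mu * RSP * thickness)`
  (mu = 0.01/mm, a contrast constant, not a physical cross-section).  Edge
  scattering is modelled phenomenologically as a difference-of-Gaussians
  overlay `A (G_sigma - G_2sigma)` applied to the transmission; on a sharp
  step the resulting bump has measured FWHM `2.337 sigma`.  The preset widths
  sigma(200 MeV) = 0.1284 mm and sigma(150 MeV) = 0.1626 mm therefore give
  edge FWHMs of 0.300 and 0.380 mm — the 0.08 mm widening at lower energy
  that motivates imaging at 200 MeV.  The map is normalised to mean fluence 1
  (redistribution conserves fluence).  No particle transport is simulated.
* **Mouse pair.**  A procedural skull-like plan image (elliptical shell,
  sutures, five fiducial blobs, an embedded hippocampus-shaped label) is
  warped through a known similarity transform and rendered through the
  acquisition model; true landmark coordinates in both frames satisfy the
  transform exactly.
* **Label volume.**  Nested ellipsoids (brain = 1, hippocampal region = 2,
  strictly inside) with a correlated intensity volume; sagittal planes along
  axis 0, at least 25 of them.
* **Depth dose.**  A parametric stand-in: power-law range-energy relation
  `R = 0.0022 E^1.77` cm (R(90 MeV) ~ 63.3 mm water), entrance plateau plus a
  Gaussian Bragg peak at the residual range `R(E) - WET`, lateral top-hat
  with Gaussian penumbra, normalised to the prescribed peak dose.  It is
  labelled non-physical beyond benchmarking.  WET itself is computed from
  first-order Bethe stopping powers (no shell/density corrections) with
  standard compositions; the 46.51 mm polycarbonate shifter evaluates to
  53.16 mm water-equivalent at 90 MeV, and the water values agree with
  tabulated stopping powers to ~0.1% in the 90-200 MeV window.
* **Nuclei.**  DAPI nuclei are Gaussian blobs placed by minimum-distance
  rejection sampling (cell-list accelerated, bounded retries); each nucleus
  is damaged with probability `p(D) = p_bg + (p_max - p_bg) D/(D + D50)` — a
  saturating stand-in, chosen because the real study demonstrates spatial
  correlation, not a functional form.  Damaged nuclei receive a gamma-H2AX
  blob.  Background noise (sigma 20 counts) sits far below the detection
  prominences (600/1400).  Truth counts are binned by the nucleus's nearest
  pixel, matching the detector's rounded representative.

## Planning agreement

Plans are maximum-intensity projections over 15-25 sagittal planes (warned
outside that window) and priority label projections (hippocampus wins).
Observer agreement uses the Jaccard coefficient against a pixelwise
majority-voted reference; an even number of voters is rejected (ties).
Conventions fixed here: an empty union scores J = 1 (two empty contours agree
perfectly); the intra-observer reference is the majority of that observer's
three repeats, mirroring the inter-observer formula; summaries are mean +/-
population SD, matching small-n reporting.

## Registration and stage coordinates

The beam isocenter is the intensity-weighted subpixel centroid (weights =
intensity above threshold) of the largest connected component above the Otsu
threshold of the collimator radiograph, with quality flags for border contact
and circularity < 0.8; the estimate is invariant to global intensity scaling.
Collimator magnification is taken as 1 (close-coupled geometry).

The plan-to-radiograph mapping is `x' = s R(theta) x + t` on (row, col)
coordinates, fitted in closed form: with `z = row + i col`, the optimal
`s e^{i theta}` is `sum(conj(p) q) / sum(|p|^2)` over centroid-centred
pairs — the least-squares similarity estimate with reflections excluded by
construction.  It is exact on consistent pairs for any n >= 2; with five
landmarks and 1 px coordinate noise the median mapped-target error is well
below 0.1 mm at the 0.05 mm pitch, and the error scales like
`sigma / sqrt(n)`.

Stage shifts are `(target - isocenter) * pitch` with the image-to-stage axis
mapping (swap/sign) taken from a named convention registry, because the
physical axis assignment is hardware-specific.  Target spread across
observers is reported as the mean (and SD of) Euclidean distance to the
centroid — the variability statistic is a documented choice, not asserted to
be the source study's exact formula.

The daily QA check segments the dark irradiated spot on the film (Otsu,
largest dark component, with a contrast guard so a blank film is never
mistaken for a spot), fills it, and takes the enclosed bright region as the
steel-ball shadow; the check passes when both centers lie within tolerance
(0.5 mm default) of the expected beam position.

## DNA-damage mapping

Cell counting is prominence-based maxima detection with explicit semantics:
8-connectivity, strict comparisons, connected equal-value plateaus count once
(centroid representative, rounded), deterministic output ordering.  A summit
is accepted when every path to strictly higher ground first descends by at
least the prominence threshold; the global maximum, having no higher ground,
is always reported, with its height above the image minimum as prominence.
The production implementation is a single descending sweep with union-find
bookkeeping (the persistence construction), numba-compiled; an exhaustive
flood-fill oracle with the same semantics is kept in the package and the two
agree exactly on hundreds of random images.  For *counting*, maxima are
additionally required to clear the prominence threshold, so the noise ceiling
of a featureless channel contributes zero cells.

Counts are detected once per whole channel and binned into 256 px tiles
(so tile sums equal whole-image counts); per tile the damage count is clipped
to the nucleus count (the ratio is a fraction of cells, a documented
resolution of an ambiguity in how "relative damage" is normalised), and tiles
with fewer than 5 nuclei are flagged invalid rather than reporting unstable
ratios.  Edge tiles are processed and flagged partial, preserving beam-edge
information.  The ratio field is resampled onto a dose grid by nearest-tile
lookup through a user-supplied affine (deformable histology registration is
out of scope), and dose/damage profiles are averaged per beam-axis bin, with
invalid tiles excluded, before computing a Pearson correlation.

## The dose-damage benchmark

`studies.dose_damage_study` runs the whole chain at a desk scale: a
1536 x 384 px "section" at 10 um pixels (6000 nuclei, minimum spacing 7 px,
~72% of the random-packing limit), 32 px tiles, a 90 MeV beam range-shifted
by 58 mm WET so the Bragg peak sits two-thirds along the 15.4 mm field, 8 Gy
peak dose, D50 = 5 Gy, and 48 beam-axis bins.  These sizes were fixed by a
power analysis on a binomial surrogate before running the pipeline: they give
an expected correlation near 0.95 (2nd percentile ~0.93), and for the
dose-independent null (constant p = 0.3) the exact null distribution of r at
48 bins leaves less than 1% of seeds beyond |r| = 0.4.  Full-slide scans at
0.325 um with 256 px tiles are the production configuration; the benchmark
scales the geometry, not the algorithms.

## What the synthetic data does and does not show

The generators emulate the *structure* of the real inputs (backgrounds,
counting noise, impulse noise, known transforms, saturating dose response)
but not detector gain nonlinearity, anatomical variability, staining
heterogeneity, or deformable motion.  Passing tests therefore demonstrate
that the algorithms are correct and well-calibrated under their stated
models — not that the biological dose-response of real tissue follows the
stand-in hyperbola, nor that observer variability of real planners matches
the synthetic observers.  Empirical study results (observer Jaccard levels,
measured resolution-dose curves) are properties of particular animals and
hardware and are out of the package's test scope.

## Numerical conventions

Pixel coordinates are 0-based (row, col) with rows increasing downward;
physical units are mm via the pixel pitch.  FWHM crossings use linear
interpolation.  Even-count medians average the central pair.  Maxima ties
are broken row-major.  All stochastic operations require an explicit seed
and are bit-reproducible; the acceptance entry point threads a single seed
through every stochastic step.
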