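# Methods

## The measurement problem

Flow-imaging instruments photograph particles passing through a flowcell
and report per-particle measurements from the binarized silhouette. For
copepods two of those measurements are problematic: the reported "length"
and "width" derive from projected extents (feret diameters) of the whole
silhouette, so extended first antennae — which contribute almost no volume
— can stretch the length reading far past the prosome. The package's
canonical illustration: an animal with a 400.1 × 102.9 µm prosome whose
silhouette reads 690.6 × 477.8 µm, inflating the length×width² biovolume
37-fold. The area-based diameter is far more robust: appendage pixels of
relative area ε change `d_ABD` by exactly `√(1+ε)` and `V_ABD` by
`(1+ε)^1.5`, so a 10% area contribution inflates the biovolume proxy by
only ~15%. `V_ABD` is therefore used as the biovolume proxy, and the
remaining taxon-dependent bias is removed empirically by per-morphotype
calibration against manual measurements.

## Morphometrics

* **Segmentation.** Fixed absolute gray threshold (default 128, dark
  particle on light background) or Otsu's method; the instrument's internal
  segmentation is proprietary, so both are exposed as configuration.
  Components are 8-connected — thin diagonal antennae must stay attached to
  the body. Components whose equivalent-circle (ABD) diameter falls outside
  the instrument's particle-size window (default 30–300 µm, configurable,
  either bound can be disabled) are dropped; border-touching components are
  flagged and excluded from distributions by default, because partial
  bodies bias sizes low.
* **Feret diameters.** The silhouette's convex hull is built from the
  corner points of its boundary pixels (each pixel occupies a unit square),
  then projected onto `n_angles` equally spaced directions over [0, π);
  default 180 directions, giving ≤0.02% extent error for convex shapes.
  The corner convention makes a w-pixel bar measure w pixels and an
  axis-aligned L×W rectangle measure `feret_max = √(L²+W²)`,
  `feret_min = W`; its one quirk is that a single-pixel mask measures
  `feret_min = 1 px` but `feret_max = √2 px` (the pixel's diagonal).
  Tests compare the angle-sweep method against an exhaustive
  extreme-point/hull-edge oracle.
* **Lengths and widths** are reported from feret max/min, as instruments
  do, and are documented as antenna-contaminated; automatic prosome
  landmark detection is out of scope (the instrument cannot do it either).
  Units are µm throughout, via the mandatory pixel calibration.

## Calibration

OLS of `ln(V_microscopy)` on `ln(V_ABD)` per morphotype, with r², the
classical slope t-test (df = n−2) and t-based confidence intervals. Two
fixed conventions:

* **Regression direction** is microscopy-on-instrument, because the map is
  used to predict microscopy-equivalent biovolume from instrument readings.
  Errors-in-variables fits are deliberately not offered.
* **Log base is natural log.** The shipped reference intercepts are only
  numerically self-consistent — predicted magnitudes matching observed
  1e5–1e7 µm³ copepod biovolumes — under ln; under log10 the conversion is
  off by orders of magnitude. Slopes are base-invariant (both axes rescale
  identically), which the tests assert numerically.

Morphotype labels are a closed enumeration of the seven classes (calanoid /
oithonid / corycaeid / oncaeid copepodites; calanoid / cyclopoid /
harpacticoid nauplii); unknown labels are rejected rather than silently
pooled. The shipped coefficients are region- and protocol-specific;
re-ground-truthing on local paired data is recommended, and the workbook
loader (`read_s1_table`) plus `fit_calibration` support exactly that
workflow.

## Synthetic data

The generator's silhouette model is two ellipses (prosome, optional
urosome) plus thin rectangular antennae attached at the anterior pole —
the simplest family that (i) has closed-form area and feret oracles and
(ii) reproduces the antenna bias quantitatively. Contrast is
transmitted-light style (dark particle ~40, background ~220, 8-bit) with
additive Gaussian noise; the real instrument's background and thresholding
are not documented, so this contrast model is the package's own choice.
Population size priors default to lognormal (sdlog 0.2 around a
morphotype-typical prosome length), since plankton biovolume histograms
are right-skewed; a uniform prior is available. All randomness flows
through explicit per-call seeds; identical spec+seed gives byte-identical
images.

Rasterization is pixel-center-in-shape; the mask area converges to the
analytic ellipse area as pixel size shrinks, with relative error of order
(pixel size)/(body width) on average but not monotone at every orientation
(lattice effects); the convergence test uses the axis-aligned fixture,
where the decrease is clean. Particles spanning fewer than 4 pixels raise
an "under-resolved" error.

Calibration-pair simulation draws `ln V_instrument` uniformly on a log
range (default 1e4–1e7 µm³) and adds Gaussian log-scale residuals. A
variant re-centres and de-correlates the realized residuals from the
regressor so that OLS recovers the generating coefficients exactly while
keeping realistic scatter; the synthetic ground-truthing workbook
(`write_synthetic_s1_table`, n=100 pairs per morphotype, σ=0.3) is built
this way, with the shipped reference coefficients as generating truth. It
exercises the loader, the log transform, the regression direction and the
log-base convention end to end — but it is a synthetic stand-in, and
passing against it says nothing about how well the reference coefficients
describe any real assemblage.

What the synthetic fixtures do *not* emulate: real gray-level texture,
motion blur, out-of-focus halos, body curvature, overlapping animals, and
3-D orientation effects (a tilted copepod projects a smaller area). Tests
passing on synthetic silhouettes validate the measurement algebra and the
pipeline plumbing, not instrument-specific segmentation quality.

## Recycling simulation

The recycling procedure (returning specimens intact and re-imaging the
same sample repeatedly) is modelled as per-individual Bernoulli capture
per pass, independent across passes, with multiplicative lognormal
measurement noise parameterized by its CV and symmetric on the log scale
(median multiplier 1, so the pooled log-mean is unbiased for the true
log-mean). No flow physics is modelled — this is the minimal quantitative
model of the procedure. Duplicate observations of one individual are
retained by default (that is what the instrument records); a de-duplicated
mode exists for sensitivity analysis. Convergence is measured as the mean
two-sample KS distance between the pooled sample and the truth, which is
non-increasing in the number of passes.

## Growth rates

`g = ln(W_T/W_0)/T` per day, with `W` the mean individual carbon biomass
of the cohort. The biovolume-to-carbon power law `W = c·V^k` is a
**required** argument with no shipped default: its constants are taxon-
and study-specific, and inventing values would be false precision. Two
exact algebraic properties are load-bearing and tested: multiplicative
bias in `W` cancels in `g`, and for power-law carbon a multiplicative
volume bias applied at both time points cancels too (the `bias^k` factors
divide out). Consequently uncalibrated `V_ABD` is sufficient for growth
estimation even when its absolute scale is biased. Incubation conditions
(temperature, food) and stage-resolved growth are out of scope.

## Problem sizes and numerical choices

Default problem sizes used by the test suite and the acceptance script:
100 calibration pairs per morphotype; 200 replicate datasets for CI
coverage; 50 seeds × {1, 5, 20} passes for recycling convergence; 500
individuals per time point for growth recovery; disk fixtures of 50–300 µm
at 1 µm/px. These sizes give Monte-Carlo error comfortably below the
assertion tolerances while keeping the whole suite in seconds. Histogram
bins default to 20 log-spaced bins spanning the observed range; explicit
user bins report out-of-range particles as underflow/overflow rather than
dropping them silently. CSV output is one documented dialect (comma, UTF-8,
"." decimal, `#` comments carrying the config hash).

## Known limitations

* Feret-based length/width only approximate any particular instrument's
  proprietary length algorithm.
* The shipped calibration coefficients carry no uncertainty information
  (diagnostics marked unavailable) and transfer poorly across regions.
* The growth estimator compares cohort means; distributional change beyond
  the mean (stage structure, mortality-biased size shifts) is not tested.
* 2-D projection bias (animals imaged off-axis) is inherent to the data
  model and is not corrected, only absorbed into the calibration.
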