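# Methods

## The measurement model

The optic nerve head is treated as a two-region scene: the central
retinal vessels (whole blood, by definition 100% Hb) and the surrounding
disc tissue, whose color is an Hb-weighted mixture between pale,
bloodless tissue and blood.  The per-pixel Hb percentage is the
vessel-referenced red–green contrast

    h = (r − g̃) / max(r, ε),     Hb% = 100 · h_pixel / h_vessel,

with `h_vessel` formed from the per-channel *medians* over vessel pixels
(medians rather than means so specular highlights and partial-volume
edge pixels do not move the reference).  The key property is invariance:
any per-channel multiplicative factor common to vessels and tissue —
illumination intensity, camera gain, spectral tint of the light — cancels
from the ratio, because the numerator and denominator of `h` share the
pixel and the reference shares the eye.  The estimate is clamped to
[0, 120]: tissue redder than the vessel median is possible under noise,
and such values are retained (above 100, flaggable) rather than
destroyed.  Blue never enters the index; it is reserved for lens
assessment (below).  `ε = 10⁻³` guards the division.

Assumptions this rests on: (i) the disc's color is dominated by a single
pigment, Hb; (ii) reflectance varies approximately linearly with the Hb
amount over the physiological range; (iii) the vessels crossing the disc
are resolvable and carry whole blood.  Assumption (ii) is exactly what
the dilution-series experiment checks (below).

## Lens compensation

A yellowed crystalline lens absorbs short wavelengths: blue is attenuated
by a factor κ ∈ (0, 1] and green by approximately (κ+1)/2, red hardly at
all.  Both vessels and tissue sit behind the same lens, so the vessels'
observed blue/green ratio, divided by the clear-lens calibration ratio
(configurable; default 0.55, the blue/green ratio of the blood endmember),
equals κ / ((κ+1)/2).  Inverting gives

    κ̂ = ρ / (2 − ρ),   ρ = (b_vessel / g_vessel) / ratio_clear,

clamped to [0.05, 1] and flagged when clamping was needed (a degenerate
blue channel, say).  Compensation multiplies green by 2/(κ̂+1)
everywhere before the Hb index is formed.  The correction is
multiplicative because the attenuation is multiplicative; an additive
green offset cannot undo it and was rejected during design.  For a clear
lens κ̂ = 1 and the compensation is the identity.

## Segmentation

*Disc.*  Two passes.  A coarse pass thresholds the red channel at its
95th percentile (whole image, or a 256-px window when a manual seed is
given) and keeps the largest connected component — this only localizes
the disc, because a global quantile interacts badly with illumination
gradients.  The refinement pass re-thresholds red inside a region of
interest around the coarse component with the isodata (Ridler–Calvard)
criterion — the midpoint between the two class means, which is stable
under skewed disc/background proportions where Otsu's criterion can
place the cut at the background's bright edge.  A morphological closing
(11×11) bridges the slits cut by vessels crossing the disc *before* the
largest-component step (the vessel tree otherwise fragments the disc),
holes are filled, and an ellipse is fitted to the component boundary by
least squares.  "Semi-automatic" means: a manual seed point can steer the
search, and an externally supplied geometry (sidecar JSON) bypasses the
step entirely.  Discs below 500 px² are rejected as implausible.

*Vessels.*  Inside the disc a vessel pixel must be dark in green — below
median − k·MAD (k = 1.5) of the disc's green values, green being the
channel with the classically strongest blood contrast — *and* dark in
red, below 0.75 × the disc's median red.  The red conjunct is essential:
highly perfused tissue approaches whole-blood chromaticity in green, but
its red stays bright, while vessels are dark in both channels.  All
thresholds are proportional to the data, so the rule is equivariant
under global intensity rescaling.  A 3×3 opening removes speckle.  Masks
whose vessel fraction falls outside [0.05, 0.60] of the disc area are
returned flagged low-confidence rather than rejected.

## Sector geometry

Eight 45° wedges × three concentric rings with boundaries at 1/3 and 2/3
of the local radius give 24 sectors; ring radii are measured in
normalized *elliptical* coordinates (scaled copies of the fitted
ellipse), so oblique discs keep the exact 1/9 : 3/9 : 5/9 ring-area
split.  Numbering is wedge-major, ring-minor (inner→outer): sector
= 3·(wedge−1) + ring, so the outer ring — the neuroretinal rim, where
axonal loss should show first — is exactly the indices divisible by 3.
Wedge 1 starts at the temporal horizontal meridian; wedges advance
clockwise in image coordinates for right eyes and counterclockwise for
left eyes, so a given index is anatomically comparable across eyes (the
same mirroring convention used for OCT clock hours).  `mirror_profile`
converts profiles produced with a fixed clockwise map; profiles built
through the eye-aware sector map need no conversion.  Aggregation is
tissue-only (vessel pixels excluded), and the whole-disc mean is the
pixel-count-weighted mean of the sectors by construction.

## Cohort statistics

Pooled-variance Student's t (two-sided) per variable, with the Bonferroni
family level base_alpha/m: the Hb family is mean + 24 sectors (m = 25,
0.05/25 = 0.002), the Cirrus RNFL family mean + 4 quadrants + 12 clock
hours (m = 17 → ≈0.003), the Spectralis family mean + 4 quadrants + 4
sectors (m = 9 → ≈0.006).  Pooled variance is the literal "Student's
t-test"; a Welch variant sits behind a flag for sensitivity analyses,
since real group SDs can differ markedly.  The Kolmogorov–Smirnov gate is
Lilliefors-style (parameters estimated from the sample) and advisory: it
is logged, never used to switch tests silently.  Missing data are
handled complete-case per variable (comparisons) or per pair
(correlations).  Degenerate inputs are explicit: two zero-variance groups
with equal means give t = 0, p = 1; with unequal means the row is flagged
rather than silently infinite.

## The synthetic generator

`render_fundus` implements the forward optical model: disc tissue color
is a linear mix (1−f)·pale + f·blood of an achromatic pale endmember
(0.86, 0.86, 0.86) and a red-dominant blood endmember (0.86, 0.20, 0.11),
weighted by the true Hb fraction f; vessels are whole blood at 0.55×
albedo, drawn as a branching tree (two near-vertical trunks plus four
branches, widths 7/5 px) crossing the disc; a multiplicative left-right
illumination ramp (default ±10%), the lens term (blue ×κ, green
×(κ+1)/2) and additive Gaussian sensor noise (default sd 0.01 ≈ 2.5
digitization steps at 8 bit) complete the image.  The background retina
is a darker orange.  The per-sector Hb field is blockwise constant and
smoothed with a 3-px Gaussian so sector borders are not step edges.

Two deliberate choices: the endmembers share the same red value, so disc
red is independent of Hb — pallor is a loss of redness *relative* to
brightness, and the model keeps the signal entirely in green; and the
generator (endmember mixing) is not the algebraic inverse of the
estimator (vessel-normalized contrast), so recovery tests are
non-circular.  The blood endmember's blue/green ratio equals the
clear-lens calibration constant, which is what makes κ identifiable.

`generate_cohort` draws, per subject: 24 sector Hb values ~
Normal(group mean_s, group sd_s) truncated (clipped) to [0, 100] —
truncation, not resampling, which slightly biases sectors with extreme
SDs; RNFL fields ~ Normal per device parameter; Hoehn-Yahr ~
Normal(2.68, 0.82) truncated to [1, 5] for the PD group; uniform ages in
the group ranges; 59% male; random eye; disc geometry jittered
(radius ~ N(80, 5) px clipped to [65, 95], center ±20 px on a 512×512
canvas).  Group defaults (sizes 91/155 and all means/SDs) reproduce the
summary tables of the reference case-control cohort; `lens_kappa`
defaults to 1 because that cohort required transparent ocular media.
The master seed fans out per-subject seeds through a `SeedSequence`, so
cohorts are bit-reproducible.

What the generator does *not* emulate: photorealistic retinal texture,
cup topography (the pale cup emerges only through the inner-ring Hb
values), peripapillary atrophy, camera-specific color response, optic
media scatter beyond the single κ term.  Passing tests therefore show
that the pipeline recovers what this model encodes — they do not certify
accuracy on real photographs, for which no per-sector Hb ground truth
exists.

## Validation experiments and problem sizes

The test suite runs the following at desk scale (sizes chosen to keep a
full run in the tens of minutes on one CPU):

* dilution series: 5 uniform Hb levels, noiseless, same geometry/seed;
  estimate vs truth must be strictly monotone with R² ≥ 0.95;
* lens: κ = 0.7 must shift mean Hb ≤ 2 points with compensation and
  strictly more without;
* segmentation: 20 seeds, center error ≤ 5 px, radii ≤ 10%, vessel
  Dice ≥ 0.7 (noiseless), ≥ 0.6 with default noise;
* cohort recovery/discrimination: 20 replicate cohorts at full size
  (91/155, 512×512); the estimated group means must sit within ±3 points
  of the generating means and the mean-Hb group difference must be
  significant at the 0.002 family level in ≥ 95% of replicates;
* oracle equivalence: sector aggregation, pooled t and Pearson r against
  brute-force reimplementations to 10⁻¹⁰ on ≤ 64×64 / n ≤ 50 fixtures;
* statistical calibration: Lilliefors type-I error near nominal, null
  false-positive rate of the family test near base alpha, p-values of
  independent columns near uniform.

## Numerical choices and degenerate inputs

Images are processed as float32 in [0, 1]; stored values are treated as
gamma-encoded sRGB without linearization (the index is ratio-based and
any monotone per-channel encoding cancels against the vessel reference).
QC gates default to mean luminance ∈ [0.15, 0.85] and ≤ 1% saturated
pixels per channel (saturation: value ≥ 1 − 1/255); the gates reject,
never enhance — any contrast or color "improvement" would corrupt the
colorimetry downstream.  The vessel reference requires ≥ 50 vessel
pixels and red dominance (r_v > g̃_v), else explicit errors; sectors with
zero tissue pixels report NaN and are excluded from family statistics by
the complete-case rule.  Pseudoimages map [0, 120] onto a 256-level
perceptually ordered palette (default `inferno`), which is invertible to
within one palette step (< 0.5 Hb units).

## Known limitations

* Equivalence with the commercial disc-Hb software whose workflow this
  package mirrors cannot be claimed or tested: its formula set,
  calibration coefficients, segmentation algorithms and sector numbering
  are unpublished.  This implementation is openly specified instead.
* The Hb percentage is relative (vessel-referenced), never absolute
  g/dL; oxy/deoxy-Hb are not distinguished.
* The segmentation is designed for disc-centered, QC-passed photographs;
  peripapillary vessel tracking and cup/rim delineation are out of scope.
* Per-sector Hb is assumed Normal in the cohort simulator; real
  distributions show large dispersion and possible skew, which only
  raw data could settle.
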