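# Methods

This note documents the models implemented in `beadpcr`, the defaults
and why they were chosen, the numerical details that affect results, and
what the synthetic data can and cannot say about real instruments.

## Poisson quantification

Partitioning a sample across `N` compartments puts a Poisson-distributed
number of targets into each; the mean `lambda` is estimated from the
fraction of PCR-negative compartments, `lambda = -ln(N_neg / N)`.  For
bead partitions the concentration follows without any volume term,

    c_S = lambda * N_B / V_S,

because the `N_B` beads incubated with the `V_S` microlitres of sample
captured (essentially) all targets; the classical droplet formula
`C_s = (-ln(N_neg/N) / V_C) * D` is implemented alongside for reference
instruments.  When every bead has volume `V_C` and `N_B` beads exactly
tile the sample (`V_S = N_B * V_C`, `D = 1`) the two formulas coincide —
a useful consistency check that the tests exercise.

Edge cases are reported as flags rather than numbers: `N_neg = 0` admits
no finite estimate (`above_range`), `N_neg = N` is a clean zero
(`all_negative`), and wells with too few beads are `indeterminate`.
A unimodal intensity distribution is resolved against a configured
positive-control intensity — single-mode wells below it are
all-negative, above it all-positive — because the data alone cannot
distinguish the two; without a control the well is flagged
indeterminate.  An optional Wilson-interval CI on `N_neg/N`, propagated
through `-ln`, is available but off by default (it is auxiliary
plumbing, not part of the core procedure).

Default study constants: `N_B = 90,400` beads, `V_S = 16 uL`, ~3,300
beads analysed per replicate well, 12 replicates per level, droplet-mode
`V_C = 0.849 nL` (117.5 um droplets) and `D = 5`.  Per-replicate
quantification is the default; pooling all replicates of a level into
one `lambda` is available as a toggle (`pooled_lambda`).

## Thresholding

The per-well intensity distribution is classified unimodal or bimodal by
fitting 1- and 2-component Gaussian mixtures (EM, k-means
initialisation, 5 restarts, fixed seed) and comparing BIC
(`k ln N - 2 ln L`).  A 2-component win is demoted to unimodal when a
component weight falls below `5/N` or the means are closer than 2 pooled
SDs — both patterns are spurious splits of one mode.  The demotion rule
has a visible scientific consequence: a well with only a handful of
positive beads (fewer than ~5) reports zero, which is precisely why the
most dilute level of a dilution series loses most of its replicates when
only a fraction of the incubated beads is imaged.

For bimodal wells the threshold is the argmin of a Gaussian KDE
(Silverman bandwidth, 512-point grid) restricted to the interval between
the component means, ties broken toward lower intensity; a monotone
density (no interior minimum) falls back to the midpoint with a flag.

## Bead segmentation

Beads are detected on the **marker channel**, where every bead
fluoresces regardless of PCR outcome — negative beads must be counted
for `N` — and the detection-channel intensity is then measured inside
the same circles.

The detector follows the maximally-stable-extremal-region idea: the
image is normalised (min to 99.9th percentile, making detection
invariant to positive intensity rescaling and robust to hot pixels),
binarised on a ladder of 40 levels, and connected components are chained
across levels through each region's peak pixel.  A region's variation is
the relative area change across `delta = 0.05` of normalised intensity;
chains whose peak rises less than 0.05 above their lowest stable level
are pruned as noise.  For each chain the reported region is the
*largest* stable member that still contains a single chain peak — the
outer boundary of one bead; regions swallowing two peaks are mergers of
adjacent beads and are skipped.  Everything is deterministic for a given
image and parameter set.

Each region gets its minimal enclosing circle (computed on convex-hull
vertices; a single pixel is radius 0.5 by convention, two pixels fall
back to the bounding box and are flagged degenerate).  Because the
region is a superlevel set at threshold height `u` relative to the bead
peak, the enclosing radius underestimates the bead radius by
`sqrt(1-u^2)`; the radius is corrected analytically using the fitted
amplitude, iterating twice since the amplitude fit depends on the
radius.

The representative intensity is the least-squares amplitude `A` of the
projected-sphere profile `I(r) = A*sqrt(1-(r/R)^2) + bg` over interior
pixels — the natural profile of a uniformly fluorescing sphere, whose
projected brightness is proportional to the chord length.  The local
background comes from an annulus at 1.1–1.5 R, summarised by its lower
quartile: in a dense monolayer the annulus routinely clips neighbouring
beads, and a lower quartile is robust to that one-sided contamination
(at the cost of a small positive bias in `A`, irrelevant next to the
mode separation).  An annulus fully outside the image falls back to the
global median with a flag.

Validity filters, applied in order of precedence with a single recorded
reason: radius outside `[min_radius, max_radius]`; shape score (region
area over circle area) below 0.5; circle crossing the image-border
margin; overlap of more than 50% of the circle's area with an
already-accepted circle, larger region winning (doublet artifacts are
rarer than true beads).  The MSER area bounds are deliberately wider
than the radius bounds (minimum region 4 px) so that small bright
artifacts are *detected* and then *invalidated* by the size filter,
keeping an audit trail instead of silently ignoring them.

## Synthetic wells

The generator emulates the features of the real data that the analysis
depends on, with exact ground truth:

* Bead diameters are log-normal with mean 94.8 um and CV 0.07 (log-normal
  preserves the stated mean/CV without negative draws); the mean bead
  volume is then 0.446 nL.
* Monolayers are 2-D non-overlapping discs in a circular well.  Random
  sequential ("dart-throwing") placement jams near packing fraction
  0.55, below real monolayer density (~0.60 for 3,300 beads of 94.8 um
  in a 7 mm well), so dense fields use a jittered hexagonal lattice with
  spacing set by the site budget; sparse fields use dart throwing
  (`auto` picks by density).  Beads may interpenetrate by at most 5%
  (`packing_tolerance`) — hydrogel beads barely compress, and deeper
  overlap would also merge their fluorescence profiles into a single
  extremal region, which no detector could honestly separate.
* Rendering uses the same projected-sphere profile as the analysis, plus
  constant background, optional Gaussian pixel noise, and optional small
  bright artifact blobs; output is 16-bit with clipping warnings.
* Detection-channel peaks are Gaussian per class: negatives 6,000 ± 600,
  positives 16,000 ± 900 over background 500 (arbitrary units).  The
  modes sit ~10 pooled SDs apart: endpoint PCR separates classes nearly
  completely, and the observed zero-positive wells at the most dilute
  level of the reference study bound per-bead misclassification well
  below 1e-3, which a ~5 SD separation could not deliver.  The raw
  instrument distributions are unpublished, so these are stand-ins with
  the right *consequences*, not calibrated values.

What passing tests on this generator show: the estimator chain is
correct under its own assumptions (Poisson partitioning, spherical
beads, class-conditional Gaussian intensities, uniform background).
What they do not show: robustness to uneven illumination, focus drift,
stitching seams, spectral crosstalk, bead aggregation, or PCR
inhibition — none of which the generator emulates.

## Langmuir binding

Equilibrium isotherm, per bead:

    bound = q_max * free / (K_D + free)

with `q_max` in ng/bead and `K_D` in ng/uL (divide by 1,000 for ug/uL).
Adsorption kinetics in a closed vessel start fully unbound and deplete
both free DNA and surface sites:

    db/dt = (k_a / b_max) * (C_0 - b) * (b_max - b),   b(0) = 0,

whose closed form is monotone, bounded by `min(C_0, b_max)`, and reduces
to `b = C_0 (1 - e^{-k_a t})` in the dilute limit — so `k_a` (1/s) is
the pseudo-first-order rate constant.  Desorption is neglected, which is
appropriate when `K_D` is far below the working concentrations (here
`K_D ~ 1 ng/uL` against tens to hundreds).  At the reference conditions
(13,900 beads, 100 uL, `C_0 = 50 ng/uL`, `k_a = 0.21 1/s`) binding is
>99% complete by 600 s.

Fits are trust-region nonlinear least squares with multi-start initial
guesses (`q_max` from the largest observed bound amount, `K_D` from the
free concentration nearest half of it; rate guess from the earliest
sizeable rise).  The optimiser choice is an implementation detail — the
tests verify the optimum against a brute-force grid.  95% CIs are by
seeded nonparametric bootstrap over rows (2,000 resamples by default;
resample fits restart from the full-data optimum) with an asymptotic
Jacobian-based option; bootstrap is the default because the measurement
noise enters multiplicatively and the asymptotic intervals undercover
`q_max` in that regime.  In the kinetics fit `b_max` can be fixed to the
isotherm capacity or refit jointly; both modes are exposed because
either convention is defensible.

The capture-fraction prediction solves the equilibrium mass balance

    free*V + N*q_max*free/(K_D + free) = input

for the free concentration by bracketed root finding on
`[0, input/V]` (relative tolerance 1e-10) and returns the bound
fraction.  At the highest reference study concentration (0.0172 ng/bead
over 90,400 beads in 200 uL) the predicted capture is ~99.8%, which is
what justifies the volume-free concentration formula.

Synthetic binding assays measure the supernatant (free DNA), as a
photometer would (1 absorbance unit = 50 ng/uL dsDNA); noise is
proportional to the measured value (`noise_rel`), with an additive
channel (`noise_sd`) also available.  Assays default to the reference
input ladder 10–401 ng/uL and a sampling schedule dense in the first
tens of seconds where a 0.2 1/s process carries its information.
Measurements are taken in triplicate in the recovery tests: a single
6-point ladder fundamentally cannot pin `K_D` to a few percent under 5%
measurement noise, and triplicates are ordinary practice for these
assays.

## Method comparison

Two platforms are compared on log10 concentrations.  Deming regression
uses the closed-form errors-in-variables estimator with variance ratio 1
by default (log-scale noise of two dPCR platforms is comparable; the
ratio is configurable), with leave-one-out jackknife 95% CIs (bootstrap
optional).  Bland–Altman reports the mean difference and
`mean ± 1.96 SD` limits of agreement.  Replicate precision is the SD of
log10 concentrations over nonzero replicates per level, with zero-result
replicates counted separately — at high dilution that count, not the SD,
is the informative number.  Level means (not per-replicate points) enter
the regression by default, and levels outside the measurement range
(fewer than 8 of 12 nonzero replicates by default) are excluded, as is
standard when a level sits below the working range.

## Problem sizes in the test suite

The suite favours scaled-down versions of the study-shaped experiments:
the end-to-end dilution series renders 5 levels x 12 replicates x 2,000
beads at 12 um/px (beads ~4 px in radius) rather than full instrument
resolution; bead-count precision uses 9 wells of ~1,200 beads at
monolayer density; bootstrap coverage uses 30 seeds x 199 resamples.
These sizes keep every statistical margin comfortable (e.g. the log-log
slope's sampling SD is ~0.02 against an acceptance band of ±0.05) while
remaining economical.

## Known limitations

* The image model has no PSF, illumination field, or spectral crosstalk;
  segmentation performance on real images will be worse than the
  near-perfect recall seen here.
* The kinetic model ignores desorption and diffusion limitation; `k_a`
  is an effective rate under the stated mixing conditions.
* The GMM demotion rule makes very-low-count wells report zero rather
  than an uncertain positive; this is a deliberate false-positive guard
  and the source of the sensitivity loss at extreme dilution.
* Fully merged bead pairs (overlap beyond the packing tolerance) cannot
  be split; they are invalidated by size/overlap filters instead.
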