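# Methods

## Stimulus model

A Gabor patch is rendered as
`L(x, y) = L_mean (1 + c · exp(−(x² + y²)/(2σ²)) · cos(2π f u + φ))`
with `u` the coordinate perpendicular to the carrier bars. Default
photometry and geometry describe a 1024 × 768 raster at 2.14 arcmin per
pixel and 47.6 cd/m² mean luminance; the carrier is 1 cycle/deg, so one
wavelength λ = 1 deg ≈ 28 px. The triplet places the target at the
raster center and the flankers at ±(separation·λ) along the global axis,
with offsets computed in degrees and rounded to the nearest pixel
(placement error ≤ ½ px). Collinear flankers share the target's carrier
orientation; orthogonal flankers are rotated 90°. Modulations superpose
additively on the shared pedestal; at the defaults the envelope overlap
at 3λ is e⁻⁴·⁵ ≈ 0.01 and negligible.

Two parameters of the display are not constrained by the measurement
protocol and are package conventions: the envelope σ defaults to λ/2
(keeps the three patches distinct at 3λ, the common choice in
lateral-masking work) and the carrier phase defaults to 0
(even-symmetric). Both are configurable.

**Rendered contrast.** The Michelson contrast of a windowed grating
conventionally refers to its underlying carrier. Because the Gaussian
window attenuates the carrier trough nearest the envelope peak (to
~0.61 of the peak at σ = λ/2), the raw (max−min)/(max+min) of the patch
under-reads the carrier contrast by ~20 %. The package therefore
estimates rendered contrast as `max |L − L_mean| / L_mean`, which equals
the nominal contrast exactly at cosine phase whenever the grid samples
the envelope peak, and is attenuated by at most
`exp(−(λ/4)²/(2σ²)) ≈ 0.88` at the worst-case quarter-cycle phase.
Luminance is kept continuous internally; quantization to the display
bit depth happens only on export (mean luminance → mid-gray).

## Observer model

Detection follows a Weibull psychometric function on linear contrast,
`P(c) = 0.5 + (0.5 − lapse)(1 − exp(−(c/α)^β))` (guess 0.5 for 2AFC).
Defaults β = 3 and lapse = 0.02 are typical empirical values for
contrast detection; the lapse cap (0.1) keeps the 79.37 % point
reachable. Rather than specifying α, each observer is parameterized by
its *threshold* — the contrast of the 79.37 %-correct point, the
3-down/1-up equilibrium — per orthogonal-baseline condition, plus a
lateral-interaction profile TE(d) in log₁₀ units; the collinear
threshold at separation d is `orthogonal · 10^TE(d)`. This makes
staircase recovery unbiased by construction and makes
`log10(collinear/orthogonal) = TE(d)` an exact identity. TE profiles
interpolate piecewise-linearly between the measured separations; the
perceptual-field border is the profile's first zero crossing
(inhibition inside, facilitation outside). The profile is
phenomenological: no crowding, fixation instability or cortical
magnification is modeled.

## Staircase

3-down/1-up with multiplicative 10^±0.1 steps, start 0.5 Michelson
(clearly visible; the protocol's starting value is a free convention),
ceiling 1.0, floor 10⁻⁴ (only to keep log arithmetic finite).
Termination after 14 reversals or 120 trials. Counter semantics follow
the standard transformed-staircase convention: the consecutive-correct
counter resets on every error and on every executed down-step; a step
blocked by the floor/ceiling clamp is not executed and cannot create a
phantom reversal. The threshold is the mean of the last 6 reversal
contrasts; since steps are log-spaced the default averages in log₁₀ and
exponentiates (an arithmetic-mean option exists because the averaging
convention varies between labs — on these tracks the two differ by
< 2 %).

The equilibrium is analytic: equal expected up/down rates require
p³ = 0.5, i.e. p = 0.5^⅓ ≈ 0.7937 ("79 % correct"). *Post-convergence
percent correct* is measured over trials from the first reversal onward:
the first-reversal trial already belongs to the oscillatory regime, and
excluding it would systematically drop one guaranteed error per track
and bias the estimate upward by ~1.5 points. Monte-Carlo behaviour at
the defaults (β = 3, threshold 0.2): ~79.6 % post-convergence correct,
|bias| ≈ 0.01–0.02 log₁₀, SD ≈ 0.07 log₁₀ per track.

## Threshold-elevation statistics

TE = log₁₀(CT_collinear / CT_orthogonal) per participant, phase and
separation; no imputation — a missing partner row is an error. Group
summaries use the sample SD (n − 1). One-sample (TE vs 0), pooled
two-sample (df = n₁ + n₂ − 2) and paired t-tests are two-tailed;
exactly-constant samples short-circuit to t = 0 (p = 1) or a flagged
infinite t rather than dividing by a rounding-error SD. Holm adjustment
comes from statsmodels.

**Aligned Rank Transform.** For each effect, all *other* effects
(estimated from unweighted cell means — balanced designs only, enforced)
are stripped from each response, the aligned responses are ranked with
midranks, and an ANOVA is run on the ranks, of which only the aligned
effect is interpreted. Error strata follow the design: between-group
effects are tested on subject-mean ranks against subjects-within-groups;
within effects (after collapsing over any other within factors) against
the effect × subject-within-group residual, via a closed-form balanced
split-plot decomposition (validated against pingouin's mixed ANOVA in
the test suite). The group × separation interaction uses the
repeated-measures alignment — subject means (which absorb the group
effect) and the within-factor means are removed before ranking — and is
provided only for one-between × one-within designs; richer interactions
are refused explicitly, the same restriction the available
repeated-measures aligned-rank tools impose. Under 1000 null
simulations of the 2-group × 4-separation design (n = 5/group) each
effect's type-I error is within [0.03, 0.07] at α = 0.05.

Interaction post-hocs compare *differences of differences*: for within
levels c, d, the per-subject difference of interaction-aligned ranks
r(c) − r(d) is compared between groups with a pooled t-test, Holm-
adjusted within the requested family. Degenerate all-tied contrasts
report t = 0, p = 1.

## Synthetic cohorts

Group-level generating parameters (orthogonal-threshold geometric means
and TE means per separation; between-subject SDs) are estimated from the
packaged baseline table at run time, never hard-coded. Each observer
receives one scalar log₁₀-threshold offset ~ N(0, between_subject_sd)
applied across separations (observer-level sensitivity) and independent
per-separation TE jitter ~ N(0, te_between_sd). Thresholds are
log-normal by construction — they are positive and the staircase is
log-stepped. Training effects are drawn per condition (not per session)
from the packaged difference table's group means/SDs; post-phase true
thresholds are pre + effect, clipped positive, and both phases are
re-measured through independent staircases. With 50 observers per group
the recovered group-mean TE per separation lands within ±0.03 log₁₀ of
the generating means.

What the generator does *not* emulate: session-by-session learning
curves, eccentricity-continuous PF scaling, fixation instability,
threshold drift within a session, or any transfer task. Passing tests
therefore demonstrate that the pipeline recovers the statistical
structure it assumes, not that real MD data satisfy those assumptions.

## Packaged tables and reconstruction

The two packaged CSVs are verbatim transcriptions (values kept as
strings alongside parsed floats, sha256-verified at load). Post-training
thresholds are reconstructed as baseline + difference, cell by cell.
Three control cells yield *negative* reconstructed thresholds (e.g.
0.071 − 0.116 at one 6λ orthogonal cell): the difference table cannot
everywhere be relative to the baseline table, so the trained
participants' true pre-training values evidently differed from their
baseline measurements in those cells. The package keeps the arithmetic
reconstruction, flags the non-physical cells, and excludes the affected
participant × separation pairs from TE analysis with a warning rather
than silently clipping them. Control paired tests at those separations
consequently rest on 2 participants and should be read as descriptive.

## Problem sizes and determinism

All randomness flows through numpy Generators seeded via SeedSequence
spawning, so cohorts, staircases and reports are bit-reproducible for a
given seed. Monte-Carlo sizes (500 staircase replicates, 1000 null ART
simulations, 50-observer recovery cohorts) were chosen so each check's
sampling error is several times smaller than the tolerance it verifies.
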