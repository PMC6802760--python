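# Methods

## The measurement

The visual span is the number of adjacent characters a reader can recognize
reliably in a single fixation, without eye movements. It is measured with the
trigram task: three characters of matched pattern complexity are flashed
briefly (too briefly for a saccade) centered at one of several horizontal
positions around fixation, and the observer reports all three. Each
character's correctness is credited to the character position it occupied
(positions are integers; 0 is fixation, one position ≈ 1° of visual angle).
Accumulated over a session this yields, per participant and complexity level,
a *span profile*: percent correct at each scored position −7…+7.

The default session design has 17 trigram center positions (−8…+8), three
complexity levels run in 3 blocks each, and 3 repetitions of every center per
block — 459 trials per participant. Centers ±8 place one character at ±9;
scoring is restricted to −7…+7, where (by enumeration) every position
receives characters from exactly three centers, once in each trigram role
(first/middle/last), for a balanced 27 observations per position per
complexity level.

## Span from a fitted profile

Each profile (15 points) is fitted by bounded least squares with both a
single Gaussian `A·exp(−(x−μ)²/(2σ²))` and a sum of two Gaussians (six
parameters). Span size is the width of the selected curve at the 80%-correct
criterion: the outermost crossings `x_L`, `x_R` of the criterion are located
by a 0.001-position grid scan of [−9, +9] refined by bracketed root finding
(Brent, xtol 1e−9), and `span = x_R − x_L`. For a single Gaussian with
amplitude above criterion this equals the closed form
`2σ·sqrt(2·ln(A/θ))`, which the tests verify to 1e−4. If the fitted curve
never reaches the criterion anywhere in the window, the span is recorded as
zero (extents zero, asymmetry undefined). Left/right extents are measured
from fixation and clamped at zero when the supra-criterion region lies
entirely on one side; asymmetry is right minus left extent.

Model choice is deterministic where the original analysis tradition uses
visual inspection alongside r²: the double fit is selected only when its r²
exceeds the single fit's by at least Δ = 0.01 (configurable) *and* it is
admissible — both amplitudes positive, both means within the scored range,
and its supra-criterion region a single interval (a span is one contiguous
stretch). This guards against the known failure mode of pure single-Gaussian
fits, which overestimate span when forced to straddle the near-chance tails;
the second Gaussian can absorb the tail plateau.

Numerical choices: amplitudes are bounded to [0, 110] (percent, small
overshoot allowed), means to [−9, 9], σ to [0.3, 12]; multi-start
initialization is deterministic (single: data maximum at the empirical peak
with σ ∈ {2, 4}; double: symmetric ±2-position perturbations of the peak,
plus one narrow+broad start that can capture a tail plateau); convergence
tolerances 1e−10. Reported spans are rounded to one decimal place only when
written to CSV; all internal values keep full precision.

## Span in bits

Information transmitted by a single character report at accuracy p, for a
set of N characters with uniform confusion among the other N−1, is

    I(p) = log2(N) + p·log2(p) + (1−p)·log2((1−p)/(N−1)),

with p clamped to [1/N, 1]; I(1/N) = 0 and I(1) = log2(N) = 4.7 bits for
N = 26. Span in bits sums I over the 15 scored positions using the *raw*
per-position accuracies (not the fitted curve), following the definition of
the measure as a criterion-free summary of the profile; ceiling is
15·log2(26) ≈ 70.5 bits.

## Group statistics

Span tables (participant × complexity, complete within-subject design) enter
a 2 (age group, between) × 3 (complexity, within) mixed-design ANOVA,
computed via pingouin with partial η² per effect. The Greenhouse-Geisser
ε (sample-covariance estimator) optionally multiplies the within-subject
degrees of freedom, with p recomputed from the F distribution; ε ∈ [0.5, 1]
for three levels. Follow-up tests are independent-samples t-tests
(young − older) at each complexity level, df = n₁+n₂−2, pooled-SD Cohen's d,
Bonferroni-corrected over the three levels — matching the between-age
structure of the interaction follow-ups. Asymmetry is summarized
descriptively by cell and, for participants with a defined (non-zero-span)
asymmetry at every level, by the same mixed ANOVA; zero-span cells are
excluded rather than imputed.

Reading speed is 60·characters/seconds per sentence, averaged per
participant (mean of per-sentence speeds by default; the total-characters /
total-time alternative is provided since the two differ whenever sentence
speeds vary). Span–speed association is a Pearson correlation, pooled two
ways: one pair per participant using the across-complexity mean span, and
separately within each complexity level. Both pooling modes are exposed
because the pooling unit genuinely matters for the n and the value.

## The synthetic cohort generator

No raw participant data for this paradigm is available in machine-readable
form, so the generator emulates the study conditions: 2 age groups × 21
participants, 3 complexity levels, the 459-trial design, and 20 sentences of
17–25 characters per participant for reading.

The latent accuracy function per participant × complexity is an asymmetric
Gaussian over position with a guessing floor at chance = 1/26:

    base(x) = chance + (peak − chance)·exp(−(x − shift)²/(2σ(x)²)),

σ = σ_left left of the peak and σ_right right of it. Middle-slot characters
(flanked on both sides) have their above-chance component multiplied by a
crowding penalty in (0, 1]. Because each scored position receives the three
trigram roles equally often, the observable profile is the role mixture,
with effective amplitude (2 + penalty)/3 · (peak − chance); the closed-form
*true span* of a participant is the width of that mixture curve at the
criterion, `(σ_L + σ_R)·sqrt(2·ln(amp/(θ − chance)))`.

Cell defaults are calibrated so that: group-mean true spans equal the
study's reported cell means (young 7.2/6.5/5.5, older 7.1/6.4/3.1 characters
for low/medium/high); middle-role accuracy at fixation for high complexity
is 89% (young) and 76% (older) with first/last roles near 96%/95%; and
rightward asymmetry (carried by σ_right > σ_left plus a small positive peak
shift) is ≈0.5 characters for young and ≈0.25 for older adults.
Between-participant variability is a single shared standard-normal ability
draw per participant that shifts the true span in every cell by the cell's
SD, implemented by rescaling the latent σ's and floored just above zero;
the shared draw makes spans correlated across complexity levels, as they
are for real observers. The cell SDs are calibrated to the *observed*
spread of estimated spans — the reported per-cell SEs × √21, and for the
high-complexity cells the reported contrast effect size d = 1.36 (printed
with more precision than the SEs and consistent with them) — deconvolved
for the pipeline's own span-estimation noise (≈0.7 characters SD at 27
observations/position), since reported spreads describe estimated, not
latent, spans: latent SD = √(observed SD² − σ_est²). Trial simulation draws
three distinct characters uniformly from the 26-set, flips each character's
correctness by its latent probability, and on an error records a uniformly
drawn wrong response (scoring uses the correctness flags).

Reading speed is linear in the participant's mean true span with Gaussian
noise (SD 120 cpm) and a 60 cpm floor: intercepts 357 (young) and 149
(older) cpm with slope 20 cpm/character reproduce group means near 485 and
260 cpm. The reported group speeds appear transposed against the
accompanying claim that young adults read faster; the generator follows the
claim (young faster). The per-group intercept — rather than a single shared
one — is what lets the generator show both the group speed difference and
the group span difference at high complexity; their alignment is also what
makes the pooled correlation strongest at high complexity, the qualitative
pattern the replication test checks.

All randomness flows from one seed through spawned child streams, so a
manifest (config + seed + config hash) fully reproduces every output file.

### What the generator does and does not emulate

It reproduces the design balance, eccentricity-dependent accuracy with
rightward asymmetry, complexity- and age-dependent crowding of middle
characters, correlated individual differences, and a span-dependent reading
speed. It does not emulate: non-Gaussian (flatter-tailed) empirical profile
shapes — consequently span-in-bits totals run lower than typically observed
for profiles with the same character span, and no bits-level quantity is
calibrated; character-similarity structure in confusions (uniform foils
only); out-of-set responses; fixation errors; or response times. Passing
tests therefore demonstrate correctness of the pipeline and recoverability
of spans under the stated generative model, not fidelity of that model to
every feature of real data.

## Problem sizes used in the test suite

Unit and property tests run on small cohorts (≤ 6 per group) or directly on
constructed profiles. The two simulation-heavy checks use the sizes their
questions require: span recovery uses 200 binomial-profile replicates per
truth configuration, and the qualitative replication runs 100 full
experiments at 21 participants per group, checking that the age difference
is significant (Bonferroni) at high complexity only and that the span–speed
correlation is positive and strongest at high complexity, each in ≥90% of
experiments.

## Known limitations

- The 80% criterion, the Δr² = 0.01 selection threshold, and the fit bounds
  are conventions; all are configurable but defaults follow the measurement
  tradition described above.
- Zero-span participants make asymmetry undefined in that cell; the
  inferential asymmetry summary silently restricts to complete cases.
- The ANOVA assumes a complete balanced design; unbalanced or missing data
  raise errors rather than falling back to mixed models.
- Bits totals are sensitive to tail accuracies where the mutual-information
  measure is convex; with only 27 observations per position the per-position
  estimates are noisy, and no small-sample bias correction is applied.
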