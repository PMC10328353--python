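# Methods

This note documents the statistical procedures `equisym` implements, the
assumptions behind the synthetic-data generator, the defaults and numerical
choices, and the limits of what the test suite demonstrates.

## Asymmetry quantification

**Per-stride parameters.** A stride is bounded by successive right-forelimb
stance events and split at the intervening left-forelimb event into a right
and a left half-cycle. Within each half-cycle the head and pelvis vertical
displacement (local reference frame, mm) reach one minimum and one
maximum. The stride's parameters are the right-minus-left differences:
HDmin/HDmax on the head signal, PDmin/PDmax on the pelvis. The sign
convention — negative attributes the asymmetry to the left side, positive
to the right — is fixed end to end by which half-cycle carries the
right-forelimb stance marker. Half-cycles whose extremum falls on a window
boundary carry no interior extremum; such strides are skipped and logged
rather than contributing a spurious value.

**Outlier strides.** Head parameters are filtered per parameter,
independently, by the iterative rule: compute mean and sample SD of the
current values, remove every value at |x − mean| ≥ 3 SD, repeat until a
pass removes nothing. Removal is non-strict ("three or more SDs"), all
offending strides are removed before recomputing, and an SD of zero
terminates immediately. The rule is a fixpoint operation: its output is a
subsequence of its input and re-application changes nothing. Pelvis
parameters are never filtered. On a univariate series this is exactly the
Mahalanobis-distance criterion; implementing it jointly across parameters
was considered and rejected since the per-parameter form is the defensible
univariate reading.

**Classification.** A trial-mean parameter is *asymmetric* when |mean|
strictly exceeds its threshold (6 mm head, 3 mm pelvis — the
manufacturer-recommended clinical values) **and** the stride SD is at most
100 % of |mean| (non-strict). "Exceed" is read literally, so a mean of
exactly −6.0 mm against the 6 mm threshold stays symmetric. Sample SDs
(n − 1 denominator) are used throughout; both reading choices are exposed
as configuration (`ThresholdConfig`).

**Total asymmetry score.** TAS = |HDmin|/2 + |HDmax|/2 + |PDmin| + |PDmax|.
Halving the head terms maps the 6 mm head threshold onto the 3 mm pelvic
scale, so each parameter contributes comparably near its clinical boundary;
the head weight is configurable (`head_tas_weight`). TAS is non-negative
and invariant under any sign flip of its inputs.

## Preference-test scoring

The laterality index is LI = 100·(nR − nL)/(nR + nL) on the valid
observations (invalid attempts are screened out upstream and only counted).
Side preference is judged by the exact two-sided binomial test against 0.5,
defined as twice the smaller tail capped at 1 — identical, for this
symmetric null, to the minimum-likelihood definition used by R's
`binom.test`. At the 15-observation target and α = 0.05 the critical count
is 12. A horse with fewer than 15 valid observations is included only when
the outcome is already decided: writing k* for the critical count,
*decided positive* when max(nL, nR) ≥ k*, *decided negative* when even
awarding all remaining observations to the leading side stays below k*,
*undecided* (excluded) otherwise. This closed form is verified in the test
suite against brute-force enumeration of all completions for every partial
state. For included short runs the reported p-value is computed at the
actual number of valid observations; the inclusion decision alone refers to
the 15-observation target.

## Correlation stage

**Visit agreement.** ICC(A,k) — two-way random effects, absolute
agreement, average of k measurements — from the ANOVA mean squares:
ICC = (MSR − MSE)/(MSR + (MSC − MSE)/n), with F = MSR/MSE on
(n − 1, (n − 1)(k − 1)) df. Complete-case filtering is the caller's
responsibility and enforced (missing cells raise). The implementation is
cross-checked in the tests against an independent ICC routine.

**Questionnaire contrasts.** Side questions are binarized (LEFT/RIGHT →
YES; no/none → NO; "no perception/did not answer" → record dropped).
Each question is modelled only against its designated responses: overall
sidedness grade (q1) against TAS, perceived weaker hindlimb (q2a) and its
inner/outer refinement (q2b) against the pelvic parameters, neck stiffness
(q4) against the head parameters, body stiffness (q3) and canter-lead
difficulty (q5) against all four. The model is a Gaussian random-intercept
(per horse) linear mixed model of the absolute trial-mean parameter on the
answer, surface and mean stride duration, fitted by REML. When the
untransformed fit's residual skewness exceeds |1| the response is Box-Cox
transformed (maximum-likelihood λ; 0.1 mm offset first if zeros are
present) and the model refitted; the trigger threshold replaces visual
QQ-plot inspection and is configurable. Ordinal questions (q1, q2b) get a
joint Wald test across answer levels instead of a single contrast. Tests
are referenced to the large-sample Wald distribution (`df_method="wald"` in
the result): the fitting backend provides neither Kenward-Roger nor
Satterthwaite small-sample corrections, and at the cohort sizes the package
targets the calibration tests show the Wald reference is accurate (null
rejection rate 0.038 over 500 simulated 200-horse cohorts, band 0.03–0.07).
No multiple-testing correction is applied; α = 0.05 throughout.

**Side agreement.** For side-specific questions the answered side is
cross-tabulated against the side of the largest threshold-exceeding pelvic
parameter (PDmin and PDmax pooled; ties to the larger |mean|). Sensitivity
is the YES fraction among parameter-positive records, specificity the NO
fraction among parameter-negative ones. Cramér's V = sqrt(χ²/(N·(min(r,c) − 1)))
is computed on the full table; Fisher's exact p is attached for 2×2 tables
and the χ² p, flagged as such, for larger ones. Empty margins yield NaN
metrics, not exceptions.

**LI correlations.** Pearson r with two-sided p for LI against each
parameter and TAS, computed twice: on absolute values (is the *magnitude*
of laterality related to the magnitude of asymmetry?) and on signed values
(is the *side* preferred related to the side the asymmetry is attributed
to?). Zero-variance inputs are flagged undefined.

## Synthetic-data generator

The generator emulates the study design the analysis targets: a cohort of
horses measured over repeated visits, each visit contributing one
straight-line trot trial and one rider questionnaire, plus one
preference-test run per horse.

Ground truth per horse: latent expected parameter values drawn uniformly
from ±15 mm (head) and ±8 mm (pelvis); a right-protraction probability
uniform on [0.2, 0.8]; a severity grade binned from the TAS-scale magnitude
of the latent vector. The extremum-level trial model places, per stride and
half-cycle, a minimum and maximum at baseline ±amplitude, adds the latent
asymmetry to the right half-cycle's extrema, and adds independent Gaussian
noise (SD 2 mm) to every extremum, so each stride's right-minus-left
difference is latent + N(0, √2·2 mm). With per-stride probability 0.02 one
head extremum is displaced 60 mm away from baseline (head toss), feeding
the outlier-removal stage. The waveform is a piecewise half-cosine through
the extrema, anchored to zero at every stance boundary; knots are snapped
to the 200 Hz sample grid so the sampled series attains its designed
extrema exactly, which makes the zero-noise round trip through segmentation
and extraction *exact*, not approximate. Defaults: 65 horses, 3 visits, 40
strides per trial, stride duration 0.72 ± 0.04 s (truncated at 0.3 s),
head amplitude 45 mm, pelvis 30 mm — typical trot magnitudes, all
configurable.

Because the waveform interpolation carries no information beyond the
extrema, a vectorized fast path (`simulate_stride_table`) draws the
per-stride differences directly from the same extremum-level model; the
test suite checks that both paths agree in distribution. Cohort-scale
simulations (the mixed-model calibration over 500 cohorts of 200 horses,
and the acceptance script) use the fast path; waveform-level generation is
used wherever segmentation and extraction are themselves under test.

Questionnaire answers are linked to the latent truth through a softmax over
{no, left, right} with utilities (0, −s·x, +s·x), where s is
`questionnaire_link_slope` and x the linked latent (q2a: pelvic minima
latent; q4: mean head latent; q3/q5: mean of all four; q1: ordered logit on
the TAS-scale magnitude). s = 0 (the default) makes answers independent of
the gait truth — the null configuration used for calibration testing — and
large s·x saturates P(right) → 1. Each question is independently missing
with probability 0.15.

**What the generator does not emulate:** compensatory head–withers–pelvis
coupling, circle or ridden trials, surface-dependent asymmetry changes,
serially correlated stride noise, drift within a trial, or realistic
questionnaire psychology (answers depend only on the latent gait vector).
Passing tests therefore demonstrate the *statistical machinery* —
extraction, filtering, classification, testing, calibration — not that the
pipeline's clinical thresholds are appropriate for any real population.

## Numerical choices and degenerate inputs

- Sample SD (ddof = 1) everywhere a stride SD enters a rule or summary.
- Exact binomial tails via the binomial CDF/SF; critical counts by scan
  from ⌈n/2⌉; the count may be reported as "none" when even unanimity is
  not significant (n ≤ 5 at α = 0.05).
- Outlier removal on < 2 values, or removing every value, raises; identical
  values short-circuit (SD = 0).
- ICC on matrices with missing cells raises with an instruction to filter;
  a zero denominator yields NaN.
- Mixed models: responses with zero variance, or questions with a single
  observed level, return a degenerate-flagged result instead of fitting;
  convergence warnings are surfaced as a `singular` flag.
- Pipeline reports are byte-identical across runs at a fixed seed; all
  randomness flows from named `SeedSequence` streams.

## Problem sizes used in validation

Parameter recovery uses 50 waveform-level horses × 40 strides (bias of the
trial-mean estimator < 0.3 mm per parameter; injected outliers fully
removed in ≥ 95 % of affected trials). ICC recovery uses 200 subjects × 3
visits against the variance-component value 16/(16 + 4/3) ≈ 0.923. The
null calibration of the contrast stage uses 500 cohorts of 200 horses × 3
visits. The early-stopping rule is verified exhaustively (136 partial
states against enumeration of all completions).

## Known limitations

- Small-sample df corrections (Kenward-Roger/Satterthwaite) are not
  available in the fitting backend; results carry `df_method="wald"` and
  small cohorts (≪ 50 horses) should interpret contrast p-values with care.
- Fisher's exact test is available only for 2×2 tables; larger side tables
  fall back to the χ² p (flagged).
- The early-stopping rule assumes the target run length (default 15) is
  the inclusion criterion; the per-horse p-value at a shorter n is reported
  as observed and can disagree in principle with the target-n criterion
  only in the direction of being more conservative.
- The generator's uniform latent distributions are a design choice for
  identifiability in recovery tests, not an empirical claim about any horse
  population.
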