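# Methods

## Experimental design being modelled

A session interleaves *encoding* phases (the reference presented 5
times, no response) with 66-trial *decoding* phases: nine test levels,
each judged same/different against the memorized reference, with every
non-reference level shown 6 times and the reference 18 times. The
duration task uses a 600 ms reference and tests of 284–1268 ms; the
numerosity task uses a 24-dot reference and tests of 11–51 dots, shown
for 200 ms to preclude counting. While-running sessions measure a
baseline (T1), a phase during running (after a 3-min warm-up to ~80% of
the age-predicted maximum heart rate, 208 − 0.7·age), and a post-run
baseline (T2); after-running sessions measure T1 and a test phase that
begins the moment the treadmill stops, with no T2. Two blocks per
session give 396 (while) or 264 (after) decoding trials per
participant.

Two design constants deserve note:

- **Duration levels are generated outward from the reference**,
  `ref · r^k` with `r = (1268/600)^(1/4)`, not by end-to-end
  interpolation; only the anchored rule reproduces the published list
  after integer rounding (end-to-end interpolation gives 724 ms where
  the published list has 723). Rounding is half-away-from-zero for
  display; unrounded levels are retained on the `StimulusSet` for
  numeric work.
- **Numerosity levels are stored verbatim** (11, 14, 17, 20, 24, 29,
  35, 42, 51): no single-ratio geometric rule reproduces the 17 (the
  geometric rule gives 16), so the published list is treated as ground
  truth rather than forcing a generation rule that contradicts it.

The training-to-criterion phase humans performed (feedback until 80%
correct) is represented as a fixed nine-trial placeholder: simulating
human learning is out of scope, and the phase contributes no analysed
data.

One ambiguity: "132 trials per block" could mean per condition-pair or
per block-repetition. The plan adopts 3 measurement phases × 66 trials
per block repetition and 2 repetitions, which is the only reading
consistent with the stated total of 396.

## Generative observer

Perceived log-magnitude is modelled as `ln(g·test/reference) + ε`,
`ε ~ N(0, σ_s² + σ_m²)`, where `g` is a phase-specific multiplicative
gain (g > 1 ⇒ the test looks larger ⇒ the same-curve peak shifts to
`reference/g`), `σ_s` is sensory noise and `σ_m` reference-memory
noise, both in natural-log units. The observer responds "same" when the
perceived difference falls within a symmetric criterion `±c`; with
probability λ it lapses and says "same" with probability γ instead.
The closed-form same-probability is

    P(same|x) = (1−λ)·[Φ((c−μ_d)/σ_d) − Φ((−c−μ_d)/σ_d)] + λγ,
    μ_d = ln(g·x/ref),  σ_d = √(σ_s²+σ_m²).

The log-symmetric criterion makes the curve a near-Gaussian bump on the
log axis whose argmax is exactly `reference/g`; the lapse mixture keeps
the peak below 1, as observed empirically. This observer is the
package's own construction — the study it emulates specifies no
generative model — and alternatives (criterion drift, pacemaker-rate
formulations) would produce similar curves; none is implemented.

### Default parameters

| parameter | duration | numerosity | units | rationale |
|---|---|---|---|---|
| σ_s, σ_m | 0.12 | 0.06 | ln units | see below |
| c | 0.20 | 0.15 | ln units | see below |
| λ | 0.05 | 0.05 | — | keeps fitted amplitude ≈ 0.75/0.90, below 1 |
| γ | 0.5 | 0.5 | — | unbiased guessing |
| run gain g | 600/513 | 1.0 | — | puts the while-running duration PSE at 513 ms; running leaves numerosity unaffected |
| between-subject SD | 0.05 | 0.05 | ln units | ~5% participant scatter in PSE and criterion |

Noise and criterion were calibrated once, by fitting the noise-free
analytic curves, so the fitted Weber fraction lands near 0.25 for
duration and 0.15 for numerosity — the qualitative ordering (duration
noisier than numerosity) that motivates the precision analyses. Each
participant draws one log-normal perturbation of gain and one of
criterion, shared across phases; a stable individual bias cancels in
within-subject contrasts, which also keeps the aggregate null
calibration honest (both phases see the same participants).

Heart-rate traces are a saturating exponential from resting (87.06 bpm
default) to target (150.9 bpm default), time constant chosen so the
noise-free ramp lands within 1% of target at the 3-min mark, then
Gaussian fluctuation (SD 2 bpm) around target for the 5-min plateau,
sampled at 1 Hz. The traces emulate the group-average ramp-plateau
shape only; they carry no beat-to-beat autocorrelation structure and no
link to the trial stream.

### What the generator does not emulate

Real same/different data may show asymmetric criteria, sequential
dependencies, drifting attention, and training effects; participants
differ in lapse rate, not only gain and criterion. Passing tests
therefore demonstrate that the pipeline recovers the parameters of
*this* observer family at the study's trial counts — not that the
published individual-level values would be recovered from the deposited
raw data.

## Fitting

Fits minimise squared error between per-level proportions and
`A·exp(−(log₁₀x−μ)²/(2σ²))`. Choices:

- **Unweighted by default.** The curves being fitted are the plotted
  proportions; binomial-count weighting (reference level carries 3× the
  trials) is available via `weighted=True`.
- **Log base 10 internally.** PSE and Weber fraction are base-invariant
  (asserted to 1e-12 in tests), so the base is fixed purely for
  reproducibility.
- **Bounds** A ∈ (0, 1], σ ∈ (0, 2] log₁₀ units, μ within ±0.5 of the
  observed level range.
- **Multistart:** μ initialized at each observed level, σ at
  {0.05, 0.1, 0.2}, A at the maximum observed proportion; lowest
  residual sum of squares wins, earlier starts breaking ties. Each
  start first runs unbounded Levenberg–Marquardt (fast; the sign of σ
  is immaterial so |σ| is taken) and falls back to bounded
  trust-region only when the unconstrained optimum leaves the valid
  box — the two routes agree to machine precision on interior optima.
- **Degenerate inputs:** flat proportions, or widths escaping to the
  σ bound, return `converged=False` with a diagnostic message; fewer
  than 4 distinct levels raise. Non-converged fits are never silently
  used downstream.
- The Weber fraction is computed as `10^σ − 1`; the JND/PSE ratio
  reading is exposed as a named accessor and is algebraically identical
  for this parameterisation.

## Inference

- **Bootstrap:** the resampling unit is the trial row of the
  (aggregate) table, resampled with replacement to the original count;
  each resample is re-aggregated and refitted starting from the
  full-data solution. Failed refits are counted and excluded; >10%
  failures flags the distribution unstable. Default 10,000 iterations;
  tests and the null-calibration study use 200–2000, which is ample for
  a standard error of the peak.
- **Z-test:** `|Δmean|/√(se₁²+se₂²)` with two-sided normal p;
  Bonferroni α = 0.05/3 ≈ 0.017 when the three while-running contrasts
  are run together. In 200 simulated null experiments at study scale
  the test rejects ~0.5% of the time at α = 0.017 — slightly
  conservative, because the bootstrap SE mildly overestimates the
  sampling SE of the fitted peak.
- **t-tests** operate on log₁₀ PSEs by default (multiplicative biases
  become additive; a linear-unit option exists). Cohen's d is
  mean/SD of the differences; its sign is negative for a PSE decrease
  under this convention. A spread of differences at floating-point
  roundoff scale is treated as zero spread.
- **JZS Bayes factor:** BF₁₀ is the ratio of the marginal likelihood of
  t under δ ~ Cauchy(0, 0.707) (noncentral-t mixture, integrated by
  adaptive quadrature split at the likelihood peak) to the central-t
  null density. The test suite cross-checks this δ-space route against
  an independent g-prior-integral implementation (pingouin) to 1e-6.
- **Median split:** each phase's aggregated trials are partitioned at
  that phase's median timestamp, ties to the early half; each half is
  fitted and bootstrap-compared independently. A partition that leaves
  a half empty, or a half with fewer than 4 levels, raises rather than
  returning a misleading comparison.
- The repeated-measures ANOVA appearing alongside these analyses in the
  source study is deliberately not reimplemented: it is a standard
  off-the-shelf procedure (statsmodels/pingouin provide it) and its
  published values depend on raw data not bundled here.

## Problem sizes

The package's simulation studies use the study's own scale: 15
participants × 2 blocks × 66 trials per phase (1980 aggregate trials
per condition). The null-calibration study uses 200 replicate cohorts
with 200 bootstrap iterations per condition; power and recovery studies
use 100 replicates. The acceptance script simulates one cohort at full
study scale and fits the aggregate while-running curve.

## Known limitations

- PSE recovery at study scale carries a small finite-sample bias
  (aggregate fits land within ±2 bootstrap SEs, ~±10 ms, of the
  generative 513 ms) because participant heterogeneity makes the
  aggregate curve a mixture, slightly wider than any individual curve.
- The observer family is one of several that produce log-Gaussian
  same-curves; parameter estimates are not identifiable between, e.g.,
  a criterion change and a noise change from a single condition.
- Heart-rate traces are descriptive scenery for I/O testing, not a
  physiological model, and are not coupled to perception.
- The externally deposited raw dataset's internal schema is unknown here; a
  converter to the canonical trial table is the documented extension
  point (`magcomp.io.TRIAL_COLUMNS`), and no download logic is
  provided.
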