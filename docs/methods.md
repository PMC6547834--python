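# Methods

## Scoring model

Each mSHAP task attempt with completion time `t` (seconds) is scaled to a
task score

    Ts(t) = 100 · (m − t) / (m − n)

where `n` is the normative time for the task ("normal function", scores
100) and `m` the minimal-function bound, conventionally `m = 8n` (scores
0). The map is the unique linear function satisfying those two boundary
conditions. Scores are clamped to [0, 100]: times faster than normative
score 100, slower than minimal score 0, and unsuccessful attempts (DNF)
score 0 by definition. Clamping is a package choice — super-normative
performance is not rewarded beyond 100 — made so that every downstream
aggregate stays on the 0–100 scale.

Task scores aggregate two ways:

* **LIF** (linear index of functionality): the arithmetic mean of the task
  scores loading one prehensile pattern (spherical, tripod, power, lateral,
  tip, extension).
* **wLIF**: the pattern LIFs combined with weights 3, 3, 6, 5, 5, 3 over a
  divisor of 25. Because the weights sum to the divisor, six equal LIFs
  pass through unchanged.

The weights sum to 25 while the assessment has 22 tasks, which implies
task-to-pattern loading is not one-to-one. The package therefore treats the
mapping as a task → set-of-patterns relation carried in the bounds table
(pipe-separated labels). The shipped default maps each task to a single
pattern chosen by task-name convention (counts 2, 2, 6, 5, 5, 2); the
worked fixture exercises genuine multi-pattern loading. The shipped
normative bounds themselves are illustrative placeholder values (n between
1.4 s and 5 s; m = 8n) because no public normative table exists for this
task set; any substantive analysis must supply its own via the bounds CSV.

The BBT session score is the mean blocks-per-minute over the session's
trials. Three trials per session is the design; the mean is taken over
however many trials are present so a lost trial degrades gracefully rather
than failing.

## Learning-curve model

Score series follow the inverse learning curve

    Y = a − b / X

with plateau `a` (asymptotic performance, score units) and rate `b`
(magnitude of first-session-to-plateau gains, score units). `X` is the
administration index, not the calendar session: mSHAP administrations start
in session 1 (offset 0), BBT administrations start in session 2 (offset 1),
and reported endpoints are `X + offset`.

The model is linear in the basis {1, 1/X}, so the least-squares problem is
solved exactly with a two-column design matrix instead of iterative
nonlinear optimisation — identical estimates, deterministic, and no
starting-value or convergence concerns. R² is `1 − SS_res/SS_tot`; a
constant series has `SS_tot = 0`, making R² meaningless, so the fit reports
`a = Y, b = 0` with R² = NaN rather than claiming a perfect fit.

Two fitting pathways are exposed because group studies can fit either the
per-session mean across subjects (default, one point per session) or the
pooled subject-level points. For balanced designs the point estimates
coincide; R² does not, since the pooled residual includes between-subject
variance.

**Training endpoint.** With endpoint fraction `f` (default 0.9), the
endpoint is the smallest integer `X ≥ 1` with `a − b/X ≥ f·a`, i.e.
`ceil(b / ((1−f)·a))`, plus the session offset. A non-positive rate means
the plateau is met immediately (endpoint 1 + offset); a non-positive
plateau leaves the endpoint undefined and raises. The ceiling is evaluated
with a 1e-9 slack so that exactly-integer ratios do not overshoot by one
session through float noise. This rule reproduces all 28 published
per-category endpoints as well as the published whole-assessment (session
3) and BBT (session 6) endpoints.

## Effect sizes

For each transition into session `i ≥ 2`, the effect size is the mean of
the paired per-subject differences divided by the standard deviation of
those differences. The SD uses the `n − 1` sample denominator by default
(configurable to `n`), a choice documented here because the usual verbal
definition ("the standard deviation of the differences") does not fix the
denominator. Magnitudes classify as negative (< 0), negligible [0, 0.20),
small [0.20, 0.50), medium [0.50, 0.80), large (≥ 0.80); the 0.20 boundary
is inclusive of "small".

Degenerate input: when the difference SD is zero — including zero only to
within float roundoff, detected as `sd ≤ 1e-9 · max(1, max|Δ|)` — the
effect size is flagged undefined (NaN) instead of dividing by a
numerically meaningless quantity. Subjects observed in only one of the two
sessions are dropped from the pairing with a logged warning.

## Prepositioning analysis

The orientation of the terminal device is recorded per task as a quadrant
code 1–4; the prepositioning measure `q` for an administration is the
number of adjacent task pairs with differing quadrants (0–21 for 22
tasks). Orientations exactly on a quadrant boundary are a data-entry
concern: the pipeline accepts only integer codes and assumes boundary calls
were resolved at recording time.

Performance is session-normalized (`wLIF` minus the session mean over
subjects, so each session's column sums to zero), normalized scores are
grouped by `q` and averaged, and an ordinary least-squares line is fitted
through the (q, group mean) points. The regression is unweighted by
default — one point per q group, matching the grouped-means construction —
with a count-weighted option. Alongside slope and R² the package reports
Pearson `r`, because slope, `r` and R² answer subtly different questions
and reporting all three avoids ambiguity. A zero-variance response yields
slope 0 with `r` flagged NaN.

## Synthetic cohort generator

The generator emulates the study design the analysis assumes: default 6
subjects × 10 sessions. Per subject `i`, plateau and rate are drawn
`a_i ~ N(79.75, 8²)` and `b_i ~ N(22.09, 5²)` (population means set to the
published whole-assessment fit; the dispersions are package choices sized
to the spread of the published per-category plateaus, with `a_i` clipped to
(0, 100] and `b_i` to ≥ 0). The session-level target is
`wLIF_i(X) = a_i − b_i/X + ε`, `ε ~ N(0, 3²)`, clamped to [0, 100]. Task
times are back-solved through the inverse of the scoring map so that
re-scoring the log reproduces the target wLIF — exactly when all noise is
zero, in expectation otherwise — then multiplied by mean-one lognormal
jitter (σ = 0.08) so times stay positive. DNF events fire with probability
`0.10 · 0.5^(X−1)`: failures are geometrically rarer as training
progresses, qualitatively matching rising scores. BBT trials (3 per
session, sessions 2..10) follow `37.21 − 15.91/k` on the administration
index `k` with N(0, 2²) trial noise, rounded and clipped to non-negative
integers. Quadrant sequences are a Markov switch process: stay with
probability `1 − p`, otherwise move to a uniformly chosen other quadrant
(`p` = 0.3 by default), independent of performance — so the generator is a
null model for the prepositioning regression.

What the generator does **not** emulate: within-session task-difficulty
structure (every task aims at the same session target, so between-task
variance is pure jitter), learning-curve shapes other than inverse,
forgetting across long between-session gaps, coaching effects, and any
dependence of prepositioning on skill. Passing tests therefore demonstrate
that the pipeline recovers the structure it assumes, not that real cohorts
satisfy those assumptions.

Calibrations used by the test suite (computed with this package): fitting a
single 10-session series with σ = 3 noise recovers `a` within ±5 and `b`
within ±8 points at the 99.9th percentile over 2000 replicates; over 1000
default cohorts the mean recovered plateau sits within ±2 points of the
population value (observed bias ≈ +0.6, driven by early-session DNFs and
score clamping); the null prepositioning slope distribution is centred on 0.

## Pipeline and formats

Interchange is plain CSV (UTF-8, header row): session log
(`subject_id, session, task_id, time_s, dnf, quadrant`; `time_s` blank on
DNF), BBT trials (`subject_id, session, trial, blocks`), and bounds
(`task_id, n_lower_s, m_upper_s, pattern`). Floats serialize at full
round-trip precision (`%.17g`). Session numbering is 1-based everywhere;
administration offsets are explicit fields, never implicit. The report
bundle is deterministic given inputs and options. Categories whose series
are too short to fit (e.g. a two-administration BBT) are logged and
skipped, not fatal. The CLI (`mshap score|fit|effect-size|preposition|
simulate|report|validate|default-bounds`) exposes every documented default
as a flag (`--endpoint-fraction`, `--r2-threshold`, `--pathway`, `--ddof`,
`--weighted`), so shipped defaults reproduce the documented conventions.

Problem sizes in the test suite (1000 cohorts for recovery calibrations,
2000 Monte-Carlo replicates, 40-cohort null-slope checks) were chosen so
the whole suite completes in well under a minute of compute per thousand
cohorts while keeping Monte-Carlo standard errors far below the asserted
tolerances.

## Known limitations

* The shipped normative bounds are placeholders; absolute score levels from
  them are not comparable to any published assessment.
* The default task→pattern mapping is a convention; analyses relying on
  pattern-level conclusions should supply the mapping their assessment
  actually uses.
* The endpoint rule depends on the fitted plateau; for poorly fitting
  series (low R²) the endpoint inherits that uncertainty, which is why the
  pipeline reports R² summaries and a configurable reporting threshold
  (default 0.4) alongside endpoints.
* Only the inverse-curve model is implemented; exponential or power-law
  learning models are out of scope.
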