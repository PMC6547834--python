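# mshap

Quantitative training-assessment analytics for bypass-prosthesis users.

A bypass prosthesis lets an able-bodied person operate a prosthetic terminal
device (here the archetype is a body-powered hook with manual wrist
rotation) with amputee-like controls. Research protocols that use bypass
devices need a defensible answer to a simple question: **how many training
sessions are enough?** This package implements the full analysis pipeline
for answering it from objective outcome measures:

* **Scoring** — converts raw task times from a 22-task modified Southampton
  Hand Assessment Procedure (mSHAP) into 0–100 task scores
  `Ts = 100·(m − t)/(m − n)` (where `n` is the normative time, `m = 8n` the
  minimal-function bound, DNF = 0), aggregates them into six prehensile-
  pattern linear indexes of functionality (LIF) and the weighted summary

  `wLIF = (3·LIF_spherical + 3·LIF_tripod + 6·LIF_power + 5·LIF_lateral + 5·LIF_tip + 3·LIF_extension) / 25`,

  and averages Box and Blocks Test (BBT) trials into blocks/minute.
* **Learning curves** — fits the inverse learning-curve model
  `Y = a − b/X` (plateau `a`, rate `b`) to any score series by exact linear
  least squares, and derives the **training endpoint**: the first session
  whose fitted value reaches 90% of the plateau,
  `X* = ceil(b / (0.1·a))`. BBT administrations are offset by one session
  (they start in session 2), so their endpoint is `X* + 1`.
* **Effect sizes** — paired session-to-session effect size
  `ES = mean(ΔY) / sd(ΔY)` with the 0.20/0.50/0.80
  small/medium/large classification.
* **Prepositioning** — counts terminal-device orientation-quadrant changes
  across each 22-task administration, session-centres the wLIF, groups by
  change count `q` and regresses group means on `q` to test whether
  prepositioning tracks above-average performance.
* **Synthetic cohorts** — a generator that emulates a six-subject,
  ten-session training study (inverse-curve trajectories, subject
  variation, DNF events, three BBT trials per session from session 2,
  22-entry quadrant sequences), so every stage is testable without raw
  subject data.

## Worked example

Simulate a cohort and run the full report:

```bash
mshap simulate --seed 1 --out cohort
mshap report --log cohort/session_log.csv --bounds cohort/bounds.csv \
             --bbt cohort/bbt.csv --out report
```

The report directory gains `session_scores.csv`, `task_scores.csv`,
`fits.csv`, `effect_sizes.csv`, `preposition_groups.csv`,
`preposition_regression.csv` and `summary.json`. For seed 1 the summary
begins:

```json
{
  "n_subjects": 6,
  "n_sessions": 10,
  "fits": {
    "wLIF": {"a": 82.2986..., "b": 30.7147..., "r2": 0.9659..., "endpoint": 4},
    "BBT":  {"a": 37.1055..., "b": 15.8301..., "r2": 0.9966..., "endpoint": 6}
  }
}
```

Read: this cohort's mean wLIF plateaus at ≈82 points with early gains of
≈31 points, the fit explains 97% of the variance, and the curve crosses 90%
of its plateau in session 4 — additional sessions buy little. The BBT
(which starts one session later and measures gross dexterity rather than
task strategy) needs until session 6. `effect_sizes.csv` tells the same
story per transition (large effects early, negligible or negative ones
late), and `preposition_regression.csv` shows the quadrant-change slope —
near zero here, as the generator draws prepositioning independently of
performance.

The same stages are importable:

```python
import mshap

fit = mshap.fit_inverse_curve([57.9, 68.4, 72.5, 74.1, 75.8,
                               76.0, 76.8, 77.1, 77.5, 77.6])
fit.a, fit.b, fit.endpoint_session   # (79.847..., 22.113..., 3)
```

The packaged normative-bounds table (`mshap.default_bounds()`) is
illustrative: real analyses should supply their own normative data via
`--bounds`.

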