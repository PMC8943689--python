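# Methods

## Decision engine

The engine is a pure function from a context snapshot (timestamp, trailing
step count, weather, location, POI list, work schedule, goal progress) and
the last fired-prompt time to an intervention decision. Its rules:

- **Inactivity.** Fewer than `inactivity_step_threshold` (67) steps over the
  trailing `inactivity_window` (40 min). The trial literature quantifies the
  *break* criterion (≥ 67 steps ≙ a 1–3-min walk) but not inactivity itself;
  we reuse the same threshold for the trigger, configurably.
- **Cooldown.** Fired prompts are at least `inactivity_window` apart; the
  cooldown clock resets on fired prompts only, never on suppressed
  decisions. Trigger windows and the cooldown share this single timer.
- **Time windows.** `pre_lunch` spans `[lunch − 30 min, lunch)`,
  `pre_endofwork` `[work_end − 60 min, work_end)` and `pre_endofday`
  `[day_end − 60 min, day_end)`. The first two exist only on workdays;
  precedence on overlap is pre_lunch > pre_endofwork > pre_endofday, on the
  reasoning that earlier commitments need earlier planning. Timestamps are
  timezone-naive local time (single-site design).
- **Weather.** Suitable iff temperature ∈ [13, 35] °C (both bounds
  inclusive), humidity strictly < 90 %, and a suitable forecast label. The
  inclusive temperature bounds follow from the published classification
  listing "> 35" as unsuitable; the exact boundary is otherwise unspecified
  and resolved to suitable. Unknown forecast labels raise rather than guess.
- **Destinations.** Haversine distance on a 6,371-km sphere; radius 1.5 km
  in the pre-lunch window, 6 km pre-end-of-work, 500 m otherwise. Results
  are sorted by (distance, name) so ties are reproducible.

The 15 message categories form a decision tree over
window × weather × POI availability × goal progress:

| window | leaves |
|---|---|
| pre_lunch | lunch-walk-out (suitable + POI), lunch-walk-near (suitable), lunch-indoor |
| pre_endofwork | afterwork-{park,gym,mall} by nearest POI kind (suitable + POI), afterwork-indoor |
| pre_endofday | endofday-goal-met, endofday-goal-push (suitable), endofday-indoor |
| generic | generic-goal (goal met), generic-outdoor-near (suitable + POI), generic-outdoor (suitable), generic-indoor (POI), generic-stretch |

The original deployment's flowchart is not public; this tree is our
reconstruction, chosen because it spans every named tailoring variable and
yields exactly 15 leaves.

## Message bank

The bundled bank holds 105 templates: 15 categories × (4 gain-framed +
2 loss-framed + 1 self-efficacy). Within-category selection is a uniform
seeded draw, so the realized type mix is 57.1 / 28.6 / 14.3 % — matching the
58.5 / 28.3 / 13.2 % mix observed in the deployed trial's non-dismissed
messages. Slots are single-brace names from a closed vocabulary
(`poi_name`, `poi_kind`, `distance_m`, `minutes_to_lunch`,
`minutes_to_endofwork`, `steps_today`, `step_goal`, `steps_remaining`,
`temperature_c`); distances and counts are rendered as plain integers.
`{poi_name}` resolves to the nearest eligible POI, preferring the
destination kind the category implies (a park for `afterwork-park`); a POI
slot with no eligible POI raises, and callers fall back to a POI-free
template of the same category. Loading validates category, type, slot
vocabulary and brace balance, and requires every category to carry at least
one template of each type.

## Simulator

The simulator emulates the trial's data collection; it is the package's
source of inputs, since the original logs are not deposited.

**Trace model (per participant-day, 1,440 one-minute bins).** Workdays
(Sunday–Thursday, as at the study's site): near-zero desk baseline
(Poisson(0.03)/min) across work hours including a desk lunch; micro-breaks
(5–25 steps, ~1 per 2.5 h) too small to reach the break criterion; a walking
commute ending 15 min before work (60–100 steps/min for 8–14 min) and one
starting 35 min after work; an optional evening leisure walk (p = 0.35,
15–30 min) scheduled to finish before the end-of-day prompt window opens.
Weekends have 1–3 leisure walks and no prompts. Default schedule: work
8:00–16:30, lunch 12:30, day end 22:00, goal ∈ {6, 8, 10} k steps.

Decision points run minute-by-minute through work hours and the
pre-end-of-day window; the off-work gap is prompt-free (commute time). This
placement is deliberate: every spontaneous burst lies outside any possible
post-prompt 30-minute delta window, so the measured break rate is an
unbiased estimate of the generating response probability. Without it,
commute bursts landing inside evening prompts' delta windows inflated the
estimate by ~9 percentage points.

**Response model.** Each fired prompt is dismissed with `p_dismiss`
(default 0.15 — the trial reports only post-cleaning counts, so this is a
plausible notification-dismissal rate chosen once); dismissed views are
uniform < 2 s (half flagged explicit with views up to 5 s), read views are
2 s + lognormal. A non-dismissed prompt triggers a break with probability
0.532 (context-aware) or 0.199 (static) — the per-arm break proportions
realized in the deployed trial — injecting 67–300 steps over a 1–3-min
burst placed uniformly in the following 30 min.

**Cohort model.** IPAQ reports are drawn from plausible questionnaire
answers, scored, and stratified-allocated so every category splits within
one participant between arms (and totals within one). Enrollment lengths
are drawn per arm from the engagement-tier bins {7–21, 22–42, 43–66} days
with the deployed trial's tier proportions (control 11/12/6 of 29,
intervention 1/12/16), making the engagement χ² recoverable in expectation.
Gender (62 % female) and age band (72 % 23–30) follow the trial demographics.
All randomness flows from one `numpy.random.SeedSequence`, spawned per user,
so outputs are byte-identical under a fixed seed.

The default 29 + 29 × 66-day run produces ~9 k control and ~12 k
intervention records — the same order as, though larger than, the deployed
trial's 1,125 / 5,228, whose per-user volumes are unpublished. It completes
in a few seconds on one CPU.

## Analytics and statistics

Dismissal uses strict `< 2 s`; the 67-step break criterion is `≥`;
weeks = ⌈days/7⌉ (the tier boundaries 21/22 and 42/43 days follow from
this choice). An *active minute* is ≥ 10 steps/min (the trial does not
define it; 10 separates genuine movement from desk-scale sensor noise, and
it is configurable). Records missing the 30-minute follow-up counter are
excluded from break analysis; no other cleaning is applied. The step
counter is cumulative and monotone within a day, resetting at midnight;
`traces.csv` omits zero-step minutes and readers re-densify to 1,440.

Chi-square (scipy, Yates correction on 2×2 by default — required to match
published 2×2 values computed with standard software) and Mann-Whitney
(scipy; exact null for tie-free samples with n, m ≤ 8, tie-corrected normal
approximation otherwise) sit behind typed result objects; both are
cross-checked in the test suite against hand-formula and enumeration
oracles. Mann-Kendall is implemented here: S = Σ sign differences,
tie-corrected variance, ±1 continuity correction. The trial's "multivariant"
trend test is not further specified; we apply the standard univariate test
per group series. Mann-Whitney's U and W both follow the sample-1
convention (rank-sum of sample 1 minus its minimum) because published
reports print that W.

The arm-level active-minute comparison mirrors the trial's design: the six
longest-enrolled users per arm, truncated to their common enrollment span,
averaged per day; Mann-Kendall per arm, Mann-Whitney between arms.

## What passing tests do and do not show

The simulator reproduces the *structure* of the trial data — sedentary
bouts, prompt cadence, arm-dependent responses, dropout tiers — but not
physiological realism (gait, cadence, energy expenditure), geographic
mobility, weekday/holiday effects, or behavioral feedback over time (the
response probabilities are stationary). Parameter-recovery tests therefore
show that the pipeline correctly estimates what the generator encodes, not
that the intervention effect would replicate in the field. The published
rank-test statistics (W = 119, 572, …) and trend Z values are computed from
unpublished per-participant data and are not reproducible; for those
operations the package instead proves oracle equivalence. The five
published χ² statistics and four percentages *are* reproduced exactly from
their printed count tables.

## Numerical and degenerate-input choices

Thresholds are compared exactly as stated (no epsilon); contingency tables
with a zero margin raise, and the cohort-level analyzer reports `None` for
an engagement χ² that a short study renders degenerate (all users in one
tier); a one-row table is constructible (a single group's break counts) but
not testable. Probabilities are validated to [0, 1]; break bursts must
reach the 67-step criterion by construction. Seeds below 2³¹ are accepted
everywhere a seed is taken.
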