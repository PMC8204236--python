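# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the assumptions behind the synthetic data generator,
and the design choices made where the design was genuinely open.

## The decision algorithm

The engine operates on a single sensing channel: patient self-monitoring
entries. It is deliberately rule-based and deterministic — the clinical
premise is that the *clinician*, not a learning algorithm, controls when and
on what the system intervenes, by configuring goals, content, and timing.
Identical inputs always produce identical deliveries, which makes every
decision auditable after the fact.

**Detection rules** (per entry, evaluated against the running state):

| rule | fires when | default parameter |
| --- | --- | --- |
| regular eating | ≥ `regular_eating_gap_h` *waking* hours since the last logged eating episode, measured at the entry's timestamp | 5 h |
| eat enough | eating episode, no loss of control, and "ate enough" or "macro range" answered *no* | — |
| feared foods | eating episode with the optional `included_feared_food` question answered *no* | — |
| urge management | urge reported and no urge strategy used (unanswered counts as not used) | — |
| mood management | mood ≥ `mood_trigger_threshold` and the strategy question explicitly answered *no* | threshold 4 on the 1–5 scale |
| trigger awareness | any behavior or urge logged | — |

Asymmetry between the urge and mood rules is intentional: the urge question
is treated as opt-out (an unanswered question on an urge entry still signals
an unmanaged urge), while the mood rule requires an explicit "no" — a mood
rating alone, without the follow-up question answered, is too weak a signal.

The feared-foods momentary cue needs an entry-level signal that plain
meal logging does not carry, so it is driven by an optional clinician-enabled
per-entry question (`included_feared_food`); clinicians can also reach the
skill through scheduled custom pushes.

**Gating.** Only skills carrying an active priority goal may receive
interventions. Goal activity intervals are `[visit date, next visit date)`;
at most 3 goals are active at once, enforced at both the visit workflow and
the timeline container.

**Selection** emits at most one intervention per entry. The observed economy
of real systems of this kind (roughly one intervention per day against ~3
entries per day) implies a single-winner policy rather than firing every
rule. Order of operations:

1. *Rate limit*: a skill intervened on within `per_skill_min_gap_h` of now is
   skipped. Gaps default to 0 (fire whenever triggered) except regular
   eating, which defaults to the eating-gap itself so one long gap cannot
   fire again on the very next entry. Rate-limit gaps are wall-clock hours:
   they are a delivery throttle, whereas waking-hour arithmetic is reserved
   for the eating-gap rule, the one rule defined in waking time.
2. *Goal priority*: the clinician's `goal_priority_order` ranks candidates;
   goals the clinician left unranked are tied behind the ranked ones.
3. *Skill precedence* breaks ties: regular eating > eat enough > feared
   foods > urge management > mood management > trigger awareness. Restraint
   skills come first because reduced dietary restraint is the
   best-established mechanism of symptom change in CBT for BN.
4. *Rotation*: content rotates round-robin through the winning goal's linked
   templates (a per-goal cursor), so repeat triggers see varied wording —
   repetitive content is the most common complaint about momentary
   interventions.

A fresh patient with no logged eating episode cannot fire the gap rule: the
engine senses only the log, so the first logged episode starts the clock.

## Waking-hours arithmetic

Waking time between two instants is the length of the interval intersected
with the daily waking window (default 08:00–23:00, clinician adjustable per
patient; "waking hours" is otherwise undefined, and 15 h/day is a reasonable
adult norm). The measure is additive over concatenated intervals and zero
overnight. The self-monitoring reminder is due when
`monitoring_reminder_gap_h` (default 5) waking hours have elapsed since the
last entry; a new entry cancels the pending reminder and restarts the clock,
and one reminder is scheduled per gap. Reminders always land inside the
window; a threshold crossed exactly at window end rolls to the next morning's
window start. Custom pushes support one-time datetimes and a deliberately
small recurrence grammar (days-of-week + clock time between two dates) —
enough for "Friday 16:00 before happy hour" and "weekday evenings" without
cron generality.

## Entry validation

Timestamps are naive local datetimes; a single timezone per patient is
assumed because the algorithm reasons in patient-local waking time. Six
meal/snack slots plus `other` are modeled. Mood (1 good – 5 bad) is required
on meal/snack entries and optional on `other` entries, but an `other` entry
must record at least one of a behavior, an urge, or a mood — that is what
such entries are for. A "significant mood change" is operationalized simply
as a mood being recorded on an `other` entry; no delta rule is computed.
Post-meal questions (`ate_enough`, `ate_macro_range`, `included_feared_food`)
are only valid on eating episodes; `urge_target` requires `urge_present`;
loss of control is an independent boolean rather than being inferred from the
binge flag, because the eating-enough analyses exclude loss-of-control
episodes independently. A single entry may record multiple compensatory
behaviors (set-valued field).

## Analytics

Treatment weeks are 7-day bins anchored at the earliest entry date, making
all metrics invariant to record order. The analysis period for adherence
metrics is the enrollment interval truncated at dropout. Weekly
eating-enough utilization counts non-loss-of-control eating episodes where
either post-meal question ("and/or" = logical OR) was endorsed; weekly urge
skill use conditions on entries reporting an urge; weeks with no eligible
records are missing, not zero. Rates are reported to 1 decimal, distribution
shares to 2 decimals, the custom-push session rate to the nearest integer
(matching the precision such summaries are conventionally printed at).
Deliveries without a skill (custom motivational pushes) count toward the
distribution's total but toward neither the restraint nor the cue-response
aggregate.

## The synthetic patient

The generator emulates a 16-week outpatient course and is closed-loop: every
generated entry passes through the real engine, and subsequent behavior
depends on the interventions actually delivered. Defaults (the `pilot`
preset):

| parameter | default | meaning / why |
| --- | --- | --- |
| `weeks` | 16 | standard treatment length |
| meal slots | 6/day (08:00…21:00) | 3 meals + 3 snack slots |
| `p_skip_meal` | 0.30 | scheduled episode never happens (restraint/irregularity) |
| `p_log_entry` | 0.85 | an occurring episode gets logged |
| `p_miss_day` | 0.13 | whole-day nonadherence; needed for ~86 % days-with-entry, since per-entry noise alone cannot produce entry-free days |
| `adherence_decay` | 0.985/week | multiplicative drift on `p_log_entry`; modest decline over 16 weeks |
| `p_other_event` | 0.30/day | logged off-schedule urge/behavior/mood event |
| `p_urge_base` | 0.15/entry | clinically plausible urge frequency |
| `p_behavior_given_urge` | 0.40 | urges escalate to behavior; binges carry loss of control |
| `mood_dist` | (.15,.30,.30,.17,.08) | mild negative skew on the 1–5 scale |
| `skill_learning` | (0.2, 0.8, 0.05) | saturating dose-response (below) |
| `p_dropout_weekly` | 0.03 | memoryless hazard ⇒ ~37 % attrition by week 16 (≈ 2 of 5) |
| `p_intend` | 0.97 | intend-to-use response rate |

Measured over 10 seeds, the preset yields a mean of ≈ 3.0–3.1 entries/day
(declining week over week) and ≈ 86 % of days with at least one entry. The
default clinician course opens restraint skills first (regular eating from
week 1) and cue skills in the latter half, so restraint interventions
dominate the delivery distribution, as they do in practice.

**Skill learning.** The probability of using a skill at a relevant moment is
`p(I) = p0 + (p_max − p0)(1 − exp(−k·I))`, with `I` the cumulative
interventions received for that skill: the simplest monotone dose-response
with interpretable parameters (baseline, ceiling, per-intervention rate).
Urges and moods are drawn independently per entry, except that a behavior
requires a same-entry urge — affect-regulation accounts motivate the link,
but no joint distribution is claimed.

**What the generator does not emulate**, and hence what passing tests do not
show about real data: no circadian or weekday structure beyond the slot
schedule, no autocorrelation in mood or urges, no reactive adherence (real
patients log *because* they are symptomatic), no content effects (all
templates are equally effective), and no claim of clinical validity anywhere
— the generator exists to exercise the software. One known quantitative
mismatch is the momentary intervention rate: the preset produces ≈ 1.5–1.9
interventions/day, above the ≈ 0.8/day seen in comparable real deployments,
because per-entry trigger rates in real use are unpublished and the default
course keeps several goals active at once.

## Learning-curve estimation

`SkillLearningModel` fits the Bernoulli dose-response by maximum likelihood.
The optimizer works on an unconstrained transform (logit p0, logit of the
remaining headroom for p_max, log k), so `0 ≤ p0 ≤ p_max ≤ 1` and `k ≥ 0`
hold by construction; starting values come from the low- and high-dose
quartile means. Standard errors are observed-information (numerical Hessian
on the natural scale) and degrade to NaN when curvature is degenerate — e.g.
k is unidentified when the dose never varies. In the flat-curve limit
(k → 0) the fit collapses p0 and p_max onto the empirical rate.

**Identifiability and the recovery study.** The ceiling `p_max` is
identifiable only if the cumulative dose saturates the curve (k·I ≳ 3;
roughly 60+ interventions at k = 0.05): a Fisher-information calculation
shows that with the dose stalling below ~50 the best achievable error on
`p_max` exceeds 0.1 regardless of estimator. The recovery scenario is
therefore designed to saturate: frequent urges (p = 0.5/entry), the
urge-management goal active for all 16 weeks with no re-delivery gap, and no
adherence decay or dropout (these only censor exposure and are irrelevant to
the estimand). Because the generator applies one shared learning triple to
the urge, mood, and eat-enough skills, the study fits the pooled likelihood
across all three — the skills whose dose never moves contribute pure
baseline observations that pin down p0. Over 50 replicates the median
absolute errors are ≈ 0.013 for p0 and ≈ 0.06 for p_max, with the median k̂
at ≈ 0.048 against a truth of 0.05.

## Verification approach

Problem sizes were chosen to keep the full suite fast while retaining power:
the engine is checked against an independent stateless brute-force oracle on
100 randomized scenarios of up to 250 entries each (with randomized configs,
goal timelines, and priority orders); scheduler additivity over 1000 random
triples plus hand-derived overnight-wrap cases; simulator calibration over
10 seeds; dropout frequency against the configured hazard by binomial test
(n = 60, α = 0.01); and the 50-replicate recovery study above. Clinical
instrument outcomes (interview-based symptom scores, quality-of-life scales)
are outside what a log-only system can compute and are deliberately out of
scope; the property suites above are the verification surface instead.

## Known limitations

- The engine trusts entry timestamps; retrospective logging (entries made
  long after the fact) is indistinguishable from real-time logging.
- Goal re-declaration is required at each visit; goals do not persist
  implicitly across visits.
- Whether more than one intervention per entry could ever be appropriate is
  an open clinical question; the single-winner policy is a design choice.
- The per-skill rate limiter uses wall-clock hours; a waking-hours variant
  would throttle slightly differently across overnight gaps.
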