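# Methods

`rtp` models the computational core of a game-based assessment of manual
dexterity: a player controls a one-dimensional game paddle (slaved to the
rotation of a hand-held, sensor-instrumented object) while a game engine
moves objects on screen; a logger records both at 100 Hz; and a set of
performance measures quantifies tracking precision, response latency and
movement consistency. This note records the model, its assumptions, the
numerical choices, and what the synthetic tests do and do not establish.

## Coordinate system and session model

All geometry is in normalized screen units on [0, 1] x [0, 1], origin
top-left, x rightward, y downward; pixel mapping is presentation only.
The paddle is one-dimensional and lives on a fixed axis line at 0.95
(the bottom line for falling-object games). Timestamps are integer
milliseconds; the default 100 Hz rate gives 10 ms spacing with no jitter
modelling, and the sample rate is restricted to divisors of 1000 so
spacing stays integral. A session is a JSON header (trial config,
participant, event list) plus a CSV sample table
(`t_ms, paddle_pos, target_x, target_y, event_id`); floats are written
at full `repr` precision and read back with round-trip parsing, so
`read(write(log)) == log` exactly.

At most one game object is active per sample; a mode where a distractor
and a target coexist on screen is not modelled.

## Cyclic tracking (CT)

The target waveform is a sinusoid,
`x(t) = center + A sin(2*pi*f*t + phase)`, with amplitude `A <= 0.5` and
frequency `f` configurable and phase 0 by default (the target starts at
center). A sinusoid is the minimal smooth cyclic waveform consistent
with "configurable amplitude and frequency", and it makes half-cycle
segmentation analytic. A triangular waveform would be the main
alternative; nothing downstream depends on the choice beyond the
half-cycle boundary times.

Measures (all per trial, after the exclusion below):

* **TRE / ARE** — total / average residual error: sum / mean of the
  per-sample *absolute* difference between target and paddle along the
  tracking axis. Absolute rather than signed, so errors cannot cancel;
  whether the instrument intends axis-wise absolute or Euclidean error
  is not documented anywhere we could find, and axis-wise absolute in
  normalized units is assumed. TRE is in normalized-unit·samples.
* **Amplitude variation** — half-cycle boundaries are placed at
  consecutive extrema of the *target* waveform (every `1/(2f)` s,
  starting `1/(4f)` after trial start for phase 0); only complete
  extremum-to-extremum intervals are used. Boundaries come from the
  known target, not from detected paddle extrema, which keeps the
  segmentation well-defined for impaired, non-periodic paddle motion.
  The per-interval amplitude is the paddle's max − min (2A for a perfect
  tracker). The mean, sample SD (n − 1) and COV = 100·SD/mean are
  reported; a COV needs at least 4 analyzed half cycles and a positive
  mean, otherwise it is flagged missing (`None`).
* **Exclusion rule** — the first two full target periods (`t < 2/f`),
  measured from trial start, are excluded from every statistic, because
  tracking typically takes a cycle or two to settle. Trials shorter
  than three full cycles are rejected outright.

## Motor skill game (MSG)

Events are sequential and non-overlapping: `floor(duration / event_s)`
back-to-back events, each spawning on the top edge at an abscissa drawn
uniformly from the admissible range and traversing linearly to the
paddle line in exactly the event duration. Straight trajectories fall
vertically; diagonal ones shear by ±0.25 units (sign drawn per event,
clipped at the admissible range). Each event is independently a
distractor with the configured probability. The admissible range keeps
a margin of `max(object_radius, 0.1)` from the screen edges — objects
stay fully visible, and the arrival band stays clear of a paddle idling
at its home position (see the simulator below).

Per-event measures:

* **Movement onset time (MOT)** — the first sample at which the paddle
  has moved at least 5 % of the required movement distance
  (`|end_x − paddle(appearance)|`) away from its position at object
  appearance, sustained for 30 ms (3 samples at 100 Hz) or to the event
  end. The threshold has an absolute floor of 0.04 units: for
  short-distance events 5 % of the distance falls below the position-
  noise floor and a pure relative rule fires on noise; 0.04 is ~1.5x
  the displacement-noise SD at a position noise of 0.02 and still below
  the distance a brisk movement covers in one sample, so detection
  latency stays within one sample period. Both threshold and debounce
  are configurable arguments. A paddle that never crosses the threshold
  yields a null onset (the no-movement contract, not an error).
  "Response time" in outcome tables is this same quantity.
* **Success** — decided only at the object's arrival sample (the last
  sample of the event window): a target is caught iff
  `|paddle − end_x| <= paddle_halfwidth + object_radius`; a distractor
  is a success iff *not* overlapping there. Transit overlap is
  irrelevant because the games catch falling objects at the paddle line.
* **Movement error (ME)** — mean `|paddle − end_x|` over samples from
  onset to event end; missing (NaN) when there is no onset.
* **Movement time (MT)** — onset to arrival stabilization, where
  stabilization is the start of the final run inside the catch window
  that persists through arrival; null when the paddle is outside the
  window at arrival.
* **Movement variation** — COV of per-response peak displacement within
  each heading group (needs ≥ 2 responses per group).

The trial summary reports the success rate as
`100 · caught targets / target events` — distractors never enter the
denominator — and means of MOT/MT/ME over target responses with a
detected onset.

## Synthetic player

The simulator exists so every metric is testable by parameter recovery
without patient data. It is deliberately minimal — each parameter maps
one-to-one onto a measure:

| parameter | default | maps to |
|---|---|---|
| `tracking_lag_ms` | 0 | pure pursuit delay → TRE/ARE |
| `gain` | 1.0 | multiplier on required displacement → amplitude |
| `noise_sd` | 0.0 | additive position noise (units) → COV, ME |
| `reaction_time_mean_ms` / `_sd_ms` | 300 / 0 | onset latency → MOT |
| `miss_prob` | 0.0 | P(no response to a target) → SR |
| `max_speed_units_per_s` | 5.0 | speed cap of the response ramp |

CT: `paddle(t) = center + gain·(target(t − lag) − center) + noise`.
MSG: the paddle rests at a home position on the screen edge (0.0) and
re-homes at each event boundary — an idealized between-trials reset
that keeps events independent and means an unresponsive paddle never
catches anything (required for SR to track `1 − miss_prob`); real
players instead retain their terminal posture between events. A
responding player holds home until the drawn reaction time, then ramps
at the capped speed toward `home + gain·(end_x + scatter − home)` and
holds; endpoint scatter is Gaussian with SD `noise_sd`. The default
speed cap (full screen in 200 ms) is generous by design: 5 % of any
on-screen distance is covered within one sample period, so the detected
onset lags the programmed reaction time by at most one sample. All
randomness comes from one seeded generator per session; per target
event the draws (miss, reaction, scatter) happen in fixed order
regardless of outcome, so runs differing only in `miss_prob` share
draws and SR is monotone in `miss_prob` at fixed seed.

What a green synthetic test establishes: the metric pipeline recovers
programmed parameters under the stated model. What it does not: any
claim about real pediatric or post-stroke kinematics — the simulator
has no biomechanics, no spasticity, no within-response corrections, and
its between-event reset is idealized.

## Outcomes and reliability

Percent change is `100·(post − pre)/pre`, percent reduction its
negation, both rounded half away from zero to integer percent — the
convention that reproduces every self-consistent printed cell of the
shipped worked-example tables. Change from a zero baseline is flagged,
never silently dropped. Group averages are rounded means. Outcome
tables first average a participant's values over the task's movement
directions, then compute per-participant change and the group average.
The worked-example fixtures carry known data errata as annotations
(`rtp.fixtures.ERRATA`) — e.g. one post score with an obvious extra
digit, and several printed change cells inconsistent with their own
pre/post cells — asserted in tests, never silently corrected.

Reliability is the two-way random-effects, absolute-agreement,
single-measure intraclass correlation ICC(2,1), computed directly from
the ANOVA mean squares (n ≥ 3 subjects, 2 sessions):

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)
    SEM = SD·sqrt(1 − ICC)      (SD pooled over both sessions)
    MDC = 1.96·sqrt(2)·SEM      (95 % level)

The model choice (absolute agreement rather than consistency) and the
95 % MDC level are conventional defaults; a table with zero total
variance is flagged degenerate rather than reported as a number. The
direct mean-squares implementation handles the perfect-agreement and
degenerate cases without warnings; `pingouin`'s ICC(A,1) serves as an
independent cross-check in the test suite.

## Known limitations

* One object on screen at a time; concurrent distractor/target scenes
  and curved or accelerating trajectories are out of scope.
* No frequency-domain tracking measures (gain/phase), no smoothing of
  raw samples, no kinematic smoothness indices.
* The half-cycle count of a trial depends on the waveform phase: a
  phase-0 sinusoid of `n` periods yields `2n − 1` complete
  extremum-to-extremum half cycles, not `2n`.
* Integer-millisecond timestamps restrict sample rates to divisors of
  1000 Hz.
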