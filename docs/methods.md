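# Methods

## The model

`tirsim` simulates the temporal control of articulatory gestures as an
interaction of dynamical systems.  A *gestural system* is a control unit,
not a movement: its activation `g` is normalized to [0, 1], switches on
and off in a single time step, and, while active, can drive a
tract-variable plant.  Gestures never time themselves.  Initiation and
termination are caused by **time-representing systems (TiRs)** acting on
binary *gating systems* interposed between TiRs and gestures.  A TiR
represents elapsed time only indirectly — its state is an activation that
grows by integrating experienced forces — and it acts when that state
crosses learned thresholds `tau`, with a sign `chi` that opens (+1) or
closes (−1) the target gate.

Five TiR classes are implemented:

| class | dynamics | parameters |
|---|---|---|
| `eps` (aperiodic clock) | `dx/dt = omega` while gated open; frozen closed | growth rate `omega` (activation/s), `tau`, `chi` |
| `theta` (planning oscillator) | `dtheta_i/dt = omega_i + sum_j K_ij sin(theta_j − theta_i)`; radial amplitude `rho` relaxes (critically damped, 95% in `amp_response_s`) toward 1 (gate open) or 0 | angular frequency, coupling row `K`, amplitude threshold (0.5), trigger phase |
| `T_int` (internal/predictive feedback) | `dx/dt = alpha * g_source(t)` | integration rate `alpha`, `tau`, `chi` |
| `T_ext` (external/sensory feedback) | `dx/dt = alpha * g_source(t − d)` | as `T_int` plus sensory loop delay `d` |
| `T_intra` (intra-gestural) | as `T_int`, but may only source from and act on its own gesture | as `T_int` |

Oscillators trigger at phase 0 mod 2π (the peak of cos, taken as the
phase of maximal population activity) provided their amplitude is at or
above threshold; a sub-threshold crossing is consumed silently and the
opportunity moves to the next cycle.  Every action is one-shot per arming
episode and re-arms only when its host TiR is re-gated — this is the
gating that prevents oscillators from re-triggering gestures on later
cycles.  Actions are realized as instantaneous gate flips; only their
timing is observable, so no force magnitude is modeled.

**Coupling convention.** Only the first Fourier mode is used: `K_ij > 0`
attracts toward in-phase, `K_ij < 0` repels toward anti-phase.  For the
C/R pair repelled with strength `b` and both attracted to V with strength
`a`, the symmetric phase displacement satisfies `cos(phi) = a/(2b)`, so
the displacement is bounded by a quarter cycle.  This bound drives the
calibration choices below.

**Competitive selection.** Serial order lives in two parallel domains.
Syllable-sized sets of co-selected gestures (mu-systems) and word-sized
sets of concept systems each carry an initial activation *gradient*;
de-gated units grow linearly (default rate 1/s, threshold 1) until one is
selected, which closes every gate in the competition set.  The selected
unit is suppressed — reset to zero and retired — by the designated
feedback TiR of the last gesture in its set (the vowel for CV, the coda
release for CVC); both the internal and the external member of that
gesture's TiR pair are designated, so whichever fires first suppresses
and the other is disarmed.  Suppression re-opens the gates of the
not-yet-selected units *of the same competition set* (a mu-system
competes only against its concept's other members).  A concept retires
when its last member mu retires.  Suppressed units never re-compete.
Ties in gradient values resolve to the lowest index with a logged
warning; a sibling frozen exactly at threshold by a tie is selected
immediately on re-de-gating.

**Context modulation.** Two context variables in [0, 1] reshape timing:

* self-attention `lambda_attention` divides feedback integration rates,
  `alpha = alpha' / (1 + beta * lambda)`, with `beta_internal = 1 <
  beta_external = 4`;
* pace `lambda_pace` maps to oscillator frequency through a logistic
  centered at 0.5 (scale 0.15) affinely mapped onto `(f_min, f_max)` — a
  smooth, strictly increasing map that saturates at both ends, honoring
  the hypothesis that planning oscillations are confined to a band
  (theta, about 3–8 Hz).

The rate-control experiments drive both variables with a single lambda.
Although external feedback carries the larger `beta`, the internal →
external handoff as attention rises still obtains because the shipped
internal route has a much longer base interval than the external route's
integration component (see calibration): the internal line
`A(1 + beta_int * lambda)` is steeper in absolute milliseconds than the
external line `d + B(1 + beta_ext * lambda)` whenever
`A * beta_int > B * beta_ext`, and the first TiR to fire governs the
interval.  With the shipped constants the crossover sits at
`lambda* = (d + B − A)/(A beta_int − B beta_ext) = 3/7 ≈ 0.43`.

*Selectional anticipation*: the feedback TiRs of the final mu-system of
each word have `beta` multiplied by `gamma_word_final` (1.2), and those
of the utterance-final word additionally by `gamma_utterance_final`
(1.5).  At `lambda = 0`, boosts have no effect; as attention grows they
produce word-final and utterance-final lengthening.

**Noise.** Stochasticity is inter-utterance, not white in time: each run
draws one multiplicative factor per TiR applied to its rate (`omega` or
`alpha`) and frozen for the run, `(1 + sigma_global * eta)(1 +
sigma_local * eta_i)` with `eta` shared and `eta_i` independent standard
normals, clipped at 0.05.  Global noise moves all clocks together and
correlates successive intervals; local noise decorrelates (chains) or
anti-correlates them (independent/hybrid triggers acting on the middle
gesture).

## Numerics

Forward Euler on a fixed grid, default `dt = 1 ms`.  Between events,
clocks and integrators are piecewise linear in time, so threshold
crossings are solved exactly: event timestamps are the exact
continuous-time crossing times, gesture activation intervals are stored
with those refined on/off times, and integrators consume them with exact
fractional-step overlap (external feedback shifts the interval endpoints
by `d` before overlap).  Grid quantization therefore affects *when state
changes are realized* (the step after the event, detection lag ≤ 2 steps
for integrator chains) but not the measured event times; halving `dt`
moves noise-off event times by far less than one step in the test suite.
Only the oscillator bank, whose coupling is genuinely nonlinear, carries
O(dt) phase error — negligible in practice because the shipped models
start at or near the coupling fixed point, where phase velocity is
constant.

Two integrators racing on the same gate within a single step resolve in
declaration order (error bounded by `dt`); the shipped calibrations keep
competing crossings comfortably apart.  Each Monte-Carlo repetition uses
an independent child stream spawned from the root seed by run index, so
run counts can change without altering any individual run.  Simulations
may stop early once nothing can fire again (`stop_when_quiescent`).

The tract-variable plant is a critically damped point attractor
(`x'' = omega_n^2 (x0 − x) − 2 omega_n x'`, `omega_n` set so a step
settles to 95% in `response_s = 150 ms`), blending simultaneous drivers
by averaging their targets and holding position when undriven.  It is
for movement traces and the optional transduced-feedback route only; by
default the external sensory signal is the gesture's activation delayed
by `d`, not the plant trajectory.

## Shipped calibration

Constants live in `src/tirsim/data/hybrid_default.json`, not in code.

* **Feedback pairs** (`tau = 0.25`): internal `alpha' = 2.128` (base
  interval `A = 117.5 ms`), external `alpha' = 10` (`B = 25 ms`) with
  sensory delay `d = 100 ms`.  At `lambda = 0.5` the V-to-c interval is
  `min(176.25, 175) = 175 ms`, inside the 150–400 ms range typical of
  post-vocalic timing, and the crossover lies at `lambda ≈ 0.43`.  The
  delay default reflects the premise that the efferent–afferent loop is
  too slow for pre-vocalic constriction–release timing (≈50–100 ms), so
  `d` must exceed that scale.
* **Hybrid-syllable oscillators**: attraction `a = 1`, repulsion
  `b = 10`, hence `phi = arccos(0.05) ≈ 87°`.  The pace band for the
  hybrid models is (3, 5) Hz, so `f(0.5) = 4 Hz` and the C-to-V interval
  is `phi/omega ≈ 60.5 ms`.  A wider band reaching 8 Hz at its top would
  make a 50 ms CV interval unreachable at the neutral rate, because the
  quarter-cycle bound caps the displacement at `T/4 = 45 ms` for
  `T = 182 ms`; 3–5 Hz stays within theta while placing the neutral-rate
  CV interval in the empirical 50–100 ms range.  Initial phases start at
  the fixed point (V at π, C and R at ±phi), so the pattern is stationary
  from the outset.
* **Correlation-zoo oscillators** (`fig8_coupled_osc`): `a = 100`,
  `b = 200` rad/s at 4 Hz.  The positive-correlation signature of this
  topology presumes strong coupling: detuning shifts the locked phase
  pattern by `~delta_omega / k`, and with weak coupling that local effect
  overwhelms the shared-frequency effect and flips the correlation sign.
  The shipped strengths put the model firmly in the locked regime
  (5% frequency noise shifts phases by ≲0.01 rad).
* **Clock/chain zoo**: link thresholds 0.15 activation-seconds (150 ms
  per link at unit rates), gesture self-termination at 0.5, utterance
  initiation at 0.05.
* **Selection**: growth rate 1/s, threshold 1, gradients evenly spaced
  from 0.9 down to 0.3 (earlier = higher).

## Experiment sizes

Monte-Carlo experiments default to 200 runs per noise cell (500 where
the expected correlation is zero, as in the local-noise chain cell),
five noise levels 0–10% in 2.5% steps with the all-zero cell excluded,
and rate sweeps use 11 evenly spaced lambda values.  A single
three-gesture run is ~1 s of simulated time; the full summary script
(`scripts/acceptance.py`) runs ~900 simulations in well under a minute
on one core.

## What the generator does and does not emulate

All inputs are parameter settings; there are no external data.  The
simulations reproduce the *control topology* consequences measured on
event times: interval covariance under global/local rate noise,
symmetric displacement from phase coupling, internal/external control
handoffs, plateau vs. open-ended interval scaling with rate, and
selection-driven serial order.  They do not emulate articulator
kinematics beyond the optional one-dimensional plant, acoustics,
perception, multi-articulator weighting, stress/accentual gestures, or
trial-to-trial temporal drift within an utterance (noise is frozen per
run).  Passing tests therefore certify the mechanics and calibrated
ranges of the control model, not fits to any articulatory corpus.

## Known limitations

* Event ordering between oscillator-caused and integrator-caused events
  that fall within ~2 steps of each other follows processing phase, not
  refined time, until the final per-run sort of the event log.
* The amplitude dynamics and action-pulse forms are this package's own
  commitments (critically damped second-order relaxation; instantaneous
  flips); other smooth choices would shift absolute times slightly but
  not the qualitative signatures.
* `T_ext` may alternatively integrate the tract-variable position
  (config switch); that route is sampled on the grid rather than
  event-refined, so its crossings carry O(dt) error.
* The geminate demo is qualitative; no quantitative anchor is claimed.
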