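# tirsim

A simulator of **feedback-based temporal control of speech articulation**.
It is built for researchers in speech motor control and laboratory
phonology who want to reason about *what causes articulatory gestures to
start and stop* — and how the same machinery, scaled up, produces speech
rate variation and boundary-related lengthening.

## The model in brief

Articulatory gestures are modeled as control systems with normalized
activation `g ∈ [0, 1]`, switched by binary gates.  Gates are acted on by
**time-representing systems (TiRs)** whose states are activations, never
clock time: an aperiodic clock `ε` grows at rate `ω`; a planning
oscillator `θ` obeys `θ̇_i = ω_i + Σ_j Φ_ij sin(θ_j − θ_i)` and triggers
at its phase peak once its gated amplitude exceeds threshold; internal
(`T̂`) and external (`T̄`) feedback integrators accumulate
`ẋ = α · g_src(t)` and `ẋ = α · g_src(t − d)` respectively, the latter
paying the sensory loop delay `d`.  Each TiR acts when its state crosses
thresholds `τ`, opening (`χ = +1`) or closing (`χ = −1`) a gate.

Serial order comes from competitive selection in two parallel domains
(syllable-sized μ-systems; word-sized concept systems): units with a
gradient of initial activations grow when de-gated, the first to reach
threshold is selected, and feedback from the last gesture of the set
suppresses it, starting the next round.

Speech rate is controlled by context, not by a tempo knob: self-attention
`λ` rescales feedback integration rates as `α = α′/(1 + βλ)` with
`β_internal < β_external`, and pace maps onto oscillator frequency
through a saturating logistic bounded by the theta band.  Raising `λ`
slows speech, hands post-vocalic control from internal to external
feedback (crossover near `λ ≈ 0.43` with the shipped calibration), and —
because oscillator frequency saturates — compresses pre-vocalic intervals
only so far while post-vocalic intervals keep growing.

## Worked example

Simulate the hybrid CVC syllable — pre-vocalic gestures triggered by
coupled oscillators, vocalic/post-vocalic timing governed by feedback —
at the neutral rate:

```python
import tirsim as ts

model = ts.build_model("fig9d_hybrid_cvc", lam=0.5)
_, events = ts.simulate(model, seed=1)
print({e.system_id: round(e.time, 4) for e in events
       if e.event_kind == "activation_on"})
table = ts.extract_intervals(events, model)
print(table.frame)
```

```
{'C': 0.0645, 'V': 0.125, 'R': 0.1855, 'c': 0.3, 'r': 0.475}
   run_id interval    value_ms  flagged
0       0       CV   60.509733    False
1       0      C-R  121.019467    False
2       0       VC  175.000000    False
3       0      R-c  114.490267    False
4       0      c-r  175.000000    False
```

The constriction and release initiations flank the vowel symmetrically
(±60.5 ms — the c-center pattern produced by repulsive C–R coupling with
attraction to V), the CV interval sits in the empirically typical
50–100 ms range, and the V-to-coda interval (175 ms, here governed by the
external feedback TiR) sits in the 150–400 ms range.

Monte-Carlo interval correlations diagnose control topology.  With one
TiR triggering both later gestures, successive intervals correlate
perfectly no matter the noise:

```python
m = ts.build_model("fig8_shared_trigger").model_copy(deep=True)
m.noise.sigma_global = m.noise.sigma_local = 0.05
_, ev = ts.run_simulation(m, ts.SimConfig(duration=1.2, seed=11, n_runs=200,
                                          record_timeseries=False,
                                          stop_when_quiescent=True))
print(ts.delta_correlation(ts.extract_intervals(ev, m)))
# CorrelationResult(r=1.0, n=200, flagged=False, reason='')
```

The same machinery is available from the shell:

```bash
tirsim list-models
tirsim run --model fig9d_hybrid_cvc --lambda 0.5 --seed 1 --out out/
tirsim corr --model fig8_chain_internal --runs 200 --seed 7 --out surface.csv
tirsim sweep --out sweep.csv            # 11-point lambda rate sweep
tirsim export-textgrid --events out/events.csv --out out/syllable.TextGrid
```

Every `run` writes a `manifest.json`; passing it back as `--config`
reproduces the outputs byte-for-byte.

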