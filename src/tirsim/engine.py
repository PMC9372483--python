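"""Fixed-step simulation engine with event-refined timing.

The engine advances all systems on a fixed grid (forward Euler, default
dt = 1 ms) but timestamps events by exact linear interpolation of the
threshold crossing that caused them.  Because autonomous clocks grow at
constant rates and feedback TiRs integrate binary activation traces, their
state is piecewise linear in time, so the interpolated crossing times are
*exact* continuous-time event times, not grid approximations: gesture
activation intervals are stored with these refined on/off times and
integrating TiRs consume them with exact fractional-step overlap.  Only
the oscillator bank (whose phase coupling is genuinely nonlinear) carries
O(dt) integration error.

State changes still take effect on the grid (a gate opened mid-step drives
its gesture from the next step), and an action fired by an integrator may
be *detected* a step or two after its refined timestamp; the event log is
sorted by refined time before it is returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from ._core import (ConfigurationError, NumericalInstabilityError,
                    SelectionStateError, crossing_time, detect_crossing)
from . import control as ctl
from .model import ModelSpec
from .selection import CompetitiveUnit, Domain
from .systems import (GesturalSystem, TractVariable, active_overlap,
                      step_gesture, step_tract_variable)
from .tirs import (Action, AperiodicTiR, IntegratorTiR, OscillatorTiR,
                   TWO_PI, detect_phase_trigger, trigger_time)

__all__ = [
    "SimConfig", "EventRecord", "Timeseries", "run_simulation",
    "detect_crossing", "ConfigurationError", "NumericalInstabilityError",
    "SelectionStateError",
]


class SimConfig(BaseModel):
    """Simulation clock, seeding and output options."""

    model_config = ConfigDict(extra="forbid")

    dt: float = Field(default=0.001, gt=0.0)
    duration: float = Field(default=1.0, gt=0.0)
    seed: int = Field(default=0, ge=0)
    n_runs: int = Field(default=1, ge=1)
    record_timeseries: bool = True
    stop_when_quiescent: bool = False

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.duration < self.dt:
            raise ValueError("duration must be at least one time step")
        return self


class EventRecord(NamedTuple):
    """One timestamped event.  Times are refined (sub-step) seconds."""

    run_id: int
    time: float
    system_id: str
    event_kind: str  # gate_open | gate_close | activation_on |
    #                  activation_off | trigger | selected | suppressed


@dataclass
class Timeseries:
    """Grid-sampled state traces for one run.

    ``data[system_id][variable]`` is an array aligned with ``time``; for a
    full (non-early-stopped) run the length is floor(duration/dt)+1.
    """

    run_id: int
    time: np.ndarray
    data: dict[str, dict[str, np.ndarray]]

    def to_frame(self):
        """Long-format DataFrame (run_id, time_s, system_id, variable, value)."""
        import pandas as pd
        rows = []
        for sid, vars_ in self.data.items():
            for var, arr in vars_.items():
                rows.append(pd.DataFrame({
                    "run_id": self.run_id, "time_s": self.time,
                    "system_id": sid, "variable": var, "value": arr,
                }))
        return pd.concat(rows, ignore_index=True)


# --------------------------------------------------------------------------
# runtime assembly

class _Runtime:
    """Mutable per-run state compiled from a ModelSpec."""

    def __init__(self, model: ModelSpec, multipliers: np.ndarray):
        self.model = model
        mod = model.modulation
        self.gestures = {g.id: GesturalSystem(g.id, g.role, g.word)
                         for g in model.gestures}
        self.tirs = []
        self.by_id: dict[str, object] = dict(self.gestures)
        for k, spec in enumerate(model.tirs):
            mult = float(multipliers[k])
            if spec.cls == "eps":
                tir = AperiodicTiR(spec, omega_eff=spec.rate * mult)
            elif spec.cls == "theta":
                f = spec.freq_hz if spec.freq_hz is not None else \
                    ctl.pace_to_frequency(mod.lambda_pace, mod.f_min_hz,
                                          mod.f_max_hz, mod.pace_scale)
                tir = OscillatorTiR(spec, omega_eff=TWO_PI * f * mult)
            else:
                alpha = spec.rate
                if spec.modulated:
                    beta = spec.beta
                    if beta is None:
                        beta = (mod.beta_external if spec.cls == "T_ext"
                                else mod.beta_internal)
                    alpha = ctl.attention_to_alpha(
                        spec.rate, beta * spec.beta_scale,
                        mod.lambda_attention)
                tir = IntegratorTiR(spec, alpha_eff=alpha * mult)
                tir.cursor = 0.0
            self.tirs.append(tir)
            self.by_id[spec.id] = tir
        self.oscillators = [t for t in self.tirs
                            if isinstance(t, OscillatorTiR)]
        self.integrators = [t for t in self.tirs
                            if isinstance(t, IntegratorTiR)]
        self.clocks = [t for t in self.tirs if isinstance(t, AperiodicTiR)]
        # precompute coupling index lists for the oscillator bank
        osc_index = {o.spec.id: j for j, o in enumerate(self.oscillators)}
        for o in self.oscillators:
            o.coupling_idx = [(osc_index[other], k)
                              for other, k in o.spec.coupling.items()]

        self.mu_units = [CompetitiveUnit(m) for m in model.mus]
        self.concept_units = [CompetitiveUnit(c) for c in model.concepts]
        for u in self.mu_units + self.concept_units:
            self.by_id[u.spec.id] = u
        self.mu_domain = Domain(self.mu_units, "mu") if self.mu_units else None
        self.concept_domain = (Domain(self.concept_units, "concept")
                               if self.concept_units else None)
        # mu gates start open only when no concept domain de-gates them
        if self.mu_units and not self.concept_units:
            for u in self.mu_units:
                u.gate.open = True
        for u in self.concept_units:
            u.gate.open = True
        self.mu_of_concept = {c.id: [m for m in self.mu_units
                                     if m.spec.id in c.members]
                              for c in model.concepts}
        self.concept_of_mu = {}
        for c in model.concepts:
            for mid in c.members:
                self.concept_of_mu[mid] = c.id

        self.tract_vars = [TractVariable(v) for v in model.tract_variables]
        for tv in self.tract_vars:
            self.by_id.setdefault(tv.spec.id, tv)

    def source_windows(self, tir: IntegratorTiR, a: float, b: float):
        """Active sub-intervals of the (delayed) source trace on [a, b)."""
        src = self.by_id[tir.spec.source]
        if isinstance(src, GesturalSystem):
            return active_overlap(src.intervals, a, b, delay=tir.spec.delay)
        raise ConfigurationError(
            f"integrator {tir.spec.id!r} has non-gestural source; use "
            "source_force instead")

    def source_is_plant(self, tir: IntegratorTiR) -> bool:
        return isinstance(self.by_id[tir.spec.source], TractVariable)


# --------------------------------------------------------------------------
# the simulation loop

def run_simulation(model: ModelSpec, config: SimConfig
                   ) -> tuple[list[Timeseries], list[EventRecord]]:
    """Simulate ``model`` for ``config.n_runs`` Monte-Carlo repetitions.

    Returns the per-run state traces (empty list when
    ``record_timeseries`` is off) and the merged event log, sorted by
    refined event time within each run.  Identical (model, config) pairs
    produce bit-identical event logs.
    """
    if not isinstance(model, ModelSpec):
        raise ConfigurationError("model must be a ModelSpec")
    traces: list[Timeseries] = []
    events: list[EventRecord] = []
    n_tirs = len(model.tirs)
    for run_id in range(config.n_runs):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed,
                                   spawn_key=(run_id,)))
        mult = ctl.draw_noise_multipliers(model.noise, n_tirs, rng)
        rt = _Runtime(model, mult)
        ts, ev = _run_one(rt, config, run_id)
        if ts is not None:
            traces.append(ts)
        events.extend(ev)
    return traces, events


def _run_one(rt: _Runtime, config: SimConfig, run_id: int):
    dt = config.dt
    n_steps = int(math.floor(config.duration / dt + 1e-9))
    record = config.record_timeseries
    ev: list[EventRecord] = []

    rec = _Recorder(rt, n_steps) if record else None
    if rec:
        rec.snapshot(rt, 0)

    steps_done = n_steps
    for n in range(n_steps):
        t0 = n * dt
        t1 = t0 + dt
        fired: list[tuple[float, object, Action]] = []

        # -- autonomous clocks
        for tir in rt.clocks:
            if tir.gate.open:
                x0 = tir.x
                tir.x = x0 + tir.omega_eff * dt
                for act in tir.actions:
                    if act.armed and detect_crossing(x0, tir.x, act.spec.tau):
                        act.armed = False
                        fired.append((crossing_time(t0, t1, x0, tir.x,
                                                    act.spec.tau), tir, act))

        # -- oscillator bank (single globally coupled bank)
        if rt.oscillators:
            _step_bank(rt.oscillators, dt)
            for osc in rt.oscillators:
                if detect_phase_trigger(osc):
                    t_star = trigger_time(osc, t0, t1)
                    for act in osc.actions:
                        if act.armed:
                            act.armed = False
                            fired.append((t_star, osc, act))

        # -- apply clock/oscillator actions in refined-time order
        fired.sort(key=lambda f: f[0])
        for t_star, host, act in fired:
            _apply_action(rt, host, act, t_star, run_id, ev)

        # -- feedback integrators: exact integration up to the settled
        #    horizon t0 (all switches <= t0 are final).  Each integrator's
        #    actions apply immediately so that causal chains declared in
        #    order see their upstream switches within the same step;
        #    crossings of two integrators racing on the same gate within
        #    one step resolve in declaration order (error <= dt).
        for tir in rt.integrators:
            if not tir.gate.open or tir.cursor >= t0:
                tir.cursor = max(tir.cursor, t0)
                continue
            if rt.source_is_plant(tir):
                src = rt.by_id[tir.spec.source]
                x0 = tir.x
                tir.x = x0 + tir.alpha_eff * max(src.x, 0.0) \
                    * (t0 - tir.cursor)
                hits = [(crossing_time(tir.cursor, t0, x0, tir.x,
                                       act.spec.tau), act)
                        for act in tir.actions
                        if act.armed and detect_crossing(x0, tir.x,
                                                         act.spec.tau)]
                for _, act in hits:
                    act.armed = False
            else:
                windows = rt.source_windows(tir, tir.cursor, t0)
                hits = tir.advance_exact(windows)
            tir.cursor = t0
            for t_star, act in hits:
                _apply_action(rt, tir, act, t_star, run_id, ev)

        # -- competitive selection (concept domain feeds the mu domain)
        for domain in (rt.concept_domain, rt.mu_domain):
            if domain is None or domain.complete:
                continue
            hit = domain.step(t0, dt)
            if hit is not None:
                t_star, winner = hit
                _apply_selection(rt, domain, winner, t_star, run_id, ev)

        # -- gestures follow their gates (single-step transition)
        for g in rt.gestures.values():
            g.g = step_gesture(g.gate)

        # -- optional plant
        if rt.tract_vars:
            active = {gid for gid, g in rt.gestures.items() if g.g >= 0.5}
            for tv in rt.tract_vars:
                step_tract_variable(tv, active, dt)

        # -- sanity: finite states
        for tir in rt.tirs:
            x = tir.phase if isinstance(tir, OscillatorTiR) else tir.x
            if not math.isfinite(x):
                raise NumericalInstabilityError(tir.spec.id, t1)

        if rec:
            rec.snapshot(rt, n + 1)

        if config.stop_when_quiescent and _quiescent(rt, t1):
            steps_done = n + 1
            break

    ts = rec.build(run_id, dt, steps_done) if rec else None
    ev.sort(key=lambda e: e.time)
    return ts, ev


def _step_bank(bank: list[OscillatorTiR], dt: float) -> None:
    """Euler step for the coupled bank, using precompiled coupling indices."""
    phases = [o.phase for o in bank]
    for k, osc in enumerate(bank):
        force = osc.omega_eff
        pk = phases[k]
        for j, strength in osc.coupling_idx:
            force += strength * math.sin(phases[j] - pk)
        osc.phase_prev = pk
        osc.phase = pk + force * dt
        target = 1.0 if osc.gate.open else 0.0
        wn = osc.amp_omega_n
        acc = wn * wn * (target - osc.rho) - 2.0 * wn * osc.rho_dot
        osc.rho_dot += dt * acc
        osc.rho = min(max(osc.rho + dt * osc.rho_dot, 0.0), 1.0)


def _apply_action(rt: _Runtime, host, act: Action, t: float, run_id: int,
                  ev: list[EventRecord]) -> None:
    ev.append(EventRecord(run_id, t, host.spec.id, "trigger"))
    target = rt.by_id.get(act.spec.target)
    if target is None:
        raise ConfigurationError(
            f"action of {host.spec.id!r} targets unknown system "
            f"{act.spec.target!r}")
    chi = act.spec.chi
    if isinstance(target, GesturalSystem):
        _set_gesture_gate(target, chi > 0, t, run_id, ev)
    elif isinstance(target, (AperiodicTiR, IntegratorTiR, OscillatorTiR)):
        _set_tir_gate(target, chi > 0, t, run_id, ev)
    elif isinstance(target, CompetitiveUnit):
        if chi < 0:
            _suppress_unit(rt, target, t, run_id, ev)
        else:
            if not target.gate.open:
                target.gate.open = True
                ev.append(EventRecord(run_id, t, target.spec.id, "gate_open"))
    else:
        raise ConfigurationError(
            f"action target {act.spec.target!r} is not gateable")


def _set_gesture_gate(g: GesturalSystem, open_: bool, t: float, run_id: int,
                      ev: list[EventRecord]) -> None:
    if open_ and not g.gate.open:
        g.gate.open = True
        g.switch_on(t)
        ev.append(EventRecord(run_id, t, g.id, "gate_open"))
        ev.append(EventRecord(run_id, t, g.id, "activation_on"))
    elif not open_ and g.gate.open:
        g.gate.open = False
        g.switch_off(t)
        ev.append(EventRecord(run_id, t, g.id, "gate_close"))
        ev.append(EventRecord(run_id, t, g.id, "activation_off"))


def _set_tir_gate(tir, open_: bool, t: float, run_id: int,
                  ev: list[EventRecord]) -> None:
    if open_ and not tir.gate.open:
        tir.gate.open = True
        ev.append(EventRecord(run_id, t, tir.spec.id, "gate_open"))
        if isinstance(tir, OscillatorTiR):
            tir.regate()
        else:
            tir.x = 0.0
            for a in tir.actions:
                a.armed = True
            if isinstance(tir, IntegratorTiR):
                tir.cursor = t
    elif not open_ and tir.gate.open:
        tir.gate.open = False
        ev.append(EventRecord(run_id, t, tir.spec.id, "gate_close"))


def _apply_selection(rt: _Runtime, domain: Domain, winner: CompetitiveUnit,
                     t: float, run_id: int, ev: list[EventRecord]) -> None:
    ev.append(EventRecord(run_id, t, winner.spec.id, "selected"))
    for u in domain.units:
        # Domain.step already closed the gates; log closures of competitors
        if u.state == "pending" or u is winner:
            ev.append(EventRecord(run_id, t, u.spec.id, "gate_close"))
    if hasattr(winner.spec, "members"):
        # concept system: de-gate exactly its member mu-systems
        for mu in rt.mu_of_concept[winner.spec.id]:
            if not mu.gate.open and mu.state == "pending":
                mu.gate.open = True
                ev.append(EventRecord(run_id, t, mu.spec.id, "gate_open"))
    else:
        for child_id in winner.spec.children:
            child = rt.by_id[child_id]
            _set_tir_gate(child, True, t, run_id, ev)


def _suppress_unit(rt: _Runtime, unit: CompetitiveUnit, t: float, run_id: int,
                   ev: list[EventRecord]) -> None:
    if unit.state != "selected":
        raise SelectionStateError(
            f"cannot suppress {unit.spec.id!r}: state is {unit.state!r}")
    unit.activation = 0.0
    unit.state = "retired"
    ev.append(EventRecord(run_id, t, unit.spec.id, "suppressed"))
    # disarm any remaining designated suppressors of this unit
    for tir in rt.tirs:
        for a in tir.actions:
            if a.spec.target == unit.spec.id and a.spec.chi == -1:
                a.armed = False
    # close the children gates; the episode is over
    if hasattr(unit.spec, "children"):
        for child_id in unit.spec.children:
            _set_tir_gate(rt.by_id[child_id], False, t, run_id, ev)
    # next competition round, within the unit's own competition set: a
    # mu-system competes only against its concept's other members
    if unit in rt.mu_units:
        parent = rt.concept_of_mu.get(unit.spec.id)
        sibs = (rt.mu_of_concept[parent] if parent is not None
                else rt.mu_domain.units)
    else:
        sibs = rt.concept_domain.units
    for sib in sibs:
        if sib.state == "pending" and not sib.gate.open:
            sib.gate.open = True
            ev.append(EventRecord(run_id, t, sib.spec.id, "gate_open"))
    # cascade: a concept retires when its last member mu retires
    cid = rt.concept_of_mu.get(unit.spec.id)
    if cid is not None:
        members = rt.mu_of_concept[cid]
        concept = rt.by_id[cid]
        if concept.state == "selected" and all(m.state == "retired"
                                               for m in members):
            _suppress_unit(rt, concept, t, run_id, ev)


def _quiescent(rt: _Runtime, now: float) -> bool:
    """Nothing active and nothing left that could still fire."""
    if any(g.gate.open for g in rt.gestures.values()):
        return False
    for dom in (rt.mu_domain, rt.concept_domain):
        if dom is not None and not dom.complete:
            return False
    for tir in rt.tirs:
        if not any(a.armed for a in tir.actions):
            continue
        if isinstance(tir, AperiodicTiR):
            if tir.gate.open:  # will keep growing and eventually fire
                return False
        elif isinstance(tir, OscillatorTiR):
            if tir.gate.open and not tir.triggered:
                return False
        else:
            if not tir.gate.open:
                continue
            src = rt.by_id[tir.spec.source]
            if isinstance(src, GesturalSystem):
                if src.active:
                    return False
                if src.intervals:
                    last_off = src.intervals[-1][1]
                    if last_off is not None and \
                            tir.cursor < last_off + tir.spec.delay:
                        return False
            else:
                return False
    return True


class _Recorder:
    """Preallocated grid traces for one run."""

    def __init__(self, rt: _Runtime, n_steps: int):
        n = n_steps + 1
        self.arrays: dict[str, dict[str, np.ndarray]] = {}
        for gid in rt.gestures:
            self.arrays[gid] = {"activation": np.zeros(n),
                                "gate": np.zeros(n)}
        for tir in rt.tirs:
            if isinstance(tir, OscillatorTiR):
                self.arrays[tir.spec.id] = {"phase": np.zeros(n),
                                            "amplitude": np.zeros(n)}
            else:
                self.arrays[tir.spec.id] = {"activation": np.zeros(n)}
        for u in rt.mu_units + rt.concept_units:
            self.arrays[u.spec.id] = {"activation": np.zeros(n)}
        for tv in rt.tract_vars:
            self.arrays[tv.spec.id] = {"position": np.zeros(n)}

    def snapshot(self, rt: _Runtime, row: int) -> None:
        a = self.arrays
        for gid, g in rt.gestures.items():
            a[gid]["activation"][row] = g.g
            a[gid]["gate"][row] = 1.0 if g.gate.open else 0.0
        for tir in rt.tirs:
            if isinstance(tir, OscillatorTiR):
                a[tir.spec.id]["phase"][row] = tir.wrapped_phase
                a[tir.spec.id]["amplitude"][row] = tir.rho
            else:
                a[tir.spec.id]["activation"][row] = tir.x
        for u in rt.mu_units + rt.concept_units:
            a[u.spec.id]["activation"][row] = u.activation
        for tv in rt.tract_vars:
            a[tv.spec.id]["position"][row] = tv.x
        self._rows = row + 1

    def build(self, run_id: int, dt: float, steps_done: int) -> Timeseries:
        n = steps_done + 1
        time = np.arange(n) * dt
        data = {sid: {var: arr[:n] for var, arr in vars_.items()}
                for sid, vars_ in self.arrays.items()}
        return Timeseries(run_id=run_id, time=time, data=data)
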