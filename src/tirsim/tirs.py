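"""Time-representing systems (TiRs).

A TiR represents elapsed time *indirectly*, in units of activation: it
integrates the forces it experiences and acts on gating systems when its
internal state crosses learned thresholds.  Five classes are provided:

================  =============================================================
``eps``           autonomous aperiodic clock; grows at rate ``omega`` while its
                  own gate is open
``theta``         autonomous periodic planning oscillator (phase, radial
                  amplitude, amplitude derivative), phase-coupled to peers;
                  triggers at a fixed phase when its amplitude is high enough
``T_int``         non-autonomous, integrates a gesture's activation directly
                  (internal / predictive feedback, inter-gestural)
``T_ext``         non-autonomous, integrates the CNS-external trace of a
                  gesture, i.e. its activation delayed by the sensory loop
                  time ``delay`` (external / sensory feedback)
``T_intra``       as ``T_int`` but confined to a single gesture: may only
                  source from and act on the gesture it belongs to
================  =============================================================

Every TiR carries a vector of actions (threshold ``tau``, sign ``chi``):
``chi=+1`` opens the target gate, ``chi=-1`` closes it (for competitively
selected units, ``+1`` de-gates and ``-1`` suppresses).  Actions are
one-shot per arming episode and re-arm only when the host TiR is re-gated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from ._core import ConfigurationError
from .systems import GatingSystem, _SETTLE_95

TiRClass = Literal["eps", "theta", "T_int", "T_ext", "T_intra"]

TWO_PI = 2.0 * math.pi


class ActionSpec(BaseModel):
    """One threshold-triggered action on a gating system.

    ``tau`` is in activation units of the host TiR; ``chi`` is +1 to open
    (de-gate) the target and -1 to close (or suppress) it.
    """

    model_config = ConfigDict(extra="forbid")

    target: str
    tau: float = Field(ge=0.0)
    chi: Literal[1, -1]


class TiRSpec(BaseModel):
    """Declarative description of one TiR."""

    model_config = ConfigDict(extra="forbid")

    id: str
    cls: TiRClass
    rate: Optional[float] = None      # omega (eps) or alpha' (integrators)
    freq_hz: Optional[float] = None   # theta only; None -> pace map
    source: Optional[str] = None      # integrators: gesture or plant id
    delay: float = Field(default=0.0, ge=0.0)  # T_ext sensory loop time
    actions: list[ActionSpec] = Field(default_factory=list)
    coupling: dict[str, float] = Field(default_factory=dict)  # theta only
    phase0: float = Field(default=0.0, ge=0.0, lt=TWO_PI)
    amp_threshold: float = Field(default=0.5, ge=0.0, le=1.0)
    amp_response_s: float = Field(default=0.05, gt=0.0)
    starts_open: bool = False
    modulated: bool = False           # attention-modulate alpha?
    beta: Optional[float] = None      # override class beta when modulated
    beta_scale: float = Field(default=1.0, gt=0.0)

    @model_validator(mode="after")
    def _check(self) -> "TiRSpec":
        if self.cls == "eps":
            if self.rate is None or self.rate <= 0:
                raise ValueError(f"TiR {self.id!r}: aperiodic clock needs a "
                                 "positive growth rate")
        elif self.cls == "theta":
            if self.freq_hz is not None and self.freq_hz <= 0:
                raise ValueError(f"TiR {self.id!r}: frequency must be positive")
            if self.id in self.coupling:
                raise ValueError(f"TiR {self.id!r}: self-coupling not allowed")
        else:
            if self.rate is None or self.rate <= 0:
                raise ValueError(f"TiR {self.id!r}: integrator needs a "
                                 "positive integration rate")
            if self.source is None:
                raise ValueError(f"TiR {self.id!r}: integrator needs a source")
            if self.coupling:
                raise ValueError(f"TiR {self.id!r}: only oscillators couple")
        if self.cls != "T_ext" and self.delay != 0.0:
            raise ValueError(f"TiR {self.id!r}: only external-feedback TiRs "
                             "have a sensory delay")
        return self


@dataclass
class Action:
    spec: ActionSpec
    armed: bool = True


@dataclass
class AperiodicTiR:
    """Autonomous clock: x grows at ``omega_eff`` while gated open."""

    spec: TiRSpec
    omega_eff: float
    x: float = 0.0
    gate: GatingSystem = None  # type: ignore[assignment]
    actions: list[Action] = field(default_factory=list)

    def __post_init__(self):
        if self.gate is None:
            self.gate = GatingSystem(self.spec.id + ".gate",
                                     open=self.spec.starts_open)
        self.actions = [Action(a) for a in self.spec.actions]


@dataclass
class IntegratorTiR:
    """Non-autonomous TiR integrating a (possibly delayed) source trace."""

    spec: TiRSpec
    alpha_eff: float
    x: float = 0.0
    gate: GatingSystem = None  # type: ignore[assignment]
    actions: list[Action] = field(default_factory=list)

    def __post_init__(self):
        if self.gate is None:
            self.gate = GatingSystem(self.spec.id + ".gate",
                                     open=self.spec.starts_open)
        self.actions = [Action(a) for a in self.spec.actions]

    def advance_exact(self, windows: list[tuple[float, float]]
                      ) -> list[tuple[float, Action]]:
        """Integrate the binary source over refined active sub-intervals.

        ``windows`` are (start, end) times during which the source trace is
        1 within the current integration window.  Returns (exact crossing
        time, action) pairs for every armed action crossed, since growth is
        piecewise linear in time.
        """
        fired = []
        for a, b in windows:
            x0 = self.x
            self.x = x0 + self.alpha_eff * (b - a)
            for act in self.actions:
                if act.armed and x0 < act.spec.tau <= self.x:
                    t_star = a + (act.spec.tau - x0) / self.alpha_eff
                    act.armed = False
                    fired.append((t_star, act))
        return fired


@dataclass
class OscillatorTiR:
    """Periodic planning oscillator with gated amplitude dynamics.

    Phase advances continuously (unwrapped); the radial amplitude relaxes
    (critically damped) toward 1 while the oscillator's gate is open and
    toward 0 while closed.  The oscillator triggers its actions when its
    phase crosses the trigger phase (0 mod 2*pi, the conventional peak of
    cos) *and* its amplitude exceeds ``amp_threshold`` -- at most once per
    gate-open episode.
    """

    spec: TiRSpec
    omega_eff: float           # rad/s
    phase: float = 0.0         # unwrapped
    phase_prev: float = 0.0
    rho: float = 0.0
    rho_dot: float = 0.0
    gate: GatingSystem = None  # type: ignore[assignment]
    actions: list[Action] = field(default_factory=list)
    next_trigger: float = TWO_PI
    triggered: bool = False    # this gate-open episode

    def __post_init__(self):
        if self.gate is None:
            self.gate = GatingSystem(self.spec.id + ".gate",
                                     open=self.spec.starts_open)
        self.actions = [Action(a) for a in self.spec.actions]
        self.phase = self.phase_prev = self.spec.phase0
        self.amp_omega_n = _SETTLE_95 / self.spec.amp_response_s

    def regate(self) -> None:
        """Reset to the start of a new triggering episode."""
        self.phase = self.phase_prev = self.spec.phase0
        self.next_trigger = TWO_PI
        self.triggered = False
        for act in self.actions:
            act.armed = True

    @property
    def wrapped_phase(self) -> float:
        return self.phase % TWO_PI


def step_aperiodic(tir: AperiodicTiR, dt: float) -> float:
    """Advance an autonomous clock one step; frozen while its gate is closed."""
    if tir.gate.open:
        tir.x += tir.omega_eff * dt
    return tir.x


def step_integrator(tir: IntegratorTiR, input_force: float, dt: float) -> float:
    """Advance an integrator one step under a constant input force."""
    if input_force < 0:
        raise ValueError("input force must be non-negative")
    if tir.gate.open:
        tir.x += tir.alpha_eff * input_force * dt
    return tir.x


def sensory_trace(g: np.ndarray, d: float, dt: float) -> np.ndarray:
    """Delay an activation history by the sensory loop time ``d``.

    ``out[t] = g[t - d]``, zero before the delayed signal exists.  This is
    the sampled-trace counterpart of the exact interval shift the engine
    uses internally.
    """
    if d < 0:
        raise ValueError("delay must be non-negative")
    g = np.asarray(g, dtype=float)
    shift = int(round(d / dt))
    if shift == 0:
        return g.copy()
    out = np.zeros_like(g)
    if shift < len(g):
        out[shift:] = g[:len(g) - shift]
    return out


def step_oscillators(bank: list[OscillatorTiR], dt: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Advance a coupled oscillator bank one Euler step.

    Phase velocity of oscillator i is ``omega_i + sum_j K_ij sin(theta_j -
    theta_i)``: positive coupling attracts toward in-phase, negative repels
    toward anti-phase (first Fourier mode only).  Amplitudes follow
    critically damped second-order dynamics toward 1 (gate open) or 0.
    """
    idx = {o.spec.id: k for k, o in enumerate(bank)}
    phases = np.array([o.phase for o in bank])
    dphi = np.empty(len(bank))
    for k, osc in enumerate(bank):
        force = osc.omega_eff
        for other, strength in osc.spec.coupling.items():
            j = idx.get(other)
            if j is None:
                raise ConfigurationError(
                    f"oscillator {osc.spec.id!r} couples to unknown "
                    f"oscillator {other!r}")
            force += strength * math.sin(phases[j] - phases[k])
        dphi[k] = force
    for k, osc in enumerate(bank):
        osc.phase_prev = osc.phase
        osc.phase = phases[k] + dphi[k] * dt
        target = 1.0 if osc.gate.open else 0.0
        wn = osc.amp_omega_n
        acc = wn * wn * (target - osc.rho) - 2.0 * wn * osc.rho_dot
        osc.rho_dot += dt * acc
        osc.rho = min(max(osc.rho + dt * osc.rho_dot, 0.0), 1.0)
    return (np.array([o.phase for o in bank]),
            np.array([o.rho for o in bank]))


def detect_phase_trigger(osc: OscillatorTiR) -> bool:
    """Did the oscillator trigger on the step just taken?

    Fires iff the unwrapped phase crossed the next trigger phase while the
    amplitude was at or above threshold, the gate open, and no trigger has
    occurred this episode.  A sub-threshold crossing is consumed silently
    (the opportunity moves to the next cycle).
    """
    while osc.phase_prev < osc.next_trigger <= osc.phase:
        ready = (osc.gate.open and not osc.triggered
                 and osc.rho >= osc.spec.amp_threshold)
        if ready:
            osc.triggered = True
            return True
        osc.next_trigger += TWO_PI
    return False


def trigger_time(osc: OscillatorTiR, t_prev: float, t_curr: float) -> float:
    """Interpolated time of the phase crossing found by detect_phase_trigger."""
    span = osc.phase - osc.phase_prev
    # next_trigger has not advanced past the fired crossing
    frac = (osc.next_trigger - osc.phase_prev) / span if span else 1.0
    return t_prev + (t_curr - t_prev) * frac
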