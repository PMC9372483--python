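"""Gestural systems, their binary gates, and an optional tract-variable plant.

A *gestural system* is a control system, not a movement: its activation
``g`` is normalized to [0, 1] and switches in a single time step when its
gating system opens or closes.  Gestures never decide their own timing --
time-representing systems (see :mod:`tirsim.tirs`) act on the gates.

The optional :class:`TractVariable` plant turns activation intervals into
smooth movement traces (a critically damped point attractor), purely for
visualization and for the optional transduced-signal feedback route; it has
no influence on timing unless an external TiR is explicitly sourced from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field

from ._core import ConfigurationError

Role = Literal["C", "R", "V", "c", "r"]


class GestureSpec(BaseModel):
    """Declarative description of a gestural system.

    ``role`` uses the split-gesture labeling convention: C/R are the
    pre-vocalic constriction and release, V the vocalic gesture, c/r the
    post-vocalic (coda) constriction and release.
    """

    model_config = ConfigDict(extra="forbid")

    id: str
    role: Optional[Role] = None
    word: Optional[str] = None


class TractVariableSpec(BaseModel):
    """A one-dimensional vocal-tract variable driven by gestures.

    ``targets`` maps driving gesture ids to the equilibrium position each
    gesture pulls the variable toward.  ``response_s`` is the 95%-settling
    time of the critically damped response.
    """

    model_config = ConfigDict(extra="forbid")

    id: str
    targets: dict[str, float]
    response_s: float = Field(default=0.15, gt=0.0)
    x0: float = 0.0
    max_drivers: int = Field(default=4, ge=1)


@dataclass
class GatingSystem:
    """Binary gate interposed between TiRs and a gesture (or oscillator)."""

    id: str
    open: bool = False


@dataclass
class GesturalSystem:
    """Runtime state of a gestural system.

    Besides the binary grid activation, the gesture keeps the *refined*
    on/off times of its activation intervals.  Integrating TiRs consume the
    refined intervals so that feedback timing is exact rather than quantized
    to the simulation grid.
    """

    id: str
    role: Optional[str] = None
    word: Optional[str] = None
    g: float = 0.0
    gate: GatingSystem = None  # type: ignore[assignment]
    # closed intervals [(on, off)], current open interval has off=None
    intervals: list[tuple[float, Optional[float]]] = field(default_factory=list)

    def __post_init__(self):
        if self.gate is None:
            self.gate = GatingSystem(id=self.id + ".gate")

    def switch_on(self, t: float) -> None:
        self.intervals.append((t, None))

    def switch_off(self, t: float) -> None:
        on, off = self.intervals[-1]
        assert off is None
        self.intervals[-1] = (on, t)

    @property
    def active(self) -> bool:
        return bool(self.intervals) and self.intervals[-1][1] is None


def step_gesture(gate: GatingSystem) -> float:
    """Activation implied by the gate: 1 when open, 0 when closed.

    Transitions take effect on the step after the gate changes, which the
    engine realizes by calling this at the end of each step.
    """
    return 1.0 if gate.open else 0.0


def active_overlap(intervals: list[tuple[float, Optional[float]]],
                   a: float, b: float, delay: float = 0.0
                   ) -> list[tuple[float, float]]:
    """Sub-intervals of [a, b) during which the (optionally delayed)
    activation trace is 1.  Used by integrating TiRs for exact integration.
    """
    out = []
    for on, off in intervals:
        lo = max(a, on + delay)
        hi = b if off is None else min(b, off + delay)
        if hi > lo:
            out.append((lo, hi))
    return out


# critically damped settling: 1-(1+w*t)exp(-w*t) = 0.95  at  w*t = 4.7439
_SETTLE_95 = 4.743865515


@dataclass
class TractVariable:
    """Critically damped point attractor driven by active gestures.

    While driven, the position relaxes toward the mean of the active
    gestures' targets with no overshoot; while undriven it holds position.
    Positions therefore stay inside the convex hull of the initial condition
    and the targets.
    """

    spec: TractVariableSpec
    x: float = 0.0
    v: float = 0.0

    def __post_init__(self):
        self.x = self.spec.x0
        # natural frequency chosen so 95% of a step is settled in response_s
        self.omega_n = _SETTLE_95 / self.spec.response_s


def step_tract_variable(tv: TractVariable, active_gestures: set[str],
                        dt: float) -> float:
    """Advance the plant one Euler step and return the new position.

    ``active_gestures`` is the set of currently active gesture ids; only
    those appearing in the plant's target map drive it.  Multiple drivers
    are blended by averaging their targets.
    """
    drivers = [gid for gid in tv.spec.targets if gid in active_gestures]
    if len(drivers) > tv.spec.max_drivers:
        raise ConfigurationError(
            f"tract variable {tv.spec.id!r}: {len(drivers)} simultaneous "
            f"drivers exceeds max_drivers={tv.spec.max_drivers}"
        )
    if not drivers:
        tv.v = 0.0
        return tv.x
    target = sum(tv.spec.targets[g] for g in drivers) / len(drivers)
    wn = tv.omega_n
    acc = wn * wn * (target - tv.x) - 2.0 * wn * tv.v
    tv.v += dt * acc
    tv.x += dt * tv.v
    return tv.x
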