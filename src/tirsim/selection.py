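"""Competitive selection of planning units in two parallel domains.

Serial order is encoded in an initial activation *gradient*: units that are
de-gated grow linearly at a common rate, the first to reach the selection
threshold is *selected* (mutually exclusive -- all sibling gates close),
and the selected unit is later *suppressed* (activation reset to zero) by
feedback, i.e. by the designated TiR of the last gesture in its set.
Suppression re-opens the gates of the not-yet-selected siblings and the
next round begins, until every unit has been selected and suppressed.

Two domains exist in parallel: gestural-motoric mu-systems (syllable-sized
sets of co-selected gestures) and conceptual-syntactic concept systems
(roughly phonological words).  Selecting a concept system de-gates exactly
its member mu-systems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field

from ._core import SelectionStateError
from .systems import GatingSystem

logger = logging.getLogger(__name__)


class MuSpec(BaseModel):
    """A competitively selected set of co-selected gestures.

    ``children`` are gate ids de-gated on selection (typically the
    syllable's oscillator bank and any feedback TiRs); ``gestures`` are the
    member gesture ids (used for word-final boosts and interval analysis);
    ``suppressors`` names the TiRs whose designated action suppresses this
    unit, for documentation and validation -- the wiring itself is the
    TiR's action with ``chi=-1`` targeting this mu id.
    """

    model_config = ConfigDict(extra="forbid")

    id: str
    gradient: float = Field(ge=0.0)
    children: list[str] = Field(default_factory=list)
    gestures: list[str] = Field(default_factory=list)
    suppressors: list[str] = Field(default_factory=list)
    word: Optional[str] = None
    position: int = 0
    threshold: float = Field(default=1.0, gt=0.0)
    growth_rate: float = Field(default=1.0, gt=0.0)


class ConceptSpec(BaseModel):
    """A competitively selected unit of the conceptual-syntactic domain."""

    model_config = ConfigDict(extra="forbid")

    id: str
    gradient: float = Field(ge=0.0)
    members: list[str] = Field(default_factory=list)  # mu ids it de-gates
    threshold: float = Field(default=1.0, gt=0.0)
    growth_rate: float = Field(default=1.0, gt=0.0)


@dataclass
class CompetitiveUnit:
    """Runtime state of a mu- or concept system."""

    spec: MuSpec | ConceptSpec
    activation: float = 0.0
    gate: GatingSystem = None  # type: ignore[assignment]
    state: str = "pending"     # pending -> selected -> retired

    def __post_init__(self):
        self.activation = self.spec.gradient
        if self.gate is None:
            self.gate = GatingSystem(self.spec.id + ".gate")


@dataclass
class SelectionState:
    """Snapshot of a domain: who is selected, how many remain."""

    selected: Optional[str]
    remaining: int


def step_competition(units: list[CompetitiveUnit], dt: float) -> list[float]:
    """Grow activations of de-gated, pending units by one step.

    Gated (or selected/retired) units are frozen.  Returns the new
    activations in unit order.
    """
    for u in units:
        if u.gate.open and u.state == "pending":
            u.activation += u.spec.growth_rate * dt
    return [u.activation for u in units]


def select(unit: CompetitiveUnit, siblings: list[CompetitiveUnit]) -> None:
    """Mark ``unit`` selected: pin it at threshold and close every gate in
    the domain (including its own), halting all activation growth.

    Sibling activations must already reflect the exact selection time; the
    engine-facing :class:`Domain` takes care of that rolling.
    """
    unit.activation = unit.spec.threshold
    unit.state = "selected"
    for sib in siblings:
        sib.gate.open = False


def suppress(unit: CompetitiveUnit, siblings: list[CompetitiveUnit]) -> bool:
    """Suppress the selected ``unit``: reset to zero, retire, re-open siblings.

    Returns True when the domain is complete (every unit retired).
    Suppressing a unit that is not currently selected is a state error.
    """
    if unit.state != "selected":
        raise SelectionStateError(
            f"cannot suppress {unit.spec.id!r}: state is {unit.state!r}")
    unit.activation = 0.0
    unit.state = "retired"
    for sib in siblings:
        if sib.state == "pending":
            sib.gate.open = True
    return all(u.state == "retired" for u in siblings)


class Domain:
    """One competitive-selection domain driven by the engine clock.

    The engine calls :meth:`step` once per time step; the domain reports
    selection events with sub-step (refined) times, which are exact because
    growth is linear between gate changes.
    """

    def __init__(self, units: list[CompetitiveUnit], name: str):
        self.units = units
        self.name = name

    @property
    def complete(self) -> bool:
        return all(u.state == "retired" for u in self.units)

    @property
    def busy(self) -> bool:
        return any(u.state == "selected" for u in self.units)

    def state(self) -> SelectionState:
        sel = next((u.spec.id for u in self.units if u.state == "selected"),
                   None)
        remaining = sum(1 for u in self.units if u.state != "retired")
        return SelectionState(selected=sel, remaining=remaining)

    def step(self, t0: float, dt: float
             ) -> Optional[tuple[float, CompetitiveUnit]]:
        """Advance one step; return (refined time, winner) on selection."""
        if self.busy:
            return None
        growers = [u for u in self.units
                   if u.gate.open and u.state == "pending"]
        if not growers:
            return None
        # earliest threshold crossing within this step, refined
        best: Optional[tuple[float, int, CompetitiveUnit]] = None
        for i, u in enumerate(growers):
            x1 = u.activation + u.spec.growth_rate * dt
            at_threshold = u.activation >= u.spec.threshold
            if at_threshold or u.activation < u.spec.threshold <= x1:
                # a unit frozen at threshold by an exact tie crosses
                # immediately when re-de-gated
                t_star = t0 if at_threshold else \
                    t0 + (u.spec.threshold - u.activation) \
                    / u.spec.growth_rate
                if best is None or t_star < best[0] - 1e-15:
                    best = (t_star, i, u)
                elif abs(t_star - best[0]) <= 1e-15:
                    logger.warning(
                        "selection tie between %r and %r at t=%.6f; "
                        "lowest index wins", best[2].spec.id, u.spec.id, t_star)
        if best is None:
            step_competition(self.units, dt)
            return None
        t_star, _, winner = best
        # freeze siblings at their exact value at the selection time
        for u in growers:
            if u is not winner:
                u.activation += u.spec.growth_rate * (t_star - t0)
        select(winner, self.units)
        return t_star, winner
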