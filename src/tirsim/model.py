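"""Full model specification: inventory, topology, parameters.

A :class:`ModelSpec` is a JSON-compatible, schema-validated description of
one simulated system: gestural systems, the TiRs that act on their gates,
optional competitive-selection units (mu/concept domains), optional
tract-variable plants, the context modulation state, and the noise model.
Cross-references are validated up front so that a dangling target or
source fails before any simulation starts.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from ._core import ConfigurationError
from .control import ModulationState, NoiseSpec
from .selection import ConceptSpec, MuSpec
from .systems import GestureSpec, TractVariableSpec
from .tirs import TiRSpec


class ModelSpec(BaseModel):
    """A complete, validated model ready for simulation."""

    model_config = ConfigDict(extra="forbid")

    name: str = "model"
    gestures: list[GestureSpec] = Field(default_factory=list)
    tirs: list[TiRSpec] = Field(default_factory=list)
    mus: list[MuSpec] = Field(default_factory=list)
    concepts: list[ConceptSpec] = Field(default_factory=list)
    tract_variables: list[TractVariableSpec] = Field(default_factory=list)
    modulation: ModulationState = Field(default_factory=ModulationState)
    noise: NoiseSpec = Field(default_factory=NoiseSpec)

    @model_validator(mode="after")
    def _check_refs(self) -> "ModelSpec":
        gids = {g.id for g in self.gestures}
        tids = {t.id for t in self.tirs}
        mids = {m.id for m in self.mus}
        cids = {c.id for c in self.concepts}
        vids = {v.id for v in self.tract_variables}
        all_ids = [g.id for g in self.gestures] + [t.id for t in self.tirs] \
            + [m.id for m in self.mus] + [c.id for c in self.concepts] \
            + [v.id for v in self.tract_variables]
        dup = {i for i in all_ids if all_ids.count(i) > 1}
        if dup:
            raise ValueError(f"duplicate system ids: {sorted(dup)}")

        theta_ids = {t.id for t in self.tirs if t.cls == "theta"}
        for tir in self.tirs:
            if tir.source is not None and tir.source not in gids | vids:
                raise ValueError(
                    f"TiR {tir.id!r} sources unknown system {tir.source!r}")
            for act in tir.actions:
                if act.target not in gids | tids | mids:
                    raise ValueError(
                        f"TiR {tir.id!r} action targets unknown system "
                        f"{act.target!r}")
            if tir.cls == "T_intra":
                bad = [a.target for a in tir.actions if a.target != tir.source]
                if bad:
                    raise ValueError(
                        f"intra-gestural TiR {tir.id!r} may only act on its "
                        f"own gesture {tir.source!r}, not {bad}")
            for other in tir.coupling:
                if other not in theta_ids:
                    raise ValueError(
                        f"oscillator {tir.id!r} couples to {other!r}, which "
                        "is not an oscillator")

        for mu in self.mus:
            for child in mu.children:
                if child in mids or child in cids:
                    raise ValueError(
                        f"mu-system {mu.id!r} de-gates {child!r}: selection "
                        "units may not nest (exactly two domains)")
                if child not in tids:
                    raise ValueError(
                        f"mu-system {mu.id!r} de-gates unknown TiR {child!r}")
            for gid in mu.gestures:
                if gid not in gids:
                    raise ValueError(
                        f"mu-system {mu.id!r} lists unknown gesture {gid!r}")
            for sup in mu.suppressors:
                tir = next((t for t in self.tirs if t.id == sup), None)
                if tir is None:
                    raise ValueError(
                        f"mu-system {mu.id!r} names unknown suppressor {sup!r}")
                if not any(a.target == mu.id and a.chi == -1
                           for a in tir.actions):
                    raise ValueError(
                        f"suppressor {sup!r} of {mu.id!r} has no chi=-1 "
                        "action targeting it")

        for con in self.concepts:
            for member in con.members:
                if member in cids:
                    raise ValueError(
                        f"concept {con.id!r} contains concept {member!r}: "
                        "selection units may not nest (exactly two domains)")
                if member not in mids:
                    raise ValueError(
                        f"concept {con.id!r} lists unknown mu-system "
                        f"{member!r}")

        for tv in self.tract_variables:
            for gid in tv.targets:
                if gid not in gids:
                    raise ValueError(
                        f"tract variable {tv.id!r} driven by unknown gesture "
                        f"{gid!r}")
        return self

    def system_ids(self) -> set[str]:
        return ({g.id for g in self.gestures} | {t.id for t in self.tirs}
                | {m.id for m in self.mus} | {c.id for c in self.concepts}
                | {v.id for v in self.tract_variables})


def validate_model(model: ModelSpec) -> ModelSpec:
    """Re-run cross-reference validation, mapping failures to
    :class:`ConfigurationError` (the engine-facing error type)."""
    try:
        return ModelSpec.model_validate(model.model_dump())
    except ValueError as exc:
        raise ConfigurationError(str(exc)) from exc
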