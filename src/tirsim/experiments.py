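"""Model zoo and simulation experiments.

The zoo holds ready-made model configurations for the canonical
demonstrations of the framework: single-gesture timing with autonomous
clocks and feedback integrators, coupled-oscillator triggering and
symmetric displacement, the six three-gesture control topologies whose
interval correlations diagnose control structure under global vs. local
noise, the hybrid CVC syllable (oscillator-governed pre-vocalic timing,
feedback-governed post-vocalic timing), competitively selected syllable
sequences, and the attention/pace rate-control utterance.

Analysis helpers extract initiation intervals from event logs, compute
Pearson correlations of successive intervals across Monte-Carlo runs
(delta-correlations), sweep noise grids, and sweep the rate-control
parameter lambda.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._core import ConfigurationError
from .control import apply_final_position_boost
from .engine import EventRecord, SimConfig, run_simulation
from .model import ModelSpec

PI = math.pi

_CAL_CACHE: Optional[dict] = None


def calibration() -> dict:
    """Shipped default calibration constants (read from package data)."""
    global _CAL_CACHE
    if _CAL_CACHE is None:
        ref = resources.files("tirsim").joinpath("data/hybrid_default.json")
        _CAL_CACHE = json.loads(ref.read_text())
    return _CAL_CACHE


# --------------------------------------------------------------------------
# syllable assembly for the hybrid control model

def _phase_lag(attract: float, repel: float) -> float:
    """Steady-state displacement of the C/R oscillators about V.

    For sine coupling with C-R repulsion ``b`` and C-V / R-V attraction
    ``a`` the symmetric fixed point satisfies cos(phi) = a / (2 b).
    """
    return math.acos(attract / (2.0 * repel))


def _syllable(sfx: str, template: str, word: Optional[str],
              mu_id: Optional[str], cal: dict) -> tuple[list, list]:
    """Gestures and TiRs for one syllable of the hybrid control model.

    Pre-vocalic gestures (C, R, V initiations) are oscillator-triggered;
    vocalic deactivation and post-vocalic gestures are governed by an
    internal/external feedback TiR pair.  When ``mu_id`` is given, the
    designated TiR pair of the final gesture also suppresses the mu-system.
    """
    if template not in ("CV", "CVC"):
        raise ConfigurationError(f"unknown syllable template {template!r}")
    coupling = cal["coupling"]
    osc = cal["oscillator"]
    fb = cal["feedback"]
    phi = _phase_lag(coupling["attract"], coupling["repel"])
    base = osc["base_phase"]
    a, b = coupling["attract"], coupling["repel"]
    standalone = mu_id is None

    C, R, V = f"C{sfx}", f"R{sfx}", f"V{sfx}"
    gestures = [
        {"id": C, "role": "C", "word": word},
        {"id": R, "role": "R", "word": word},
        {"id": V, "role": "V", "word": word},
    ]
    oscs = []
    for gid, phase0, coup in (
            (C, base + phi, {f"osc_{V}": a, f"osc_{R}": -b}),
            (V, base, {f"osc_{C}": a, f"osc_{R}": a}),
            (R, base - phi, {f"osc_{V}": a, f"osc_{C}": -b})):
        oscs.append({
            "id": f"osc_{gid}", "cls": "theta", "coupling": coup,
            "phase0": phase0, "amp_threshold": osc["amp_threshold"],
            "amp_response_s": osc["amp_response_s"],
            "starts_open": standalone,
            "actions": [{"target": gid, "tau": 0.0, "chi": 1}],
        })

    tau_o, tau_c = fb["tau_open"], fb["tau_close"]
    tirs = list(oscs)
    suppress = ([] if mu_id is None
                else [{"target": mu_id, "tau": None, "chi": -1}])

    def pair(src, acts, alpha_int, alpha_ext):
        tirs.append({"id": f"t_{src}_int", "cls": "T_int", "source": src,
                     "rate": alpha_int, "modulated": True,
                     "starts_open": True, "actions": acts})
        tirs.append({"id": f"t_{src}_ext", "cls": "T_ext", "source": src,
                     "rate": alpha_ext, "modulated": True,
                     "delay": fb["delay_s"], "starts_open": True,
                     "actions": [dict(a) for a in acts]})

    if template == "CVC":
        c, r = f"c{sfx}", f"r{sfx}"
        gestures += [{"id": c, "role": "c", "word": word},
                     {"id": r, "role": "r", "word": word}]
        pair(V, [{"target": c, "tau": tau_o, "chi": 1},
                 {"target": V, "tau": tau_c, "chi": -1}],
             fb["alpha_int_pair"], fb["alpha_ext_pair"])
        pair(c, [{"target": r, "tau": tau_o, "chi": 1},
                 {"target": c, "tau": tau_c, "chi": -1}],
             fb["alpha_int_pair"], fb["alpha_ext_pair"])
        final_acts = [{"target": r, "tau": fb["tau_final"], "chi": -1}]
        for s in suppress:
            final_acts.append({**s, "tau": fb["tau_final"]})
        pair(r, final_acts, fb["alpha_int_final"], fb["alpha_ext_final"])
    else:  # CV: the vowel is the final gesture of the set
        final_acts = [{"target": V, "tau": tau_c, "chi": -1}]
        for s in suppress:
            final_acts.append({**s, "tau": tau_c})
        pair(V, final_acts, fb["alpha_int_pair"], fb["alpha_ext_pair"])

    # pre-vocalic gesture durations (internal feedback, self-terminating)
    tirs.append({"id": f"t_{C}_dur", "cls": "T_int", "source": C,
                 "rate": fb["alpha_int_C"], "modulated": True,
                 "starts_open": True,
                 "actions": [{"target": C, "tau": tau_o, "chi": -1}]})
    tirs.append({"id": f"t_{R}_dur", "cls": "T_int", "source": R,
                 "rate": fb["alpha_int_R"], "modulated": True,
                 "starts_open": True,
                 "actions": [{"target": R, "tau": tau_o, "chi": -1}]})
    return gestures, tirs


def _utterance(syllables: Sequence[tuple[str, Optional[str]]],
               cal: dict, concepts: Optional[list[list[int]]] = None,
               lam: float = 0.5) -> ModelSpec:
    """Compile syllable templates into a competitively selected utterance.

    ``syllables`` is a sequence of (template, word_id); ``concepts``
    optionally groups syllable indices into concept systems (phonological
    words of the conceptual-syntactic domain).
    """
    gestures, tirs, mus = [], [], []
    n = len(syllables)
    if concepts is None:
        grads = _gradient(n)
        for i, (tpl, word) in enumerate(syllables):
            mu_id = f"mu{i + 1}"
            g, t = _syllable(str(i + 1), tpl, word, mu_id, cal)
            gestures += g
            tirs += t
            mus.append({
                "id": mu_id, "gradient": grads[i], "word": word,
                "position": i,
                "children": [x["id"] for x in t if x["cls"] == "theta"],
                "gestures": [x["id"] for x in g],
                "suppressors": _suppressor_ids(t, mu_id),
            })
        concept_specs = []
    else:
        concept_specs = []
        cgrads = _gradient(len(concepts))
        for w, members in enumerate(concepts):
            word = f"w{w + 1}"
            grads = _gradient(len(members))
            mu_ids = []
            for k, i in enumerate(members):
                tpl, _ = syllables[i]
                mu_id = f"mu{i + 1}"
                g, t = _syllable(str(i + 1), tpl, word, mu_id, cal)
                gestures += g
                tirs += t
                mus.append({
                    "id": mu_id, "gradient": grads[k], "word": word,
                    "position": k,
                    "children": [x["id"] for x in t if x["cls"] == "theta"],
                    "gestures": [x["id"] for x in g],
                    "suppressors": _suppressor_ids(t, mu_id),
                })
                mu_ids.append(mu_id)
            concept_specs.append({"id": f"con_{word}",
                                  "gradient": cgrads[w],
                                  "members": mu_ids})
    modulation = dict(cal["modulation"])
    modulation["lambda_attention"] = lam
    modulation["lambda_pace"] = lam
    return ModelSpec(gestures=gestures, tirs=tirs, mus=mus,
                     concepts=concept_specs, modulation=modulation)


def _gradient(n: int) -> list[float]:
    """Default initial-activation gradient: earlier units start higher."""
    if n == 1:
        return [0.9]
    return list(np.linspace(0.9, 0.3, n))


def _suppressor_ids(tirs: list[dict], mu_id: str) -> list[str]:
    return [t["id"] for t in tirs
            if any(a["target"] == mu_id and a["chi"] == -1
                   for a in t["actions"])]


# --------------------------------------------------------------------------
# model zoo builders

def _build_fig5(cal: dict, lam: float) -> ModelSpec:
    """Two gestures: utterance-initial clock opens both, an autonomous clock
    closes g1, an internal integrator closes g2 at tau = 0.25 (elapsed-time
    parameterization: rates of 1 make activation equal elapsed seconds)."""
    return ModelSpec(
        name="fig5",
        gestures=[{"id": "g1"}, {"id": "g2"}],
        tirs=[
            {"id": "eps_prime", "cls": "eps", "rate": 1.0,
             "starts_open": True,
             "actions": [{"target": "g1", "tau": 0.10, "chi": 1},
                         {"target": "g2", "tau": 0.15, "chi": 1}]},
            {"id": "eps_1", "cls": "eps", "rate": 1.0, "starts_open": True,
             "actions": [{"target": "g1", "tau": 0.50, "chi": -1}]},
            {"id": "T2_int", "cls": "T_int", "source": "g2", "rate": 1.0,
             "starts_open": True,
             "actions": [{"target": "g2", "tau": 0.25, "chi": -1}]},
        ])


def _build_fig6(cal: dict, lam: float) -> ModelSpec:
    """Internal vs. external feedback sources: an intra-gestural TiR closes
    g1, an inter-gestural internal TiR opens g2, and an external TiR
    (delayed trace) closes g2."""
    return ModelSpec(
        name="fig6",
        gestures=[{"id": "g1"}, {"id": "g2"}],
        tirs=[
            {"id": "eps_prime", "cls": "eps", "rate": 1.0,
             "starts_open": True,
             "actions": [{"target": "g1", "tau": 0.10, "chi": 1}]},
            {"id": "T1_intra", "cls": "T_intra", "source": "g1", "rate": 1.0,
             "starts_open": True,
             "actions": [{"target": "g1", "tau": 0.30, "chi": -1}]},
            {"id": "T1_int", "cls": "T_int", "source": "g1", "rate": 1.0,
             "starts_open": True,
             "actions": [{"target": "g2", "tau": 0.15, "chi": 1}]},
            {"id": "T2_ext", "cls": "T_ext", "source": "g2", "rate": 1.0,
             "delay": 0.1, "starts_open": True,
             "actions": [{"target": "g2", "tau": 0.20, "chi": -1}]},
        ])


def _build_fig7(cal: dict, lam: float) -> ModelSpec:
    """Three coupled planning oscillators: theta1/theta3 repulsively
    coupled, both attractively coupled to theta2, so g1 and g3 initiations
    are symmetrically displaced about g2's.  theta1 starts slightly off the
    fixed point to exercise convergence."""
    f8 = cal["fig8"]
    a, b, f = f8["osc_attract"], f8["osc_repel"], f8["osc_freq_hz"]
    phi = _phase_lag(a, b)
    oscs = []
    for k, (phase0, coup) in enumerate((
            (PI + phi + 0.15, {"osc2": a, "osc3": -b}),
            (PI, {"osc1": a, "osc3": a}),
            (PI - phi, {"osc2": a, "osc1": -b}))):
        oscs.append({"id": f"osc{k + 1}", "cls": "theta",
                     "freq_hz": f, "coupling": coup, "phase0": phase0,
                     "starts_open": True,
                     "actions": [{"target": f"g{k + 1}", "tau": 0.0,
                                  "chi": 1}]})
    closers = [{"id": f"t{k}_close", "cls": "T_int", "source": f"g{k}",
                "rate": 1.0, "starts_open": True,
                "actions": [{"target": f"g{k}", "tau": f8["close_tau"],
                             "chi": -1}]} for k in (1, 2, 3)]
    return ModelSpec(name="fig7",
                     gestures=[{"id": f"g{k}"} for k in (1, 2, 3)],
                     tirs=oscs + closers)


def _fig8_frame(cal: dict, extra_tirs: list[dict],
                with_starter: bool = True) -> dict:
    f8 = cal["fig8"]
    tirs = []
    if with_starter:
        tirs.append({"id": "eps_prime", "cls": "eps", "rate": 1.0,
                     "starts_open": True,
                     "actions": [{"target": "g1", "tau": f8["start_tau"],
                                  "chi": 1}]})
    tirs += extra_tirs
    for k in (1, 2, 3):
        tirs.append({"id": f"t{k}_close", "cls": "T_int", "source": f"g{k}",
                     "rate": 1.0, "starts_open": True,
                     "actions": [{"target": f"g{k}", "tau": f8["close_tau"],
                                  "chi": -1}]})
    return {"gestures": [{"id": f"g{k}"} for k in (1, 2, 3)], "tirs": tirs}


def _build_fig8_shared_trigger(cal: dict, lam: float) -> ModelSpec:
    """One internal TiR sourced from g1 activates both g2 and g3 at two
    thresholds; successive intervals are deterministic functions of the
    same (noisy) rate, so their correlation is trivially 1."""
    f8 = cal["fig8"]
    t = {"id": "T1", "cls": "T_int", "source": "g1", "rate": 1.0,
         "starts_open": True,
         "actions": [{"target": "g2", "tau": f8["link_tau"], "chi": 1},
                     {"target": "g3", "tau": 2 * f8["link_tau"], "chi": 1}]}
    return ModelSpec(name="fig8_shared_trigger", **_fig8_frame(cal, [t]))


def _build_fig8_chain_internal(cal: dict, lam: float) -> ModelSpec:
    """Causal chain via internal feedback: g1's TiR activates g2, g2's
    activates g3."""
    f8 = cal["fig8"]
    ts = [{"id": "T1", "cls": "T_int", "source": "g1", "rate": 1.0,
           "starts_open": True,
           "actions": [{"target": "g2", "tau": f8["link_tau"], "chi": 1}]},
          {"id": "T2", "cls": "T_int", "source": "g2", "rate": 1.0,
           "starts_open": True,
           "actions": [{"target": "g3", "tau": f8["link_tau"], "chi": 1}]}]
    return ModelSpec(name="fig8_chain_internal", **_fig8_frame(cal, ts))


def _build_fig8_chain_external(cal: dict, lam: float) -> ModelSpec:
    """As the internal chain but integrating the delayed sensory trace:
    each link's interval gains a constant offset equal to the delay."""
    f8 = cal["fig8"]
    d = cal["feedback"]["delay_s"]
    ts = [{"id": "T1", "cls": "T_ext", "source": "g1", "rate": 1.0,
           "delay": d, "starts_open": True,
           "actions": [{"target": "g2", "tau": f8["link_tau"], "chi": 1}]},
          {"id": "T2", "cls": "T_ext", "source": "g2", "rate": 1.0,
           "delay": d, "starts_open": True,
           "actions": [{"target": "g3", "tau": f8["link_tau"], "chi": 1}]}]
    return ModelSpec(name="fig8_chain_external", **_fig8_frame(cal, ts))


def _build_fig8_independent(cal: dict, lam: float) -> ModelSpec:
    """Three independent extra-gestural clocks, one per gesture.  Local
    noise on g2's clock pushes the successive intervals in opposite
    directions (negative correlation)."""
    f8 = cal["fig8"]
    ts = [{"id": f"eps{k + 1}", "cls": "eps", "rate": 1.0,
           "starts_open": True,
           "actions": [{"target": f"g{k + 1}", "tau": tau, "chi": 1}]}
          for k, tau in enumerate(f8["independent_taus"])]
    return ModelSpec(name="fig8_independent",
                     **_fig8_frame(cal, ts, with_starter=False))


def _build_fig8_hybrid(cal: dict, lam: float) -> ModelSpec:
    """g1 and g3 share one extra-gestural clock (two thresholds); g2 has
    its own.  Local noise on g2's clock yields correlations even more
    negative than the independent-triggers model."""
    f8 = cal["fig8"]
    t1, t2, t3 = f8["independent_taus"]
    ts = [{"id": "eps13", "cls": "eps", "rate": 1.0, "starts_open": True,
           "actions": [{"target": "g1", "tau": t1, "chi": 1},
                       {"target": "g3", "tau": t3, "chi": 1}]},
          {"id": "eps2", "cls": "eps", "rate": 1.0, "starts_open": True,
           "actions": [{"target": "g2", "tau": t2, "chi": 1}]}]
    return ModelSpec(name="fig8_hybrid",
                     **_fig8_frame(cal, ts, with_starter=False))


def _build_fig8_coupled_osc(cal: dict, lam: float) -> ModelSpec:
    """Strongly coupled oscillator triggers for all three gestures; phase
    coupling absorbs local frequency noise, so correlations stay positive."""
    f8 = cal["fig8"]
    a, b, f = f8["osc_attract"], f8["osc_repel"], f8["osc_freq_hz"]
    phi = _phase_lag(a, b)
    oscs = []
    for k, (phase0, coup) in enumerate((
            (PI + phi, {"osc2": a, "osc3": -b}),
            (PI, {"osc1": a, "osc3": a}),
            (PI - phi, {"osc2": a, "osc1": -b}))):
        oscs.append({"id": f"osc{k + 1}", "cls": "theta", "freq_hz": f,
                     "coupling": coup, "phase0": phase0, "starts_open": True,
                     "actions": [{"target": f"g{k + 1}", "tau": 0.0,
                                  "chi": 1}]})
    return ModelSpec(name="fig8_coupled_osc",
                     **_fig8_frame(cal, oscs, with_starter=False))


def _build_fig9d(cal: dict, lam: float) -> ModelSpec:
    """The hybrid CVC syllable: C, R, V initiated by coupled oscillators;
    V deactivation and c, r activation/deactivation by internal/external
    feedback TiR pairs."""
    gestures, tirs = _syllable("", "CVC", None, None, cal)
    modulation = dict(cal["modulation"])
    modulation["lambda_attention"] = lam
    modulation["lambda_pace"] = lam
    return ModelSpec(name="fig9d_hybrid_cvc", gestures=gestures, tirs=tirs,
                     modulation=modulation)


def _build_fig10(cal: dict, lam: float) -> ModelSpec:
    """Post-vocalic control with competing internal and external TiRs: the
    interval from V to c changes governor as attention increases."""
    fb = cal["feedback"]
    modulation = dict(cal["modulation"])
    modulation["lambda_attention"] = lam
    modulation["lambda_pace"] = lam
    return ModelSpec(
        name="fig10_attention",
        gestures=[{"id": "V1", "role": "V"}, {"id": "c1", "role": "c"}],
        tirs=[
            {"id": "eps_prime", "cls": "eps", "rate": 1.0,
             "starts_open": True,
             "actions": [{"target": "V1", "tau": 0.05, "chi": 1}]},
            {"id": "t_V1_int", "cls": "T_int", "source": "V1",
             "rate": fb["alpha_int_pair"], "modulated": True,
             "starts_open": True,
             "actions": [{"target": "c1", "tau": fb["tau_open"], "chi": 1},
                         {"target": "V1", "tau": fb["tau_close"],
                          "chi": -1}]},
            {"id": "t_V1_ext", "cls": "T_ext", "source": "V1",
             "rate": fb["alpha_ext_pair"], "modulated": True,
             "delay": fb["delay_s"], "starts_open": True,
             "actions": [{"target": "c1", "tau": fb["tau_open"], "chi": 1},
                         {"target": "V1", "tau": fb["tau_close"],
                          "chi": -1}]},
            {"id": "t_c1_dur", "cls": "T_int", "source": "c1",
             "rate": fb["alpha_int_final"], "modulated": True,
             "starts_open": True,
             "actions": [{"target": "c1", "tau": fb["tau_final"],
                          "chi": -1}]},
        ],
        modulation=modulation)


def _build_fig11(cal: dict, lam: float) -> ModelSpec:
    model = _utterance([("CV", None)] * 3, cal, lam=lam)
    model.name = "fig11_three_cv"
    return model


def _build_fig12(cal: dict, lam: float) -> ModelSpec:
    """Four words of 2+3+1+3 CV syllables under parallel concept/mu
    competitive selection."""
    n = [2, 3, 1, 3]
    groups, i = [], 0
    for size in n:
        groups.append(list(range(i, i + size)))
        i += size
    model = _utterance([("CV", None)] * sum(n), cal, concepts=groups, lam=lam)
    model.name = "fig12_multiword"
    return model


def _build_fig13(cal: dict, lam: float) -> ModelSpec:
    """Rate-control utterance: CVC CV CVC, one word per syllable, with
    selectional-anticipation boosts on word-final (and utterance-final)
    feedback TiRs."""
    model = _utterance([("CVC", "w1"), ("CV", "w2"), ("CVC", "w3")],
                       cal, lam=lam)
    model.name = "fig13_rate_utterance"
    return apply_final_position_boost(model)


def _build_geminate(cal: dict, lam: float) -> ModelSpec:
    """Geminate demo: the coda closure of word 1 is held across the word
    boundary and released by word 2's onset.  Qualitative only."""
    model = _utterance([("CVC", "w1"), ("CV", "w2")], cal, lam=lam)
    model.name = "geminate_demo"
    # strip word 1's release gesture and the TiR pairs that would release
    # or close the coda; the closure c1 is held across the boundary
    model.gestures = [g for g in model.gestures if g.id != "r1"]
    drop = {"t_r1_int", "t_r1_ext", "t_c1_int", "t_c1_ext"}
    model.tirs = [t for t in model.tirs if t.id not in drop]
    for mu in model.mus:
        if mu.id == "mu1":
            mu.gestures = [g for g in mu.gestures if g != "r1"]
            mu.suppressors = ["t_gem_hold"]
    model.tirs.append(_tir_dict({
        "id": "t_gem_hold", "cls": "T_int", "source": "c1",
        "rate": cal["feedback"]["alpha_int_final"], "modulated": True,
        "starts_open": True,
        "actions": [{"target": "mu1", "tau": cal["feedback"]["tau_final"],
                     "chi": -1}]}))
    model.tirs.append(_tir_dict({
        "id": "t_gem_release", "cls": "T_int", "source": "C2",
        "rate": cal["feedback"]["alpha_int_final"], "starts_open": True,
        "actions": [{"target": "c1", "tau": 0.02, "chi": -1}]}))
    return ModelSpec.model_validate(model.model_dump())


def _tir_dict(d: dict):
    from .tirs import TiRSpec
    return TiRSpec.model_validate(d)


_ZOO = {
    "fig5": _build_fig5,
    "fig6": _build_fig6,
    "fig7": _build_fig7,
    "fig8_shared_trigger": _build_fig8_shared_trigger,
    "fig8_coupled_osc": _build_fig8_coupled_osc,
    "fig8_chain_external": _build_fig8_chain_external,
    "fig8_chain_internal": _build_fig8_chain_internal,
    "fig8_independent": _build_fig8_independent,
    "fig8_hybrid": _build_fig8_hybrid,
    "fig9d_hybrid_cvc": _build_fig9d,
    "fig10_attention": _build_fig10,
    "fig11_three_cv": _build_fig11,
    "fig12_multiword": _build_fig12,
    "fig13_rate_utterance": _build_fig13,
    "geminate_demo": _build_geminate,
}

DEFAULT_DURATION = {
    "fig5": 1.0, "fig6": 1.0, "fig7": 0.8,
    "fig8_shared_trigger": 1.2, "fig8_coupled_osc": 1.0,
    "fig8_chain_external": 1.2, "fig8_chain_internal": 1.2,
    "fig8_independent": 1.2, "fig8_hybrid": 1.2,
    "fig9d_hybrid_cvc": 1.2, "fig10_attention": 1.2,
    "fig11_three_cv": 4.0, "fig12_multiword": 14.0,
    "fig13_rate_utterance": 6.0, "geminate_demo": 5.0,
}


def list_models() -> list[str]:
    return sorted(_ZOO)


def build_model(name_or_spec, lam: Optional[float] = None) -> ModelSpec:
    """Build a zoo model by name, or validate an inline spec (dict).

    ``lam`` overrides both the attention and pace control variables, which
    the rate-control experiments vary together.
    """
    if isinstance(name_or_spec, ModelSpec):
        model = name_or_spec
    elif isinstance(name_or_spec, dict):
        try:
            model = ModelSpec.model_validate(name_or_spec)
        except ValueError as exc:
            raise ConfigurationError(str(exc)) from exc
    else:
        builder = _ZOO.get(name_or_spec)
        if builder is None:
            raise ConfigurationError(
                f"unknown model {name_or_spec!r}; available: "
                + ", ".join(list_models()))
        return builder(calibration(), 0.5 if lam is None else lam)
    if lam is not None:
        model = model.model_copy(deep=True)
        model.modulation.lambda_attention = lam
        model.modulation.lambda_pace = lam
    return model


def perturb_sensory_delay(model: ModelSpec, extra_s: float) -> ModelSpec:
    """Lengthen every external-feedback loop by ``extra_s`` seconds
    (a temporal feedback perturbation)."""
    out = model.model_copy(deep=True)
    for tir in out.tirs:
        if tir.cls == "T_ext":
            tir.delay += extra_s
    return out


# --------------------------------------------------------------------------
# running and interval analysis

def simulate(model: ModelSpec | str, *, duration: Optional[float] = None,
             dt: float = 0.001, seed: int = 0, n_runs: int = 1,
             record: bool = False, lam: Optional[float] = None):
    """Build (if needed) and run a model; returns (traces, events)."""
    model = build_model(model, lam=lam)
    if duration is None:
        duration = DEFAULT_DURATION.get(model.name, 2.0)
    config = SimConfig(dt=dt, duration=duration, seed=seed, n_runs=n_runs,
                       record_timeseries=record,
                       stop_when_quiescent=not record)
    return run_simulation(model, config)


def onsets(events: list[EventRecord], run_id: int = 0) -> dict[str, float]:
    """First activation_on time per system for one run."""
    out: dict[str, float] = {}
    for e in events:
        if e.run_id == run_id and e.event_kind == "activation_on" \
                and e.system_id not in out:
            out[e.system_id] = e.time
    return out


def offsets(events: list[EventRecord], run_id: int = 0) -> dict[str, float]:
    """Last activation_off time per system for one run."""
    out: dict[str, float] = {}
    for e in events:
        if e.run_id == run_id and e.event_kind == "activation_off":
            out[e.system_id] = e.time
    return out


@dataclass
class IntervalTable:
    """Named intervals (ms) per run, with missing-event flags."""

    frame: pd.DataFrame  # run_id, interval, value_ms, flagged

    def pivot(self) -> pd.DataFrame:
        ok = self.frame[~self.frame.flagged]
        return ok.pivot(index="run_id", columns="interval",
                        values="value_ms")

    def value(self, interval: str, run_id: int = 0) -> float:
        sel = self.frame[(self.frame.interval == interval)
                         & (self.frame.run_id == run_id)]
        return float(sel.value_ms.iloc[0])


def extract_intervals(events: list[EventRecord],
                      model: ModelSpec) -> IntervalTable:
    """Initiation-to-initiation intervals (and word durations) in ms.

    For generic three-gesture models (g1, g2, g3) the successive intervals
    delta12 and delta23 are computed.  For role-tagged models the standard
    articulatory intervals are derived per word: CV (C to V initiation),
    C-R, VC (V to c), R-c, c-r, and the word duration (first initiation to
    last termination).  Missing events yield flagged rows, never silent
    drops.
    """
    run_ids = sorted({e.run_id for e in events}) or [0]
    gids = [g.id for g in model.gestures]
    by_role: dict[Optional[str], dict[str, str]] = {}
    for g in model.gestures:
        if g.role:
            by_role.setdefault(g.word, {})[g.role] = g.id
    words = {g.word: [x.id for x in model.gestures if x.word == g.word]
             for g in model.gestures if g.word}

    rows = []

    def add(run, name, value):
        rows.append({"run_id": run, "interval": name,
                     "value_ms": value if value is not None else np.nan,
                     "flagged": value is None})

    def diff(on, a, b):
        if a in on and b in on:
            return (on[b] - on[a]) * 1000.0
        return None

    for run in run_ids:
        on = onsets(events, run)
        off = offsets(events, run)
        if {"g1", "g2", "g3"} <= set(gids):
            add(run, "delta12", diff(on, "g1", "g2"))
            add(run, "delta23", diff(on, "g2", "g3"))
        for word, roles in by_role.items():
            sfx = f":{word}" if word else ""
            pairs = [("CV", "C", "V"), ("C-R", "C", "R"), ("VC", "V", "c"),
                     ("R-c", "R", "c"), ("c-r", "c", "r")]
            for name, r1, r2 in pairs:
                if r1 in roles and r2 in roles:
                    add(run, name + sfx, diff(on, roles[r1], roles[r2]))
            if word:
                members = words[word]
                ons = [on[g] for g in members if g in on]
                offs = [off[g] for g in members if g in off]
                if ons and len(offs) == len(members):
                    add(run, f"dur:{word}",
                        (max(offs) - min(ons)) * 1000.0)
                else:
                    add(run, f"dur:{word}", None)
    return IntervalTable(pd.DataFrame(rows))


@dataclass
class CorrelationResult:
    r: float
    n: int
    flagged: bool = False
    reason: str = ""


def delta_correlation(table: IntervalTable, x: str = "delta12",
                      y: str = "delta23") -> CorrelationResult:
    """Pearson correlation of two named intervals across runs.

    Flagged (not NaN-propagating) when fewer than 3 complete runs exist or
    either interval has zero variance.
    """
    wide = table.pivot()
    if x not in wide.columns or y not in wide.columns:
        return CorrelationResult(np.nan, 0, True, "missing interval")
    sub = wide[[x, y]].dropna()
    n = len(sub)
    if n < 3:
        return CorrelationResult(np.nan, n, True, "fewer than 3 runs")
    xs, ys = sub[x].to_numpy(), sub[y].to_numpy()
    if np.ptp(xs) == 0.0 or np.ptp(ys) == 0.0:
        return CorrelationResult(np.nan, n, True, "zero variance")
    r = float(stats.pearsonr(xs, ys).statistic)
    return CorrelationResult(r, n)


@dataclass
class CorrelationSurface:
    """Delta-correlation over a (global x local) noise grid."""

    model_name: str
    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def _cell_seed(seed: int, i: int, j: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(i, j))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def corr_experiment(model_name: str, noise_grid: Optional[Sequence[float]]
                    = None, n_runs: int = 200, seed: int = 7,
                    dt: float = 0.001) -> CorrelationSurface:
    """Monte-Carlo delta-correlation surface for one zoo model.

    Crosses global and local noise levels (default: the model's five-level
    grid), excluding the cell where both are zero.  Each cell runs
    ``n_runs`` simulations with a seed derived from the cell coordinates.
    """
    if n_runs < 3:
        raise ConfigurationError("n_runs must be at least 3")
    model = build_model(model_name)
    grid = list(noise_grid if noise_grid is not None
                else model.noise.levels)
    surface = CorrelationSurface(model_name=model.name)
    duration = DEFAULT_DURATION.get(model.name, 2.0)
    for i, sg in enumerate(grid):
        for j, sl in enumerate(grid):
            if sg == 0.0 and sl == 0.0:
                continue
            m = model.model_copy(deep=True)
            m.noise.sigma_global = sg
            m.noise.sigma_local = sl
            config = SimConfig(dt=dt, duration=duration,
                               seed=_cell_seed(seed, i, j), n_runs=n_runs,
                               record_timeseries=False,
                               stop_when_quiescent=True)
            _, events = run_simulation(m, config)
            res = delta_correlation(extract_intervals(events, m))
            lo, hi = _fisher_ci(res.r, res.n)
            surface.rows.append({
                "sigma_global": sg, "sigma_local": sl, "r": res.r,
                "n": res.n, "ci_lo": lo, "ci_hi": hi,
                "flagged": res.flagged,
            })
    return surface


def _fisher_ci(r: float, n: int, conf: float = 0.95
               ) -> tuple[float, float]:
    if not np.isfinite(r) or n < 4 or abs(r) >= 1.0:
        return (np.nan, np.nan)
    z = np.arctanh(r)
    se = 1.0 / math.sqrt(n - 3)
    zc = stats.norm.ppf(0.5 + conf / 2.0)
    return (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))


def rate_sweep(model_name: str = "fig13_rate_utterance",
               lambdas: Optional[Sequence[float]] = None, seed: int = 0,
               dt: float = 0.001) -> pd.DataFrame:
    """Noise-off interval sweep over the rate-control parameter lambda.

    Returns a tidy frame (lambda, interval, value_ms) with word durations
    and the standard articulatory intervals at each of the (default 11)
    lambda values.
    """
    lams = list(lambdas if lambdas is not None else np.linspace(0, 1, 11))
    frames = []
    for lam in lams:
        model = build_model(model_name, lam=float(lam))
        _, events = simulate(model, seed=seed, dt=dt)
        tab = extract_intervals(events, model).frame.copy()
        tab.insert(0, "lambda", float(lam))
        frames.append(tab[["lambda", "interval", "value_ms", "flagged"]])
    return pd.concat(frames, ignore_index=True)
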