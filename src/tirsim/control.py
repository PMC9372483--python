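"""Contextual ("surroundings") modulation of TiR parameters, and run noise.

Two scalar context variables, both in [0, 1], reshape the temporal behavior
of the model:

* **self-attention** ``lambda_attention`` divides feedback integration
  rates, ``alpha = alpha' / (1 + beta * lambda)``.  Internal and external
  feedback TiRs carry different sensitivities ``beta``, so raising
  attention can hand control of an interval from the internal to the
  external (sensory) route.
* **pace** ``lambda_pace`` drives planning-oscillator frequency through a
  saturating logistic map bounded by a frequency band, reflecting the
  hypothesis that planning oscillations live in a neurally constrained band
  (theta, roughly 3-8 Hz).

Noise is *inter-utterance*: one multiplicative rate perturbation per TiR
per run, frozen for the duration of the run.  A *global* component scales
every TiR identically; a *local* component perturbs each TiR
independently.  The balance of the two shapes interval correlations.
"""

from __future__ import annotations

import math

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator


class ModulationState(BaseModel):
    """Attention/pace state plus the constants of their parameter maps."""

    model_config = ConfigDict(extra="forbid")

    lambda_attention: float = Field(default=0.5, ge=0.0, le=1.0)
    lambda_pace: float = Field(default=0.5, ge=0.0, le=1.0)
    beta_internal: float = Field(default=1.0, ge=0.0)
    beta_external: float = Field(default=4.0, ge=0.0)
    f_min_hz: float = Field(default=3.0, gt=0.0)
    f_max_hz: float = Field(default=8.0, gt=0.0)
    pace_scale: float = Field(default=0.15, gt=0.0)
    gamma_word_final: float = Field(default=1.2, ge=1.0)
    gamma_utterance_final: float = Field(default=1.5, ge=1.0)

    @model_validator(mode="after")
    def _check(self) -> "ModulationState":
        if not self.beta_internal < self.beta_external:
            raise ValueError(
                "beta_internal must be < beta_external (required for the "
                "internal-to-external control transition)"
            )
        if not self.f_min_hz < self.f_max_hz:
            raise ValueError("f_min_hz must be < f_max_hz")
        return self


class NoiseSpec(BaseModel):
    """Multiplicative rate-noise scales (standard deviations)."""

    model_config = ConfigDict(extra="forbid")

    sigma_global: float = Field(default=0.0, ge=0.0)
    sigma_local: float = Field(default=0.0, ge=0.0)
    # default experiment grid: five levels from zero to the maximum
    levels: list[float] = Field(
        default_factory=lambda: [0.0, 0.025, 0.05, 0.075, 0.10]
    )


def attention_to_alpha(alpha_base: float, beta: float, lam: float) -> float:
    """Effective integration rate ``alpha' / (1 + beta * lambda)``.

    Strictly decreasing in attention: closer attention to feedback slows
    feedback accumulation, so the TiR takes longer to act.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    if alpha_base <= 0.0:
        raise ValueError("alpha_base must be positive")
    if beta < 0.0:
        raise ValueError("beta must be non-negative")
    return alpha_base / (1.0 + beta * lam)


def pace_to_frequency(lam: float, f_min: float = 3.0, f_max: float = 8.0,
                      scale: float = 0.15) -> float:
    """Oscillator frequency (Hz) as a saturating function of pace.

    A logistic in ``lam`` centered at 0.5 with the given scale, mapped
    affinely onto (f_min, f_max).  Strictly increasing, with slopes
    attenuated toward both ends (soft frequency bounds), and exactly the
    band midpoint at ``lam = 0.5``.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    s = 1.0 / (1.0 + math.exp(-(lam - 0.5) / scale))
    return f_min + (f_max - f_min) * s


def apply_final_position_boost(model, word_structure=None):
    """Strengthen attention sensitivity for word- and utterance-final units.

    Implements selectional anticipation: feedback integration of the final
    set of gestures selected in each word is more strongly modulated by
    attention (beta scaled by ``gamma_word_final``), and the utterance-final
    word additionally by ``gamma_utterance_final``.  Returns a new model;
    TiRs of non-final units are untouched.

    ``word_structure`` optionally maps word id -> ordered list of mu-system
    ids; by default it is derived from the mu annotations in the model.
    """
    mod = model.modulation
    if word_structure is None:
        word_structure = {}
        for mu in model.mus:
            if mu.word is not None:
                word_structure.setdefault(mu.word, []).append(mu.id)
    if not word_structure:
        return model.model_copy(deep=True)

    words = list(word_structure)  # utterance order = declaration order
    final_mu_of_word = {w: ids[-1] for w, ids in word_structure.items()}
    mu_by_id = {mu.id: mu for mu in model.mus}

    # gestures belonging to each word-final mu
    boosted: dict[str, float] = {}
    for w, mu_id in final_mu_of_word.items():
        factor = mod.gamma_word_final
        if w == words[-1]:
            factor *= mod.gamma_utterance_final
        for gid in mu_by_id[mu_id].gestures:
            boosted[gid] = factor

    out = model.model_copy(deep=True)
    for tir in out.tirs:
        if tir.cls in ("T_int", "T_ext", "T_intra") and tir.source in boosted:
            tir.beta_scale *= boosted[tir.source]
    return out


def draw_noise_multipliers(spec: NoiseSpec, n_tirs: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Per-TiR rate multipliers for one run.

    ``(1 + sigma_global * eta) * (1 + sigma_local * eta_i)`` with ``eta``
    shared across TiRs and ``eta_i`` independent standard normals; clipped
    away from zero so rates stay positive.  Frozen within a run.
    """
    eta = rng.standard_normal()
    eta_i = rng.standard_normal(n_tirs)
    mult = (1.0 + spec.sigma_global * eta) * (1.0 + spec.sigma_local * eta_i)
    return np.clip(mult, 0.05, None)
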