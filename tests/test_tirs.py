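"""TiR dynamics: clocks, integrators, oscillators, triggering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tirsim as ts
from tirsim.engine import SimConfig, run_simulation
from tirsim.model import ModelSpec
from tirsim.systems import GatingSystem
from tirsim.tirs import (AperiodicTiR, IntegratorTiR, OscillatorTiR, TiRSpec,
                         detect_phase_trigger, step_aperiodic,
                         step_integrator, step_oscillators)


def _eps(omega, starts_open=True):
    spec = TiRSpec(id="e", cls="eps", rate=omega, starts_open=starts_open)
    return AperiodicTiR(spec, omega_eff=omega)


def _integ(alpha):
    spec = TiRSpec(id="T", cls="T_int", source="g", rate=alpha,
                   starts_open=True)
    return IntegratorTiR(spec, alpha_eff=alpha)


def _osc(oid, freq, phase0=0.0, coupling=None, gate_open=True):
    spec = TiRSpec(id=oid, cls="theta", freq_hz=freq,
                   coupling=coupling or {}, phase0=phase0,
                   starts_open=gate_open)
    o = OscillatorTiR(spec, omega_eff=2 * math.pi * freq)
    o.rho = 1.0  # amplitude already settled unless the test says otherwise
    return o


class TestAperiodic:
    def test_elapsed_time_parameterization(self):
        """omega = 1/s makes activation numerically equal elapsed seconds."""
        tir = _eps(1.0)
        for _ in range(100):
            x = step_aperiodic(tir, 0.001)
        assert x == pytest.approx(0.1, abs=1e-12)

    def test_frozen_while_gate_closed(self):
        tir = _eps(1.0, starts_open=False)
        for _ in range(100):
            x = step_aperiodic(tir, 0.001)
        assert x == 0.0

    def test_action_time_is_tau_over_omega_and_scale_invariant(self):
        """delta = tau/omega; doubling both tau and omega leaves the action
        time unchanged (constant-delta lines in omega/tau space)."""
        def action_time(omega, tau):
            model = ModelSpec(
                gestures=[{"id": "g1"}],
                tirs=[{"id": "e", "cls": "eps", "rate": omega,
                       "starts_open": True,
                       "actions": [{"target": "g1", "tau": tau, "chi": 1}]}])
            _, events = run_simulation(model, SimConfig(duration=1.0))
            return next(e.time for e in events
                        if e.event_kind == "activation_on")
        t1 = action_time(2.0, 0.5)
        t2 = action_time(1.0, 0.25)
        assert t1 == pytest.approx(0.25, abs=1e-12)
        assert t1 == pytest.approx(t2, abs=1e-12)


class TestIntegrator:
    def test_closed_form_crossing(self):
        """alpha = 2 with a unit source reaches tau = 0.25 in 0.125 s."""
        model = ModelSpec(
            gestures=[{"id": "g1"}, {"id": "g2"}],
            tirs=[{"id": "e", "cls": "eps", "rate": 1.0, "starts_open": True,
                   "actions": [{"target": "g1", "tau": 0.1, "chi": 1}]},
                  {"id": "T", "cls": "T_int", "source": "g1", "rate": 2.0,
                   "starts_open": True,
                   "actions": [{"target": "g2", "tau": 0.25, "chi": 1}]}])
        _, events = run_simulation(model, SimConfig(duration=1.0))
        on = {e.system_id: e.time for e in events
              if e.event_kind == "activation_on"}
        assert on["g2"] - on["g1"] == pytest.approx(0.125, abs=1e-12)

    def test_zero_input_never_fires(self):
        tir = _integ(1.0)
        for _ in range(1000):
            x = step_integrator(tir, 0.0, 0.001)
        assert x == 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            step_integrator(_integ(1.0), -0.5, 0.001)

    @given(alpha=st.floats(0.2, 5.0))
    @settings(max_examples=20, deadline=None)
    def test_equivalence_with_aperiodic_under_unit_input(self, alpha):
        """An integrator with constant unit input and rate alpha behaves
        identically to an autonomous clock with omega = alpha."""
        integ, clock = _integ(alpha), _eps(alpha)
        for _ in range(200):
            xi = step_integrator(integ, 1.0, 0.001)
            xc = step_aperiodic(clock, 0.001)
        assert xi == pytest.approx(xc, rel=1e-12)

    def test_virtual_cycle_deactivation_at_three_quarter_phase(self):
        """An intra-gestural TiR parameterized as a virtual cycle (period
        0.4 s, elapsed-time rates) deactivates its gesture when the cycle
        phase reaches 3*pi/2, i.e. 0.3 s after initiation."""
        period = 0.4
        tau = (3 * math.pi / 2) / (2 * math.pi) * period
        model = ModelSpec(
            gestures=[{"id": "g1"}],
            tirs=[{"id": "e", "cls": "eps", "rate": 1.0, "starts_open": True,
                   "actions": [{"target": "g1", "tau": 0.1, "chi": 1}]},
                  {"id": "Tvc", "cls": "T_intra", "source": "g1",
                   "rate": 1.0, "starts_open": True,
                   "actions": [{"target": "g1", "tau": tau, "chi": -1}]}])
        _, events = run_simulation(model, SimConfig(duration=1.0))
        times = {e.event_kind: e.time for e in events
                 if e.event_kind.startswith("activation")}
        assert times["activation_off"] - times["activation_on"] == \
            pytest.approx(0.3, abs=1e-9)


class TestSensoryDelayedChains:
    def test_external_chain_offset_by_delay(self):
        """External and internal chains with identical parameters differ
        only by a constant interval offset equal to the sensory delay."""
        cal = ts.calibration()
        d = cal["feedback"]["delay_s"]
        out = {}
        for name in ("fig8_chain_internal", "fig8_chain_external"):
            model = ts.build_model(name)
            _, events = ts.simulate(model, seed=0)
            tab = ts.extract_intervals(events, model)
            out[name] = (tab.value("delta12"), tab.value("delta23"))
        for k in range(2):
            diff = out["fig8_chain_external"][k] \
                - out["fig8_chain_internal"][k]
            assert diff == pytest.approx(d * 1000, abs=1e-6)


class TestOscillators:
    def test_attractive_coupling_pulls_in_phase(self):
        o1 = _osc("o1", 4.0, phase0=math.pi / 2, coupling={"o2": 5.0})
        o2 = _osc("o2", 4.0, phase0=0.0, coupling={"o1": 5.0})
        diffs = []
        for _ in range(2000):
            step_oscillators([o1, o2], 0.001)
            diffs.append(abs(o1.phase - o2.phase))
        assert diffs[-1] < 0.05
        assert all(b <= a + 1e-12 for a, b in zip(diffs, diffs[1:]))

    def test_repulsive_coupling_pushes_anti_phase(self):
        o1 = _osc("o1", 4.0, phase0=0.1, coupling={"o2": -5.0})
        o2 = _osc("o2", 4.0, phase0=0.0, coupling={"o1": -5.0})
        for _ in range(3000):
            step_oscillators([o1, o2], 0.001)
        assert abs(o1.phase - o2.phase) == pytest.approx(math.pi, abs=0.05)

    def test_frequency_locking_under_detuning(self):
        """Strong attractive coupling locks detuned oscillators to a common
        effective frequency (phase difference bounded, not drifting)."""
        o1 = _osc("o1", 4.0, coupling={"o2": 8.0})
        o2 = _osc("o2", 4.6, coupling={"o1": 8.0})
        for _ in range(1000):  # transient
            step_oscillators([o1, o2], 0.001)
        d0 = o2.phase - o1.phase
        for _ in range(2000):
            step_oscillators([o1, o2], 0.001)
        d1 = o2.phase - o1.phase
        assert abs(d1 - d0) < 0.01  # no drift: identical mean frequency

    def test_subthreshold_amplitude_blocks_trigger(self):
        o = _osc("o", 4.0, phase0=6.0)
        o.rho = 0.1
        fired = False
        for _ in range(200):
            step_oscillators([o], 0.001)
            fired |= detect_phase_trigger(o)
        assert not fired and o.phase > 2 * math.pi

    def test_trigger_fires_once_above_threshold(self):
        o = _osc("o", 4.0, phase0=3.0)
        fires = 0
        for _ in range(1000):  # four full cycles
            step_oscillators([o], 0.001)
            fires += detect_phase_trigger(o)
        assert fires == 1  # one-shot per gate-open episode

    def test_no_retrigger_after_gate_closed_by_intergestural_tir(self):
        """fig7: each oscillator triggers its gesture exactly once even
        though its phase keeps cycling."""
        _, events = ts.simulate("fig7", seed=0, duration=1.5)
        for g in ("g1", "g2", "g3"):
            n_on = sum(1 for e in events
                       if e.system_id == g and e.event_kind == "activation_on")
            assert n_on == 1

    def test_self_coupling_rejected(self):
        with pytest.raises(ValueError):
            TiRSpec(id="o", cls="theta", freq_hz=4.0, coupling={"o": 1.0})
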