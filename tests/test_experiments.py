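"""Zoo builders, interval extraction, correlation analysis, sweeps."""

import math

import numpy as np
import pandas as pd
import pytest

import tirsim as ts
from tirsim.engine import EventRecord
from tirsim.experiments import (DEFAULT_DURATION, IntervalTable,
                                delta_correlation)


def _onset_events(times: dict[str, float], run_id: int = 0):
    return [EventRecord(run_id, t, sid, "activation_on")
            for sid, t in times.items()]


def _pearson_oracle(pairs):
    """Brute-force covariance-formula Pearson r, independent of scipy."""
    xs = [p[0] for p in pairs]
    ys = [p[1] for p in pairs]
    n = len(pairs)
    mx, my = sum(xs) / n, sum(ys) / n
    cov = sum((x - mx) * (y - my) for x, y in pairs)
    vx = sum((x - mx) ** 2 for x in xs)
    vy = sum((y - my) ** 2 for y in ys)
    return cov / math.sqrt(vx * vy)


class TestBuildModel:
    def test_every_zoo_model_validates(self):
        for name in ts.list_models():
            model = ts.build_model(name)
            assert model.name == name

    def test_unknown_name_lists_available(self):
        with pytest.raises(ts.ConfigurationError) as err:
            ts.build_model("fig99")
        assert "fig9d_hybrid_cvc" in str(err.value)

    def test_dangling_reference_named_in_error(self):
        with pytest.raises((ts.ConfigurationError, ValueError),
                           match="g_missing"):
            ts.build_model({
                "gestures": [{"id": "g1"}],
                "tirs": [{"id": "t", "cls": "T_int", "source": "g1",
                          "rate": 1.0,
                          "actions": [{"target": "g_missing", "tau": 0.1,
                                       "chi": 1}]}]})

    def test_shared_trigger_topology(self):
        model = ts.build_model("fig8_shared_trigger")
        t1 = next(t for t in model.tirs if t.id == "T1")
        assert t1.source == "g1"
        assert {a.target for a in t1.actions} == {"g2", "g3"}

    def test_fig9d_topology(self):
        model = ts.build_model("fig9d_hybrid_cvc")
        osc_targets = {a.target for t in model.tirs if t.cls == "theta"
                       for a in t.actions}
        assert osc_targets == {"C", "R", "V"}
        fb_targets = {a.target for t in model.tirs
                      if t.cls in ("T_int", "T_ext") for a in t.actions}
        assert {"c", "r", "V"} <= fb_targets


class TestExtractIntervals:
    def test_plain_onset_differences(self):
        model = ts.build_model("fig8_shared_trigger")
        events = _onset_events({"g1": 0.10, "g2": 0.25, "g3": 0.45})
        tab = ts.extract_intervals(events, model)
        assert tab.value("delta12") == pytest.approx(150.0)
        assert tab.value("delta23") == pytest.approx(200.0)

    def test_missing_initiation_flagged_not_dropped(self):
        model = ts.build_model("fig8_shared_trigger")
        events = _onset_events({"g1": 0.10, "g2": 0.25})
        frame = ts.extract_intervals(events, model).frame
        row = frame[frame.interval == "delta23"].iloc[0]
        assert bool(row.flagged) and np.isnan(row.value_ms)

    def test_chain_links_equal_their_tau_over_alpha(self):
        """Noise off, per-link tau/alpha = 0.15 s: both intervals 150 ms."""
        model = ts.build_model("fig8_chain_internal")
        _, events = ts.simulate(model, seed=0)
        tab = ts.extract_intervals(events, model)
        assert tab.value("delta12") == pytest.approx(150.0, abs=1.0)
        assert tab.value("delta23") == pytest.approx(150.0, abs=1.0)


class TestDeltaCorrelation:
    def _table(self, pairs):
        rows = []
        for run, (x, y) in enumerate(pairs):
            rows.append({"run_id": run, "interval": "delta12",
                         "value_ms": x, "flagged": False})
            rows.append({"run_id": run, "interval": "delta23",
                         "value_ms": y, "flagged": False})
        return IntervalTable(pd.DataFrame(rows))

    def test_perfect_positive(self):
        res = delta_correlation(self._table([(1, 2), (2, 4), (3, 6)]))
        assert res.r == pytest.approx(1.0)

    def test_perfect_negative(self):
        res = delta_correlation(self._table([(1, 3), (2, 2), (3, 1)]))
        assert res.r == pytest.approx(-1.0)

    def test_matches_independent_oracle(self):
        pairs = [(1, 1), (2, 3), (4, 2)]
        res = delta_correlation(self._table(pairs))
        assert res.r == pytest.approx(_pearson_oracle(pairs), abs=1e-12)

    def test_zero_variance_flagged_not_nan_propagated(self):
        res = delta_correlation(self._table([(1, 1), (1, 2), (1, 3)]))
        assert res.flagged and res.reason == "zero variance"

    def test_too_few_runs_flagged(self):
        res = delta_correlation(self._table([(1, 1), (2, 2)]))
        assert res.flagged and "3 runs" in res.reason


class TestCorrExperiment:
    def test_shared_trigger_surface_all_ones(self):
        surface = ts.corr_experiment("fig8_shared_trigger",
                                     noise_grid=[0.0, 0.05],
                                     n_runs=40, seed=7)
        frame = surface.to_frame()
        assert len(frame) == 3  # (0,0) excluded
        assert np.allclose(frame.r, 1.0, atol=1e-9)

    def test_zero_zero_cell_excluded(self):
        surface = ts.corr_experiment("fig8_chain_internal",
                                     noise_grid=[0.0, 0.05],
                                     n_runs=10, seed=1)
        frame = surface.to_frame()
        assert not ((frame.sigma_global == 0)
                    & (frame.sigma_local == 0)).any()

    def test_surface_frame_schema(self):
        surface = ts.corr_experiment("fig8_chain_internal",
                                     noise_grid=[0.0, 0.05],
                                     n_runs=20, seed=1)
        frame = surface.to_frame()
        assert list(frame.columns) == ["sigma_global", "sigma_local", "r",
                                       "n", "ci_lo", "ci_hi", "flagged"]
        assert frame.r.between(-1, 1).all()


class TestRateSweep:
    def test_single_lambda_equals_plain_run(self):
        sweep = ts.rate_sweep(lambdas=[0.5], seed=0)
        model = ts.build_model("fig13_rate_utterance", lam=0.5)
        _, events = ts.simulate(model, seed=0)
        tab = ts.extract_intervals(events, model)
        merged = sweep.merge(tab.frame.assign(run_id=0),
                             on="interval", suffixes=("_sweep", "_run"))
        ok = merged.dropna()
        assert np.allclose(ok.value_ms_sweep, ok.value_ms_run)

    def test_default_grid_has_eleven_values(self):
        sweep = ts.rate_sweep(lambdas=None, seed=0,
                              model_name="fig13_rate_utterance")
        assert sweep["lambda"].nunique() == 11


def test_symmetric_displacement_from_coupling(cal):
    """fig7 steady state: theta1/theta3 symmetrically displaced about
    theta2, so g1/g3 initiations are symmetric about g2's (asymmetry well
    under 10% even from a perturbed start)."""
    for name in ("fig7", "fig9d_hybrid_cvc"):
        model = ts.build_model(name)
        _, events = ts.simulate(model, seed=0)
        on = ts.onsets(events)
        if name == "fig7":
            d1, d2 = on["g2"] - on["g1"], on["g3"] - on["g2"]
        else:
            d1, d2 = on["V"] - on["C"], on["R"] - on["V"]
        asym = abs(d1 - d2) / ((d1 + d2) / 2)
        assert asym <= 0.10


def test_geminate_demo_holds_closure_across_boundary():
    """The word-1 coda closure stays active until word 2's onset releases
    it: c1's activation interval spans the word boundary."""
    model = ts.build_model("geminate_demo")
    _, events = ts.simulate(model, seed=0)
    on, off = ts.onsets(events), {}
    for e in events:
        if e.event_kind == "activation_off":
            off[e.system_id] = e.time
    assert off["c1"] > on["C2"] > on["c1"]
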