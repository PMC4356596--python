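"""Bifurcation machinery: sweeps, bistability, limit cycles, phase durations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autoswitch.bifurcation import (
    BifurcationError,
    Sweep,
    SweepConfig,
    detect_bistability,
    label_sweep_windows,
    measure_phase_durations,
    slow_drift_sweep,
    two_param_diagram,
)
from autoswitch.odesim import ObservableSet, find_steady_state


class TestPhaseDurations:
    def test_square_wave_exact_durations(self):
        """Constructed-signal oracle: a square wave of known duty cycle."""
        period, high = 100.0, 30.0
        t = np.linspace(0, 1000, 20001)
        x = ((t % period) < high).astype(float) * 0.9 + 0.05
        auto, trans = measure_phase_durations(t, x)
        assert auto == pytest.approx(high, rel=0.01)
        assert trans == pytest.approx(period - high, rel=0.01)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(duty=st.floats(0.1, 0.9), period=st.floats(20.0, 300.0))
    def test_square_wave_durations_sum_to_period(self, duty, period):
        t = np.linspace(0, 12 * period, 8000)
        x = ((t % period) < duty * period).astype(float)
        auto, trans = measure_phase_durations(t, x)
        assert auto + trans == pytest.approx(period, rel=0.05)
        assert auto == pytest.approx(duty * period, rel=0.1)

    def test_non_oscillating_series_rejected(self):
        t = np.linspace(0, 10, 100)
        with pytest.raises(BifurcationError):
            measure_phase_durations(t, np.full_like(t, 0.2))


class TestSweepMechanics:
    def test_zero_width_sweep_equals_steady_state(self, nominal_network,
                                                  nofeedback_model):
        params = dict(nofeedback_model.params)
        sweep = slow_drift_sweep(
            nominal_network, params,
            SweepConfig("ampk_star", 30_000.0, 30_000.0, "up", settle=0.0))
        y, _ = find_steady_state(nominal_network, params)
        obs = ObservableSet(nominal_network)
        frac = obs.evaluate(y[None, :])[obs.names.index("frac_AMBRA1_P"), 0]
        assert sweep.input.shape == (1,)
        assert sweep.frac_ambra[0] == pytest.approx(frac, abs=1e-6)

    def test_up_sweep_input_monotone_and_covers_range(self, nominal_network,
                                                      nofeedback_model):
        sweep = slow_drift_sweep(
            nominal_network, nofeedback_model.params,
            SweepConfig("ampk_star", 0.0, 1e5, "up"))
        assert np.all(np.diff(sweep.input) > -1e-6)
        assert sweep.input[-1] == pytest.approx(1e5, rel=0.01)

    def test_drift_halving_self_consistency(self, nominal_network,
                                            nofeedback_model):
        """Branch values away from the saddle-node jump agree within 1% when
        the drift rate is halved (pseudo-steady-state check)."""
        cfg = SweepConfig("ampk_star", 0.0, 1e5, "up")
        k = cfg.default_k_eps(nofeedback_model.params)
        s1 = slow_drift_sweep(nominal_network, nofeedback_model.params,
                              SweepConfig("ampk_star", 0.0, 1e5, "up", k_eps=k))
        s2 = slow_drift_sweep(nominal_network, nofeedback_model.params,
                              SweepConfig("ampk_star", 0.0, 1e5, "up",
                                          k_eps=k / 2))
        grid = np.linspace(0, 1e5, 200)
        b1, b2 = s1.branch(grid), s2.branch(grid)
        # exclude the discontinuity: points where either branch moves fast
        slope = np.maximum(np.abs(np.gradient(b1)), np.abs(np.gradient(b2)))
        quiet = slope < 0.01
        assert quiet.sum() > 100
        assert np.max(np.abs(b1[quiet] - b2[quiet])) < 0.01

    def test_rate_constant_sweep_dispatches_to_stepped_mode(
            self, nominal_network, nofeedback_model):
        """Sweeping a rate constant (no monomer pool to drift) runs the
        quasi-static continuation and shows the same switch: low d5 favors
        autophagy (stable AMPK-ULK1 complexes), high d5 favors translation."""
        sweep = slow_drift_sweep(
            nominal_network, nofeedback_model.params,
            SweepConfig("d5", 0.5, 50.0, "up", n_out=800, settle=1e5))
        assert sweep.k_eps == 0.0
        lo_end = sweep.frac_ambra[sweep.input < 1.0]
        hi_end = sweep.frac_ambra[sweep.input > 40.0]
        assert lo_end.mean() > 0.5 > hi_end.mean()


class TestBistabilityDetection:
    def test_synthetic_hysteresis_interval_recovered(self):
        grid = np.linspace(0, 1, 500)
        up = Sweep("x", "up", grid, (grid > 0.6).astype(float), grid, grid, 1.0)
        down = Sweep("x", "down", grid, (grid > 0.3).astype(float), grid, grid, 1.0)
        (lo, hi), = detect_bistability(up, down)
        assert lo == pytest.approx(0.3, abs=0.02)
        assert hi == pytest.approx(0.6, abs=0.02)

    def test_identical_sweeps_are_monostable(self):
        grid = np.linspace(0, 1, 500)
        up = Sweep("x", "up", grid, grid, grid, grid, 1.0)
        down = Sweep("x", "down", grid, grid, grid, grid, 1.0)
        assert detect_bistability(up, down) == []


class TestRegimeMaps:
    def test_uniform_translation_grid_at_baseline_inputs(self, nominal_network,
                                                         nominal_model):
        """A 2x2 map around the unstressed operating point is all
        translation."""
        diag = two_param_diagram(nominal_network, nominal_model.params,
                                 "ampk_star", 20_000.0, 40_000.0, 2,
                                 "rapamycin_star", [0.0, 100.0])
        assert [lab for row in diag.labels for lab in row] == ["translation"] * 4

    def test_map_deterministic(self, nominal_network, nominal_model):
        args = (nominal_network, nominal_model.params,
                "ampk_star", 20_000.0, 40_000.0, 2, "rapamycin_star", [0.0])
        assert two_param_diagram(*args).labels == two_param_diagram(*args).labels


def test_window_labels_on_synthetic_sweep():
    """Quiet low, oscillating middle, quiet high series labels T / O / A."""
    n = 3000
    inp = np.linspace(0, 1, n)
    t = np.linspace(0, 3e5, n)
    x = np.where(inp < 0.33, 0.05,
                 np.where(inp > 0.66, 0.9,
                          0.5 + 0.4 * np.sin(2 * np.pi * 40 * inp)))
    sweep = Sweep("x", "up", inp, x, 1 - x, t, 1.0)
    _, labels = label_sweep_windows(sweep, 12)
    assert labels[0] == "translation"
    assert labels[-1] == "autophagy"
    assert "oscillatory" in labels[3:8]
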