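"""Mass-action ODE construction and integration."""

import numpy as np
import pytest

from autoswitch import ModelVariant, build_model
from autoswitch.fixtures import generate_fixtures
from autoswitch.network import expand_network
from autoswitch.odesim import (
    MassActionSystem,
    ObservableSet,
    apply_stress,
    find_steady_state,
    simulate,
    unstressed_steady_state,
)


class TestRightHandSide:
    def test_dimer_rhs_matches_closed_form(self):
        """A + B <-> AB: dA/dt = -kon*A*B + koff*AB, derived by hand."""
        fx = next(f for f in generate_fixtures() if f.name == "dimer")
        net = expand_network(fx.model)
        sys_ = MassActionSystem(net, fx.model.params)
        idx = {net.species[i].label: i for i in range(net.n_species)}
        ia, ib = idx["A(b)"], idx["B(a)"]
        iab = idx[[l for l in idx if "!" in l][0]]
        kon, koff = fx.model.params["kon"], fx.model.params["koff"]
        rng = np.random.default_rng(0)
        for _ in range(5):
            y = rng.uniform(0, 100, net.n_species)
            dy = sys_.rhs(0.0, y)
            flux = kon * y[ia] * y[ib] - koff * y[iab]
            assert dy[ia] == pytest.approx(-flux)
            assert dy[ib] == pytest.approx(-flux)
            assert dy[iab] == pytest.approx(flux)

    def test_phosphoform_rhs_matches_closed_form(self):
        """Independent two-site monomer: hand-assembled 6-state master
        equations with unit rates."""
        fx = next(f for f in generate_fixtures() if f.name == "phosphoforms")
        net = expand_network(fx.model)
        sys_ = MassActionSystem(net, fx.model.params)
        idx = {net.species[i].label: i for i in range(net.n_species)}

        def rate_out(x, yst):
            # transitions leaving (x, y): x toggles (1), y moves (1 or 2 ways)
            return 1 + (1 if yst in "0Q" else 2)

        rng = np.random.default_rng(1)
        y = rng.uniform(0, 50, net.n_species)
        dy = sys_.rhs(0.0, y)
        xflip = {"0": "P", "P": "0"}
        ymoves = {"0": ["P"], "P": ["0", "Q"], "Q": ["P"]}
        for xs in "0P":
            for ys in "0PQ":
                i = idx[f"M(x~{xs},y~{ys})"]
                expected = -rate_out(xs, ys) * y[i]
                expected += y[idx[f"M(x~{xflip[xs]},y~{ys})"]]
                # inflow: states whose moves lead here
                for os_ in "0PQ":
                    if ys in ymoves[os_]:
                        expected += y[idx[f"M(x~{xs},y~{os_})"]]
                assert dy[i] == pytest.approx(expected)

    def test_zero_state_zero_derivative(self, nominal_network, nominal_model):
        sys_ = MassActionSystem(nominal_network, nominal_model.params)
        y = np.zeros(nominal_network.n_species)
        assert np.all(sys_.rhs(0.0, y) == 0.0)

    def test_jacobian_matches_finite_differences(self, nominal_network,
                                                 nominal_model):
        sys_ = MassActionSystem(nominal_network, nominal_model.params)
        rng = np.random.default_rng(2)
        y = rng.uniform(0, 1000, nominal_network.n_species)
        J = sys_.jac(0.0, y)
        eps = 1e-4
        cols = rng.choice(nominal_network.n_species, 10, replace=False)
        for j in cols:
            dy = np.zeros_like(y)
            dy[j] = eps
            num = (sys_.rhs(0.0, y + dy) - sys_.rhs(0.0, y - dy)) / (2 * eps)
            # central differences are exact for mass-action fluxes up to
            # floating-point cancellation (|rhs| ~ 1e5, eps 1e-4)
            assert np.allclose(J[:, j], num, rtol=1e-5, atol=1e-6)


class TestSimulation:
    def test_molecule_totals_conserved(self, nominal_network, nominal_model,
                                       unstressed_state):
        y0 = apply_stress(nominal_network, nominal_model.params,
                          unstressed_state, ampk_star=90_000.0)
        traj = simulate(nominal_network, nominal_model.params, 4 * 3600.0,
                        y0=y0, n_points=100)
        assert traj.conservation_error() < 1e-3
        totals = traj.molecule_totals()
        assert totals["MTOR"].iloc[0] == pytest.approx(20_000.0)
        assert totals["AMPK"].iloc[-1] == pytest.approx(90_000.0, rel=1e-6)

    def test_observables_bounded_in_unit_interval(self, nominal_network,
                                                  nominal_model):
        traj = simulate(nominal_network, nominal_model.params, 3600.0,
                        n_points=50)
        obs = traj.observables().drop(columns="time").to_numpy()
        assert np.all(obs >= -1e-9)
        assert np.all(obs <= 1 + 1e-9)

    def test_tolerance_robustness(self, nominal_network, nominal_model,
                                  unstressed_state):
        """Halving the solver tolerances moves the final AMBRA1-P fraction by
        less than 1e-4 on a persistent-autophagy scenario."""
        y0 = apply_stress(nominal_network, nominal_model.params,
                          unstressed_state, ampk_star=150_000.0)
        finals = []
        for rtol, atol in ((1e-8, 1e-6), (5e-9, 5e-7)):
            traj = simulate(nominal_network, nominal_model.params, 10 * 3600.0,
                            y0=y0, n_points=5, rtol=rtol, atol=atol)
            finals.append(traj.observable("frac_AMBRA1_P")[-1])
        assert abs(finals[0] - finals[1]) < 1e-4

    def test_duration_must_be_positive(self, nominal_network, nominal_model):
        with pytest.raises(ValueError):
            simulate(nominal_network, nominal_model.params, 0.0)


class TestSteadyStates:
    def test_unstressed_state_is_translation(self, nominal_network,
                                             nominal_model, unstressed_state):
        obs = ObservableSet(nominal_network)
        vals = dict(zip(obs.names, obs.evaluate(unstressed_state[None, :])[:, 0]))
        assert vals["frac_EIF4EBP1_P"] > 0.5
        assert vals["frac_AMBRA1_P"] < 0.5

    def test_all_rates_zero_returns_initial_state(self):
        m = build_model()
        params = {k: (0.0 if k in {
            "a1", "a2", "a3", "a4", "a5", "d1", "d2", "d3", "d3max", "d4",
            "d5", "p1", "p2", "p3", "p4", "p5", "p6", "p7", "p8", "p9",
            "u0", "u1", "u2"} else v) for k, v in m.params.items()}
        net = expand_network(m)
        y0 = net.initial_state(params)
        y, converged = find_steady_state(net, params, y0=y0)
        assert converged
        assert np.array_equal(y, y0)

    def test_two_basins_without_feedback(self, nominal_network,
                                         nofeedback_model):
        """At AMPK* = 30,000 without ULK1->AMPK feedback, relaxation from the
        unmodified seeds reaches the translation state while relaxation from
        a stress-adapted state reaches the autophagy state: mutually
        exclusive high AMBRA1-P vs high EIF4EBP1-P."""
        params = dict(nofeedback_model.params)
        obs = ObservableSet(nominal_network)

        y_trans, ok1 = find_steady_state(nominal_network, params)
        high = dict(params, ampk_star=200_000.0)
        y_hi, ok2 = find_steady_state(nominal_network, high)
        y_back = apply_stress(nominal_network, params, y_hi, ampk_star=30_000.0)
        y_auto, ok3 = find_steady_state(nominal_network, params, y0=y_back)
        assert ok1 and ok2 and ok3

        def fr(y, name):
            return obs.evaluate(y[None, :])[obs.names.index(name), 0]

        assert fr(y_trans, "frac_EIF4EBP1_P") > 0.5 > fr(y_trans, "frac_AMBRA1_P")
        assert fr(y_auto, "frac_AMBRA1_P") > 0.5 > fr(y_auto, "frac_EIF4EBP1_P")


class TestStressProtocol:
    def test_apply_stress_resets_totals_exactly(self, nominal_network,
                                                nominal_model,
                                                unstressed_state):
        y = apply_stress(nominal_network, nominal_model.params,
                         unstressed_state, ampk_star=150_000.0,
                         rapamycin_star=9_000.0)
        ampk = nominal_network.species_total("AMPK")
        rapa = nominal_network.species_total("rapa")
        assert ampk @ y == pytest.approx(150_000.0)
        assert rapa @ y == pytest.approx(9_000.0)

    def test_overdraw_of_free_pool_rejected(self, nominal_network,
                                            nominal_model, unstressed_state):
        with pytest.raises(ValueError):
            apply_stress(nominal_network, nominal_model.params,
                         unstressed_state, ampk_star=0.0)
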