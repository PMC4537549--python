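import numpy as np
import pytest

from sphingoflux import (
    Compartment,
    KineticLaw,
    LawForm,
    Reaction,
    ReactionNetwork,
    Species,
    detect_divergence,
    find_stationary_state,
    make_birth_death,
    make_linear_chain,
    simulate,
    ssa_simulate,
)


class TestSimulate:
    def test_birth_death_closed_form(self, birth_death):
        traj = simulate(birth_death, np.array([0.0]), 5.0)
        assert traj.final_state()[0] == pytest.approx(10 * (1 - np.exp(-5)), rel=1e-7)

    def test_stationary_start_stays_constant(self, homeostasis):
        grid = np.linspace(0.0, 50.0, 21)
        traj = simulate(homeostasis, homeostasis.initial_state(), 50.0, grid)
        drift = np.abs(traj.values - traj.values[0]).max()
        assert drift <= 1e-6 * traj.values[0].max()

    def test_chain_limits(self, chain):
        traj = simulate(chain, np.array([0.0, 0.0]), 40.0)
        assert traj.final_state() == pytest.approx([2.0, 4.0], rel=1e-6)

    def test_time_rescaling_property(self, random_net):
        """Doubling every rate and halving time reproduces the trajectory."""
        fast = random_net.copy()
        for key, value in random_net.parameter_registry().items():
            if key.endswith((".k", ".Vmax")):
                fast.set_parameter(key, 2 * value)
        x0 = random_net.initial_state()
        grid = np.linspace(0.0, 8.0, 33)
        slow = simulate(random_net, x0, 8.0, grid)
        quick = simulate(fast, x0, 4.0, grid / 2)
        assert np.allclose(slow.values, quick.values, rtol=1e-6, atol=1e-9)

    def test_negative_initial_state_rejected(self, birth_death):
        with pytest.raises(Exception):
            simulate(birth_death, np.array([-1.0]), 1.0)


class TestStationaryState:
    def test_birth_death(self, birth_death):
        ss = find_stationary_state(birth_death, np.array([0.0]))
        assert ss.state[0] == pytest.approx(10.0, rel=1e-8)

    def test_chain(self, chain):
        ss = find_stationary_state(chain, np.array([0.0, 0.0]))
        assert ss.state == pytest.approx([2.0, 4.0], rel=1e-8)

    def test_homeostasis_residual(self, homeostasis):
        ss = find_stationary_state(homeostasis, homeostasis.initial_state())
        flux_norm = np.linalg.norm(homeostasis.compiled().flux(ss.state))
        assert ss.residual_norm <= 1e-8 * flux_norm

    def test_fixed_point_of_further_integration(self, chain):
        ss = find_stationary_state(chain, np.array([0.0, 0.0]))
        traj = simulate(chain, ss.state, 100.0)
        assert np.allclose(traj.values, ss.state, rtol=1e-7, atol=1e-10)

    def test_nonconvergence_reported(self):
        # pure production never plateaus
        net = ReactionNetwork(
            [Compartment("c")],
            [Species("X", compartment="c")],
            [Reaction("make", products=[("X", 1)],
                      law=KineticLaw(LawForm.MASS_ACTION, {"k": 1.0}))],
        )
        with pytest.raises(Exception, match="plateau"):
            find_stationary_state(net, np.array([0.0]), horizon=100.0)


class TestDetectDivergence:
    def test_bounded_trajectory_empty(self, birth_death):
        traj = simulate(birth_death, np.array([0.0]), 10.0)
        assert detect_divergence(traj, threshold=100.0) == []

    def test_pure_production_crossing_time(self):
        net = ReactionNetwork(
            [Compartment("c")],
            [Species("X", compartment="c")],
            [Reaction("make", products=[("X", 1)],
                      law=KineticLaw(LawForm.MASS_ACTION, {"k": 1.0}))],
        )
        traj = simulate(net, np.array([0.0]), 20.0, np.linspace(0, 20, 2001))
        hits = detect_divergence(traj, threshold=10.0)
        assert len(hits) == 1
        species, t_cross = hits[0]
        assert species == "X"
        assert t_cross == pytest.approx(10.0, abs=0.02)

    def test_threshold_must_exceed_initial(self, birth_death):
        traj = simulate(birth_death, np.array([5.0]), 1.0)
        with pytest.raises(ValueError):
            detect_divergence(traj, threshold=1.0)


class TestSsa:
    def test_zero_propensity_network_constant(self):
        net = ReactionNetwork(
            [Compartment("c")],
            [Species("X", compartment="c", initial_concentration=3.0),
             Species("Y", compartment="c")],
            [Reaction("r", substrates=[("Y", 1)],
                      law=KineticLaw(LawForm.MASS_ACTION, {"k": 1.0}))],
        )
        paths = ssa_simulate(net, np.array([3, 0]), t_end=5.0, n_paths=4, seed=0,
                             sample_times=np.array([1.0, 5.0]))
        assert np.all(paths[:, :, 0] == 3) and np.all(paths[:, :, 1] == 0)

    def test_reproducible_given_seed(self, birth_death):
        a = ssa_simulate(birth_death, np.array([0.0]), 5.0, n_paths=5, seed=42)
        b = ssa_simulate(birth_death, np.array([0.0]), 5.0, n_paths=5, seed=42)
        assert np.array_equal(a, b)

    def test_birth_death_poisson_moments(self, birth_death):
        """Stationary law of the linear birth-death process is Poisson(10)."""
        n = 3000
        states = ssa_simulate(birth_death, np.array([10.0]), t_end=8.0,
                              n_paths=n, seed=7)[:, -1, 0]
        se_mean = np.sqrt(10.0 / n)
        assert abs(states.mean() - 10.0) <= 3 * se_mean
        se_var = 10.0 * np.sqrt(2.0 / (n - 1))
        assert abs(states.var(ddof=1) - 10.0) <= 4 * se_var

    def test_mean_field_agreement_on_chain(self, chain):
        """SSA ensemble mean matches the ODE solution for first-order kinetics."""
        n = 1500
        t = 3.0
        states = ssa_simulate(chain, np.array([0.0, 0.0]), t_end=t,
                              n_paths=n, seed=11)[:, -1, :]
        ode = simulate(chain, np.array([0.0, 0.0]), t).final_state()
        for i in range(2):
            se = np.sqrt(max(states[:, i].var(ddof=1), 1e-9) / n)
            assert abs(states[:, i].mean() - ode[i]) <= 3.5 * se

    def test_integer_counts_required(self, birth_death):
        with pytest.raises(Exception):
            ssa_simulate(birth_death, np.array([1.5]), 1.0, 1, 0)
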