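import numpy as np
import pytest

from sphingoflux import (
    find_stationary_state,
    forward_sensitivities,
    make_birth_death,
    rank_parameters,
    sensitivity_indices,
)
from sphingoflux.sensitivity import stationary_parameter_derivatives

from conftest import finite_difference_sensitivities


class TestForwardSensitivities:
    def test_birth_death_closed_form(self, birth_death):
        """From the stationary start, dx/dk1 = (1-exp(-k2 t))/k2."""
        grid = np.linspace(0.0, 1.0, 11)
        sens = forward_sensitivities(birth_death, x0=np.array([10.0]), grid=grid)
        i = sens.param_names.index("birth.k")
        expected = (1 - np.exp(-grid)) / 1.0
        assert np.allclose(sens.derivatives[:, 0, i], expected, rtol=1e-6, atol=1e-9)
        assert sens.derivatives[-1, 0, i] == pytest.approx(1 - np.exp(-1), rel=1e-6)

    def test_upstream_species_blind_to_downstream_rate(self, chain):
        """A is untouched by the efflux rate acting strictly downstream."""
        sens = forward_sensitivities(chain, x0=np.array([2.0, 4.0]),
                                     grid=np.linspace(0, 5, 21))
        i = sens.param_names.index("efflux.k")
        assert np.allclose(sens.derivatives[:, 0, i], 0.0, atol=1e-10)

    def test_sensitivities_start_at_zero(self, random_net):
        sens = forward_sensitivities(random_net, grid=np.linspace(0, 2, 9))
        assert np.allclose(sens.derivatives[0], 0.0)

    @pytest.mark.parametrize("fixture", ["chain", "random_net"])
    def test_finite_difference_oracle(self, fixture, request):
        net = request.getfixturevalue(fixture)
        x0 = net.initial_state()
        grid = np.linspace(0.0, 5.0, 11)
        sens = forward_sensitivities(net, x0=x0, grid=grid, method="ode")
        fd = finite_difference_sensitivities(net, x0, grid)
        scale = np.abs(sens.derivatives).max()
        assert np.allclose(sens.derivatives, fd, rtol=1e-4, atol=1e-4 * scale)

    def test_expm_path_matches_ode_path(self, chain):
        """Piecewise-frozen propagation agrees with the augmented ODE on a
        dense grid, including away from stationarity."""
        grid = np.linspace(0.0, 4.0, 161)
        a = forward_sensitivities(chain, x0=np.array([0.0, 0.0]), grid=grid, method="ode")
        b = forward_sensitivities(chain, x0=np.array([0.0, 0.0]), grid=grid, method="expm")
        scale = np.abs(a.derivatives).max()
        assert np.allclose(a.derivatives, b.derivatives, atol=5e-3 * scale)

    def test_long_time_limit_is_implicit_derivative(self, chain):
        """The sensitivity course converges to -A^{-1} B from M v(Phi*)=0."""
        phi = find_stationary_state(chain, np.array([0.0, 0.0])).state
        sens = forward_sensitivities(chain, x0=phi, grid=np.linspace(0, 60, 31))
        limit = stationary_parameter_derivatives(chain, phi)
        assert np.allclose(sens.derivatives[-1], limit, rtol=1e-6, atol=1e-9)


class TestSensitivityIndices:
    def test_birth_death_integral(self, birth_death):
        grid = np.linspace(0.0, 10.0, 4001)
        sens = forward_sensitivities(birth_death, x0=np.array([10.0]), grid=grid)
        table = sensitivity_indices(sens)
        # integral of (1-e^-t) over [0, 10]
        expected = 10.0 - (1 - np.exp(-10.0))
        assert table.loc["X", "birth.k"] == pytest.approx(expected, rel=1e-5)

    def test_zero_column_zero_index(self, chain):
        sens = forward_sensitivities(chain, x0=np.array([2.0, 4.0]),
                                     grid=np.linspace(0, 5, 41))
        table = sensitivity_indices(sens)
        assert table.loc["A", "efflux.k"] == 0.0

    def test_quadrature_grid_convergence(self, random_net):
        x0 = random_net.initial_state()
        coarse = sensitivity_indices(
            forward_sensitivities(random_net, x0=x0, grid=np.linspace(0, 5, 101))
        )
        fine = sensitivity_indices(
            forward_sensitivities(random_net, x0=x0, grid=np.linspace(0, 5, 201))
        )
        denom = np.abs(fine.to_numpy()).max()
        rel = np.abs(coarse.to_numpy() - fine.to_numpy()).max() / denom
        assert rel < 1e-3

    def test_indices_invariant_to_negligible_reaction(self):
        from sphingoflux.network import KineticLaw, LawForm, Reaction

        base = make_birth_death(10.0, 1.0)
        extended = base.copy()
        extended.reactions.append(
            Reaction("ghost", substrates=[("X", 1)], products=[("X", 2)],
                     law=KineticLaw(LawForm.MASS_ACTION, {"k": 1e-300}))
        )
        extended._compiled = None
        grid = np.linspace(0.0, 5.0, 51)
        a = sensitivity_indices(forward_sensitivities(base, x0=np.array([10.0]), grid=grid))
        b = sensitivity_indices(forward_sensitivities(extended, x0=np.array([10.0]), grid=grid))
        common = [c for c in a.columns]
        assert np.allclose(a[common].to_numpy(), b[common].to_numpy(), rtol=1e-9)

    def test_log_normalization_scales_by_theta(self, chain):
        sens = forward_sensitivities(chain, x0=np.array([0.0, 0.0]),
                                     grid=np.linspace(0, 5, 21))
        norm = sens.normalized()
        assert np.allclose(
            norm.derivatives, sens.derivatives * sens.theta0[None, None, :]
        )


class TestRankParameters:
    def test_single_parameter_model(self):
        net = make_birth_death(5.0, 1.0)
        sens = forward_sensitivities(net, x0=np.array([5.0]), grid=np.linspace(0, 5, 51))
        ranked = rank_parameters(sensitivity_indices(sens))
        assert len(ranked) == 2 and ranked.iloc[0] >= ranked.iloc[1]

    def test_birth_death_stationary_ranking(self):
        """With k1=k2=1 and x0=x*, |dx*/dk2| = k1/k2^2 = 1 = |dx*/dk1|; at
        finite k2=0.5 the decay constant dominates."""
        net = make_birth_death(1.0, 0.5)
        sens = forward_sensitivities(net, x0=np.array([2.0]),
                                     grid=np.linspace(0, 80, 401))
        ranked = rank_parameters(sensitivity_indices(sens))
        # |dx*/dk2| = k1/k2^2 = 4 > |dx*/dk1| = 1/k2 = 2
        assert ranked.index[0] == "death.k"

    def test_empty_subset_rejected(self, chain):
        sens = forward_sensitivities(chain, grid=np.linspace(0, 2, 11))
        with pytest.raises(ValueError):
            rank_parameters(sensitivity_indices(sens), [])

    def test_ties_broken_lexicographically(self, chain):
        import pandas as pd

        table = pd.DataFrame(
            [[1.0, 1.0, 0.5]], index=["A"], columns=["b.k", "a.k", "c.k"]
        )
        ranked = rank_parameters(table, ["A"])
        assert list(ranked.index) == ["a.k", "b.k", "c.k"]
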