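import numpy as np
import pytest

from sphingoflux import (
    Compartment,
    KineticLaw,
    LawForm,
    NetworkError,
    Reaction,
    ReactionNetwork,
    Species,
    build_propensities,
    build_rhs,
    make_random_network,
    reaction_flux,
    stoichiometry_matrix,
)


class TestStoichiometryMatrix:
    def test_birth_death(self, birth_death):
        assert stoichiometry_matrix(birth_death).tolist() == [[1, -1]]

    def test_linear_chain(self, chain):
        assert stoichiometry_matrix(chain).tolist() == [[1, -1, 0], [0, 1, -1]]

    def test_full_model_shape(self, homeostasis):
        assert stoichiometry_matrix(homeostasis).shape == (39, 69)

    def test_modifiers_contribute_zero(self, homeostasis):
        M = stoichiometry_matrix(homeostasis)
        idx = homeostasis.species_index()
        for j, r in enumerate(homeostasis.reactions):
            touched = {sid for sid, _ in r.substrates + r.products}
            for sid in r.modifiers:
                assert sid not in idx or sid in touched or M[idx[sid], j] == 0

    def test_dangling_species_rejected(self):
        with pytest.raises(NetworkError, match="ghost"):
            ReactionNetwork(
                [Compartment("c")],
                [Species("X", compartment="c")],
                [Reaction("r", substrates=[("ghost", 1)],
                          law=KineticLaw(LawForm.MASS_ACTION, {"k": 1.0}))],
            )


class TestReactionFlux:
    def test_mass_action(self):
        r = Reaction("r", substrates=[("S", 1)],
                     law=KineticLaw(LawForm.MASS_ACTION, {"k": 2.0}))
        assert reaction_flux(r, {"S": 3.0}) == pytest.approx(6.0)

    def test_mm_half_saturation(self):
        r = Reaction("r", substrates=[("S", 1)], products=[("P", 1)],
                     law=KineticLaw(LawForm.MICHAELIS_MENTEN, {"Vmax": 10.0, "Km": 5.0}))
        assert reaction_flux(r, {"S": 5.0}) == pytest.approx(5.0)

    def test_mm_inhibited_halves_at_ki(self):
        r = Reaction(
            "r", substrates=[("S", 1)], products=[("P", 1)],
            law=KineticLaw(LawForm.MM_INHIBITED, {"Vmax": 10.0, "Km": 5.0},
                           inhibitors=[("I", 2.0)]),
        )
        assert reaction_flux(r, {"S": 5.0, "I": 2.0}) == pytest.approx(2.5)

    def test_zero_substrate_gives_zero(self):
        r = Reaction("r", substrates=[("S", 1)], products=[("P", 1)],
                     law=KineticLaw(LawForm.MICHAELIS_MENTEN, {"Vmax": 10.0, "Km": 5.0}))
        assert reaction_flux(r, {"S": 0.0}) == 0.0

    def test_negative_concentration_rejected(self):
        r = Reaction("r", substrates=[("S", 1)],
                     law=KineticLaw(LawForm.MASS_ACTION, {"k": 1.0}))
        with pytest.raises(NetworkError, match="negative"):
            reaction_flux(r, {"S": -1.0})


class TestBuildRhs:
    def test_birth_death_value(self, birth_death):
        assert build_rhs(birth_death)(np.array([4.0]))[0] == pytest.approx(6.0)

    def test_birth_death_stationary_point(self, birth_death):
        assert build_rhs(birth_death)(np.array([10.0]))[0] == pytest.approx(0.0)

    def test_chain_stationary_point(self, chain):
        rhs = build_rhs(chain)(np.array([2.0, 4.0]))
        assert np.allclose(rhs, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_rhs_equals_per_species_sum(self, seed):
        """M v(S) agrees entrywise with the per-species flux summation."""
        net = make_random_network(4, 7, mm_fraction=0.5, seed=seed)
        rhs = build_rhs(net)
        M = stoichiometry_matrix(net)
        rng = np.random.default_rng(seed)
        for _ in range(20):
            x = rng.uniform(0, 3, size=4)
            state = dict(zip((s.id for s in net.dynamic_species), x))
            manual = M @ np.array(
                [reaction_flux(r, state) for r in net.reactions]
            )
            assert np.allclose(rhs(x), manual, rtol=1e-12, atol=1e-12)

    def test_fluxes_nonnegative_for_nonnegative_states(self, homeostasis):
        compiled = homeostasis.compiled()
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.uniform(0, 50, size=39)
            assert np.all(compiled.flux(x) >= 0)


class TestBuildPropensities:
    def test_birth_death(self, birth_death):
        a = build_propensities(birth_death)(np.array([10.0]))
        assert np.allclose(a, [10.0, 10.0])

    def test_zero_copy_substrate(self, chain):
        a = build_propensities(chain)(np.array([0.0, 0.0]))
        assert a[1] == 0.0 and a[2] == 0.0 and a[0] == pytest.approx(4.0)

    def test_mm_propensity_at_km(self):
        net = ReactionNetwork(
            [Compartment("c")],
            [Species("S", compartment="c", initial_concentration=5.0)],
            [Reaction("r", substrates=[("S", 1)],
                      law=KineticLaw(LawForm.MICHAELIS_MENTEN, {"Vmax": 10.0, "Km": 5.0}))],
        )
        assert build_propensities(net)(np.array([5.0]))[0] == pytest.approx(5.0)

    def test_propensity_equals_macroscopic_flux(self, random_net):
        compiled = random_net.compiled()
        a = build_propensities(random_net)
        x = random_net.initial_state() + 0.5
        assert np.allclose(a(x), compiled.flux(x))


class TestMassConservation:
    def test_closed_conversion_chain_conserves_mass(self):
        """With boundary reactions removed, 1^T M v = 0 for every state."""
        net = ReactionNetwork(
            [Compartment("c")],
            [Species("A", compartment="c", initial_concentration=2.0),
             Species("B", compartment="c", initial_concentration=1.0)],
            [Reaction("ab", substrates=[("A", 1)], products=[("B", 1)],
                      law=KineticLaw(LawForm.MASS_ACTION, {"k": 2.0})),
             Reaction("ba", substrates=[("B", 1)], products=[("A", 1)],
                      law=KineticLaw(LawForm.MASS_ACTION, {"k": 0.5}))],
        )
        rhs = build_rhs(net)
        for x in ([1.0, 1.0], [0.3, 2.5], [5.0, 0.0]):
            assert np.sum(rhs(np.array(x))) == pytest.approx(0.0, abs=1e-14)


class TestParameterRegistry:
    def test_keys_are_reaction_scoped(self, chain):
        assert set(chain.parameter_registry()) == {
            "influx.k", "convert.k", "efflux.k"
        }

    def test_set_get_roundtrip(self, chain):
        net = chain.copy()
        net.set_parameter("convert.k", 7.5)
        assert net.get_parameter("convert.k") == 7.5
        # compiled functions see the new value
        assert build_rhs(net)(np.array([1.0, 0.0]))[1] == pytest.approx(7.5)

    def test_unknown_key_rejected(self, chain):
        with pytest.raises(NetworkError):
            chain.copy().set_parameter("convert.q", 1.0)

    def test_nonpositive_value_rejected(self, chain):
        with pytest.raises(NetworkError):
            chain.copy().set_parameter("convert.k", 0.0)


class TestTextSerialization:
    @pytest.mark.parametrize("fixture", ["birth_death", "chain", "redundant_pair",
                                         "random_net", "homeostasis"])
    def test_roundtrip_lossless(self, fixture, request):
        net = request.getfixturevalue(fixture)
        back = ReactionNetwork.from_text(net.to_text())
        assert back.to_dict() == net.to_dict()
        assert np.array_equal(stoichiometry_matrix(back), stoichiometry_matrix(net))
        assert back.parameter_registry() == net.parameter_registry()
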