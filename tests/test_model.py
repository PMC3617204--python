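"""Structural invariants of the network model and RHS assembly."""

import numpy as np
import pytest

from cd4sim.model import (
    CompiledModel,
    ModelDefinition,
    RateLaw,
    Reaction,
    Species,
    StructuralError,
    assemble_rhs,
    validate_model,
)
from cd4sim.kinetics import hill_rate, mass_action_rate
from cd4sim.reference import MASTER_REGULATORS


class TestReferenceStructure:
    def test_structural_counts(self, reference_model):
        assert len(reference_model.species) == 93
        assert len(reference_model.reactions) == 52
        assert len(reference_model.dynamic_species) == 60
        assert len(reference_model.boundary_species) == 33

    def test_validation_passes(self, reference_model):
        report = validate_model(reference_model)
        assert report.passed, report.summary()
        assert (report.n_species, report.n_reactions, report.n_odes) == (93, 52, 60)

    def test_master_regulators_and_ppar_present(self, reference_model):
        ids = set(reference_model.species_ids)
        assert set(MASTER_REGULATORS) <= ids
        assert {"PPARG", "PPARG_a"} <= ids

    def test_external_inputs_are_boundary(self, reference_model):
        for s in reference_model.species:
            if s.role in ("external_cytokine", "neutralizing_antibody"):
                assert s.is_boundary

    def test_deterministic_construction(self, reference_model):
        from cd4sim.reference import build_reference_model

        again = build_reference_model()
        assert again.to_json() == reference_model.to_json()

    def test_json_round_trip(self, reference_model):
        clone = ModelDefinition.from_json(reference_model.to_json())
        assert clone.to_json() == reference_model.to_json()


class TestValidationFailures:
    def test_dangling_reference(self, decay_toy):
        bad = decay_toy.copy()
        bad.reactions = bad.reactions + [
            Reaction(
                id="ghost",
                substrates=(("MISSING", 1.0),),
                products=(),
                rate_law=RateLaw(kind="mass_action", k="k1"),
            )
        ]
        report = validate_model(bad)
        assert not report.passed
        assert any("MISSING" in entry for entry in report.dangling_references)

    def test_negative_initial_level_rejected(self):
        with pytest.raises(ValueError):
            Species("X", "X", "signal_transducer", initial_level=-1.0)

    def test_nonpositive_constant_flagged(self, decay_toy):
        bad = decay_toy.copy()
        bad.parameters = {"k1": -2.0}
        report = validate_model(bad)
        assert not report.passed
        assert "k1" in report.nonpositive_constants

    def test_unreachable_species_flagged(self, decay_toy):
        bad = decay_toy.copy()
        bad.species = bad.species + [Species("orphan", "orphan", "signal_transducer")]
        report = validate_model(bad)
        assert "orphan" in report.unreachable_species


class TestRHS:
    def test_stoichiometry_identity_on_decay_toy(self, decay_toy):
        rhs = assemble_rhs(decay_toy)
        dy = rhs(0.0, np.array([1.0, 0.0]), None)
        assert dy == pytest.approx([-1.0, 1.0])

    def test_mass_action_vanishes_at_zero_state(self, reference_model):
        # with every level (dynamic and boundary) zero, all rates vanish
        cm = CompiledModel(reference_model)
        rates = cm.reaction_rates(np.zeros(cm.n_species))
        assert np.all(rates == 0.0)

    def test_unknown_species_raises_structural_error(self, decay_toy):
        bad = decay_toy.copy()
        bad.reactions = [
            Reaction(
                id="ghost",
                substrates=(("MISSING", 1.0),),
                products=(),
                rate_law=RateLaw(kind="mass_action", k="k1"),
            )
        ]
        with pytest.raises(StructuralError):
            assemble_rhs(bad)

    def test_rhs_linear_in_reactions(self, reference_model):
        # removing one reaction changes the derivative by exactly that
        # reaction's stoichiometry-weighted rate
        rng = np.random.default_rng(7)
        cm = CompiledModel(reference_model)
        y = rng.uniform(0.0, 2.0, cm.n_dynamic)
        full = cm.rhs(0.0, y)
        rates = cm.reaction_rates(cm.full_levels(y))
        for jr in [0, 13, 30, 51]:
            reduced = reference_model.copy()
            reduced.reactions = [r for i, r in enumerate(reduced.reactions) if i != jr]
            dy = CompiledModel(reduced).rhs(0.0, y)
            expected = full - cm.stoich[:, jr] * rates[jr]
            assert np.allclose(dy, expected, atol=1e-12)

    def test_compiled_rates_match_scalar_kinetics(self, reference_model):
        # the vectorized/JIT evaluation agrees with the scalar rate laws
        rng = np.random.default_rng(11)
        cm = CompiledModel(reference_model)
        levels = rng.uniform(0.0, 3.0, cm.n_species)
        rates = cm.reaction_rates(levels)
        idx = cm.index
        p = reference_model.parameters
        for jr, rxn in enumerate(reference_model.reactions):
            law = rxn.rate_law
            if law.kind == "mass_action":
                expected = mass_action_rate(
                    p[law.k], [(levels[idx[s]], st) for s, st in rxn.substrates]
                )
            else:
                expected = hill_rate(
                    p[law.vmax], p[law.km], p[law.n], levels[idx[law.driver]],
                    inhibitors=[(levels[idx[s]], p[pk]) for s, pk in law.inhibitors],
                    coactivators=[(levels[idx[s]], p[pk]) for s, pk in law.coactivators],
                )
                for s, st in rxn.substrates:
                    expected *= levels[idx[s]] ** st
            assert rates[jr] == pytest.approx(expected, rel=1e-12, abs=1e-300)

    def test_numpy_fallback_matches_kernel_path(self, reference_model):
        # the pure-numpy rate evaluation and the JIT kernel are interchangeable
        rng = np.random.default_rng(3)
        cm = CompiledModel(reference_model)
        levels = np.maximum(rng.uniform(-0.5, 3.0, cm.n_species), 0.0) * cm.keep_mask
        assert np.allclose(
            cm._reaction_rates_numpy(levels), cm.reaction_rates(levels),
            rtol=1e-12, atol=1e-300,
        )

    def test_boundary_species_have_zero_derivative(self, source_sink_toy):
        # boundary S feeds the influx but is never integrated
        rhs = assemble_rhs(source_sink_toy)
        dy = rhs(0.0, np.array([0.0]), {"S": 5.0})
        assert dy.shape == (1,)
        assert dy[0] == pytest.approx(0.7 * 5.0)

    def test_knockout_species_is_signaling_dead(self, source_sink_toy):
        cm = CompiledModel(source_sink_toy, knockout=["X"])
        # X's own downstream contribution (efflux) is silenced
        rates = cm.reaction_rates(cm.full_levels(np.array([3.0])))
        assert rates[1] == 0.0

    def test_knockout_unknown_target_rejected(self, decay_toy):
        with pytest.raises(StructuralError):
            CompiledModel(decay_toy, knockout=["NOPE"])

    def test_knockout_parameter_zeroes_reaction(self, decay_toy):
        cm = CompiledModel(decay_toy, knockout=["k1"])
        assert cm.rhs(0.0, np.array([1.0, 0.0]))[0] == 0.0


def test_with_parameters_rejects_unknown(decay_toy):
    with pytest.raises(KeyError):
        decay_toy.with_parameters({"nope": 1.0})


def test_rate_law_requires_fields():
    with pytest.raises(ValueError):
        RateLaw(kind="hill", vmax="v")
    with pytest.raises(ValueError):
        RateLaw(kind="mass_action")
    with pytest.raises(ValueError):
        RateLaw(kind="exotic")
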