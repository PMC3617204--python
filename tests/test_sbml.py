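"""SBML round trips, fixtures, and unsupported-construct rejection."""

import numpy as np
import pytest

from cd4sim.protocols import CANONICAL_RECIPES
from cd4sim.sbml import SBMLError, read_sbml, write_sbml
from cd4sim.simulate import simulate_time_course

MINIMAL_SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version2/core" level="3" version="2">
  <model id="handwritten" name="handwritten">
    <listOfCompartments>
      <compartment id="cell" constant="true" size="1"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="cell" initialConcentration="2.0"
               boundaryCondition="false" constant="false" hasOnlySubstanceUnits="false"/>
      <species id="B" compartment="cell" initialConcentration="0.0"
               boundaryCondition="false" constant="false" hasOnlySubstanceUnits="false"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="kf" value="0.25" constant="true"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="conv" reversible="false">
        <listOfReactants>
          <speciesReference species="A" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="B" stoichiometry="1" constant="true"/>
        </listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><times/><ci> kf </ci><ci> A </ci></apply>
          </math>
        </kineticLaw>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""

EVENT_SBML = MINIMAL_SBML.replace(
    "</listOfReactions>",
    "</listOfReactions><listOfEvents><event id=\"e\"/></listOfEvents>",
)


class TestRoundTrip:
    def test_counts_and_constants_preserved(self, reference_model, tmp_path):
        path = tmp_path / "model.xml"
        write_sbml(reference_model, path)
        back = read_sbml(path)
        assert len(back.species) == len(reference_model.species) == 93
        assert len(back.reactions) == len(reference_model.reactions) == 52
        assert len(back.dynamic_species) == 60
        assert back.parameters == reference_model.parameters
        kinds = [r.rate_law.kind for r in reference_model.reactions]
        assert [r.rate_law.kind for r in back.reactions] == kinds

    def test_round_trip_preserves_simulation(self, reference_model, tmp_path):
        path = tmp_path / "model.xml"
        write_sbml(reference_model, path)
        back = read_sbml(path)
        a = simulate_time_course(reference_model, CANONICAL_RECIPES["Th17"], n_points=60)
        b = simulate_time_course(back, CANONICAL_RECIPES["Th17"], n_points=60)
        denom = np.abs(a.states) + 1e-9
        assert np.max(np.abs(a.states - b.states) / denom) < 1e-9

    def test_diff_stable_across_writes(self, reference_model, tmp_path):
        p1, p2 = tmp_path / "m1.xml", tmp_path / "m2.xml"
        write_sbml(reference_model, p1)
        write_sbml(reference_model, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_boundary_condition_attribute(self, reference_model, tmp_path):
        path = tmp_path / "model.xml"
        write_sbml(reference_model, path)
        text = path.read_text()
        assert text.count('boundaryCondition="true"') == 33
        assert text.count('boundaryCondition="false"') == 60


class TestReader:
    def test_minimal_handwritten_fixture(self, tmp_path):
        path = tmp_path / "mini.xml"
        path.write_text(MINIMAL_SBML)
        model = read_sbml(path)
        assert len(model.species) == 2
        assert len(model.reactions) == 1
        rxn = model.reactions[0]
        assert rxn.rate_law.kind == "mass_action"
        assert rxn.rate_law.k == "kf"
        assert model.parameters["kf"] == 0.25
        # the fixture is the A -> B decay system: B(t) = A0 (1 - e^-kt)
        traj = simulate_time_course(model, {}, t_end=4.0, n_points=50)
        assert traj.final_state["B"] == pytest.approx(2.0 * (1 - np.exp(-1.0)), rel=1e-6)

    def test_event_construct_rejected(self, tmp_path):
        path = tmp_path / "event.xml"
        path.write_text(EVENT_SBML)
        with pytest.raises(SBMLError, match="[Ee]vent"):
            read_sbml(path)

    def test_malformed_xml_rejected(self, tmp_path):
        path = tmp_path / "broken.xml"
        path.write_text("<sbml><unclosed>")
        with pytest.raises(SBMLError, match="malformed"):
            read_sbml(path)

    def test_non_sbml_document_rejected(self, tmp_path):
        path = tmp_path / "other.xml"
        path.write_text("<notsbml/>")
        with pytest.raises(SBMLError):
            read_sbml(path)

    def test_unparseable_kinetic_law_rejected(self, tmp_path):
        bad = MINIMAL_SBML.replace(
            "<apply><times/><ci> kf </ci><ci> A </ci></apply>",
            "<apply><plus/><ci> kf </ci><ci> A </ci></apply>",
        )
        path = tmp_path / "bad.xml"
        path.write_text(bad)
        with pytest.raises(SBMLError, match="unsupported operator"):
            read_sbml(path)
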