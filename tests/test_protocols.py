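"""The in-silico experiments: fate table, agonist scan, knockout, plasticity."""

import numpy as np
import pytest

from cd4sim.phenotype import classify_phenotype
from cd4sim.protocols import (
    CANONICAL_RECIPES,
    PerturbationSpec,
    StimulusRecipe,
    apply_perturbations,
    commitment_time,
    induce_phenotype,
    marker_scales_for,
    plasticity_switch,
    ppar_activation_scan,
    ppar_knockout_compare,
)
from cd4sim.synthetic_data import FATE_TABLE


class TestFateTable:
    @pytest.mark.parametrize("lineage", ["Th1", "Th2", "Th17", "iTreg"])
    def test_canonical_recipe_reproduces_lineage(self, reference_model, lineage):
        traj, call = induce_phenotype(reference_model, lineage)
        assert call.label == lineage
        end = traj.final_state
        scales = marker_scales_for(reference_model)
        for marker in FATE_TABLE[lineage]["up"]:
            # induced markers rise well above the naive baseline
            assert end[marker] > 0.1
        for other in FATE_TABLE[lineage]["suppressed"]:
            # cross-inhibition keeps opposing master regulators far below
            # their own induced levels
            assert end[other] < 0.5 * scales.get(other, 1.0)

    def test_zero_dose_recipe_is_naive(self, reference_model):
        _, call = induce_phenotype(reference_model, "Th17", recipe_override={})
        assert call.label == "naive_mixed"

    def test_unknown_lineage_rejected(self, reference_model):
        with pytest.raises(KeyError):
            induce_phenotype(reference_model, "Th9")


@pytest.fixture(scope="module")
def scan(reference_model):
    return ppar_activation_scan(reference_model, np.linspace(0.0, 2.0, 10))


@pytest.fixture(scope="module")
def switch(reference_model):
    return plasticity_switch(reference_model, agonist_level=2.0)


class TestAgonistScan:
    def test_directions_monotone(self, scan):
        tol = 1e-9
        assert np.all(np.diff(scan.readouts["FOXP3"]) >= -tol)
        assert np.all(np.diff(scan.readouts["IL17_s"]) <= tol)
        assert np.all(np.diff(scan.readouts["RORGT"]) <= tol)

    def test_zero_dose_matches_unperturbed_th17(self, reference_model, scan):
        traj, _ = induce_phenotype(reference_model, "Th17")
        end = traj.final_state
        row0 = scan.readouts.iloc[0]
        assert row0["RORGT"] == pytest.approx(end["RORGT"], rel=1e-3)
        assert row0["FOXP3"] == pytest.approx(end["FOXP3"], rel=1e-3)

    def test_top_dose_converts_to_itreg(self, reference_model):
        traj = plasticity_switch(reference_model, agonist_level=2.0)
        call = classify_phenotype(
            traj.final_state, marker_scales=marker_scales_for(reference_model)
        )
        assert call.label == "iTreg"

    def test_descending_grid_rejected(self, reference_model):
        with pytest.raises(ValueError):
            ppar_activation_scan(reference_model, [1.0, 0.5])


class TestKnockout:
    def test_th17_knockout_upregulates_rorgt_and_il17(self, reference_model):
        out = ppar_knockout_compare(reference_model, "Th17")
        assert out["knockout"]["RORGT"] > out["wild_type"]["RORGT"]
        assert out["knockout"]["IL17_s"] > out["wild_type"]["IL17_s"]

    def test_itreg_knockout_downregulates_foxp3(self, reference_model):
        out = ppar_knockout_compare(reference_model, "iTreg")
        assert out["knockout"]["FOXP3"] < out["wild_type"]["FOXP3"]

    def test_knockout_of_leaf_species_changes_nothing(self, reference_model):
        # TYK2_a has no outgoing influence in the network
        out = ppar_knockout_compare(reference_model, "Th17", target="TYK2_a")
        for r in out["wild_type"]:
            assert out["knockout"][r] == pytest.approx(out["wild_type"][r], rel=1e-9)

    def test_agonist_at_zero_plus_knockout_equals_knockout(self, reference_model):
        # clamping the agonist input at 0 on top of the knockout is a no-op
        traj_ko, _ = induce_phenotype(reference_model, "Th17", knockout=["PPARG_a"])
        recipe, kos = apply_perturbations(
            reference_model,
            CANONICAL_RECIPES["Th17"],
            [
                PerturbationSpec(kind="knockout", target="PPARG_a"),
                PerturbationSpec(kind="agonist_clamp", target="PIO", level=0.0),
            ],
        )
        traj_both, _ = induce_phenotype(
            reference_model, "Th17", knockout=kos, recipe_override=recipe
        )
        assert np.allclose(traj_ko.states[-1], traj_both.states[-1], rtol=1e-9)


class TestPlasticitySwitch:
    def test_post_switch_directions(self, switch):
        t_sw = switch.solver["t_switch"]
        pre = switch.at_time(t_sw)
        post = switch.final_state
        assert post["FOXP3"] > pre["FOXP3"]
        for marker in ("IL17_s", "RORGT", "STAT3_p"):
            assert post[marker] < pre[marker]

    def test_zero_agonist_matches_uninterrupted_induction(self, reference_model):
        traj0 = plasticity_switch(reference_model, agonist_level=0.0)
        base, _ = induce_phenotype(reference_model, "Th17")
        assert traj0.final_state["RORGT"] == pytest.approx(
            base.final_state["RORGT"], rel=1e-4
        )
        assert traj0.final_state["IL17_s"] == pytest.approx(
            base.final_state["IL17_s"], rel=1e-4
        )

    def test_late_il17_ordered_by_agonist_level(self, reference_model):
        levels = [0.0, 0.5, 1.0, 2.0]
        finals = [
            plasticity_switch(reference_model, t_switch=20.0, agonist_level=a).final_state[
                "IL17_s"
            ]
            for a in levels
        ]
        assert all(b <= a + 1e-9 for a, b in zip(finals, finals[1:]))

    def test_invalid_switch_time_rejected(self, reference_model):
        with pytest.raises(ValueError):
            plasticity_switch(reference_model, t_switch=150.0)


def test_commitment_time_tracks_plateau(reference_model):
    traj, _ = induce_phenotype(reference_model, "Th17")
    t95 = commitment_time(traj)
    assert 0.0 < t95 < 100.0
    assert traj.at_time(t95)["RORGT"] >= 0.95 * traj.final_state["RORGT"] * 0.99


def test_recipe_validation():
    with pytest.raises(ValueError):
        StimulusRecipe(doses={"IL6_e": -1.0})
    with pytest.raises(ValueError):
        PerturbationSpec(kind="overexpress", target="X")
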