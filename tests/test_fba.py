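import numpy as np
import pytest

from mitoflux import (
    Reaction,
    constrain_to_diet,
    check_model_integrity,
    fba_max_atp,
    flux_variability,
)
from mitoflux.core import ModelValidationError

from .conftest import single_substrate_model
from .oracles import (
    atp_yield_glucose,
    atp_yield_glucose_anaerobic,
    atp_yield_tag,
)


class TestMaxAtp:
    def test_glucose_yield_matches_proton_accounting(
            self, fixture_model, open_exchange_bounds):
        model = single_substrate_model(fixture_model, open_exchange_bounds,
                                       "EX_glc__D_u")
        sol = fba_max_atp(model)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(atp_yield_glucose(), abs=1e-6)

    def test_palmitate_tag_beats_glucose_per_mole(
            self, fixture_model, open_exchange_bounds):
        pal = single_substrate_model(fixture_model, open_exchange_bounds,
                                     "EX_tagC160_u")
        sol = fba_max_atp(pal)
        assert sol.objective_value == pytest.approx(atp_yield_tag(16, 0), abs=1e-6)
        assert sol.objective_value > atp_yield_glucose()

    @pytest.mark.parametrize("label,carbons,bonds", [
        ("C140", 14, 0), ("C181", 18, 1), ("C205", 20, 5), ("C226", 22, 6)])
    def test_tag_yields_per_species(self, fixture_model, open_exchange_bounds,
                                    label, carbons, bonds):
        model = single_substrate_model(fixture_model, open_exchange_bounds,
                                       f"EX_tag{label}_u")
        sol = fba_max_atp(model)
        assert sol.objective_value == pytest.approx(
            atp_yield_tag(carbons, bonds), abs=1e-6)

    def test_all_exchanges_closed_gives_zero(self, fixture_model,
                                             open_exchange_bounds):
        closed = {k: (0.0, v[1]) for k, v in open_exchange_bounds.items()}
        sol = fba_max_atp(fixture_model.with_bounds(closed))
        assert sol.optimal and abs(sol.objective_value) < 1e-9

    def test_anaerobic_yield_is_fermentative(self, fixture_model,
                                             open_exchange_bounds):
        model = single_substrate_model(fixture_model, open_exchange_bounds,
                                       "EX_glc__D_u")
        anaerobic = model.with_bounds({"EX_o2_u": (0.0, 1000.0)})
        sol = fba_max_atp(anaerobic)
        assert sol.objective_value == pytest.approx(
            atp_yield_glucose_anaerobic(), abs=1e-6)

    def test_synthase_deletion_drops_to_fermentation(self, fixture_model,
                                                     open_exchange_bounds):
        model = single_substrate_model(fixture_model, open_exchange_bounds,
                                       "EX_glc__D_u")
        aerobic = fba_max_atp(model).objective_value
        broken = fba_max_atp(model.without_reactions(["ATPS4m"])).objective_value
        assert broken == pytest.approx(atp_yield_glucose_anaerobic(), abs=1e-6)
        assert broken < aerobic

    def test_steady_state_holds_at_optimum(self, fixture_model):
        from mitoflux import stoichiometric_matrix

        model = constrain_to_diet(fixture_model, "FISH44")
        sol = fba_max_atp(model)
        v = np.array([sol.fluxes[r] for r in model.reaction_ids])
        S = stoichiometric_matrix(model)
        assert np.max(np.abs(S @ v)) < 1e-6
        lb = np.array([r.lower_bound for r in model.reactions])
        ub = np.array([r.upper_bound for r in model.reactions])
        assert np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9)

    def test_relaxation_monotonicity(self, fixture_model):
        """Widening any single uptake bound never reduces the optimum."""
        base = constrain_to_diet(fixture_model, "FAT20")
        ref = fba_max_atp(base).objective_value
        for rxn_id in ("EX_glc__D_u", "EX_tagC160_u", "EX_tagC182_u", "EX_o2_u"):
            rxn = base.reaction(rxn_id)
            widened = base.with_bounds(
                {rxn_id: (rxn.lower_bound * 2 - 1e-3, rxn.upper_bound)})
            assert fba_max_atp(widened).objective_value >= ref - 1e-9

    def test_crossed_bounds_rejected_before_solving(self, fixture_model):
        with pytest.raises(ModelValidationError):
            fixture_model.with_bounds({"PDHm": (1.0, -1.0)})

    def test_missing_objective_rejected(self, toy_chain):
        model = toy_chain
        model.objective_reaction = None
        with pytest.raises(ValueError, match="objective"):
            fba_max_atp(model)


class TestIntegrity:
    def test_fixture_produces_atp_without_gaps(self, fixture_model):
        report = check_model_integrity(fixture_model)
        assert report.atp_producible
        assert report.dead_ends == []
        # phosphate is conserved internally, so its exchange is
        # structurally zero; nothing else may be blocked
        assert set(report.blocked_reactions) <= {"EX_pi_u", "PIt"}


class TestFluxVariability:
    def test_chain_maxima_follow_uptake_cap(self, toy_chain):
        fva = flux_variability(toy_chain, fraction_of_optimum=0.0)
        assert fva["AB"] == (pytest.approx(0.0, abs=1e-9), pytest.approx(1.0))
        assert fva["EX_b"] == (pytest.approx(0.0, abs=1e-9), pytest.approx(1.0))
        assert fva["EX_a"][0] == pytest.approx(-1.0)

    def test_full_optimality_pins_objective(self, fixture_model):
        model = constrain_to_diet(fixture_model, "FAT10")
        opt = fba_max_atp(model).objective_value
        fva = flux_variability(model, fraction_of_optimum=1.0)
        lo, hi = fva["DM_atp_c"]
        assert lo == pytest.approx(opt, rel=1e-6)
        assert hi == pytest.approx(opt, rel=1e-6)

    def test_zero_fraction_ranges_contain_zero_for_reversibles(self, fixture_model):
        model = constrain_to_diet(fixture_model, "FAT10")
        fva = flux_variability(model, fraction_of_optimum=0.0)
        for rxn in model.reactions:
            if rxn.lower_bound < 0 < rxn.upper_bound:
                lo, hi = fva[rxn.id]
                assert lo <= 1e-9 and hi >= -1e-9

    def test_bad_fraction_rejected(self, toy_chain):
        with pytest.raises(ValueError):
            flux_variability(toy_chain, fraction_of_optimum=1.5)


class TestSolverIndependence:
    def test_objective_agrees_with_cobra_on_sbml_export(
            self, fixture_model, tmp_path):
        """Independent cross-check: cobrapy (glpk) on the exported SBML."""
        cobra = pytest.importorskip("cobra")

        from mitoflux import save_model

        model = constrain_to_diet(fixture_model, "FISH44")
        path = tmp_path / "fish44.xml"
        save_model(model, path, format="sbml")
        cb = cobra.io.read_sbml_model(str(path))
        cb.solver = "glpk"
        ours = fba_max_atp(model).objective_value
        theirs = cb.optimize().objective_value
        assert theirs == pytest.approx(ours, abs=1e-6)
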