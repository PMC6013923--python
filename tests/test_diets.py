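import numpy as np
import pytest
from hypothesis import given, strategies as st

from mitoflux import (
    DietSpec,
    PhysiologyParams,
    UptakeBounds,
    apply_diet,
    builtin_diets,
    compute_uptake_bounds,
    default_physiology,
    fba_max_atp,
    get_diet,
)
from mitoflux.diets import glucose_exchange_id, tag_exchange_id
from mitoflux.fixture import FATTY_ACIDS, tag_molar_mass


class TestBuiltinDiets:
    def test_all_seven_present(self):
        assert [d.name for d in builtin_diets()] == [
            "FISH0", "FISH15", "FISH44", "FAT10", "FAT20", "FAT30", "FAT45"]

    def test_printed_compositions(self):
        assert get_diet("FISH0").glucose_content == 31.3
        assert get_diet("FAT45").fa_profile["C16:0"] == 39.0
        assert get_diet("FISH44").fa_profile["C22:6"] == 29.2
        assert get_diet("FISH0").fa_profile["C22:6"] == 0.9
        assert get_diet("FAT10").energy_density == 16.1

    def test_mass_fractions_below_unity(self):
        for diet in builtin_diets():
            assert diet.lipid_frac + diet.carb_frac + diet.protein_frac <= 1
            assert sum(diet.fa_profile.values()) <= 100

    def test_fat_diets_lack_marine_species(self):
        for name in ("FAT10", "FAT20", "FAT30", "FAT45"):
            profile = get_diet(name).fa_profile
            assert "C20:5" not in profile and "C22:6" not in profile

    def test_invalid_composition_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            DietSpec(name="X", lipid_frac=0.7, carb_frac=0.5, protein_frac=0.2,
                     energy_density=20, fa_profile={}, glucose_content=10)
        with pytest.raises(ValueError, match="100"):
            DietSpec(name="X", lipid_frac=0.1, carb_frac=0.5, protein_frac=0.2,
                     energy_density=20, fa_profile={"C16:0": 120.0},
                     glucose_content=10)


class TestPhysiology:
    def test_zero_intake_rejected(self):
        with pytest.raises(ValueError, match="food_intake"):
            PhysiologyParams(food_intake=0.0)

    def test_absorption_fraction_range(self):
        with pytest.raises(ValueError, match="absorption"):
            PhysiologyParams(food_intake=2.0, absorption_fraction=1.5)

    def test_defaults_per_diet(self):
        fish = default_physiology(get_diet("FISH0"))
        fat = default_physiology(get_diet("FAT10"))
        assert fish.food_intake == 2.7 and fat.food_intake == 3.7
        assert default_physiology(get_diet("FAT10"), food_intake=5.0).food_intake == 5.0


class TestUptakeBounds:
    def test_fish_diet_constrains_nine_exchanges(self):
        for name in ("FISH0", "FISH15", "FISH44"):
            diet = get_diet(name)
            bounds = compute_uptake_bounds(diet, default_physiology(diet))
            assert len(bounds.bounds) == 9  # glucose + 8 TAG species

    def test_fat_diets_constrain_seven_exchanges(self):
        for name in ("FAT10", "FAT20", "FAT30", "FAT45"):
            diet = get_diet(name)
            bounds = compute_uptake_bounds(diet, default_physiology(diet))
            assert len(bounds.bounds) == 7  # glucose + 6 TAG species

    def test_conversion_formula(self):
        """The glucose bound follows the documented unit conversion."""
        diet = get_diet("FISH0")
        phys = PhysiologyParams(food_intake=2.7, intestinal_dry_mass=0.25,
                                absorption_fraction=1.0)
        bounds = compute_uptake_bounds(diet, phys).bounds
        expected = 2.7 * 0.313 / 180.16 * 1000 / (0.25 * 24)
        assert bounds[glucose_exchange_id()] == pytest.approx(expected, rel=1e-12)
        fa = FATTY_ACIDS["C22:6"]
        expected_dha = (2.7 * 0.352 * 0.009 / tag_molar_mass(fa)) * 1000 / 6.0
        assert bounds[tag_exchange_id(fa)] == pytest.approx(expected_dha, rel=1e-12)

    def test_linearity_in_intake(self):
        diet = get_diet("FAT20")
        b1 = compute_uptake_bounds(diet, PhysiologyParams(food_intake=2.0)).bounds
        b2 = compute_uptake_bounds(diet, PhysiologyParams(food_intake=4.0)).bounds
        for key in b1:
            assert b2[key] == pytest.approx(2 * b1[key], rel=1e-12)

    @given(
        lipid=st.floats(0.01, 0.5),
        intake=st.floats(0.5, 10),
        dry_mass=st.floats(0.05, 2.0),
        profile=st.dictionaries(
            st.sampled_from(sorted(FATTY_ACIDS)),
            st.floats(0.1, 12.0), min_size=1, max_size=8),
    )
    def test_mass_conservation_property(self, lipid, intake, dry_mass, profile):
        """Grams of TAG assigned across species sum to the lipid supply."""
        diet = DietSpec(name="X", lipid_frac=lipid, carb_frac=0.2,
                        protein_frac=0.2, energy_density=18.0,
                        fa_profile=profile, glucose_content=20.0)
        phys = PhysiologyParams(food_intake=intake, intestinal_dry_mass=dry_mass)
        bounds = compute_uptake_bounds(diet, phys).bounds
        grams = sum(
            bounds[tag_exchange_id(label)]
            * tag_molar_mass(FATTY_ACIDS[label]) / 1000 * dry_mass * 24
            for label in profile
        )
        assert grams == pytest.approx(
            intake * lipid * sum(profile.values()) / 100, rel=1e-9)

    def test_scale_equivariance_in_dry_mass(self):
        diet = get_diet("FISH44")
        b1 = compute_uptake_bounds(
            diet, PhysiologyParams(food_intake=2.5, intestinal_dry_mass=0.2)).bounds
        b2 = compute_uptake_bounds(
            diet, PhysiologyParams(food_intake=2.5, intestinal_dry_mass=0.4)).bounds
        for key in b1:
            assert b1[key] == pytest.approx(2 * b2[key], rel=1e-12)

    def test_unknown_species_lists_known(self):
        diet = DietSpec(name="X", lipid_frac=0.1, carb_frac=0.3, protein_frac=0.2,
                        energy_density=18.0, fa_profile={"C17:0": 5.0},
                        glucose_content=20.0)
        with pytest.raises(KeyError, match="C14:0"):
            compute_uptake_bounds(diet, PhysiologyParams(food_intake=2.0))

    def test_negative_bound_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            UptakeBounds(bounds={"EX_glc__D_u": -1.0})


class TestApplyDiet:
    def test_sets_negative_lower_bounds(self, fixture_model):
        diet = get_diet("FISH0")
        bounds = compute_uptake_bounds(diet, default_physiology(diet))
        constrained = apply_diet(fixture_model, bounds)
        dha = constrained.reaction(tag_exchange_id("C22:6"))
        assert dha.lower_bound == -bounds.bounds[tag_exchange_id("C22:6")]
        assert 0 > dha.lower_bound > -1e-2  # small but nonzero DHA allowance

    def test_closed_default_keeps_oxygen_open(self, fixture_model):
        diet = get_diet("FAT10")
        constrained = apply_diet(
            fixture_model, compute_uptake_bounds(diet, default_physiology(diet)))
        assert constrained.reaction("EX_o2_u").lower_bound < 0
        assert constrained.reaction("EX_lac__L_u").lower_bound == 0
        # secretion unconstrained
        assert constrained.reaction("EX_co2_u").upper_bound > 0

    def test_empty_bounds_closed_default_gives_zero_atp(self, fixture_model):
        starved = apply_diet(fixture_model, UptakeBounds(bounds={}))
        sol = fba_max_atp(starved)
        assert sol.optimal and abs(sol.objective_value) < 1e-9

    def test_idempotent(self, fixture_model):
        diet = get_diet("FISH15")
        bounds = compute_uptake_bounds(diet, default_physiology(diet))
        once = apply_diet(fixture_model, bounds)
        twice = apply_diet(once, bounds)
        assert [
            (r.lower_bound, r.upper_bound) for r in once.reactions
        ] == [(r.lower_bound, r.upper_bound) for r in twice.reactions]

    def test_missing_exchange_named(self, fixture_model):
        with pytest.raises(KeyError, match="EX_ghost_u"):
            apply_diet(fixture_model, UptakeBounds(bounds={"EX_ghost_u": 1.0}))
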