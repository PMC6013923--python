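"""Dietary compositions and their conversion to exchange-reaction bounds.

Seven murine diets are built in: three isocaloric high-fat diets whose
omega-3 fraction is progressively replaced by fish oil (FISH0, FISH15,
FISH44) and four diets of increasing lipid/carbohydrate ratio (FAT10,
FAT20, FAT30, FAT45; the number is the fat energy%).

Each dietary fatty-acid species is supplied as a uniform triacylglyceride
(three identical acyl chains). For a species with profile ``p`` g per
100 g lipid, the daily TAG supply is ``food_intake * lipid_frac * p/100``
grams; dividing by the TAG molar mass, multiplying by the absorbed
fraction and normalizing by intestinal dry mass and 24 h gives an uptake
ceiling in mmol per g dry tissue per hour. Glucose is converted the same
way from its g/100 g diet content. The bounds are ceilings (lower bounds
on ``EX_`` reactions), not forced uptake rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .core import MetabolicModel, is_exchange
from .fixture import (
    FATTY_ACIDS,
    GLUCOSE_MOLAR_MASS,
    FattyAcidSpec,
    tag_molar_mass,
)

DIET_NAMES = ("FISH0", "FISH15", "FISH44", "FAT10", "FAT20", "FAT30", "FAT45")

#: Exchanges that stay open to uptake when a diet closes all other
#: substrate inputs: oxygen, water, phosphate and protons.
ALWAYS_OPEN_UPTAKE = ("EX_o2_u", "EX_h2o_u", "EX_pi_u", "EX_h_u")


@dataclass(frozen=True)
class DietSpec:
    """Composition of one diet as printed on the feed label.

    Fractions are g per g diet; ``fa_profile`` maps fatty-acid label to
    g per 100 g dietary lipid; ``glucose_content`` is g glucose
    obtainable from the carbohydrate fraction per 100 g diet;
    ``energy_density`` is kJ/g.
    """

    name: str
    lipid_frac: float
    carb_frac: float
    protein_frac: float
    energy_density: float
    fa_profile: dict[str, float]
    glucose_content: float

    def __post_init__(self) -> None:
        for label, frac in (("lipid", self.lipid_frac), ("carb", self.carb_frac),
                            ("protein", self.protein_frac)):
            if not 0 <= frac <= 1:
                raise ValueError(f"{self.name}: {label} fraction {frac} not in [0,1]")
        if self.lipid_frac + self.carb_frac + self.protein_frac > 1 + 1e-9:
            raise ValueError(f"{self.name}: macronutrient fractions exceed 1 g/g")
        if any(v < 0 for v in self.fa_profile.values()):
            raise ValueError(f"{self.name}: negative fatty-acid profile entry")
        if sum(self.fa_profile.values()) > 100 + 1e-9:
            raise ValueError(f"{self.name}: fatty-acid profile sums above 100 g/100 g")
        if not 0 <= self.glucose_content <= 100:
            raise ValueError(f"{self.name}: glucose content outside [0, 100] g/100 g")


@dataclass(frozen=True)
class PhysiologyParams:
    """Host parameters of the diet-to-bound conversion.

    ``food_intake`` g diet per mouse per day; ``intestinal_dry_mass`` g
    dry small-intestinal tissue; ``absorption_fraction`` of ingested
    substrate reaching the enterocyte.
    """

    food_intake: float
    intestinal_dry_mass: float = 0.25
    absorption_fraction: float = 1.0
    hours_per_day: float = 24.0

    def __post_init__(self) -> None:
        if self.food_intake <= 0:
            raise ValueError("food_intake must be strictly positive")
        if self.intestinal_dry_mass <= 0:
            raise ValueError("intestinal_dry_mass must be strictly positive")
        if not 0 < self.absorption_fraction <= 1:
            raise ValueError("absorption_fraction must be in (0, 1]")
        if self.hours_per_day <= 0:
            raise ValueError("hours_per_day must be strictly positive")


#: Default daily food intake (g/day). The fish-oil diets are isocaloric,
#: with a slight dose-dependent decrease in measured intake; the
#: lipid/carbohydrate series follows isoenergetic feeding at ~60 kJ/day
#: divided by each diet's energy density.
DEFAULT_FOOD_INTAKE = {
    "FISH0": 2.7,
    "FISH15": 2.6,
    "FISH44": 2.5,
    "FAT10": 3.7,
    "FAT20": 3.5,
    "FAT30": 3.3,
    "FAT45": 3.0,
}


def default_physiology(diet: DietSpec, **overrides) -> PhysiologyParams:
    """Default physiology for a builtin diet (explicit values override)."""
    intake = overrides.pop("food_intake", None)
    if intake is None:
        if diet.name not in DEFAULT_FOOD_INTAKE:
            raise ValueError(
                f"no default food intake for diet {diet.name!r}; pass food_intake"
            )
        intake = DEFAULT_FOOD_INTAKE[diet.name]
    return PhysiologyParams(food_intake=intake, **overrides)


def _profile(values: dict[str, float]) -> dict[str, float]:
    return {k: v for k, v in values.items() if v > 0}


def builtin_diets() -> list[DietSpec]:
    """The seven study diets, transcribed from the printed feed table."""
    fish_profile = {
        "FISH0": {"C14:0": 2.4, "C16:0": 11.3, "C18:0": 3.7, "C18:1": 50.8,
                  "C18:2": 19.4, "C18:3": 4.1, "C20:5": 0.2, "C22:6": 0.9},
        "FISH15": {"C14:0": 2.4, "C16:0": 10.8, "C18:0": 3.7, "C18:1": 42.3,
                   "C18:2": 16.6, "C18:3": 3.3, "C20:5": 1.3, "C22:6": 10.5},
        "FISH44": {"C14:0": 2.4, "C16:0": 9.8, "C18:0": 4.2, "C18:1": 25.9,
                   "C18:2": 11.1, "C18:3": 1.9, "C20:5": 3.3, "C22:6": 29.2},
    }
    fat_profile = {
        "FAT10": {"C14:0": 0.9, "C16:0": 24.5, "C18:0": 4.0, "C18:1": 30.6,
                  "C18:2": 35.2, "C18:3": 4.2},
        "FAT20": {"C14:0": 1.5, "C16:0": 33.8, "C18:0": 4.0, "C18:1": 35.8,
                  "C18:2": 22.6, "C18:3": 2.1},
        "FAT30": {"C14:0": 1.6, "C16:0": 36.7, "C18:0": 4.0, "C18:1": 37.5,
                  "C18:2": 18.6, "C18:3": 1.4},
        "FAT45": {"C14:0": 1.8, "C16:0": 39.0, "C18:0": 4.0, "C18:1": 38.8,
                  "C18:2": 15.4, "C18:3": 0.9},
    }
    macro = {
        # name: (lipid, carb, protein, kJ/g, glucose g/100 g)
        "FISH0": (35.2, 35.4, 20.5, 22.8, 31.3),
        "FISH15": (35.2, 35.4, 20.5, 22.8, 31.3),
        "FISH44": (35.2, 35.4, 20.5, 22.8, 31.3),
        "FAT10": (4.3, 66.4, 19.0, 16.1, 65.3),
        "FAT20": (9.0, 59.9, 20.0, 17.0, 57.7),
        "FAT30": (14.3, 52.8, 21.2, 18.0, 49.2),
        "FAT45": (23.6, 40.3, 23.3, 19.8, 34.4),
    }
    diets = []
    for name in DIET_NAMES:
        lipid, carb, protein, energy, glucose = macro[name]
        profile = fish_profile.get(name) or fat_profile[name]
        diets.append(
            DietSpec(
                name=name,
                lipid_frac=lipid / 100,
                carb_frac=carb / 100,
                protein_frac=protein / 100,
                energy_density=energy,
                fa_profile=_profile(profile),
                glucose_content=glucose,
            )
        )
    return diets


def get_diet(name: str) -> DietSpec:
    for diet in builtin_diets():
        if diet.name == name.upper():
            return diet
    raise KeyError(f"unknown diet {name!r}; builtins are {DIET_NAMES}")


@dataclass(frozen=True)
class UptakeBounds:
    """Exchange-reaction id -> uptake ceiling (mmol gDW^-1 h^-1, positive)."""

    bounds: dict[str, float]
    diet_name: str = ""

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.bounds.values()):
            raise ValueError("uptake bounds must be non-negative")


def glucose_exchange_id() -> str:
    return "EX_glc__D_u"


def tag_exchange_id(fa: FattyAcidSpec | str) -> str:
    fa = FATTY_ACIDS[fa] if isinstance(fa, str) else fa
    return f"EX_tag{fa.tag}_u"


def compute_uptake_bounds(diet: DietSpec, phys: PhysiologyParams) -> UptakeBounds:
    """Convert a diet plus physiology into exchange uptake ceilings.

    Returns one glucose entry plus one uniform-TAG entry per fatty-acid
    species with a nonzero profile. Units: mmol per g dry intestinal
    tissue per hour.
    """
    scale = phys.absorption_fraction * 1000.0 / (
        phys.intestinal_dry_mass * phys.hours_per_day
    )  # mol/day -> mmol gDW^-1 h^-1
    bounds: dict[str, float] = {}
    grams_glc = phys.food_intake * diet.glucose_content / 100.0
    bounds[glucose_exchange_id()] = scale * grams_glc / GLUCOSE_MOLAR_MASS
    for label, p_f in diet.fa_profile.items():
        if p_f == 0:
            continue
        if label not in FATTY_ACIDS:
            raise KeyError(
                f"no molar mass on record for fatty acid {label!r}; "
                f"known species: {sorted(FATTY_ACIDS)}"
            )
        fa = FATTY_ACIDS[label]
        grams_tag = phys.food_intake * diet.lipid_frac * p_f / 100.0
        bounds[tag_exchange_id(fa)] = scale * grams_tag / tag_molar_mass(fa)
    return UptakeBounds(bounds=bounds, diet_name=diet.name)


def apply_diet(
    model: MetabolicModel,
    uptake: UptakeBounds,
    closed_default: bool = True,
) -> MetabolicModel:
    """Constrain a model's exchanges to a diet's uptake ceilings.

    Each named exchange gets ``lower_bound = -bound``. With
    ``closed_default`` every other exchange is closed to uptake
    (lower bound 0) except oxygen, water, phosphate and protons;
    secretion stays unconstrained everywhere.
    """
    missing = [r for r in uptake.bounds if not model.has_reaction(r)]
    if missing:
        raise KeyError(f"model lacks exchange reaction(s): {missing}")
    new_bounds: dict[str, tuple[float, float]] = {}
    for rxn_id, bound in uptake.bounds.items():
        rxn = model.reaction(rxn_id)
        if not is_exchange(rxn):
            raise ValueError(f"{rxn_id!r} is not an exchange reaction")
        new_bounds[rxn_id] = (-bound, rxn.upper_bound)
    if closed_default:
        for rxn in model.reactions:
            if not is_exchange(rxn) or rxn.id in new_bounds:
                continue
            if rxn.id in ALWAYS_OPEN_UPTAKE:
                continue
            if rxn.lower_bound < 0:
                new_bounds[rxn.id] = (0.0, rxn.upper_bound)
    return model.with_bounds(new_bounds)


def constrain_to_diet(
    model: MetabolicModel,
    diet: DietSpec | str,
    phys: PhysiologyParams | None = None,
    closed_default: bool = True,
) -> MetabolicModel:
    """Convenience wrapper: diet (by spec or name) -> constrained model."""
    diet = get_diet(diet) if isinstance(diet, str) else diet
    phys = phys or default_physiology(diet)
    return apply_diet(model, compute_uptake_bounds(diet, phys), closed_default)
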