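"""Reduced enterocyte mitochondrial network with analytic stoichiometry.

The builder emits a three-compartment model (lumen ``u``, cytosol ``c``,
mitochondrial matrix ``m``) covering the pathways that carry essentially
all flux in enterocyte energy metabolism:

* luminal hydrolysis and absorption of dietary triacylglycerides (each
  dietary fatty-acid species supplied as a uniform TAG of three
  identical acyl chains) and of glucose,
* cytosolic fatty-acid activation and the carnitine shuttle
  (Cpt1a / Slc25a20 translocase / Cpt2),
* lumped glycolysis, lactate fermentation, the pyruvate carrier, and
  glycerol utilization via glycerol kinase and the triose branch,
* pyruvate dehydrogenase and the full TCA cycle,
* lumped mitochondrial beta-oxidation per fatty-acid species,
* the electron transport chain (complexes I, III, IV over a quinone and
  cytochrome-c pool) pumping protons from the matrix into the cytosol
  (which stands in for the intermembrane space), ATP synthase, the
  adenine-nucleotide and phosphate carriers, and a cytosolic ATP demand
  used as objective.

Every non-boundary reaction is elementally balanced (C, H, O, N, P, S,
Fe) and charge balanced; species formulas for acyl intermediates are
derived arithmetically from chain length and saturation so the balance
holds by construction.

Simplifications, stated loudly: each pre-existing double bond simply
skips one FAD-dependent dehydrogenation (the NADPH-consuming
2,4-dienoyl-CoA reductase route is not modeled); all fatty acids are
oxidized fully inside the matrix (no peroxisomal pre-shortening of DHA);
the malate-aspartate shuttle is lumped into a single redox-transfer
reaction (the glycerol-phosphate shuttle is mechanistic: G3PD1 +
G3PD2m); glycolysis is lumped into a hexose and a triose reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import MetabolicModel, Metabolite, Reaction


class FixtureConfigError(ValueError):
    """Raised for contradictory fixture overrides."""


# ----------------------------------------------------------- fatty acids


@dataclass(frozen=True)
class FattyAcidSpec:
    """One dietary fatty-acid species.

    ``label`` uses the C<carbons>:<double bonds> shorthand; ``molar_mass``
    is for the free acid in g/mol.
    """

    label: str
    carbons: int
    double_bonds: int
    molar_mass: float

    def __post_init__(self) -> None:
        if self.carbons <= 0 or self.carbons % 2 != 0:
            raise ValueError(
                f"{self.label}: only even-chain fatty acids are supported "
                f"(got {self.carbons} carbons)"
            )
        if not 0 <= self.double_bonds < self.carbons / 2:
            raise ValueError(
                f"{self.label}: {self.double_bonds} double bonds is out of range "
                f"for a C{self.carbons} chain"
            )

    @property
    def tag(self) -> str:
        """Compact id fragment, e.g. C16:0 -> 'C160'."""
        return f"C{self.carbons}{self.double_bonds}"


#: The eight dietary species: the six palm/soy-oil acids plus the two
#: marine omega-3 PUFAs (EPA and DHA). Molar masses are free-acid values.
FATTY_ACIDS: dict[str, FattyAcidSpec] = {
    fa.label: fa
    for fa in (
        FattyAcidSpec("C14:0", 14, 0, 228.37),   # myristic
        FattyAcidSpec("C16:0", 16, 0, 256.42),   # palmitic
        FattyAcidSpec("C18:0", 18, 0, 284.48),   # stearic
        FattyAcidSpec("C18:1", 18, 1, 282.46),   # oleic
        FattyAcidSpec("C18:2", 18, 2, 280.45),   # linoleic
        FattyAcidSpec("C18:3", 18, 3, 278.43),   # alpha-linolenic
        FattyAcidSpec("C20:5", 20, 5, 302.45),   # EPA
        FattyAcidSpec("C22:6", 22, 6, 328.49),   # DHA
    )
}

MARINE_LABELS = ("C20:5", "C22:6")

GLYCEROL_MOLAR_MASS = 92.09
WATER_MOLAR_MASS = 18.02
GLUCOSE_MOLAR_MASS = 180.16


def tag_molar_mass(fa: FattyAcidSpec) -> float:
    """Molar mass of the uniform triacylglyceride of ``fa`` (ester bond water loss)."""
    return 3 * fa.molar_mass + GLYCEROL_MOLAR_MASS - 3 * WATER_MOLAR_MASS


@dataclass(frozen=True)
class BetaOxidationStoichiometry:
    """Products of complete matrix beta-oxidation of one acyl-CoA."""

    acetyl_coa: int
    nadh: int
    fadh2: int
    cycles: int


def fa_beta_oxidation_stoichiometry(fa: FattyAcidSpec) -> BetaOxidationStoichiometry:
    """Cofactor yield of complete beta-oxidation of ``fa``.

    A C(2k) chain takes k-1 cycles yielding k acetyl-CoA; every cycle
    reduces one NAD+, and every cycle except those consuming a
    pre-existing double bond (isomerase-mediated) reduces one FAD.
    """
    cycles = fa.carbons // 2 - 1
    return BetaOxidationStoichiometry(
        acetyl_coa=fa.carbons // 2,
        nadh=cycles,
        fadh2=cycles - fa.double_bonds,
        cycles=cycles,
    )


# ------------------------------------------------------------- formulas


def _fmt_formula(counts: dict[str, int]) -> str:
    order = ("C", "H", "N", "O", "P", "S", "Fe")
    parts = []
    for el in order:
        n = counts.get(el, 0)
        if n == 1:
            parts.append(el)
        elif n > 1:
            parts.append(f"{el}{n}")
    return "".join(parts)


def fa_anion_formula(fa: FattyAcidSpec) -> str:
    n, d = fa.carbons, fa.double_bonds
    return _fmt_formula({"C": n, "H": 2 * n - 1 - 2 * d, "O": 2})


def tag_formula(fa: FattyAcidSpec) -> str:
    n, d = fa.carbons, fa.double_bonds
    return _fmt_formula({"C": 3 * n + 3, "H": 6 * n - 6 * d + 2, "O": 6})


def acyl_coa_formula(fa: FattyAcidSpec) -> str:
    n, d = fa.carbons, fa.double_bonds
    return _fmt_formula(
        {"C": n + 21, "H": 2 * n + 30 - 2 * d, "N": 7, "O": 17, "P": 3, "S": 1}
    )


def acyl_carnitine_formula(fa: FattyAcidSpec) -> str:
    n, d = fa.carbons, fa.double_bonds
    return _fmt_formula({"C": n + 7, "H": 2 * n + 13 - 2 * d, "N": 1, "O": 4})


# -------------------------------------------------------- configuration


@dataclass
class FixtureConfig:
    """Tunable stoichiometric and bound parameters of the fixture.

    Proton counts are protons pumped into the cytosolic face per
    catalytic event: complex I per NADH, complex III per quinol,
    complex IV per O2. ``synthase_h`` is protons taken from the
    cytosolic face per ATP synthesized (one of which is consumed in the
    condensation chemistry, the rest returned to the matrix). Defaults
    give 10 H+ pumped per matrix NADH, 6 per FADH2-equivalent quinol and
    an effective cost of 4 H+ per ATP delivered to the cytosol, i.e.
    P/O ratios of 2.5 and 1.5.
    """

    ci_h_pumped: int = 4
    ciii_h_pumped: int = 4
    civ_h_pumped_per_o2: int = 4
    synthase_h: int = 4
    default_bound: float = 1000.0
    include_biosynthetic_drain: bool = False

    def __post_init__(self) -> None:
        if min(self.ci_h_pumped, self.civ_h_pumped_per_o2) < 0:
            raise FixtureConfigError("proton pumping stoichiometry must be >= 0")
        if self.ciii_h_pumped < 2:
            raise FixtureConfigError(
                "complex III releases the two quinol protons; pumped count must be >= 2"
            )
        if self.synthase_h < 1:
            raise FixtureConfigError("ATP synthase must consume at least one proton")
        if self.default_bound <= 0:
            raise FixtureConfigError("default flux bound must be positive")

    @property
    def h_per_nadh(self) -> int:
        """Protons pumped per matrix NADH through complexes I+III+IV."""
        return self.ci_h_pumped + self.ciii_h_pumped + self.civ_h_pumped_per_o2 // 2

    @property
    def h_per_qh2(self) -> int:
        """Protons pumped per quinol entering at complex III (FADH2 level)."""
        return self.ciii_h_pumped + self.civ_h_pumped_per_o2 // 2


# ------------------------------------------------------------- builder


class _Builder:
    def __init__(self) -> None:
        self.metabolites: list[Metabolite] = []
        self.reactions: list[Reaction] = []
        self._seen: set[str] = set()

    def met(self, base: str, compartment: str, formula: str, charge: int,
            name: str = "") -> str:
        met_id = f"{base}_{compartment}"
        if met_id not in self._seen:
            self._seen.add(met_id)
            self.metabolites.append(
                Metabolite(id=met_id, name=name or base, compartment=compartment,
                           formula=formula, charge=charge)
            )
        return met_id

    def rxn(self, rxn_id: str, stoich: dict[str, float], *, name: str = "",
            lb: float, ub: float, gene_rule: str = "", subsystem: str = "") -> None:
        self.reactions.append(
            Reaction(id=rxn_id, name=name, stoichiometry=stoich,
                     lower_bound=lb, upper_bound=ub, gene_rule=gene_rule,
                     subsystem=subsystem)
        )


def build_fixture_model(
    include_marine_fa: bool = True,
    config: FixtureConfig | None = None,
) -> MetabolicModel:
    """Build the reduced enterocyte mitochondrial model.

    ``include_marine_fa`` controls whether the EPA (C20:5) and DHA
    (C22:6) branches — uptake, shuttle and FAOXC205/FAOXC226 — are part
    of the network.
    """
    cfg = config or FixtureConfig()
    B = cfg.default_bound
    b = _Builder()

    fas = [
        fa for fa in FATTY_ACIDS.values()
        if include_marine_fa or fa.label not in MARINE_LABELS
    ]

    # -- shared species ------------------------------------------------
    def shared(base, formula, charge, comps, name=""):
        return {c: b.met(base, c, formula, charge, name) for c in comps}

    glc = shared("glc__D", "C6H12O6", 0, "uc", "D-glucose")
    pyr = shared("pyr", "C3H3O3", -1, "cm", "pyruvate")
    lac = shared("lac__L", "C3H5O3", -1, "uc", "L-lactate")
    atp = shared("atp", "C10H12N5O13P3", -4, "cm", "ATP")
    adp = shared("adp", "C10H12N5O10P2", -3, "cm", "ADP")
    amp = b.met("amp", "c", "C10H12N5O7P", -2, "AMP")
    pi = shared("pi", "HO4P", -2, "ucm", "phosphate")
    ppi = b.met("ppi", "c", "HO7P2", -3, "pyrophosphate")
    h = shared("h", "H", 1, "ucm", "proton")
    h2o = shared("h2o", "H2O", 0, "ucm", "water")
    o2 = shared("o2", "O2", 0, "ucm", "oxygen")
    co2 = shared("co2", "CO2", 0, "ucm", "carbon dioxide")
    nad = shared("nad", "C21H26N7O14P2", -1, "cm", "NAD+")
    nadh = shared("nadh", "C21H27N7O14P2", -2, "cm", "NADH")
    fad = b.met("fad", "m", "C27H31N9O15P2", -2, "FAD")
    fadh2 = b.met("fadh2", "m", "C27H33N9O15P2", -2, "FADH2")
    coa = shared("coa", "C21H32N7O16P3S", -4, "cm", "coenzyme A")
    accoa = b.met("accoa", "m", "C23H34N7O17P3S", -4, "acetyl-CoA")
    crn = shared("crn", "C7H15NO3", 0, "cm", "L-carnitine")
    q10 = b.met("q10", "m", "C59H90O4", 0, "ubiquinone-10")
    q10h2 = b.met("q10h2", "m", "C59H92O4", 0, "ubiquinol-10")
    ficytc = b.met("ficytc", "c", "Fe", 3, "ferricytochrome c")
    focytc = b.met("focytc", "c", "Fe", 2, "ferrocytochrome c")
    glyc = shared("glyc", "C3H8O3", 0, "uc", "glycerol")
    oaa = b.met("oaa", "m", "C4H2O5", -2, "oxaloacetate")
    cit = b.met("cit", "m", "C6H5O7", -3, "citrate")
    icit = b.met("icit", "m", "C6H5O7", -3, "isocitrate")
    akg = b.met("akg", "m", "C5H4O5", -2, "2-oxoglutarate")
    succoa = b.met("succoa", "m", "C25H35N7O19P3S", -5, "succinyl-CoA")
    succ = b.met("succ", "m", "C4H4O4", -2, "succinate")
    fum = b.met("fum", "m", "C4H2O4", -2, "fumarate")
    mal = b.met("mal__L", "m", "C4H4O5", -2, "L-malate")

    # -- exchanges and inter-compartment housekeeping -------------------
    def exchange(met_id, name):
        b.rxn(f"EX_{met_id}", {met_id: -1.0}, name=name, lb=-B, ub=B,
              subsystem="Exchange")

    exchange(glc["u"], "glucose exchange")
    exchange(o2["u"], "oxygen exchange")
    exchange(co2["u"], "carbon dioxide exchange")
    exchange(h2o["u"], "water exchange")
    exchange(pi["u"], "phosphate exchange")
    exchange(h["u"], "proton exchange")
    exchange(glyc["u"], "glycerol exchange")
    exchange(lac["u"], "lactate exchange")

    def transport(rxn_id, met_by_comp, c_from, c_to, name, lb=-B, extra=None,
                  gene_rule=""):
        stoich = {met_by_comp[c_from]: -1.0, met_by_comp[c_to]: 1.0}
        if extra:
            stoich.update(extra)
        b.rxn(rxn_id, stoich, name=name, lb=lb, ub=B, subsystem="Transport",
              gene_rule=gene_rule)

    transport("GLCt", glc, "u", "c", "glucose absorption", lb=0)
    transport("O2t", o2, "u", "c", "oxygen diffusion (lumen)")
    transport("O2tm", o2, "c", "m", "oxygen diffusion (matrix)")
    transport("CO2tm", co2, "m", "c", "CO2 release (matrix)", lb=0)
    transport("CO2t", co2, "c", "u", "CO2 release (lumen)", lb=0)
    transport("H2Ot", h2o, "u", "c", "water diffusion (lumen)")
    transport("H2Otm", h2o, "c", "m", "water diffusion (matrix)")
    transport("PIt", pi, "u", "c", "phosphate absorption")
    transport("Ht", h, "u", "c", "proton equilibration with lumen")
    transport("GLYCt", glyc, "u", "c", "glycerol absorption")
    transport("L_LACt", lac, "c", "u", "lactate export")

    # -- glycolysis, fermentation, pyruvate entry ------------------------
    b.rxn(
        "GLYCOLYSIS",
        {glc["c"]: -1, adp["c"]: -2, pi["c"]: -2, nad["c"]: -2,
         pyr["c"]: 2, atp["c"]: 2, nadh["c"]: 2, h2o["c"]: 2, h["c"]: 2},
        name="glycolysis (lumped, glucose to pyruvate)",
        lb=0, ub=B, subsystem="Glycolysis",
    )
    b.rxn(
        "LDH_L",
        {pyr["c"]: -1, nadh["c"]: -1, h["c"]: -1, lac["c"]: 1, nad["c"]: 1},
        name="L-lactate dehydrogenase", lb=-B, ub=B, subsystem="Glycolysis",
    )
    b.rxn(
        "PYRt2m",
        {pyr["c"]: -1, h["c"]: -1, pyr["m"]: 1, h["m"]: 1},
        name="mitochondrial pyruvate carrier (H+ symport)",
        lb=0, ub=B, subsystem="Transport", gene_rule="Mpc1 and Mpc2",
    )

    # -- PDH and TCA cycle ----------------------------------------------
    b.rxn(
        "PDHm",
        {pyr["m"]: -1, coa["m"]: -1, nad["m"]: -1,
         accoa: 1, co2["m"]: 1, nadh["m"]: 1},
        name="pyruvate dehydrogenase", lb=0, ub=B, subsystem="TCA cycle",
        gene_rule="Pdha1 and Pdhb and Dlat and Dld",
    )
    b.rxn(
        "CSm",
        {accoa: -1, oaa: -1, h2o["m"]: -1, cit: 1, coa["m"]: 1, h["m"]: 1},
        name="citrate synthase", lb=0, ub=B, subsystem="TCA cycle",
        gene_rule="Cs",
    )
    b.rxn("ACONTm", {cit: -1, icit: 1}, name="aconitase", lb=-B, ub=B,
          subsystem="TCA cycle", gene_rule="Aco2")
    b.rxn(
        "ICDHxm",
        {icit: -1, nad["m"]: -1, akg: 1, co2["m"]: 1, nadh["m"]: 1},
        name="isocitrate dehydrogenase (NAD+)", lb=0, ub=B,
        subsystem="TCA cycle", gene_rule="Idh3a and Idh3b and Idh3g",
    )
    b.rxn(
        "AKGDm",
        {akg: -1, coa["m"]: -1, nad["m"]: -1,
         succoa: 1, co2["m"]: 1, nadh["m"]: 1},
        name="2-oxoglutarate dehydrogenase", lb=0, ub=B,
        subsystem="TCA cycle", gene_rule="Ogdh and Dlst and Dld",
    )
    b.rxn(
        "SUCOASm",
        {succoa: -1, adp["m"]: -1, pi["m"]: -1,
         succ: 1, coa["m"]: 1, atp["m"]: 1},
        name="succinyl-CoA synthetase", lb=-B, ub=B, subsystem="TCA cycle",
    )
    b.rxn(
        "SUCD1m",
        {succ: -1, q10: -1, fum: 1, q10h2: 1},
        name="succinate dehydrogenase (complex II)", lb=0, ub=B,
        subsystem="Oxidative phosphorylation", gene_rule="Sdha and Sdhb",
    )
    b.rxn("FUMm", {fum: -1, h2o["m"]: -1, mal: 1}, name="fumarase",
          lb=-B, ub=B, subsystem="TCA cycle")
    b.rxn(
        "MDHm",
        {mal: -1, nad["m"]: -1, oaa: 1, nadh["m"]: 1, h["m"]: 1},
        name="malate dehydrogenase", lb=-B, ub=B, subsystem="TCA cycle",
        gene_rule="Mdh2",
    )

    # -- glycerol utilization and redox shuttles --------------------------
    glyc3p = b.met("glyc3p", "c", "C3H7O6P", -2, "sn-glycerol 3-phosphate")
    dhap = b.met("dhap", "c", "C3H5O6P", -2, "dihydroxyacetone phosphate")
    b.rxn(
        "GLYK",
        {glyc["c"]: -1, atp["c"]: -1, glyc3p: 1, adp["c"]: 1, h["c"]: 1},
        name="glycerol kinase", lb=0, ub=B, subsystem="Glycolysis",
        gene_rule="Gk",
    )
    b.rxn(
        "G3PD1",
        {glyc3p: -1, nad["c"]: -1, dhap: 1, nadh["c"]: 1, h["c"]: 1},
        name="glycerol-3-phosphate dehydrogenase (cytosolic, NAD)",
        lb=-B, ub=B, subsystem="Shuttles", gene_rule="Gpd1",
    )
    b.rxn(
        "G3PD2m",
        {glyc3p: -1, q10: -1, dhap: 1, q10h2: 1},
        name="glycerol-3-phosphate dehydrogenase (mitochondrial face); "
             "with G3PD1 this forms the glycerol-phosphate shuttle",
        lb=0, ub=B, subsystem="Shuttles", gene_rule="Gpd2",
    )
    b.rxn(
        "LOWERGLYC",
        {dhap: -1, adp["c"]: -2, pi["c"]: -1, nad["c"]: -1,
         pyr["c"]: 1, atp["c"]: 2, nadh["c"]: 1, h2o["c"]: 1},
        name="lower glycolysis (lumped, DHAP to pyruvate)",
        lb=0, ub=B, subsystem="Glycolysis",
    )
    b.rxn(
        "MALASPSHm",
        {nadh["c"]: -1, h["c"]: -1, nad["m"]: -1,
         nad["c"]: 1, nadh["m"]: 1, h["m"]: 1},
        name="malate-aspartate shuttle (lumped NADH transfer)",
        lb=0, ub=B, subsystem="Shuttles",
    )

    # -- electron transport chain ----------------------------------------
    p1, p3, p4 = cfg.ci_h_pumped, cfg.ciii_h_pumped, cfg.civ_h_pumped_per_o2
    b.rxn(
        "NADH2_u10m",
        {nadh["m"]: -1, q10: -1, h["m"]: -(p1 + 1),
         nad["m"]: 1, q10h2: 1, h["c"]: p1},
        name="NADH dehydrogenase (complex I)", lb=0, ub=B,
        subsystem="Oxidative phosphorylation",
    )
    b.rxn(
        "ETFQOm",
        {fadh2: -1, q10: -1, fad: 1, q10h2: 1},
        name="electron-transferring flavoprotein:Q oxidoreductase",
        lb=0, ub=B, subsystem="Oxidative phosphorylation", gene_rule="Etfdh",
    )
    b.rxn(
        "CYOR_u10m",
        {q10h2: -1, ficytc: -2, h["m"]: -(p3 - 2),
         q10: 1, focytc: 2, h["c"]: p3},
        name="cytochrome bc1 (complex III)", lb=0, ub=B,
        subsystem="Oxidative phosphorylation",
    )
    b.rxn(
        "CYOOm",
        {focytc: -4, o2["m"]: -1, h["m"]: -(p4 + 4),
         ficytc: 4, h2o["m"]: 2, h["c"]: p4},
        name="cytochrome c oxidase (complex IV)", lb=0, ub=B,
        subsystem="Oxidative phosphorylation", gene_rule="Cox4i1 and Cox6b2",
    )
    q = cfg.synthase_h
    b.rxn(
        "ATPS4m",
        {adp["m"]: -1, pi["m"]: -1, h["c"]: -q,
         atp["m"]: 1, h2o["m"]: 1, h["m"]: q - 1},
        name="ATP synthase", lb=0, ub=B,
        subsystem="Oxidative phosphorylation", gene_rule="Atp5f1a and Atp5f1b",
    )
    b.rxn(
        "ATPtm",
        {atp["m"]: -1, adp["c"]: -1, atp["c"]: 1, adp["m"]: 1},
        name="adenine nucleotide translocase", lb=0, ub=B,
        subsystem="Transport", gene_rule="Slc25a4",
    )
    b.rxn(
        "PIt2m",
        {pi["c"]: -1, h["c"]: -1, pi["m"]: 1, h["m"]: 1},
        name="mitochondrial phosphate carrier (H+ symport)", lb=0, ub=B,
        subsystem="Transport", gene_rule="Slc25a3",
    )
    b.rxn(
        "DM_atp_c",
        {atp["c"]: -1, h2o["c"]: -1, adp["c"]: 1, pi["c"]: 1, h["c"]: 1},
        name="ATP demand (objective)", lb=0, ub=B, subsystem="Demand",
    )

    # -- fatty-acid handling, per species --------------------------------
    b.rxn(
        "PPA",
        {ppi: -1, h2o["c"]: -1, pi["c"]: 2, h["c"]: 1},
        name="inorganic pyrophosphatase", lb=0, ub=B, subsystem="Lipid handling",
    )
    b.rxn(
        "ADK1",
        {amp: -1, atp["c"]: -1, adp["c"]: 2},
        name="adenylate kinase", lb=-B, ub=B, subsystem="Lipid handling",
    )

    for fa in fas:
        t = fa.tag
        n, d = fa.carbons, fa.double_bonds
        tag_u = b.met(f"tag{t}", "u", tag_formula(fa), 0,
                      f"triacylglycerol ({fa.label})")
        fa_u = b.met(f"fa{t}", "u", fa_anion_formula(fa), -1,
                     f"fatty acid {fa.label} (lumen)")
        fa_c = b.met(f"fa{t}", "c", fa_anion_formula(fa), -1,
                     f"fatty acid {fa.label}")
        acoa_c = b.met(f"acoa{t}", "c", acyl_coa_formula(fa), -4,
                       f"{fa.label}-CoA (cytosol)")
        acoa_m = b.met(f"acoa{t}", "m", acyl_coa_formula(fa), -4,
                       f"{fa.label}-CoA (matrix)")
        acrn_c = b.met(f"acrn{t}", "c", acyl_carnitine_formula(fa), 0,
                       f"{fa.label}-carnitine (cytosol)")
        acrn_m = b.met(f"acrn{t}", "m", acyl_carnitine_formula(fa), 0,
                       f"{fa.label}-carnitine (matrix)")

        exchange(tag_u, f"dietary TAG exchange ({fa.label})")
        b.rxn(
            f"LPS{t}",
            {tag_u: -1, h2o["u"]: -3, fa_u: 3, glyc["u"]: 1, h["u"]: 3},
            name=f"luminal TAG hydrolysis ({fa.label})", lb=0, ub=B,
            subsystem="Lipid handling", gene_rule="Pnlip",
        )
        b.rxn(f"FAt{t}", {fa_u: -1, fa_c: 1},
              name=f"fatty-acid absorption ({fa.label})", lb=0, ub=B,
              subsystem="Transport", gene_rule="Cd36")
        b.rxn(
            f"FACOAL{t}",
            {fa_c: -1, coa["c"]: -1, atp["c"]: -1, acoa_c: 1, amp: 1, ppi: 1},
            name=f"fatty-acyl-CoA ligase ({fa.label})", lb=0, ub=B,
            subsystem="Lipid handling", gene_rule="Acsl5",
        )
        b.rxn(
            f"CPT1{t}",
            {acoa_c: -1, crn["c"]: -1, acrn_c: 1, coa["c"]: 1},
            name=f"carnitine palmitoyltransferase 1 ({fa.label})", lb=0, ub=B,
            subsystem="Carnitine shuttle", gene_rule="Cpt1a",
        )
        b.rxn(
            f"CRNtim{t}",
            {acrn_c: -1, crn["m"]: -1, acrn_m: 1, crn["c"]: 1},
            name=f"carnitine/acylcarnitine translocase ({fa.label})",
            lb=-B, ub=B, subsystem="Carnitine shuttle", gene_rule="Slc25a20",
        )
        b.rxn(
            f"CPT2{t}",
            {acrn_m: -1, coa["m"]: -1, acoa_m: 1, crn["m"]: 1},
            name=f"carnitine palmitoyltransferase 2 ({fa.label})", lb=0, ub=B,
            subsystem="Carnitine shuttle", gene_rule="Cpt2",
        )
        box = fa_beta_oxidation_stoichiometry(fa)
        stoich = {
            acoa_m: -1.0,
            coa["m"]: -float(box.cycles),
            nad["m"]: -float(box.cycles),
            h2o["m"]: -float(box.cycles),
            accoa: float(box.acetyl_coa),
            nadh["m"]: float(box.nadh),
            h["m"]: float(box.cycles),
        }
        if box.fadh2 > 0:
            stoich[fad] = -float(box.fadh2)
            stoich[fadh2] = float(box.fadh2)
        b.rxn(
            f"FAOX{t}",
            stoich,
            name=f"mitochondrial beta-oxidation ({fa.label}, lumped)",
            lb=0, ub=B, subsystem="Beta-oxidation",
            gene_rule="Acadvl and Hadha and Hadhb and Acaa2",
        )

    if cfg.include_biosynthetic_drain:
        # placeholder for the phospholipid/heme branches of the full
        # model; closed by default and opened only by explicit bounds
        b.rxn("SK_accoa_m", {accoa: -1},
              name="biosynthetic precursor drain (default closed)",
              lb=0.0, ub=0.0, subsystem="Exchange")

    return MetabolicModel(
        metabolites=b.metabolites,
        reactions=b.reactions,
        objective_reaction="DM_atp_c",
        id="enterocyte_mito_fixture",
    )
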