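"""Compartmentalized constraint-based metabolic models.

A model is a stoichiometric reaction network over three compartments
(luminal ``u``, cytosolic ``c``, mitochondrial matrix ``m``) with flux
bounds in mmol per g dry intestinal tissue per hour. Reversibility is
encoded purely by the bounds: a reaction is reversible iff its lower
bound is negative. Exchange reactions follow the BiGG convention
(``EX_`` prefix, single metabolite, uptake = negative flux).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

COMPARTMENTS = ("u", "c", "m")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelValidationError(ValueError):
    """Raised when a model or one of its parts violates an invariant."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental composition string like ``C6H12O6`` into counts."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ModelValidationError(f"malformed formula {formula!r}")
        pos = match.end()
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    if pos != len(formula):
        raise ModelValidationError(f"malformed formula {formula!r}")
    return counts


@dataclass(frozen=True)
class Metabolite:
    """A chemical species in one compartment.

    The id carries a trailing compartment tag (``glc__D_u``); the tag must
    agree with the ``compartment`` field.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {self.id!r}: unknown compartment tag "
                f"{self.compartment!r} (expected one of {COMPARTMENTS})"
            )
        if not self.id.endswith(f"_{self.compartment}"):
            raise ModelValidationError(
                f"metabolite id {self.id!r} does not end in compartment tag "
                f"'_{self.compartment}'"
            )

    def elements(self) -> dict[str, int] | None:
        return None if self.formula is None else parse_formula(self.formula)


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric conversion with flux bounds and an optional gene rule.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = consumed). Bounds are in mmol gDW^-1 h^-1.
    """

    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    gene_rule: str = ""
    subsystem: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r} has no metabolites")
        for met, coef in self.stoichiometry.items():
            if coef == 0:
                raise ModelValidationError(
                    f"reaction {self.id!r}: zero coefficient for {met!r}"
                )
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def genes(self) -> set[str]:
        """Gene ids referenced by the boolean gene rule."""
        tokens = re.split(r"[\s()]+", self.gene_rule)
        return {t for t in tokens if t and t.lower() not in ("and", "or")}


@dataclass
class MetabolicModel:
    """A compartmentalized reaction network with an ATP-demand objective."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_reaction: str | None = None
    id: str = "model"
    genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups -------------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise KeyError(f"no metabolite {met_id!r} in model {self.id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise KeyError(f"no reaction {rxn_id!r} in model {self.id!r}") from None

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dupes = {m for m in met_ids if met_ids.count(m) > 1}
            raise ModelValidationError(f"duplicate metabolite ids: {sorted(dupes)}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = {r for r in rxn_ids if rxn_ids.count(r) > 1}
            raise ModelValidationError(f"duplicate reaction ids: {sorted(dupes)}")
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}
        for rxn in self.reactions:
            for met_id in rxn.stoichiometry:
                if met_id not in self._met_index:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references undeclared metabolite "
                        f"{met_id!r}"
                    )
        if self.objective_reaction is not None and (
            self.objective_reaction not in self._rxn_index
        ):
            raise ModelValidationError(
                f"objective reaction {self.objective_reaction!r} not in model"
            )
        self.genes = set().union(*(r.genes() for r in self.reactions)) if self.reactions else set()

    # -- mutation helpers (return new models; reactions are frozen) ----

    def with_bounds(self, bounds: dict[str, tuple[float, float]]) -> "MetabolicModel":
        """Return a copy with the named reactions' bounds replaced."""
        missing = [r for r in bounds if r not in self._rxn_index]
        if missing:
            raise KeyError(f"no such reaction(s): {missing}")
        new_rxns = [
            replace(r, lower_bound=bounds[r.id][0], upper_bound=bounds[r.id][1])
            if r.id in bounds
            else r
            for r in self.reactions
        ]
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=new_rxns,
            objective_reaction=self.objective_reaction,
            id=self.id,
        )

    def without_reactions(self, rxn_ids: list[str]) -> "MetabolicModel":
        drop = set(rxn_ids)
        missing = drop - set(self._rxn_index)
        if missing:
            raise KeyError(f"no such reaction(s): {sorted(missing)}")
        obj = self.objective_reaction
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=[r for r in self.reactions if r.id not in drop],
            objective_reaction=None if obj in drop else obj,
            id=self.id,
        )


# -- structural analysis ----------------------------------------------


def stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """Dense stoichiometric matrix S (metabolites x reactions)."""
    met_pos = {m: i for i, m in enumerate(model.metabolite_ids)}
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for met_id, coef in rxn.stoichiometry.items():
            S[met_pos[met_id], j] = coef
    return S


def is_exchange(rxn: Reaction) -> bool:
    """Boundary reaction touching exactly one metabolite."""
    return len(rxn.stoichiometry) == 1


def find_dead_end_metabolites(model: MetabolicModel) -> list[str]:
    """Metabolites that can only be produced or only consumed.

    A reversible reaction counts as both producer and consumer of every
    participant. Exchange reactions count too: a metabolite whose only
    other contact is a reversible exchange is not a dead end.
    """
    producers: dict[str, bool] = {m: False for m in model.metabolite_ids}
    consumers: dict[str, bool] = {m: False for m in model.metabolite_ids}
    for rxn in model.reactions:
        fwd = rxn.upper_bound > 0
        rev = rxn.lower_bound < 0
        for met_id, coef in rxn.stoichiometry.items():
            makes = (coef > 0 and fwd) or (coef < 0 and rev)
            takes = (coef < 0 and fwd) or (coef > 0 and rev)
            producers[met_id] = producers[met_id] or makes
            consumers[met_id] = consumers[met_id] or takes
    return [m for m in model.metabolite_ids if not (producers[m] and consumers[m])]


CLASS_NAMES = ("luminal", "cytosolic", "mitochondrial", "transport", "exchange")

_COMPARTMENT_CLASS = {"u": "luminal", "c": "cytosolic", "m": "mitochondrial"}


@dataclass
class ReactionClassification:
    """Partition of reactions into compartment / transport / exchange classes."""

    counts: dict[str, int]
    assignment: dict[str, str]


def classify_reactions(model: MetabolicModel) -> ReactionClassification:
    """Assign every reaction exactly one class.

    Exchange: boundary reaction of a single metabolite. Transport:
    non-exchange reaction whose participants span two or more
    compartments. Otherwise the class is the (single) compartment of its
    metabolites.
    """
    assignment: dict[str, str] = {}
    for rxn in model.reactions:
        if is_exchange(rxn):
            assignment[rxn.id] = "exchange"
            continue
        comps = {model.metabolite(m).compartment for m in rxn.stoichiometry}
        if len(comps) > 1:
            assignment[rxn.id] = "transport"
        else:
            assignment[rxn.id] = _COMPARTMENT_CLASS[comps.pop()]
    counts = {name: 0 for name in CLASS_NAMES}
    for cls in assignment.values():
        counts[cls] += 1
    return ReactionClassification(counts=counts, assignment=assignment)


def element_balance(model: MetabolicModel, rxn: Reaction) -> dict[str, float]:
    """Net elemental (and charge) imbalance of a reaction.

    Returns a map element -> net production; all zeros for a balanced
    reaction. Metabolites without a formula make the reaction unauditable
    and raise.
    """
    net: dict[str, float] = {}
    for met_id, coef in rxn.stoichiometry.items():
        met = model.metabolite(met_id)
        elems = met.elements()
        if elems is None:
            raise ModelValidationError(f"metabolite {met_id!r} has no formula")
        for element, count in elems.items():
            net[element] = net.get(element, 0) + coef * count
        if met.charge is not None:
            net["charge"] = net.get("charge", 0) + coef * met.charge
    return {k: v for k, v in net.items() if abs(v) > 1e-9}
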