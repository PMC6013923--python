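import numpy as np
import pytest
from hypothesis import settings

from mitoflux import (
    MetabolicModel,
    Metabolite,
    Reaction,
    build_fixture_model,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_model():
    return build_fixture_model()


@pytest.fixture(scope="session")
def open_exchange_bounds(fixture_model):
    """Bounds closing every substrate exchange except O2/H2O/Pi/H."""
    from mitoflux.core import is_exchange

    bounds = {
        r.id: (0.0, r.upper_bound)
        for r in fixture_model.reactions
        if is_exchange(r) and r.lower_bound < 0
    }
    for keep in ("EX_o2_u", "EX_h2o_u", "EX_pi_u", "EX_h_u"):
        bounds[keep] = (-1000.0, 1000.0)
    return bounds


def single_substrate_model(fixture_model, bounds, exchange_id, rate=1.0):
    updated = dict(bounds)
    updated[exchange_id] = (-rate, 1000.0)
    return fixture_model.with_bounds(updated)


@pytest.fixture
def toy_chain():
    """EX_A -> transport A->B -> EX_B with uptake capped at 1."""
    mets = [
        Metabolite(id="a_c", compartment="c"),
        Metabolite(id="b_c", compartment="c"),
    ]
    rxns = [
        Reaction(id="EX_a", stoichiometry={"a_c": -1}, lower_bound=-1.0,
                 upper_bound=0.0),
        Reaction(id="AB", stoichiometry={"a_c": -1, "b_c": 1}, lower_bound=0.0),
        Reaction(id="EX_b", stoichiometry={"b_c": -1}, lower_bound=0.0),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns,
                          objective_reaction="EX_b", id="chain")


def random_small_model(rng: np.random.Generator) -> MetabolicModel:
    """A random valid model with <= 20 reactions for property tests."""
    n_mets = int(rng.integers(2, 8))
    comps = rng.choice(["u", "c", "m"], size=n_mets)
    mets = [
        Metabolite(id=f"x{i}_{comps[i]}", compartment=str(comps[i]))
        for i in range(n_mets)
    ]
    n_rxns = int(rng.integers(1, 21))
    rxns = []
    for j in range(n_rxns):
        k = int(rng.integers(1, min(4, n_mets) + 1))
        chosen = rng.choice(n_mets, size=k, replace=False)
        coefs = rng.choice([-2.0, -1.0, 1.0, 2.0], size=k)
        stoich = {mets[int(i)].id: float(c) for i, c in zip(chosen, coefs)}
        reversible = bool(rng.integers(0, 2))
        rxns.append(
            Reaction(
                id=f"r{j}",
                stoichiometry=stoich,
                lower_bound=-1000.0 if reversible else 0.0,
                upper_bound=1000.0,
            )
        )
    return MetabolicModel(metabolites=mets, reactions=rxns, id="random")
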