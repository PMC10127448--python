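import numpy as np
import pytest

from degrank import (
    GeneRule,
    MediumSpec,
    MetabolicModel,
    Metabolite,
    Reaction,
    generate_linear_chain,
)

BIG = 1000.0


def build_model(reactions, objective_id, model_id="test", compartment="c",
                met_names=None):
    """Terse model builder: reactions = {id: (stoich, lb, ub, gpr-or-None)}."""
    met_names = met_names or {}
    mets = {}
    rxns = {}
    for rid, (stoich, lb, ub, gpr) in reactions.items():
        for met in stoich:
            if met not in mets:
                mets[met] = Metabolite(
                    met, name=met_names.get(met, met), compartment=compartment
                )
        rxns[rid] = Reaction(
            rid, dict(stoich), lb, ub, gpr=GeneRule(gpr) if gpr else None
        )
    return MetabolicModel(
        id=model_id, metabolites=mets, reactions=rxns, objective_id=objective_id
    )


@pytest.fixture
def chain3():
    """EX_S -> r_1 -> r_2 -> r_3 -> BIOMASS, uptake 10."""
    return generate_linear_chain(3, uptake=10.0)


@pytest.fixture
def parallel_routes():
    """Two equal-yield routes S->X: a 1-reaction shortcut and a 2-reaction
    detour; both feed biomass.  The classic pFBA / FVA degeneracy toy."""
    return build_model(
        {
            "EX_S": ({"S": -1}, -10, BIG, None),
            "short": ({"S": -1, "X": 1}, 0, BIG, "Gs"),
            "long1": ({"S": -1, "Y": 1}, 0, BIG, "Gl1"),
            "long2": ({"Y": -1, "X": 1}, 0, BIG, "Gl2"),
            "BIOMASS": ({"X": -1}, 0, BIG, None),
        },
        "BIOMASS",
    )


@pytest.fixture
def yield_branch():
    """A yield-1.0 route and a wasteful yield-0.5 route to biomass."""
    return build_model(
        {
            "EX_S": ({"S": -1}, -10, BIG, None),
            "good": ({"S": -1, "X": 1}, 0, BIG, None),
            "waste": ({"S": -2, "X": 1}, 0, BIG, None),
            "BIOMASS": ({"X": -1}, 0, BIG, None),
        },
        "BIOMASS",
    )


def random_toy(seed, max_reactions=12):
    """Small random viable network for oracle-agreement tests.

    A backbone chain plus random extra conversions between existing
    metabolites; always grows (the backbone survives).
    """
    rng = np.random.default_rng(seed)
    n_core = int(rng.integers(3, 6))
    model = generate_linear_chain(n_core, uptake=10.0)
    rxns = {
        rid: (dict(r.stoichiometry), r.lower_bound, r.upper_bound,
              r.gpr.expression if r.gpr else None)
        for rid, r in model.reactions.items()
    }
    met_ids = list(model.metabolites)
    n_extra = int(rng.integers(0, max_reactions - len(rxns) + 1))
    for e in range(n_extra):
        a, b = rng.choice(met_ids, size=2, replace=False)
        lb = 0.0 if rng.random() < 0.7 else -BIG
        gpr = None
        if rng.random() < 0.7:
            gpr = f"GE{e}" if rng.random() < 0.6 else f"GE{e}a or GE{e}b"
        rxns[f"extra_{e}"] = ({a: -1.0, b: 1.0}, lb, BIG, gpr)
    return build_model(rxns, "BIOMASS", model_id=f"random_{seed}")
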