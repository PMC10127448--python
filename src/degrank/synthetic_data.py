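"""Seeded generator of toy stoichiometric networks with known ground truth.

The generator plants every feature the selection pipeline must handle —
a growth backbone, isozyme-gated and single-gene reactions, branch routes,
currency-metabolite hubs, and a heterologous product pathway tapping the
backbone at an exactly known reaction distance from a planted target enzyme —
and records that ground truth *constructively*, i.e. from the construction
itself, never by running the solvers under test.

Topology
--------
::

    EX_S -> S -(r_1)-> M_1 -> ... -(r_n)-> M_n -> BIOMASS
                         |                        (drain)
                 (tap at M_j)  P_1 -> ... -> P_L -> EX_prod

The planted target gene gates backbone reaction ``r_t`` with ``t = j + D``;
on the pruned reaction graph the nearest pathway reaction ``P_1`` (which
consumes ``M_j``) is then exactly ``D`` steps away.  Reactions strictly
between the tap and the target are isozyme-gated so the planted target is the
unique minimum-distance single-enzyme essential; every other gated reaction
draws its rule from ``isozyme_fraction``.

Currency hubs are cofactor couples: decorated reactions co-convert
``cur_a -> cur_b`` and one free reversible regeneration reaction closes the
loop, so optima are untouched while the hub connects many reactions — exactly
the shortcut that metabolite pruning must remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    BIG_BOUND,
    GeneRule,
    MediumSpec,
    MetabolicModel,
    Metabolite,
    Reaction,
)
from .pathways import PathwayDefinition

__all__ = ["ToySpec", "GroundTruth", "generate_toy_model", "generate_linear_chain"]

GENERATOR_VERSION = "1"


@dataclass(frozen=True)
class ToySpec:
    n_linear_core: int = 10
    n_branches: int = 2
    isozyme_fraction: float = 0.3
    currency_hubs: int = 1
    planted_pathway_distance: int = 2
    pathway_length: int = 3
    uptake: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_linear_core < 3:
            raise ValueError("n_linear_core must be >= 3")
        if self.n_branches < 0 or self.currency_hubs < 0:
            raise ValueError("counts must be non-negative")
        if not 0 <= self.isozyme_fraction <= 1:
            raise ValueError("isozyme_fraction must be in [0, 1]")
        if self.planted_pathway_distance < 1:
            raise ValueError("planted_pathway_distance must be >= 1")
        if self.planted_pathway_distance >= self.n_linear_core:
            raise ValueError(
                "planted_pathway_distance must be smaller than n_linear_core"
            )
        if self.pathway_length < 1:
            raise ValueError("pathway_length must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Constructive truth about one generated toy (independent of any solver)."""

    essential_genes: frozenset[str]
    single_enzyme_essential_genes: frozenset[str]
    planted_target_gene: str
    planted_target_reaction: str
    planted_distance: int
    production_support_ids: frozenset[str]
    currency_metabolite_ids: frozenset[str] = frozenset()
    isozyme_gated_reactions: frozenset[str] = frozenset()
    gated_reactions: frozenset[str] = frozenset()


def generate_linear_chain(n: int, uptake: float = 10.0) -> MetabolicModel:
    """Exchange → n unit conversions → biomass; every conversion essential."""
    if n < 2:
        raise ValueError("chain needs n >= 2 conversions")
    mets = {"S_c": Metabolite("S_c", name="substrate", compartment="c")}
    rxns = {
        "EX_S": Reaction("EX_S", {"S_c": -1.0}, lower_bound=-uptake, upper_bound=BIG_BOUND)
    }
    prev = "S_c"
    for k in range(1, n + 1):
        mid = f"M{k}_c"
        mets[mid] = Metabolite(mid, name=f"intermediate {k}", compartment="c")
        rxns[f"r_{k}"] = Reaction(
            f"r_{k}", {prev: -1.0, mid: 1.0}, lower_bound=0.0, upper_bound=BIG_BOUND,
            gpr=GeneRule(f"G{k}"),
        )
        prev = mid
    rxns["BIOMASS"] = Reaction(
        "BIOMASS", {prev: -1.0}, lower_bound=0.0, upper_bound=BIG_BOUND
    )
    return MetabolicModel(
        id=f"chain_{n}", metabolites=mets, reactions=rxns, objective_id="BIOMASS",
        annotations={"generator": f"degrank-toy-v{GENERATOR_VERSION}"},
    )


def generate_toy_model(
    spec: ToySpec,
) -> tuple[MetabolicModel, MediumSpec, PathwayDefinition, GroundTruth]:
    """Generate a host model, its medium, a product pathway, and ground truth.

    The host is returned ungrafted; grafting is the pipeline's job
    (:func:`degrank.pathways.add_pathway`).  Ground-truth statements about
    distances and production support refer to the grafted network.
    """
    rng = np.random.default_rng(spec.seed)
    n, D = spec.n_linear_core, spec.planted_pathway_distance
    t = int(rng.integers(D + 1, n + 1))  # planted target reaction index
    j = t - D  # pathway tap: P_1 consumes M_j

    chain = generate_linear_chain(n, uptake=spec.uptake)
    mets = dict(chain.metabolites)
    rxns: dict[str, Reaction] = {rid: r for rid, r in chain.reactions.items()}

    def met_of(k: int) -> str:
        return "S_c" if k == 0 else f"M{k}_c"

    # --- gene rules -------------------------------------------------------
    isozyme_gated: set[str] = set()
    gated: set[str] = set()

    def assign_gpr(rid: str, gene_base: str, force: str | None = None) -> None:
        gated.add(rid)
        iso = {"iso": True, "single": False}.get(
            force, bool(rng.random() < spec.isozyme_fraction)
        )
        rule = f"{gene_base}a or {gene_base}b" if iso else gene_base
        if iso:
            isozyme_gated.add(rid)
        rxns[rid] = Reaction(
            rid, rxns[rid].stoichiometry, rxns[rid].lower_bound,
            rxns[rid].upper_bound, gpr=GeneRule(rule), name=rxns[rid].name,
        )

    for k in range(1, n + 1):
        if k == t:
            force = "single"
        elif j < k < t:
            force = "iso"  # keeps the planted target the unique nearest candidate
        else:
            force = None
        assign_gpr(f"r_{k}", f"G{k}", force)

    # --- branches ---------------------------------------------------------
    spanned: set[int] = set()
    branch_rxn_ids: list[str] = []
    for b in range(spec.n_branches):
        rejoin_possible = t < n
        rejoin = rejoin_possible and bool(rng.random() < 0.5)
        if rejoin:
            a = int(rng.integers(t, n))  # a >= t protects the planted reaction
            bb = int(rng.integers(a + 1, n + 1))
            mid = f"B{b}_c"
            mets[mid] = Metabolite(mid, name=f"branch {b}", compartment="c")
            r1, r2 = f"br_{b}_in", f"br_{b}_out"
            rxns[r1] = Reaction(r1, {met_of(a): -1.0, mid: 1.0}, 0.0, BIG_BOUND)
            rxns[r2] = Reaction(r2, {mid: -1.0, met_of(bb): 1.0}, 0.0, BIG_BOUND)
            spanned.update(range(a + 1, bb + 1))
            branch_rxn_ids += [r1, r2]
            for rid, gbase in ((r1, f"GB{b}i"), (r2, f"GB{b}o")):
                assign_gpr(rid, gbase)
        else:
            a = int(rng.integers(1, n))
            mid = f"D{b}_c"
            mets[mid] = Metabolite(mid, name=f"dead-end {b}", compartment="c")
            r1, sink = f"de_{b}", f"EX_D{b}"
            rxns[r1] = Reaction(r1, {met_of(a): -1.0, mid: 1.0}, 0.0, BIG_BOUND)
            rxns[sink] = Reaction(sink, {mid: -1.0}, 0.0, BIG_BOUND)
            branch_rxn_ids.append(r1)
            assign_gpr(r1, f"GD{b}")

    # --- currency hubs ----------------------------------------------------
    currency_ids: set[str] = set()
    hub_regen: dict[str, list[str]] = {}  # regen reaction -> decorated rxn ids
    backbone_ids = [f"r_{k}" for k in range(1, n + 1)]
    for h in range(spec.currency_hubs):
        ca, cb = f"cur{h}a_c", f"cur{h}b_c"
        mets[ca] = Metabolite(ca, name=f"currency {h} charged", compartment="c")
        mets[cb] = Metabolite(cb, name=f"currency {h} discharged", compartment="c")
        currency_ids |= {ca, cb}
        # always decorate the tap→target span (the shortcut pruning must cut),
        # plus a random sample elsewhere
        decorated = {f"r_{k}" for k in range(j, t + 1)}
        extra = [r for r in backbone_ids + branch_rxn_ids if r not in decorated]
        n_extra = min(len(extra), max(2, len(extra) // 3))
        decorated |= set(rng.choice(extra, size=n_extra, replace=False)) if extra else set()
        for rid in sorted(decorated):
            st = dict(rxns[rid].stoichiometry)
            st[ca] = st.get(ca, 0.0) - 1.0
            st[cb] = st.get(cb, 0.0) + 1.0
            rxns[rid] = Reaction(rid, st, rxns[rid].lower_bound,
                                 rxns[rid].upper_bound, gpr=rxns[rid].gpr,
                                 name=rxns[rid].name)
        regen = f"regen_{h}"
        rxns[regen] = Reaction(regen, {cb: -1.0, ca: 1.0}, -BIG_BOUND, BIG_BOUND)
        hub_regen[regen] = sorted(decorated)

    # --- product pathway (returned as a definition, not grafted) ----------
    tap = met_of(j)
    new_mets = [
        Metabolite(f"Q{i}_c", name=f"pathway intermediate {i}", compartment="c")
        for i in range(1, spec.pathway_length + 1)
    ]
    prxns: list[Reaction] = []
    prev = tap
    for i in range(1, spec.pathway_length + 1):
        prxns.append(
            Reaction(f"P_{i}", {prev: -1.0, f"Q{i}_c": 1.0}, 0.0, BIG_BOUND,
                     gpr=GeneRule(f"HET{i}"))
        )
        prev = f"Q{i}_c"
    product = prev
    prxns.append(Reaction("EX_prod", {product: -1.0}, 0.0, BIG_BOUND))
    pathway = PathwayDefinition(
        name=f"toy_product_d{D}",
        reactions=prxns,
        new_metabolites=new_mets,
        host_mapping={tap: tap},
        product_exchange_id="EX_prod",
        product_metabolite_id=product,
    )

    model = MetabolicModel(
        id=f"toy_seed{spec.seed}",
        metabolites=mets,
        reactions=rxns,
        objective_id="BIOMASS",
        annotations={
            "generator": f"degrank-toy-v{GENERATOR_VERSION}",
            "seed": str(spec.seed),
        },
    )
    medium = MediumSpec(uptake_bounds={"EX_S": spec.uptake}, default_closed=True)

    # --- constructive ground truth ---------------------------------------
    essential = set()
    single_enzyme = set()
    for k in range(1, n + 1):
        rid = f"r_{k}"
        if k in spanned:
            continue  # a branch detours around this step
        if rid in isozyme_gated:
            continue  # either isozyme alone sustains the reaction
        gene = f"G{k}"
        essential.add(gene)
        single_enzyme.add(gene)
    support = {"EX_S"} | {f"r_{k}" for k in range(1, j + 1)} \
        | {f"P_{i}" for i in range(1, spec.pathway_length + 1)} | {"EX_prod"}
    for regen, decorated in hub_regen.items():
        if any(r in support for r in decorated):
            support.add(regen)

    truth = GroundTruth(
        essential_genes=frozenset(essential),
        single_enzyme_essential_genes=frozenset(single_enzyme),
        planted_target_gene=f"G{t}",
        planted_target_reaction=f"r_{t}",
        planted_distance=D,
        production_support_ids=frozenset(support),
        currency_metabolite_ids=frozenset(currency_ids),
        isozyme_gated_reactions=frozenset(isozyme_gated),
        gated_reactions=frozenset(gated),
    )
    return model, medium, pathway, truth
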