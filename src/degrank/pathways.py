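"""Heterologous production pathways: definition files, grafting, and the
classification of reactions as needed / not needed for optimal production.

A pathway file declares new reactions (with explicit stoichiometry), the new
metabolites they introduce, a mapping from its precursor/cofactor species to
host metabolites, and the product exchange.  Reactions marked ``auxiliary``
travel with the pathway (e.g. cofactor-supply enzymes co-expressed in the
strain) but are *not* counted as pathway members for distance calculations.

Grafting never perturbs the host: added reactions may always carry zero flux,
so the host biomass optimum is invariant under :func:`add_pathway`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .lp_engine import DEFAULT_CONFIG, SolveConfig, fba, flux_variability, lmoma, pfba
from .model_core import (
    GeneRule,
    MetabolicModel,
    Metabolite,
    ModelError,
    FluxState,
    Reaction,
)

__all__ = [
    "PathwayDefinition",
    "load_pathway",
    "add_pathway",
    "production_support",
    "growth_essential_under_production",
]


@dataclass(frozen=True)
class PathwayDefinition:
    """A heterologous route to a secreted product.

    ``reactions`` holds every reaction the file ships, auxiliary ones
    included; ``pathway_reaction_ids`` (the distance substrate) excludes the
    auxiliary ids.  ``host_mapping`` resolves the file's local species names
    to host metabolites by id or, failing that, by unique metabolite name.
    """

    name: str
    reactions: list[Reaction]
    new_metabolites: list[Metabolite]
    host_mapping: dict[str, str]
    product_exchange_id: str
    product_metabolite_id: str
    auxiliary_reaction_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.id for r in self.reactions]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ModelError(f"duplicate reaction id(s) in pathway: {dup}")
        missing_aux = set(self.auxiliary_reaction_ids) - set(ids)
        if missing_aux:
            raise ModelError(f"auxiliary ids not defined in file: {sorted(missing_aux)}")
        ex = next((r for r in self.reactions if r.id == self.product_exchange_id), None)
        if ex is None:
            raise ModelError(f"product exchange {self.product_exchange_id!r} not defined")
        if set(ex.stoichiometry) != {self.product_metabolite_id}:
            raise ModelError(
                f"product exchange {self.product_exchange_id!r} must export exactly "
                f"{self.product_metabolite_id!r}"
            )

    @property
    def pathway_reaction_ids(self) -> list[str]:
        """Member reactions for distance purposes: no auxiliaries, no exchange."""
        skip = set(self.auxiliary_reaction_ids) | {self.product_exchange_id}
        return [r.id for r in self.reactions if r.id not in skip]


def load_pathway(path) -> PathwayDefinition:
    """Parse a pathway YAML file (see the packaged muconic/glycolic files)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    host_mapping = dict(doc.get("host_mapping", {}))
    new_mets = [
        Metabolite(
            id=m["id"],
            name=m.get("name", ""),
            compartment=m.get("compartment", "c"),
            formula=m.get("formula"),
        )
        for m in doc.get("new_metabolites", [])
    ]
    known = {m.id for m in new_mets} | set(host_mapping)
    reactions, auxiliary = [], []
    for r in doc["reactions"]:
        unknown = set(r["stoich"]) - known
        if unknown:
            raise ModelError(
                f"pathway reaction {r['id']!r} references species neither defined "
                f"in the file nor mapped to the host: {sorted(unknown)}"
            )
        reactions.append(
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoich"].items()},
                lower_bound=float(r.get("lb", 0.0)),
                upper_bound=float(r.get("ub", 1000.0)),
                gpr=GeneRule(r["gpr"]) if r.get("gpr") else None,
            )
        )
        if r.get("auxiliary", False):
            auxiliary.append(r["id"])
    return PathwayDefinition(
        name=doc["name"],
        reactions=reactions,
        new_metabolites=new_mets,
        host_mapping=host_mapping,
        product_exchange_id=doc["product_exchange"],
        product_metabolite_id=doc["product_metabolite"],
        auxiliary_reaction_ids=auxiliary,
    )


def _resolve_host_metabolite(model: MetabolicModel, spec: str) -> str:
    """Resolve a host-mapping value: exact id first, else unique name match.

    Name matching is case-insensitive and accepts ``name [compartment]``.
    """
    if spec in model.metabolites:
        return spec
    name, comp = spec, None
    if spec.endswith("]") and "[" in spec:
        name, comp = spec[: spec.rindex("[")].strip(), spec[spec.rindex("[") + 1 : -1]
    hits = [
        m.id
        for m in model.metabolites.values()
        if m.name.lower() == name.lower() and (comp is None or m.compartment == comp)
    ]
    if len(hits) == 1:
        return hits[0]
    if not hits:
        raise ModelError(f"cannot resolve host metabolite {spec!r} by id or name")
    raise ModelError(f"host metabolite name {spec!r} is ambiguous: {sorted(hits)}")


def add_pathway(model: MetabolicModel, pathway: PathwayDefinition) -> MetabolicModel:
    """Graft *pathway* onto a copy of *model*; the host content is unchanged."""
    collisions = {r.id for r in pathway.reactions} & set(model.reactions)
    if collisions:
        raise ModelError(f"pathway reaction id(s) collide with host: {sorted(collisions)}")
    met_collisions = {m.id for m in pathway.new_metabolites} & set(model.metabolites)
    if met_collisions:
        raise ModelError(f"pathway metabolite id(s) collide with host: {sorted(met_collisions)}")
    mapping = {
        local: _resolve_host_metabolite(model, host)
        for local, host in pathway.host_mapping.items()
    }
    new = model.copy()
    for m in pathway.new_metabolites:
        new.metabolites[m.id] = m
    for r in pathway.reactions:
        stoich = {mapping.get(met, met): coef for met, coef in r.stoichiometry.items()}
        new.reactions[r.id] = Reaction(
            id=r.id,
            name=r.name,
            stoichiometry=stoich,
            lower_bound=r.lower_bound,
            upper_bound=r.upper_bound,
            gpr=r.gpr,
        )
    new.validate()
    return new


def production_support(
    model_with_pathway: MetabolicModel,
    product_exchange_id: str,
    config: SolveConfig = DEFAULT_CONFIG,
    optimum_fraction: float = 1.0,
) -> set[str]:
    """Reactions needed for optimal production of the pathway product.

    Maximizes product export by FBA, re-solves parsimoniously (pFBA) at
    ``optimum_fraction`` of that optimum, and keeps a reaction only when flux
    variability at that production level forces it to carry flux — i.e. its
    minimum absolute flux exceeds the zero-flux threshold.  This FVA
    refinement makes the set independent of which pFBA vertex the solver
    happened to return.
    """
    opt = fba(model_with_pathway, product_exchange_id, config=config)
    if opt.status != "optimal" or opt.objective_value <= config.zero_flux_threshold:
        raise RuntimeError(
            "pathway cannot carry flux under the applied medium "
            f"(product optimum {opt.objective_value!r}, status {opt.status})"
        )
    sol = pfba(model_with_pathway, product_exchange_id,
               optimum_fraction=optimum_fraction, config=config)
    carriers = [
        rid for rid, v in sol.fluxes.items() if abs(v) > config.zero_flux_threshold
    ]
    ranges = flux_variability(
        model_with_pathway, carriers, product_exchange_id,
        optimum_fraction=optimum_fraction, config=config,
    )
    # forced to carry flux <=> the feasible interval excludes zero
    thr = config.zero_flux_threshold
    return {rid for rid, (lo, hi) in ranges.items() if lo > thr or hi < -thr}


def growth_essential_under_production(
    model_with_pathway: MetabolicModel,
    candidate_reaction_ids: list[str],
    reference: FluxState,
    growth_fraction: float = 0.90,
    config: SolveConfig = DEFAULT_CONFIG,
) -> bool:
    """Is near-optimal growth impossible without the candidate reactions?

    The candidate's reactions are closed, growth is constrained to at least
    ``growth_fraction`` of the unperturbed optimum, and the cell's response is
    simulated by linear MOMA against *reference*.  Returns True (the enzyme is
    growth-essential at this stringency) iff that problem is infeasible.
    """
    wt = fba(model_with_pathway, config=config)
    if wt.status != "optimal":
        raise RuntimeError(f"wild-type FBA {wt.status}; cannot assess candidates")
    biomass = model_with_pathway.objective_id
    ko = model_with_pathway.with_bounds(
        {r: (0.0, 0.0) for r in candidate_reaction_ids}
    )
    floor = growth_fraction * wt.objective_value
    ko = ko.with_bounds(
        {biomass: (floor, ko.reactions[biomass].upper_bound)}
    )
    response = lmoma(ko, reference, config=config)
    return response.status != "optimal"


def packaged_pathway(name: str) -> PathwayDefinition:
    """Load a pathway shipped with the package: 'muconic_acid' or 'glycolic_acid'."""
    from importlib import resources

    ref = resources.files("degrank.data").joinpath(f"{name}.yaml")
    if not ref.is_file():
        raise ModelError(f"no packaged pathway named {name!r}")
    with resources.as_file(ref) as path:
        return load_pathway(path)


def write_pathway(pathway: PathwayDefinition, path) -> None:
    """Serialize a PathwayDefinition back to the YAML dialect."""
    doc = {
        "name": pathway.name,
        "host_mapping": dict(pathway.host_mapping),
        "new_metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment,
             **({"formula": m.formula} if m.formula else {})}
            for m in pathway.new_metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoich": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                **({"gpr": r.gpr.expression} if r.gpr else {}),
                **({"auxiliary": True} if r.id in pathway.auxiliary_reaction_ids else {}),
            }
            for r in pathway.reactions
        ],
        "product_exchange": pathway.product_exchange_id,
        "product_metabolite": pathway.product_metabolite_id,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
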