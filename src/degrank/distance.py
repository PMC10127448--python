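"""Pathway distance on the currency-pruned reaction network.

Two reactions are *adjacent* (distance 1) when they share at least one
surviving metabolite on either side — the classic network-proximity notion in
which distance 1 means direct precursor competition.  Highly connected
currency metabolites (ATP, NAD(P)(H), H2O, ...) are removed first, because a
shared proton or cofactor would otherwise put almost every enzyme two steps
from everything else.  Biomass and exchange pseudo-reactions are excluded
from the graph: they are accounting devices, not biochemistry, and would
create meaningless shortcuts.

Distances come in two independent formulations that must agree:

* :func:`shortest_distance` — multi-source breadth-first search;
* :func:`lp_distance` — a binary min-cost-flow program selecting the smallest
  chain of reactions linking a source to a target reaction, each consecutive
  pair sharing a surviving metabolite.

The agreement of the two routes on every instance is the module's primary
correctness property and is enforced in the test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import numpy as np
from scipy.optimize import LinearConstraint, milp
from scipy.sparse import lil_matrix

from .model_core import MetabolicModel
from .pathways import PathwayDefinition

__all__ = [
    "UNREACHABLE",
    "PruneSpec",
    "DistanceTable",
    "default_currency_prune",
    "prune_metabolites",
    "build_reaction_graph",
    "shortest_distance",
    "lp_distance",
    "enzyme_pathway_distances",
]

#: Sentinel for "no path on the pruned network"; sorts after every distance.
UNREACHABLE = math.inf


@dataclass(frozen=True)
class PruneSpec:
    """Which metabolites to drop before building the reaction graph.

    Exactly one mode is active: an explicit id list (the portable equivalent
    of a curated highly-connected-metabolite table) or a participation-degree
    threshold.
    """

    mode: str  # "explicit_list" | "degree_threshold"
    metabolite_ids: tuple[str, ...] = ()
    max_degree: int = 0

    def __post_init__(self):
        if self.mode not in ("explicit_list", "degree_threshold"):
            raise ValueError(f"unknown prune mode {self.mode!r}")
        if self.mode == "degree_threshold" and self.max_degree < 1:
            raise ValueError("max_degree must be a positive integer")

    @classmethod
    def explicit(cls, metabolite_ids) -> "PruneSpec":
        return cls(mode="explicit_list", metabolite_ids=tuple(metabolite_ids))

    @classmethod
    def by_degree(cls, max_degree: int) -> "PruneSpec":
        return cls(mode="degree_threshold", max_degree=max_degree)


def currency_metabolite_names() -> list[str]:
    """The packaged currency-metabolite base names (one per line, comments #)."""
    text = resources.files("degrank.data").joinpath("currency_metabolites.txt").read_text()
    return [
        ln.strip().lower()
        for ln in text.splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]


def default_currency_prune(model: MetabolicModel) -> PruneSpec:
    """Explicit PruneSpec matching the packaged currency list in every
    compartment, by metabolite name or by id with compartment suffix removed."""
    names = set(currency_metabolite_names())
    hits = []
    for m in model.metabolites.values():
        base = m.id.lower()
        if "_" in base:
            base = base.rsplit("_", 1)[0]
        mname = m.name.lower().split(" [")[0] if m.name else ""
        if base in names or mname in names:
            hits.append(m.id)
    return PruneSpec.explicit(sorted(hits))


def prune_metabolites(model: MetabolicModel, spec: PruneSpec) -> set[str]:
    """Surviving metabolite ids after removing hubs per *spec*.

    Explicit ids absent from the model are tolerated (curated lists travel
    across model versions) — a warning is emitted, not an error.
    """
    all_ids = set(model.metabolites)
    if spec.mode == "explicit_list":
        listed = set(spec.metabolite_ids)
        missing = listed - all_ids
        if missing:
            import warnings

            warnings.warn(
                f"{len(missing)} prune-list metabolite(s) absent from model: "
                f"{sorted(missing)[:5]}...",
                stacklevel=2,
            )
        return all_ids - listed
    degree: dict[str, int] = {m: 0 for m in all_ids}
    for rxn in model.reactions.values():
        for met in rxn.stoichiometry:
            degree[met] += 1
    return {m for m in all_ids if degree[m] <= spec.max_degree}


def _graph_reaction_ids(model: MetabolicModel) -> list[str]:
    """Internal reactions only: no exchanges, no biomass pseudo-reaction."""
    out = []
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        if rxn.is_exchange or rid == model.objective_id:
            continue
        if "biomass" in rid.lower():
            continue
        out.append(rid)
    return out


def build_reaction_graph(
    model: MetabolicModel, surviving_metabolites: set[str]
) -> nx.Graph:
    """Undirected reaction graph: edge iff two reactions share a survivor."""
    unknown = surviving_metabolites - set(model.metabolites)
    if unknown:
        raise KeyError(f"surviving set contains unknown metabolites: {sorted(unknown)}")
    graph = nx.Graph()
    graph.add_nodes_from(_graph_reaction_ids(model))
    met_to_rxns: dict[str, list[str]] = {}
    for rid in graph.nodes:
        for met in model.reactions[rid].stoichiometry:
            if met in surviving_metabolites:
                met_to_rxns.setdefault(met, []).append(rid)
    for rxns in met_to_rxns.values():
        for i, r1 in enumerate(rxns):
            for r2 in rxns[i + 1 :]:
                if r1 != r2:
                    graph.add_edge(r1, r2)
    return graph


def shortest_distance(graph: nx.Graph, from_reactions, to_reactions) -> float:
    """Minimum edge count between two reaction sets (0 when they intersect)."""
    src, dst = set(from_reactions), set(to_reactions)
    if not src or not dst:
        raise KeyError("from/to reaction sets must be non-empty")
    unknown = (src | dst) - set(graph.nodes)
    if unknown:
        raise KeyError(f"reaction id(s) not in graph: {sorted(unknown)}")
    if src & dst:
        return 0
    lengths = nx.multi_source_dijkstra_path_length(graph, src, weight=None)
    best = min((lengths[t] for t in dst if t in lengths), default=UNREACHABLE)
    return UNREACHABLE if math.isinf(best) else int(best)


def lp_distance(
    model: MetabolicModel,
    surviving_metabolites: set[str],
    from_reactions,
    to_reactions,
) -> float:
    """Chain-selection program for the pathway distance.

    Builds the same adjacency as :func:`build_reaction_graph` and solves a
    binary min-cost unit-flow problem: select arcs forming a connected chain
    from any source reaction to any target reaction, minimizing the number of
    reaction-to-reaction steps.  Must equal :func:`shortest_distance`.
    """
    graph = build_reaction_graph(model, surviving_metabolites)
    src, dst = set(from_reactions), set(to_reactions)
    if not src or not dst:
        raise KeyError("from/to reaction sets must be non-empty")
    unknown = (src | dst) - set(graph.nodes)
    if unknown:
        raise KeyError(f"reaction id(s) not in graph: {sorted(unknown)}")
    if src & dst:
        return 0

    nodes = list(graph.nodes) + ["__s__", "__t__"]
    node_index = {n: i for i, n in enumerate(nodes)}
    arcs: list[tuple[str, str, float]] = []
    for u, v in graph.edges:
        arcs.append((u, v, 1.0))
        arcs.append((v, u, 1.0))
    for s in sorted(src):
        arcs.append(("__s__", s, 0.0))
    for t in sorted(dst):
        arcs.append((t, "__t__", 0.0))

    A = lil_matrix((len(nodes), len(arcs)))
    for j, (u, v, _) in enumerate(arcs):
        A[node_index[u], j] = 1.0  # leaves u
        A[node_index[v], j] = -1.0  # enters v
    b = np.zeros(len(nodes))
    b[node_index["__s__"]] = 1.0
    b[node_index["__t__"]] = -1.0
    cost = np.array([c for _, _, c in arcs])
    res = milp(
        c=cost,
        constraints=LinearConstraint(A.tocsr(), b, b),
        integrality=np.ones(len(arcs)),
        bounds=(0, 1),
    )
    if res.status == 2:  # infeasible: no chain exists
        return UNREACHABLE
    if not res.success:
        raise RuntimeError(f"distance MILP failed: {res.message}")
    return int(round(res.fun))


@dataclass
class DistanceTable:
    """Per (enzyme gene, pathway reaction) shortest distances and per-gene minima."""

    entries: dict[tuple[str, str], float]
    min_distance: dict[str, float] = field(init=False)

    def __post_init__(self):
        mins: dict[str, float] = {}
        for (gene, _), d in self.entries.items():
            mins[gene] = min(mins.get(gene, UNREACHABLE), d)
        self.min_distance = mins

    def to_rows(self) -> list[dict]:
        return [
            {"gene": g, "pathway_reaction": p,
             "distance": None if d is UNREACHABLE else int(d)}
            for (g, p), d in sorted(self.entries.items())
        ]


def enzyme_pathway_distances(
    model_with_pathway: MetabolicModel,
    enzymes: list[tuple[str, list[str]]],
    pathway: PathwayDefinition,
    prune: PruneSpec,
) -> DistanceTable:
    """Distances from each enzyme's reaction set to each pathway reaction.

    A multifunctional enzyme contributes its whole reaction set; its
    ``min_distance`` aggregates over that set and over all pathway reactions.
    """
    surviving = prune_metabolites(model_with_pathway, prune)
    graph = build_reaction_graph(model_with_pathway, surviving)
    entries: dict[tuple[str, str], float] = {}
    for gene, rxn_ids in enzymes:
        if not rxn_ids:
            raise ValueError(f"enzyme {gene!r} has an empty reaction set")
        present = [r for r in rxn_ids if r in graph]
        if not present:
            raise ValueError(
                f"none of the reactions of enzyme {gene!r} are in the pruned graph"
            )
        lengths = nx.multi_source_dijkstra_path_length(graph, set(present), weight=None)
        for prxn in pathway.pathway_reaction_ids:
            entries[(gene, prxn)] = (
                int(lengths[prxn]) if prxn in lengths else UNREACHABLE
            )
    return DistanceTable(entries=entries)


def load_prune(path) -> PruneSpec:
    """Read a PruneSpec from YAML ({mode, metabolite_ids | max_degree}) or a
    one-metabolite-id-per-line list file."""
    import yaml

    text = open(path).read()
    if str(path).endswith((".yaml", ".yml")):
        doc = yaml.safe_load(text)
        if doc.get("mode", "explicit_list") == "degree_threshold":
            return PruneSpec.by_degree(int(doc["max_degree"]))
        return PruneSpec.explicit(doc["metabolite_ids"])
    ids = [ln.strip() for ln in text.splitlines()
           if ln.strip() and not ln.lstrip().startswith("#")]
    return PruneSpec.explicit(ids)
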