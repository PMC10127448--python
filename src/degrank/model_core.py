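"""Stoichiometric model data structures and I/O.

The in-memory containers are deliberately small and explicit: a
:class:`MetabolicModel` is a dict-backed network of :class:`Metabolite` and
:class:`Reaction` objects with gene-protein-reaction (GPR) rules, a declared
objective reaction (the biomass pseudo-reaction by default) and flux bounds in
mmol·gDW⁻¹·h⁻¹.  SBML reading is delegated to cobrapy; a lossless JSON dialect
is provided for round-tripping and for the toy fixtures the test-suite builds.

Conventions
-----------
* An exchange reaction touches exactly one metabolite; uptake is the negative
  flux direction (``EX_glc: glc ->`` with flux −10 imports 10 units).
* A :class:`MediumSpec` lists maximum uptake rates per exchange reaction; with
  ``default_closed`` every unlisted exchange has its uptake bound set to zero
  while secretion stays open.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace

__all__ = [
    "Metabolite",
    "Reaction",
    "GeneRule",
    "MetabolicModel",
    "MediumSpec",
    "FluxState",
    "ModelError",
    "load_sbml",
    "load_model_json",
    "write_model_json",
    "load_medium",
    "apply_medium",
    "to_cobra",
    "from_cobra",
]

#: Finite stand-in for infinite bounds, the usual genome-scale convention.
BIG_BOUND = 1000.0


class ModelError(ValueError):
    """Raised for malformed models, media, or GPR rules."""


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

_GPR_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize_gpr(expression: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    while pos < len(expression):
        m = _GPR_TOKEN.match(expression, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _GprParser:
    """Recursive-descent parser for ``A and (B or C)`` style rules.

    ``and`` binds tighter than ``or``; keywords are case-insensitive.  The AST
    is nested tuples: ``("gene", id)``, ``("and", [..])``, ``("or", [..])``.
    """

    def __init__(self, expression: str):
        self.expression = expression
        self.tokens = _tokenize_gpr(expression)
        self.i = 0

    def _peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def _error(self, msg: str):
        pos = self.tokens[self.i][1] if self.i < len(self.tokens) else len(self.expression)
        raise ModelError(f"GPR parse error at position {pos} in {self.expression!r}: {msg}")

    def parse(self):
        if not self.tokens:
            self._error("empty rule")
        node = self._or()
        if self.i != len(self.tokens):
            self._error(f"unexpected token {self._peek()!r}")
        return node

    def _or(self):
        parts = [self._and()]
        while self._peek() is not None and self._peek().lower() == "or":
            self.i += 1
            parts.append(self._and())
        return parts[0] if len(parts) == 1 else ("or", parts)

    def _and(self):
        parts = [self._atom()]
        while self._peek() is not None and self._peek().lower() == "and":
            self.i += 1
            parts.append(self._atom())
        return parts[0] if len(parts) == 1 else ("and", parts)

    def _atom(self):
        tok = self._peek()
        if tok is None:
            self._error("expected gene id or '('")
        if tok == "(":
            self.i += 1
            node = self._or()
            if self._peek() != ")":
                self._error("expected ')'")
            self.i += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            self._error(f"unexpected token {tok!r}")
        self.i += 1
        return ("gene", tok)


@dataclass(frozen=True)
class GeneRule:
    """Boolean gene association of a reaction (AND = complex, OR = isozymes)."""

    expression: str

    def __post_init__(self):
        object.__setattr__(self, "_ast", _GprParser(self.expression).parse())

    @property
    def ast(self):
        return self._ast

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()

        def walk(node):
            if node[0] == "gene":
                out.add(node[1])
            else:
                for child in node[1]:
                    walk(child)

        walk(self._ast)
        return frozenset(out)

    def evaluate(self, deleted_genes: set[str] | frozenset[str]) -> bool:
        """True when the enzyme activity survives deletion of *deleted_genes*."""

        def walk(node) -> bool:
            kind = node[0]
            if kind == "gene":
                return node[1] not in deleted_genes
            if kind == "and":
                return all(walk(c) for c in node[1])
            return any(walk(c) for c in node[1])

        return walk(self._ast)

    def is_single_gene(self) -> bool:
        return self._ast[0] == "gene"


# ---------------------------------------------------------------------------
# Network containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None

    def __post_init__(self):
        if not self.compartment:
            raise ModelError(f"metabolite {self.id!r}: compartment must be non-empty")


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -BIG_BOUND
    upper_bound: float = BIG_BOUND
    gpr: GeneRule | None = None
    name: str = ""

    def __post_init__(self):
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r}: empty stoichiometry")

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class MetabolicModel:
    """Compartmentalized stoichiometric network with bounds, GPRs, objective."""

    id: str
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    objective_id: str
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for met in rxn.stoichiometry:
                if met not in self.metabolites:
                    raise ModelError(
                        f"reaction {rxn.id!r} references unknown metabolite {met!r}"
                    )
        if self.objective_id not in self.reactions:
            raise ModelError(f"objective reaction {self.objective_id!r} not in model")

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            if rxn.gpr is not None:
                out |= rxn.gpr.genes
        return frozenset(out)

    def gene_to_reactions(self) -> dict[str, list[str]]:
        mapping: dict[str, list[str]] = {}
        for rxn in self.reactions.values():
            if rxn.gpr is None:
                continue
            for g in rxn.gpr.genes:
                mapping.setdefault(g, []).append(rxn.id)
        for rxns in mapping.values():
            rxns.sort()
        return mapping

    def exchange_ids(self) -> list[str]:
        return [r.id for r in self.reactions.values() if r.is_exchange]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=dict(self.metabolites),
            reactions=dict(self.reactions),
            objective_id=self.objective_id,
            annotations=dict(self.annotations),
        )

    def with_bounds(self, bounds: dict[str, tuple[float, float]]) -> "MetabolicModel":
        """Copy with per-reaction (lb, ub) overrides; used for in-silico deletions."""
        new = self.copy()
        for rid, (lb, ub) in bounds.items():
            if rid not in new.reactions:
                raise ModelError(f"unknown reaction {rid!r}")
            new.reactions[rid] = replace(new.reactions[rid], lower_bound=lb, upper_bound=ub)
        return new


@dataclass(frozen=True)
class MediumSpec:
    """Maximum uptake rate per exchange reaction (non-negative values)."""

    uptake_bounds: dict[str, float]
    default_closed: bool = True

    def __post_init__(self):
        for rid, v in self.uptake_bounds.items():
            if v < 0:
                raise ModelError(f"medium uptake bound for {rid!r} must be >= 0, got {v}")


@dataclass
class FluxState:
    """One solver outcome: flux per reaction, objective value, status."""

    fluxes: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    def flux(self, reaction_id: str) -> float:
        return self.fluxes.get(reaction_id, 0.0)

    def check(self, model: MetabolicModel, tol: float = 1e-6) -> None:
        """Assert steady state and bound feasibility (optimal states only)."""
        if self.status != "optimal":
            return
        balance: dict[str, float] = {m: 0.0 for m in model.metabolites}
        for rid, rxn in model.reactions.items():
            v = self.fluxes.get(rid, 0.0)
            lb = max(rxn.lower_bound, -BIG_BOUND)
            ub = min(rxn.upper_bound, BIG_BOUND)
            if v < lb - tol or v > ub + tol:
                raise ModelError(f"flux {v} of {rid!r} violates bounds [{lb}, {ub}]")
            for met, coef in rxn.stoichiometry.items():
                balance[met] += coef * v
        bad = {m: b for m, b in balance.items() if abs(b) > tol}
        if bad:
            worst = max(bad, key=lambda m: abs(bad[m]))
            raise ModelError(
                f"steady state violated for {len(bad)} metabolites "
                f"(worst {worst!r}: {bad[worst]:.3g})"
            )


# ---------------------------------------------------------------------------
# Medium handling
# ---------------------------------------------------------------------------

def apply_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Return a copy of *model* with exchange bounds set from *medium*.

    Listed exchanges get lower bound ``-uptake``; with ``default_closed`` every
    other exchange gets lower bound 0 (secretion bounds are never touched).
    Idempotent by construction.
    """
    exchange = set(model.exchange_ids())
    for rid in medium.uptake_bounds:
        if rid not in model.reactions:
            raise ModelError(f"medium refers to unknown reaction {rid!r}")
        if rid not in exchange:
            raise ModelError(f"medium reaction {rid!r} is not an exchange reaction")
    bounds: dict[str, tuple[float, float]] = {}
    for rid in exchange:
        rxn = model.reactions[rid]
        if rid in medium.uptake_bounds:
            bounds[rid] = (-medium.uptake_bounds[rid], rxn.upper_bound)
        elif medium.default_closed:
            bounds[rid] = (max(rxn.lower_bound, 0.0), rxn.upper_bound)
    return model.with_bounds(bounds)


def load_medium(path) -> MediumSpec:
    """Read a MediumSpec from YAML ({uptake_bounds: {...}, default_closed}) or
    two-column TSV (exchange_id, max_uptake)."""
    import yaml

    text = open(path).read()
    if str(path).endswith((".tsv", ".txt")):
        bounds = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rid, val = line.split("\t")[:2]
            bounds[rid] = float(val)
        return MediumSpec(uptake_bounds=bounds)
    data = yaml.safe_load(text)
    return MediumSpec(
        uptake_bounds={k: float(v) for k, v in data["uptake_bounds"].items()},
        default_closed=bool(data.get("default_closed", True)),
    )


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def write_model_json(model: MetabolicModel, path) -> None:
    doc = {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
            }
            for m in sorted(model.metabolites.values(), key=lambda m: m.id)
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoich": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "gpr": r.gpr.expression if r.gpr else None,
                "exchange": r.is_exchange,
            }
            for r in sorted(model.reactions.values(), key=lambda r: r.id)
        ],
        "objective": model.objective_id,
        "annotations": model.annotations,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=False)
        fh.write("\n")


def load_model_json(path) -> MetabolicModel:
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("metabolites", "reactions", "objective"):
        if key not in doc:
            raise ModelError(f"model JSON missing required field at /{key}")
    mets = {}
    for i, m in enumerate(doc["metabolites"]):
        if "id" not in m:
            raise ModelError(f"model JSON missing id at /metabolites/{i}")
        mets[m["id"]] = Metabolite(
            id=m["id"],
            name=m.get("name", ""),
            compartment=m.get("compartment", "c"),
            formula=m.get("formula"),
        )
    rxns = {}
    for i, r in enumerate(doc["reactions"]):
        for key in ("id", "stoich", "lb", "ub"):
            if key not in r:
                raise ModelError(f"model JSON missing {key} at /reactions/{i}")
        if r["lb"] > r["ub"]:
            raise ModelError(
                f"model JSON invariant violation at /reactions/{i}: lb > ub"
            )
        rxns[r["id"]] = Reaction(
            id=r["id"],
            name=r.get("name", ""),
            stoichiometry={k: float(v) for k, v in r["stoich"].items()},
            lower_bound=float(r["lb"]),
            upper_bound=float(r["ub"]),
            gpr=GeneRule(r["gpr"]) if r.get("gpr") else None,
        )
    return MetabolicModel(
        id=doc.get("id", "model"),
        metabolites=mets,
        reactions=rxns,
        objective_id=doc["objective"],
        annotations=doc.get("annotations", {}),
    )


# ---------------------------------------------------------------------------
# SBML via cobrapy, plus cobra interconversion (also used by test oracles)
# ---------------------------------------------------------------------------

def _clip(value: float) -> float:
    if value is None or math.isinf(value):
        return math.copysign(BIG_BOUND, value if value is not None else 1.0)
    return float(value)


def from_cobra(cm, objective_id: str | None = None) -> MetabolicModel:
    """Convert a cobrapy model to the internal representation."""
    mets = {
        m.id: Metabolite(
            id=m.id,
            name=m.name or "",
            compartment=m.compartment or "c",
            formula=m.formula or None,
        )
        for m in cm.metabolites
    }
    rxns = {}
    for r in cm.reactions:
        gpr = str(r.gene_reaction_rule).strip()
        rxns[r.id] = Reaction(
            id=r.id,
            name=r.name or "",
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            lower_bound=_clip(r.lower_bound),
            upper_bound=_clip(r.upper_bound),
            gpr=GeneRule(gpr) if gpr else None,
        )
    if objective_id is None:
        obj = [r.id for r in cm.reactions if r.objective_coefficient]
        if len(obj) == 1:
            objective_id = obj[0]
        else:
            biomass = [
                r.id
                for r in cm.reactions
                if "biomass" in r.id.lower() or "biomass" in (r.name or "").lower()
            ]
            if len(obj) == 0 and len(biomass) == 1:
                objective_id = biomass[0]
            else:
                raise ModelError(
                    "no unambiguous objective: declare one in the file or pass "
                    "objective_id explicitly"
                )
    return MetabolicModel(
        id=cm.id or "model", metabolites=mets, reactions=rxns, objective_id=objective_id
    )


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (for SBML export and oracle cross-checks)."""
    import cobra

    cm = cobra.Model(model.id)
    cm.add_metabolites(
        [
            cobra.Metabolite(
                m.id, name=m.name, compartment=m.compartment, formula=m.formula
            )
            for m in model.metabolites.values()
        ]
    )
    crxns = []
    for r in model.reactions.values():
        cr = cobra.Reaction(r.id, name=r.name)
        cr.lower_bound = r.lower_bound
        cr.upper_bound = r.upper_bound
        crxns.append(cr)
    cm.add_reactions(crxns)
    for r in model.reactions.values():
        cr = cm.reactions.get_by_id(r.id)
        cr.add_metabolites(
            {cm.metabolites.get_by_id(m): c for m, c in r.stoichiometry.items()}
        )
        if r.gpr is not None:
            cr.gene_reaction_rule = r.gpr.expression
    cm.objective = model.objective_id
    return cm


def load_sbml(path, objective_id: str | None = None) -> MetabolicModel:
    """Read an SBML Level 3 (fbc) file into a MetabolicModel.

    The declared fbc objective is used unless *objective_id* overrides it; a
    file with no objective and no unique biomass-named reaction is rejected.
    """
    import cobra.io

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises several types for bad SBML
        raise ModelError(f"failed to parse SBML file {path}: {exc}") from exc
    return from_cobra(cm, objective_id=objective_id)


def write_medium(medium: MediumSpec, path) -> None:
    """Serialize a MediumSpec to YAML."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "uptake_bounds": dict(sorted(medium.uptake_bounds.items())),
                "default_closed": medium.default_closed,
            },
            fh,
            sort_keys=False,
        )
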