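"""Gene/reaction knockout screens and the single-enzyme essential filter.

A gene deletion is simulated through its GPR rules: every reaction whose rule
evaluates to False with the gene removed has its bounds closed to [0, 0], and
growth is re-optimized by FBA.  A target is *essential* when knockout growth
falls below ``essentiality_fraction`` of wild-type growth (default 1%, robust
to LP tolerance).  Deletions are always simulated by bounding, never by
structural removal, so indices stay stable across the screen.

The single-enzyme filter keeps essential genes all of whose reactions are
gated by exactly that one gene — no OR-isozymes and no AND-complex partners —
i.e. proteins whose removal unambiguously removes the catalytic activity.
"""

from __future__ import annotations

from dataclasses import dataclass

from .lp_engine import DEFAULT_CONFIG, SolveConfig, fba
from .model_core import GeneRule, MetabolicModel

__all__ = [
    "KnockoutResult",
    "eval_gpr",
    "gene_knockout_screen",
    "reaction_knockout_screen",
    "single_enzyme_essentials",
]

#: Knockout growth below this fraction of wild type counts as no growth.
ESSENTIALITY_FRACTION = 0.01


@dataclass(frozen=True)
class KnockoutResult:
    target_id: str
    target_kind: str  # "gene" | "reaction"
    wt_growth: float
    ko_growth: float
    essential: bool


def eval_gpr(rule: GeneRule, deleted_genes: set[str]) -> bool:
    """Does the reaction remain catalyzed when *deleted_genes* are absent?"""
    return rule.evaluate(deleted_genes)


def _wild_type_growth(model: MetabolicModel, config: SolveConfig) -> float:
    wt = fba(model, config=config)
    if wt.status != "optimal" or wt.objective_value <= config.zero_flux_threshold:
        raise RuntimeError(
            "medium does not support growth: wild-type FBA is "
            f"{wt.status} with objective {wt.objective_value!r}"
        )
    return wt.objective_value


def _knockout_growth(model: MetabolicModel, reaction_ids: list[str],
                     config: SolveConfig) -> float:
    ko = fba(model.with_bounds({r: (0.0, 0.0) for r in reaction_ids}), config=config)
    return ko.objective_value if ko.status == "optimal" else 0.0


def gene_knockout_screen(
    model: MetabolicModel,
    config: SolveConfig = DEFAULT_CONFIG,
    essentiality_fraction: float = ESSENTIALITY_FRACTION,
) -> list[KnockoutResult]:
    """Single-gene deletion screen over every gene in the model's GPR rules."""
    wt = _wild_type_growth(model, config)
    results = []
    for gene in sorted(model.genes):
        disabled = [
            r.id
            for r in model.reactions.values()
            if r.gpr is not None and not r.gpr.evaluate({gene})
        ]
        ko = _knockout_growth(model, disabled, config) if disabled else wt
        ko = min(ko, wt)  # deletion can never beat wild type; clamp LP noise
        results.append(
            KnockoutResult(
                target_id=gene,
                target_kind="gene",
                wt_growth=wt,
                ko_growth=ko,
                essential=ko < essentiality_fraction * wt,
            )
        )
    return results


def reaction_knockout_screen(
    model: MetabolicModel,
    config: SolveConfig = DEFAULT_CONFIG,
    essentiality_fraction: float = ESSENTIALITY_FRACTION,
) -> list[KnockoutResult]:
    """Single-reaction deletion screen (bounds closed to [0, 0] per reaction)."""
    wt = _wild_type_growth(model, config)
    results = []
    for rid in sorted(model.reactions):
        ko = min(_knockout_growth(model, [rid], config), wt)
        results.append(
            KnockoutResult(
                target_id=rid,
                target_kind="reaction",
                wt_growth=wt,
                ko_growth=ko,
                essential=ko < essentiality_fraction * wt,
            )
        )
    return results


def single_enzyme_essentials(
    model: MetabolicModel,
    gene_screen: list[KnockoutResult],
) -> list[tuple[str, list[str]]]:
    """Essential genes whose every reaction is gated by exactly that gene.

    Genes with isozyme alternatives (OR) or complex partners (AND) anywhere in
    their reaction set are excluded: their degradation would either be buffered
    or would implicate other proteins.  Returns ``(gene, sorted reaction ids)``
    pairs sorted by gene id.
    """
    gene_to_rxns = model.gene_to_reactions()
    out = []
    for res in gene_screen:
        if res.target_kind != "gene" or not res.essential:
            continue
        rxns = gene_to_rxns.get(res.target_id, [])
        if not rxns:
            continue
        sole = all(
            (gpr := model.reactions[r].gpr) is not None
            and gpr.is_single_gene()
            and res.target_id in gpr.genes
            for r in rxns
        )
        if sole:
            out.append((res.target_id, rxns))
    return sorted(out)
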