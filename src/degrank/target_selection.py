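"""End-to-end selection of inducible-degradation targets.

Stage sequence (each stage a library call, errors propagate with the stage
name):

1. apply the medium and confirm growth;
2. single-gene knockout screen → growth-essential genes;
3. keep single-enzyme essentials (no isozymes, no complex partners);
4. graft the heterologous production pathway;
5. drop enzymes whose reactions are needed for optimal production
   (pFBA support, FVA-refined);
6. flag whether each remaining enzyme is still required when growth is held
   at ≥ 90% of optimum (linear MOMA against the wild-type pFBA reference);
7. rank remaining candidates by minimum pathway distance on the
   currency-pruned reaction graph (ties broken by gene id).

The report carries every intermediate artifact plus provenance hashes so two
runs on identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

from .distance import (
    UNREACHABLE,
    DistanceTable,
    PruneSpec,
    enzyme_pathway_distances,
)
from .essentiality import (
    ESSENTIALITY_FRACTION,
    KnockoutResult,
    gene_knockout_screen,
    single_enzyme_essentials,
)
from .lp_engine import DEFAULT_CONFIG, SolveConfig, fba, pfba
from .model_core import MediumSpec, MetabolicModel, apply_medium
from .pathways import (
    PathwayDefinition,
    add_pathway,
    growth_essential_under_production,
    production_support,
)

__all__ = ["CandidateRow", "TargetReport", "select_targets", "write_report"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class CandidateRow:
    gene: str
    reaction_ids: tuple[str, ...]
    essential_in_medium: bool
    single_enzyme: bool
    needed_for_production: bool | None
    growth_essential_at_90pct: bool | None
    min_distance: float | None  # UNREACHABLE allowed; None when not computed
    rank: int | None


@dataclass
class TargetReport:
    model_id: str
    pathway_name: str
    rows: list[CandidateRow]
    gene_screen: list[KnockoutResult]
    support: set[str]
    distances: DistanceTable | None
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def ranked(self) -> list[CandidateRow]:
        return sorted(
            (r for r in self.rows if r.rank is not None), key=lambda r: r.rank
        )


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def select_targets(
    model: MetabolicModel,
    medium: MediumSpec,
    pathway: PathwayDefinition,
    prune: PruneSpec,
    config: SolveConfig = DEFAULT_CONFIG,
    growth_fraction: float = 0.90,
    essentiality_fraction: float = ESSENTIALITY_FRACTION,
) -> TargetReport:
    """Run the full target-selection pipeline and return the ranked report."""
    # stage 1: medium
    try:
        fed = apply_medium(model, medium)
        wt = fba(fed, config=config)
        if wt.status != "optimal" or wt.objective_value <= config.zero_flux_threshold:
            raise RuntimeError("medium does not support growth")
    except Exception as exc:
        raise StageError("medium", exc) from exc

    # stage 2+3: essentiality screen and single-enzyme filter
    try:
        screen = gene_knockout_screen(fed, config, essentiality_fraction)
        singles = single_enzyme_essentials(fed, screen)
    except Exception as exc:
        raise StageError("essentiality", exc) from exc
    essential_genes = {r.target_id for r in screen if r.essential}

    # stage 4: pathway grafting
    try:
        grafted = add_pathway(fed, pathway)
    except Exception as exc:
        raise StageError("grafting", exc) from exc

    # stage 5: production support
    try:
        support = production_support(
            grafted, pathway.product_exchange_id, config=config
        )
    except Exception as exc:
        raise StageError("production_support", exc) from exc

    single_map = dict(singles)
    not_needed = [
        (g, rxns)
        for g, rxns in singles
        if not any(r in support for r in rxns)
    ]

    # stage 6: growth essentiality at >= growth_fraction of optimum
    try:
        reference = pfba(grafted, config=config)
        still_essential = {
            g: growth_essential_under_production(
                grafted, rxns, reference, growth_fraction, config
            )
            for g, rxns in not_needed
        }
    except Exception as exc:
        raise StageError("growth_check", exc) from exc

    # stage 7: distances and ranking
    try:
        distances = (
            enzyme_pathway_distances(grafted, not_needed, pathway, prune)
            if not_needed
            else None
        )
    except Exception as exc:
        raise StageError("distance", exc) from exc

    order = sorted(
        (g for g, _ in not_needed),
        key=lambda g: (distances.min_distance.get(g, UNREACHABLE), g),
    )
    rank_of = {g: i + 1 for i, g in enumerate(order)}

    rows = []
    gene_to_rxns = fed.gene_to_reactions()
    for gene in sorted(essential_genes):
        is_single = gene in single_map
        rxns = tuple(single_map.get(gene, gene_to_rxns.get(gene, [])))
        needed = (
            any(r in support for r in rxns) if is_single else None
        )
        rows.append(
            CandidateRow(
                gene=gene,
                reaction_ids=rxns,
                essential_in_medium=True,
                single_enzyme=is_single,
                needed_for_production=needed,
                growth_essential_at_90pct=still_essential.get(gene),
                min_distance=(
                    distances.min_distance.get(gene)
                    if distances is not None and gene in rank_of
                    else None
                ),
                rank=rank_of.get(gene),
            )
        )

    provenance = {
        "model_id": model.id,
        "medium_hash": _hash_obj(
            {"bounds": medium.uptake_bounds, "closed": medium.default_closed}
        ),
        "pathway_hash": _hash_obj(
            {
                "name": pathway.name,
                "reactions": [
                    (r.id, sorted(r.stoichiometry.items()), r.lower_bound, r.upper_bound)
                    for r in pathway.reactions
                ],
                "auxiliary": sorted(pathway.auxiliary_reaction_ids),
            }
        ),
        "prune_hash": _hash_obj(
            {"mode": prune.mode, "ids": sorted(prune.metabolite_ids),
             "max_degree": prune.max_degree}
        ),
        "config": _hash_obj(
            {
                "feas": config.feasibility_tolerance,
                "zero": config.zero_flux_threshold,
                "frac": config.optimum_fraction,
                "growth_fraction": growth_fraction,
                "essentiality_fraction": essentiality_fraction,
            }
        ),
    }
    return TargetReport(
        model_id=model.id,
        pathway_name=pathway.name,
        rows=rows,
        gene_screen=screen,
        support=support,
        distances=distances,
        provenance=provenance,
    )


def _row_dict(row: CandidateRow) -> dict:
    d = row.min_distance
    return {
        "gene": row.gene,
        "reactions": list(row.reaction_ids),
        "essential_in_medium": row.essential_in_medium,
        "single_enzyme": row.single_enzyme,
        "needed_for_production": row.needed_for_production,
        "growth_essential_at_90pct": row.growth_essential_at_90pct,
        "min_distance": ("unreachable" if d is not None and math.isinf(d) else d),
        "rank": row.rank,
    }


def report_to_dict(report: TargetReport) -> dict:
    return {
        "model_id": report.model_id,
        "pathway": report.pathway_name,
        "provenance": report.provenance,
        "candidates": [_row_dict(r) for r in report.rows],
        "production_support": sorted(report.support),
        "gene_screen": [
            {
                "target_id": k.target_id,
                "kind": k.target_kind,
                "wt_growth": round(k.wt_growth, 9),
                "ko_growth": round(k.ko_growth, 9),
                "essential": k.essential,
            }
            for k in report.gene_screen
        ],
        "distances": report.distances.to_rows() if report.distances else [],
    }


def write_report(report: TargetReport, path, fmt: str = "json") -> None:
    """Serialize a report as JSON (full) or TSV (one row per candidate)."""
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(report_to_dict(report), fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif fmt == "tsv":
        cols = [
            "rank", "gene", "min_distance", "essential_in_medium", "single_enzyme",
            "needed_for_production", "growth_essential_at_90pct", "reactions",
        ]
        ranked_first = sorted(
            report.rows,
            key=lambda r: (r.rank is None, r.rank if r.rank is not None else 0, r.gene),
        )
        with open(path, "w") as fh:
            fh.write("# model=%s pathway=%s %s\n" % (
                report.model_id, report.pathway_name,
                " ".join(f"{k}={v}" for k, v in sorted(report.provenance.items())),
            ))
            fh.write("\t".join(cols) + "\n")
            for row in ranked_first:
                d = _row_dict(row)
                d["reactions"] = ";".join(row.reaction_ids)
                fh.write("\t".join(str(d[c]) for c in cols) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")
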