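"""External validation against the yeast genome-scale model (yeast-GEM).

The yeast-GEM SBML file (v8.6.0, ~15 MB) is not distributed with this
package; download it from the SysBioChalmers yeast-GEM releases and place it
at ``models/yeast-GEM.xml`` (or pass an explicit path).  The routines here
run the same pipeline stages the toy tests exercise, on the real network:
SDM medium, gene essentiality, the single-enzyme filter, grafting of the
muconic-acid and glycolic-acid pathways, and the pruned-graph distances of
the Aro1/Hom3/Acc1 target enzymes to each pathway.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .distance import PruneSpec, default_currency_prune, enzyme_pathway_distances
from .essentiality import gene_knockout_screen, single_enzyme_essentials
from .model_core import MetabolicModel, apply_medium, load_medium, load_sbml
from .pathways import add_pathway, packaged_pathway

DEFAULT_MODEL_PATH = Path("models/yeast-GEM.xml")

#: Systematic ORF names of the three benchmark enzymes.
TARGET_GENES = {"ACC1": "YNR016C", "ARO1": "YDR127W", "HOM3": "YER052C"}


def sdm_medium():
    """The packaged synthetic-defined-medium spec (yeast-GEM exchange ids)."""
    ref = resources.files("degrank.data").joinpath("yeast_gem_sdm.yaml")
    with resources.as_file(ref) as path:
        return load_medium(path)


def load_yeast_gem(path=DEFAULT_MODEL_PATH) -> MetabolicModel:
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(
            f"yeast-GEM SBML not found at {path}; download yeast-GEM v8.6.0 "
            "(SysBioChalmers/yeast-GEM releases) and place it there to run "
            "the external validation"
        )
    return load_sbml(path)


def _gene_reactions(model: MetabolicModel, gene: str) -> list[str]:
    mapping = model.gene_to_reactions()
    if gene in mapping:
        return mapping[gene]
    raise KeyError(f"gene {gene!r} not found in model GPR rules")


def essential_trio_check(model: MetabolicModel) -> dict:
    """Run the SDM gene screen and report whether Acc1/Aro1/Hom3 qualify."""
    fed = apply_medium(model, sdm_medium())
    screen = gene_knockout_screen(fed)
    singles = {g for g, _ in single_enzyme_essentials(fed, screen)}
    essential = {r.target_id for r in screen if r.essential}
    return {
        "n_essential_genes": len(essential),
        "n_single_enzyme_essentials": len(singles),
        "trio": {
            std: {
                "gene": orf,
                "essential": orf in essential,
                "single_enzyme": orf in singles,
            }
            for std, orf in TARGET_GENES.items()
        },
    }


def trio_pathway_distances(
    model: MetabolicModel, prune: PruneSpec | None = None
) -> dict:
    """Minimum distances of Aro1/Hom3/Acc1 to the MA and GA pathways.

    Uses the packaged currency list unless an explicit prune list (e.g. a
    curated highly-connected-metabolite table) is provided.
    """
    fed = apply_medium(model, sdm_medium())
    out: dict[str, dict[str, float]] = {}
    for pathway_name in ("muconic_acid", "glycolic_acid"):
        pathway = packaged_pathway(pathway_name)
        grafted = add_pathway(fed, pathway)
        spec = prune if prune is not None else default_currency_prune(grafted)
        enzymes = [
            (orf, _gene_reactions(grafted, orf)) for orf in TARGET_GENES.values()
        ]
        table = enzyme_pathway_distances(grafted, enzymes, pathway, spec)
        for std, orf in TARGET_GENES.items():
            out.setdefault(std, {})[pathway_name] = table.min_distance[orf]
    return out
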