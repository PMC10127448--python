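#!/usr/bin/env python
"""Generate the demonstration toy network used by the downstream analyses.

Emits a compartmentalized host model with a growth backbone, isozyme-gated
steps, a currency-hub cofactor couple, branch routes, and a product pathway
tapping the backbone at a known distance from a planted target enzyme —
together with its medium, pathway definition, and constructive ground truth.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from degrank import generate_toy_model, write_model_json
from degrank.model_core import write_medium
from degrank.pathways import write_pathway
from degrank.synthetic_data import ToySpec

OUT = Path(__file__).resolve().parents[1] / "results" / "toy"

SPEC = ToySpec(
    n_linear_core=10,
    n_branches=2,
    isozyme_fraction=0.3,
    currency_hubs=1,
    planted_pathway_distance=3,
    seed=42,
)


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    model, medium, pathway, truth = generate_toy_model(SPEC)
    write_model_json(model, OUT / "model.json")
    write_medium(medium, OUT / "medium.yaml")
    write_pathway(pathway, OUT / "pathway.yaml")
    with open(OUT / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "essential_genes": sorted(truth.essential_genes),
                "single_enzyme_essential_genes": sorted(
                    truth.single_enzyme_essential_genes
                ),
                "planted_target_gene": truth.planted_target_gene,
                "planted_target_reaction": truth.planted_target_reaction,
                "planted_distance": truth.planted_distance,
                "production_support_ids": sorted(truth.production_support_ids),
                "currency_metabolite_ids": sorted(truth.currency_metabolite_ids),
            },
            fh, indent=1,
        )
        fh.write("\n")
    print(f"toy network: {len(model.reactions)} reactions, "
          f"{len(model.metabolites)} metabolites, "
          f"{len(model.genes)} genes")
    print(f"planted target {truth.planted_target_gene} "
          f"({truth.planted_target_reaction}) at distance "
          f"{truth.planted_distance} from the product pathway")
    print(f"written to {OUT}/")


if __name__ == "__main__":
    main()
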