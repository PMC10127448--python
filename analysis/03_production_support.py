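#!/usr/bin/env python
"""Graft the product pathway and classify reactions by production need.

Maximal product export is computed by FBA, the parsimonious flux at that
optimum by pFBA, and flux variability then refines the support to reactions
that *must* carry flux at optimal production.  Enzymes in this support are
excluded as degradation targets: repressing them would directly cut product
formation.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from degrank import (
    add_pathway,
    apply_medium,
    fba,
    load_medium,
    load_model_json,
    load_pathway,
    pfba,
    production_support,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    model = load_model_json(ROOT / "toy" / "model.json")
    medium = load_medium(ROOT / "toy" / "medium.yaml")
    pathway = load_pathway(ROOT / "toy" / "pathway.yaml")
    grafted = add_pathway(apply_medium(model, medium), pathway)

    growth = fba(grafted).objective_value
    product = fba(grafted, pathway.product_exchange_id).objective_value
    support = production_support(grafted, pathway.product_exchange_id)

    out = ROOT / "production_support.txt"
    out.write_text("\n".join(sorted(support)) + "\n")
    print(f"growth optimum after grafting: {growth:.3f} (pathway optional)")
    print(f"product optimum: {product:.3f}")
    print(f"{len(support)} reactions needed for optimal production "
          f"(pFBA support, FVA-refined): {', '.join(sorted(support))}")
    print(f"support written to {out}")


if __name__ == "__main__":
    main()
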