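#!/usr/bin/env python
"""External validation on the real yeast genome-scale model (yeast-GEM).

Needs the yeast-GEM v8.6.0 SBML file (not redistributable here; download it
from the SysBioChalmers yeast-GEM releases) at models/yeast-GEM.xml or at a
path given as the first argument.  Reports whether Acc1/Aro1/Hom3 are
single-enzyme growth-essential under SDM and their minimum pruned-graph
distances to the muconic-acid and glycolic-acid pathways.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from degrank.yeast_gem import (  # noqa: E402
    DEFAULT_MODEL_PATH,
    essential_trio_check,
    load_yeast_gem,
    trio_pathway_distances,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    path = Path(sys.argv[1]) if len(sys.argv) > 1 else DEFAULT_MODEL_PATH
    if not path.is_file():
        print(f"yeast-GEM SBML not found at {path}.")
        print("Download yeast-GEM v8.6.0 (SysBioChalmers/yeast-GEM releases), "
              "place it there, and re-run; skipping external validation.")
        return
    model = load_yeast_gem(path)
    print(f"loaded {model.id}: {len(model.reactions)} reactions, "
          f"{len(model.metabolites)} metabolites")
    trio = essential_trio_check(model)
    print(f"{trio['n_essential_genes']} essential genes under SDM, "
          f"{trio['n_single_enzyme_essentials']} single-enzyme essentials")
    for std, info in trio["trio"].items():
        print(f"  {std} ({info['gene']}): essential={info['essential']} "
              f"single_enzyme={info['single_enzyme']}")
    distances = trio_pathway_distances(model)
    out = ROOT / "yeast_gem_distances.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w") as fh:
        fh.write("enzyme\tpathway\tmin_distance\n")
        for std, per_pathway in sorted(distances.items()):
            for pathway_name, d in sorted(per_pathway.items()):
                print(f"  {std} -> {pathway_name}: {d}")
                fh.write(f"{std}\t{pathway_name}\t{d}\n")
    print(f"distance table written to {out}")


if __name__ == "__main__":
    main()
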