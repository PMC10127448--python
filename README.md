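# degrank

Model-guided selection of inducible protein-degradation targets in
genome-scale metabolic models.

## The problem

Redirecting flux from growth to a heterologous product is a central trade-off
in metabolic engineering. One way to make it switchable is to tag a
growth-essential enzyme for inducible proteolysis (e.g. ssrA tagging with a
heterologous ClpXP protease in *Saccharomyces cerevisiae*): induce the
protease, growth stops, and resources flow to the product. Which enzyme to
tag is a network question, and `degrank` answers it computationally:

1. **Essentiality** — single-gene knockout screen by flux balance analysis
   (FBA) under a minimal medium (by default SDM: glucose and ammonium as
   sole carbon and nitrogen sources): a gene is essential when knockout
   growth falls below 1% of wild type.
2. **Single-enzyme filter** — keep genes whose every reaction is gated by
   exactly that gene (no OR-isozymes, no AND-complex partners), so
   degrading the one protein unambiguously removes the activity.
3. **Pathway grafting** — add the heterologous production pathway (packaged
   definitions: cis,cis-muconic acid from 3-dehydroshikimate; glycolic acid
   from oxaloacetate) and its product exchange to the host model.
4. **Production-support exclusion** — reactions needed for optimal
   production are found by parsimonious FBA (pFBA) at the product optimum,
   refined by flux variability analysis (FVA) so only reactions *forced* to
   carry flux count; enzymes in this set are excluded as targets.
5. **Growth check at 90%** — each remaining candidate is re-examined by
   linear minimization of metabolic adjustment (lMOMA) with growth
   constrained to ≥ 90% of optimum: infeasibility confirms the enzyme is
   required for near-optimal growth.
6. **Distance ranking** — candidates are ranked by their minimum pathway
   distance on the reaction graph: reactions are adjacent (distance 1) when
   they share a metabolite, after currency metabolites (ATP, NAD(P)(H),
   H₂O, …) are pruned to remove spurious shortcuts. Distance 1 means direct
   precursor competition with the production pathway.

All linear programs share one steady-state formulation
(maximize/minimize c·v subject to S·v = 0, lb ≤ v ≤ ub) solved with HiGHS
via SciPy; the distance metric is computed twice, by breadth-first search
and by an independent binary min-cost-flow program, which must agree.

## Worked example

The numbered scripts under `analysis/` run the pipeline on a generated toy
network with planted ground truth:

```
$ python analysis/01_generate_toy.py
toy network: 17 reactions, 15 metabolites, 16 genes
planted target G4 (r_4) at distance 3 from the product pathway

$ python analysis/02_essentiality_screen.py
screened 16 genes: 7 growth-essential, 7 single-enzyme essentials

$ python analysis/03_production_support.py
product optimum: 10.000
7 reactions needed for optimal production (pFBA support, FVA-refined):
EX_S, EX_prod, P_1, P_2, P_3, r_1, regen_0

$ python analysis/04_distance_ranking.py
ranked degradation-target candidates (min distance to the product pathway):
  1. G4  distance=3  growth_essential_at_90pct=True
  2. G5  distance=4  growth_essential_at_90pct=True
  ...
planted target G4 at distance 3: recovered (rank-1 candidate: G4)
```

The rank-1 candidate is the enzyme closest to the production pathway that is
growth-essential, isozyme-free, and dispensable for production — on the toy,
exactly the planted target. The same pipeline is exposed as a CLI
(`degrank rank model.json medium.yaml muconic_acid --out-dir results/`) and
as library calls (`degrank.select_targets`). `analysis/06_yeast_gem_validation.py`
runs the identical stages on the real yeast model when the SBML file is
supplied, reporting the Acc1/Aro1/Hom3 essentiality calls and their
distances to the muconic- and glycolic-acid pathways.

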