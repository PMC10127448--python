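# Methods

## Constraint-based model and solvers

A model is a stoichiometric matrix S (metabolites × reactions) with flux
bounds lb ≤ v ≤ ub in mmol·gDW⁻¹·h⁻¹, boolean gene–protein–reaction (GPR)
rules, and one objective reaction (the biomass drain unless declared
otherwise). Every analysis is a linear program over the steady-state
polytope {v : S·v = 0, lb ≤ v ≤ ub}, solved with HiGHS through
`scipy.optimize.linprog` (primal feasibility tolerance 1e-9). Infinite
bounds are replaced by ±1000, the customary genome-scale convention, before
solving.

* **FBA** maximizes a single flux (growth or product export).
* **pFBA** holds the objective at ≥ f × optimum (default f = 1.0) and
  minimizes Σ|v|, linearized by splitting each reaction into non-negative
  forward/backward halves. f = 1.0 is used for "needed for optimal
  production" because the question is about the optimum itself; f is
  configurable for sensitivity analyses.
* **FVA** reports each reaction's attainable [min, max] flux at ≥ f ×
  optimum.
* **lMOMA** minimizes Σ|v − v_ref| with non-negative deviation variables.
  The reference is the wild-type pFBA growth solution of the grafted model
  under the medium — pFBA rather than raw FBA because the parsimonious
  vertex is reproducible and biologically conservative, and the reference
  choice is recorded in report provenance.

Alternate LP optima are unavoidable at genome scale, so no downstream
decision depends on a particular flux vector: essentiality uses objective
values only, and production support is refined by FVA (a reaction is
"needed" only when its feasible flux interval at the production optimum
excludes zero, threshold 1e-6). Degenerate inputs behave predictably:
infeasible problems return a status rather than raising, a zero-growth
medium aborts the pipeline at stage 1 with a named stage error, and blocked
reactions show FVA range [0, 0].

## Essentiality and the single-enzyme filter

Gene deletions are simulated through the GPR rules (AND = complex, OR =
isozymes; AND binds tighter than OR, keywords case-insensitive): every
reaction whose rule evaluates false with the gene removed is bounded to
[0, 0] — bounding, never structural removal, so indices stay stable — and
growth is re-optimized. A target is essential when knockout growth is below
1% of wild type (`essentiality_fraction = 0.01`); the cutoff is far above
LP tolerance and far below any biologically meaningful growth, so calls are
insensitive to its exact value. The single-enzyme filter keeps essential
genes all of whose reactions are gated by exactly that gene. Complex
members (GPR `A and B`) are excluded even though each member's deletion is
lethal: degradation of one subunit implicates a shared activity rather
than a single protein, and the benchmark yeast trio (Acc1, Aro1, Hom3) are
all single-gene enzymes. Null-mutant viability databases are a recommended
manual cross-check and outside computational scope.

## Media

A medium lists maximum uptake rates per exchange reaction; exchanges are
detected as reactions touching exactly one metabolite, uptake being the
negative direction. With `default_closed` every unlisted exchange keeps
secretion open but loses uptake — that closure is what makes the listed
carbon/nitrogen sources "sole". The packaged SDM file sets glucose ≤ 10
mmol·gDW⁻¹·h⁻¹ (the customary aerobic batch value) and leaves ammonium,
oxygen, phosphate, sulfate, water, protons, and trace inorganics
effectively unconstrained. The exchange ids follow yeast-GEM v8.x; on
other model versions `apply_medium` rejects unknown ids by name, and
essentiality results on real models should always be reported together
with the medium file used (its hash travels in report provenance).

## Pathway definitions and grafting

Pathway YAML files declare heterologous reactions with explicit
stoichiometry, the new metabolites, a product exchange, and a host-mapping
table resolved by metabolite id first and unique name + compartment second
— name-level mapping is what lets one file serve different model versions;
unresolved species abort grafting with the offending names listed.
Reactions marked `auxiliary` (the Pad1 prenyl-FMN supply for the
muconic-acid route, the GapN NADPH boost for the glycolic-acid route) are
grafted with the pathway but excluded from pathway membership for distance
purposes, since they support the pathway rather than constitute it. The
packaged stoichiometries are balanced from standard biochemical references
(per-reaction provenance comments in the files); host activities that the
engineering context overexpresses but that already exist in the host model
(e.g. DHQ synthase/dehydratase steps) are deliberately not duplicated.
Grafting is non-invasive: added reactions can always carry zero flux, so
the host biomass optimum is invariant (asserted in tests).

## Pathway distance

Reactions are nodes; an undirected edge joins two reactions sharing at
least one surviving metabolite on either side. Undirected adjacency is
deliberate: the canonical distance-1 case is two reactions *competing for*
the same precursor, which a directed product-to-substrate graph would
miss. Compartments are respected (the same compound in two compartments is
two nodes; transporters provide connectivity), and biomass plus exchange
pseudo-reactions are excluded as biologically meaningless shortcuts.
Before building the graph, highly connected currency metabolites are
removed — otherwise nearly every enzyme pair would be two steps apart via
ATP or water. The packaged default list (adenylates and other NTPs,
NAD(P)(H), FAD, CoA and acetyl-CoA, SAM/SAH, water, protons, phosphate,
diphosphate, CO₂, O₂, ammonium) is matched per compartment by name or
id-stem; an explicit curated list, when available for a given model
version, overrides it, and a participation-degree threshold mode is also
provided. Unreachable pairs carry an infinite sentinel that sorts last.

The distance is computed by two independent routes — multi-source BFS, and
a binary min-cost unit-flow MILP (HiGHS via `scipy.optimize.milp`) that
selects the shortest chain of pairwise-adjacent reactions — whose equality
on every tested instance is the module's primary correctness property. A
multifunctional enzyme (e.g. the pentafunctional Aro1) contributes its
whole reaction set, and its reported distance is the minimum over that set
and all pathway reactions.

## Selection pipeline

Candidates ranked are exactly the genes that are essential in the medium,
single-enzyme, and not needed for optimal production; the sort key is
(minimum pathway distance ascending, gene id ascending) — the lexicographic
tie-break buys byte-identical reports. Each candidate also carries a
90%-growth lMOMA verdict (`growth_fraction = 0.90`): with the candidate's
reactions closed and growth floored at 90% of optimum, infeasibility
confirms the enzyme is required for near-optimal growth. Because
infeasibility is reference-independent, this agrees with a plain FBA
feasibility check (tested), but the lMOMA solution additionally yields the
minimal flux rearrangement when feasible. Reports embed provenance hashes
of the medium, pathway, prune list, and solver configuration.

## Synthetic networks and what they do (not) show

The generator plants every pipeline-relevant feature constructively: a
linear growth backbone (uptake 10, unit stoichiometry, so the optimum
equals the uptake bound exactly), isozyme-gated steps at a configurable
fraction, dead-end and rejoining branches, currency hubs, and a product
pathway tapping the backbone so the planted target enzyme sits at an
exactly known pruned-graph distance D (tap at backbone position t − D for
target position t). Reactions strictly between tap and target are
isozyme-gated, making the planted target the unique minimum-distance
single-enzyme essential — recovery is therefore 100% by construction and
tests exactly that construction. Currency hubs are cofactor couples: a
decorated reaction co-converts hub_a → hub_b and one free reversible
regeneration reaction closes the loop, so hubs create the graph shortcuts
that pruning must remove while leaving every optimum untouched. Ground
truth (essential genes, single-enzyme set, production support, planted
distance) is derived from the construction, never from the solvers under
test.

These toys exercise the logic, not yeast biochemistry: they have no
cofactor stoichiometry coupling flux to redox balance, no compartmental
transport costs, and trivially small alternate-optima spaces. Passing the
desk-scale suite therefore demonstrates correctness of the algorithms, not
the fidelity of any particular genome-scale model; the external validation
on yeast-GEM (essential-trio containment and the printed trio distances)
covers that and requires the user-supplied SBML file plus, ideally, the
curated highly-connected-metabolite list of the original study — with the
packaged currency stand-in, individual distances may differ where the
curated list and the stand-in disagree on borderline hubs.

## Problem sizes and limitations

The shipped analyses and the acceptance script use 200 random networks of
≤ 15 reactions for oracle agreement, 80 pipeline runs for recovery, and one
demonstration toy (10-step backbone); these sizes give sub-minute runs on a
single CPU while covering every code path, and all randomness flows from a
single seed. Known limitations: no thermodynamic or enzyme-capacity
constraints, no quadratic MOMA, no flux- or atom-mapping-weighted
distances, no strain-design search (the tool ranks given candidates, it
does not optimize knockout sets), and no modeling of protease kinetics or
induction dynamics — the ranking is a static network statement about which
enzyme degradations trade growth for product most directly.
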