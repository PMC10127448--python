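"""Independent oracles used by the tests.

Everything here is deliberately written against different machinery than the
package under test: hand-rolled BFS instead of networkx, brute-force vertex
enumeration instead of an LP solver, and cobrapy (GLPK) instead of the
package's scipy/HiGHS engine.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


# ---------------------------------------------------------------------------
# Graph oracles
# ---------------------------------------------------------------------------

def pairwise_adjacency(model, surviving, node_ids):
    """O(n²) reaction adjacency by direct stoichiometry intersection."""
    edges = set()
    for r1, r2 in itertools.combinations(sorted(node_ids), 2):
        shared = (
            set(model.reactions[r1].stoichiometry)
            & set(model.reactions[r2].stoichiometry)
            & set(surviving)
        )
        if shared:
            edges.add((r1, r2))
    return edges


def bfs_distance(edges, nodes, sources, targets):
    """Plain deque BFS over an undirected edge set; None when unreachable."""
    sources, targets = set(sources), set(targets)
    if sources & targets:
        return 0
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen = dict.fromkeys(sources, 0)
    queue = deque(sources)
    while queue:
        node = queue.popleft()
        for nxt in adj[node]:
            if nxt not in seen:
                seen[nxt] = seen[node] + 1
                if nxt in targets:
                    return seen[nxt]
                queue.append(nxt)
    return None


# ---------------------------------------------------------------------------
# LP oracle: exhaustive vertex enumeration of {v: S v = 0, lb <= v <= ub}
# ---------------------------------------------------------------------------

def enumerate_vertices(model, tol=1e-9):
    """All vertices of the flux polytope of a tiny model (n <= ~10)."""
    rxn_ids = sorted(model.reactions)
    met_ids = sorted(model.metabolites)
    n = len(rxn_ids)
    S = np.zeros((len(met_ids), n))
    mi = {m: i for i, m in enumerate(met_ids)}
    for j, rid in enumerate(rxn_ids):
        for met, coef in model.reactions[rid].stoichiometry.items():
            S[mi[met], j] += coef
    lb = np.array([max(model.reactions[r].lower_bound, -1000.0) for r in rxn_ids])
    ub = np.array([min(model.reactions[r].upper_bound, 1000.0) for r in rxn_ids])
    rank = np.linalg.matrix_rank(S, tol=1e-10)
    k = n - rank  # bounds to activate at a vertex
    vertices = []
    for fixed in itertools.combinations(range(n), k):
        free = [j for j in range(n) if j not in fixed]
        for levels in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            rhs = -S[:, list(fixed)] @ np.array(levels)
            A = S[:, free]
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            if np.linalg.norm(A @ sol - rhs) > 1e-7:
                continue
            v = np.empty(n)
            for j, val in zip(fixed, levels):
                v[j] = val
            for j, val in zip(free, sol):
                v[j] = val
            if np.all(v >= lb - 1e-7) and np.all(v <= ub + 1e-7):
                vertices.append(v)
    return rxn_ids, vertices


def vertex_optimum(model, objective_id, maximize=True):
    """Best objective value over enumerated vertices (None if polytope empty)."""
    rxn_ids, vertices = enumerate_vertices(model)
    if not vertices:
        return None
    j = rxn_ids.index(objective_id)
    vals = [v[j] for v in vertices]
    return max(vals) if maximize else min(vals)


# ---------------------------------------------------------------------------
# cobra oracle
# ---------------------------------------------------------------------------

def cobra_fba_optimum(model):
    """Growth optimum via cobrapy/GLPK, fully independent of the LP engine."""
    from degrank.model_core import to_cobra

    cm = to_cobra(model)
    sol = cm.optimize()
    return 0.0 if sol.status != "optimal" else float(sol.objective_value)


def cobra_gene_essentials(model, fraction=0.01):
    from cobra.flux_analysis import single_gene_deletion

    from degrank.model_core import to_cobra

    cm = to_cobra(model)
    wt = cm.slim_optimize()
    df = single_gene_deletion(cm, processes=1)
    essential = set()
    for _, row in df.iterrows():
        growth = row["growth"]
        if np.isnan(growth) or growth < fraction * wt:
            essential |= set(row["ids"])
    return essential
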