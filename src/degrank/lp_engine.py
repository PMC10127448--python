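"""Linear programs on stoichiometric models: FBA, pFBA, FVA, linear MOMA.

All four problems share the steady-state polytope {v : S·v = 0, lb ≤ v ≤ ub}
and are solved with the HiGHS simplex/IPM backend behind
:func:`scipy.optimize.linprog`:

* **FBA** maximizes one reaction flux (growth, or product export).
* **pFBA** fixes the objective at a fraction of its optimum and minimizes
  total absolute flux Σ|v|, linearized by splitting every reaction into two
  non-negative half-variables.
* **FVA** reports the attainable [min, max] flux per reaction at a fraction
  of the optimum; used to decide which reactions *must* carry flux.
* **lMOMA** minimizes the L1 distance Σ|v − v_ref| to a reference flux
  distribution, linearized with non-negative deviation variables.

Downstream logic only ever consumes objective values and must-carry-flux
ranges, never a particular vertex, so alternate LP optima are harmless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix, hstack, identity, lil_matrix
from scipy.sparse import vstack as sparse_vstack

from .model_core import BIG_BOUND, FluxState, MetabolicModel

__all__ = ["SolveConfig", "fba", "pfba", "flux_variability", "lmoma"]


@dataclass(frozen=True)
class SolveConfig:
    """Numerical knobs shared by every solve.

    feasibility_tolerance is handed to HiGHS; zero_flux_threshold is the level
    below which a flux counts as "not carried"; optimum_fraction is the default
    objective retention for secondary problems (pFBA/FVA).
    """

    feasibility_tolerance: float = 1e-9
    zero_flux_threshold: float = 1e-6
    optimum_fraction: float = 1.0

    def __post_init__(self):
        if self.feasibility_tolerance <= 0 or self.zero_flux_threshold <= 0:
            raise ValueError("tolerances must be positive")
        if not 0 < self.optimum_fraction <= 1:
            raise ValueError("optimum_fraction must be in (0, 1]")


DEFAULT_CONFIG = SolveConfig()


class _Problem:
    """Cached S-matrix view of a model, with stable reaction/metabolite order."""

    def __init__(self, model: MetabolicModel):
        self.model = model
        self.rxn_ids = sorted(model.reactions)
        self.met_ids = sorted(model.metabolites)
        self.rxn_index = {r: i for i, r in enumerate(self.rxn_ids)}
        met_index = {m: i for i, m in enumerate(self.met_ids)}
        S = lil_matrix((len(self.met_ids), len(self.rxn_ids)))
        for j, rid in enumerate(self.rxn_ids):
            for met, coef in model.reactions[rid].stoichiometry.items():
                S[met_index[met], j] = coef
        self.S = csr_matrix(S)
        self.lb = np.array(
            [max(model.reactions[r].lower_bound, -BIG_BOUND) for r in self.rxn_ids]
        )
        self.ub = np.array(
            [min(model.reactions[r].upper_bound, BIG_BOUND) for r in self.rxn_ids]
        )

    def n(self) -> int:
        return len(self.rxn_ids)


def _solve(c, A_eq, b_eq, A_ub, b_ub, bounds, config: SolveConfig):
    return linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": config.feasibility_tolerance},
    )


def _status(res) -> str:
    if res.status == 0:
        return "optimal"
    if res.status == 3:
        return "unbounded"
    return "infeasible"


def fba(
    model: MetabolicModel,
    objective_id: str | None = None,
    maximize: bool = True,
    config: SolveConfig = DEFAULT_CONFIG,
) -> FluxState:
    """Flux balance analysis: optimize one reaction flux over the polytope."""
    prob = _Problem(model)
    objective_id = objective_id or model.objective_id
    if objective_id not in prob.rxn_index:
        raise KeyError(f"objective reaction {objective_id!r} not in model")
    c = np.zeros(prob.n())
    c[prob.rxn_index[objective_id]] = -1.0 if maximize else 1.0
    res = _solve(c, prob.S, np.zeros(prob.S.shape[0]), None, None,
                 list(zip(prob.lb, prob.ub)), config)
    status = _status(res)
    if status != "optimal":
        return FluxState(fluxes={}, objective_value=float("nan"), status=status)
    fluxes = dict(zip(prob.rxn_ids, res.x))
    return FluxState(
        fluxes=fluxes,
        objective_value=float(fluxes[objective_id]),
        status="optimal",
    )


def _split_problem(prob: _Problem):
    """Forward/backward split: v = v⁺ − v⁻ with v⁺, v⁻ ≥ 0.

    Returns (A_eq for S(v⁺−v⁻)=0, variable bounds) over 2n variables.
    """
    A_eq = hstack([prob.S, -prob.S]).tocsr()
    fwd = [(max(lb, 0.0), max(ub, 0.0)) for lb, ub in zip(prob.lb, prob.ub)]
    bwd = [(max(-ub, 0.0), max(-lb, 0.0)) for lb, ub in zip(prob.lb, prob.ub)]
    return A_eq, fwd + bwd


def pfba(
    model: MetabolicModel,
    objective_id: str | None = None,
    optimum_fraction: float | None = None,
    config: SolveConfig = DEFAULT_CONFIG,
) -> FluxState:
    """Parsimonious FBA: minimal Σ|v| at ≥ fraction × the FBA optimum.

    The returned ``objective_value`` is the flux of the (biological) objective
    reaction; the attained Σ|v| is stored under ``fluxes`` implicitly.
    """
    objective_id = objective_id or model.objective_id
    frac = config.optimum_fraction if optimum_fraction is None else optimum_fraction
    ref = fba(model, objective_id, config=config)
    if ref.status != "optimal":
        return ref
    prob = _Problem(model)
    n = prob.n()
    A_eq, bounds = _split_problem(prob)
    # hold the objective flux at >= frac * optimum
    row = lil_matrix((1, 2 * n))
    j = prob.rxn_index[objective_id]
    row[0, j] = -1.0
    row[0, n + j] = 1.0  # -(v+ - v-) <= -frac*opt
    target = frac * ref.objective_value
    res = _solve(
        np.ones(2 * n), A_eq, np.zeros(A_eq.shape[0]),
        csr_matrix(row), np.array([-target]), bounds, config,
    )
    status = _status(res)
    if status != "optimal":
        return FluxState(fluxes={}, objective_value=float("nan"), status=status)
    v = res.x[:n] - res.x[n:]
    fluxes = dict(zip(prob.rxn_ids, v))
    return FluxState(fluxes=fluxes, objective_value=float(fluxes[objective_id]),
                     status="optimal")


def total_flux(state: FluxState) -> float:
    """Σ|v| of a flux distribution (pFBA's criterion)."""
    return float(sum(abs(v) for v in state.fluxes.values()))


def flux_variability(
    model: MetabolicModel,
    reaction_ids: list[str] | None = None,
    objective_id: str | None = None,
    optimum_fraction: float | None = None,
    config: SolveConfig = DEFAULT_CONFIG,
) -> dict[str, tuple[float, float]]:
    """Per-reaction [min, max] flux at ≥ fraction × the FBA optimum."""
    objective_id = objective_id or model.objective_id
    frac = config.optimum_fraction if optimum_fraction is None else optimum_fraction
    ref = fba(model, objective_id, config=config)
    if ref.status != "optimal":
        raise RuntimeError(f"FBA not optimal ({ref.status}); cannot run FVA")
    prob = _Problem(model)
    reaction_ids = list(reaction_ids) if reaction_ids is not None else prob.rxn_ids
    j = prob.rxn_index[objective_id]
    row = lil_matrix((1, prob.n()))
    row[0, j] = -1.0
    A_ub = csr_matrix(row)
    b_ub = np.array([-frac * ref.objective_value])
    bounds = list(zip(prob.lb, prob.ub))
    out: dict[str, tuple[float, float]] = {}
    for rid in reaction_ids:
        if rid not in prob.rxn_index:
            raise KeyError(f"unknown reaction {rid!r}")
        c = np.zeros(prob.n())
        c[prob.rxn_index[rid]] = 1.0
        lo = _solve(c, prob.S, np.zeros(prob.S.shape[0]), A_ub, b_ub, bounds, config)
        hi = _solve(-c, prob.S, np.zeros(prob.S.shape[0]), A_ub, b_ub, bounds, config)
        if lo.status != 0 or hi.status != 0:
            raise RuntimeError(f"FVA subproblem for {rid!r} not optimal")
        out[rid] = (float(lo.x[prob.rxn_index[rid]]), float(hi.x[prob.rxn_index[rid]]))
    return out


def lmoma(
    model: MetabolicModel,
    reference: FluxState,
    config: SolveConfig = DEFAULT_CONFIG,
) -> FluxState:
    """Linear minimization of metabolic adjustment.

    Minimizes Σ|v − v_ref| subject to the current model's steady-state polytope
    (reference fluxes missing a reaction are treated as 0).  The attained L1
    distance is returned as ``objective_value``.
    """
    prob = _Problem(model)
    n = prob.n()
    v_ref = np.array([reference.fluxes.get(r, 0.0) for r in prob.rxn_ids])
    # variables: [v, d+, d-], constraint v - d+ + d- = v_ref
    A_top = hstack(
        [prob.S, csr_matrix((prob.S.shape[0], 2 * n))]
    )
    eye = identity(n, format="csr")
    A_dev = hstack([eye, -eye, eye])
    A_eq = sparse_vstack([A_top, A_dev]).tocsr()
    b_eq = np.concatenate([np.zeros(prob.S.shape[0]), v_ref])
    c = np.concatenate([np.zeros(n), np.ones(2 * n)])
    bounds = list(zip(prob.lb, prob.ub)) + [(0.0, None)] * (2 * n)
    res = _solve(c, A_eq, b_eq, None, None, bounds, config)
    status = _status(res)
    if status != "optimal":
        return FluxState(fluxes={}, objective_value=float("nan"), status=status)
    fluxes = dict(zip(prob.rxn_ids, res.x[:n]))
    return FluxState(fluxes=fluxes, objective_value=float(res.fun), status="optimal")
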