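"""Linear-programming core: FBA and net maximal secretion potentials.

Flux balance analysis solves ``optimize c.v  s.t.  S.v = 0, lb <= v <= ub``
with scipy's HiGHS backend.  The net maximal secretion potential of a
metabolite in a community model is the community's capability to *produce*
it: maximise the fecal exchange flux, read the diet exchange flux at that
optimum, and report ``|v_fe + v_diet|`` (diet flux is <= 0 at uptake, so the
sum is secretion minus uptake; a pure pass-through scores 0).

Degenerate optima are resolved by a lexicographic second stage that fixes
the objective at its optimum and minimises total absolute flux, making the
reported diet flux (and hence the potential) deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, sparse

from .recon_core import stoichiometric_matrix

logger = logging.getLogger(__name__)

FEASIBILITY_TOL = 1e-6
OPTIMALITY_TOL = 1e-7


@dataclass
class FluxSolution:
    objective_value: float
    fluxes: dict[str, float]
    status: str  # optimal | infeasible | unbounded

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


class InfeasibleModelError(RuntimeError):
    def __init__(self, status: str, message: str = ""):
        self.status = status
        super().__init__(message or f"LP terminated with status {status!r}")


def _solve(S, lb, ub, c, sense: str):
    """One linprog call; returns (status, x, objective)."""
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    sign = -1.0 if sense == "max" else 1.0
    res = optimize.linprog(
        sign * c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
        options={"primal_feasibility_tolerance": OPTIMALITY_TOL},
    )
    if res.status == 0:
        return "optimal", res.x, sign * res.fun
    if res.status == 2:
        return "infeasible", None, math.nan
    if res.status == 3:
        return "unbounded", None, math.nan
    return "failed", None, math.nan


def fba(model, objective_reaction: str, sense: str = "max") -> FluxSolution:
    """Optimise one reaction flux; never raises on infeasible/unbounded."""
    S, met_index, rxn_index = stoichiometric_matrix(model)
    if objective_reaction not in rxn_index:
        raise KeyError(f"objective reaction {objective_reaction!r} not in model")
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    c = np.zeros(len(rxn_index))
    c[rxn_index[objective_reaction]] = 1.0
    status, x, obj = _solve(S, lb, ub, c, sense)
    if status != "optimal":
        return FluxSolution(math.nan, {}, status)
    fluxes = {rid: float(x[j]) for rid, j in rxn_index.items()}
    return FluxSolution(float(obj), fluxes, "optimal")


def _parsimonious_fluxes(model, fixed_rxn: str, fixed_value: float):
    """Minimise total |v| with one flux pinned; resolves degenerate optima.

    Split each flux into v = p - n with p, n >= 0 and minimise sum(p + n).
    """
    S, _, rxn_index = stoichiometric_matrix(model)
    n = S.shape[1]
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    j = rxn_index[fixed_rxn]
    # tiny slack so the pinned optimum stays feasible under solver tolerance
    lb[j] = fixed_value - 1e-7
    ub[j] = fixed_value + 1e-7
    A = sparse.hstack([S, -S]).tocsr()
    # v = p - n with p in [lb+, ub+], n in [(-ub)+, (-lb)+]; at the optimum of
    # sum(p + n) at most one of p, n is interior, so sum(p + n) = sum |v|
    p_bounds = [(max(l, 0.0), max(u, 0.0)) for l, u in zip(lb, ub)]
    n_bounds = [(max(-u, 0.0), max(-l, 0.0)) for l, u in zip(lb, ub)]
    bounds = p_bounds + n_bounds
    c = np.ones(2 * n)
    res = optimize.linprog(
        c, A_eq=A, b_eq=np.zeros(A.shape[0]), bounds=bounds, method="highs"
    )
    if res.status != 0:
        return None
    v = res.x[:n] - res.x[n:]
    return {rid: float(v[jj]) for rid, jj in rxn_index.items()}


def secretion_potential(model, metabolite_id: str) -> float:
    """Net maximal secretion potential of one metabolite in a community model.

    Requires ``Diet_EX_<met>[d]`` and ``EX_<met>[fe]`` exchange reactions (the
    community builder creates both for every lumen metabolite).
    """
    diet_id = f"Diet_EX_{metabolite_id}[d]"
    fe_id = f"EX_{metabolite_id}[fe]"
    rxn_ids = set(model.reaction_ids)
    if diet_id not in rxn_ids or fe_id not in rxn_ids:
        raise KeyError(
            f"metabolite {metabolite_id!r} lacks diet/fecal exchange pair "
            f"({diet_id}, {fe_id})"
        )
    sol = fba(model, fe_id, "max")
    if not sol.ok:
        raise InfeasibleModelError(sol.status, f"FBA for {fe_id}: {sol.status}")
    fluxes = _parsimonious_fluxes(model, fe_id, sol.objective_value)
    if fluxes is None:  # fall back to the first-stage solution
        fluxes = sol.fluxes
    v_fe = fluxes[fe_id]
    v_diet = fluxes[diet_id]  # <= 0 at uptake
    potential = abs(v_fe + v_diet)
    return potential if potential > FEASIBILITY_TOL else 0.0


def secretion_screen(model, metabolite_ids, subject_id: str = "") -> dict[str, float]:
    """Per-metabolite secretion potentials; infeasibilities become NaN."""
    out: dict[str, float] = {}
    for met in metabolite_ids:
        try:
            out[met] = secretion_potential(model, met)
        except InfeasibleModelError as exc:
            logger.warning("subject %s metabolite %s: %s", subject_id, met, exc.status)
            out[met] = math.nan
    return out


def check_solution(model, sol: FluxSolution, tol: float = FEASIBILITY_TOL * 10):
    """Verify S.v = 0 and bound satisfaction for an optimal solution."""
    if not sol.ok:
        raise ValueError("can only check optimal solutions")
    S, _, rxn_index = stoichiometric_matrix(model)
    v = np.array([sol.fluxes[r.id] for r in model.reactions])
    resid = np.abs(S @ v).max() if S.shape[0] else 0.0
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    bound_viol = max(np.max(lb - v, initial=0.0), np.max(v - ub, initial=0.0))
    return float(resid), float(bound_viol)
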