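"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the LP oracle enumerates
polytope vertices with dense linear algebra, the cobra oracle routes the same
model through an unrelated solver stack (GLPK), and the KS oracle evaluates
the empirical-CDF supremum by direct scanning.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np


def brute_force_lp_max(S, lb, ub, c):
    """Maximise c.v over {S v = 0, lb <= v <= ub} by vertex enumeration.

    Only for tiny systems (a handful of variables).  Returns the best
    objective over all basic feasible points, or None if none is feasible.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    lb, ub, c = (np.asarray(a, dtype=float) for a in (lb, ub, c))
    n = S.shape[1]
    r = np.linalg.matrix_rank(S)
    n_fix = n - r
    best = None
    for fixed in combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed]
        for bounds_choice in product(*[(lb[j], ub[j]) for j in fixed]):
            v = np.zeros(n)
            for j, val in zip(fixed, bounds_choice):
                v[j] = val
            rhs = -S[:, list(fixed)] @ np.array(bounds_choice)
            sol, residuals, rank, _ = np.linalg.lstsq(S[:, free], rhs, rcond=None)
            v[free] = sol
            if np.max(np.abs(S @ v)) > 1e-8:
                continue
            if np.any(v < lb - 1e-8) or np.any(v > ub + 1e-8):
                continue
            obj = float(c @ v)
            if best is None or obj > best:
                best = obj
    return best


def model_to_cobra(model):
    """Translate a Reconstruction/CommunityModel into a cobra model."""
    import cobra

    cm = cobra.Model(getattr(model, "strain_id", "community"))
    mets = {m.id: cobra.Metabolite(m.id) for m in model.metabolites}
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id)
        cr.lower_bound = r.lower_bound
        cr.upper_bound = r.upper_bound
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions:
        cm.reactions.get_by_id(r.id).add_metabolites(
            {mets[k]: v for k, v in r.stoichiometry.items()}
        )
    return cm


def cobra_fba_max(model, objective: str) -> tuple[str, float]:
    cm = model_to_cobra(model)
    cm.objective = objective
    sol = cm.optimize()
    return sol.status, (sol.objective_value if sol.status == "optimal" else float("nan"))


def ks_statistic_brute(a, b) -> float:
    """sup_x |F_a(x) - F_b(x)| by scanning all pooled data points."""
    a, b = np.sort(a), np.sort(b)
    pool = np.concatenate([a, b])
    best = 0.0
    for x in pool:
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return float(best)
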