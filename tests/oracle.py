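"""Independent brute-force oracles for the LP analyses.

These formulations are written constraint-by-constraint from the model
equations, on a different solver stack (optlang/GLPK) than the production
path (scipy/HiGHS), so agreement is a genuine dual-route check. They are
deliberately naive (dense iteration over every reaction), which is fine on
the <= 8-reaction toys they are used for.
"""

from __future__ import annotations

import numpy as np
from optlang.glpk_interface import Constraint, Model, Objective, Variable

from imic.community import EXTRACELLULAR, CommunityModel
from imic.expression import CorrectionFactors


def _setup(model: CommunityModel, factors: CorrectionFactors | None,
           beta_box: float = 1000.0, uniform_factor: float | None = None):
    """Variables and shared constraints of the growth LP, built naively."""
    n = model.n_reactions
    v = [Variable(f"v_{j}", lb=0, ub=model.reactions[j].upper_bound)
         for j in range(n)]
    constraints = []
    # steady state, one row per metabolite
    S = model.S.toarray()
    for i in range(S.shape[0]):
        expr = sum(float(S[i, j]) * v[j] for j in range(n) if S[i, j] != 0)
        if not isinstance(expr, (int, float)):
            constraints.append(Constraint(expr, lb=0, ub=0))
    # expression-scaled bounds with relaxations
    bp, bm, penalty = {}, {}, 0
    for j, rxn in enumerate(model.reactions):
        if rxn.gpr is None or rxn.member == EXTRACELLULAR:
            continue
        key = (rxn.member, rxn.original_id)
        if uniform_factor is not None:
            s = uniform_factor
        elif factors is not None and key in factors.scaled:
            s = factors.scaled[key]
        else:
            continue
        bp[j] = Variable(f"bp_{j}", lb=0, ub=beta_box)
        bm[j] = Variable(f"bm_{j}", lb=0, ub=beta_box)
        vmax = model.reactions[j].upper_bound
        constraints.append(Constraint(
            v[j] - vmax * (bp[j] - bm[j]), ub=vmax * s))
        constraints.append(Constraint(bp[j] - bm[j], lb=-s, ub=1.0 - s))
        penalty = penalty + bp[j] + bm[j]
    growth = sum(v[c] for c in model.biomass_columns.values())
    return v, bp, bm, growth, penalty, constraints


def brute_force_imic(
    model: CommunityModel,
    factors: CorrectionFactors | None,
    lam: float,
    beta_box: float = 1000.0,
    uniform_factor: float | None = None,
) -> tuple[float, dict[str, float]]:
    """Optimal objective and growth rates of the growth LP via GLPK."""
    v, bp, bm, growth, penalty, constraints = _setup(
        model, factors, beta_box, uniform_factor)
    prob = Model(name="oracle")
    prob.add(constraints)
    prob.objective = Objective(growth - lam * penalty, direction="max")
    status = prob.optimize()
    assert status == "optimal", f"oracle LP not optimal: {status}"
    mu = {member: float(v[c].primal)
          for member, c in model.biomass_columns.items()}
    return float(prob.objective.value), mu


def brute_force_flux_sum(
    model: CommunityModel,
    factors: CorrectionFactors | None,
    lam: float,
    z_star: float,
    metabolite_id: str,
    beta_box: float = 1000.0,
) -> float:
    """Minimum flux sum of a metabolite at the pinned optimum, via GLPK."""
    v, bp, bm, growth, penalty, constraints = _setup(model, factors, beta_box)
    eps = 1e-6 * max(1.0, abs(z_star))
    constraints.append(Constraint(growth - lam * penalty, lb=z_star - eps))
    row = np.asarray(
        model.S.toarray()[model.met_index[metabolite_id], :]).ravel()
    phi = sum(0.5 * abs(float(c)) * v[j] for j, c in enumerate(row) if c != 0)
    prob = Model(name="oracle_fluxsum")
    prob.add(constraints)
    prob.objective = Objective(phi, direction="min")
    status = prob.optimize()
    assert status == "optimal", f"oracle flux-sum LP not optimal: {status}"
    return float(prob.objective.value)
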