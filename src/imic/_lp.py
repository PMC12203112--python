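"""Shared linear-program assembly for the growth LP and its derivatives.

Variable layout: x = [v (one per irreversible column), beta_plus, beta_minus
(one pair per GPR-bearing column with a correction factor)]. The constraint
system is

    S v = 0
    v_k <= v_max_k * (s_k + bp_k - bm_k)      k with GPR factor s_k
    0 <= v <= v_max
    0 <= s_k + bp_k - bm_k <= 1
    0 <= beta <= beta_box

assembled once as sparse blocks and reused by the solver, the variability
analysis and the flux-sum analysis, which differ only in objective vector
and in extra rows pinning the incumbent objective value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .community import CommunityModel, EXTRACELLULAR
from .expression import CorrectionFactors

__all__ = ["LPSystem", "build_system", "SolverError", "lp_solve"]


class SolverError(RuntimeError):
    """LP solve failed; carries the solver status."""

    def __init__(self, message: str, status: str = "error"):
        super().__init__(message)
        self.status = status


@dataclass
class LPSystem:
    model: CommunityModel
    n_v: int
    n_beta: int
    gpr_cols: np.ndarray  # column indices carrying a factor
    factors: np.ndarray  # scaled factor s_k per gpr col
    A_ub: sparse.csr_matrix
    b_ub: np.ndarray
    A_eq: sparse.csr_matrix
    b_eq: np.ndarray
    bounds: list[tuple[float, float]]
    objective_row: np.ndarray  # max-growth-minus-penalty coefficients
    biomass_cols: dict[str, int]
    lam: float

    @property
    def n_x(self) -> int:
        return self.n_v + 2 * self.n_beta


def build_system(
    model: CommunityModel,
    factors: CorrectionFactors | None,
    lam: float,
    beta_box: float = 1000.0,
    with_beta: bool = True,
    with_beta_minus: bool = True,
    uniform_factor: float | None = None,
) -> LPSystem:
    """Assemble the LP constraint system for one sample.

    ``uniform_factor`` overrides all scaled factors with a constant (used
    for the no-expression baseline); ``with_beta=False`` drops relaxation
    variables, giving hard expression-scaled bounds; ``with_beta_minus=False``
    keeps the beta_minus variables pinned at zero.
    """
    if not model.irreversible:
        raise ValueError("LP requires the irreversible community model")
    if lam <= 0:
        raise ValueError(f"balancing factor lambda must be > 0, got {lam}")

    n_v = model.n_reactions
    ub = model.upper_bounds
    gpr_cols: list[int] = []
    svals: list[float] = []
    for j, rxn in enumerate(model.reactions):
        if rxn.gpr is None or rxn.member == EXTRACELLULAR:
            continue
        key = (rxn.member, rxn.original_id)
        if uniform_factor is not None:
            s = float(uniform_factor)
        elif factors is not None and key in factors.scaled:
            s = float(factors.scaled[key])
        else:
            continue
        gpr_cols.append(j)
        svals.append(s)
    gpr_idx = np.asarray(gpr_cols, dtype=int)
    s = np.asarray(svals, dtype=float)
    m = len(gpr_idx) if with_beta else 0

    bounds: list[tuple[float, float]] = [(0.0, float(u)) for u in ub]
    if not with_beta:
        # hard E-flux-style bounds
        for t, j in enumerate(gpr_idx):
            bounds[j] = (0.0, float(ub[j]) * s[t])
        A_ub = sparse.csr_matrix((0, n_v))
        b_ub = np.zeros(0)
    else:
        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []
        b: list[float] = []
        r = 0
        for t, j in enumerate(gpr_idx):
            vj = float(ub[j])
            bp, bm = n_v + t, n_v + m + t
            # v_j - vmax*bp + vmax*bm <= vmax*s
            rows += [r, r, r]
            cols += [j, bp, bm]
            vals += [1.0, -vj, vj]
            b.append(vj * s[t])
            r += 1
            # s + bp - bm <= 1
            rows += [r, r]
            cols += [bp, bm]
            vals += [1.0, -1.0]
            b.append(1.0 - s[t])
            r += 1
            # s + bp - bm >= 0
            rows += [r, r]
            cols += [bp, bm]
            vals += [-1.0, 1.0]
            b.append(s[t])
            r += 1
        A_ub = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(r, n_v + 2 * m)
        )
        b_ub = np.asarray(b)
        bounds += [(0.0, float(beta_box))] * m
        if with_beta_minus:
            bounds += [(0.0, float(beta_box))] * m
        else:
            bounds += [(0.0, 0.0)] * m

    n_x = n_v + 2 * m
    A_eq = sparse.hstack(
        [model.S.tocsr(), sparse.csr_matrix((model.S.shape[0], 2 * m))],
        format="csr",
    )
    b_eq = np.zeros(model.S.shape[0])

    biomass_cols = model.biomass_columns
    obj = np.zeros(n_x)
    for col in biomass_cols.values():
        obj[col] = 1.0
    obj[n_v:] = -lam

    return LPSystem(
        model=model,
        n_v=n_v,
        n_beta=m,
        gpr_cols=gpr_idx,
        factors=s,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        objective_row=obj,
        biomass_cols=biomass_cols,
        lam=lam,
    )


_STATUS = {1: "iteration limit", 2: "infeasible", 3: "unbounded",
           4: "numerical difficulty"}


def lp_solve(
    system: LPSystem,
    c: np.ndarray,
    extra_A_ub: sparse.spmatrix | None = None,
    extra_b_ub: np.ndarray | None = None,
    feasibility_tol: float = 1e-9,
    optimality_tol: float = 1e-9,
):
    """Minimise c.x over the system (plus optional extra <= rows)."""
    A_ub, b_ub = system.A_ub, system.b_ub
    if extra_A_ub is not None:
        A_ub = sparse.vstack([A_ub, extra_A_ub], format="csr")
        b_ub = np.concatenate([b_ub, np.atleast_1d(extra_b_ub)])
    res = linprog(
        c,
        A_ub=A_ub if A_ub.shape[0] else None,
        b_ub=b_ub if b_ub.size else None,
        A_eq=system.A_eq,
        b_eq=system.b_eq,
        bounds=system.bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": max(feasibility_tol, 1e-10),
            "dual_feasibility_tolerance": max(optimality_tol, 1e-10),
        },
    )
    if res.status != 0:
        raise SolverError(
            f"LP solve failed: {res.message}",
            status=_STATUS.get(res.status, "error"),
        )
    return res
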