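"""The expression-constrained community growth LP and its lambda selection.

The core problem maximises total community growth minus a penalty on
relaxations of the expression-derived flux bounds,

    max  sum_j mu_j - lambda * sum_{i,j} (beta+_{ij} + beta-_{ij})
    s.t. S v = 0
         0 <= v_{ij} <= v_max_{ij} * (f_{ij}/M + beta+_{ij} - beta-_{ij})
                                             for reactions with a GPR
         0 <= v_{ij} <= v_max_{ij}
         0 <= f_{ij}/M + beta+_{ij} - beta-_{ij} <= 1
         0 <= beta+, beta- <= 1000

where mu_j is the flux through member j's biomass reaction and f/M the
GPR-derived correction factor of :mod:`imic.expression`. The single free
parameter lambda balances growth maximisation against relaxation of the
transcriptome-derived bounds; it is chosen either from the inflection
(knee) of the objective-vs-lambda curve or by cross-validation against
relative abundances when those are available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats

from ._lp import LPSystem, SolverError, build_system, lp_solve
from .community import CommunityModel
from .expression import CorrectionFactors

__all__ = [
    "IMICConfig",
    "IMICSolution",
    "LambdaScan",
    "VariabilityResult",
    "default_lambda_grid",
    "solve_imic",
    "select_lambda_sensitivity",
    "select_lambda_cv",
    "growth_variability",
    "SolverError",
]


def default_lambda_grid() -> list[float]:
    """The standard balancing-factor grid: 0.1, 0.5, then 1..50 by 1."""
    return [0.1, 0.5] + [float(k) for k in range(1, 51)]


@dataclass
class IMICConfig:
    """Solver configuration.

    ``lam`` is the balancing factor lambda (> 0); ``lambda_grid`` the
    strictly increasing grid scanned by the selection procedures;
    ``beta_box`` the box bound on each relaxation variable.
    """

    lam: float = 1.0
    lambda_grid: list[float] = field(default_factory=default_lambda_grid)
    beta_box: float = 1000.0
    feasibility_tol: float = 1e-9
    optimality_tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError(f"lambda must be positive, got {self.lam}")
        grid = list(self.lambda_grid)
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("lambda_grid must be strictly increasing")


@dataclass
class IMICSolution:
    """Optimal point of the growth LP for one sample."""

    sample_id: str
    mu: dict[str, float]  # member -> growth rate (1/h)
    v: np.ndarray  # flux vector over irreversible columns
    beta_plus: dict[str, float]  # column id -> relaxation
    beta_minus: dict[str, float]
    objective: float  # z* = sum(mu) - lambda * sum(beta)
    lam: float

    @property
    def sum_mu(self) -> float:
        return float(sum(self.mu.values()))

    @property
    def sum_beta(self) -> float:
        return float(sum(self.beta_plus.values())
                     + sum(self.beta_minus.values()))


@dataclass
class LambdaScan:
    """Objective path over the lambda grid and the selected value."""

    grid: list[float]
    records: pd.DataFrame  # columns: lam, z, sum_mu, sum_beta [, mean_rho]
    selected: float
    method: str  # "sensitivity" | "cross_validation" | "user"


@dataclass
class VariabilityResult:
    """Growth-rate ranges at the fixed LP optimum.

    ``relative_variability = (mu_max - mu_min)/mu_max`` (0 when mu_max = 0)
    — values near 0 mean the growth prediction is tightly determined.
    """

    records: dict[str, tuple[float, float, float]]  # member -> (min, max, rel)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m, lo, hi, rel) for m, (lo, hi, rel) in self.records.items()],
            columns=["member", "mu_min", "mu_max", "relative_variability"],
        )


def _extract_solution(
    system: LPSystem, res, sample_id: str, lam: float
) -> IMICSolution:
    x = res.x
    n_v, m = system.n_v, system.n_beta
    v = x[:n_v]
    bp = x[n_v:n_v + m]
    bm = x[n_v + m:n_v + 2 * m]
    col_ids = [system.model.reactions[j].id for j in system.gpr_cols]
    mu = {
        member: float(v[col]) for member, col in system.biomass_cols.items()
    }
    return IMICSolution(
        sample_id=sample_id,
        mu=mu,
        v=v,
        beta_plus=dict(zip(col_ids, map(float, bp))),
        beta_minus=dict(zip(col_ids, map(float, bm))),
        objective=float(system.objective_row @ x),
        lam=lam,
    )


def solve_imic(
    model: CommunityModel,
    factors: CorrectionFactors | None,
    config: IMICConfig | None = None,
    *,
    lam: float | None = None,
    with_beta: bool = True,
    with_beta_minus: bool = True,
    uniform_factor: float | None = None,
) -> IMICSolution:
    """Solve the growth LP for one sample.

    ``uniform_factor=1.0`` with ``factors=None`` reproduces plain FBA on
    the community model (all expression bounds at v_max); ``with_beta=False``
    gives the hard-bound (pure E-flux scaling) variant.
    """
    config = config or IMICConfig()
    lam = config.lam if lam is None else lam
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    system = build_system(
        model, factors, lam, beta_box=config.beta_box,
        with_beta=with_beta, with_beta_minus=with_beta_minus,
        uniform_factor=uniform_factor,
    )
    res = lp_solve(
        system, -system.objective_row,
        feasibility_tol=config.feasibility_tol,
        optimality_tol=config.optimality_tol,
    )
    sample_id = factors.sample_id if factors is not None else ""
    return _extract_solution(system, res, sample_id, lam)


# ---------------------------------------------------------------------------
# Lambda selection
# ---------------------------------------------------------------------------

def _as_profile_list(
    factors_per_sample,
) -> list[CorrectionFactors]:
    if isinstance(factors_per_sample, CorrectionFactors):
        return [factors_per_sample]
    if isinstance(factors_per_sample, dict):
        return [factors_per_sample[k] for k in sorted(factors_per_sample)]
    return list(factors_per_sample)


def _scan_records(
    model: CommunityModel,
    samples: list[CorrectionFactors],
    config: IMICConfig,
) -> tuple[pd.DataFrame, dict[tuple[str, float], IMICSolution]]:
    """Solve over the grid; return per-lambda means and per-sample solutions."""
    solutions: dict[tuple[str, float], IMICSolution] = {}
    rows = []
    for lam in config.lambda_grid:
        zs, mus, betas = [], [], []
        for fac in samples:
            sol = solve_imic(model, fac, config, lam=lam)
            solutions[(fac.sample_id, lam)] = sol
            zs.append(sol.objective)
            mus.append(sol.sum_mu)
            betas.append(sol.sum_beta)
        rows.append((lam, float(np.mean(zs)), float(np.mean(mus)),
                     float(np.mean(betas))))
    records = pd.DataFrame(rows, columns=["lam", "z", "sum_mu", "sum_beta"])
    return records, solutions


def _check_monotone(z: np.ndarray, what: str = "z*") -> None:
    scale = max(1.0, float(np.max(np.abs(z))))
    if np.any(np.diff(z) > 1e-5 * scale):
        raise SolverError(
            f"{what}(lambda) is not non-increasing along the grid; "
            "the LP solves are inconsistent", status="numerical difficulty")


def select_lambda_sensitivity(
    model: CommunityModel,
    factors_per_sample,
    config: IMICConfig | None = None,
) -> LambdaScan:
    """Pick lambda at the inflection (knee) of the objective curve.

    The LP value z*(lambda) is piecewise linear, convex and non-increasing;
    after min-max normalising both axes to [0, 1], the grid point with the
    largest discrete curvature (second divided difference) marks the
    transition where growth maximisation and relaxation penalty balance.
    Ties break toward the smallest lambda; a flat curve returns the
    smallest grid value with a warning.
    """
    config = config or IMICConfig()
    samples = _as_profile_list(factors_per_sample)
    grid = list(config.lambda_grid)
    if len(grid) < 3:
        raise ValueError("sensitivity analysis needs >= 3 grid points")
    records, _ = _scan_records(model, samples, config)
    z = records["z"].to_numpy()
    _check_monotone(z)

    z_range = float(z.max() - z.min())
    if z_range <= 1e-9 * max(1.0, abs(float(z.max()))):
        warnings.warn(
            "objective curve is flat over the lambda grid; returning the "
            "smallest grid value", stacklevel=2)
        return LambdaScan(grid, records, float(grid[0]), "sensitivity")

    x = np.asarray(grid, dtype=float)
    x = (x - x.min()) / (x.max() - x.min())
    y = (z - z.min()) / z_range
    slopes = np.diff(y) / np.diff(x)
    curvature = (slopes[1:] - slopes[:-1]) / ((x[2:] - x[:-2]) / 2.0)
    best_interior = int(np.argmax(curvature))  # first max = smallest lambda
    selected = float(grid[best_interior + 1])
    return LambdaScan(grid, records, selected, "sensitivity")


def select_lambda_cv(
    model: CommunityModel,
    factors_per_sample,
    abundances_per_sample: dict[str, dict[str, float]],
    k: int,
    config: IMICConfig | None = None,
    seed: int | None = None,
) -> LambdaScan:
    """Pick lambda by k-fold cross-validation against relative abundances.

    Samples are randomly partitioned into k folds (mandatory seed). For
    each fold, the Spearman correlation between predicted growth rates and
    relative abundance is averaged over the held-out samples at every grid
    lambda; the fold's best lambda is the argmax (ties toward the smaller
    value), and the returned lambda is the mean of the per-fold bests.
    """
    config = config or IMICConfig()
    if seed is None:
        raise ValueError("cross-validation requires an explicit seed")
    samples = _as_profile_list(factors_per_sample)
    usable: list[CorrectionFactors] = []
    for fac in samples:
        abund = abundances_per_sample.get(fac.sample_id)
        if abund is None:
            raise ValueError(f"no abundance vector for sample {fac.sample_id!r}")
        vals = [abund.get(m, 0.0) for m in model.members]
        if np.ptp(vals) == 0:
            warnings.warn(
                f"sample {fac.sample_id!r}: constant abundance vector, "
                "correlation undefined; sample excluded", stacklevel=2)
            continue
        usable.append(fac)
    if k < 1 or k > len(usable):
        raise ValueError(
            f"k={k} folds need at least k usable samples (have {len(usable)})")

    records, solutions = _scan_records(model, usable, config)
    grid = list(config.lambda_grid)
    rho = np.zeros((len(usable), len(grid)))
    for si, fac in enumerate(usable):
        abund = abundances_per_sample[fac.sample_id]
        target = np.array([abund.get(m, 0.0) for m in model.members])
        for li, lam in enumerate(grid):
            mu_vec = np.array([
                solutions[(fac.sample_id, lam)].mu[m] for m in model.members
            ])
            if np.ptp(mu_vec) == 0:
                rho[si, li] = np.nan
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho[si, li] = stats.spearmanr(mu_vec, target).statistic
    records = records.assign(mean_rho=np.nanmean(rho, axis=0))

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(usable))
    folds = np.array_split(order, k)
    best_lams = []
    for fold in folds:
        if len(fold) == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fold_rho = np.nanmean(rho[fold, :], axis=0)
        fold_rho = np.where(np.isnan(fold_rho), -np.inf, fold_rho)
        best_lams.append(grid[int(np.argmax(fold_rho))])
    selected = float(np.mean(best_lams))
    return LambdaScan(grid, records, selected, "cross_validation")


# ---------------------------------------------------------------------------
# Growth-rate variability at the fixed optimum
# ---------------------------------------------------------------------------

def growth_variability(
    model: CommunityModel,
    factors: CorrectionFactors | None,
    lam: float,
    z_star: float,
    config: IMICConfig | None = None,
    *,
    uniform_factor: float | None = None,
) -> VariabilityResult:
    """Min/max each member's growth rate while pinning the LP objective.

    The incumbent objective z* is enforced as a two-sided inequality
    z* - eps <= sum(mu) - lambda*sum(beta) <= z* with
    eps = 1e-6 * max(1, |z*|) — exact equality is numerically brittle.
    """
    config = config or IMICConfig()
    system = build_system(
        model, factors, lam, beta_box=config.beta_box,
        uniform_factor=uniform_factor,
    )
    eps = 1e-6 * max(1.0, abs(z_star))
    obj = system.objective_row
    extra_A = sparse.csr_matrix(np.vstack([obj, -obj]))
    extra_b = np.array([z_star, -(z_star - eps)])

    records: dict[str, tuple[float, float, float]] = {}
    for member, col in system.biomass_cols.items():
        c = np.zeros(system.n_x)
        c[col] = 1.0
        try:
            lo = lp_solve(system, c, extra_A, extra_b,
                          config.feasibility_tol, config.optimality_tol)
            hi = lp_solve(system, -c, extra_A, extra_b,
                          config.feasibility_tol, config.optimality_tol)
        except SolverError as exc:
            if exc.status == "infeasible":
                raise SolverError(
                    "fixed-objective constraint is infeasible; the supplied "
                    "z* is stale — re-solve the growth LP with the same "
                    "lambda and factors", status="infeasible") from exc
            raise
        mu_min = max(0.0, float(lo.fun))
        mu_max = max(mu_min, float(-hi.fun))
        rel = 0.0 if mu_max <= 0 else (mu_max - mu_min) / mu_max
        records[member] = (mu_min, mu_max, min(max(rel, 0.0), 1.0))
    return VariabilityResult(records)
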