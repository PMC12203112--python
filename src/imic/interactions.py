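"""Metabolite-interaction and key-reaction analyses at the growth optimum.

Flux-sum analysis quantifies the turnover of a metabolite m,
Phi_m = 1/2 * sum_i |S_mi| * v_i, which at steady state equals both its
total production and total consumption and serves as a proxy for pool
size. Minimising Phi_m while holding the community growth objective at
its optimum asks how much turnover of m is unavoidable: metabolites with
Phi_min above a small threshold (default 1e-5) are essential imports for
optimal community growth. Comparing essentiality across samples classifies
each metabolite as time-dependent (needed at some time points) or
time-independent (needed at all of them).

Key reactions are common reactions whose fluxes track member abundances
(Spearman rho > 0.7, Benjamini-Hochberg adjusted p < 0.05) in a majority
of samples; their causal role is probed by community-wide knockouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from ._lp import SolverError, build_system, lp_solve
from .community import EXTRACELLULAR, CommunityModel
from .expression import CorrectionFactors
from .solver import IMICConfig, IMICSolution, solve_imic

__all__ = [
    "FluxSumResult",
    "KeyReactionReport",
    "min_flux_sum",
    "essential_imports",
    "common_reactions",
    "key_reactions",
    "knockout_scan",
    "flux_table_from_solutions",
]

#: Minimum-flux-sum threshold above which an import is called essential.
ESSENTIALITY_THRESHOLD = 1e-5


@dataclass
class FluxSumResult:
    """Per-sample minimum flux sums with cross-sample classification.

    ``table`` columns: sample, metabolite, phi_min, essential.
    ``classes`` maps metabolite -> time_independent | time_dependent |
    never_essential.
    """

    table: pd.DataFrame
    classes: dict[str, str] = field(default_factory=dict)
    threshold: float = ESSENTIALITY_THRESHOLD

    def ranked(self, sample: str | None = None, top: int | None = None
               ) -> pd.DataFrame:
        """Rows ranked by phi_min descending (optionally one sample/top-k)."""
        t = self.table
        if sample is not None:
            t = t[t["sample"] == sample]
        t = t.sort_values("phi_min", ascending=False, kind="mergesort")
        return t.head(top) if top else t


@dataclass
class KeyReactionReport:
    """Per-(sample, reaction) Spearman statistics and the key flags.

    ``table`` columns: sample, reaction, rho, p, p_adj, passes;
    ``key`` maps reaction -> bool (passes in >= min fraction of samples);
    ``skipped`` lists (sample, reaction, reason) rows dropped from testing.
    """

    table: pd.DataFrame
    key: dict[str, bool]
    skipped: pd.DataFrame


def min_flux_sum(
    model: CommunityModel,
    factors: CorrectionFactors | None,
    lam: float,
    z_star: float,
    metabolite_id: str,
    config: IMICConfig | None = None,
    *,
    uniform_factor: float | None = None,
) -> float:
    """Minimum flux sum of one metabolite at the pinned growth optimum.

    Minimises Phi_m = 1/2 sum_i |S_mi| v_i subject to the full growth-LP
    constraint system plus sum(mu) - lambda*sum(beta) >= z* - eps with
    eps = 1e-6*max(1, |z*|). With irreversible fluxes the objective is
    linear. A metabolite with no incident reactions yields 0.
    """
    config = config or IMICConfig()
    if metabolite_id not in model.met_index:
        raise KeyError(f"unknown metabolite {metabolite_id!r}")
    row = model.S.tocsr().getrow(model.met_index[metabolite_id]).tocoo()
    if row.nnz == 0:
        warnings.warn(
            f"metabolite {metabolite_id!r} has no incident reactions; "
            "flux sum is 0", stacklevel=2)
        return 0.0
    system = build_system(model, factors, lam, beta_box=config.beta_box,
                          uniform_factor=uniform_factor)
    c = np.zeros(system.n_x)
    c[row.col] = 0.5 * np.abs(row.data)
    eps = 1e-6 * max(1.0, abs(z_star))
    extra_A = sparse.csr_matrix(-system.objective_row.reshape(1, -1))
    extra_b = np.array([-(z_star - eps)])
    res = lp_solve(system, c, extra_A, extra_b,
                   config.feasibility_tol, config.optimality_tol)
    return max(0.0, float(res.fun))


def _import_metabolites(model: CommunityModel) -> dict[str, set[str]]:
    """Extracellular species -> set of members importing it.

    An import reaction consumes an extracellular species into a member
    compartment; on the irreversible model this is any member column with a
    negative coefficient on an extracellular row.
    """
    ec_rows = {model.met_index[m]: m
               for m in model.extracellular_metabolites()}
    importers: dict[str, set[str]] = {m: set() for m in ec_rows.values()}
    S = model.S.tocsc()
    for j, rxn in enumerate(model.reactions):
        if rxn.member == EXTRACELLULAR:
            continue
        col = S.getcol(j).tocoo()
        for i, coeff in zip(col.row, col.data):
            if i in ec_rows and coeff < 0:
                importers[ec_rows[i]].add(rxn.member)
    return importers


def candidate_metabolites(
    model: CommunityModel, mode: str = "common_imports"
) -> list[str]:
    """Metabolites analysed by :func:`essential_imports`.

    ``common_imports``: extracellular species imported by every member;
    ``all_extracellular``: every shared extracellular species.
    """
    if mode == "all_extracellular":
        return model.extracellular_metabolites()
    if mode != "common_imports":
        raise ValueError(f"unknown candidate mode {mode!r}")
    importers = _import_metabolites(model)
    members = set(model.members)
    return [m for m, who in importers.items() if who == members]


def essential_imports(
    model: CommunityModel,
    factors_per_sample,
    lam: float,
    threshold: float = ESSENTIALITY_THRESHOLD,
    candidates: str | list[str] = "common_imports",
    config: IMICConfig | None = None,
) -> FluxSumResult:
    """Flag metabolites whose import is required for optimal growth.

    For each sample the growth LP is solved, then Phi_min is computed per
    candidate metabolite at that optimum; essential means Phi_min >
    threshold. Metabolites essential in every sample are time_independent,
    in at least one but not all samples time_dependent, otherwise
    never_essential.
    """
    config = config or IMICConfig()
    if isinstance(factors_per_sample, CorrectionFactors):
        factors_per_sample = [factors_per_sample]
    if isinstance(factors_per_sample, dict):
        factors_per_sample = [factors_per_sample[k]
                              for k in sorted(factors_per_sample)]
    mets = (candidate_metabolites(model, candidates)
            if isinstance(candidates, str) else list(candidates))
    if not mets:
        warnings.warn("no candidate metabolites (no common imports)",
                      stacklevel=2)
        return FluxSumResult(
            pd.DataFrame(columns=["sample", "metabolite", "phi_min",
                                  "essential"]),
            {}, threshold)
    rows = []
    for fac in factors_per_sample:
        sol = solve_imic(model, fac, config, lam=lam)
        for met in mets:
            phi = min_flux_sum(model, fac, lam, sol.objective, met, config)
            rows.append((fac.sample_id, met, phi, phi > threshold))
    table = pd.DataFrame(rows, columns=["sample", "metabolite", "phi_min",
                                        "essential"])
    classes: dict[str, str] = {}
    for met, chunk in table.groupby("metabolite"):
        n_ess = int(chunk["essential"].sum())
        if n_ess == len(chunk):
            classes[met] = "time_independent"
        elif n_ess > 0:
            classes[met] = "time_dependent"
        else:
            classes[met] = "never_essential"
    return FluxSumResult(table, classes, threshold)


def common_reactions(
    model: CommunityModel, require_gpr: bool = False
) -> list[str]:
    """Original reaction ids present in every member.

    With ``require_gpr`` only reactions carrying a GPR in every member are
    kept.
    """
    per_member: dict[str, set[str]] = {m: set() for m in model.members}
    gpr_ok: dict[str, set[str]] = {m: set() for m in model.members}
    for rxn in model.reactions:
        if rxn.member == EXTRACELLULAR:
            continue
        per_member[rxn.member].add(rxn.original_id)
        if rxn.gpr is not None:
            gpr_ok[rxn.member].add(rxn.original_id)
    sets = gpr_ok if require_gpr else per_member
    common = set.intersection(*sets.values()) if sets else set()
    return sorted(common)


def flux_table_from_solutions(
    model: CommunityModel,
    solutions: dict[str, IMICSolution],
    reaction_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Long table (sample, member, reaction, net_flux) of member net fluxes."""
    if reaction_ids is None:
        reaction_ids = common_reactions(model, require_gpr=True)
    wanted = set(reaction_ids)
    rows = []
    for sample_id, sol in solutions.items():
        nets = model.net_fluxes(sol.v)
        for (member, original_id), flux in nets.items():
            if member != EXTRACELLULAR and original_id in wanted:
                rows.append((sample_id, member, original_id, flux))
    return pd.DataFrame(rows, columns=["sample", "member", "reaction",
                                       "net_flux"])


def key_reactions(
    flux_table: pd.DataFrame,
    abundance_table: pd.DataFrame,
    rho_min: float = 0.7,
    alpha: float = 0.05,
    min_sample_fraction: float = 0.5,
    abundance_tol: float = 1e-6,
) -> KeyReactionReport:
    """Identify reactions whose member fluxes track member abundances.

    Per sample and reaction, Spearman rho is computed across members
    between net flux and relative abundance; p-values are BH-corrected
    across the reactions of each sample. A reaction is key when it passes
    both cutoffs (rho > rho_min, adjusted p < alpha) in strictly more than
    ``min_sample_fraction`` of the samples.

    ``flux_table`` columns: sample, member, reaction, net_flux.
    ``abundance_table`` columns: sample, member, abundance (summing to 1
    per sample within ``abundance_tol``).
    """
    n_members = flux_table["member"].nunique()
    if n_members < 4:
        raise ValueError(
            f"key-reaction analysis needs >= 4 members (got {n_members}): "
            "Spearman p-values are degenerate below that")
    sums = abundance_table.groupby("sample")["abundance"].sum()
    off = sums[(sums - 1.0).abs() > max(abundance_tol, 1e-6)]
    if len(off):
        raise ValueError(
            f"abundances must sum to 1 per sample; offending samples: "
            f"{list(off.index)[:5]}")
    abund = abundance_table.set_index(["sample", "member"])["abundance"]

    rows, skipped = [], []
    for (sample, reaction), chunk in flux_table.groupby(["sample", "reaction"]):
        flux = chunk["net_flux"].to_numpy(float)
        try:
            target = np.array([abund.loc[(sample, m)]
                               for m in chunk["member"]])
        except KeyError:
            skipped.append((sample, reaction, "missing abundance"))
            continue
        if np.ptp(flux) == 0:
            skipped.append((sample, reaction, "constant flux across members"))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, p = stats.spearmanr(flux, target)
        if not np.isfinite(rho):
            skipped.append((sample, reaction, "correlation undefined"))
            continue
        rows.append((sample, reaction, float(rho), float(p)))
    stat = pd.DataFrame(rows, columns=["sample", "reaction", "rho", "p"])

    adjusted = []
    for sample, chunk in stat.groupby("sample"):
        _, p_adj, _, _ = multipletests(chunk["p"].to_numpy(),
                                       method="fdr_bh")
        adjusted.append(chunk.assign(p_adj=p_adj))
    if adjusted:
        stat = pd.concat(adjusted, ignore_index=True)
        stat["passes"] = (stat["rho"] > rho_min) & (stat["p_adj"] < alpha)
    else:
        stat = stat.assign(p_adj=[], passes=[])

    n_samples = flux_table["sample"].nunique()
    key: dict[str, bool] = {}
    for reaction in flux_table["reaction"].unique():
        sub = stat[stat["reaction"] == reaction]
        key[reaction] = bool(
            len(sub) and sub["passes"].sum() > min_sample_fraction * n_samples
        )
    return KeyReactionReport(
        table=stat,
        key=key,
        skipped=pd.DataFrame(skipped,
                             columns=["sample", "reaction", "reason"]),
    )


def knockout_scan(
    model: CommunityModel,
    reaction_ids: list[str],
    factors: CorrectionFactors | None,
    lam: float,
    config: IMICConfig | None = None,
) -> pd.DataFrame:
    """Knock out each reaction community-wide and re-solve the growth LP.

    Every column of the reaction (fwd/rev, all members) gets v_max = 0;
    the model is restored after each knockout. Returns a table
    (reaction, z_ko, sum_mu_ko, delta_sum_mu, error) with delta measured
    against the unperturbed baseline.
    """
    config = config or IMICConfig()
    baseline = solve_imic(model, factors, config, lam=lam)
    rows = []
    for rid in reaction_ids:
        cols = model.columns_of(rid)
        if not cols:
            rows.append((rid, np.nan, np.nan, np.nan,
                         f"unknown reaction id {rid!r}"))
            continue
        saved = [(j, model.reactions[j].upper_bound) for j in cols]
        try:
            for j in cols:
                model.reactions[j].upper_bound = 0.0
            sol = solve_imic(model, factors, config, lam=lam)
            rows.append((rid, sol.objective, sol.sum_mu,
                         sol.sum_mu - baseline.sum_mu, ""))
        except SolverError as exc:
            rows.append((rid, np.nan, np.nan, np.nan, str(exc)))
        finally:
            for j, ub in saved:
                model.reactions[j].upper_bound = ub
    return pd.DataFrame(rows, columns=["reaction", "z_ko", "sum_mu_ko",
                                       "delta_sum_mu", "error"])
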