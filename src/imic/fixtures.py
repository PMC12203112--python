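"""Deterministic toy communities with known ground truth.

The generator builds the smallest community that still exercises every
stage of the pipeline: each member runs a linear uptake -> conversion ->
biomass pathway on a shared extracellular substrate, secretes a byproduct
that the next member requires (cross-feeding), and carries genes whose
designed activity levels drive the synthetic expression profiles. Because
the pathway is a chain, the optimal growth rates are analytically known,
and the designed activities double as ground-truth relative abundances.

Design notes. The transporter carries an OR-family of isozymes so that the
sparsity typical of metatranscriptomes (a fraction of genes reading zero)
attenuates rather than erases a member's uptake signal; transport caps are
staggered by 0.1% across members to keep the LP vertex unique. Activities
default to a geometric ladder (1, 3, 9, 27, ...) — community members
commonly span orders of magnitude in activity. Expression noise is
multiplicative lognormal, the standard dispersion model for TPM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .community import (CommunityModel, MemberModel, build_community,
                        to_irreversible)
from .expression import CorrectionFactors, ExpressionProfile, correction_factors
from .gpr import GprTree

__all__ = [
    "FixtureSpec",
    "make_toy_community",
    "make_expression",
    "make_kink_toy",
    "make_random_toy",
    "write_fixture",
]


@dataclass
class FixtureSpec:
    """Parameters of the synthetic community generator.

    ``designed_activity`` is the ground-truth growth propensity per member
    (defaults to a geometric ladder 1, 3, 9, ...); ``expression_sparsity``
    is the fraction of gene entries forced to zero; ``noise_sd`` the sd of
    the lognormal multiplicative expression noise. The same seed always
    yields a bit-identical fixture.
    """

    n_members: int = 4
    designed_activity: list[float] | None = None
    n_shared_metabolites: int = 2
    pathway_depth: int = 3
    expression_sparsity: float = 0.2
    noise_sd: float = 0.1
    seed: int = 0
    uptake_bound: float = 10.0
    n_transport_isozymes: int = 5

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if self.pathway_depth < 1:
            raise ValueError("pathway_depth must be >= 1")
        if not (0.0 <= self.expression_sparsity < 1.0):
            raise ValueError("expression_sparsity must be in [0, 1)")
        if self.designed_activity is None:
            self.designed_activity = [3.0 ** i for i in range(self.n_members)]
        if len(self.designed_activity) != self.n_members:
            raise ValueError("designed_activity must list one value per member")
        if any(a <= 0 for a in self.designed_activity):
            raise ValueError("designed activities must be positive")

    @property
    def member_ids(self) -> list[str]:
        return [f"m{j + 1}" for j in range(self.n_members)]

    def transport_cap(self, j: int) -> float:
        """Transport v_max of member j (0-based): staggered just below u."""
        return self.uptake_bound * (1.0 - 0.001 * (self.n_members - 1 - j))


def _member_genes(spec: FixtureSpec, member: str) -> dict[str, float]:
    """Gene -> pathway-position weight for one member."""
    genes = {f"{member}_tpt{i + 1}": 1.0
             for i in range(spec.n_transport_isozymes)}
    for k in range(1, spec.pathway_depth + 1):
        genes[f"{member}_g{k}"] = 0.8 ** (k - 1)
    return genes


def make_toy_community(spec: FixtureSpec) -> tuple[CommunityModel, dict]:
    """Build the cross-feeding chain community (reversible/assembled form).

    Returns the community model plus a ground-truth record with the
    designed activities, the analytically known maximum growth rate per
    member (its transport cap), byproduct/decoy species ids, and gene
    weights. Member j+1's biomass requires 0.1 unit of member j's secreted
    byproduct per unit growth, so the byproducts are obligate cross-feeding
    links.
    """
    members: list[MemberModel] = []
    u = spec.uptake_bound
    decoys = [f"decoy{t}_e" for t in range(1, spec.n_shared_metabolites)]
    gene_weights: dict[str, dict[str, float]] = {}

    for j, member in enumerate(spec.member_ids):
        mets: list[tuple[str, str]] = [("sub_e", "e"), (f"byp_{member}_e", "e")]
        mets += [(f"c{k}_c", "c") for k in range(spec.pathway_depth + 1)]
        rxns: list[dict] = []
        gene_weights[member] = _member_genes(spec, member)

        isozymes = GprTree.any_of(*(
            GprTree.leaf(f"{member}_tpt{i + 1}")
            for i in range(spec.n_transport_isozymes)
        )) if spec.n_transport_isozymes > 1 else GprTree.leaf(f"{member}_tpt1")
        rxns.append({
            "id": "TRANS",
            "stoichiometry": {"sub_e": -1.0, "c0_c": 1.0},
            "lower_bound": 0.0,
            "upper_bound": spec.transport_cap(j),
            "gpr": isozymes,
        })
        for k in range(1, spec.pathway_depth + 1):
            stoich = {f"c{k - 1}_c": -1.0, f"c{k}_c": 1.0}
            if k == 1:
                stoich[f"byp_{member}_e"] = 1.0  # overflow byproduct
            rxns.append({
                "id": f"CONV{k}",
                "stoichiometry": stoich,
                "lower_bound": 0.0,
                "upper_bound": 1000.0,
                "gpr": GprTree.leaf(f"{member}_g{k}"),
            })
        biomass_stoich = {f"c{spec.pathway_depth}_c": -1.0}
        if j > 0:
            upstream = spec.member_ids[j - 1]
            mets += [(f"byp_{upstream}_e", "e"), ("bypin_c", "c")]
            rxns.append({
                "id": "UPT_BYP",
                "stoichiometry": {f"byp_{upstream}_e": -1.0, "bypin_c": 1.0},
                "lower_bound": 0.0,
                "upper_bound": 1000.0,
                "gpr": None,
            })
            biomass_stoich["bypin_c"] = -0.1
        rxns.append({
            "id": "BIOMASS",
            "stoichiometry": biomass_stoich,
            "lower_bound": 0.0,
            "upper_bound": 1000.0,
            "gpr": None,
        })
        # community exchanges (deduplicated during assembly)
        rxns.append({
            "id": "EX_sub",
            "stoichiometry": {"sub_e": -1.0},
            "lower_bound": -1.2 * u * spec.n_members,
            "upper_bound": 1000.0,
            "gpr": None,
        })
        rxns.append({
            "id": f"EX_byp_{member}",
            "stoichiometry": {f"byp_{member}_e": -1.0},
            "lower_bound": 0.0,  # secretion only
            "upper_bound": 1000.0,
            "gpr": None,
        })
        if j == 0:
            # a dead-end reaction (forced zero flux) and unconsumed medium
            # decoys, for knockout and flux-sum negative controls
            mets.append(("deadend_c", "c"))
            rxns.append({
                "id": "DEAD",
                "stoichiometry": {"c0_c": -1.0, "deadend_c": 1.0},
                "lower_bound": 0.0,
                "upper_bound": 1000.0,
                "gpr": None,
            })
            for decoy in decoys:
                mets.append((decoy, "e"))
                rxns.append({
                    "id": f"EX_{decoy[:-2]}",
                    "stoichiometry": {decoy: -1.0},
                    "lower_bound": -10.0,
                    "upper_bound": 1000.0,
                    "gpr": None,
                })
        members.append(MemberModel(
            member_id=member,
            metabolites=mets,
            reactions=rxns,
            biomass_reaction_id="BIOMASS",
        ))

    model = build_community(members, extracellular_compartment="e")
    truth = {
        "designed_activity": dict(zip(spec.member_ids,
                                      spec.designed_activity)),
        "max_growth": {m: spec.transport_cap(j)
                       for j, m in enumerate(spec.member_ids)},
        "substrate": "sub_e",
        "byproducts": {m: f"byp_{m}_e" for m in spec.member_ids},
        "decoys": decoys,
        "dead_reaction": "DEAD",
        "gene_weights": gene_weights,
    }
    return model, truth


def make_expression(
    spec: FixtureSpec,
    activities: dict[str, float] | None = None,
    sample_id: str = "s1",
    sample_index: int = 0,
) -> ExpressionProfile:
    """Synthesise one sample's expression profile.

    Gene TPM = activity(member) * position weight * lognormal(0, noise_sd);
    then exactly round(sparsity * n_genes) gene entries are zeroed, and the
    profile is renormalised to sum to 1e6. ``activities`` overrides the
    spec's designed activities (a time-point schedule); ``sample_index``
    decorrelates the noise of successive samples under one seed.
    """
    acts = activities or dict(zip(spec.member_ids, spec.designed_activity))
    rng = np.random.default_rng([spec.seed, sample_index])
    keys: list[tuple[str, str]] = []
    vals: list[float] = []
    for member in spec.member_ids:
        act = float(acts[member])
        for gene, weight in _member_genes(spec, member).items():
            noise = (float(rng.lognormal(0.0, spec.noise_sd))
                     if spec.noise_sd > 0 else 1.0)
            keys.append((member, gene))
            vals.append(act * weight * noise)
    arr = np.asarray(vals)
    n_zero = round(spec.expression_sparsity * len(arr))
    if n_zero:
        arr[rng.choice(len(arr), size=n_zero, replace=False)] = 0.0
    total = arr.sum()
    if total > 0:
        arr = arr * (1e6 / total)
    return ExpressionProfile(sample_id, dict(zip(keys, map(float, arr))))


def make_kink_toy() -> tuple[CommunityModel, ExpressionProfile]:
    """Single-member chain whose objective curve kinks exactly at lambda=10.

    Uptake of ``a_e`` is capped at 10; the transport a -> b has v_max 10
    and correction factor 1/2 (its gene is expressed at half the biomass
    gene's level), so relaxing its bound gains 10 units of growth per unit
    relaxation: z*(lambda) = 10 - lambda/2 below 10 and 5 above.
    """
    member = MemberModel(
        member_id="m1",
        metabolites=[("a_e", "e"), ("b_c", "c")],
        reactions=[
            {"id": "EX_a", "stoichiometry": {"a_e": -1.0},
             "lower_bound": -10.0, "upper_bound": 1000.0, "gpr": None},
            {"id": "R1", "stoichiometry": {"a_e": -1.0, "b_c": 1.0},
             "lower_bound": 0.0, "upper_bound": 10.0,
             "gpr": GprTree.leaf("g1")},
            {"id": "BIOMASS", "stoichiometry": {"b_c": -1.0},
             "lower_bound": 0.0, "upper_bound": 1000.0,
             "gpr": GprTree.leaf("g2")},
        ],
        biomass_reaction_id="BIOMASS",
    )
    model = to_irreversible(build_community([member]))
    profile = ExpressionProfile("s1", {("m1", "g1"): 1.0, ("m1", "g2"): 2.0})
    return model, profile


def make_random_toy(
    rng: np.random.Generator,
) -> tuple[CommunityModel, CorrectionFactors]:
    """Random small community (<= 8 reactions) for oracle cross-checks.

    One or two members, each a substrate -> intermediate -> biomass chain
    with random bounds and random expression; one conversion may be
    reversible to exercise the fwd/rev split.
    """
    n_members = int(rng.integers(1, 3))
    members = []
    theta: dict[tuple[str, str], float] = {}
    for j in range(n_members):
        member = f"t{j + 1}"
        uptake = float(rng.uniform(2.0, 10.0))
        vmax1 = float(rng.uniform(2.0, 12.0))
        reversible = bool(rng.integers(0, 2))
        lb1 = -float(rng.uniform(1.0, 5.0)) if reversible else 0.0
        rxns = [
            {"id": f"EX_s{j}", "stoichiometry": {f"s{j}_e": -1.0},
             "lower_bound": -uptake, "upper_bound": 1000.0, "gpr": None},
            {"id": "R1", "stoichiometry": {f"s{j}_e": -1.0, "x_c": 1.0},
             "lower_bound": lb1, "upper_bound": vmax1,
             "gpr": GprTree.any_of(GprTree.leaf(f"{member}_a"),
                                   GprTree.leaf(f"{member}_b"))},
            {"id": "R2", "stoichiometry": {"x_c": -1.0, "y_c": 1.0},
             "lower_bound": 0.0, "upper_bound": float(rng.uniform(2.0, 12.0)),
             "gpr": GprTree.all_of(GprTree.leaf(f"{member}_c"),
                                   GprTree.leaf(f"{member}_d"))},
            {"id": "BIOMASS", "stoichiometry": {"y_c": -1.0},
             "lower_bound": 0.0, "upper_bound": 1000.0, "gpr": None},
        ]
        members.append(MemberModel(
            member_id=member,
            metabolites=[(f"s{j}_e", "e"), ("x_c", "c"), ("y_c", "c")],
            reactions=rxns,
            biomass_reaction_id="BIOMASS",
        ))
        for g in ("a", "b", "c", "d"):
            theta[(member, f"{member}_{g}")] = float(rng.uniform(0.0, 10.0))
    model = to_irreversible(build_community(members))
    profile = ExpressionProfile("rand", theta)
    return model, correction_factors(model, profile)


def write_fixture(
    spec: FixtureSpec,
    directory: str | Path,
    n_samples: int = 1,
) -> Path:
    """Emit the fixture as standard formats: one SBML per member plus
    expression and abundance TSVs (so fixtures double as round-trip tests)."""
    import cobra
    import cobra.io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    model, truth = make_toy_community(spec)

    # regroup the community back into per-member cobra models for export;
    # exchanges are attached to every member whose reactions touch the species
    for member_id in spec.member_ids:
        cmodel = cobra.Model(member_id)
        mets: dict[str, cobra.Metabolite] = {}
        S = model.S.tocsc()
        for j, rxn in enumerate(model.reactions):
            owned = rxn.member == member_id
            if rxn.member == "extracellular":
                col = S.getcol(j).tocoo()
                touched = {model.metabolites[i] for i in col.row}
                member_rows = set()
                for jj, r2 in enumerate(model.reactions):
                    if r2.member == member_id:
                        c2 = S.getcol(jj).tocoo()
                        member_rows |= {model.metabolites[i] for i in c2.row}
                owned = bool(touched & member_rows)
            if not owned or rxn.direction == "rev":
                continue
            crxn = cobra.Reaction(rxn.original_id)
            crxn.lower_bound = rxn.lower_bound
            crxn.upper_bound = rxn.upper_bound
            cmodel.add_reactions([crxn])
            col = S.getcol(j).tocoo()
            stoich = {}
            for i, coeff in zip(col.row, col.data):
                mid = model.metabolites[i]
                local = mid.split("::", 1)[-1]
                if local not in mets:
                    met = cobra.Metabolite(
                        local,
                        compartment=model.metabolite_compartments[mid])
                    mets[local] = met
                stoich[mets[local]] = coeff
            crxn.add_metabolites(stoich)
            if rxn.gpr is not None:
                crxn.gene_reaction_rule = rxn.gpr.to_string()
        cobra.io.write_sbml_model(cmodel, str(directory / f"{member_id}.xml"))

    rows = []
    for t in range(n_samples):
        profile = make_expression(spec, sample_id=f"s{t + 1}", sample_index=t)
        for (member, gene), tpm in profile.values.items():
            rows.append((profile.sample_id, member, gene, tpm))
    pd.DataFrame(rows, columns=["sample_id", "member_id", "gene_id", "tpm"]
                 ).to_csv(directory / "expression.tsv", sep="\t", index=False)

    acts = np.asarray(spec.designed_activity, dtype=float)
    rel = acts / acts.sum()
    ab_rows = [(f"s{t + 1}", m, rel[j])
               for t in range(n_samples)
               for j, m in enumerate(spec.member_ids)]
    pd.DataFrame(ab_rows, columns=["sample_id", "member_id", "abundance"]
                 ).to_csv(directory / "abundance.tsv", sep="\t", index=False)
    return directory
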