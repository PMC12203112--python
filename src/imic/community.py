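"""Compartmentalised community metabolic models.

Member genome-scale models (GEMs) are loaded from SBML and assembled into a
single stoichiometric matrix in which each member keeps a private namespace
(``member::reaction``) while extracellular species are merged into shared
rows, so that metabolites can be exchanged through a common medium.
Community-level exchange reactions (extracellular species <-> environment)
are deduplicated to one per species.

The flux-analysis layer works on the irreversible form of the model
(every flux satisfies 0 <= v <= v_max); :func:`to_irreversible` splits
reversible reactions into forward/reverse column pairs and keeps the map
needed to reconstruct signed net fluxes.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .gpr import GprTree, from_cobra_gpr

__all__ = [
    "MemberModel",
    "Reaction",
    "CommunityModel",
    "ModelError",
    "load_member_model",
    "build_community",
    "to_irreversible",
    "apply_medium",
    "read_medium_table",
    "write_bundle",
    "read_bundle",
    "to_cobra_model",
    "write_sbml",
]

#: Pseudo-member owning the deduplicated community exchange reactions.
EXTRACELLULAR = "extracellular"

#: Upper bound substituted for non-finite bounds (standard FBA convention;
#: also the magnitude of the relaxation box in the growth LP).
DEFAULT_V_MAX = 1000.0


class ModelError(ValueError):
    """Fatal problem with a member model or community assembly."""


@dataclass
class MemberModel:
    """A single member's metabolic model, decoupled from cobra objects."""

    member_id: str
    metabolites: list[tuple[str, str]]  # (metabolite_id, compartment)
    reactions: list[dict]  # id, stoichiometry, lower_bound, upper_bound, gpr
    biomass_reaction_id: str
    genes: set[str] = field(default_factory=set)
    unparsed_gprs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rxn_ids = {r["id"] for r in self.reactions}
        if self.biomass_reaction_id not in rxn_ids:
            raise ModelError(
                f"member {self.member_id!r}: biomass reaction "
                f"{self.biomass_reaction_id!r} not among reactions"
            )
        declared = {m for m, _ in self.metabolites}
        for rxn in self.reactions:
            missing = set(rxn["stoichiometry"]) - declared
            if missing:
                raise ModelError(
                    f"member {self.member_id!r}: reaction {rxn['id']!r} uses "
                    f"undeclared metabolites {sorted(missing)}"
                )
            if rxn["lower_bound"] > rxn["upper_bound"]:
                raise ModelError(
                    f"member {self.member_id!r}: reaction {rxn['id']!r} has "
                    "lower bound above upper bound"
                )


@dataclass
class Reaction:
    """One column of the community stoichiometric matrix."""

    id: str
    member: str  # member_id or EXTRACELLULAR
    original_id: str
    direction: str  # "fwd" | "rev"
    lower_bound: float
    upper_bound: float
    gpr: GprTree | None = None
    is_biomass: bool = False


@dataclass
class CommunityModel:
    """Unified stoichiometric model of a microbial community.

    Rows of ``S`` are namespaced metabolites (shared extracellular species
    keep their original id); columns are namespaced reactions described by
    ``reactions``. ``irreversible`` marks whether all lower bounds are 0.
    """

    members: list[str]
    metabolites: list[str]
    metabolite_compartments: dict[str, str]
    S: sparse.csc_matrix
    reactions: list[Reaction]
    extracellular_compartment: str = "e"
    irreversible: bool = False
    #: fwd column index -> rev column index, for net-flux reconstruction
    reverse_of: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.met_index = {m: i for i, m in enumerate(self.metabolites)}
        self.rxn_index = {r.id: j for j, r in enumerate(self.reactions)}
        if len(self.rxn_index) != len(self.reactions):
            raise ModelError("duplicate reaction column ids")

    # -- structural queries -------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def biomass_columns(self) -> dict[str, int]:
        cols: dict[str, int] = {}
        for j, rxn in enumerate(self.reactions):
            if rxn.is_biomass and rxn.direction == "fwd":
                cols[rxn.member] = j
        return cols

    @property
    def upper_bounds(self) -> np.ndarray:
        return np.array([r.upper_bound for r in self.reactions], dtype=float)

    def extracellular_metabolites(self) -> list[str]:
        ec = self.extracellular_compartment
        return [m for m in self.metabolites
                if self.metabolite_compartments[m] == ec]

    def columns_of(self, original_id: str, member: str | None = None) -> list[int]:
        """Column indices of all directions/members of one original reaction."""
        return [
            j for j, r in enumerate(self.reactions)
            if r.original_id == original_id
            and (member is None or r.member == member)
        ]

    def gpr_reactions(self) -> dict[tuple[str, str], GprTree]:
        """(member, original_id) -> GPR tree, for GPR-bearing reactions."""
        out: dict[tuple[str, str], GprTree] = {}
        for r in self.reactions:
            if r.gpr is not None:
                out[(r.member, r.original_id)] = r.gpr
        return out

    def genes_of_member(self, member: str) -> set[str]:
        genes: set[str] = set()
        for r in self.reactions:
            if r.member == member and r.gpr is not None:
                genes |= r.gpr.genes()
        return genes

    def net_fluxes(self, v: np.ndarray) -> dict[tuple[str, str], float]:
        """Collapse an irreversible flux vector to signed net fluxes.

        Keys are (member, original_id); net = fwd - rev.
        """
        out: dict[tuple[str, str], float] = {}
        rev_cols = set(self.reverse_of.values())
        for j, rxn in enumerate(self.reactions):
            if j in rev_cols:
                continue
            net = float(v[j])
            if j in self.reverse_of:
                net -= float(v[self.reverse_of[j]])
            out[(rxn.member, rxn.original_id)] = net
        return out

    def copy(self) -> "CommunityModel":
        return CommunityModel(
            members=list(self.members),
            metabolites=list(self.metabolites),
            metabolite_compartments=dict(self.metabolite_compartments),
            S=self.S.copy(),
            reactions=[replace(r) for r in self.reactions],
            extracellular_compartment=self.extracellular_compartment,
            irreversible=self.irreversible,
            reverse_of=dict(self.reverse_of),
        )


# ---------------------------------------------------------------------------
# SBML loading
# ---------------------------------------------------------------------------

def load_member_model(
    path: str | Path,
    member_id: str,
    biomass_pattern: str = "biomass",
) -> MemberModel:
    """Load one member GEM from SBML (Level 3 / fbc).

    ``biomass_pattern`` is a case-insensitive regex used to locate the
    biomass reaction; exactly one reaction must match.
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise IOError(f"SBML file not found: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cmodel = cobra.io.read_sbml_model(str(path))
    except Exception as exc:
        raise IOError(f"cannot read SBML file {path}: {exc}") from exc

    pat = re.compile(biomass_pattern, re.IGNORECASE)
    matches = [r.id for r in cmodel.reactions if pat.search(r.id)]
    if not matches:
        raise ModelError(
            f"no biomass reaction matching /{biomass_pattern}/i in {path}"
        )
    if len(matches) > 1:
        raise ModelError(
            f"multiple biomass candidates in {path}: {matches}; "
            "disambiguate with a stricter biomass pattern"
        )

    metabolites = [(m.id, m.compartment or "") for m in cmodel.metabolites]
    reactions = []
    unparsed: dict[str, str] = {}
    genes: set[str] = set()
    for rxn in cmodel.reactions:
        tree = None
        rule = rxn.gene_reaction_rule
        if rule and rule.strip():
            try:
                tree = from_cobra_gpr(rxn.gpr)
            except Exception:
                unparsed[rxn.id] = rule
        if tree is not None:
            genes |= tree.genes()
        lb = float(rxn.lower_bound)
        ub = float(rxn.upper_bound)
        if not np.isfinite(ub):
            ub = DEFAULT_V_MAX
        if not np.isfinite(lb):
            lb = -DEFAULT_V_MAX
        reactions.append({
            "id": rxn.id,
            "stoichiometry": {m.id: float(c) for m, c in rxn.metabolites.items()},
            "lower_bound": lb,
            "upper_bound": ub,
            "gpr": tree,
        })
    return MemberModel(
        member_id=member_id,
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=matches[0],
        genes=genes,
        unparsed_gprs=unparsed,
    )


# ---------------------------------------------------------------------------
# Community assembly
# ---------------------------------------------------------------------------

def _namespaced(member_id: str, local_id: str) -> str:
    return f"{member_id}::{local_id}"


def build_community(
    members: list[MemberModel],
    extracellular_compartment: str = "e",
) -> CommunityModel:
    """Assemble member models into one compartmentalised community model.

    Intracellular metabolites and member reactions are namespaced
    ``member::id``; extracellular species with identical original ids are
    merged into single shared rows; exchange reactions (those touching only
    extracellular species) are pooled community-wide and deduplicated.
    The returned model is in the original (possibly reversible) form.
    """
    if not members:
        raise ModelError("cannot build a community from zero members")
    ids = [m.member_id for m in members]
    if len(set(ids)) != len(ids):
        raise ModelError(f"duplicate member ids: {ids}")
    if EXTRACELLULAR in ids:
        raise ModelError(f"member id {EXTRACELLULAR!r} is reserved")

    ec = extracellular_compartment
    met_rows: list[str] = []
    met_comp: dict[str, str] = {}
    met_pos: dict[str, int] = {}

    def add_met(row_id: str, comp: str) -> int:
        if row_id not in met_pos:
            met_pos[row_id] = len(met_rows)
            met_rows.append(row_id)
            met_comp[row_id] = comp
        return met_pos[row_id]

    # deterministic row order: extracellular species first (sorted), then
    # members' intracellular metabolites in member order
    shared = sorted({mid for m in members for mid, comp in m.metabolites
                     if comp == ec})
    for mid in shared:
        add_met(mid, ec)

    member_row_of: dict[str, dict[str, str]] = {}
    for member in members:
        mapping: dict[str, str] = {}
        for mid, comp in member.metabolites:
            if comp == ec:
                mapping[mid] = mid
            else:
                row = _namespaced(member.member_id, mid)
                add_met(row, comp)
                mapping[mid] = row
        member_row_of[member.member_id] = mapping

    reactions: list[Reaction] = []
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    exchange_seen: dict[str, int] = {}

    def add_column(rxn: Reaction, stoich: dict[int, float]) -> None:
        j = len(reactions)
        reactions.append(rxn)
        for i, coeff in stoich.items():
            rows.append(i)
            cols.append(j)
            vals.append(coeff)

    for member in members:
        mapping = member_row_of[member.member_id]
        comp_of = dict(member.metabolites)
        for rxn in member.reactions:
            stoich_rows = {
                met_pos[mapping[mid]]: coeff
                for mid, coeff in rxn["stoichiometry"].items()
            }
            is_exchange = bool(rxn["stoichiometry"]) and all(
                comp_of[mid] == ec for mid in rxn["stoichiometry"]
            )
            if is_exchange:
                if rxn["id"] in exchange_seen:
                    j = exchange_seen[rxn["id"]]
                    prev = reactions[j]
                    if (prev.lower_bound != rxn["lower_bound"]
                            or prev.upper_bound != rxn["upper_bound"]):
                        warnings.warn(
                            f"exchange reaction {rxn['id']!r}: conflicting "
                            f"bounds across members; keeping the first "
                            f"occurrence", stacklevel=2)
                    continue
                exchange_seen[rxn["id"]] = len(reactions)
                add_column(
                    Reaction(
                        id=rxn["id"],
                        member=EXTRACELLULAR,
                        original_id=rxn["id"],
                        direction="fwd",
                        lower_bound=rxn["lower_bound"],
                        upper_bound=rxn["upper_bound"],
                        gpr=None,
                    ),
                    stoich_rows,
                )
            else:
                add_column(
                    Reaction(
                        id=_namespaced(member.member_id, rxn["id"]),
                        member=member.member_id,
                        original_id=rxn["id"],
                        direction="fwd",
                        lower_bound=rxn["lower_bound"],
                        upper_bound=rxn["upper_bound"],
                        gpr=rxn["gpr"],
                        is_biomass=(rxn["id"] == member.biomass_reaction_id),
                    ),
                    stoich_rows,
                )

    S = sparse.csc_matrix(
        (vals, (rows, cols)), shape=(len(met_rows), len(reactions))
    )
    return CommunityModel(
        members=ids,
        metabolites=met_rows,
        metabolite_compartments=met_comp,
        S=S,
        reactions=reactions,
        extracellular_compartment=ec,
        irreversible=False,
    )


def to_irreversible(model: CommunityModel) -> CommunityModel:
    """Split reversible reactions into fwd/rev columns with 0 <= v bounds.

    Both halves inherit the reaction's GPR tree; the net flux is
    fwd - rev (see :meth:`CommunityModel.net_fluxes`).
    """
    if model.irreversible:
        return model.copy()
    S = model.S.tocsc()
    new_cols = []
    reactions: list[Reaction] = []
    reverse_of: dict[int, int] = {}
    for j, rxn in enumerate(model.reactions):
        lb, ub = rxn.lower_bound, rxn.upper_bound
        col = S.getcol(j)
        if lb > ub:
            raise ModelError(f"reaction {rxn.id!r}: lb > ub")
        if lb > 0:
            warnings.warn(
                f"reaction {rxn.id!r} has forced flux (lb={lb} > 0); kept "
                f"as-is, the nonnegative-flux convention does not apply to it",
                stacklevel=2,
            )
            reactions.append(replace(rxn))
            new_cols.append(col)
            continue
        fwd_idx = len(reactions)
        reactions.append(replace(rxn, lower_bound=0.0, upper_bound=ub))
        new_cols.append(col)
        if lb < 0:
            reactions.append(Reaction(
                id=f"{rxn.id}__rev",
                member=rxn.member,
                original_id=rxn.original_id,
                direction="rev",
                lower_bound=0.0,
                upper_bound=-lb,
                gpr=rxn.gpr,
                is_biomass=False,
            ))
            new_cols.append(-col)
            reverse_of[fwd_idx] = len(reactions) - 1
    return CommunityModel(
        members=list(model.members),
        metabolites=list(model.metabolites),
        metabolite_compartments=dict(model.metabolite_compartments),
        S=sparse.hstack(new_cols, format="csc"),
        reactions=reactions,
        extracellular_compartment=model.extracellular_compartment,
        irreversible=True,
        reverse_of=reverse_of,
    )


def apply_medium(model: CommunityModel, medium: dict[str, float]) -> None:
    """Impose maximum uptake rates on exchange reactions, in place.

    ``medium`` maps exchange reaction id -> max uptake (nonnegative). The
    exchange convention is ``species -> (nothing)``, so uptake is reverse
    flux: on a reversible model the lower bound becomes ``-max_uptake``; on
    an irreversible model the ``__rev`` column's upper bound is set.
    """
    for ex_id, max_uptake in medium.items():
        if max_uptake < 0:
            raise ModelError(f"medium uptake for {ex_id!r} must be >= 0")
        if model.irreversible:
            cols = [j for j, r in enumerate(model.reactions)
                    if r.original_id == ex_id and r.member == EXTRACELLULAR
                    and r.direction == "rev"]
            if not cols:
                raise ModelError(f"no reverse exchange column for {ex_id!r}")
            for j in cols:
                model.reactions[j].upper_bound = max_uptake
        else:
            if ex_id not in model.rxn_index:
                raise ModelError(f"unknown exchange reaction {ex_id!r}")
            model.reactions[model.rxn_index[ex_id]].lower_bound = -max_uptake


def read_medium_table(path: str | Path) -> dict[str, float]:
    """Read a two-column (exchange_reaction_id, max_uptake) TSV."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ModelError(f"medium table {path} needs two columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


# ---------------------------------------------------------------------------
# Serialisation: compact matrix bundle and SBML
# ---------------------------------------------------------------------------

def write_bundle(model: CommunityModel, directory: str | Path) -> Path:
    """Write the community model as a compact plain-text bundle.

    The bundle is a directory holding sparse stoichiometry triplets plus
    reaction/metabolite metadata tables, all TSV, and a small JSON header.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = model.S.tocoo()
    pd.DataFrame({
        "metabolite": [model.metabolites[i] for i in coo.row],
        "reaction": [model.reactions[j].id for j in coo.col],
        "coefficient": coo.data,
    }).to_csv(directory / "stoichiometry.tsv", sep="\t", index=False)
    pd.DataFrame({
        "id": [r.id for r in model.reactions],
        "member": [r.member for r in model.reactions],
        "original_id": [r.original_id for r in model.reactions],
        "direction": [r.direction for r in model.reactions],
        "lower_bound": [r.lower_bound for r in model.reactions],
        "upper_bound": [r.upper_bound for r in model.reactions],
        "gpr": [r.gpr.to_string() if r.gpr else "" for r in model.reactions],
        "is_biomass": [int(r.is_biomass) for r in model.reactions],
    }).to_csv(directory / "reactions.tsv", sep="\t", index=False)
    pd.DataFrame({
        "id": model.metabolites,
        "compartment": [model.metabolite_compartments[m]
                        for m in model.metabolites],
    }).to_csv(directory / "metabolites.tsv", sep="\t", index=False)
    header = {
        "members": model.members,
        "extracellular_compartment": model.extracellular_compartment,
        "irreversible": model.irreversible,
        "reverse_of": {str(k): v for k, v in model.reverse_of.items()},
    }
    (directory / "community.json").write_text(json.dumps(header, indent=1))
    return directory


def read_bundle(directory: str | Path) -> CommunityModel:
    """Load a community model written by :func:`write_bundle`."""
    from .gpr import parse_gpr

    directory = Path(directory)
    header = json.loads((directory / "community.json").read_text())
    mets = pd.read_csv(directory / "metabolites.tsv", sep="\t",
                       keep_default_na=False)
    rxns = pd.read_csv(directory / "reactions.tsv", sep="\t",
                       keep_default_na=False)
    trip = pd.read_csv(directory / "stoichiometry.tsv", sep="\t")
    metabolites = mets["id"].astype(str).tolist()
    met_index = {m: i for i, m in enumerate(metabolites)}
    reactions = [
        Reaction(
            id=str(row.id),
            member=str(row.member),
            original_id=str(row.original_id),
            direction=str(row.direction),
            lower_bound=float(row.lower_bound),
            upper_bound=float(row.upper_bound),
            gpr=parse_gpr(str(row.gpr)) if row.gpr else None,
            is_biomass=bool(row.is_biomass),
        )
        for row in rxns.itertuples()
    ]
    rxn_index = {r.id: j for j, r in enumerate(reactions)}
    S = sparse.csc_matrix(
        (
            trip["coefficient"].to_numpy(float),
            (
                trip["metabolite"].map(met_index).to_numpy(int),
                trip["reaction"].map(rxn_index).to_numpy(int),
            ),
        ),
        shape=(len(metabolites), len(reactions)),
    )
    return CommunityModel(
        members=list(header["members"]),
        metabolites=metabolites,
        metabolite_compartments=dict(zip(mets["id"].astype(str),
                                         mets["compartment"].astype(str))),
        S=S,
        reactions=reactions,
        extracellular_compartment=header["extracellular_compartment"],
        irreversible=bool(header["irreversible"]),
        reverse_of={int(k): int(v)
                    for k, v in header.get("reverse_of", {}).items()},
    )


def to_cobra_model(model: CommunityModel, model_id: str = "community"):
    """Convert to a cobra.Model (for SBML export and interoperability)."""
    import cobra

    cmodel = cobra.Model(model_id)
    mets = {}
    for mid in model.metabolites:
        met = cobra.Metabolite(
            mid.replace("::", "__"),
            compartment=model.metabolite_compartments[mid] or "c",
        )
        mets[mid] = met
    cmodel.add_metabolites(list(mets.values()))
    rxns = []
    S = model.S.tocsc()
    for j, rxn in enumerate(model.reactions):
        crxn = cobra.Reaction(rxn.id.replace("::", "__"))
        crxn.lower_bound = rxn.lower_bound
        crxn.upper_bound = rxn.upper_bound
        rxns.append(crxn)
    cmodel.add_reactions(rxns)
    for j, rxn in enumerate(model.reactions):
        col = S.getcol(j).tocoo()
        rxns[j].add_metabolites({
            mets[model.metabolites[i]]: v for i, v in zip(col.row, col.data)
        })
        if model.reactions[j].gpr is not None:
            rxns[j].gene_reaction_rule = model.reactions[j].gpr.to_string()
    return cmodel


def write_sbml(model: CommunityModel, path: str | Path) -> None:
    import cobra.io

    cobra.io.write_sbml_model(to_cobra_model(model), str(path))
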