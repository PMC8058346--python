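"""Preparing a model for reaction lumping.

The lumping procedure works on a direction-explicit, reduced form of the
network: reversible reactions are split into irreversible halves, biomass
and exchange reactions are excluded, and the columns of the stoichiometric
matrix belonging to thermodynamically undetermined reactions are collected
into the reduced matrix R.  Metabolites of unknown formation energy are
then partitioned into groups — connected components of the bipartite
metabolite–reaction graph restricted to unknown metabolites — which can be
lumped independently of each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .model_io import Model, ThermoData

__all__ = [
    "ReactionRole",
    "ReducedSystem",
    "MetaboliteGroup",
    "split_reversible",
    "classify_reactions",
    "extract_reduced_system",
    "partition_groups",
]


class ReactionRole(str, Enum):
    INTERNAL = "internal"
    EXCHANGE = "exchange"
    BIOMASS = "biomass"
    TRANSPORT = "transport"


def split_reversible(model: Model, default_cap: float = 1000.0) -> Model:
    """Split every reversible reaction into two irreversible ones.

    A reaction with lb < 0 < ub is replaced by ``<id>_fwd`` (original
    column, bounds [0, ub]) and ``<id>_rev`` (negated column, bounds
    [0, -lb]).  Purely backwards reactions (lb < 0, ub <= 0) are flipped in
    place.  Infinite bounds are capped at ``default_cap``.  The mapping
    original id -> (fwd, rev) is retained in ``split_pairs``.
    """
    S = model.S.tocsc()
    cols, ids, lb, ub = [], [], [], []
    split_pairs: dict[str, tuple[str, str]] = {}
    for j, rid in enumerate(model.reaction_ids):
        lo = max(model.lb[j], -default_cap)
        hi = min(model.ub[j], default_cap)
        col = S[:, [j]]
        if lo < 0 < hi:
            fwd, rev = f"{rid}_fwd", f"{rid}_rev"
            split_pairs[rid] = (fwd, rev)
            cols += [col, -col]
            ids += [fwd, rev]
            lb += [0.0, 0.0]
            ub += [hi, -lo]
        elif hi <= 0:
            # backwards-only reaction: flip so all fluxes are nonnegative
            cols.append(-col)
            ids.append(rid)
            lb.append(max(0.0, -hi))
            ub.append(-lo)
        else:
            cols.append(col)
            ids.append(rid)
            lb.append(max(lo, 0.0))
            ub.append(hi)
    objective = model.objective_reaction
    if objective in split_pairs:
        objective = split_pairs[objective][0]
    return Model(
        metabolite_ids=list(model.metabolite_ids),
        reaction_ids=ids,
        S=sp.hstack(cols, format="csc"),
        lb=np.array(lb),
        ub=np.array(ub),
        compartments=dict(model.compartments),
        objective_reaction=objective,
        split_pairs=split_pairs,
    )


def _base_species(met_id: str) -> str:
    return met_id.rsplit("_", 1)[0] if "_" in met_id else met_id


def classify_reactions(model: Model) -> dict[str, ReactionRole]:
    """Assign each reaction a role: biomass, exchange, transport or internal.

    The objective reaction is biomass.  A reaction with exactly one nonzero
    stoichiometric entry is an exchange.  A reaction in which the same
    chemical species (id stripped of its compartment suffix) appears in at
    least two compartments is a transport reaction.  Everything else is
    internal.
    """
    roles: dict[str, ReactionRole] = {}
    for rid in model.reaction_ids:
        if rid == model.objective_reaction or (
            model.split_base(rid)[0] == model.split_base(model.objective_reaction)[0]
        ):
            roles[rid] = ReactionRole.BIOMASS
            continue
        stoich = model.reaction_stoichiometry(rid)
        if len(stoich) == 1:
            roles[rid] = ReactionRole.EXCHANGE
            continue
        by_species: dict[str, set[str]] = {}
        for met in stoich:
            comp = model.compartments.get(met) or (
                met.rsplit("_", 1)[1] if "_" in met else ""
            )
            by_species.setdefault(_base_species(met), set()).add(comp)
        if any(len(comps) >= 2 for comps in by_species.values()):
            roles[rid] = ReactionRole.TRANSPORT
        else:
            roles[rid] = ReactionRole.INTERNAL
    return roles


@dataclass
class ReducedSystem:
    """The reduced matrix R consumed by the lumping procedure.

    Columns are the thermodynamically undetermined, lump-eligible
    reactions of a direction-split model; rows are every metabolite
    touched by those columns.  ``unknown_rows`` flags the rows belonging
    to metabolites without formation energy.  ``col_pairs`` maps a column
    to its opposite split direction when both halves of a reversible
    reaction are eligible.
    """

    R: np.ndarray
    row_metabolites: list[str]
    col_reactions: list[str]
    unknown_rows: list[int]
    col_pairs: dict[int, int] = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return self.R.shape[0]

    @property
    def n_cols(self) -> int:
        return self.R.shape[1]

    def row_index(self, met_id: str) -> int:
        return self.row_metabolites.index(met_id)

    def col_index(self, rxn_id: str) -> int:
        return self.col_reactions.index(rxn_id)


def extract_reduced_system(
    model: Model, thermo: ThermoData, include_transport: bool = True
) -> ReducedSystem:
    """Extract the submatrix of undetermined, lump-eligible reactions.

    Biomass and exchange reactions are always excluded; transport
    reactions are excluded when ``include_transport`` is off.  The model
    must already be reversible-split.  An empty column set yields an empty
    system, not an error.
    """
    if np.any(model.lb < 0):
        raise ValueError("extract_reduced_system expects a reversible-split model")
    roles = classify_reactions(model)
    unknown_rxns = thermo.unknown_reactions(model)
    eligible_roles = {ReactionRole.INTERNAL}
    if include_transport:
        eligible_roles.add(ReactionRole.TRANSPORT)
    cols = [
        rid
        for rid in model.reaction_ids
        if rid in unknown_rxns and roles[rid] in eligible_roles
    ]
    if not cols:
        return ReducedSystem(
            R=np.zeros((0, 0)), row_metabolites=[], col_reactions=[], unknown_rows=[]
        )
    col_idx = [model.rxn_index(r) for r in cols]
    sub = model.S[:, col_idx].toarray()
    touched = np.flatnonzero(np.any(sub != 0, axis=1))
    row_mets = [model.metabolite_ids[i] for i in touched]
    unknown_mets = thermo.unknown_metabolites(model)
    unknown_rows = [i for i, m in enumerate(row_mets) if m in unknown_mets]
    col_pos = {r: k for k, r in enumerate(cols)}
    col_pairs: dict[int, int] = {}
    for _, (fwd, rev) in model.split_pairs.items():
        if fwd in col_pos and rev in col_pos:
            col_pairs[col_pos[fwd]] = col_pos[rev]
            col_pairs[col_pos[rev]] = col_pos[fwd]
    return ReducedSystem(
        R=sub[touched, :],
        row_metabolites=row_mets,
        col_reactions=cols,
        unknown_rows=unknown_rows,
        col_pairs=col_pairs,
    )


@dataclass
class MetaboliteGroup:
    """A connected component of unknown metabolites in the reduced system."""

    members: list[str]  # unknown metabolite ids, in model row order
    member_rows: list[int]  # row indices into the reduced system
    touched_cols: list[int]  # columns in which at least one member appears


def partition_groups(rs: ReducedSystem) -> list[MetaboliteGroup]:
    """Partition unknown metabolites into independently lumpable groups.

    Two unknown metabolites belong to the same group iff they share a
    reaction (directly or transitively).  Formally the groups are the
    connected components of the bipartite graph on unknown rows and
    reduced-system columns with an edge wherever the coefficient is
    nonzero — metabolites with known formation energy are not part of the
    graph.  Groups are ordered by their smallest member row index, and
    members within a group follow model order, so the downstream
    procedures are deterministic.
    """
    graph = nx.Graph()
    unknown = set(rs.unknown_rows)
    graph.add_nodes_from(("m", i) for i in rs.unknown_rows)
    for j in range(rs.n_cols):
        for i in np.flatnonzero(rs.R[:, j]):
            if int(i) in unknown:
                graph.add_edge(("m", int(i)), ("r", j))
    groups = []
    for component in nx.connected_components(graph):
        rows = sorted(i for kind, i in component if kind == "m")
        if not rows:
            continue
        cols = sorted(j for kind, j in component if kind == "r")
        groups.append(
            MetaboliteGroup(
                members=[rs.row_metabolites[i] for i in rows],
                member_rows=rows,
                touched_cols=cols,
            )
        )
    groups.sort(key=lambda g: g.member_rows[0])
    return groups
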