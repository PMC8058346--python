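"""Deterministic desk-scale fixtures: the worked toy network and random models.

The toy network packages the canonical two-group example: unknown
metabolites A and B form one group (eliminable at once by lumping r1, r2
and r7), while E, G and H form a second group whose 3x4 submatrix over
reactions r3..r6 is

        r3  r4  r5  r6
    E [ -1   1  -1   0 ]
    G [  0  -1   0   1 ]
    H [ -1   0   1  -1 ]

Summing the three rows shows every column except r3 cancels, so a
combination zeroing all of E, G, H needs alpha_3 = 0 — impossible because
r3 contains group members and must enter with alpha_3 >= 1.  The group is
therefore not eliminable at once, but G alone is, via r4 + r5 + r6.

Only the unknown-metabolite submatrix is canonical; the coefficients of
the known filler metabolites are this package's own reconstruction, chosen
by bounded integer search so that the sequential procedure follows the
reference walkthrough exactly (LP counts 3/2/3 for seeds E/G/H, 2 per seed
on the A-B group).  :func:`verify_toy` re-checks every property of the
reconstruction against the LP solver and is exercised by the test suite.

The synthetic generator emulates genome-scale-like models: a linear
pathway backbone guaranteeing a nonzero FBA optimum, sparse noise
reactions, a controllable fraction of reversible reactions and of
metabolites with missing formation energy, and formation energies drawn
from a normal distribution with mean -300 and standard deviation
200 kJ/mol.  Generation is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .lump_core import (
    INFEASIBLE,
    LumpProblem,
    combined_procedure,
    group_lump,
    sequential_lump,
    solve_lump_lp,
)
from .model_io import Model, ThermoData
from .network_prep import (
    MetaboliteGroup,
    ReducedSystem,
    extract_reduced_system,
    partition_groups,
    split_reversible,
)

__all__ = [
    "ToyNetwork",
    "SyntheticGEM",
    "U2_SUBMATRIX",
    "make_toy_network",
    "verify_toy",
    "make_synthetic_gem",
]

#: canonical submatrix of the second group: rows (E, G, H) x columns (r3..r6)
U2_SUBMATRIX = np.array(
    [
        [-1.0, 1.0, -1.0, 0.0],
        [0.0, -1.0, 0.0, 1.0],
        [-1.0, 0.0, 1.0, -1.0],
    ]
)

# frozen reconstruction of the toy network: stoichiometries of the seven
# lump-eligible reactions (unknown metabolites a, b, e, g, h; known fillers
# k, p, q, w, z) plus determined internal reactions, exchanges and biomass
_TOY_REACTIONS: dict[str, dict] = {
    "r1": {"metabolites": {"p_c": -2, "a_c": 1}},
    "r2": {"metabolites": {"a_c": -1, "b_c": 1}},
    "r3": {"metabolites": {"e_c": -1, "h_c": -1, "k_c": 1}},
    "r4": {"metabolites": {"g_c": -1, "k_c": -1, "e_c": 1}},
    "r5": {"metabolites": {"e_c": -1, "h_c": 1, "w_c": 2}},
    "r6": {"metabolites": {"h_c": -1, "g_c": 1, "z_c": 1}},
    "r7": {"metabolites": {"b_c": -1, "q_c": 2}},
    "r8": {"metabolites": {"p_c": -1, "k_c": 1}},
    "r9": {"metabolites": {"w_c": -1, "q_c": 1}},
    "r10": {"metabolites": {"z_c": -1, "q_c": 1}},
    "EX_p": {"metabolites": {"p_c": -1}, "lb": -10.0, "ub": 0.0},
    "EX_k": {"metabolites": {"k_c": -1}, "lb": -20.0, "ub": 1000.0},
    "EX_q": {"metabolites": {"q_c": -1}},
    "EX_w": {"metabolites": {"w_c": -1}},
    "EX_z": {"metabolites": {"z_c": -1}},
    "biomass": {"metabolites": {"q_c": -1, "z_c": -1}, "objective": True},
}

_TOY_METABOLITES = [
    "a_c", "b_c", "e_c", "g_c", "h_c", "k_c", "p_c", "q_c", "w_c", "z_c",
]

#: formation energies (kJ/mol) of the known filler metabolites
_TOY_DFG0 = {
    "k_c": -310.5,
    "p_c": -150.0,
    "q_c": -80.0,
    "w_c": -95.2,
    "z_c": -200.0,
}


@dataclass
class ToyNetwork:
    """The packaged worked example plus its expected lumping behaviour."""

    model: Model
    thermo: ThermoData
    group_members: list[list[str]] = field(
        default_factory=lambda: [["a_c", "b_c"], ["e_c", "g_c", "h_c"]]
    )
    u1_support: set[str] = field(default_factory=lambda: {"r1", "r2", "r7"})
    u2_lump_support: set[str] = field(default_factory=lambda: {"r4", "r5", "r6"})


def _build_model(
    metabolites: list[str],
    reactions: dict[str, dict],
    compartment: str = "c",
) -> Model:
    met_index = {m: i for i, m in enumerate(metabolites)}
    rows, cols, data, lb, ub = [], [], [], [], []
    objective = None
    rxn_ids = list(reactions)
    for j, (rid, spec) in enumerate(reactions.items()):
        lb.append(float(spec.get("lb", 0.0)))
        ub.append(float(spec.get("ub", 1000.0)))
        for met, coef in spec["metabolites"].items():
            rows.append(met_index[met])
            cols.append(j)
            data.append(float(coef))
        if spec.get("objective"):
            objective = rid
    S = sp.csc_array(
        (data, (rows, cols)), shape=(len(metabolites), len(rxn_ids)), dtype=float
    )
    return Model(
        metabolite_ids=list(metabolites),
        reaction_ids=rxn_ids,
        S=S,
        lb=np.array(lb),
        ub=np.array(ub),
        compartments={m: m.rsplit("_", 1)[1] for m in metabolites},
        objective_reaction=objective,
    )


def make_toy_network() -> ToyNetwork:
    """Build the packaged two-group toy network with its annotations."""
    model = _build_model(_TOY_METABOLITES, _TOY_REACTIONS)
    thermo = ThermoData(dfG0=dict(_TOY_DFG0))
    return ToyNetwork(model=model, thermo=thermo)


def _toy_reduced(toy: ToyNetwork) -> tuple[Model, ReducedSystem, list[MetaboliteGroup]]:
    split = split_reversible(toy.model)
    rs = extract_reduced_system(split, toy.thermo, include_transport=True)
    return split, rs, partition_groups(rs)


def verify_toy(toy: ToyNetwork, integer_alpha: bool = False) -> None:
    """Re-check every frozen property of the toy against the LP solver.

    Raises AssertionError naming the first violated property.  Covers: the
    canonical unknown-metabolite submatrix, the two-group partition, group
    LP success on {A, B} with support {r1, r2, r7}, group LP infeasibility
    on {E, G, H}, the per-seed LP counts of the sequential walkthrough
    (E: 3, G: 2, H: 3, A: 2, B: 2), the eliminated sets, and the primitive
    support {r4, r5, r6} of the G lump.
    """
    _, rs, groups = _toy_reduced(toy)
    assert [g.members for g in groups] == toy.group_members, (
        f"group partition mismatch: {[g.members for g in groups]}"
    )
    sub_rows = [rs.row_index(m) for m in ("e_c", "g_c", "h_c")]
    sub_cols = [rs.col_index(r) for r in ("r3", "r4", "r5", "r6")]
    sub = rs.R[np.ix_(sub_rows, sub_cols)]
    assert np.array_equal(sub, U2_SUBMATRIX), f"U2 submatrix mismatch:\n{sub}"

    u1, u2 = groups
    lump1 = group_lump(rs, u1, 0, integer_alpha=integer_alpha)
    assert lump1 is not None, "group LP on {A,B} must succeed"
    assert set(lump1.composition) == toy.u1_support, (
        f"U1 lump support {set(lump1.composition)} != {toy.u1_support}"
    )
    sol2 = solve_lump_lp(
        LumpProblem(
            R=rs.R,
            U_rows=frozenset(u2.member_rows),
            seed_rows=frozenset(u2.member_rows),
            integer_alpha=integer_alpha,
        )
    )
    assert sol2 is INFEASIBLE, "group LP on {E,G,H} must be infeasible"

    expected = {"a_c": (2, True), "b_c": (2, True),
                "e_c": (3, False), "g_c": (2, True), "h_c": (3, False)}
    for met, (n_lps, lumped) in expected.items():
        row = rs.row_index(met)
        pseudo = MetaboliteGroup(members=[met], member_rows=[row], touched_cols=[])
        res = sequential_lump(rs, pseudo, integer_alpha=integer_alpha)
        assert res.lps_sequential == n_lps, (
            f"seed {met}: {res.lps_sequential} LPs, expected {n_lps}"
        )
        assert bool(res.lumps) == lumped, f"seed {met}: lump acceptance mismatch"
        if met == "g_c":
            assert set(res.lumps[0].composition) == toy.u2_lump_support, (
                f"G lump support {set(res.lumps[0].composition)}"
            )
    res_u2 = sequential_lump(rs, u2, integer_alpha=integer_alpha)
    assert res_u2.lps_sequential == 8, f"U2 sequential: {res_u2.lps_sequential} LPs"
    assert res_u2.eliminated == {"g_c"}, f"U2 eliminated {res_u2.eliminated}"
    res_u1 = sequential_lump(rs, u1, integer_alpha=integer_alpha)
    assert res_u1.lps_sequential == 4, f"U1 sequential: {res_u1.lps_sequential} LPs"
    assert res_u1.eliminated == {"a_c", "b_c"}
    combined = combined_procedure(rs, groups, integer_alpha=integer_alpha)
    assert combined.lps_group == 2 and combined.lps_sequential == 8, (
        f"combined LP counts {combined.lps_group}+{combined.lps_sequential}"
    )
    assert combined.eliminated == {"a_c", "b_c", "g_c"}


@dataclass
class SyntheticGEM:
    """A reproducible random model with partial thermodynamic annotation."""

    model: Model
    thermo: ThermoData
    seed: int
    params: dict


def make_synthetic_gem(
    n_metabolites: int = 20,
    n_noise_reactions: int = 15,
    reversible_fraction: float = 0.3,
    missing_fraction: float = 0.2,
    mets_per_reaction: tuple[int, int] = (2, 4),
    seed: int = 0,
    dfG0_mean: float = -300.0,
    dfG0_sd: float = 200.0,
    max_attempts: int = 10,
) -> SyntheticGEM:
    """Generate a random sparse model admitting a nonzero FBA optimum.

    The model is a chained pathway backbone (importer exchange, a linear
    chain of conversions, a biomass drain on the terminal metabolite) plus
    ``n_noise_reactions`` sparse random internal reactions.  The backbone
    guarantees flux; noise reactions may be reversible with probability
    ``reversible_fraction``.  Formation energies are drawn from
    N(dfG0_mean, dfG0_sd) and a fraction ``missing_fraction`` of
    metabolites is left unannotated.  Everything is a pure function of
    ``seed``.
    """
    if n_metabolites < 2:
        raise ValueError("need at least 2 metabolites")
    if not 0 <= missing_fraction <= 1 or not 0 <= reversible_fraction <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    from .tmfa import fba_optimum

    for attempt in range(max_attempts):
        rng = np.random.default_rng((seed + 1_000_003 * attempt) % 2**31)
        mets = [f"m{i:03d}_c" for i in range(n_metabolites)]
        reactions: dict[str, dict] = {}
        reactions["EX_in"] = {"metabolites": {mets[0]: 1}, "lb": 0.0, "ub": 10.0}
        for i in range(n_metabolites - 1):
            reactions[f"bb{i:03d}"] = {"metabolites": {mets[i]: -1, mets[i + 1]: 1}}
        reactions["biomass"] = {
            "metabolites": {mets[-1]: -1},
            "objective": True,
        }
        lo_k, hi_k = mets_per_reaction
        for r in range(n_noise_reactions):
            k = int(rng.integers(lo_k, hi_k + 1))
            chosen = rng.choice(n_metabolites, size=min(k, n_metabolites),
                                replace=False)
            coefs = {}
            for pos, i in enumerate(chosen):
                mag = int(rng.integers(1, 3))
                coefs[mets[i]] = mag if pos % 2 else -mag
            spec: dict = {"metabolites": coefs}
            if rng.random() < reversible_fraction:
                spec["lb"] = -1000.0
            reactions[f"nz{r:03d}"] = spec
        model = _build_model(mets, reactions)
        n_missing = int(round(missing_fraction * n_metabolites))
        missing = set(
            rng.choice(n_metabolites, size=n_missing, replace=False).tolist()
        )
        dfG0 = {
            mets[i]: float(rng.normal(dfG0_mean, dfG0_sd))
            for i in range(n_metabolites)
            if i not in missing
        }
        thermo = ThermoData(dfG0=dfG0)
        if fba_optimum(model) > 1e-6:
            return SyntheticGEM(
                model=model,
                thermo=thermo,
                seed=seed,
                params={
                    "n_metabolites": n_metabolites,
                    "n_noise_reactions": n_noise_reactions,
                    "reversible_fraction": reversible_fraction,
                    "missing_fraction": missing_fraction,
                    "attempt": attempt,
                },
            )
    raise RuntimeError(
        f"no parameter draw produced a nonzero FBA optimum in {max_attempts} attempts"
    )
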