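"""Thermodynamic metabolic flux analysis with lumped-reaction constraints.

TMFA augments flux balance analysis with Gibbs-energy constraints: a
reaction may carry flux only if its concentration-dependent Gibbs energy
change is negative,

    dG_j = dG0_j + R*T * sum_i s_ij * ln(x_i),

coupled to the fluxes through binary feasibility indicators and a big-M
constant.  Reactions whose standard Gibbs energy cannot be computed carry
flux variables but no thermodynamic constraint.  Lumped reactions close
part of that gap: a lump k with composition weights alpha_kj over model
reactions carries no flux variable (the steady-state space is untouched)
but contributes the constraints

    dG_k <= (1 - y_k) * M
    sum_j alpha_kj * z_j <= sum_j alpha_kj - (1 - y_k)
    dG_k  = dG0_k + R*T * sum_i s_ik * ln(x_i)

so that an infeasible lump forces at least one member reaction inactive.

Thermodynamic constraints are imposed on internal and transport reactions
only; exchange and biomass pseudo-reactions have no physical Gibbs energy
and remain unconstrained.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .model_io import Lump, Model, ThermoData
from .network_prep import ReactionRole, classify_reactions

__all__ = [
    "GAS_CONSTANT_KJ",
    "TMFAConfig",
    "TMFAProblem",
    "DeltaGRange",
    "TMFAInfeasibleError",
    "lump_dG0",
    "build_tmfa",
    "fba_optimum",
    "tmfa_optimum",
    "dG_variability",
    "classify_reversibility",
]

#: universal gas constant, kJ/(mol*K)
GAS_CONSTANT_KJ = 8.314e-3


class TMFAInfeasibleError(RuntimeError):
    """The TMFA problem admits no solution under the given bounds."""


@dataclass
class TMFAConfig:
    """Parameters of the TMFA encoding.

    Concentrations are bounded between 1 uM and 20 mM by default, with
    per-metabolite overrides for species (water, highly abundant cofactors)
    whose default range would render the problem infeasible.  ``bigM`` must
    dominate every attainable |dG|; ``epsilon`` implements the strict
    negativity of dG for active reactions.
    """

    temperature: float = 298.15  # K
    gas_constant: float = GAS_CONSTANT_KJ  # kJ/(mol*K)
    bigM: float = 1000.0  # kJ/mol
    conc_lb: float = 1e-6  # mol/L
    conc_ub: float = 2e-2  # mol/L
    conc_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    biomass_fraction: float = 0.9
    epsilon: float = 1e-6  # kJ/mol
    time_limit: float = 120.0  # s per MILP solve

    def __post_init__(self) -> None:
        if not 0 < self.biomass_fraction <= 1:
            raise ValueError("biomass_fraction must be in (0, 1]")
        for met, (lo, hi) in {"": (self.conc_lb, self.conc_ub),
                              **self.conc_overrides}.items():
            if not lo < hi:
                raise ValueError(f"concentration bounds {lo} >= {hi} for {met!r}")

    @property
    def RT(self) -> float:
        return self.gas_constant * self.temperature

    def ln_bounds(self, met_id: str) -> tuple[float, float]:
        lo, hi = self.conc_overrides.get(met_id, (self.conc_lb, self.conc_ub))
        return math.log(lo), math.log(hi)


def lump_dG0(lump: Lump, thermo: ThermoData) -> float:
    """Standard Gibbs energy change of a lumped reaction (kJ/mol).

    Computed metabolite-wise as the net-stoichiometry-weighted sum of
    formation energies; every metabolite with nonzero net coefficient must
    be annotated — unknown metabolites are required to cancel exactly.
    """
    total = 0.0
    for met, coef in lump.net.items():
        if met not in thermo.dfG0:
            raise ValueError(
                f"lump {lump.lump_id}: metabolite {met} has nonzero net "
                f"coefficient {coef} but no formation energy"
            )
        total += coef * thermo.dfG0[met]
    return total


@dataclass
class TMFAProblem:
    """Assembled TMFA MILP in scipy ``milp`` form.

    Variable layout: fluxes v (one per model reaction), log concentrations
    ln x (one per metabolite), then dG variables for thermodynamically
    determined internal/transport reactions and for lumps, then binary
    indicators z (thermo-coupled model reactions) and y (lumps).  Only
    model reactions enter the steady-state constraint S v = 0.
    """

    model: Model
    constraints: list[LinearConstraint]
    lower: np.ndarray
    upper: np.ndarray
    integrality: np.ndarray
    v_offset: int
    lnx_offset: int
    dg_index: dict[str, int]  # reaction or lump id -> variable index
    z_index: dict[str, int]
    y_index: dict[str, int]

    @property
    def n_vars(self) -> int:
        return len(self.lower)

    def solve(
        self,
        c: np.ndarray,
        maximize: bool = False,
        extra_constraints: list[LinearConstraint] | None = None,
        time_limit: float | None = None,
    ):
        cons = self.constraints + (extra_constraints or [])
        res = milp(
            c=-c if maximize else c,
            constraints=cons,
            bounds=Bounds(self.lower, self.upper),
            integrality=self.integrality,
            options={} if time_limit is None else {"time_limit": time_limit},
        )
        return res


def build_tmfa(
    model: Model,
    lumps: list[Lump],
    thermo: ThermoData,
    cfg: TMFAConfig | None = None,
    transport_adjustment=None,
) -> TMFAProblem:
    """Assemble the TMFA MILP for a reversible-split model plus lumps.

    ``transport_adjustment`` is an optional hook mapping a cross-compartment
    lump to an additive dG0 correction (kJ/mol) for membrane transport; by
    default no correction is applied and a warning is emitted for lumps
    spanning compartments.
    """
    if cfg is None:
        cfg = TMFAConfig()
    if np.any(model.lb < 0):
        raise ValueError("build_tmfa expects a reversible-split model")
    roles = classify_reactions(model)
    thermo_roles = {ReactionRole.INTERNAL, ReactionRole.TRANSPORT}
    n, m = model.n_reactions, model.n_metabolites
    RT, M, eps = cfg.RT, cfg.bigM, cfg.epsilon

    coupled = [r for r in model.reaction_ids if roles[r] in thermo_roles]
    determined = [r for r in coupled if thermo.reaction_dG0(model, r) is not None]

    # variable layout
    v_off, lnx_off = 0, n
    dg_index: dict[str, int] = {}
    pos = lnx_off + m
    for r in determined:
        dg_index[r] = pos
        pos += 1
    for lump in lumps:
        dg_index[lump.lump_id] = pos
        pos += 1
    z_index = {}
    for r in coupled:
        z_index[r] = pos
        pos += 1
    y_index = {}
    for lump in lumps:
        y_index[lump.lump_id] = pos
        pos += 1
    nvar = pos

    lower = np.full(nvar, -np.inf)
    upper = np.full(nvar, np.inf)
    lower[v_off:v_off + n] = model.lb
    upper[v_off:v_off + n] = model.ub
    for i, met in enumerate(model.metabolite_ids):
        lower[lnx_off + i], upper[lnx_off + i] = cfg.ln_bounds(met)
    integrality = np.zeros(nvar)
    for idx in list(z_index.values()) + list(y_index.values()):
        integrality[idx] = 1
        lower[idx], upper[idx] = 0, 1

    rows, cols, data, lo_list, hi_list = [], [], [], [], []
    row = 0

    def add_terms(terms: list[tuple[int, float]], lo: float, hi: float) -> None:
        nonlocal row
        for col, val in terms:
            rows.append(row)
            cols.append(col)
            data.append(val)
        lo_list.append(lo)
        hi_list.append(hi)
        row += 1

    # (i) steady state S v = 0 over model reactions only
    S = model.S.tocoo()
    for i, j, v in zip(S.row, S.col, S.data):
        rows.append(i)
        cols.append(v_off + j)
        data.append(v)
    lo_list.extend([0.0] * m)
    hi_list.extend([0.0] * m)
    row = m

    # (ii) flux/indicator coupling and dG definition for model reactions
    for r in coupled:
        j = model.rxn_index(r)
        # v_j - ub_j z_j <= 0
        add_terms([(v_off + j, 1.0), (z_index[r], -model.ub[j])], -np.inf, 0.0)
    for r in determined:
        j = model.rxn_index(r)
        dg0 = thermo.reaction_dG0(model, r)
        # dG_j - RT * sum_i s_ij lnx_i = dG0_j
        terms = [(dg_index[r], 1.0)]
        for met, coef in model.reaction_stoichiometry(r).items():
            terms.append((lnx_off + model.met_index(met), -RT * coef))
        add_terms(terms, dg0, dg0)
        # dG_j + M z_j <= M - eps
        add_terms([(dg_index[r], 1.0), (z_index[r], M)], -np.inf, M - eps)

    # (iii) lumped-reaction constraints
    for lump in lumps:
        dg0 = lump_dG0(lump, thermo)
        comps = {model.compartments.get(met, "") for met in lump.net}
        if len(comps) > 1:
            if transport_adjustment is not None:
                dg0 += float(transport_adjustment(lump))
            else:
                warnings.warn(
                    f"lump {lump.lump_id} spans compartments {sorted(comps)}; "
                    "no membrane-transport dG adjustment applied",
                    stacklevel=2,
                )
        # dG_k - RT * sum_i s_ik lnx_i = dG0_k
        terms = [(dg_index[lump.lump_id], 1.0)]
        for met, coef in lump.net.items():
            terms.append((lnx_off + model.met_index(met), -RT * coef))
        add_terms(terms, dg0, dg0)
        # dG_k + M y_k <= M
        add_terms([(dg_index[lump.lump_id], 1.0), (y_index[lump.lump_id], M)],
                  -np.inf, M)
        # sum_j alpha_kj z_j - y_k <= sum_j alpha_kj - 1
        terms = []
        alpha_sum = 0.0
        for rxn, alpha in lump.composition.items():
            if rxn not in z_index:
                raise ValueError(
                    f"lump {lump.lump_id} references reaction {rxn!r} with no "
                    "feasibility indicator in the model"
                )
            terms.append((z_index[rxn], alpha))
            alpha_sum += alpha
        terms.append((y_index[lump.lump_id], -1.0))
        add_terms(terms, -np.inf, alpha_sum - 1.0)

    A = sp.csr_array((data, (rows, cols)), shape=(row, nvar))
    constraints = [LinearConstraint(A, np.array(lo_list), np.array(hi_list))]
    return TMFAProblem(
        model=model,
        constraints=constraints,
        lower=lower,
        upper=upper,
        integrality=integrality,
        v_offset=v_off,
        lnx_offset=lnx_off,
        dg_index=dg_index,
        z_index=z_index,
        y_index=y_index,
    )


def fba_optimum(model: Model) -> float:
    """Plain FBA: maximize the objective flux subject to S v = 0 and bounds."""
    n = model.n_reactions
    c = np.zeros(n)
    c[model.rxn_index(model.objective_reaction)] = -1.0
    res = linprog(
        c,
        A_eq=model.S,
        b_eq=np.zeros(model.n_metabolites),
        bounds=np.column_stack([model.lb, model.ub]),
        method="highs",
    )
    if res.status == 2:
        raise TMFAInfeasibleError("FBA problem infeasible")
    if not res.success:
        raise RuntimeError(f"FBA solve failed: {res.message}")
    return -res.fun


def tmfa_optimum(problem: TMFAProblem, cfg: TMFAConfig | None = None) -> float:
    """Maximum objective flux under the full TMFA constraints."""
    if cfg is None:
        cfg = TMFAConfig()
    c = np.zeros(problem.n_vars)
    c[problem.v_offset + problem.model.rxn_index(problem.model.objective_reaction)] = 1.0
    res = problem.solve(c, maximize=True, time_limit=cfg.time_limit)
    if res.status == 2:
        raise TMFAInfeasibleError(
            "TMFA problem infeasible; consider relaxing concentration bounds "
            "for highly abundant metabolites (e.g. water, major cofactors)"
        )
    if not res.success:
        raise RuntimeError(f"TMFA solve failed: {res.message}")
    return -res.fun


@dataclass
class DeltaGRange:
    """Attainable [min, max] of a reaction's Gibbs energy change (kJ/mol)."""

    reaction_id: str
    dG_min: float
    dG_max: float

    @property
    def classification(self) -> str:
        # irreversible iff the maximum is strictly negative
        return "irreversible" if self.dG_max < 0 else "reversible"


def dG_variability(
    problem: TMFAProblem, cfg: TMFAConfig | None = None
) -> list[DeltaGRange]:
    """Min/max each dG variable at a fixed fraction of the FBA optimum.

    The biomass flux is constrained to at least ``cfg.biomass_fraction``
    times the plain FBA optimum, then each Gibbs energy variable (model
    reactions and lumps alike) is minimized and maximized subject to the
    full TMFA MILP.
    """
    if cfg is None:
        cfg = TMFAConfig()
    fba = fba_optimum(problem.model)
    bio_col = problem.v_offset + problem.model.rxn_index(
        problem.model.objective_reaction
    )
    sel = sp.csr_array(
        (np.array([1.0]), (np.array([0]), np.array([bio_col]))),
        shape=(1, problem.n_vars),
    )
    biomass_floor = LinearConstraint(sel, cfg.biomass_fraction * fba, np.inf)
    ranges = []
    for name, idx in problem.dg_index.items():
        c = np.zeros(problem.n_vars)
        c[idx] = 1.0
        bounds_pair = []
        for maximize in (False, True):
            res = problem.solve(
                c, maximize=maximize, extra_constraints=[biomass_floor],
                time_limit=cfg.time_limit,
            )
            if res.status == 2:
                raise TMFAInfeasibleError(
                    f"TMFA infeasible at biomass fraction {cfg.biomass_fraction}; "
                    "relax concentration bounds of the binding metabolites"
                )
            if not res.success:
                raise RuntimeError(f"variability solve failed for {name}: {res.message}")
            bounds_pair.append(-res.fun if maximize else res.fun)
        ranges.append(DeltaGRange(name, bounds_pair[0], bounds_pair[1]))
    return ranges


def classify_reversibility(ranges: list[DeltaGRange]) -> dict[str, int]:
    """Tally reactions by the strict-negativity rule on max dG."""
    counts = {"irreversible": 0, "reversible": 0}
    for r in ranges:
        counts[r.classification] += 1
    return counts
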