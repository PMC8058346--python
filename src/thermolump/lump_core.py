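"""The lumping linear program and the elimination procedures built on it.

A lumped reaction is a nonnegative linear combination y = R·alpha of the
columns of the reduced matrix R such that every target metabolite u in a
set U receives net coefficient zero.  Among all such combinations the
program picks one minimizing the sum of absolute values of the net
stoichiometric coefficients, via the standard split y = y+ − y−:

    min  sum(y+ + y−)
    s.t. R·alpha = y+ − y−
         y_u = 0            for all u in U
         alpha_min <= alpha <= alpha_max,   y+, y− >= 0

with alpha_min_j = 1 for every column j in which a *seed* metabolite
appears (so no reaction containing a seed can opt out) and 0 otherwise.

Three procedures drive the LP:

* the **group implementation** tries to eliminate a whole group of
  unknown metabolites in one LP;
* the **sequential implementation** starts from a single seed metabolite,
  and whenever the optimal lump drags in another unknown metabolite, adds
  it to the target set, appends the interim solution as a fresh column of
  R, and re-solves;
* the **combined procedure** runs the group LP first and falls back to the
  sequential implementation per group, maximizing eliminated metabolites
  at a reduced LP count.

A **naive iterative** baseline applies the sequential iteration to every
unknown metabolite while ignoring the group structure.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .model_io import Lump
from .network_prep import MetaboliteGroup, ReducedSystem

__all__ = [
    "LumpProblem",
    "LumpSolution",
    "LumpRunResult",
    "SolverError",
    "INFEASIBLE",
    "solve_lump_lp",
    "group_lump",
    "sequential_lump",
    "sequential_only",
    "naive_iterative",
    "combined_procedure",
]

#: default upper bound on combination coefficients (boundedness of the LP)
DEFAULT_ALPHA_MAX = 1000.0
#: coefficients below this magnitude count as zero
DEFAULT_TOL = 1e-9
#: per-seed iteration cap in the sequential implementation
MAX_SEQUENTIAL_ITERATIONS = 50


class SolverError(RuntimeError):
    """Numerical solver failure — distinct from a proven infeasibility."""


class _Infeasible:
    """Distinguished marker for an infeasible lumping program."""

    def __repr__(self) -> str:  # pragma: no cover
        return "INFEASIBLE"

    def __bool__(self) -> bool:
        return False


INFEASIBLE = _Infeasible()


@dataclass
class LumpProblem:
    """One instance of the lumping program.

    ``U_rows`` are row indices whose net coefficient is constrained to
    zero; ``seed_rows`` determine which columns get alpha_min = 1.  In
    group mode the seeds are all of U; in sequential mode the seed stays
    the single starting metabolite even as U grows.
    """

    R: np.ndarray
    U_rows: frozenset[int]
    seed_rows: frozenset[int]
    alpha_max: float = DEFAULT_ALPHA_MAX
    integer_alpha: bool = False

    def alpha_min(self) -> np.ndarray:
        amin = np.zeros(self.R.shape[1])
        if self.seed_rows:
            seeds = sorted(self.seed_rows)
            amin[np.any(self.R[seeds, :] != 0, axis=0)] = 1.0
        return amin


@dataclass
class LumpSolution:
    """An optimal solution of the lumping program."""

    alpha: np.ndarray
    y: np.ndarray
    objective: float

    def involved_rows(
        self, unknown_rows: list[int], U_rows: frozenset[int], tol: float = DEFAULT_TOL
    ) -> list[int]:
        """Unknown-metabolite rows outside U with nonzero net coefficient."""
        return [
            u for u in unknown_rows if u not in U_rows and abs(self.y[u]) > tol
        ]


def solve_lump_lp(problem: LumpProblem) -> LumpSolution | _Infeasible:
    """Solve the lumping program; return a solution or ``INFEASIBLE``.

    The program is linear in alpha; with ``integer_alpha`` the combination
    coefficients are additionally required to be integers and the problem
    is solved as a MILP.  A numerical solver failure raises
    :class:`SolverError` instead of being conflated with infeasibility.
    """
    m, n = problem.R.shape
    amin = problem.alpha_min()
    if np.any(amin > problem.alpha_max):
        return INFEASIBLE
    # variables: alpha (n), y+ (m), y- (m)
    c = np.concatenate([np.zeros(n), np.ones(2 * m)])
    A = np.hstack([problem.R, -np.eye(m), np.eye(m)])
    y_cap = np.full(m, np.inf)
    y_cap[sorted(problem.U_rows)] = 0.0
    lower = np.concatenate([amin, np.zeros(2 * m)])
    upper = np.concatenate([np.full(n, problem.alpha_max), y_cap, y_cap])
    if problem.integer_alpha:
        res = milp(
            c=c,
            constraints=[LinearConstraint(A, np.zeros(m), np.zeros(m))],
            bounds=Bounds(lower, upper),
            integrality=np.concatenate([np.ones(n), np.zeros(2 * m)]),
        )
        infeasible = res.status == 2
    else:
        res = linprog(
            c,
            A_eq=A,
            b_eq=np.zeros(m),
            bounds=np.column_stack([lower, upper]),
            method="highs",
        )
        infeasible = res.status == 2
    if infeasible:
        return INFEASIBLE
    if not res.success:
        raise SolverError(f"lumping program failed: {res.message}")
    alpha = np.asarray(res.x[:n], dtype=float)
    return LumpSolution(alpha=alpha, y=problem.R @ alpha, objective=float(res.fun))


def _cancel_split_pairs(
    alpha: np.ndarray, col_pairs: dict[int, int], tol: float
) -> np.ndarray:
    """Remove null combinations of both directions of a split reaction.

    When fwd and rev columns of one reversible reaction both carry weight,
    the smaller weight is subtracted from both: the pair is a perfect
    cancellation invisible to the objective on y.
    """
    alpha = alpha.copy()
    for j, k in col_pairs.items():
        if j < k and alpha[j] > tol and alpha[k] > tol:
            low = min(alpha[j], alpha[k])
            alpha[j] -= low
            alpha[k] -= low
    return alpha


LPLog = Callable[..., None]


@dataclass
class LumpRunResult:
    """Aggregate outcome of a lumping run."""

    lumps: list[Lump] = field(default_factory=list)
    eliminated: set[str] = field(default_factory=set)
    lps_group: int = 0
    lps_sequential: int = 0
    groups_solved_by_group: int = 0
    infeasible_groups: int = 0
    lp_durations: list[float] = field(default_factory=list)

    @property
    def lps_total(self) -> int:
        return self.lps_group + self.lps_sequential

    def merge(self, other: "LumpRunResult") -> None:
        self.lumps.extend(other.lumps)
        self.eliminated |= other.eliminated
        self.lps_group += other.lps_group
        self.lps_sequential += other.lps_sequential
        self.groups_solved_by_group += other.groups_solved_by_group
        self.infeasible_groups += other.infeasible_groups
        self.lp_durations.extend(other.lp_durations)


def _timed_solve(
    problem: LumpProblem, result: LumpRunResult, phase: str
) -> LumpSolution | _Infeasible:
    start = time.perf_counter()
    sol = solve_lump_lp(problem)
    result.lp_durations.append(time.perf_counter() - start)
    if phase == "group":
        result.lps_group += 1
    else:
        result.lps_sequential += 1
    return sol


def _make_lump(
    rs: ReducedSystem,
    primitive_alpha: np.ndarray,
    group_index: int,
    eliminated: list[str],
    lump_id: str,
    tol: float,
) -> Lump:
    alpha = _cancel_split_pairs(primitive_alpha, rs.col_pairs, tol)
    y = rs.R @ alpha
    composition = {
        rs.col_reactions[j]: float(alpha[j]) for j in np.flatnonzero(alpha > tol)
    }
    net = {
        rs.row_metabolites[i]: float(y[i]) for i in np.flatnonzero(np.abs(y) > tol)
    }
    return Lump(
        lump_id=lump_id,
        composition=composition,
        net=net,
        eliminated=eliminated,
        group=group_index,
    )


def group_lump(
    rs: ReducedSystem,
    group: MetaboliteGroup,
    group_index: int = 0,
    alpha_max: float = DEFAULT_ALPHA_MAX,
    integer_alpha: bool = False,
    tol: float = DEFAULT_TOL,
    result: LumpRunResult | None = None,
    log: LPLog | None = None,
) -> Lump | None:
    """Try to eliminate an entire group with a single LP.

    Returns the lump if the program is feasible *and* its solution touches
    no unknown metabolite outside the group; returns None otherwise.
    """
    if result is None:
        result = LumpRunResult()
    rows = frozenset(group.member_rows)
    problem = LumpProblem(
        R=rs.R, U_rows=rows, seed_rows=rows,
        alpha_max=alpha_max, integer_alpha=integer_alpha,
    )
    sol = _timed_solve(problem, result, "group")
    if log is not None:
        log(
            phase="group", group=group_index, seed=",".join(group.members),
            U_size=len(rows),
            status="infeasible" if sol is INFEASIBLE else "optimal",
            objective=None if sol is INFEASIBLE else sol.objective,
            duration=result.lp_durations[-1],
        )
    if sol is INFEASIBLE:
        return None
    if sol.involved_rows(rs.unknown_rows, rows, tol):
        return None
    return _make_lump(
        rs, sol.alpha, group_index, list(group.members),
        f"LUMP_G{group_index}", tol,
    )


def sequential_lump(
    rs: ReducedSystem,
    group: MetaboliteGroup,
    group_index: int = 0,
    alpha_max: float = DEFAULT_ALPHA_MAX,
    integer_alpha: bool = False,
    tol: float = DEFAULT_TOL,
    log: LPLog | None = None,
) -> LumpRunResult:
    """Run the per-seed sequential iteration over every group member.

    Every member is used as a seed in model order, without skipping
    metabolites already eliminated by an earlier seed.  Per seed, the
    target set U' starts as {seed}; after each feasible solve that still
    involves other unknown metabolites, the smallest-index newly involved
    metabolite joins U' and the interim solution y is appended to the
    working matrix as a fresh column (with alpha_min 0).  Augmentations
    are discarded when moving to the next seed; accepted lumps are never
    fed back into R — they contain no unknown metabolites, so they cannot
    help eliminate any.
    """
    result = LumpRunResult()
    n_primitive = rs.n_cols
    for seed_row in group.member_rows:
        seed_met = rs.row_metabolites[seed_row]
        work_R = rs.R
        # primitive composition of each augmentation column
        aug_comp: list[np.ndarray] = []
        U_rows = {seed_row}
        for _ in range(MAX_SEQUENTIAL_ITERATIONS):
            problem = LumpProblem(
                R=work_R,
                U_rows=frozenset(U_rows),
                seed_rows=frozenset({seed_row}),
                alpha_max=alpha_max,
                integer_alpha=integer_alpha,
            )
            sol = _timed_solve(problem, result, "sequential")
            if log is not None:
                log(
                    phase="sequential", group=group_index, seed=seed_met,
                    U_size=len(U_rows),
                    status="infeasible" if sol is INFEASIBLE else "optimal",
                    objective=None if sol is INFEASIBLE else sol.objective,
                    duration=result.lp_durations[-1],
                )
            if sol is INFEASIBLE:
                break  # abandon this seed
            primitive = sol.alpha[:n_primitive].copy()
            for k, comp in enumerate(aug_comp):
                primitive += sol.alpha[n_primitive + k] * comp
            involved = sol.involved_rows(rs.unknown_rows, frozenset(U_rows), tol)
            if not involved:
                lump = _make_lump(
                    rs, primitive, group_index, [seed_met],
                    f"LUMP_S{group_index}_{seed_met}", tol,
                )
                result.lumps.append(lump)
                result.eliminated.add(seed_met)
                break
            U_rows.add(involved[0])  # smallest model index first
            work_R = np.hstack([work_R, sol.y.reshape(-1, 1)])
            aug_comp.append(primitive)
        else:
            raise SolverError(
                f"sequential iteration cap exceeded for seed {seed_met!r}"
            )
    return result


def combined_procedure(
    rs: ReducedSystem,
    groups: list[MetaboliteGroup],
    alpha_max: float = DEFAULT_ALPHA_MAX,
    integer_alpha: bool = False,
    tol: float = DEFAULT_TOL,
    log: LPLog | None = None,
) -> LumpRunResult:
    """Group implementation first, sequential fallback, per group.

    If the single group LP eliminates the whole group, all members are
    marked eliminated at the cost of one LP; otherwise every member is
    evaluated on its own by the sequential implementation.
    """
    result = LumpRunResult()
    for gi, group in enumerate(groups):
        lump = group_lump(
            rs, group, gi, alpha_max, integer_alpha, tol, result=result, log=log
        )
        if lump is not None:
            result.lumps.append(lump)
            result.eliminated |= set(group.members)
            result.groups_solved_by_group += 1
        else:
            result.infeasible_groups += 1
            result.merge(
                sequential_lump(rs, group, gi, alpha_max, integer_alpha, tol, log=log)
            )
    return result


def sequential_only(
    rs: ReducedSystem,
    groups: list[MetaboliteGroup],
    alpha_max: float = DEFAULT_ALPHA_MAX,
    integer_alpha: bool = False,
    tol: float = DEFAULT_TOL,
    log: LPLog | None = None,
) -> LumpRunResult:
    """Sequential implementation on every group, no group shortcut."""
    result = LumpRunResult()
    for gi, group in enumerate(groups):
        result.merge(
            sequential_lump(rs, group, gi, alpha_max, integer_alpha, tol, log=log)
        )
    return result


def naive_iterative(
    rs: ReducedSystem,
    alpha_max: float = DEFAULT_ALPHA_MAX,
    integer_alpha: bool = False,
    tol: float = DEFAULT_TOL,
    log: LPLog | None = None,
) -> LumpRunResult:
    """Baseline: per-metabolite sequential iteration, ignoring groups.

    Equivalent to the sequential-only mode over all groups — at least one
    LP is solved per unknown metabolite.
    """
    pseudo = MetaboliteGroup(
        members=[rs.row_metabolites[i] for i in rs.unknown_rows],
        member_rows=list(rs.unknown_rows),
        touched_cols=list(range(rs.n_cols)),
    )
    return sequential_lump(rs, pseudo, 0, alpha_max, integer_alpha, tol, log=log)
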