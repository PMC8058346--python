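"""Independent brute-force oracles used to cross-check the solvers."""

import itertools

import numpy as np


def grid_lump_oracle(R, U_rows, seed_rows, alpha_max=3, tol=1e-9):
    """Exhaustive search over integer combination coefficients.

    Enumerates every alpha in {amin_j, ..., alpha_max}^n, keeps those whose
    net stoichiometry vanishes on all of U, and returns the minimal sum of
    absolute net coefficients, or None if no grid point is feasible.
    """
    R = np.asarray(R, dtype=float)
    m, n = R.shape
    amin = np.zeros(n, dtype=int)
    for j in range(n):
        if any(abs(R[u, j]) > tol for u in seed_rows):
            amin[j] = 1
    best = None
    for alpha in itertools.product(*(range(amin[j], alpha_max + 1) for j in range(n))):
        y = R @ np.array(alpha, dtype=float)
        if all(abs(y[u]) <= tol for u in U_rows):
            obj = float(np.abs(y).sum())
            if best is None or obj < best:
                best = obj
    return best


def transitive_partition_oracle(R, unknown_rows, tol=1e-9):
    """Group unknown rows by repeated pairwise merging over shared columns."""
    R = np.asarray(R, dtype=float)
    groups = [{u} for u in unknown_rows]
    changed = True
    while changed:
        changed = False
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                share = any(
                    any(abs(R[u, j]) > tol for u in groups[a])
                    and any(abs(R[v, j]) > tol for v in groups[b])
                    for j in range(R.shape[1])
                )
                if share:
                    groups[a] |= groups[b]
                    del groups[b]
                    changed = True
                    break
            if changed:
                break
    return sorted((frozenset(g) for g in groups), key=min)
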