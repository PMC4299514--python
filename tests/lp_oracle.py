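"""Independent exact-arithmetic LP oracle for small fixtures.

Solves ``max / min  c @ v  s.t.  A v = b,  lb <= v <= ub`` by brute-force
vertex enumeration over exact rationals: every basic feasible solution is
obtained by fixing ``n - rank(A)`` variables at one of their bounds and
solving the remaining square system with fraction-exact Gaussian
elimination.  Intended for networks with at most ~12 reactions; entirely
independent of the package's scipy-based solver, so it can serve as the
ground-truth oracle in tests.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from typing import List, Optional, Sequence, Tuple

__all__ = ["solve_lp_exact", "fba_exact", "min_at_fixed_exact"]


def _frac(x) -> Fraction:
    return x if isinstance(x, Fraction) else Fraction(x).limit_denominator(10**12)


def _rref(rows: List[List[Fraction]]) -> Tuple[List[List[Fraction]], List[int]]:
    """Reduced row echelon form; returns (matrix, pivot column indices)."""
    mat = [row[:] for row in rows]
    m = len(mat)
    ncol = len(mat[0]) if m else 0
    pivots: List[int] = []
    r = 0
    for c in range(ncol):
        pivot = next((i for i in range(r, m) if mat[i][c] != 0), None)
        if pivot is None:
            continue
        mat[r], mat[pivot] = mat[pivot], mat[r]
        inv = Fraction(1, 1) / mat[r][c]
        mat[r] = [v * inv for v in mat[r]]
        for i in range(m):
            if i != r and mat[i][c] != 0:
                f = mat[i][c]
                mat[i] = [a - f * bb for a, bb in zip(mat[i], mat[r])]
        pivots.append(c)
        r += 1
        if r == m:
            break
    return mat[:r], pivots


def _solve_square(A: List[List[Fraction]], b: List[Fraction]) -> Optional[List[Fraction]]:
    """Solve a (consistent, possibly rank-deficient) exact linear system;
    None if inconsistent or under-determined."""
    n = len(A[0]) if A else 0
    aug = [row[:] + [rhs] for row, rhs in zip(A, b)]
    red, pivots = _rref(aug)
    for row in red:
        if all(v == 0 for v in row[:-1]) and row[-1] != 0:
            return None
    if len(pivots) < n or any(p >= n for p in pivots):
        # under-determined or pivot in the rhs column
        if any(p == n for p in pivots):
            return None
        if len([p for p in pivots if p < n]) < n:
            return None
    x = [Fraction(0)] * n
    for row, p in zip(red, pivots):
        x[p] = row[-1]
    return x


def solve_lp_exact(
    A: Sequence[Sequence],
    b: Sequence,
    lb: Sequence,
    ub: Sequence,
    c: Sequence,
    sense: str = "max",
) -> Optional[Fraction]:
    """Optimal value by vertex enumeration; None if infeasible."""
    A = [[_frac(v) for v in row] for row in A]
    b = [_frac(v) for v in b]
    lb = [_frac(v) for v in lb]
    ub = [_frac(v) for v in ub]
    c = [_frac(v) for v in c]
    n = len(lb)
    _, pivots = _rref([row[:] for row in A])
    rank = len(pivots)
    k = n - rank  # number of variables fixed at bounds per vertex
    best: Optional[Fraction] = None
    for free in itertools.combinations(range(n), k):
        free_set = set(free)
        basic = [j for j in range(n) if j not in free_set]
        for choice in itertools.product((0, 1), repeat=k):
            fixed_vals = {j: (ub[j] if pick else lb[j]) for j, pick in zip(free, choice)}
            rhs = [
                bi - sum(row[j] * fixed_vals[j] for j in free)
                for row, bi in zip(A, b)
            ]
            sub = [[row[j] for j in basic] for row in A]
            sol = _solve_square(sub, rhs)
            if sol is None:
                continue
            v = [Fraction(0)] * n
            for j, val in fixed_vals.items():
                v[j] = val
            for j, val in zip(basic, sol):
                v[j] = val
            if any(vj < lb[j] or vj > ub[j] for j, vj in enumerate(v)):
                continue
            obj = sum(ci * vi for ci, vi in zip(c, v))
            if best is None or (sense == "max" and obj > best) or (sense == "min" and obj < best):
                best = obj
    return best


def _model_arrays(model):
    rids = model.reaction_ids
    S = [[Fraction(0)] * len(rids) for _ in model.metabolites]
    met_idx = {m.id: i for i, m in enumerate(model.metabolites)}
    for j, r in enumerate(model.reactions):
        for met, coeff in r.stoichiometry.items():
            S[met_idx[met]][j] = _frac(coeff)
    lb = [_frac(r.lower_bound) for r in model.reactions]
    ub = [_frac(r.upper_bound) for r in model.reactions]
    return rids, S, lb, ub


def fba_exact(model, target: Optional[str] = None, sense: str = "max") -> Optional[Fraction]:
    """Exact FBA optimum of a StoichiometricModel via vertex enumeration."""
    rids, S, lb, ub = _model_arrays(model)
    target = target or model.objective_reaction
    c = [Fraction(1) if rid == target else Fraction(0) for rid in rids]
    return solve_lp_exact(S, [Fraction(0)] * len(S), lb, ub, c, sense)


def min_at_fixed_exact(model, target: str, fixed: dict, sense: str = "min") -> Optional[Fraction]:
    """Exact extremum of *target* with other reactions pinned to exact values."""
    rids, S, lb, ub = _model_arrays(model)
    for rid, value in fixed.items():
        j = rids.index(rid)
        lb[j] = ub[j] = _frac(value)
    c = [Fraction(1) if rid == target else Fraction(0) for rid in rids]
    return solve_lp_exact(S, [Fraction(0)] * len(S), lb, ub, c, sense)
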