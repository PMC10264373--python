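"""Self-contained tableau simplex for flux-cone LPs.

The extraction algorithm needs more than an optimal flux vector: it reads
the final simplex tableau and performs additional pivots to walk to
adjacent vertices of the constrained flux cone.  Library solvers do not
expose their tableau in a portable way, so a small dense two-phase simplex
with Bland's anti-cycling rule lives here.  All problems have the shape

    optimise  f = sum_i a_i v[i]
    s.t.      S v = 0
              sum_{i in T1} v[i] = 1     (optional positive seed)
              sum_{i in T2} v[i] = 0     (optional negative seed)
              v >= 0

With a positive seed, non-negative costs and minimisation, any optimal
basic solution is a vertex of the sliced cone and therefore (after
scaling) an elementary flux mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .network import MetabolicNetwork

__all__ = [
    "LPProblem",
    "SimplexState",
    "SimplexError",
    "build_lp",
    "solve",
    "pivot_neighbors",
]

ZERO_TOL = 1e-9
FEAS_TOL = 1e-7


class SimplexError(ArithmeticError):
    """Numerical failure inside the simplex (cycling guard, bad pivot)."""


@dataclass
class LPProblem:
    net: MetabolicNetwork
    objective: np.ndarray  # per-reaction coefficients a_i
    sense: str = "min"  # min | max
    positive_seed: Optional[frozenset[str]] = None  # sum_{T1} v = 1
    negative_seed: Optional[frozenset[str]] = None  # sum_{T2} v = 0

    def __post_init__(self) -> None:
        self.objective = np.asarray(self.objective, dtype=float)
        if self.objective.shape != (self.net.n_reactions,):
            raise ValueError("objective length must equal number of reactions")
        if not np.all(np.isfinite(self.objective)):
            raise ValueError("objective coefficients must be finite")
        if self.sense not in ("min", "max"):
            raise ValueError("sense must be 'min' or 'max'")
        if self.positive_seed is not None:
            self.positive_seed = frozenset(self.positive_seed)
            if not self.positive_seed:
                raise ValueError(
                    "positive seed must be non-empty: sum over the empty set "
                    "can never equal 1"
                )
        if self.negative_seed is not None:
            self.negative_seed = frozenset(self.negative_seed)


@dataclass
class SimplexState:
    """Final state of a solved LP supporting post-optimal pivoting.

    ``tableau`` rows are the constraint system with the basis inverse
    applied; the last column is the right-hand side.  ``basis`` lists the
    basic variable indices (J1) row by row; ``nonbasic`` is the
    complementary set J2 over structural (reaction) variables.
    """

    tableau: np.ndarray
    basis: list[int]
    nonbasic: set[int]
    status: str  # optimal | infeasible | unbounded
    solution: np.ndarray
    objective_value: float
    n_structural: int


def build_lp(
    net: MetabolicNetwork,
    objective: np.ndarray | Iterable[float],
    positive_seed: Optional[Iterable[str]] = None,
    negative_seed: Optional[Iterable[str]] = None,
    sense: str = "min",
) -> LPProblem:
    """Assemble a flux-cone LP with optional positive/negative seeds."""
    pos = frozenset(positive_seed) if positive_seed is not None else None
    neg = frozenset(negative_seed) if negative_seed is not None else None
    if pos is not None:
        unknown = pos - set(net.reaction_ids)
        if unknown:
            raise KeyError(f"unknown reactions in positive seed: {sorted(unknown)}")
    if neg is not None:
        unknown = neg - set(net.reaction_ids)
        if unknown:
            raise KeyError(f"unknown reactions in negative seed: {sorted(unknown)}")
    return LPProblem(
        net=net,
        objective=np.asarray(list(objective), dtype=float),
        sense=sense,
        positive_seed=pos,
        negative_seed=neg,
    )


def _assemble(lp: LPProblem) -> tuple[np.ndarray, np.ndarray]:
    net = lp.net
    rows = [net.S]
    rhs = [np.zeros(net.n_metabolites)]
    if lp.positive_seed is not None:
        row = np.zeros(net.n_reactions)
        for rid in lp.positive_seed:
            row[net.reaction_index(rid)] = 1.0
        rows.append(row[None, :])
        rhs.append(np.array([1.0]))
    if lp.negative_seed is not None:
        row = np.zeros(net.n_reactions)
        for rid in lp.negative_seed:
            row[net.reaction_index(rid)] = 1.0
        rows.append(row[None, :])
        rhs.append(np.array([0.0]))
    return np.vstack(rows), np.concatenate(rhs)


def _pivot(T: np.ndarray, basis: list[int], row: int, col: int) -> None:
    T[row] /= T[row, col]
    piv = T[row]
    for i in range(T.shape[0]):
        if i != row and abs(T[i, col]) > 0.0:
            T[i] -= T[i, col] * piv
    basis[row] = col


def _run_phase(
    T: np.ndarray,
    basis: list[int],
    allowed: np.ndarray,
    max_iter: int,
) -> str:
    """Bland-rule simplex on a tableau whose last row holds reduced costs."""
    m = T.shape[0] - 1
    for _ in range(max_iter):
        red = T[-1, :-1]
        enter = -1
        for j in np.flatnonzero(allowed):
            if red[j] < -ZERO_TOL:
                enter = int(j)
                break
        if enter < 0:
            return "optimal"
        col = T[:m, enter]
        rows = np.flatnonzero(col > ZERO_TOL)
        if rows.size == 0:
            return "unbounded"
        ratios = T[rows, -1] / col[rows]
        rmin = ratios.min()
        ties = rows[ratios <= rmin + 1e-10]
        leave = int(min(ties, key=lambda i: basis[i]))
        _pivot(T, basis, leave, enter)
    raise SimplexError("simplex iteration guard exceeded (cycling?)")


def solve(lp: LPProblem, max_iter: int = 200_000) -> SimplexState:
    """Two-phase dense simplex with Bland's rule; deterministic.

    Artificial variables carry phase 1 and never re-enter; rows whose
    artificial cannot be driven out are redundant and are dropped, so the
    returned tableau always has a structural basis.
    """
    A, b = _assemble(lp)
    m, n = A.shape
    c = lp.objective.copy()
    if lp.sense == "max":
        c = -c

    # phase 1 tableau: [A | I | b] with b made non-negative
    T = np.zeros((m + 1, n + m + 1))
    T[:m, :n] = A
    T[:m, -1] = b
    flip = T[:m, -1] < 0
    T[:m][flip] *= -1.0
    T[:m, n : n + m] = np.eye(m)
    basis = list(range(n, n + m))
    # reduced costs of phase-1 objective (sum of artificials)
    T[-1, n : n + m] = 1.0
    for i in range(m):
        T[-1] -= T[i]
    allowed = np.zeros(n + m, dtype=bool)
    allowed[:n] = True  # artificials never (re-)enter
    status = _run_phase(T, basis, allowed, max_iter)
    if status != "optimal":  # pragma: no cover - phase 1 is always bounded
        raise SimplexError("phase 1 terminated " + status)
    if -T[-1, -1] > FEAS_TOL:
        return SimplexState(
            tableau=T[:m],
            basis=basis,
            nonbasic=set(range(n)) - set(basis),
            status="infeasible",
            solution=np.zeros(n),
            objective_value=float("nan"),
            n_structural=n,
        )

    # drive artificials out of the basis; all-zero structural rows are
    # redundant constraints and are removed
    drop_rows: list[int] = []
    for i in range(m):
        if basis[i] >= n:
            structural = np.flatnonzero(np.abs(T[i, :n]) > ZERO_TOL)
            if structural.size:
                _pivot(T, basis, i, int(structural[0]))
            else:
                drop_rows.append(i)
    if drop_rows:
        keep = [i for i in range(m) if i not in drop_rows]
        T = T[keep + [m]]
        basis = [basis[i] for i in keep]
        m = len(keep)

    # phase 2: strip artificial columns, install the real objective
    T2 = np.zeros((m + 1, n + 1))
    T2[:m, :n] = T[:m, :n]
    T2[:m, -1] = T[:m, -1]
    T2[-1, :n] = c
    for i in range(m):
        cb = c[basis[i]]
        if cb != 0.0:
            T2[-1] -= cb * T2[i]
    allowed2 = np.ones(n, dtype=bool)
    status = _run_phase(T2, basis, allowed2, max_iter)

    x = np.zeros(n)
    for i, bi in enumerate(basis):
        x[bi] = T2[i, -1]
    x[np.abs(x) < ZERO_TOL] = 0.0
    obj = float(lp.objective @ x)
    return SimplexState(
        tableau=T2[:m],
        basis=list(basis),
        nonbasic=set(range(n)) - set(basis),
        status="optimal" if status == "optimal" else status,
        solution=x,
        objective_value=obj,
        n_structural=n,
    )


def pivot_neighbors(
    state: SimplexState,
    explore_degenerate: bool = True,
    max_bases: int = 500,
) -> list[np.ndarray]:
    """Feasible adjacent vertices reachable by one pivot of the tableau.

    For each nonbasic variable j2, entering j2 moves along an edge of the
    feasible polytope; the minimum-ratio test names the basic variables j1
    whose rows can leave while keeping feasibility, and each such (j1, j2)
    exchange yields an adjacent basic solution.  Edges with no blocking
    row are unbounded rays and yield nothing.  Results are deduplicated by
    support and never include the current vertex.

    At a degenerate vertex some edges are invisible from the basis the
    simplex happens to hold: a zero-ratio pivot changes the basis without
    leaving the vertex, and different bases expose different edges.  With
    ``explore_degenerate`` (the default) those zero-ratio pivots are
    traversed, enumerating up to ``max_bases`` bases of the current vertex
    and collecting neighbours from each, so the result is the adjacency of
    the *vertex* rather than of one arbitrary basis.  With it off, only
    the held tableau is pivoted (at most |J1|x|J2| candidates).
    """
    if state.status != "optimal":
        raise ValueError("pivot_neighbors requires an optimal state")
    n = state.n_structural
    cur = state.solution
    cur_support = frozenset(np.flatnonzero(cur > FEAS_TOL * max(1.0, cur.max())))
    out: dict[frozenset[int], np.ndarray] = {}
    seen_bases: set[frozenset[int]] = set()
    stack: list[tuple[np.ndarray, list[int]]] = [
        (state.tableau, list(state.basis))
    ]
    while stack:
        T, basis = stack.pop()
        key = frozenset(basis)
        if key in seen_bases:
            continue
        seen_bases.add(key)
        m = T.shape[0]
        rhs = T[:, -1]
        basis_set = set(basis)
        for j2 in range(n):
            if j2 in basis_set:
                continue
            col = T[:m, j2]
            rows = np.flatnonzero(col > ZERO_TOL)
            if rows.size == 0:
                continue  # unbounded edge, no adjacent vertex this way
            ratios = rhs[rows] / col[rows]
            theta = ratios.min()
            if theta <= 1e-10:
                # zero-ratio pivot: same vertex, different basis
                if explore_degenerate and len(seen_bases) < max_bases:
                    for r in rows[ratios <= 1e-10]:
                        T2 = T.copy()
                        b2 = list(basis)
                        _pivot(T2, b2, int(r), j2)
                        if frozenset(b2) not in seen_bases:
                            stack.append((T2, b2))
                continue
            # all min-ratio rows lead to the same adjacent vertex (only
            # its basis differs), so one solution per entering column
            x = np.zeros(n)
            for i, bi in enumerate(basis):
                x[bi] = rhs[i] - theta * col[i]
            x[j2] = theta
            x[np.abs(x) < ZERO_TOL] = 0.0
            if x.max() <= 0.0:
                continue
            supp = frozenset(np.flatnonzero(x > FEAS_TOL * x.max()))
            if supp != cur_support and supp not in out:
                out[supp] = x
    return list(out.values())
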