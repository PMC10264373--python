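"""Exact enumeration of all EFMs for small-to-medium networks.

Two independent routes to the complete EFM set serve as ground truth for
the biased extractor:

* :func:`enumerate_ddm` — the double description method on the flux cone
  {S v = 0, v >= 0}, run in exact rational arithmetic: start from the
  extreme rays of the non-negative orthant and intersect with one
  steady-state hyperplane at a time, combining positive/negative ray pairs
  and keeping only rays with minimal support.
* :func:`enumerate_bruteforce` — direct application of the rank
  characterisation: every candidate support whose stoichiometric submatrix
  has rank |support| - 1 and admits a strictly positive kernel vector is an
  EFM.  Exponential in the reaction count, hence guarded, but maximally
  simple — it shares no code path with the DDM.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

import numpy as np

from .efm import EFM, EFMCollection, canonicalize, is_futile_pair
from .network import MetabolicNetwork

__all__ = ["EnumerationResult", "enumerate_ddm", "enumerate_bruteforce"]

BRUTEFORCE_GUARD = 22  # 2^22 supports is the most we will ever sweep


@dataclass
class EnumerationResult:
    efms: EFMCollection  # complete, in the method's deterministic order
    method: str  # nullspace_ddm | support_bruteforce
    certified_max_size: float  # largest support size guaranteed enumerated

    def supports(self) -> set[frozenset[str]]:
        return self.efms.supports()

    def __len__(self) -> int:
        return len(self.efms)


class RayExplosionError(RuntimeError):
    """DDM intermediate ray count exceeded the configured cap."""


def _as_fraction_matrix(S: np.ndarray) -> list[list[Fraction]]:
    return [[Fraction(x).limit_denominator(10**9) for x in row] for row in S]


def _primitive(ray: list[Fraction]) -> tuple[Fraction, ...]:
    """Scale a rational ray to a primitive integer vector (gcd 1)."""
    den = math.lcm(*(f.denominator for f in ray)) if ray else 1
    ints = [int(f * den) for f in ray]
    g = math.gcd(*ints) if any(ints) else 1
    return tuple(Fraction(v, g) for v in ints)


def enumerate_ddm(
    net: MetabolicNetwork,
    max_rays: int = 200_000,
    include_futile: bool = True,
) -> EnumerationResult:
    """Complete EFM enumeration by the double description method.

    Constraint rows are processed in the order minimising the number of
    positive/negative ray pair combinations at each step (a standard
    heuristic).  Exact Fraction arithmetic keeps the adjacency filtering
    free of tolerance choices.  ``include_futile`` controls whether the
    two-cycle artifacts of split reversible reactions are kept.
    """
    n = net.n_reactions
    rows = _as_fraction_matrix(net.S)
    # rays of the non-negative orthant: the unit vectors
    rays: list[tuple[Fraction, ...]] = [
        tuple(Fraction(int(i == j)) for j in range(n)) for i in range(n)
    ]
    pending = list(range(len(rows)))
    while pending:
        # cheapest row first: fewest pos*neg combinations
        def cost(ri: int) -> int:
            row = rows[ri]
            pos = neg = 0
            for ray in rays:
                d = sum(c * x for c, x in zip(row, ray) if x)
                if d > 0:
                    pos += 1
                elif d < 0:
                    neg += 1
            return pos * neg

        ri = min(pending, key=cost)
        pending.remove(ri)
        row = rows[ri]
        dots = [sum(c * x for c, x in zip(row, ray) if x) for ray in rays]
        zero = [r for r, d in zip(rays, dots) if d == 0]
        pos = [(r, d) for r, d in zip(rays, dots) if d > 0]
        neg = [(r, d) for r, d in zip(rays, dots) if d < 0]
        combined: list[tuple[Fraction, ...]] = []
        for (rp, dp), (rn, dn) in itertools.product(pos, neg):
            new = _primitive(
                [dp * xn - dn * xp for xp, xn in zip(rp, rn)]
            )
            combined.append(new)
        # keep only support-minimal rays (adjacency filtering)
        candidates = zero + combined
        supports = [frozenset(i for i, x in enumerate(r) if x) for r in candidates]
        keep: list[tuple[Fraction, ...]] = []
        seen: set[frozenset[int]] = set()
        for idx, (ray, supp) in enumerate(zip(candidates, supports)):
            if supp in seen:
                continue
            minimal = True
            for jdx, other in enumerate(supports):
                if jdx != idx and other < supp:
                    minimal = False
                    break
            if minimal:
                seen.add(supp)
                keep.append(ray)
        rays = keep
        if len(rays) > max_rays:
            raise RayExplosionError(
                f"intermediate ray count {len(rays)} exceeds cap {max_rays}"
            )

    collection = EFMCollection(net, keep_futile_pairs=include_futile)
    for ray in sorted(rays, key=lambda r: tuple(float(x) for x in r)):
        v = np.array([float(x) for x in ray])
        collection.add(canonicalize(v, net.reaction_ids))
    return EnumerationResult(
        efms=collection, method="nullspace_ddm", certified_max_size=math.inf
    )


def enumerate_bruteforce(
    net: MetabolicNetwork,
    max_support: Optional[int] = None,
    include_futile: bool = True,
) -> EnumerationResult:
    """Sweep candidate supports and apply the rank test directly.

    A support T qualifies iff rank(S[:, T]) = |T| - 1 and the 1-dimensional
    kernel of that submatrix contains a vector strictly positive on all of
    T (after a global sign flip).  By the rank characterisation these are
    exactly the EFM supports, so no minimality post-filter is needed.
    """
    n = net.n_reactions
    if max_support is None:
        max_support = n
    if n > BRUTEFORCE_GUARD and max_support >= n:
        raise RuntimeError(
            f"bruteforce guard: {n} reactions > {BRUTEFORCE_GUARD}; "
            "bound max_support or use enumerate_ddm"
        )
    found: list[np.ndarray] = []
    idx_all = range(n)
    for k in range(1, max_support + 1):
        for cols in itertools.combinations(idx_all, k):
            sub = net.S[:, cols]
            rows = np.flatnonzero(np.any(sub != 0.0, axis=1))
            A = sub[rows]
            if A.size == 0:
                rank = 0
                if k != 1:
                    continue
                # empty submatrix: a single reaction touching no internal
                # metabolite is itself an EFM of length 1
                v = np.zeros(n)
                v[cols[0]] = 1.0
                found.append(v)
                continue
            u, s, vt = np.linalg.svd(A)
            rank = int(np.sum(s > 1e-9 * s[0]))
            if rank != k - 1:
                continue
            kernel = vt[-1]  # 1-dim nullspace of A
            if np.max(np.abs(kernel)) == 0.0:
                continue
            kernel = kernel * np.sign(kernel[np.argmax(np.abs(kernel))])
            if np.min(kernel) <= 1e-9 * np.max(kernel):
                continue  # mixed sign or a zero entry: not a mode on all of T
            v = np.zeros(n)
            v[list(cols)] = kernel
            found.append(v)
    collection = EFMCollection(net, keep_futile_pairs=include_futile)
    for v in found:
        collection.add(canonicalize(v, net.reaction_ids))
    return EnumerationResult(
        efms=collection,
        method="support_bruteforce",
        certified_max_size=float(max_support),
    )
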