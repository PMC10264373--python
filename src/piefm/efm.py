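"""Elementary flux modes: canonical form, rank-test verification, collections.

An elementary flux mode (EFM) is a steady-state, sign-feasible flux vector
whose support is minimal.  The algebraic characterisation used throughout:
a mode v with support of size k is elementary iff the submatrix of S
restricted to the support columns has rank k - 1.  That theorem also makes
the support a sound identity key — the solution space over a fixed
elementary support is one-dimensional, so two EFMs with equal support are
equal up to scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .network import MetabolicNetwork

__all__ = [
    "EFM",
    "EFMCollection",
    "support_of",
    "is_efm",
    "canonicalize",
    "is_futile_pair",
    "write_efms",
    "read_efms",
]

SUPPORT_TOL = 1e-7  # on the canonical (max = 1) scale
RANK_RTOL = 1e-9  # singular values > RANK_RTOL * s_max count toward rank


@dataclass(frozen=True)
class EFM:
    flux: tuple[float, ...]  # canonical scale, max component = 1
    support: frozenset[str]

    @property
    def length(self) -> int:
        return len(self.support)

    def flux_array(self) -> np.ndarray:
        return np.asarray(self.flux)


def support_of(
    v: np.ndarray | Sequence[float],
    reaction_ids: Sequence[str],
    tol: float = SUPPORT_TOL,
) -> frozenset[str]:
    """Reactions carrying flux above ``tol`` (absolute, caller's scale)."""
    v = np.asarray(v, dtype=float)
    if np.any(v < -tol):
        raise ValueError("flux vector has a negative component")
    return frozenset(reaction_ids[i] for i in np.flatnonzero(v > tol))


def is_efm(
    net: MetabolicNetwork,
    v: np.ndarray | Sequence[float],
    tol: float = SUPPORT_TOL,
) -> bool:
    """Rank test for elementarity of a steady-state mode.

    Restricts S to the support columns (and to metabolite rows occurring in
    them) and checks rank == |support| - 1.  Scale-invariant.
    """
    v = np.asarray(v, dtype=float)
    if not np.any(v > 0):
        raise ValueError("the zero vector is not a mode")
    vmax = v.max()
    cols = np.flatnonzero(v > tol * vmax)
    k = cols.size
    sub = net.S[:, cols]
    rows = np.flatnonzero(np.any(sub != 0.0, axis=1))
    sub = sub[rows]
    if sub.size == 0:
        rank = 0
    else:
        s = np.linalg.svd(sub, compute_uv=False)
        rank = int(np.sum(s > RANK_RTOL * s[0]))
    return rank == k - 1


def canonicalize(
    v: np.ndarray | Sequence[float], reaction_ids: Sequence[str]
) -> EFM:
    """Scale a verified mode so its maximum component is 1; record support."""
    v = np.asarray(v, dtype=float).copy()
    vmax = v.max()
    if vmax <= 0:
        raise ValueError("cannot canonicalize the zero vector")
    v /= vmax
    v[v < SUPPORT_TOL] = 0.0
    support = frozenset(
        reaction_ids[i] for i in np.flatnonzero(v > SUPPORT_TOL)
    )
    return EFM(flux=tuple(float(x) for x in v), support=support)


def is_futile_pair(net: MetabolicNetwork, efm: EFM) -> bool:
    """True for the two-cycle artifact of one split reversible reaction.

    The forward/backward pair of a split reaction passes the rank test
    (rank([c, -c]) = 1 = 2 - 1) yet carries no net conversion; it exists
    only because of the decoupling and is excluded from collections by
    default.
    """
    if len(efm.support) != 2:
        return False
    idx = [net.reaction_index(r) for r in efm.support]
    o1, o2 = net.origin[idx[0]], net.origin[idx[1]]
    return (
        o1.original_id == o2.original_id
        and {o1.direction, o2.direction} == {"forward", "backward"}
    )


@dataclass
class EFMCollection:
    """Ordered multiset of EFMs keyed by support.

    Keeps discovery order, an occurrence count per EFM (how many times the
    extractor re-computed it) and an explored flag used by the expansion
    queue.  Futile two-cycles are rejected on ``add`` unless
    ``keep_futile_pairs`` is set.
    """

    net: MetabolicNetwork
    keep_futile_pairs: bool = False
    efms: list[EFM] = field(default_factory=list)
    occurrences: list[int] = field(default_factory=list)
    explored: list[bool] = field(default_factory=list)
    _index: dict[frozenset[str], int] = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.efms)

    def __iter__(self) -> Iterator[EFM]:
        return iter(self.efms)

    def __contains__(self, support: frozenset[str]) -> bool:
        return frozenset(support) in self._index

    def index_of(self, support: Iterable[str]) -> int:
        return self._index[frozenset(support)]

    def add(self, efm: EFM) -> bool:
        """Store an EFM, or bump its occurrence count; True iff new."""
        if not self.keep_futile_pairs and is_futile_pair(self.net, efm):
            return False
        i = self._index.get(efm.support)
        if i is not None:
            self.occurrences[i] += 1
            return False
        self._index[efm.support] = len(self.efms)
        self.efms.append(efm)
        self.occurrences.append(1)
        self.explored.append(False)
        return True

    def supports(self) -> set[frozenset[str]]:
        return set(self._index)

    def lengths(self) -> list[int]:
        return [e.length for e in self.efms]


# ---------------------------------------------------------------------------
# interchange format: one EFM per row, support reaction ids tab-separated;
# flux values (canonical scale) in an optional JSON sidecar
# ---------------------------------------------------------------------------


def write_efms(
    efms: Iterable[EFM],
    path: str | Path,
    reaction_ids: Optional[Sequence[str]] = None,
    flux_json: Optional[str | Path] = None,
    header: Optional[str] = None,
) -> None:
    path = Path(path)
    efms = list(efms)
    lines = []
    if header:
        for h in header.splitlines():
            lines.append(f"# {h}")
    for e in efms:
        lines.append("\t".join(sorted(e.support)))
    path.write_text("\n".join(lines) + "\n")
    if flux_json is not None:
        if reaction_ids is None:
            raise ValueError("flux sidecar needs reaction_ids for alignment")
        payload = [
            {
                reaction_ids[i]: e.flux[i]
                for i in range(len(e.flux))
                if e.flux[i] > 0.0
            }
            for e in efms
        ]
        Path(flux_json).write_text(json.dumps(payload))


def read_efms(path: str | Path) -> list[frozenset[str]]:
    """Read supports from the interchange TSV (discovery order preserved)."""
    out: list[frozenset[str]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.append(frozenset(line.split("\t")))
    return out
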