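"""Representativeness and stability metrics for extracted EFM sets.

A biased extractor yields a subset E' of the full EFM set E.  Whether E'
is *representative* for a parameter (mean support length, or the
per-reaction proportion p(r) of EFMs containing r) can only be checked
when E is available; *stability* — agreement of the parameter between two
prefixes of the same extraction stream — can always be checked and is a
necessary (not sufficient) condition for representativeness.  The central
comparison statistic is the mean relative error

    mre(p_est, p_ref) = mean over r of |p_est(r) - p_ref(r)| / p_ref(r)

taken over the non-blocked reactions with p_ref(r) > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .efm import EFM

__all__ = [
    "ParameterTrace",
    "ProportionMap",
    "mean_length_trace",
    "reaction_proportions",
    "mre",
    "relative_errors",
    "stability_trace",
    "stopping_index",
    "compatible_reactions",
    "coupled_classes",
    "drop_coupled",
    "simulate_k_extreme",
    "jaccard_trace",
    "pearson_proportions",
]

SupportLike = frozenset  # EFMs or bare support sets are both accepted


def _supports(efms: Sequence) -> list[frozenset[str]]:
    return [e.support if isinstance(e, EFM) else frozenset(e) for e in efms]


@dataclass
class ParameterTrace:
    """A parameter evaluated on growing prefixes of an extraction stream."""

    checkpoints: list[int]
    values: list[float]

    def __post_init__(self) -> None:
        if len(self.checkpoints) != len(self.values):
            raise ValueError("checkpoints and values must align")
        if any(
            b <= a for a, b in zip(self.checkpoints, self.checkpoints[1:])
        ):
            raise ValueError("checkpoints must be strictly increasing")

    def to_frame(self, name: str = "value") -> pd.DataFrame:
        return pd.DataFrame({"k": self.checkpoints, name: self.values})


@dataclass
class ProportionMap:
    """Per-reaction fraction of EFMs whose support contains the reaction."""

    values: dict[str, float]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        for r, p in self.values.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"proportion out of [0,1] for {r!r}: {p}")

    def __getitem__(self, r: str) -> float:
        return self.values.get(r, 0.0)


def default_checkpoints(n: int, step: int = 500) -> list[int]:
    """Every ``step`` EFMs, always including the final count."""
    ks = list(range(step, n + 1, step))
    if not ks or ks[-1] != n:
        ks.append(n)
    return ks


def mean_length_trace(
    efms: Sequence, checkpoints: Optional[Iterable[int]] = None
) -> ParameterTrace:
    """Mean support length over the first k EFMs, per checkpoint."""
    lengths = np.array([len(s) for s in _supports(efms)], dtype=float)
    ks = list(checkpoints) if checkpoints is not None else list(
        range(1, len(lengths) + 1)
    )
    csum = np.cumsum(lengths)
    return ParameterTrace(ks, [float(csum[k - 1] / k) for k in ks])


def reaction_proportions(
    efms: Sequence, universe: Iterable[str]
) -> ProportionMap:
    supports = _supports(efms)
    if not supports:
        raise ValueError("cannot compute proportions of an empty EFM list")
    uni = frozenset(universe)
    counts = {r: 0 for r in uni}
    for s in supports:
        for r in s & uni:
            counts[r] += 1
    n = len(supports)
    return ProportionMap({r: c / n for r, c in counts.items()}, uni)


def relative_errors(
    p_est: ProportionMap | Mapping[str, float],
    p_ref: ProportionMap | Mapping[str, float],
    universe: Iterable[str],
) -> dict[str, float]:
    """|p_est(r) - p_ref(r)| / p_ref(r) per reaction; requires p_ref > 0."""
    est = p_est.values if isinstance(p_est, ProportionMap) else dict(p_est)
    ref = p_ref.values if isinstance(p_ref, ProportionMap) else dict(p_ref)
    out: dict[str, float] = {}
    for r in universe:
        pr = ref.get(r, 0.0)
        if pr <= 0.0:
            raise ValueError(
                f"reference proportion is zero for {r!r}; exclude it from "
                "the universe"
            )
        out[r] = abs(est.get(r, 0.0) - pr) / pr
    return out


def mre(
    p_est: ProportionMap | Mapping[str, float],
    p_ref: ProportionMap | Mapping[str, float],
    universe: Iterable[str],
) -> float:
    """Mean relative error of estimated vs reference proportions."""
    errs = relative_errors(p_est, p_ref, universe)
    if not errs:
        raise ValueError("empty universe")
    return float(np.mean(list(errs.values())))


def stability_trace(
    efms: Sequence,
    d: int,
    checkpoints: Optional[Iterable[int]] = None,
    universe: Optional[Iterable[str]] = None,
) -> ParameterTrace:
    """Self-comparison of proportions d extraction steps apart.

    The value at checkpoint k is mre(p_k, p_{k-d}) where p_k is computed on
    the first k EFMs of the stream; reactions with p_{k-d}(r) = 0 are
    dropped from that checkpoint's average.  Defined for k >= 2d so the
    reference prefix is never shorter than the offset.
    """
    supports = _supports(efms)
    if d < 1:
        raise ValueError("offset d must be >= 1")
    uni = (
        frozenset(universe)
        if universe is not None
        else frozenset().union(*supports)
    )
    if checkpoints is None:
        ks = [k for k in default_checkpoints(len(supports)) if k >= 2 * d]
    else:
        ks = [k for k in checkpoints]
        if any(k < 2 * d for k in ks):
            raise ValueError("stability checkpoints must satisfy k >= 2d")
    values = []
    for k in ks:
        p_k = reaction_proportions(supports[:k], uni)
        p_ref = reaction_proportions(supports[: k - d], uni)
        active = [r for r in uni if p_ref[r] > 0.0]
        values.append(mre(p_k, p_ref, active))
    return ParameterTrace(ks, values)


def stopping_index(
    stability: ParameterTrace,
    threshold: float = 0.05,
    consecutive: int = 3,
) -> Optional[int]:
    """First checkpoint opening a run of ``consecutive`` values < threshold.

    Interpreted as the point from which the extraction could stop: the
    self-comparison error has stayed below the line for an uninterrupted
    run.  None when no such run exists.
    """
    if consecutive < 1:
        raise ValueError("consecutive must be >= 1")
    vals = stability.values
    run = 0
    for i, v in enumerate(vals):
        run = run + 1 if v < threshold else 0
        if run >= consecutive:
            return stability.checkpoints[i - consecutive + 1]
    return None


def compatible_reactions(efms: Sequence, r: str) -> frozenset[str]:
    """Union of supports of all EFMs containing r (variability measure).

    Two reactions are compatible when some EFM contains both; the set of
    reactions compatible with a fixed anchor (typically biomass) summarises
    how much of the network the extracted EFMs actually visit.
    """
    out: set[str] = set()
    for s in _supports(efms):
        if r in s:
            out |= s
    return frozenset(out)


def coupled_classes(
    efms: Sequence, universe: Iterable[str]
) -> list[frozenset[str]]:
    """Partition of the universe by identical EFM-membership pattern.

    Requires a complete enumeration: two reactions are partially coupled
    when every EFM contains either both or neither.  Singleton classes are
    the non-partially-coupled reactions.  Classes are returned in order of
    first member appearance in the universe iteration order.
    """
    supports = _supports(efms)
    patterns: dict[str, tuple[bool, ...]] = {
        r: tuple(r in s for s in supports) for r in universe
    }
    groups: dict[tuple[bool, ...], list[str]] = {}
    order: list[tuple[bool, ...]] = []
    for r, pat in patterns.items():
        if pat not in groups:
            groups[pat] = []
            order.append(pat)
        groups[pat].append(r)
    return [frozenset(groups[pat]) for pat in order]


def drop_coupled(
    efms: Sequence,
    universe: Iterable[str],
    mode: str = "drop",
) -> frozenset[str]:
    """Universe restricted for the coupling-corrected comparison.

    ``mode="drop"`` removes every member of each non-singleton coupling
    class (keeps only non-partially-coupled reactions, the default);
    ``mode="representative"`` keeps one member per class.
    """
    classes = coupled_classes(efms, universe)
    if mode == "drop":
        return frozenset(r for cls in classes if len(cls) == 1 for r in cls)
    if mode == "representative":
        return frozenset(sorted(cls)[0] for cls in classes)
    raise ValueError("mode must be 'drop' or 'representative'")


def simulate_k_extreme(
    efms: Sequence, order: str, k: int
) -> list[frozenset[str]]:
    """First k EFMs after a stable sort by support length.

    ``order="shortest"`` sorts ascending (mimicking methods that emit EFMs
    in increasing length), ``order="largest"`` descending; ties keep the
    enumeration order, and the reported mean length at any k depends only
    on the sorted length multiset.
    """
    supports = _supports(efms)
    if order == "shortest":
        ranked = sorted(supports, key=len)
    elif order == "largest":
        ranked = sorted(supports, key=lambda s: -len(s))
    else:
        raise ValueError("order must be 'shortest' or 'largest'")
    return ranked[:k]


def jaccard_trace(efms: Sequence) -> ParameterTrace:
    """Jaccard distance between consecutive EFM supports in the stream."""
    supports = _supports(efms)
    if len(supports) < 2:
        raise ValueError("need at least two EFMs")
    vals = []
    for a, b in zip(supports, supports[1:]):
        vals.append(1.0 - len(a & b) / len(a | b))
    return ParameterTrace(list(range(1, len(supports))), vals)


def pearson_proportions(
    p_est: ProportionMap, p_ref: ProportionMap, universe: Iterable[str]
) -> float:
    """Pearson correlation of estimated vs reference proportions (optional
    alternative to the mean relative error; less sensitive)."""
    uni = list(universe)
    a = np.array([p_est[r] for r in uni])
    b = np.array([p_ref[r] for r in uni])
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("constant proportions: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])
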