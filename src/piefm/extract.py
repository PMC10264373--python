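"""Pivot-expansion EFM extraction (PiEFM).

The method interleaves two ideas.  A *seeding* phase poses LPs over the
flux cone: first one per reaction (positive constraint v[r] = 1, random
positive objective) so every reaction is covered by at least one EFM, then
n further LPs anchored on the biomass reaction with fresh random
objectives.  Every optimal basic solution of such an LP is a vertex of the
sliced cone and hence an EFM.  An *expansion* phase then walks the cone's
vertex graph: it repeatedly picks the least-recomputed unexplored EFM,
rebuilds an LP whose unique optimum is that EFM, and pivots the final
tableau to all feasible adjacent vertices, which are new EFMs.  Occurrence
counts (how often each EFM was re-computed) steer the queue toward
under-sampled regions of the cone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .efm import EFM, EFMCollection, canonicalize, is_efm
from .network import MetabolicNetwork, NetworkValidationError
from .simplex import LPProblem, build_lp, pivot_neighbors, solve

__all__ = [
    "PiefmConfig",
    "ExtractionTrace",
    "seed_phase",
    "select_next",
    "exploration_lp",
    "expand_phase",
    "run_piefm",
    "random_baseline",
]

log = logging.getLogger(__name__)


@dataclass
class PiefmConfig:
    n_seed_lps: int = 0  # biomass-anchored LPs after the coverage pass
    rng_seed: int = 0
    biomass_reaction: Optional[str] = None
    max_efms: Optional[int] = None
    max_time: Optional[float] = None  # seconds
    coefficient_range: tuple[float, float] = (0.1, 1.0)
    keep_futile_pairs: bool = False

    def __post_init__(self) -> None:
        if self.n_seed_lps < 0:
            raise ValueError("n_seed_lps must be >= 0")
        lo, hi = self.coefficient_range
        if not (0 < lo <= hi):
            raise ValueError("coefficient_range must be strictly positive")


@dataclass
class ExtractionTrace:
    collection: EFMCollection
    events: list[tuple[int, int, str]] = field(default_factory=list)
    # (step = LPs solved so far, EFM index in collection, source)
    lp_count: int = 0
    pivot_count: int = 0

    @property
    def efficiency(self) -> float:
        """Distinct EFMs per LP solved — the usual efficiency ratio."""
        return len(self.collection) / self.lp_count if self.lp_count else 0.0

    def write_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for step, idx, source in self.events:
                fh.write(
                    json.dumps(
                        {
                            "step": step,
                            "efm": idx,
                            "source": source,
                            "support": sorted(
                                self.collection.efms[idx].support
                            ),
                        }
                    )
                    + "\n"
                )


def _random_objective(
    rng: np.random.Generator, n: int, lo: float, hi: float
) -> np.ndarray:
    return rng.uniform(lo, hi, size=n)


def _record(
    trace: ExtractionTrace, net: MetabolicNetwork, v: np.ndarray, source: str
) -> bool:
    efm = canonicalize(v, net.reaction_ids)
    new = trace.collection.add(efm)
    if new:
        trace.events.append(
            (trace.lp_count, trace.collection.index_of(efm.support), source)
        )
    return new


def seed_phase(net: MetabolicNetwork, config: PiefmConfig) -> ExtractionTrace:
    """Coverage pass (one LP per reaction) then biomass-anchored LPs.

    Requires a preprocessed network (all-irreversible, non-blocked); an
    infeasible v[r] = 1 constraint means r was blocked and preprocessing
    was skipped.  When no biomass reaction is configured, step two falls
    back to random singleton positive seeds (documented deviation switch).
    """
    if not net.all_irreversible:
        raise NetworkValidationError("seed_phase expects an all-irreversible network")
    rng = np.random.default_rng(config.rng_seed)
    lo, hi = config.coefficient_range
    trace = ExtractionTrace(
        collection=EFMCollection(net, keep_futile_pairs=config.keep_futile_pairs)
    )
    n = net.n_reactions

    def budget_left() -> bool:
        return config.max_efms is None or len(trace.collection) < config.max_efms

    for rid in net.reaction_ids:  # network order, deterministic
        if not budget_left():
            return trace
        lp = build_lp(net, _random_objective(rng, n, lo, hi), positive_seed=[rid])
        state = solve(lp)
        trace.lp_count += 1
        if state.status != "optimal":
            raise NetworkValidationError(
                f"v[{rid}] = 1 is infeasible: reaction is blocked; "
                "run remove_blocked before extraction"
            )
        _record(trace, net, state.solution, "seed_coverage")

    biomass = config.biomass_reaction or net.biomass_reaction
    for _ in range(config.n_seed_lps):
        if not budget_left():
            return trace
        if biomass is not None:
            seed = [biomass]
        else:
            seed = [net.reaction_ids[int(rng.integers(n))]]
        lp = build_lp(net, _random_objective(rng, n, lo, hi), positive_seed=seed)
        state = solve(lp)
        trace.lp_count += 1
        if state.status != "optimal":
            raise NetworkValidationError(
                f"biomass seed {seed[0]!r} gives an infeasible LP"
            )
        _record(trace, net, state.solution, "seed_biomass")
    log.info(
        "seed phase: %d LPs, %d distinct EFMs",
        trace.lp_count,
        len(trace.collection),
    )
    return trace


def select_next(collection: EFMCollection) -> Optional[int]:
    """Index of the unexplored EFM computed the fewest times; ties go to the
    earliest-discovered; None when all are explored.  Marks it explored."""
    best: Optional[int] = None
    best_count = None
    for i, (occ, done) in enumerate(
        zip(collection.occurrences, collection.explored)
    ):
        if done:
            continue
        if best_count is None or occ < best_count:
            best, best_count = i, occ
    if best is None:
        return None
    collection.explored[best] = True
    return best


def exploration_lp(net: MetabolicNetwork, efm: EFM) -> LPProblem:
    """LP whose unique optimum (value 0) is the given EFM.

    The positive constraint runs over I, the support reactions that are
    originally irreversible; the objective charges unit cost to every
    reaction outside the support.  If I is empty the EFM cannot anchor an
    exploration LP (see :func:`expand_phase`, which skips it).
    """
    I = {
        r
        for r in efm.support
        if net.origin[net.reaction_index(r)].direction == "native"
    }
    if not I:
        raise LookupError(
            "support contains no originally-irreversible reaction"
        )
    obj = np.array(
        [0.0 if r in efm.support else 1.0 for r in net.reaction_ids]
    )
    return build_lp(net, obj, positive_seed=I)


def expand_phase(
    net: MetabolicNetwork, trace: ExtractionTrace, config: PiefmConfig
) -> ExtractionTrace:
    """Pivot-expansion over the exploration queue (in place on ``trace``).

    Loop: pick the least-recomputed unexplored EFM, solve its exploration
    LP, pivot the final tableau to all feasible adjacent vertices, verify
    each candidate with the rank test, and store the new EFMs.  Stops on
    max_efms, max_time or queue exhaustion.
    """
    t0 = time.monotonic()
    discarded = 0
    while True:
        if config.max_efms is not None and len(trace.collection) >= config.max_efms:
            break
        if config.max_time is not None and time.monotonic() - t0 > config.max_time:
            break
        idx = select_next(trace.collection)
        if idx is None:
            break  # queue exhausted
        efm = trace.collection.efms[idx]
        try:
            lp = exploration_lp(net, efm)
        except LookupError:
            log.info(
                "skipping EFM %d: no originally-irreversible reaction in support",
                idx,
            )
            continue
        state = solve(lp)
        trace.lp_count += 1
        if state.status != "optimal":  # pragma: no cover - guaranteed feasible
            log.warning("exploration LP for EFM %d returned %s", idx, state.status)
            continue
        _record(trace, net, state.solution, "pivot")  # re-computes efm itself
        for v in pivot_neighbors(state):
            trace.pivot_count += 1
            if config.max_efms is not None and (
                len(trace.collection) >= config.max_efms
            ):
                break
            if not is_efm(net, v):
                discarded += 1
                log.warning("pivot candidate failed the rank test; discarded")
                continue
            _record(trace, net, v, "pivot")
    log.info(
        "expansion done: %d EFMs, %d LPs, %d pivots, %d candidates discarded",
        len(trace.collection),
        trace.lp_count,
        trace.pivot_count,
        discarded,
    )
    return trace


def run_piefm(net: MetabolicNetwork, config: PiefmConfig) -> ExtractionTrace:
    """Seeding followed by pivot expansion."""
    trace = seed_phase(net, config)
    return expand_phase(net, trace, config)


def random_baseline(
    net: MetabolicNetwork, n_lps: int, rng_seed: int = 0
) -> ExtractionTrace:
    """Purely random LP extraction, used only as a comparison baseline:
    each LP has a random objective and a random singleton positive seed."""
    rng = np.random.default_rng(rng_seed)
    trace = ExtractionTrace(collection=EFMCollection(net))
    n = net.n_reactions
    for _ in range(n_lps):
        rid = net.reaction_ids[int(rng.integers(n))]
        lp = build_lp(net, rng.uniform(0.1, 1.0, size=n), positive_seed=[rid])
        state = solve(lp)
        trace.lp_count += 1
        if state.status == "optimal":
            _record(trace, net, state.solution, "seed_coverage")
    return trace
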