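"""Deterministic synthetic networks with known, exactly enumerable EFM sets.

Every builder is a pure function of its parameters, so test fixtures are
reproducible without any model download.  Networks are mass-balanced,
all-irreversible and (after construction) free of blocked reactions.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .network import (
    EmptyNetworkError,
    MetabolicNetwork,
    find_blocked,
    remove_blocked,
)

__all__ = [
    "make_chain",
    "make_fan",
    "make_diamond",
    "make_reversible_chain",
    "make_blocked_pair",
    "make_random",
    "toy_lin",
]


def make_chain(m: int) -> MetabolicNetwork:
    """Linear pathway ->A1->A2->...->Am-> ; exactly one EFM of length m+1."""
    if m < 1:
        raise ValueError("chain needs at least one metabolite")
    mets = [f"A{i}" for i in range(1, m + 1)]
    rxns = [f"r{j}" for j in range(1, m + 2)]
    S = np.zeros((m, m + 1))
    for i in range(m):
        S[i, i] = 1.0  # produced by r_{i+1}
        S[i, i + 1] = -1.0  # consumed by r_{i+2}
    return MetabolicNetwork(mets, rxns, S, np.zeros(m + 1, dtype=bool))


def make_fan(b: int) -> MetabolicNetwork:
    """One import ->A and b parallel exits A-> ; exactly b EFMs of length 2."""
    if b < 1:
        raise ValueError("fan needs at least one exit")
    rxns = [f"r{j}" for j in range(1, b + 2)]
    S = np.zeros((1, b + 1))
    S[0, 0] = 1.0
    S[0, 1:] = -1.0
    return MetabolicNetwork(["A"], rxns, S, np.zeros(b + 1, dtype=bool))


def toy_lin() -> MetabolicNetwork:
    """The 3-reaction, 1-metabolite fan (b = 2): EFMs {r1,r2}, {r1,r3}."""
    return make_fan(2)


def make_diamond() -> MetabolicNetwork:
    """Two parallel 2-step branches between a source and a sink.

    ->A, A->B, A->C, B->D, C->D, D-> ; exactly two EFMs of length 4:
    {r1,r2,r4,r6} and {r1,r3,r5,r6}.
    """
    mets = ["A", "B", "C", "D"]
    rxns = [f"r{j}" for j in range(1, 7)]
    S = np.array(
        [
            #  r1   r2   r3   r4   r5   r6
            [1.0, -1.0, -1.0, 0.0, 0.0, 0.0],  # A
            [0.0, 1.0, 0.0, -1.0, 0.0, 0.0],  # B
            [0.0, 0.0, 1.0, 0.0, -1.0, 0.0],  # C
            [0.0, 0.0, 0.0, 1.0, 1.0, -1.0],  # D
        ]
    )
    return MetabolicNetwork(
        mets, rxns, S, np.zeros(6, dtype=bool), biomass_reaction="r6"
    )


def make_reversible_chain() -> MetabolicNetwork:
    """->A, A<->B, B-> ; after splitting: one pathway EFM plus the futile
    two-cycle {r2_fwd, r2_bwd}."""
    S = np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])
    return MetabolicNetwork(
        ["A", "B"],
        ["r1", "r2", "r3"],
        S,
        np.array([False, True, False]),
    )


def make_blocked_pair() -> MetabolicNetwork:
    """->A, A->B with B internal and unconsumed: both reactions blocked."""
    S = np.array([[1.0, -1.0], [0.0, 1.0]])
    return MetabolicNetwork(
        ["A", "B"], ["r1", "r2"], S, np.zeros(2, dtype=bool)
    )


def make_random(
    n_met: int,
    n_rxn: int,
    density: float,
    rng_seed: int,
    max_tries: int = 200,
) -> MetabolicNetwork:
    """Random sparse integer-stoichiometry network, blocked reactions removed.

    Internal coefficients are drawn from {-2, -1, 1, 2}; one import and one
    export column are always present so the cone is non-trivial.  Candidate
    matrices are rejected and resampled (advancing the stream) until at
    least one EFM survives preprocessing.  Deterministic per seed.
    """
    rng = np.random.default_rng(rng_seed)
    for _ in range(max_tries):
        S = np.zeros((n_met, n_rxn + 2))
        mask = rng.random((n_met, n_rxn)) < density
        vals = rng.choice([-2.0, -1.0, 1.0, 2.0], size=(n_met, n_rxn))
        S[:, :n_rxn] = np.where(mask, vals, 0.0)
        # no empty columns: give each a random entry
        for j in range(n_rxn):
            if not np.any(S[:, j]):
                S[rng.integers(n_met), j] = rng.choice([-1.0, 1.0])
        S[rng.integers(n_met), n_rxn] = 1.0  # import
        S[rng.integers(n_met), n_rxn + 1] = -1.0  # export
        rxns = [f"r{j}" for j in range(1, n_rxn + 1)] + ["imp", "exp"]
        net = MetabolicNetwork(
            [f"M{i}" for i in range(1, n_met + 1)],
            rxns,
            S,
            np.zeros(n_rxn + 2, dtype=bool),
        )
        try:
            net = remove_blocked(net)
        except EmptyNetworkError:
            continue
        return net
    raise RuntimeError(
        f"no viable random network in {max_tries} tries (seed {rng_seed})"
    )
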