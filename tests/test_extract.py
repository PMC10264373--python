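"""The pivot-expansion extraction method: seeding, queue, completeness."""

import numpy as np
import pytest

from piefm import (
    EFMCollection,
    PiefmConfig,
    canonicalize,
    exploration_lp,
    expand_phase,
    random_baseline,
    run_piefm,
    seed_phase,
    select_next,
    solve,
)
from piefm import fixtures as fx
from piefm.network import NetworkValidationError
from piefm.oracle import enumerate_bruteforce


class TestSeedPhase:
    def test_diamond_coverage_hits_both_branches(self, diamond, diamond_efms):
        trace = seed_phase(diamond, PiefmConfig(n_seed_lps=0, rng_seed=0))
        assert trace.collection.supports() == set(diamond_efms)
        assert trace.lp_count == diamond.n_reactions

    def test_biomass_lps_increment_occurrences(self, lin):
        # the only EFM containing r2 is {r1, r2}: all 10 anchored LPs re-find it
        cfg = PiefmConfig(n_seed_lps=10, rng_seed=1, biomass_reaction="r2")
        trace = seed_phase(lin, cfg)
        idx = trace.collection.index_of({"r1", "r2"})
        assert trace.collection.occurrences[idx] >= 11
        assert trace.lp_count == 3 + 10

    def test_single_efm_chain(self):
        net = fx.make_chain(2)
        trace = seed_phase(net, PiefmConfig(n_seed_lps=0))
        assert len(trace.collection) == 1
        assert trace.lp_count == net.n_reactions

    def test_blocked_reaction_raises(self):
        trace_net = fx.make_blocked_pair()
        with pytest.raises(NetworkValidationError):
            seed_phase(trace_net, PiefmConfig())

    def test_reversible_input_rejected(self):
        with pytest.raises(NetworkValidationError):
            seed_phase(fx.make_reversible_chain(), PiefmConfig())


class TestSelectNext:
    def _collection(self, lin, counts, explored):
        col = EFMCollection(lin)
        vs = [np.array([1.0, 1.0, 0.0]), np.array([1.0, 0.0, 1.0]),
              np.array([0.0, 0.0, 0.0])]
        col.add(canonicalize(np.array([1.0, 1.0, 0.0]), lin.reaction_ids))
        col.add(canonicalize(np.array([1.0, 0.0, 1.0]), lin.reaction_ids))
        col.occurrences[:] = counts[: len(col)]
        col.explored[:] = explored[: len(col)]
        return col

    def test_minimal_count_earliest_tie(self, lin):
        col = self._collection(lin, [1, 1], [False, False])
        col.occurrences[0] = 3
        col.add(canonicalize(np.array([1.0, 1.0, 0.0]), lin.reaction_ids))
        # counts now [4, 1]; e2 has the minimum
        assert select_next(col) == 1
        assert col.explored[1]

    def test_earliest_discovery_breaks_ties(self, lin):
        col = self._collection(lin, [1, 1], [False, False])
        assert select_next(col) == 0

    def test_explored_are_skipped_and_exhaustion_returns_none(self, lin):
        col = self._collection(lin, [1, 5], [True, False])
        assert select_next(col) == 1
        assert select_next(col) is None


class TestExplorationLp:
    def test_optimum_zero_at_the_efm(self, diamond):
        efm = canonicalize(
            np.array([1, 1, 0, 1, 0, 1], float), diamond.reaction_ids
        )
        lp = exploration_lp(diamond, efm)
        assert lp.positive_seed == efm.support  # all originally irreversible
        outside = {"r3", "r5"}
        coeffs = dict(zip(diamond.reaction_ids, lp.objective))
        assert all(coeffs[r] == 1.0 for r in outside)
        assert all(coeffs[r] == 0.0 for r in efm.support)
        st = solve(lp)
        assert st.status == "optimal"
        assert st.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_positive_seed_excludes_split_directions(self, rev_split):
        efm = canonicalize(
            np.array([1.0, 1.0, 0.0, 1.0]), rev_split.reaction_ids
        )
        lp = exploration_lp(rev_split, efm)
        assert lp.positive_seed == {"r1", "r3"}

    def test_all_split_support_signals_skip(self, rev_split):
        efm = canonicalize(
            np.array([0.0, 1.0, 1.0, 0.0]), rev_split.reaction_ids
        )
        with pytest.raises(LookupError):
            exploration_lp(rev_split, efm)


class TestExpandPhase:
    def test_diamond_exhaustion_finds_both(self, diamond, diamond_efms):
        cfg = PiefmConfig(n_seed_lps=0, rng_seed=0)
        trace = expand_phase(diamond, seed_phase(diamond, cfg), cfg)
        assert trace.collection.supports() == set(diamond_efms)
        assert all(trace.collection.explored)

    def test_random_fixture_matches_oracle_exactly(self):
        net = fx.make_random(4, 10, 0.35, 42)
        cfg = PiefmConfig(n_seed_lps=0, rng_seed=42)
        trace = run_piefm(net, cfg)
        oracle = enumerate_bruteforce(net)
        assert trace.collection.supports() == oracle.supports()

    def test_max_efms_stops_early(self, diamond):
        cfg = PiefmConfig(n_seed_lps=0, rng_seed=0, max_efms=1)
        trace = run_piefm(diamond, cfg)
        assert len(trace.collection) == 1


class TestProperties:
    def test_completeness_on_fixture_suite(self, random_nets):
        """Unlimited budget terminates by exhaustion with the oracle's set."""
        for seed, net in enumerate(random_nets[:10]):
            trace = run_piefm(net, PiefmConfig(n_seed_lps=0, rng_seed=seed))
            assert trace.collection.supports() == enumerate_bruteforce(net).supports()

    def test_every_stored_efm_passes_rank_test(self, random_nets):
        from piefm import is_efm

        for net in random_nets[:5]:
            trace = run_piefm(net, PiefmConfig(n_seed_lps=0, rng_seed=9))
            for e in trace.collection.efms:
                assert is_efm(net, np.array(e.flux))

    def test_determinism_bitwise(self):
        net = fx.make_random(4, 10, 0.35, 7)
        cfg = PiefmConfig(n_seed_lps=5, rng_seed=3)
        a = run_piefm(net, cfg)
        b = run_piefm(net, cfg)
        assert a.events == b.events
        assert a.lp_count == b.lp_count and a.pivot_count == b.pivot_count
        assert [e.flux for e in a.collection.efms] == [
            e.flux for e in b.collection.efms
        ]

    def test_efficiency_beats_random_baseline_on_average(self):
        """Distinct-EFMs-per-LP, averaged over 10 seeds, is at least the
        purely random method's ratio on the same fixtures."""
        gains = []
        for seed in range(10):
            net = fx.make_random(4, 10, 0.4, 50 + seed)
            trace = run_piefm(net, PiefmConfig(n_seed_lps=0, rng_seed=seed))
            base = random_baseline(net, n_lps=trace.lp_count, rng_seed=seed)
            gains.append(trace.efficiency - base.efficiency)
        assert np.mean(gains) >= 0.0

    def test_trace_jsonl_round_trip(self, tmp_path, diamond):
        trace = run_piefm(diamond, PiefmConfig(n_seed_lps=0, rng_seed=0))
        p = tmp_path / "trace.jsonl"
        trace.write_jsonl(p)
        import json

        lines = [json.loads(l) for l in p.read_text().splitlines()]
        assert len(lines) == len(trace.collection)
        assert lines[0]["source"] == "seed_coverage"
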