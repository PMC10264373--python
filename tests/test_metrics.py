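"""Representativeness and stability metric suite."""

import numpy as np
import pytest

from piefm import metrics as mx
from piefm.oracle import enumerate_bruteforce

S = frozenset


class TestMeanLengthTrace:
    def test_constant_lengths(self):
        t = mx.mean_length_trace([S({"a", "b"}), S({"c", "d"})], [1, 2])
        assert t.values == [2.0, 2.0]

    def test_growing_mean(self):
        t = mx.mean_length_trace([S("ab"), S("abcd")], [1, 2])
        assert t.values == [2.0, 3.0]

    def test_default_checkpoints_every_prefix(self):
        t = mx.mean_length_trace([S("ab"), S("abcd"), S("abc")])
        assert t.checkpoints == [1, 2, 3]
        assert t.values[-1] == pytest.approx(3.0)


class TestProportions:
    def test_diamond_full_set(self, diamond, diamond_efms):
        p = mx.reaction_proportions(diamond_efms, diamond.reaction_ids)
        assert p["r1"] == 1.0 and p["r6"] == 1.0
        assert p["r2"] == 0.5 and p["r3"] == 0.5

    def test_single_efm_is_indicator(self):
        p = mx.reaction_proportions([S({"a", "b"})], ["a", "b", "c"])
        assert (p["a"], p["b"], p["c"]) == (1.0, 1.0, 0.0)

    def test_independent_recount(self, random_nets):
        """Agrees exactly with a brute-force counter on oracle sets."""
        for net in random_nets[:5]:
            efms = [e.support for e in enumerate_bruteforce(net).efms]
            p = mx.reaction_proportions(efms, net.reaction_ids)
            for r in net.reaction_ids:
                manual = sum(r in s for s in efms) / len(efms)
                assert p[r] == manual

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            mx.reaction_proportions([], ["a"])


class TestMre:
    def test_identity_is_zero(self):
        p = mx.ProportionMap({"a": 1.0, "b": 0.5}, {"a", "b"})
        assert mx.mre(p, p, ["a", "b"]) == 0.0

    def test_hand_computed_value(self):
        ref = {"r1": 1.0, "r2": 0.5}
        est = {"r1": 1.0, "r2": 0.25}
        assert mx.mre(est, ref, ["r1", "r2"]) == pytest.approx(0.25)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            mx.mre({"a": 0.5}, {"a": 0.0}, ["a"])

    def test_half_prefix_matches_brute_force(self, random_nets):
        rng = np.random.default_rng(3)
        for net in random_nets[:3]:
            efms = [e.support for e in enumerate_bruteforce(net).efms]
            if len(efms) < 4:
                continue
            order = rng.permutation(len(efms))
            shuffled = [efms[i] for i in order]
            half = shuffled[: len(efms) // 2]
            p_ref = mx.reaction_proportions(efms, net.reaction_ids)
            uni = [r for r in net.reaction_ids if p_ref[r] > 0]
            got = mx.mre(mx.reaction_proportions(half, uni), p_ref, uni)
            manual = np.mean(
                [
                    abs(sum(r in s for s in half) / len(half) - p_ref[r])
                    / p_ref[r]
                    for r in uni
                ]
            )
            assert got == pytest.approx(manual)


class TestStability:
    def test_repeated_stream_is_identically_zero(self):
        stream = [S({"a", "b"})] * 12
        t = mx.stability_trace(stream, d=2, checkpoints=[4, 6, 8, 12])
        assert t.values == [0.0] * 4

    def test_identical_halves_at_two_d(self):
        stream = [S({"a"}), S({"a"})]
        t = mx.stability_trace(stream, d=1, checkpoints=[2])
        assert t.values == [0.0]

    def test_checkpoints_below_two_d_rejected(self):
        with pytest.raises(ValueError):
            mx.stability_trace([S("a")] * 10, d=3, checkpoints=[4])

    def test_uniform_sampling_trends_to_zero(self, diamond_efms):
        """Sampling the diamond's 2 EFMs with replacement: the self-
        comparison error shrinks as k grows (law of large numbers),
        checked as a mean over 10 seeds."""
        early, late = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            stream = [diamond_efms[i] for i in rng.integers(2, size=400)]
            t = mx.stability_trace(stream, d=50, checkpoints=[100, 400])
            early.append(t.values[0])
            late.append(t.values[-1])
        assert np.mean(late) <= np.mean(early)


class TestStoppingIndex:
    def _trace(self, values):
        return mx.ParameterTrace(list(range(1, len(values) + 1)), values)

    def test_first_run_start_returned(self):
        t = self._trace([0.2, 0.04, 0.03, 0.02])
        assert mx.stopping_index(t, 0.05, consecutive=3) == 2

    def test_never_below_threshold(self):
        t = self._trace([0.2, 0.3, 0.4])
        assert mx.stopping_index(t, 0.05, consecutive=2) is None

    def test_run_must_be_uninterrupted(self):
        t = self._trace([0.04, 0.2, 0.04, 0.04, 0.04])
        assert mx.stopping_index(t, 0.05, consecutive=3) == 3

    def test_monotone_in_threshold(self):
        t = self._trace([0.2, 0.1, 0.04, 0.03, 0.02, 0.01])
        loose = mx.stopping_index(t, 0.15, consecutive=3)
        tight = mx.stopping_index(t, 0.05, consecutive=3)
        assert loose is not None and tight is not None and loose <= tight


class TestCompatibleReactions:
    def test_diamond_sink_sees_everything(self, diamond_efms):
        assert mx.compatible_reactions(diamond_efms, "r6") == S(
            {"r1", "r2", "r3", "r4", "r5", "r6"}
        )

    def test_branch_reaction_sees_its_pathway(self, diamond_efms):
        assert mx.compatible_reactions(diamond_efms, "r2") == S(
            {"r1", "r2", "r4", "r6"}
        )

    def test_empty_list(self):
        assert mx.compatible_reactions([], "r1") == frozenset()


class TestCoupledClasses:
    def test_diamond_partition(self, diamond, diamond_efms):
        classes = {
            frozenset(c)
            for c in mx.coupled_classes(diamond_efms, diamond.reaction_ids)
        }
        assert classes == {S({"r1", "r6"}), S({"r2", "r4"}), S({"r3", "r5"})}

    def test_lin_all_singletons(self, lin):
        efms = [S({"r1", "r2"}), S({"r1", "r3"})]
        classes = mx.coupled_classes(efms, lin.reaction_ids)
        assert sorted(map(sorted, classes)) == [["r1"], ["r2"], ["r3"]]

    def test_single_efm_single_class(self):
        classes = mx.coupled_classes([S({"a", "b"})], ["a", "b"])
        assert classes == [S({"a", "b"})]

    def test_drop_modes(self, diamond, diamond_efms):
        dropped = mx.drop_coupled(diamond_efms, diamond.reaction_ids, "drop")
        assert dropped == frozenset()  # every diamond reaction is coupled
        reps = mx.drop_coupled(
            diamond_efms, diamond.reaction_ids, "representative"
        )
        assert len(reps) == 3


class TestKExtreme:
    def test_whole_list_either_order(self, diamond_efms):
        assert len(mx.simulate_k_extreme(diamond_efms, "shortest", 2)) == 2
        assert len(mx.simulate_k_extreme(diamond_efms, "largest", 2)) == 2

    def test_sandwich_inequality(self, random_nets):
        """mean(k shortest) <= overall mean <= mean(k largest) for all k."""
        for net in random_nets[:8]:
            efms = [e.support for e in enumerate_bruteforce(net).efms]
            overall = np.mean([len(s) for s in efms])
            for k in range(1, len(efms) + 1):
                short = np.mean(
                    [len(s) for s in mx.simulate_k_extreme(efms, "shortest", k)]
                )
                large = np.mean(
                    [len(s) for s in mx.simulate_k_extreme(efms, "largest", k)]
                )
                assert short <= overall + 1e-12
                assert overall <= large + 1e-12

    def test_stable_ties_keep_enumeration_order(self):
        efms = [S({"a", "b"}), S({"c", "d"}), S({"e"})]
        got = mx.simulate_k_extreme(efms, "largest", 2)
        assert got == [S({"a", "b"}), S({"c", "d"})]


class TestJaccard:
    def test_identical_zero(self):
        t = mx.jaccard_trace([S({"a"}), S({"a"})])
        assert t.values == [0.0]

    def test_disjoint_one(self):
        t = mx.jaccard_trace([S({"a"}), S({"b"})])
        assert t.values == [1.0]

    def test_hand_value(self):
        t = mx.jaccard_trace([S({"r1", "r2"}), S({"r1", "r3"})])
        assert t.values[0] == pytest.approx(1 - 1 / 3)


def test_parameter_trace_requires_increasing_checkpoints():
    with pytest.raises(ValueError):
        mx.ParameterTrace([2, 2], [0.0, 0.0])
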