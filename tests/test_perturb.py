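"""Mutants, transient bitflips, transition statistics, Derrida curve."""

import math

import numpy as np
import pytest

import boolmac as bm
from boolmac import (Environment, KauffmanSpec, LabelRule, MutationSpec,
                     apply_mutation, brute_force_attractors, derrida_map,
                     find_attractors_exhaustive, parse_bnet, random_kauffman,
                     transient_perturb, transition_table)


@pytest.fixture
def on_rules():
    return [LabelRule("ON", {"A"}, set(), 1), LabelRule("OFF", set(), set(), 0)]


class TestMutants:
    def test_knockout_toggle_leaves_single_fixed_point(self, toggle):
        mutated = apply_mutation(toggle, MutationSpec("A", "knockout"))
        aset = brute_force_attractors(mutated)
        assert [(a.states, a.basin_size) for a in aset] == [((2,), 4)]

    def test_mutation_recorded(self, toggle):
        mutated = apply_mutation(toggle, MutationSpec("B", "overexpression"))
        assert mutated.metadata["mutations"] == [("B", "overexpression")]

    def test_invalid_kind_rejected(self):
        with pytest.raises(ValueError):
            MutationSpec("A", "duplication")

    @pytest.mark.parametrize("seed", range(6))
    def test_clamping_steady_value_preserves_steady_state(self, seed):
        """Fixing a node to the value it holds in a fixed point keeps it."""
        net = random_kauffman(KauffmanSpec(n=7, k=2, seed=seed))
        for a in brute_force_attractors(net):
            if a.period != 1:
                continue
            state = net.index_to_state(a.states[0])
            node = net.nodes[0]
            kind = "overexpression" if state[0] else "knockout"
            mut = apply_mutation(net, MutationSpec(node, kind))
            assert mut.step_sync(state) == state

    def test_mutant_report_wild_type_only(self, toggle, on_rules):
        env = Environment("free-ish", {})
        df = bm.mutant_report(toggle, [], on_rules, [env])
        assert set(df["variant"]) == {"wild_type"}


class TestTransientPerturb:
    def test_toggle_fixed_point_flips_into_cycle(self, toggle):
        aset = brute_force_attractors(toggle)
        by_first = {a.states[0]: i for i, a in enumerate(aset.attractors)}
        src = aset.attractors[by_first[2]]        # (0,1) fixed point
        tgt = transient_perturb(toggle, aset, src, 0, ["A"])
        assert aset.attractors[tgt].states == (0, 3)  # the 2-cycle

    def test_null_perturbation_returns_source(self, toggle):
        aset = brute_force_attractors(toggle)
        for i, a in enumerate(aset.attractors):
            assert transient_perturb(toggle, aset, a, 0, []) == i

    def test_flip_restored_input_returns_home(self):
        net = parse_bnet("targets, factors\nI, I\nA, I\n")
        env = Environment("on", {"I": 1})
        aset = bm.attractors_by_environment(net, env)
        (a,) = aset.attractors
        # flipping the clamped input is undone by its constant rule
        assert transient_perturb(net, aset, a, 0, ["I"]) == 0

    def test_duplicate_nodes_rejected(self, toggle):
        aset = brute_force_attractors(toggle)
        with pytest.raises(ValueError):
            transient_perturb(toggle, aset, aset.attractors[0], 0, ["A", "A"])

    def test_bad_state_index_rejected(self, toggle):
        aset = brute_force_attractors(toggle)
        with pytest.raises(ValueError):
            transient_perturb(toggle, aset, aset.attractors[0], 5, ["A"])

    @pytest.mark.parametrize("seed", range(5))
    def test_closure_targets_are_known_attractors(self, seed):
        net = random_kauffman(KauffmanSpec(n=8, k=2, n_inputs=2, seed=seed))
        aset = find_attractors_exhaustive(net)
        smap = aset.state_to_attractor()
        for a in aset.attractors[:4]:
            for node in net.nodes:
                tgt = transient_perturb(net, aset, a, 0, [node], _state_map=smap)
                assert 0 <= tgt < len(aset)


class TestTransitionTable:
    def test_record_count_on_toggle(self, toggle, on_rules):
        # 2 fixed points x 2 nodes + 2 cycle states x 2 nodes = 8 records
        recs, summ, _ = transition_table(
            toggle, [Environment("free", {})], on_rules, "single")
        assert summ.n_perturbations == 8 == len(recs)

    def test_double_order_pairs(self, toggle, on_rules):
        # C(2,2)=1 pair per state; 4 attractor states in total
        recs, summ, _ = transition_table(
            toggle, [Environment("free", {})], on_rules, "double")
        assert summ.n_perturbations == 4
        assert (recs["node2"] != "").all()

    def test_self_returning_records_give_zero_rates(self, on_rules):
        net = parse_bnet("targets, factors\nI, I\nA, I\n")
        envs = bm.all_input_environments(net)
        recs, summ, rates = transition_table(net, envs, on_rules, "single")
        # the copy chain always relaxes back: no label ever changes
        assert summ.pct_type_change == 0.0
        assert (rates["pct_type_change"] == 0).all()

    def test_percentages_consistent_with_counts(self, toggle, on_rules):
        _, summ, rates = transition_table(
            toggle, [Environment("free", {})], on_rules, "single")
        assert summ.pct_type_change == 100.0 * summ.n_base_change / 8
        assert rates["n_perturbations"].sum() == 8

    def test_unknown_order_rejected(self, toggle, on_rules):
        with pytest.raises(ValueError):
            transition_table(toggle, [], on_rules, "triple")


class TestDerrida:
    def test_identity_network_is_the_diagonal(self):
        net = parse_bnet("targets, factors\n" +
                         "\n".join(f"N{i}, N{i}" for i in range(6)))
        for p in derrida_map(net, max_h=6, samples=200, seed=0):
            assert p.mean_final_hamming == pytest.approx(p.initial_hamming)

    def test_constant_network_collapses_to_zero(self):
        net = parse_bnet("targets, factors\n" +
                         "\n".join(f"N{i}, 0" for i in range(5)))
        for p in derrida_map(net, max_h=5, samples=100, seed=1):
            assert p.mean_final_hamming == 0.0

    def test_toggle_preserves_single_flips(self, toggle):
        (p,) = derrida_map(toggle, max_h=1, samples=10, seed=0)
        assert p.method == "exhaustive"
        assert p.mean_final_hamming == pytest.approx(1.0)

    def test_sampled_estimate_matches_exhaustive_within_3se(self):
        net = random_kauffman(KauffmanSpec(n=8, k=2, seed=11))
        exact = derrida_map(net, max_h=3, samples=1)
        sampled = derrida_map(net, max_h=3, samples=4000, seed=7,
                              exhaustive_limit=0)
        for pe, ps in zip(exact, sampled):
            assert pe.method == "exhaustive" and ps.method == "sampled"
            se = math.sqrt(net.n ** 2 / 4 / ps.n_samples)  # crude bound
            assert abs(pe.mean_final_hamming - ps.mean_final_hamming) < 3 * se

    def test_seed_reproducibility(self, toggle):
        a = derrida_map(toggle, max_h=2, samples=50, seed=5,
                        exhaustive_limit=0)
        b = derrida_map(toggle, max_h=2, samples=50, seed=5,
                        exhaustive_limit=0)
        assert [p.mean_final_hamming for p in a] == \
            [p.mean_final_hamming for p in b]

    def test_parameter_validation(self, toggle):
        with pytest.raises(ValueError):
            derrida_map(toggle, max_h=3)
        with pytest.raises(ValueError):
            derrida_map(toggle, max_h=1, samples=0)

    @pytest.mark.parametrize("seed", range(4))
    def test_means_bounded_by_n(self, seed):
        net = random_kauffman(KauffmanSpec(n=9, k=3, bias=0.3, seed=seed))
        for p in derrida_map(net, max_h=9, samples=500, seed=seed):
            assert 0.0 <= p.mean_final_hamming <= net.n
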