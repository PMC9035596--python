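"""Behavior of the built-in macrophage model (reconstruction fixture).

These tests pin the documented behavior of the shipped rule set: structural
invariants (node/interaction counts, the named regulatory circuits), the
cell-type menus recovered in each polarizing micro-environment, stability
under transient perturbation, and the reference mutant phenotypes.
"""

import pytest

import boolmac as bm
from boolmac.network import INHIBITION

M2_FAMILY = {"M2", "M2a", "M2b", "M2c", "M2d"}


class TestStructure:
    def test_node_and_interaction_counts(self, macro_net):
        assert macro_net.n == 29
        between = [e for e in macro_net.interaction_graph()
                   if e.source != e.target]
        assert len(between) == 52

    def test_inputs_are_the_extrinsic_cytokines(self, macro_net):
        assert set(macro_net.input_nodes()) == {
            "IFNG_e", "GMCSF_e", "LPS_e", "IL4_e", "IC_e", "IL1B_e",
            "IL10_e", "NECA_e", "EGFR_e"}

    def test_stat3_star_display_alias(self, macro_net):
        assert macro_net.metadata["aliases"]["STAT3_s"] == "STAT3*"

    def test_il6_negative_circuit(self, macro_net):
        """STAT3 induces SOCS3, which shuts down IL6R: the negative feedback
        behind the cyclic attractors."""
        signs = {(e.source, e.target): e.sign
                 for e in macro_net.interaction_graph()}
        assert signs[("STAT3", "SOCS3")] != INHIBITION
        assert signs[("SOCS3", "IL6R")] == INHIBITION

    def test_socs1_inhibits_stat1_stat5_stat6(self, macro_net):
        signs = {(e.source, e.target): e.sign
                 for e in macro_net.interaction_graph()}
        for stat in ("STAT1", "STAT5", "STAT6"):
            assert signs[("SOCS1", stat)] == INHIBITION

    def test_corrupt_fixture_detected(self, monkeypatch):
        from boolmac import macrophage

        monkeypatch.setitem(macrophage._CHECKSUMS,
                            "macrophage_reconstruction.bnet", "0" * 64)
        with pytest.raises(RuntimeError, match="corrupt"):
            macrophage.load_macrophage_network()


class TestEnvironments:
    def test_named_environment_compositions(self, macro_envs):
        assert set(macro_envs) == {"pro-M1", "pro-M2a", "pro-M2b", "pro-M2c",
                                   "pro-M2d", "mixed", "free"}
        present = {n: set(e.present()) for n, e in macro_envs.items()}
        assert present["pro-M1"] == {"IFNG_e", "GMCSF_e", "LPS_e"}
        assert present["pro-M2a"] == {"IL4_e"}
        assert present["pro-M2b"] == {"LPS_e", "IC_e", "IL1B_e"}
        assert present["pro-M2c"] == {"IL10_e"}
        assert present["pro-M2d"] == {"IC_e", "IL4_e", "IL10_e"}
        assert present["mixed"] == {"LPS_e", "IFNG_e", "IL4_e"}
        assert macro_envs["free"].free

    def test_every_input_assigned_in_named_envs(self, macro_net, macro_envs):
        inputs = set(macro_net.input_nodes())
        for name, env in macro_envs.items():
            if not env.free:
                assert set(env.assignment) == inputs, name


class TestCellTypeMenus:
    """Which cell types each micro-environment recovers."""

    def test_pro_m2a_recovers_only_m2a(self, macro_env_census):
        _, df = macro_env_census["pro-M2a"]
        assert set(df["label"]) == {"M2a"}

    def test_pro_m2c_recovers_only_m2c(self, macro_env_census):
        _, df = macro_env_census["pro-M2c"]
        assert set(df["label"]) == {"M2c"}

    def test_pro_m1_dominated_by_steady_m1(self, macro_env_census):
        _, df = macro_env_census["pro-M1"]
        assert set(df["base_label"]) == {"M1"}
        by_label = df.groupby("label")["basin_size"].sum()
        assert by_label["M1"] > 0.5 * df["basin_size"].sum()
        assert "M1*" in by_label.index  # minority cyclic M1

    def test_pro_m2b_is_m2_family_with_cycles(self, macro_env_census):
        _, df = macro_env_census["pro-M2b"]
        assert set(df["base_label"]) <= M2_FAMILY
        assert "M2b*" in set(df["label"])

    def test_pro_m2d_recovers_m2d(self, macro_env_census):
        _, df = macro_env_census["pro-M2d"]
        assert "M2d" in set(df["label"])
        assert set(df["base_label"]) <= {"M2d", "M2", "M2a"}

    def test_mixed_recovers_m0_m1_m1star_m2a(self, macro_env_census):
        _, df = macro_env_census["mixed"]
        assert {"M0", "M1", "M1*", "M2a"} <= set(df["label"])
        # the naive M0 state dominates the mixed environment
        agg = df.groupby("base_label")["basin_size"].sum()
        assert agg.idxmax() == "M0"

    def test_environment_basins_conserved(self, macro_env_census):
        for name, (aset, df) in macro_env_census.items():
            assert df["basin_size"].sum() == aset.total_states == 2 ** 20


class TestGlobalCensus:
    def test_exactly_eight_base_labels(self, macro_full_census):
        _, labels = macro_full_census
        assert set(labels["base_label"]) == {
            "M0", "M1", "M2", "M2a", "M2b", "M2c", "M2d", "il6"}

    def test_periods_restricted(self, macro_full_census):
        _, labels = macro_full_census
        assert set(labels["period"]) <= {1, 2, 3, 6}

    def test_steady_and_cyclic_attractors_coexist(self, macro_full_census):
        _, labels = macro_full_census
        assert (labels["period"] == 1).any() and (labels["period"] > 1).any()

    def test_basin_conservation_over_full_space(self, macro_full_census):
        aset, labels = macro_full_census
        assert labels["basin_size"].sum() == 2 ** 29 == aset.total_states

    def test_steady_il6_requires_egfr(self, macro_full_census):
        """Steady IL-6-producing macrophages occur only with EGFR ligand."""
        _, labels = macro_full_census
        il6_steady = labels[(labels.base_label == "il6")
                            & (labels.period == 1)]
        assert len(il6_steady) > 0
        assert il6_steady["environment"].str.contains("EGFR_e=1").all()

    def test_basin_rank_m0_m2_m2a_m1(self, macro_full_census):
        """Combined basins order as M0 > M2 > M2a > M1, il6 smallest."""
        _, labels = macro_full_census
        agg = labels.groupby("base_label")["basin_size"].sum()
        assert agg["M0"] > agg["M2"] > agg["M2a"] > agg["M1"]
        assert agg["il6"] == agg.min()

    def test_cyclic_attractors_have_smaller_basin_share(self, macro_full_census):
        _, labels = macro_full_census
        cyc = labels[labels.period > 1]
        share_attr = len(cyc) / len(labels)
        share_basin = cyc["basin_size"].sum() / 2 ** 29
        assert share_basin < share_attr


@pytest.fixture(scope="module")
def named_single_flux(macro_net, macro_rules, macro_envs):
    envs = [e for e in macro_envs.values() if not e.free]
    recs, summ, rates = bm.transition_table(
        macro_net, envs, macro_rules, "single")
    return recs, summ, rates


@pytest.fixture(scope="module")
def mutant_panel_report(macro_net, macro_rules, macro_envs):
    envs = [e for e in macro_envs.values() if not e.free]
    return bm.mutant_report(macro_net, [
        bm.MutationSpec("STAT1", "knockout"),
        bm.MutationSpec("PPARG", "knockout"),
        bm.MutationSpec("STAT6", "overexpression"),
    ], macro_rules, envs)


class TestStability:
    def test_pro_m2a_and_pro_m2c_are_stable(self, named_single_flux):
        recs, _, _ = named_single_flux
        for env in ("pro-M2a", "pro-M2c"):
            sub = recs[recs.environment == env]
            assert (sub["source_base"] == sub["target_base"]).all()

    def test_mixed_transitions_route_through_m0(self, named_single_flux):
        """Cross-type flux in the mixed environment involves M0; there are
        no direct M1 <-> M2a conversions."""
        recs, _, _ = named_single_flux
        flux = bm.label_flux(recs)
        mixed = flux[(flux.environment == "mixed")
                     & (flux.source_base != flux.target_base)]
        assert len(mixed) > 0
        assert (((mixed.source_base == "M0") | (mixed.target_base == "M0"))
                ).all()

    def test_top_transition_nodes_are_key_stats(self, named_single_flux):
        _, _, rates = named_single_flux
        r = rates.groupby("node")[["n_perturbations", "n_type_change"]].sum()
        r["pct"] = r.n_type_change / r.n_perturbations
        top4 = set(r.sort_values("pct", ascending=False).index[:4])
        assert {"STAT1", "STAT3_s", "STAT6"} <= top4

    def test_output_and_quiet_nodes_cause_no_transitions(self,
                                                         named_single_flux):
        _, _, rates = named_single_flux
        r = rates.groupby("node")["n_type_change"].sum()
        for node in ("IL12_out", "VEGF_out", "NECA_e", "IL1R", "TLR4"):
            assert r[node] == 0, node


class TestMutants:
    @staticmethod
    def basin(report, variant, labels):
        sub = report[(report.variant == variant)
                     & (report.base_label.isin(labels))]
        return sub["basin_size"].sum()

    def test_stat1_knockout_eliminates_m1(self, mutant_panel_report):
        assert self.basin(mutant_panel_report, "wild_type", {"M1"}) > 0
        assert self.basin(mutant_panel_report, "STAT1_KO", {"M1"}) == 0

    def test_pparg_knockout_reduces_il10_producers(self, mutant_panel_report):
        il10 = M2_FAMILY
        assert self.basin(mutant_panel_report, "PPARG_KO", il10) < \
            self.basin(mutant_panel_report, "wild_type", il10)

    def test_stat6_overexpression_enriches_m2_depletes_m1(self, mutant_panel_report):
        assert self.basin(mutant_panel_report, "STAT6_OE", M2_FAMILY) > \
            self.basin(mutant_panel_report, "wild_type", M2_FAMILY)
        assert self.basin(mutant_panel_report, "STAT6_OE", {"M1"}) < \
            self.basin(mutant_panel_report, "wild_type", {"M1"})
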