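"""Compartment labels, mean aggregation and redundancy flagging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from helpers import random_binary_matrix
from metaland.adjustment import aggregate, compartment_label, detect_redundant_groups
from metaland.entropy import reaction_graph, rule_group_entropies
from metaland.network import network_from_dict
from metaland.stats import pca, select_variables
from metaland.synthetic import HubSpec, generate_hub_network


def _net(reactions, metabolites):
    return network_from_dict({"metabolites": metabolites, "reactions": reactions})


@pytest.fixture()
def multi_compartment_net():
    mets = [
        {"id": "A_c", "compartment": "c"},
        {"id": "A_e", "compartment": "e"},
        {"id": "B_m", "compartment": "m"},
        {"id": "B_c", "compartment": "c"},
    ]
    rxns = [
        {"id": "T1", "stoich": {"A_c": -1, "A_e": 1}, "lb": 0, "ub": 10, "rule": "G1"},
        {"id": "T2", "stoich": {"B_m": -1, "A_c": -1, "B_c": 1}, "lb": 0, "ub": 10, "rule": "G1"},
        {"id": "EX", "stoich": {"A_e": 1}, "lb": 0, "ub": 10},
    ]
    return _net(rxns, mets)


class TestCompartmentLabel:
    def test_simple_transport(self, multi_compartment_net):
        net = multi_compartment_net
        assert compartment_label(net.reactions["T1"], net) == "c-e"

    def test_substrate_side_sorted(self, multi_compartment_net):
        net = multi_compartment_net
        assert compartment_label(net.reactions["T2"], net) == "cm-c"

    def test_products_only_renders_empty_substrate_side(self, multi_compartment_net):
        net = multi_compartment_net
        assert compartment_label(net.reactions["EX"], net) == "-e"

    def test_multicharacter_codes_use_commas(self):
        net = _net(
            [{"id": "R", "stoich": {"X": -1, "Y": 1}, "lb": 0, "ub": 1}],
            [{"id": "X", "compartment": "cyto"}, {"id": "Y", "compartment": "mito"}],
        )
        assert compartment_label(net.reactions["R"], net) == "cyto-mito"

    def test_canonical_mode_orients_sides(self, multi_compartment_net):
        net = multi_compartment_net
        rev = net.reactions["T1"]
        rev.stoich = {"A_e": -1, "A_c": 1}  # written backwards
        assert compartment_label(rev, net) == "e-c"
        assert compartment_label(rev, net, canonical=True) == "c-e"


@pytest.fixture()
def paired_rule_net():
    mets = [{"id": "A", "compartment": "c"}, {"id": "B", "compartment": "c"}]
    rxns = [
        {"id": "R1", "stoich": {"A": -1, "B": 1}, "lb": 0, "ub": 10, "rule": "G1"},
        {"id": "R2", "stoich": {"A": -1, "B": 1}, "lb": 0, "ub": 10, "rule": "G1"},
        {"id": "R3", "stoich": {"B": -1}, "lb": 0, "ub": 10, "rule": "G2"},
        {"id": "R4", "stoich": {"A": 1}, "lb": 0, "ub": 10},
    ]
    return _net(rxns, mets)


class TestAggregate:
    def test_same_rule_same_label_averaged(self, paired_rule_net):
        M = pd.DataFrame({"R1": [1, 1], "R2": [0, 1], "R3": [1, 0], "R4": [0, 0]},
                         index=["S1", "S2"])
        adj = aggregate(M, paired_rule_net)
        merged = [c for c, members in adj.groups.items() if set(members) == {"R1", "R2"}]
        assert len(merged) == 1
        assert adj.frame.loc["S1", merged[0]] == pytest.approx(0.5)
        assert adj.frame.loc["S2", merged[0]] == pytest.approx(1.0)

    def test_singletons_unchanged(self, paired_rule_net):
        M = pd.DataFrame({"R1": [1], "R2": [0], "R3": [1], "R4": [1]}, index=["S1"])
        adj = aggregate(M, paired_rule_net)
        assert adj.frame.loc["S1", "R3"] == 1.0
        assert adj.frame.loc["S1", "R4"] == 1.0  # rule-free pass-through

    def test_rule_restriction(self, paired_rule_net):
        M = pd.DataFrame({"R1": [1], "R2": [0], "R3": [1], "R4": [1]}, index=["S1"])
        adj = aggregate(M, paired_rule_net, rules=set())  # nothing flagged
        assert list(adj.frame.columns) == ["R1", "R2", "R3", "R4"]

    def test_planted_hub_collapses_to_single_column(self):
        spec = HubSpec(n_background_reactions=5, n_hubs=1, hub_size=94, seed=1)
        net = generate_hub_network(spec)
        hub_cols = [r for r in net.reactions if r.startswith("H0R")]
        M = pd.DataFrame(1, index=["S1", "S2"], columns=list(net.reactions))
        adj = aggregate(M, net)
        assert M.shape[1] - adj.frame.shape[1] == 93
        hub_agg = [c for c, mem in adj.groups.items() if set(mem) == set(hub_cols)]
        assert len(hub_agg) == 1 and (adj.frame[hub_agg[0]] == 1.0).all()

    @given(st.integers(0, 2 ** 30))
    def test_mass_conservation(self, seed):
        """Per sample, sum over aggregates of size x value equals the sum
        of member activities."""
        rng = np.random.default_rng(seed)
        spec = HubSpec(n_background_reactions=8, n_hubs=1, hub_size=5, seed=0)
        net = generate_hub_network(spec)
        M = random_binary_matrix(rng, 4, len(net.reactions))
        M.columns = list(net.reactions)
        adj = aggregate(M, net)
        for s in M.index:
            total = sum(len(adj.groups[c]) * adj.frame.loc[s, c] for c in adj.frame.columns)
            assert total == pytest.approx(M.loc[s].sum())

    def test_idempotent(self, paired_rule_net):
        M = pd.DataFrame({"R1": [1, 0], "R2": [0, 0], "R3": [1, 1], "R4": [0, 1]},
                         index=["S1", "S2"])
        once = aggregate(M, paired_rule_net)
        twice = aggregate(once, paired_rule_net)
        pd.testing.assert_frame_equal(once.frame, twice.frame)
        assert once.groups == twice.groups


class TestDetectRedundantGroups:
    @pytest.fixture()
    def hub_setup(self):
        spec = HubSpec(n_background_reactions=30, n_hubs=1, hub_size=20,
                       internal_density=1.0, external_links=2, seed=6)
        net = generate_hub_network(spec)
        ents = rule_group_entropies(net, reaction_graph(net), n_samples=300, seed=0)
        return spec, net, ents

    def test_hub_driving_pc1_is_flagged(self, hub_setup):
        spec, net, ents = hub_setup
        rng = np.random.default_rng(0)
        hub_cols = [r for r in net.reactions if r.startswith("H0R")]
        M = random_binary_matrix(rng, 30, len(net.reactions))
        M.columns = list(net.reactions)
        # hub columns move together, driven by one latent gene state
        hub_state = rng.integers(0, 2, size=30)
        for c in hub_cols:
            M[c] = hub_state
        sel = select_variables(pca(M, 2), f="frac:0.5", k=1)
        flagged = detect_redundant_groups(sel, ents, net)
        assert [g.rule.render() for g in flagged] == [spec.hub_gene(0)]

    def test_high_entropy_group_not_flagged(self, hub_setup):
        spec, net, ents = hub_setup
        # pretend every background reaction was selected: their groups are
        # singletons with ordinary entropy, so criterion (b) fails
        rng = np.random.default_rng(1)
        M = random_binary_matrix(rng, 20, len(net.reactions))
        M.columns = list(net.reactions)
        sel = select_variables(pca(M, 2), f="frac:0", k=2)  # select everything
        relaxed = ents.copy()
        flagged = detect_redundant_groups(sel, relaxed, net)
        bg_rules = {f"GB{j}" for j in range(30)}
        flagged_bg = [g for g in flagged if g.rule.render() in bg_rules
                      and ents.set_index("rule").loc[g.rule.render(), "percentile"] >= 5]
        assert flagged_bg == []

    def test_empty_selection_flags_nothing(self, hub_setup):
        _, net, ents = hub_setup
        rng = np.random.default_rng(2)
        M = random_binary_matrix(rng, 10, len(net.reactions))
        M.columns = list(net.reactions)
        dec = pca(M, 1)
        sel = select_variables(dec, f="frac:0.5", k=0)
        assert detect_redundant_groups(sel, ents, net) == []
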