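"""Taxon removal and synergistic complementation simulations."""

import itertools

import pandas as pd
import pytest

from conftest import make_bank, make_reaction
from rhizoscope._errors import ValidationError
from rhizoscope.perturb import (
    ALL_GROUPS,
    core_enzymes,
    dominated_enzymes,
    simulate_complementation,
    simulate_removal,
)


def dom_table(assignments, environment="root"):
    """assignments: {taxon: [enzymes]} -> a dominance table where each listed
    enzyme is dominated by its taxon, plus one non-dominated enzyme."""
    rows = []
    for taxon, enzymes in assignments.items():
        for e in enzymes:
            rows.append((e, environment, 0.9, taxon, True))
    rows.append(("9.9.9.9", environment, 0.15, None, False))
    return pd.DataFrame(
        rows,
        columns=["enzyme", "environment", "simpson_mean", "consensus_taxon", "dominated"],
    )


@pytest.fixture
def bridge_bank():
    """Chain A -> B -> C -> D; taxon X dominates the A->B bridge, taxon Y the
    C->D tail; 2.2.2.2 (B->C) is core."""
    return make_bank(
        make_reaction("R1", ["A"], ["B"], ec="1.1.1.1"),
        make_reaction("R2", ["B"], ["C"], ec="2.2.2.2"),
        make_reaction("R3", ["C"], ["D"], ec="3.3.3.3"),
        compound_pathways={"A": {"pw1"}, "B": {"pw1"}, "C": {"pw1"}, "D": {"pw2"}},
    )


class TestDominatedEnzymes:
    def test_planted_assignment_recovered(self, fixture_study):
        fx, _, table, _ = fixture_study
        for taxon, ecs in fx.assignments.items():
            for env in fx.catalog.design["environment"].unique():
                assert dominated_enzymes(table, env, taxon) == ecs

    def test_non_key_taxon_rejected_with_key_list(self, fixture_study):
        _, _, table, _ = fixture_study
        with pytest.raises(ValidationError, match="key group"):
            dominated_enzymes(table, "root", "Vibrionales")

    def test_all_sentinel_is_union(self, fixture_study):
        fx, _, table, _ = fixture_study
        union = frozenset().union(*fx.assignments.values())
        assert dominated_enzymes(table, "root", ALL_GROUPS) == union


class TestSimulateRemoval:
    def test_bridge_removal_loses_downstream(self, bridge_bank):
        table = dom_table({"X": ["1.1.1.1"], "Y": ["3.3.3.3"]})
        enzymes = {"1.1.1.1", "2.2.2.2", "3.3.3.3"}
        res = simulate_removal(bridge_bank, enzymes, {"A"}, table, "root", "X")
        assert res.missing_metabolites == {"B", "C", "D"}
        assert res.reduction_fraction == pytest.approx(3 / 4)

    def test_tail_removal_loses_only_tail(self, bridge_bank):
        table = dom_table({"X": ["1.1.1.1"], "Y": ["3.3.3.3"]})
        enzymes = {"1.1.1.1", "2.2.2.2", "3.3.3.3"}
        res = simulate_removal(bridge_bank, enzymes, {"A"}, table, "root", "Y")
        assert res.missing_metabolites == {"D"}

    def test_pathway_effect_fractions(self, bridge_bank):
        table = dom_table({"X": ["1.1.1.1"], "Y": ["3.3.3.3"]})
        enzymes = {"1.1.1.1", "2.2.2.2", "3.3.3.3"}
        res = simulate_removal(bridge_bank, enzymes, {"A"}, table, "root", "Y")
        eff = res.pathway_effects
        assert eff["pw1"].fraction_remaining == pytest.approx(1.0)
        assert eff["pw2"].fraction_missing == pytest.approx(1.0)
        for e in eff.values():
            assert e.fraction_remaining + e.fraction_missing == pytest.approx(1.0)
        tab = res.effect_table()
        assert list(tab["effect_score"]) == list(tab["fraction_remaining"])

    def test_removing_nothing_loses_nothing(self, bridge_bank):
        table = dom_table({"X": [], "Y": ["3.3.3.3"]})
        table = pd.concat(
            [table, dom_table({"X": ["5.5.5.5"]})], ignore_index=True
        )  # X dominates an enzyme absent from the bank
        enzymes = {"1.1.1.1", "2.2.2.2", "3.3.3.3"}
        res = simulate_removal(bridge_bank, enzymes, {"A"}, table, "root", "X")
        assert not res.missing_metabolites
        assert res.reduction_fraction == 0.0

    def test_planted_fixture_exact_recovery(self, fixture_study):
        fx, _, table, meta_seeds = fixture_study
        for env in ("root", "soil"):
            for taxon, expected in fx.truth["removal_missing"].items():
                res = simulate_removal(
                    fx.bank, fx.bank.enzymes, meta_seeds, table, env, taxon
                )
                assert sorted(res.missing_metabolites) == expected

    def test_all_removal_superset_of_singles(self, fixture_study):
        fx, _, table, meta_seeds = fixture_study
        res_all = simulate_removal(
            fx.bank, fx.bank.enzymes, meta_seeds, table, "root", ALL_GROUPS
        )
        for taxon in fx.assignments:
            res = simulate_removal(
                fx.bank, fx.bank.enzymes, meta_seeds, table, "root", taxon
            )
            assert res.missing_metabolites <= res_all.missing_metabolites
            assert res.truncated.reachable <= res.reference.reachable


class TestSimulateComplementation:
    def _three_step_bank(self):
        """Core makes A; X dominates A->B; Y dominates B->C."""
        return make_bank(
            make_reaction("R0", ["S"], ["A"], ec="0.1.1.1"),
            make_reaction("R1", ["A"], ["B"], ec="1.1.1.1"),
            make_reaction("R2", ["B"], ["C"], ec="2.2.2.2"),
            compound_pathways={"C": {"pwC"}},
        )

    def test_sequential_steps_complement(self):
        bank = self._three_step_bank()
        table = dom_table({"X": ["1.1.1.1"], "Y": ["2.2.2.2"]})
        res = simulate_complementation(
            bank, bank.enzymes, {"S"}, table, "root", {"X", "Y"}
        )
        assert res.complementary_metabolites == {"C"}
        assert res.pathway_counts == {"pwC": 1}

    def test_disconnected_dominated_reactions_give_empty(self):
        bank = make_bank(
            make_reaction("R0", ["S"], ["A"], ec="0.1.1.1"),
            make_reaction("R1", ["A"], ["B"], ec="1.1.1.1"),
            make_reaction("R2", ["S"], ["D"], ec="2.2.2.2"),
        )
        table = dom_table({"X": ["1.1.1.1"], "Y": ["2.2.2.2"]})
        res = simulate_complementation(
            bank, bank.enzymes, {"S"}, table, "root", {"X", "Y"}
        )
        assert not res.complementary_metabolites

    def test_joint_equal_union_gives_empty(self):
        bank = make_bank(
            make_reaction("R0", ["S"], ["A"], ec="0.1.1.1"),
            make_reaction("R1", ["A"], ["B"], ec="1.1.1.1"),
            make_reaction("R2", ["A"], ["B"], ec="2.2.2.2"),  # same conversion
        )
        table = dom_table({"X": ["1.1.1.1"], "Y": ["2.2.2.2"]})
        res = simulate_complementation(
            bank, bank.enzymes, {"S"}, table, "root", {"X", "Y"}
        )
        assert not res.complementary_metabolites

    def test_pair_required(self):
        bank = self._three_step_bank()
        table = dom_table({"X": ["1.1.1.1"], "Y": ["2.2.2.2"]})
        with pytest.raises(ValidationError):
            simulate_complementation(bank, bank.enzymes, {"S"}, table, "root", {"X"})

    def test_symmetric_in_member_order(self, fixture_study):
        fx, _, table, meta_seeds = fixture_study
        a, b = fx.truth["complementation"]["pair"]
        r1 = simulate_complementation(
            fx.bank, fx.bank.enzymes, meta_seeds, table, "root", {a, b}
        )
        r2 = simulate_complementation(
            fx.bank, fx.bank.enzymes, meta_seeds, table, "root", {b, a}
        )
        assert r1.complementary_metabolites == r2.complementary_metabolites

    def test_planted_chain_recovered_with_negative_control(self, fixture_study):
        fx, _, table, meta_seeds = fixture_study
        ct = fx.truth["complementation"]
        a, b = ct["pair"]
        res = simulate_complementation(
            fx.bank, fx.bank.enzymes, meta_seeds, table, "root", {a, b}
        )
        assert sorted(res.complementary_metabolites) == ct["expected_complementary"]
        # invariants: joint covers singles; surplus is exactly complementary
        union = frozenset().union(*(s.reachable for s in res.singles.values()))
        assert union <= res.joint.reachable
        assert res.complementary_metabolites == res.joint.reachable - union

    def test_core_excludes_every_key_group(self, fixture_study):
        fx, _, table, _ = fixture_study
        core = core_enzymes(table, "root", fx.bank.enzymes)
        for ecs in fx.assignments.values():
            assert not core & ecs
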