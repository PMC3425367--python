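"""Cascade engine: channel enumeration, sampling, propagation, tree oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from augermc import EnergyModel, make_toy_atom
from augermc.atomic import ValidationError
from augermc.cascade import (
    AtomState,
    Channel,
    NodeBudgetExceeded,
    allowed_transitions,
    apply_transition,
    enumerate_cascade_tree,
    run_cascade,
    select_transition,
)


class TestAllowedTransitions:
    def test_neutral_state_weights_equal_table_rates(self, toy5):
        table, rates, model = toy5
        state = AtomState.neutral(table)
        state.ionize("K")
        channels = allowed_transitions(state, "K", rates, model)
        for c in channels:
            key = tuple(c.shells)
            rate = rates.radiative[key] if c.kind == "xray" else rates.nonradiative[key]
            assert c.weight == pytest.approx(rate)

    def test_emptied_subshell_disables_its_channels(self, toy5):
        table, rates, model = toy5
        state = AtomState.neutral(table)
        state.ionize("K")
        state.occupancy["L1"] = 0
        channels = allowed_transitions(state, "K", rates, model)
        assert all("L1" not in c.shells for c in channels)

    def test_missing_vacancy_is_a_contract_violation(self, toy5):
        table, rates, model = toy5
        state = AtomState.neutral(table)
        with pytest.raises(ValidationError, match="no vacancy"):
            allowed_transitions(state, "K", rates, model)

    def test_z_plus_one_mode_excludes_marginal_channels(self):
        """A channel open with neutral energies closes under the Z+1 rule.

        K - L1 - L2 = 15 eV > 0 with neutral binding energies, but the Z+1
        neighbour binds L2 at 130 eV, driving the Auger energy negative; the
        expected channel lists are enumerated by hand.
        """
        table, rates = make_toy_atom(
            3, binding_energies=[1000.0, 880.0, 105.0], occupancies=[2, 2, 1]
        )
        zp1, _ = make_toy_atom(
            3, binding_energies=[1200.0, 990.0, 130.0], occupancies=[2, 2, 2]
        )
        neutral = EnergyModel("neutral", table)
        zmode = EnergyModel("z_plus_one", table, zp1)
        state = AtomState.neutral(table)
        state.ionize("K")
        chan_n = {(c.kind,) + c.shells for c in
                  allowed_transitions(state, "K", rates, neutral)}
        # by hand: radiative K<-L1 (120 eV), K<-L2 (895 eV); Auger KL1L1
        # (1000-880-880 < 0) closed, KL1L2 (1000-880-105 = 15 eV) open,
        # KL2L2 needs two L2 electrons but only one is present
        assert chan_n == {
            ("xray", "K", "L1"),
            ("xray", "K", "L2"),
            ("auger", "K", "L1", "L2"),
        }
        chan_z = {(c.kind,) + c.shells for c in
                  allowed_transitions(state, "K", rates, zmode)}
        # under Z+1 the ejected L2 electron costs 130 eV: 1000-880-130 < 0
        assert chan_z == {("xray", "K", "L1"), ("xray", "K", "L2")}


class TestSelectTransition:
    def test_single_channel_always_selected(self, rng):
        c = Channel("xray", ("K", "L1"), 900.0, 0.3)
        for _ in range(50):
            assert select_transition([c], rng) is c

    def test_frequencies_match_normalized_weights(self, rng):
        channels = [
            Channel("xray", ("K", "L1"), 900.0, 3.0),
            Channel("auger", ("K", "L1", "L1"), 800.0, 1.0),
        ]
        n = 100_000
        hits = sum(
            1 for _ in range(n) if select_transition(channels, rng).kind == "xray"
        )
        sigma = np.sqrt(n * 0.75 * 0.25)
        assert abs(hits - n * 0.75) < 4 * sigma

    def test_empty_list_rejected(self, rng):
        with pytest.raises(ValidationError):
            select_transition([], rng)


class TestApplyTransition:
    def test_xray_moves_the_vacancy_outward(self, toy5):
        table, rates, model = toy5
        state = AtomState.neutral(table)
        state.ionize("K")
        state.vacancies.pop()
        e = apply_transition(state, Channel("xray", ("K", "L3"), 900.0, 1.0), 1)
        assert state.occupancy["K"] == table["K"].neutral_occupancy
        assert state.occupancy["L3"] == table["L3"].neutral_occupancy - 1
        assert state.vacancies == [("L3", 1)]
        assert state.n_vacancies() == 1
        assert e.kind == "xray" and e.step == 1

    def test_auger_converts_one_vacancy_into_two(self, toy5):
        table, rates, model = toy5
        state = AtomState.neutral(table)
        state.ionize("K")
        state.vacancies.pop()
        apply_transition(state, Channel("auger", ("K", "L1", "L2"), 800.0, 1.0), 1)
        assert state.occupancy["L1"] == table["L1"].neutral_occupancy - 1
        assert state.occupancy["L2"] == table["L2"].neutral_occupancy - 1
        assert sorted(state.vacancies) == [("L1", 1), ("L2", 1)]
        assert state.n_vacancies() == 2

    def test_replay_of_logged_channels_reproduces_final_state(self, toy5, rng):
        table, rates, model = toy5
        event = run_cascade(table, rates, "K", rng, model)
        # replay: re-apply the logged emissions in order on a fresh state
        state = AtomState.neutral(table)
        state.ionize("K")
        for e in event.emissions:
            state.vacancies.remove((e.shells[0], e.step - 1))
            apply_transition(state, Channel(e.kind, e.shells, e.energy, 1.0), e.step)
        assert state.n_vacancies() == event.final_charge


class TestRunCascade:
    def test_valence_initial_vacancy_emits_nothing(self, toy3, rng):
        table, rates, model = toy3
        event = run_cascade(table, rates, "L1", rng, model)
        assert event.emissions == ()
        assert event.final_charge == 1
        assert event.terminal_vacancies == ("L1",)

    def test_charge_equals_one_plus_auger_count(self, toy5, rng):
        table, rates, model = toy5
        for _ in range(500):
            event = run_cascade(table, rates, "K", rng, model)
            assert event.final_charge == 1 + event.n_auger

    def test_vacancy_with_no_channels_is_frozen(self):
        # single deep shell with an empty rate table: nothing can happen
        table, _ = make_toy_atom(3, rate_seed=0)
        from augermc.atomic import RateSet

        rates = RateSet(radiative={}, nonradiative={})
        model = EnergyModel("neutral", table)
        event = run_cascade(table, rates, "K", np.random.default_rng(0), model)
        assert event.emissions == ()
        assert event.frozen_vacancies == ("K",)
        assert event.final_charge == 1

    def test_step_indices_follow_vacancy_genealogy(self, toy5, rng):
        table, rates, model = toy5
        for _ in range(100):
            event = run_cascade(table, rates, "K", rng, model)
            if not event.emissions:
                continue
            assert event.emissions[0].step == 1
            assert all(e.step >= 1 for e in event.emissions)
            assert event.steps_used == max(e.step for e in event.emissions)


class TestTreeOracle:
    def test_single_forced_path_has_probability_one(self):
        table, _ = make_toy_atom(2, binding_energies=[1000.0, 10.0])
        from augermc.atomic import RateSet

        rates = RateSet(radiative={("K", "L1"): 1.0}, nonradiative={})
        model = EnergyModel("neutral", table)
        tree = enumerate_cascade_tree(table, rates, "K", model)
        assert tree.outcomes == {(("xray", "K", "L1"),): pytest.approx(1.0)}

    @pytest.mark.parametrize("n,seed", [(3, 7), (4, 7), (5, 3)])
    def test_outcome_probabilities_sum_to_one(self, n, seed):
        table, rates = make_toy_atom(n, rate_seed=seed)
        model = EnergyModel("neutral", table)
        tree = enumerate_cascade_tree(table, rates, "K", model)
        assert tree.total_probability() == pytest.approx(1.0, abs=1e-12)

    def test_node_budget_refusal(self, toy5):
        table, rates, model = toy5
        with pytest.raises(NodeBudgetExceeded):
            enumerate_cascade_tree(table, rates, "K", model, node_budget=10)

    def test_mc_frequencies_match_tree(self, toy3, rng):
        table, rates, model = toy3
        tree = enumerate_cascade_tree(table, rates, "K", model)
        n = 20_000
        counts = {}
        for _ in range(n):
            key = run_cascade(table, rates, "K", rng, model).outcome_key()
            counts[key] = counts.get(key, 0) + 1
        assert set(counts) <= set(tree.outcomes)
        for key, p in tree.outcomes.items():
            sigma = max(np.sqrt(n * p * (1 - p)), 1.0)
            assert abs(counts.get(key, 0) - n * p) < 4 * sigma

    def test_first_step_split_reproduces_fluorescence_yield(self, toy5, rng):
        """Fraction of radiative first transitions equals omega_K."""
        table, rates, model = toy5
        omega = rates.fluorescence_yield("K")
        n = 50_000
        radiative = 0
        for _ in range(n):
            event = run_cascade(table, rates, "K", rng, model)
            assert event.emissions, "K vacancy must relax in this fixture"
            radiative += event.emissions[0].kind == "xray"
        sigma = np.sqrt(n * omega * (1 - omega))
        assert abs(radiative - n * omega) < 4 * sigma


class TestPropagationProperties:
    @given(
        n=st.integers(2, 5),
        rate_seed=st.integers(0, 10_000),
        mc_seed=st.integers(0, 10_000),
    )
    def test_termination_outward_flow_and_positive_energies(
        self, n, rate_seed, mc_seed
    ):
        table, rates = make_toy_atom(n, rate_seed=rate_seed)
        model = EnergyModel("neutral", table)
        rng = np.random.default_rng(mc_seed)
        event = run_cascade(table, rates, "K", rng, model)
        for e in event.emissions:
            assert e.energy > 0
            x, rest = e.shells[0], e.shells[1:]
            for y in rest:
                assert table.binding(x) > table.binding(y)
        assert event.final_charge == 1 + event.n_auger
        assert all(lab in table.valence_labels for lab in event.terminal_vacancies)
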