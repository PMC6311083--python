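"""Core dynamics: resources, unit-step evolution, asynchronous state graphs."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brnest import (
    CapacityError,
    Entity,
    IncompleteParametrizationError,
    Interaction,
    ModelError,
    Parametrization,
    RegulatoryNetwork,
    build_state_graph,
    evolve_level,
    resources,
    state_space_size,
    successors,
)
from brnest.fixtures import hbp_like_model, random_brn

from conftest import random_parametrization


class TestNetworkValidation:
    def test_rejects_duplicate_entities(self):
        with pytest.raises(ModelError, match="duplicate"):
            RegulatoryNetwork([Entity("a", 1), Entity("a", 2)], [])

    def test_rejects_undeclared_endpoint(self):
        with pytest.raises(ModelError, match="undeclared"):
            RegulatoryNetwork([Entity("a", 1)], [Interaction("a", "b", 1, "+")])

    def test_rejects_threshold_above_source_range(self):
        with pytest.raises(ModelError, match="threshold"):
            RegulatoryNetwork(
                [Entity("a", 1), Entity("b", 1)], [Interaction("a", "b", 2, "+")]
            )

    def test_rejects_parallel_interactions(self):
        with pytest.raises(ModelError, match="multiple interactions"):
            RegulatoryNetwork(
                [Entity("a", 1)],
                [Interaction("a", "a", 1, "+"), Interaction("a", "a", 1, "-")],
            )

    def test_max_level_out_degree_mismatch_warns_not_fails(self, caplog):
        # the declared VAR range is authoritative; a mismatch only warns
        with caplog.at_level("WARNING", logger="brnest.model_core"):
            net = RegulatoryNetwork(
                [Entity("a", 3), Entity("b", 1)], [Interaction("a", "b", 1, "+")]
            )
        assert net.entity("a").max_level == 3
        assert any("out-degree" in r.message for r in caplog.records)


class TestResources:
    def test_self_activator_present_inhibitor_excluded(self, pseudomonas):
        # x at threshold 2 is its own resource; inhibitor y present, excluded
        assert resources(pseudomonas.network, (2, 1), "x") == ("x",)

    def test_absent_inhibitor_counts_as_resource(self, pseudomonas):
        assert resources(pseudomonas.network, (0, 0), "x") == ("y",)

    @pytest.mark.parametrize("state", [(0, 0), (1, 0), (2, 0), (0, 1), (1, 1), (2, 1)])
    def test_entity_without_predecessors_has_empty_resources(self, state):
        net = RegulatoryNetwork(
            [Entity("x", 2), Entity("y", 1)], [Interaction("x", "y", 1, "+")]
        )
        assert resources(net, state, "x") == ()

    def test_unknown_entity_rejected(self, pseudomonas):
        with pytest.raises(ModelError, match="not declared"):
            resources(pseudomonas.network, (0, 0), "z")

    def test_monotone_in_regulator_levels(self):
        # raising an activator never removes it from W; raising an
        # inhibitor never adds it
        rng = random.Random(7)
        for seed in range(20):
            fx = random_brn(4, 2, 0.6, seed=seed)
            net = fx.network
            state = tuple(rng.randint(0, e.max_level) for e in net.entities)
            for target in net.names:
                base = set(resources(net, state, target))
                for ia in net.incoming(target):
                    i = net.index_of(ia.source)
                    if state[i] == net.entities[i].max_level:
                        continue
                    raised = state[:i] + (state[i] + 1,) + state[i + 1:]
                    after = set(resources(net, raised, target))
                    if ia.sign == "+" and ia.source in base:
                        assert ia.source in after
                    if ia.sign == "-" and ia.source not in base:
                        assert ia.source not in after


class TestEvolveLevel:
    @pytest.mark.parametrize(
        "current,k,expected",
        [(0, 2, 1), (1, 1, 1), (2, 0, 1), (0, 1, 1), (3, 1, 2), (2, 2, 2)],
    )
    def test_moves_one_unit_toward_target(self, current, k, expected):
        assert evolve_level(current, k) == expected

    def test_rejects_negative_levels(self):
        with pytest.raises(ModelError):
            evolve_level(-1, 0)


class TestSuccessors:
    def test_stable_pathogenic_state_is_deadlock(self, pseudomonas, pseudo_param):
        assert successors(pseudomonas.network, pseudo_param, (2, 1)) == frozenset()

    def test_single_step_toward_target(self, pseudomonas, pseudo_param):
        assert successors(pseudomonas.network, pseudo_param, (1, 1)) == frozenset({(0, 1)})

    def test_all_entities_on_target_gives_no_successor(self):
        net = RegulatoryNetwork([Entity("a", 1), Entity("b", 1)], [])
        p = Parametrization({("a", ()): 1, ("b", ()): 0})
        assert successors(net, p, (1, 0)) == frozenset()

    def test_incomplete_parametrization_rejected(self, pseudomonas):
        p = Parametrization({("x", ()): 0})
        with pytest.raises(IncompleteParametrizationError):
            successors(pseudomonas.network, p, (0, 0))


class TestStateGraph:
    def test_pseudomonas_graph_has_six_states(self, pseudo_graph):
        assert pseudo_graph.n_states == 6

    def test_contains_homeostasis_cycle_and_stable_state(self, pseudo_graph):
        cycle = [(0, 0), (1, 0), (1, 1), (0, 1)]
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            assert (a, b) in pseudo_graph.transitions
        assert (2, 1) in pseudo_graph.deadlocks

    def test_hbp_like_graph_has_512_states(self):
        fx = hbp_like_model()
        rng = random.Random(0)
        graph = build_state_graph(fx.network, random_parametrization(fx.network, rng))
        assert graph.n_states == 512 == state_space_size(fx.network)

    def test_capacity_cap_raises(self, pseudomonas, pseudo_param):
        with pytest.raises(CapacityError, match="cap"):
            build_state_graph(pseudomonas.network, pseudo_param, state_cap=5)

    def test_rebuild_is_identical(self, pseudomonas, pseudo_param):
        g1 = build_state_graph(pseudomonas.network, pseudo_param)
        g2 = build_state_graph(pseudomonas.network, pseudo_param)
        assert g1.transitions == g2.transitions
        assert g1.deadlocks == g2.deadlocks

    @pytest.mark.parametrize("seed", range(8))
    def test_unit_step_deadlock_and_size_invariants(self, seed):
        # every transition moves exactly one entity by one unit; deadlocks
        # are exactly the states with every level on its K target; the
        # state count equals the level-range product
        rng = random.Random(seed)
        fx = random_brn(3, 2, 0.6, seed=seed)
        p = random_parametrization(fx.network, rng)
        graph = build_state_graph(fx.network, p)
        assert graph.n_states == state_space_size(fx.network)
        for s, t in graph.transitions:
            assert sum(abs(a - b) for a, b in zip(s, t)) == 1
            assert s != t
        for s in graph.states:
            stable = all(
                s[i] == p.k(e.name, resources(fx.network, s, e.name))
                for i, e in enumerate(fx.network.entities)
            )
            assert (s in graph.deadlocks) == stable
            out_degree = sum(1 for (a, _) in graph.transitions if a == s)
            assert out_degree <= len(fx.network.entities)


class TestStateSpaceSize:
    def test_nine_boolean_entities(self):
        net = RegulatoryNetwork([Entity(f"g{i}", 1) for i in range(9)], [])
        assert state_space_size(net) == 512

    def test_single_boolean_entity(self):
        assert state_space_size(RegulatoryNetwork([Entity("a", 1)], [])) == 2

    def test_twenty_three_boolean_entities(self):
        net = RegulatoryNetwork([Entity(f"g{i}", 1) for i in range(23)], [])
        assert state_space_size(net) == 8_388_608

    @given(levels=st.lists(st.integers(min_value=1, max_value=4), min_size=1, max_size=6))
    @settings(derandomize=True, max_examples=30)
    def test_equals_product_of_ranges(self, levels):
        net = RegulatoryNetwork([Entity(f"g{i}", l) for i, l in enumerate(levels)], [])
        expected = 1
        for l in levels:
            expected *= l + 1
        assert state_space_size(net) == expected
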