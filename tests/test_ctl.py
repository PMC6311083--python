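"""CTL parsing and fixpoint labeling, checked against a naive path/SCC oracle."""

import random

import pytest

from brnest import (
    CtlSyntaxError,
    Entity,
    ModelError,
    Parametrization,
    RegulatoryNetwork,
    StateGraph,
    build_state_graph,
    holds_everywhere,
    parse_ctl,
    sat_set,
    unparse,
    violating_states,
)
from brnest import ctl as c
from brnest.fixtures import hbp_like_model

from conftest import random_formula, random_small_graph
from naive_ctl import naive_sat


class TestParser:
    def test_published_observation_shape(self):
        net = hbp_like_model().network
        f = parse_ctl(
            "(OGT=1,OGA=0) -> EF(AG(OGT=1,OGA=0,PI3K=1,FoXM1=1,P21=0,CMyc=1))", net
        )
        assert isinstance(f, c.Implies)
        assert f.left == c.And(c.LevelAtom("OGT", 1), c.LevelAtom("OGA", 0))
        assert isinstance(f.right, c.EF)
        assert isinstance(f.right.operand, c.AG)
        # the AG body is a left-nested conjunction of six atoms
        body, n_atoms = f.right.operand.operand, 0
        while isinstance(body, c.And):
            assert isinstance(body.right, c.LevelAtom)
            n_atoms += 1
            body = body.left
        assert isinstance(body, c.LevelAtom)
        assert n_atoms + 1 == 6

    def test_simple_atom(self, pseudomonas):
        assert parse_ctl("x=0", pseudomonas.network) == c.LevelAtom("x", 0)

    @pytest.mark.parametrize("text", ["EF(x=2", "x=", "->x=0", "E[x=0 U", "x=0 y=1"])
    def test_syntax_errors_carry_position(self, text, pseudomonas):
        with pytest.raises(CtlSyntaxError, match="position"):
            parse_ctl(text, pseudomonas.network)

    def test_unknown_entity_rejected(self, pseudomonas):
        with pytest.raises(ModelError, match="not declared"):
            parse_ctl("z=0", pseudomonas.network)

    def test_level_outside_declared_range_rejected(self, pseudomonas):
        with pytest.raises(ModelError, match="outside"):
            parse_ctl("x=9", pseudomonas.network)

    def test_precedence_and_associativity(self, pseudomonas):
        # ! > & > | > ->, with -> right-associative and comma == &
        f = parse_ctl("!x=0 & x=1 | y=0 -> x=2 -> y=1", pseudomonas.network)
        x0, x1, x2 = (c.LevelAtom("x", n) for n in range(3))
        y0, y1 = c.LevelAtom("y", 0), c.LevelAtom("y", 1)
        assert f == c.Implies(c.Or(c.And(c.Not(x0), x1), y0), c.Implies(x2, y1))
        assert parse_ctl("x=0,y=1", pseudomonas.network) == parse_ctl(
            "x=0 & y=1", pseudomonas.network
        )

    def test_until_forms_and_bare_x(self, pseudomonas):
        f = parse_ctl("E[x=0 U y=1]", pseudomonas.network)
        assert f == c.EU(c.LevelAtom("x", 0), c.LevelAtom("y", 1))
        g = parse_ctl("A[x=0 U y=1]", pseudomonas.network)
        assert g == c.AU(c.LevelAtom("x", 0), c.LevelAtom("y", 1))
        # a bare X is read as AX
        assert parse_ctl("X(x=0)", pseudomonas.network) == c.AX(c.LevelAtom("x", 0))

    def test_unparse_round_trip(self, pseudomonas):
        rng = random.Random(11)
        for _ in range(30):
            f = random_formula(pseudomonas.network, rng, depth=3)
            assert parse_ctl(unparse(f), pseudomonas.network) == f


def _two_state_chain():
    """a -> b with b a deadlock (self-loop appears only after totalization)."""
    net = RegulatoryNetwork([Entity("g", 1)], [])
    return StateGraph(
        network=net,
        states=frozenset({(0,), (1,)}),
        transitions=frozenset({((0,), (1,))}),
        deadlocks=frozenset({(1,)}),
    )


class TestSatSet:
    def test_true_holds_everywhere(self, pseudo_graph):
        assert sat_set(pseudo_graph, c.TRUE).states == pseudo_graph.states

    def test_two_state_chain_af_and_eg(self):
        graph = _two_state_chain()
        phi = c.LevelAtom("g", 1)  # true only at the deadlock b
        assert sat_set(graph, c.AF(phi)).states == {(0,), (1,)}
        assert sat_set(graph, c.EG(phi)).states == {(1,)}

    def test_stable_state_satisfies_ag(self, pseudo_graph):
        # (2,1) is a deadlock; its totalization self-loop is the only path
        assert (2, 1) in sat_set(pseudo_graph, c.AG(c.LevelAtom("x", 2))).states

    def test_totalization_gives_every_state_a_successor(self, pseudo_graph):
        succ = c.totalized_successors(pseudo_graph)
        assert all(len(ts) >= 1 for ts in succ.values())

    def test_eu_least_fixpoint_is_stable(self, pseudo_graph):
        # one more fixpoint iteration adds nothing
        phi, psi = c.TRUE, c.LevelAtom("x", 2)
        sat = sat_set(pseudo_graph, c.EU(phi, psi)).states
        succ = c.totalized_successors(pseudo_graph)
        assert sat_set(pseudo_graph, psi).states <= sat
        expanded = sat | {
            s for s in pseudo_graph.states
            if s in sat_set(pseudo_graph, phi).states
            and any(t in sat for t in succ[s])
        }
        assert expanded == sat

    def test_atom_for_foreign_entity_rejected(self, pseudo_graph):
        with pytest.raises(ModelError, match="not declared"):
            sat_set(pseudo_graph, c.LevelAtom("nope", 0))


class TestHoldsEverywhere:
    def test_tautology_accepted(self, pseudo_graph):
        assert holds_everywhere(pseudo_graph, [c.TRUE])

    def test_contradiction_rejected(self, pseudo_graph):
        assert not holds_everywhere(pseudo_graph, [c.FALSE])

    def test_fixture_observations_hold(self, pseudo_graph, pseudo_formulas):
        assert holds_everywhere(pseudo_graph, pseudo_formulas)

    def test_empty_formula_list_is_usage_error(self, pseudo_graph):
        with pytest.raises(ValueError, match="at least one"):
            holds_everywhere(pseudo_graph, [])

    def test_violating_states_diagnostic(self, pseudo_graph):
        bad = violating_states(pseudo_graph, c.LevelAtom("x", 2))
        assert bad == {s for s in pseudo_graph.states if s[0] != 2}


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(25))
    def test_fixpoint_matches_naive_semantics(self, seed):
        """Random graphs (<=64 states), random formulas: labeling == oracle."""
        graph = random_small_graph(seed)
        rng = random.Random(1000 + seed)
        formulas = [random_formula(graph.network, rng, depth=3) for _ in range(4)]
        # ensure every operator family is exercised as the outermost node
        sub = random_formula(graph.network, rng, depth=1)
        sub2 = random_formula(graph.network, rng, depth=1)
        formulas += [
            c.EX(sub), c.AX(sub), c.EF(sub), c.AF(sub), c.EG(sub), c.AG(sub),
            c.EU(sub, sub2), c.AU(sub, sub2),
        ]
        for f in formulas:
            assert sat_set(graph, f).states == naive_sat(graph, f)

    @pytest.mark.parametrize("seed", range(10))
    def test_duality_identities(self, seed):
        """AG == !EF! and AF == !EG! on arbitrary graph/formula pairs."""
        graph = random_small_graph(100 + seed)
        rng = random.Random(seed)
        phi = random_formula(graph.network, rng, depth=2)
        all_states = graph.states
        assert sat_set(graph, c.AG(phi)).states == all_states - sat_set(
            graph, c.EF(c.Not(phi))).states
        assert sat_set(graph, c.AF(phi)).states == all_states - sat_set(
            graph, c.EG(c.Not(phi))).states

    @pytest.mark.parametrize("seed", range(6))
    def test_ef_monotone_in_operand(self, seed):
        # phi |= phi & psi ... the weaker formula reaches at least as much
        graph = random_small_graph(200 + seed)
        rng = random.Random(seed)
        phi = random_formula(graph.network, rng, depth=2)
        psi = random_formula(graph.network, rng, depth=2)
        stronger = c.And(phi, psi)
        assert sat_set(graph, c.EF(stronger)).states <= sat_set(graph, c.EF(phi)).states
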