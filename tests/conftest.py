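import random

import pytest

from brnest import (
    Parametrization,
    build_state_graph,
    parameter_slots,
    parse_ctl,
    pseudomonas_model,
)
from brnest import ctl as c
from brnest.fixtures import random_brn


@pytest.fixture(scope="session")
def pseudomonas():
    return pseudomonas_model()


@pytest.fixture(scope="session")
def pseudo_param():
    """The parametrization whose state graph shows the homeostasis cycle
    plus the stable pathogenic state (2,1)."""
    return Parametrization({
        ("x", ()): 0,
        ("x", ("x",)): 2,
        ("x", ("y",)): 1,
        ("x", ("x", "y")): 2,
        ("y", ()): 0,
        ("y", ("x",)): 1,
    })


@pytest.fixture(scope="session")
def pseudo_graph(pseudomonas, pseudo_param):
    return build_state_graph(pseudomonas.network, pseudo_param)


@pytest.fixture(scope="session")
def pseudo_formulas(pseudomonas):
    return [parse_ctl(src, pseudomonas.network) for src in pseudomonas.formulas]


def random_parametrization(network, rng: random.Random) -> Parametrization:
    slots = parameter_slots(network)
    return Parametrization({s.key: rng.choice(s.allowed_values) for s in slots})


#: small network shapes with at most 64 qualitative states
SMALL_SHAPES = [(6, 1, 0.25), (5, 1, 0.3), (3, 2, 0.5), (2, 3, 0.8), (4, 1, 0.4)]


def random_small_graph(seed: int):
    """A random state graph with <= 64 states, from a seeded random BRN
    and a random parametrization."""
    rng = random.Random(seed)
    n, level, density = SMALL_SHAPES[seed % len(SMALL_SHAPES)]
    fx = random_brn(n, level, density, seed=seed)
    return build_state_graph(fx.network, random_parametrization(fx.network, rng))


def random_formula(network, rng: random.Random, depth: int = 2) -> c.CtlFormula:
    """A random CTL formula over the network's level atoms."""
    def atom():
        e = rng.choice(network.entities)
        return c.LevelAtom(e.name, rng.randint(0, e.max_level))

    def build(d: int) -> c.CtlFormula:
        if d <= 0 or rng.random() < 0.3:
            return rng.choice([atom(), atom(), c.TRUE, c.FALSE])
        op = rng.randrange(12)
        if op == 0:
            return c.Not(build(d - 1))
        if op == 1:
            return c.And(build(d - 1), build(d - 1))
        if op == 2:
            return c.Or(build(d - 1), build(d - 1))
        if op == 3:
            return c.Implies(build(d - 1), build(d - 1))
        if op == 4:
            return c.EX(build(d - 1))
        if op == 5:
            return c.AX(build(d - 1))
        if op == 6:
            return c.EF(build(d - 1))
        if op == 7:
            return c.AF(build(d - 1))
        if op == 8:
            return c.EG(build(d - 1))
        if op == 9:
            return c.AG(build(d - 1))
        if op == 10:
            return c.EU(build(d - 1), build(d - 1))
        return c.AU(build(d - 1), build(d - 1))

    return build(depth)
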