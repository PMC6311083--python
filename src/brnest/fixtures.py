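"""Built-in example networks: every other module is testable offline.

Two hand-built biological models and a seeded random-network generator:

* the 2-entity mucus-production network of *Pseudomonas aeruginosa*
  (ALGU and its anti-sigma-factor inhibitor), the classic small system
  for qualitative parameter estimation;
* a 9-entity Boolean stand-in for the hexosamine biosynthetic pathway
  (HBP) intersection with PI3K-mTOR-Myc and P53-MDM2 signaling, used for
  structural tests on a 512-state graph;
* ``random_brn`` for property-based testing.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import List, Tuple

from .model_core import ACTIVATION, INHIBITION, Entity, Interaction, ModelError, RegulatoryNetwork

__all__ = ["FixtureSpec", "pseudomonas_model", "hbp_like_model", "random_brn"]


@dataclass(frozen=True)
class FixtureSpec:
    """A named example network plus its CTL observation sources."""

    name: str
    network: RegulatoryNetwork
    formulas: Tuple[str, ...]
    notes: str = ""


def pseudomonas_model() -> FixtureSpec:
    """The two-entity mucus-production network of *P. aeruginosa*.

    Entity ``x`` is the sigma factor ALGU (levels 0..2) with a positive
    autoregulation at threshold 2; ``y`` is its inhibitor (levels 0..1),
    activated by x at threshold 1 and repressing x at threshold 1.  The
    observations encode the two wet-lab behaviors: from the resting state
    the system never over-expresses x (normal homeostasis), and the
    over-expressed state (2,1) is stable (the pathogenic, mucus-producing
    steady state).

    Thresholds and formula texts are reconstructions from the published
    network diagram and its caption prose; they are not printed as data in
    any source, so downstream checks rely on structural claims (existence
    of a cycle and of the stable state (2,1)), never on specific K values.
    """
    network = RegulatoryNetwork(
        entities=[Entity("x", 2), Entity("y", 1)],
        interactions=[
            Interaction("x", "x", 2, ACTIVATION),
            Interaction("x", "y", 1, ACTIVATION),
            Interaction("y", "x", 1, INHIBITION),
        ],
    )
    formulas = (
        "(x=0 & y=0) -> AG(!(x=2))",
        "(x=2 & y=1) -> AG(x=2)",
    )
    return FixtureSpec(
        name="pseudomonas",
        network=network,
        formulas=formulas,
        notes=(
            "ALGU (x) / anti-ALGU (y) mucus-production switch; thresholds and "
            "observation texts reconstructed from the published figure caption."
        ),
    )


#: HBP entity order used for state tuples, matching the published
#: state-graph notation (NFkB,P21,FoXM1,PI3K,P53,MDM2,OGT,OGA,CMyc).
HBP_ENTITY_ORDER = ("NFkB", "P21", "FoXM1", "PI3K", "P53", "MDM2", "OGT", "OGA", "CMyc")


def hbp_like_model() -> FixtureSpec:
    """A 9-entity Boolean stand-in for the HBP/cancer-signaling network.

    The entity order is fixed to the published state notation.  The
    topology is a documented stand-in, not a reproduction of the deposited
    model: it contains the text-attested motifs — the P53-MDM2 negative
    feedback (homeostasis oscillator), CMyc activating OGT, OGA inhibiting
    OGT, and the OGT-CMyc positive loop — plus plausible wiring for the
    remaining entities.  It is intended for structural tests (512-state
    graphs, deadlock queries), not for reproducing published accepted-set
    counts.
    """
    entities = [Entity(name, 1) for name in HBP_ENTITY_ORDER]
    interactions = [
        Interaction("P53", "MDM2", 1, ACTIVATION),
        Interaction("MDM2", "P53", 1, INHIBITION),
        Interaction("CMyc", "OGT", 1, ACTIVATION),
        Interaction("OGA", "OGT", 1, INHIBITION),
        Interaction("OGT", "CMyc", 1, ACTIVATION),
        Interaction("OGT", "FoXM1", 1, ACTIVATION),
        Interaction("FoXM1", "P21", 1, INHIBITION),
        Interaction("P53", "P21", 1, ACTIVATION),
        Interaction("PI3K", "CMyc", 1, ACTIVATION),
        Interaction("PI3K", "NFkB", 1, ACTIVATION),
        Interaction("NFkB", "P53", 1, INHIBITION),
    ]
    network = RegulatoryNetwork(entities, interactions)
    formulas = (
        "(OGT=1,OGA=0) -> EF(AG(OGT=1,OGA=0,PI3K=1,FoXM1=1,P21=0,CMyc=1))",
    )
    return FixtureSpec(
        name="hbp_like",
        network=network,
        formulas=formulas,
        notes=(
            "Synthetic stand-in topology containing the attested motifs "
            "(P53-MDM2 negative feedback, CMyc->OGT, OGA-|OGT, OGT-CMyc loop); "
            "does not reproduce the deposited HBP model."
        ),
    )


def random_brn(
    n_entities: int,
    max_level: int = 1,
    edge_density: float = 0.3,
    seed: int = 0,
) -> FixtureSpec:
    """A seeded random BRN with uniform signs and valid thresholds.

    Every ordered entity pair (self-pairs included) carries an interaction
    with probability ``edge_density``; signs are drawn uniformly and
    thresholds uniformly from ``1..max_level``.  Deterministic across
    platforms for a fixed seed (stdlib Mersenne Twister).
    """
    if n_entities < 1:
        raise ModelError(f"n_entities must be >= 1, got {n_entities}")
    if max_level < 1:
        raise ModelError(f"max_level must be >= 1, got {max_level}")
    if not (0.0 <= edge_density <= 1.0):
        raise ModelError(f"edge_density must lie in [0, 1], got {edge_density}")
    rng = random.Random(seed)
    names = [f"g{i}" for i in range(n_entities)]
    entities = [Entity(n, max_level) for n in names]
    interactions: List[Interaction] = []
    for source in names:
        for target in names:
            if rng.random() < edge_density:
                sign = rng.choice((ACTIVATION, INHIBITION))
                threshold = rng.randint(1, max_level)
                interactions.append(Interaction(source, target, threshold, sign))
    # random topologies do not follow the max_level/out-degree convention,
    # so the validator's advisory warning is suppressed here
    core_logger = logging.getLogger("brnest.model_core")
    previous = core_logger.level
    core_logger.setLevel(logging.ERROR)
    try:
        network = RegulatoryNetwork(entities, interactions)
    finally:
        core_logger.setLevel(previous)
    # a trivially satisfiable observation so the fixture is runnable as-is
    formulas = (f"EF({names[0]}=0) | EF(!({names[0]}=0))",)
    return FixtureSpec(
        name=f"random_n{n_entities}_l{max_level}_d{edge_density}_s{seed}",
        network=network,
        formulas=formulas,
        notes=f"seeded random network (seed={seed})",
    )
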