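"""Qualitative regulatory networks and their asynchronous dynamics.

This module implements the discrete (René Thomas) modeling formalism for
biological regulatory networks (BRNs).  A BRN is a signed, thresholded
directed graph of biological entities (genes, proteins).  Each entity ``v``
holds a discrete expression level in ``{0, ..., max_level}``.  The dynamics
are driven by *logical parameters* ``K_v(W)``: for every entity ``v`` and
every subset ``W`` of its regulators (its *resources*), ``K_v(W)`` is the
level toward which ``v`` evolves, one unit at a time, whenever its current
resource set is ``W``.  The resources of ``v`` in a state are its present
activators plus its absent inhibitors.

Under the asynchronous updating scheme exactly one entity moves per
transition, producing a non-deterministic state graph (a Kripke structure)
over the cartesian product of all level ranges.  States with no outgoing
transition are deadlocks — biologically, stable steady states.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, Mapping, Optional, Sequence, Tuple

logger = logging.getLogger(__name__)

#: interaction signs
ACTIVATION = "+"
INHIBITION = "-"

#: default guard against explicit-state construction of huge graphs
DEFAULT_STATE_CAP = 1_000_000

#: a qualitative state is a plain tuple of levels, one per entity in
#: declaration order; tuples give the immutable value semantics needed for
#: set/dict keys.
State = Tuple[int, ...]


class ModelError(ValueError):
    """Invalid network, state, or parametrization input."""


class CapacityError(ModelError):
    """State-space product exceeds the configured explicit-state cap."""


class IncompleteParametrizationError(ModelError):
    """A required K_v(W) entry is missing."""


@dataclass(frozen=True)
class Entity:
    """A biological entity with discrete levels ``0..max_level``."""

    name: str
    max_level: int

    def __post_init__(self) -> None:
        if not self.name or not self.name.replace("_", "a").isalnum():
            raise ModelError(f"entity name {self.name!r} is not an identifier")
        if self.name[0].isdigit():
            raise ModelError(f"entity name {self.name!r} may not start with a digit")
        if self.max_level < 1:
            raise ModelError(
                f"entity {self.name!r}: max_level must be >= 1, got {self.max_level}"
            )

    @property
    def levels(self) -> range:
        return range(self.max_level + 1)


@dataclass(frozen=True)
class Interaction:
    """A signed, thresholded regulation ``source -> target``.

    The interaction is *active* in a state when the source's level is at or
    above ``threshold``.  ``sign`` is ``"+"`` for activation, ``"-"`` for
    inhibition.
    """

    source: str
    target: str
    threshold: int
    sign: str

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATION, INHIBITION):
            raise ModelError(f"interaction sign must be '+' or '-', got {self.sign!r}")
        if self.threshold < 1:
            raise ModelError(
                f"interaction {self.source}->{self.target}: threshold must be >= 1"
            )


class RegulatoryNetwork:
    """A validated BRN: entities in declaration order plus interactions.

    Declaration order is authoritative everywhere downstream: state tuples,
    canonical resource-set ordering and parameter-slot ordering all follow
    it.

    The declared level range is authoritative even where it differs from the
    entity's out-degree (the classical convention ties the two together);
    a mismatch is logged as a warning, not rejected, since published models
    do not always satisfy the equality.
    """

    def __init__(self, entities: Sequence[Entity], interactions: Iterable[Interaction]):
        self.entities: Tuple[Entity, ...] = tuple(entities)
        self.interactions: Tuple[Interaction, ...] = tuple(interactions)
        names = [e.name for e in self.entities]
        if len(set(names)) != len(names):
            raise ModelError("duplicate entity names in network")
        self._index: Dict[str, int] = {n: i for i, n in enumerate(names)}
        seen_pairs = set()
        for ia in self.interactions:
            for endpoint in (ia.source, ia.target):
                if endpoint not in self._index:
                    raise ModelError(
                        f"interaction {ia.source}->{ia.target} references "
                        f"undeclared entity {endpoint!r}"
                    )
            if (ia.source, ia.target) in seen_pairs:
                raise ModelError(
                    f"multiple interactions between {ia.source!r} and {ia.target!r}"
                )
            seen_pairs.add((ia.source, ia.target))
            src_max = self.entity(ia.source).max_level
            if ia.threshold > src_max:
                raise ModelError(
                    f"interaction {ia.source}->{ia.target}: threshold "
                    f"{ia.threshold} exceeds source max_level {src_max}"
                )
        # predecessors in declaration order (canonical resource ordering)
        self._preds: Dict[str, Tuple[str, ...]] = {}
        self._pred_edges: Dict[str, Tuple[Interaction, ...]] = {}
        for e in self.entities:
            incoming = [ia for ia in self.interactions if ia.target == e.name]
            incoming.sort(key=lambda ia: self._index[ia.source])
            self._pred_edges[e.name] = tuple(incoming)
            self._preds[e.name] = tuple(ia.source for ia in incoming)
        for e in self.entities:
            out_degree = sum(1 for ia in self.interactions if ia.source == e.name)
            if out_degree >= 1 and e.max_level != out_degree:
                logger.warning(
                    "entity %s: declared max_level %d differs from out-degree %d",
                    e.name, e.max_level, out_degree,
                )

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(e.name for e in self.entities)

    def entity(self, name: str) -> Entity:
        try:
            return self.entities[self._index[name]]
        except KeyError:
            raise ModelError(f"entity {name!r} is not declared in the network") from None

    def index_of(self, name: str) -> int:
        if name not in self._index:
            raise ModelError(f"entity {name!r} is not declared in the network")
        return self._index[name]

    def predecessors(self, name: str) -> Tuple[str, ...]:
        """Regulators of ``name``, in declaration order."""
        if name not in self._preds:
            raise ModelError(f"entity {name!r} is not declared in the network")
        return self._preds[name]

    def incoming(self, name: str) -> Tuple[Interaction, ...]:
        if name not in self._pred_edges:
            raise ModelError(f"entity {name!r} is not declared in the network")
        return self._pred_edges[name]

    def validate_state(self, state: State) -> None:
        if len(state) != len(self.entities):
            raise ModelError(
                f"state {state!r} has {len(state)} levels, expected {len(self.entities)}"
            )
        for level, e in zip(state, self.entities):
            if not (0 <= level <= e.max_level):
                raise ModelError(
                    f"level {level} of entity {e.name!r} outside [0, {e.max_level}]"
                )

    def iter_states(self) -> Iterator[State]:
        """All qualitative states, in lexicographic (row-major) order."""
        return itertools.product(*(e.levels for e in self.entities))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, RegulatoryNetwork)
            and self.entities == other.entities
            and self.interactions == other.interactions
        )

    def __repr__(self) -> str:
        return (
            f"RegulatoryNetwork({len(self.entities)} entities, "
            f"{len(self.interactions)} interactions)"
        )


ResourceKey = Tuple[str, Tuple[str, ...]]


class Parametrization:
    """A complete assignment of logical parameters K_v(W).

    Keys are ``(entity, resource_members)`` pairs where ``resource_members``
    is the canonical (declaration-ordered) tuple of regulator names.  One
    parametrization is one candidate model.
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[ResourceKey, int]):
        self._values: Dict[ResourceKey, int] = {
            (entity, tuple(members)): int(k) for (entity, members), k in values.items()
        }

    def k(self, entity: str, members: Sequence[str]) -> int:
        key = (entity, tuple(members))
        try:
            return self._values[key]
        except KeyError:
            raise IncompleteParametrizationError(
                f"no K value for entity {entity!r} with resources {tuple(members)!r}"
            ) from None

    def items(self) -> Iterator[Tuple[ResourceKey, int]]:
        return iter(sorted(self._values.items()))

    def as_dict(self) -> Dict[ResourceKey, int]:
        return dict(self._values)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Parametrization) and self._values == other._values

    def __hash__(self) -> int:
        return hash(tuple(sorted(self._values.items())))

    def __repr__(self) -> str:
        parts = ", ".join(
            f"K_{e}({','.join(m)})={k}" for (e, m), k in sorted(self._values.items())
        )
        return f"Parametrization({parts})"

    # pickling support for process workers
    def __getstate__(self):
        return self._values

    def __setstate__(self, state):
        self._values = state


def validate_parametrization(network: RegulatoryNetwork, parametrization: Parametrization) -> None:
    """Check completeness and level ranges of a parametrization."""
    for e in network.entities:
        preds = network.predecessors(e.name)
        for r in range(len(preds) + 1):
            for members in itertools.combinations(preds, r):
                k = parametrization.k(e.name, members)
                if not (0 <= k <= e.max_level):
                    raise ModelError(
                        f"K_{e.name}({','.join(members)})={k} outside [0, {e.max_level}]"
                    )


def resources(network: RegulatoryNetwork, state: State, entity: str) -> Tuple[str, ...]:
    """The resource set W of ``entity`` in ``state``.

    A regulator x of v is a resource when it currently *helps* v: an
    activator at or above its threshold, or an inhibitor below its
    threshold.  Returned in canonical (declaration) order.
    """
    network.validate_state(state)
    members = []
    for ia in network.incoming(entity):
        level = state[network.index_of(ia.source)]
        if ia.sign == ACTIVATION and level >= ia.threshold:
            members.append(ia.source)
        elif ia.sign == INHIBITION and level < ia.threshold:
            members.append(ia.source)
    return tuple(members)


def evolve_level(current: int, k: int) -> int:
    """One asynchronous evolution step of a level toward its target K.

    Moves by exactly one unit: ``current+1`` if below K, ``current-1`` if
    above, unchanged at K.  Levels never jump.
    """
    if current < 0 or k < 0:
        raise ModelError(f"levels must be non-negative, got ({current}, {k})")
    if current < k:
        return current + 1
    if current > k:
        return current - 1
    return current


def successors(
    network: RegulatoryNetwork, parametrization: Parametrization, state: State
) -> FrozenSet[State]:
    """Asynchronous successors of ``state``: one per entity off its K target.

    Each successor changes exactly one entity's level by one unit toward
    ``K_v(W_v(state))``.  An empty result means ``state`` is a deadlock
    (stable steady state).
    """
    network.validate_state(state)
    out = set()
    for i, e in enumerate(network.entities):
        w = resources(network, state, e.name)
        target = evolve_level(state[i], parametrization.k(e.name, w))
        if target != state[i]:
            out.add(state[:i] + (target,) + state[i + 1:])
    return frozenset(out)


@dataclass(frozen=True)
class StateGraph:
    """The asynchronous state graph (Kripke structure) of one parametrization.

    ``transitions`` never contains self-loops: a deadlock is recorded in
    ``deadlocks`` and receives its self-loop only during the CTL module's
    totalization step.
    """

    network: RegulatoryNetwork
    states: FrozenSet[State]
    transitions: FrozenSet[Tuple[State, State]]
    deadlocks: FrozenSet[State]

    def successor_map(self) -> Dict[State, Tuple[State, ...]]:
        """Raw successor lists (no totalization), deterministically ordered."""
        succ: Dict[State, list] = {s: [] for s in self.states}
        for s, t in sorted(self.transitions):
            succ[s].append(t)
        return {s: tuple(ts) for s, ts in succ.items()}

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)


def state_space_size(network: RegulatoryNetwork) -> int:
    """Number of qualitative states: the product of all level-range sizes."""
    size = 1
    for e in network.entities:
        size *= e.max_level + 1
    return size


def build_state_graph(
    network: RegulatoryNetwork,
    parametrization: Parametrization,
    state_cap: Optional[int] = DEFAULT_STATE_CAP,
) -> StateGraph:
    """Construct the full asynchronous state graph for one parametrization.

    Enumerates the complete cartesian product of level ranges; deterministic
    for identical inputs.  Raises :class:`CapacityError` when the product
    exceeds ``state_cap`` (pass ``None`` to disable the guard) — the
    explicit-state representation is intended for graphs well below the
    multi-million-state regime.
    """
    size = state_space_size(network)
    if state_cap is not None and size > state_cap:
        raise CapacityError(
            f"state space has {size} states, above the cap of {state_cap}; "
            "raise state_cap explicitly to proceed"
        )
    states = frozenset(network.iter_states())
    transitions = set()
    deadlocks = set()
    for s in states:
        succ = successors(network, parametrization, s)
        if succ:
            transitions.update((s, t) for t in succ)
        else:
            deadlocks.add(s)
    return StateGraph(
        network=network,
        states=states,
        transitions=frozenset(transitions),
        deadlocks=frozenset(deadlocks),
    )
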