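"""Enumeration and partitioning of the logical-parameter space.

For a network with entities v_1..v_n, every entity contributes one
*parameter slot* per subset of its regulators, and an unrestricted slot
ranges over 0..max_level.  The total number of parametrizations is
therefore prod_i (max_level_i + 1) ** (2 ** |predecessors(v_i)|) — huge
even for small networks, which is why the space is indexed rather than
materialized: a mixed-radix bijection maps global indices to
parametrizations, and contiguous index blocks are handed to independent
workers.

Conventions fixed here (so accepted-model indices are stable across runs
and worker counts): slots are ordered by entity declaration order, then by
resource-subset bitmask over declaration-ordered predecessors (empty set
first); the mixed radix varies the *last* slot fastest; block remainders go
to the earliest blocks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .model_core import ModelError, Parametrization, RegulatoryNetwork, ResourceKey

__all__ = [
    "ParameterSlot", "IndexRange", "parameter_slots", "total_count",
    "index_to_parametrization", "parametrization_to_index", "block_partition",
]


@dataclass(frozen=True)
class ParameterSlot:
    """One logical parameter K_entity(resources) and its allowed values."""

    entity: str
    resources: Tuple[str, ...]
    allowed_values: Tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.allowed_values:
            raise ModelError(
                f"slot K_{self.entity}({{{','.join(self.resources)}}}): empty value range"
            )
        if list(self.allowed_values) != sorted(set(self.allowed_values)):
            raise ModelError(
                f"slot K_{self.entity}: allowed values must be strictly increasing"
            )

    @property
    def key(self) -> ResourceKey:
        return (self.entity, self.resources)

    @property
    def size(self) -> int:
        return len(self.allowed_values)


@dataclass(frozen=True)
class IndexRange:
    """A half-open block [start, end) of global parametrization indices."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ModelError(f"invalid index range [{self.start}, {self.end})")

    @property
    def size(self) -> int:
        return self.end - self.start


def _subsets_in_mask_order(predecessors: Tuple[str, ...]) -> List[Tuple[str, ...]]:
    # bitmask order: bit i selects the i-th declaration-ordered predecessor
    out = []
    for mask in range(1 << len(predecessors)):
        out.append(tuple(p for i, p in enumerate(predecessors) if mask >> i & 1))
    return out


def parameter_slots(
    network: RegulatoryNetwork,
    para_restrictions: Optional[Mapping[ResourceKey, Sequence[int]]] = None,
) -> Tuple[ParameterSlot, ...]:
    """All parameter slots of ``network`` in canonical global order.

    ``para_restrictions`` maps ``(entity, resource_tuple)`` to the allowed
    K values for that slot (the PARA mechanism); unrestricted slots default
    to the full 0..max_level range.  Unknown restriction keys are rejected.
    """
    restrictions = dict(para_restrictions or {})
    restrictions = {(e, tuple(m)): tuple(v) for (e, m), v in restrictions.items()}
    slots: List[ParameterSlot] = []
    for e in network.entities:
        for members in _subsets_in_mask_order(network.predecessors(e.name)):
            key = (e.name, members)
            allowed = restrictions.pop(key, None)
            if allowed is None:
                allowed = tuple(range(e.max_level + 1))
            else:
                allowed = tuple(sorted(set(int(v) for v in allowed)))
                for v in allowed:
                    if not (0 <= v <= e.max_level):
                        raise ModelError(
                            f"PARA restriction K_{e.name}({{{','.join(members)}}}): "
                            f"value {v} outside [0, {e.max_level}]"
                        )
            slots.append(ParameterSlot(e.name, members, allowed))
    if restrictions:
        (entity, members), _ = next(iter(restrictions.items()))
        raise ModelError(
            f"PARA restriction references unknown slot "
            f"K_{entity}({{{','.join(members)}}})"
        )
    return tuple(slots)


def total_count(slots: Sequence[ParameterSlot]) -> int:
    """Size of the parametrization space spanned by ``slots``."""
    n = 1
    for slot in slots:
        n *= slot.size
    return n


def index_to_parametrization(slots: Sequence[ParameterSlot], index: int) -> Parametrization:
    """Mixed-radix decode of a global index (last slot varies fastest)."""
    total = total_count(slots)
    if not (0 <= index < total):
        raise ModelError(f"index {index} outside [0, {total})")
    values: Dict[ResourceKey, int] = {}
    remainder = index
    for slot in reversed(slots):
        remainder, digit = divmod(remainder, slot.size)
        values[slot.key] = slot.allowed_values[digit]
    return Parametrization(values)


def parametrization_to_index(slots: Sequence[ParameterSlot], parametrization: Parametrization) -> int:
    """Inverse of :func:`index_to_parametrization` (round-trip identity)."""
    values = parametrization.as_dict()
    index = 0
    for slot in slots:
        try:
            k = values[slot.key]
        except KeyError:
            raise ModelError(f"parametrization missing slot K_{slot.entity}"
                             f"({{{','.join(slot.resources)}}})") from None
        try:
            digit = slot.allowed_values.index(k)
        except ValueError:
            raise ModelError(
                f"value {k} not allowed for slot K_{slot.entity}"
                f"({{{','.join(slot.resources)}}}): allowed {slot.allowed_values}"
            ) from None
        index = index * slot.size + digit
    return index


def block_partition(total: int, parts: int) -> Tuple[IndexRange, ...]:
    """Split [0, total) into ``parts`` contiguous near-equal blocks.

    Sizes differ by at most one; the remainder goes to the earliest blocks
    so the partition is deterministic.
    """
    if parts < 1:
        raise ModelError(f"parts must be >= 1, got {parts}")
    if total < 0:
        raise ModelError(f"total must be >= 0, got {total}")
    base, remainder = divmod(total, parts)
    ranges = []
    start = 0
    for i in range(parts):
        size = base + (1 if i < remainder else 0)
        ranges.append(IndexRange(start, start + size))
        start += size
    return tuple(ranges)
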