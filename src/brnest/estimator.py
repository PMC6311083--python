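"""Master/worker driver for logical-parameter estimation.

The estimation loop is embarrassingly parallel: each candidate
parametrization is evaluated independently by building its asynchronous
state graph and model-checking the CTL observations on it.  The index
space is block-partitioned, each worker sweeps its own contiguous range
with no shared mutable state, and a final reduction merges the accepted
lists in global-index order.  The result is identical for every worker
count — parallelism changes only who evaluates what, never the answer.

Workers are OS processes (``concurrent.futures.ProcessPoolExecutor``);
a distributed transport could replace them without changing results
because the partition/reduce contract is all they rely on.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from . import ctl as _ctl
from .model_core import (
    DEFAULT_STATE_CAP,
    ModelError,
    Parametrization,
    RegulatoryNetwork,
    ResourceKey,
    build_state_graph,
)
from .param_space import (
    IndexRange,
    ParameterSlot,
    block_partition,
    index_to_parametrization,
    parameter_slots,
    total_count,
)

__all__ = [
    "EstimationResult", "EstimationError", "evaluate_parametrization",
    "estimate", "merge_results",
]

logger = logging.getLogger(__name__)


class EstimationError(ModelError):
    """A worker failed or partial results are inconsistent."""


@dataclass
class EstimationResult:
    """Accepted parametrizations of one estimation run (or one partition).

    ``accepted`` holds ``(global_index, parametrization)`` pairs in strictly
    increasing index order.  ``formula_failures`` (diagnostics mode only)
    counts, per formula source text, how many evaluated models violated it.
    """

    accepted: List[Tuple[int, Parametrization]]
    total_evaluated: int
    index_range: IndexRange
    formula_failures: Optional[Dict[str, int]] = None

    def __post_init__(self) -> None:
        indices = [i for i, _ in self.accepted]
        if indices != sorted(set(indices)):
            raise EstimationError("accepted indices must be strictly increasing")

    @property
    def accepted_indices(self) -> Tuple[int, ...]:
        return tuple(i for i, _ in self.accepted)


def evaluate_parametrization(
    network: RegulatoryNetwork,
    parametrization: Parametrization,
    formulas: Sequence[_ctl.CtlFormula],
    state_cap: Optional[int] = DEFAULT_STATE_CAP,
) -> bool:
    """Accept or reject one candidate model.

    Builds the full asynchronous state graph and requires the conjunction
    of all observations to hold in every state (totalized semantics).
    Pure: no side effects, deterministic.
    """
    graph = build_state_graph(network, parametrization, state_cap=state_cap)
    return _ctl.holds_everywhere(graph, formulas)


def _evaluate_range(
    network: RegulatoryNetwork,
    formulas: Sequence[_ctl.CtlFormula],
    slots: Sequence[ParameterSlot],
    index_range: IndexRange,
    diagnostics: bool,
    state_cap: Optional[int],
    log_every: int = 0,
) -> EstimationResult:
    """Worker body: sweep one contiguous index block (top-level, picklable)."""
    accepted: List[Tuple[int, Parametrization]] = []
    failures: Optional[Dict[str, int]] = (
        {_ctl.unparse(f): 0 for f in formulas} if diagnostics else None
    )
    for i in range(index_range.start, index_range.end):
        p = index_to_parametrization(slots, i)
        graph = build_state_graph(network, p, state_cap=state_cap)
        if diagnostics:
            ok = True
            for f in formulas:
                if _ctl.sat_set(graph, f).states != graph.states:
                    ok = False
                    failures[_ctl.unparse(f)] += 1
            if ok:
                accepted.append((i, p))
        else:
            if _ctl.holds_everywhere(graph, formulas):
                accepted.append((i, p))
        if log_every and (i - index_range.start + 1) % log_every == 0:
            logger.info(
                "range [%d,%d): %d/%d evaluated, %d accepted",
                index_range.start, index_range.end,
                i - index_range.start + 1, index_range.size, len(accepted),
            )
    return EstimationResult(
        accepted=accepted,
        total_evaluated=index_range.size,
        index_range=index_range,
        formula_failures=failures,
    )


def merge_results(partials: Sequence[EstimationResult]) -> EstimationResult:
    """Reduce worker results into one, sorted by global index.

    Linear in the number of accepted models.  Partials must cover pairwise
    disjoint index ranges.
    """
    ordered = sorted(partials, key=lambda r: (r.index_range.start, r.index_range.end))
    for a, b in zip(ordered, ordered[1:]):
        if b.index_range.start < a.index_range.end and b.index_range.size and a.index_range.size:
            raise EstimationError(
                f"overlapping index ranges [{a.index_range.start},{a.index_range.end}) "
                f"and [{b.index_range.start},{b.index_range.end})"
            )
    accepted: List[Tuple[int, Parametrization]] = []
    for r in ordered:
        accepted.extend(r.accepted)
    accepted.sort(key=lambda pair: pair[0])
    failures: Optional[Dict[str, int]] = None
    if any(r.formula_failures is not None for r in partials):
        failures = {}
        for r in partials:
            for key, n in (r.formula_failures or {}).items():
                failures[key] = failures.get(key, 0) + n
    start = min((r.index_range.start for r in ordered), default=0)
    end = max((r.index_range.end for r in ordered), default=0)
    return EstimationResult(
        accepted=accepted,
        total_evaluated=sum(r.total_evaluated for r in partials),
        index_range=IndexRange(start, end),
        formula_failures=failures,
    )


def estimate(
    network: RegulatoryNetwork,
    formulas: Sequence[_ctl.CtlFormula],
    para_restrictions: Optional[Mapping[ResourceKey, Sequence[int]]] = None,
    workers: int = 1,
    diagnostics: bool = False,
    state_cap: Optional[int] = DEFAULT_STATE_CAP,
    log_every: int = 0,
) -> EstimationResult:
    """Sweep the whole (optionally PARA-restricted) parametrization space.

    The index space is split into ``workers`` contiguous blocks; each block
    is evaluated independently and the partial results are merged.  The
    accepted set is identical for every ``workers`` value.
    """
    if workers < 1:
        raise EstimationError(f"workers must be >= 1, got {workers}")
    if not formulas:
        raise EstimationError("estimate requires at least one CTL formula")
    slots = parameter_slots(network, para_restrictions)
    total = total_count(slots)
    ranges = block_partition(total, workers)
    logger.info("parameter space: %d parametrizations, %d worker(s)", total, workers)
    if workers == 1:
        partials = [_evaluate_range(network, formulas, slots, ranges[0],
                                    diagnostics, state_cap, log_every)]
    else:
        partials = []
        with ProcessPoolExecutor(max_workers=workers) as pool:
            futures = [
                pool.submit(_evaluate_range, network, formulas, slots, r,
                            diagnostics, state_cap, log_every)
                for r in ranges
            ]
            for r, fut in zip(ranges, futures):
                try:
                    partials.append(fut.result())
                except Exception as exc:  # surface the failed block
                    raise EstimationError(
                        f"worker for index range [{r.start},{r.end}) failed: {exc}"
                    ) from exc
    result = merge_results(partials)
    logger.info("accepted %d of %d parametrizations", len(result.accepted), total)
    return result
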