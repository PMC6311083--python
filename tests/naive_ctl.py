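"""Naive reference CTL evaluator, independent of the fixpoint labeling path.

Semantics are computed by explicit graph reasoning on the totalized
transition relation: EF by reachability closure, EG by restriction to the
candidate set plus SCC-or-self-loop detection, E[. U .] by per-state
search.  Universal forms follow from the semantic dualities applied to
these naive pieces.  networkx supplies the graph machinery, so nothing is
shared with the worklist/fixpoint implementation under test.
"""

from __future__ import annotations

import networkx as nx

from brnest import ctl as c


def _to_nx(graph) -> nx.DiGraph:
    succ = c.totalized_successors(graph)
    g = nx.DiGraph()
    g.add_nodes_from(succ)
    for s, ts in succ.items():
        g.add_edges_from((s, t) for t in ts)
    return g


def _naive_eg(g: nx.DiGraph, sat_p: set) -> set:
    """States in sat_p from which an infinite path stays inside sat_p."""
    h = g.subgraph(sat_p)
    on_cycle = set()
    for scc in nx.strongly_connected_components(h):
        if len(scc) > 1:
            on_cycle |= scc
        else:
            (s,) = tuple(scc)
            if h.has_edge(s, s):
                on_cycle.add(s)
    out = set()
    for s in sat_p:
        if s in on_cycle or (nx.descendants(h, s) & on_cycle):
            out.add(s)
    return out


def _exists_until(g: nx.DiGraph, start, sat_p: set, sat_q: set) -> bool:
    """Is there a finite path start..t with t in sat_q and all earlier states in sat_p?"""
    if start in sat_q:
        return True
    if start not in sat_p:
        return False
    stack, seen = [start], {start}
    while stack:
        s = stack.pop()
        for t in g.successors(s):
            if t in sat_q:
                return True
            if t in sat_p and t not in seen:
                seen.add(t)
                stack.append(t)
    return False


def naive_sat(graph, formula) -> frozenset:
    """Decide ``formula`` on every state of ``graph`` by explicit search."""
    g = _to_nx(graph)
    all_states = set(g.nodes)
    net = graph.network

    def reach(s):
        return nx.descendants(g, s) | {s}

    def ev(f) -> set:
        if isinstance(f, c.TrueAtom):
            return set(all_states)
        if isinstance(f, c.FalseAtom):
            return set()
        if isinstance(f, c.LevelAtom):
            idx = net.index_of(f.entity)
            return {s for s in all_states if s[idx] == f.level}
        if isinstance(f, c.Not):
            return all_states - ev(f.operand)
        if isinstance(f, c.And):
            return ev(f.left) & ev(f.right)
        if isinstance(f, c.Or):
            return ev(f.left) | ev(f.right)
        if isinstance(f, c.Implies):
            return (all_states - ev(f.left)) | ev(f.right)
        if isinstance(f, c.EX):
            sat = ev(f.operand)
            return {s for s in all_states if set(g.successors(s)) & sat}
        if isinstance(f, c.AX):
            sat = ev(f.operand)
            return {s for s in all_states if set(g.successors(s)) <= sat}
        if isinstance(f, c.EF):
            sat = ev(f.operand)
            return {s for s in all_states if reach(s) & sat}
        if isinstance(f, c.AG):
            sat = ev(f.operand)
            return {s for s in all_states if reach(s) <= sat}
        if isinstance(f, c.EG):
            return _naive_eg(g, ev(f.operand))
        if isinstance(f, c.AF):
            return all_states - _naive_eg(g, all_states - ev(f.operand))
        if isinstance(f, c.EU):
            sat_p, sat_q = ev(f.left), ev(f.right)
            return {s for s in all_states if _exists_until(g, s, sat_p, sat_q)}
        if isinstance(f, c.AU):
            not_q = all_states - ev(f.right)
            bad = (all_states - ev(f.left)) & not_q
            eu_bad = {s for s in all_states if _exists_until(g, s, not_q, bad)}
            return all_states - (eu_bad | _naive_eg(g, not_q))
        raise TypeError(f"not a CTL formula: {f!r}")

    return frozenset(ev(formula))
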