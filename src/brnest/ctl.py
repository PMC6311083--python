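"""Computation Tree Logic over qualitative state graphs.

Biological observations ("starting from x=0 the system never reaches x=2",
"the pathogenic state is stable") are written as CTL formulas over level
atoms ``entity=n`` and decided exhaustively on the state graph with the
classical explicit-state fixpoint labeling algorithm: EX is a pre-image,
E[. U .] a least fixpoint, EG a greatest fixpoint, and the universal
operators reduce to these through the standard dualities.

CTL path semantics require a total transition relation, so deadlocks are
given a self-loop before evaluation ("totalization").  This makes AG(phi)
hold at a stable state satisfying phi — exactly the reading under which a
deadlock "cannot recover" to another behavior.

Grammar accepted by :func:`parse_ctl`::

    atom     :  name=int | TRUE | FALSE
    unary    :  ! f | EX f | AX f | EF f | AF f | EG f | AG f | X f (= AX)
    until    :  E[f U g] | A[f U g]
    binary   :  f & g | f , g (= &) | f | g | f -> g
    precedence  ! > & > | > ->   (-> right-associative); parentheses free.

Commas are accepted as conjunction because published observation strings
write e.g. ``(OGT=1,OGA=0)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

from .model_core import ModelError, RegulatoryNetwork, State, StateGraph

__all__ = [
    "CtlFormula", "TrueAtom", "FalseAtom", "LevelAtom", "Not", "And", "Or",
    "Implies", "EX", "AX", "EF", "AF", "EG", "AG", "EU", "AU",
    "CtlSyntaxError", "parse_ctl", "unparse", "SatSet", "sat_set",
    "holds_everywhere", "totalized_successors", "TRUE", "FALSE",
]


class CtlSyntaxError(ModelError):
    """Malformed CTL text; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------

class CtlFormula:
    """Base class for CTL AST nodes (all nodes are frozen and hashable)."""
    __slots__ = ()


@dataclass(frozen=True)
class TrueAtom(CtlFormula):
    pass


@dataclass(frozen=True)
class FalseAtom(CtlFormula):
    pass


@dataclass(frozen=True)
class LevelAtom(CtlFormula):
    """Atomic proposition ``entity = level``."""
    entity: str
    level: int


@dataclass(frozen=True)
class Not(CtlFormula):
    operand: CtlFormula


@dataclass(frozen=True)
class And(CtlFormula):
    left: CtlFormula
    right: CtlFormula


@dataclass(frozen=True)
class Or(CtlFormula):
    left: CtlFormula
    right: CtlFormula


@dataclass(frozen=True)
class Implies(CtlFormula):
    left: CtlFormula
    right: CtlFormula


@dataclass(frozen=True)
class EX(CtlFormula):
    operand: CtlFormula


@dataclass(frozen=True)
class AX(CtlFormula):
    operand: CtlFormula


@dataclass(frozen=True)
class EF(CtlFormula):
    operand: CtlFormula


@dataclass(frozen=True)
class AF(CtlFormula):
    operand: CtlFormula


@dataclass(frozen=True)
class EG(CtlFormula):
    operand: CtlFormula


@dataclass(frozen=True)
class AG(CtlFormula):
    operand: CtlFormula


@dataclass(frozen=True)
class EU(CtlFormula):
    """E[left U right]"""
    left: CtlFormula
    right: CtlFormula


@dataclass(frozen=True)
class AU(CtlFormula):
    """A[left U right]"""
    left: CtlFormula
    right: CtlFormula


TRUE = TrueAtom()
FALSE = FalseAtom()

_UNARY_TEMPORAL = {"EX": EX, "AX": AX, "EF": EF, "AF": AF, "EG": EG, "AG": AG}


# ---------------------------------------------------------------------------
# Parser (recursive descent)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<arrow>->)|(?P<name>[A-Za-z_][A-Za-z0-9_]*)|(?P<int>\d+)"
    r"|(?P<sym>[=!&,|()\[\]]))"
)

# words with reserved meaning at the formula level; a bare X is read as AX
_KEYWORDS = {"EX", "AX", "EF", "AF", "EG", "AG", "E", "A", "U", "X", "TRUE", "FALSE"}


class _Tokens:
    def __init__(self, text: str):
        self.text = text
        self.toks: List[Tuple[str, str, int]] = []  # (kind, value, pos)
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if m is None or m.end() == pos:
                stripped = text[pos:].lstrip()
                if not stripped:
                    break
                at = len(text) - len(stripped)
                raise CtlSyntaxError(f"unexpected character {stripped[0]!r}", at)
            if m.lastgroup is not None:
                self.toks.append((m.lastgroup, m.group(m.lastgroup), m.start(m.lastgroup)))
            pos = m.end()
        self.i = 0

    def peek(self) -> Tuple[str, str, int]:
        if self.i < len(self.toks):
            return self.toks[self.i]
        return ("eof", "", len(self.text))

    def next(self) -> Tuple[str, str, int]:
        tok = self.peek()
        self.i += 1
        return tok

    def expect(self, kind: str, value: str | None = None) -> Tuple[str, str, int]:
        tok = self.next()
        if tok[0] != kind or (value is not None and tok[1] != value):
            want = value if value is not None else kind
            raise CtlSyntaxError(f"expected {want!r}, found {tok[1] or 'end of input'!r}", tok[2])
        return tok


def parse_ctl(text: str, network: RegulatoryNetwork) -> CtlFormula:
    """Parse a CTL formula and validate its atoms against ``network``.

    Raises :class:`CtlSyntaxError` with a character position on malformed
    input; unknown entities and out-of-range levels raise
    :class:`~brnest.model_core.ModelError`.
    """
    toks = _Tokens(text)
    formula = _parse_implies(toks, network)
    kind, value, pos = toks.peek()
    if kind != "eof":
        raise CtlSyntaxError(f"unexpected trailing input {value!r}", pos)
    return formula


def _parse_implies(toks: _Tokens, net: RegulatoryNetwork) -> CtlFormula:
    left = _parse_or(toks, net)
    if toks.peek()[0] == "arrow":
        toks.next()
        right = _parse_implies(toks, net)  # right-associative
        return Implies(left, right)
    return left


def _parse_or(toks: _Tokens, net: RegulatoryNetwork) -> CtlFormula:
    node = _parse_and(toks, net)
    while toks.peek()[:2] == ("sym", "|"):
        toks.next()
        node = Or(node, _parse_and(toks, net))
    return node


def _parse_and(toks: _Tokens, net: RegulatoryNetwork) -> CtlFormula:
    node = _parse_unary(toks, net)
    while toks.peek()[0] == "sym" and toks.peek()[1] in ("&", ","):
        toks.next()
        node = And(node, _parse_unary(toks, net))
    return node


def _parse_unary(toks: _Tokens, net: RegulatoryNetwork) -> CtlFormula:
    kind, value, pos = toks.peek()
    if kind == "sym" and value == "!":
        toks.next()
        return Not(_parse_unary(toks, net))
    if kind == "name" and value in _UNARY_TEMPORAL:
        toks.next()
        return _UNARY_TEMPORAL[value](_parse_unary(toks, net))
    if kind == "name" and value == "X":  # bare X read as AX
        toks.next()
        return AX(_parse_unary(toks, net))
    if kind == "name" and value in ("E", "A"):
        toks.next()
        toks.expect("sym", "[")
        left = _parse_implies(toks, net)
        toks.expect("name", "U")
        right = _parse_implies(toks, net)
        toks.expect("sym", "]")
        return EU(left, right) if value == "E" else AU(left, right)
    return _parse_primary(toks, net)


def _parse_primary(toks: _Tokens, net: RegulatoryNetwork) -> CtlFormula:
    kind, value, pos = toks.next()
    if kind == "sym" and value == "(":
        node = _parse_implies(toks, net)
        toks.expect("sym", ")")
        return node
    if kind == "name":
        if value == "TRUE":
            return TRUE
        if value == "FALSE":
            return FALSE
        if value in _KEYWORDS:
            raise CtlSyntaxError(f"misplaced keyword {value!r}", pos)
        # level atom: name = int
        entity = net.entity(value)  # raises ModelError for unknown names
        toks.expect("sym", "=")
        lk, lv, lp = toks.next()
        if lk != "int":
            raise CtlSyntaxError(f"expected a level after '{value}=', found {lv!r}", lp)
        level = int(lv)
        if not (0 <= level <= entity.max_level):
            raise ModelError(
                f"level {level} outside [0, {entity.max_level}] for entity {value!r}"
            )
        return LevelAtom(value, level)
    raise CtlSyntaxError(f"expected a formula, found {value or 'end of input'!r}", pos)


def unparse(formula: CtlFormula) -> str:
    """Render an AST back to canonical, fully parenthesized source text."""
    if isinstance(formula, TrueAtom):
        return "TRUE"
    if isinstance(formula, FalseAtom):
        return "FALSE"
    if isinstance(formula, LevelAtom):
        return f"{formula.entity}={formula.level}"
    if isinstance(formula, Not):
        return f"!({unparse(formula.operand)})"
    if isinstance(formula, And):
        return f"({unparse(formula.left)} & {unparse(formula.right)})"
    if isinstance(formula, Or):
        return f"({unparse(formula.left)} | {unparse(formula.right)})"
    if isinstance(formula, Implies):
        return f"({unparse(formula.left)} -> {unparse(formula.right)})"
    for cls, word in ((EX, "EX"), (AX, "AX"), (EF, "EF"), (AF, "AF"), (EG, "EG"), (AG, "AG")):
        if isinstance(formula, cls):
            return f"{word}({unparse(formula.operand)})"
    if isinstance(formula, EU):
        return f"E[{unparse(formula.left)} U {unparse(formula.right)}]"
    if isinstance(formula, AU):
        return f"A[{unparse(formula.left)} U {unparse(formula.right)}]"
    raise TypeError(f"not a CTL formula: {formula!r}")


# ---------------------------------------------------------------------------
# Fixpoint labeling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SatSet:
    """States of a graph in which a formula holds."""
    formula: CtlFormula
    states: FrozenSet[State]


def totalized_successors(graph: StateGraph) -> Dict[State, Tuple[State, ...]]:
    """Successor map with a self-loop added at every deadlock."""
    succ = graph.successor_map()
    for s in graph.deadlocks:
        succ[s] = (s,)
    return succ


def _predecessor_map(succ: Dict[State, Tuple[State, ...]]) -> Dict[State, List[State]]:
    pred: Dict[State, List[State]] = {s: [] for s in succ}
    for s, ts in succ.items():
        for t in ts:
            pred[t].append(s)
    return pred


def _validate_atoms(formula: CtlFormula, network: RegulatoryNetwork) -> None:
    stack = [formula]
    while stack:
        f = stack.pop()
        if isinstance(f, LevelAtom):
            e = network.entity(f.entity)
            if not (0 <= f.level <= e.max_level):
                raise ModelError(
                    f"atom {f.entity}={f.level}: level outside [0, {e.max_level}]"
                )
        elif isinstance(f, (Not, EX, AX, EF, AF, EG, AG)):
            stack.append(f.operand)
        elif isinstance(f, (And, Or, Implies, EU, AU)):
            stack.extend((f.left, f.right))


def sat_set(graph: StateGraph, formula: CtlFormula) -> SatSet:
    """Decide ``formula`` in every state of ``graph`` (totalized semantics).

    Bottom-up labeling: EX by pre-image, E[. U .] as a least fixpoint
    (backward worklist), EG as a greatest fixpoint (iterated pruning of
    states with no successor inside the candidate set).  The universal
    forms are rewritten: AX = !EX!, EF p = E[TRUE U p], AF p = !EG!p,
    AG p = !EF!p, A[p U q] = !(E[!q U (!p & !q)] | EG !q).
    """
    _validate_atoms(formula, graph.network)
    succ = totalized_successors(graph)
    pred = _predecessor_map(succ)
    all_states = frozenset(succ)
    cache: Dict[CtlFormula, FrozenSet[State]] = {}

    def ex(sat: FrozenSet[State]) -> FrozenSet[State]:
        return frozenset(s for s in all_states if any(t in sat for t in succ[s]))

    def eu(sat_p: FrozenSet[State], sat_q: FrozenSet[State]) -> FrozenSet[State]:
        result: Set[State] = set(sat_q)
        worklist = list(sat_q)
        while worklist:
            t = worklist.pop()
            for s in pred[t]:
                if s not in result and s in sat_p:
                    result.add(s)
                    worklist.append(s)
        return frozenset(result)

    def eg(sat_p: FrozenSet[State]) -> FrozenSet[State]:
        current = set(sat_p)
        changed = True
        while changed:
            changed = False
            for s in list(current):
                if not any(t in current for t in succ[s]):
                    current.remove(s)
                    changed = True
        return frozenset(current)

    def ev(f: CtlFormula) -> FrozenSet[State]:
        if f in cache:
            return cache[f]
        if isinstance(f, TrueAtom):
            out = all_states
        elif isinstance(f, FalseAtom):
            out = frozenset()
        elif isinstance(f, LevelAtom):
            idx = graph.network.index_of(f.entity)
            out = frozenset(s for s in all_states if s[idx] == f.level)
        elif isinstance(f, Not):
            out = all_states - ev(f.operand)
        elif isinstance(f, And):
            out = ev(f.left) & ev(f.right)
        elif isinstance(f, Or):
            out = ev(f.left) | ev(f.right)
        elif isinstance(f, Implies):
            out = (all_states - ev(f.left)) | ev(f.right)
        elif isinstance(f, EX):
            out = ex(ev(f.operand))
        elif isinstance(f, AX):
            out = all_states - ex(all_states - ev(f.operand))
        elif isinstance(f, EF):
            out = eu(all_states, ev(f.operand))
        elif isinstance(f, AF):
            out = all_states - eg(all_states - ev(f.operand))
        elif isinstance(f, EG):
            out = eg(ev(f.operand))
        elif isinstance(f, AG):
            out = all_states - eu(all_states, all_states - ev(f.operand))
        elif isinstance(f, EU):
            out = eu(ev(f.left), ev(f.right))
        elif isinstance(f, AU):
            not_q = all_states - ev(f.right)
            not_p_and_not_q = (all_states - ev(f.left)) & not_q
            out = all_states - (eu(not_q, not_p_and_not_q) | eg(not_q))
        else:
            raise TypeError(f"not a CTL formula: {f!r}")
        cache[f] = out
        return out

    return SatSet(formula=formula, states=ev(formula))


def holds_everywhere(graph: StateGraph, formulas: Sequence[CtlFormula]) -> bool:
    """True iff every formula holds in *every* state of the totalized graph.

    This is the model-acceptance test: observations are typically written
    as implication-guarded formulas, vacuously true outside their guard
    states, so requiring them globally matches checking from unconstrained
    initial states.  Short-circuits on the first failing formula.
    """
    if not formulas:
        raise ValueError("holds_everywhere requires at least one formula")
    for f in formulas:
        if sat_set(graph, f).states != graph.states:
            return False
    return True


def violating_states(graph: StateGraph, formula: CtlFormula) -> FrozenSet[State]:
    """Diagnostic: the states in which ``formula`` does not hold."""
    return graph.states - sat_set(graph, formula).states
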