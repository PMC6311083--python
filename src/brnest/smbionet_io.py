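"""Reading and writing the four-section model format, results and exports.

Model files follow the SMBioNet-style layout of four sections in fixed
order — VAR (entities and level ranges), REG (interactions), PARA
(optional K-value restrictions) and CTL (observations) — with ``#``
comments and ``;``-terminated statements that may span lines::

    VAR
    x = 0..2 ;
    y = 0..1 ;
    REG
    x [2] -> + x ;
    x [1] -> + y ;
    y [1] -> - x ;
    PARA
    K_x:{} = 0 ;          # single value, range v1..v2, or list v1,v2
    CTL
    (x=0 & y=0) -> AG(!(x=2)) ;

The exact grammar of the original tool is not published, so this dialect
is defined and documented here.  ``parse_model_file(..., compat=True)``
gives a best-effort reader for files from other sources: unrecognized
statements are collected in ``ModelDocument.warnings`` and reported
instead of raising.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import networkx as nx

from . import ctl as _ctl
from .estimator import EstimationResult
from .model_core import (
    Entity,
    Interaction,
    ModelError,
    Parametrization,
    RegulatoryNetwork,
    ResourceKey,
    StateGraph,
)
from .param_space import ParameterSlot, parameter_slots, parametrization_to_index, total_count

__all__ = [
    "ModelDocument", "ModelFileError", "parse_model_file", "write_model_file",
    "write_results", "parse_results", "export_state_graph",
]

_SECTIONS = ("VAR", "REG", "PARA", "CTL")


class ModelFileError(ModelError):
    """Malformed model or results file; message carries line number/section."""

    def __init__(self, message: str, line: Optional[int] = None, section: Optional[str] = None):
        where = []
        if section is not None:
            where.append(f"section {section}")
        if line is not None:
            where.append(f"line {line}")
        suffix = f" ({', '.join(where)})" if where else ""
        super().__init__(f"{message}{suffix}")
        self.line = line
        self.section = section


@dataclass
class ModelDocument:
    """A parsed model file: network, PARA restrictions and observations."""

    network: RegulatoryNetwork
    para_restrictions: Dict[ResourceKey, Tuple[int, ...]]
    formula_sources: List[str]
    formulas: List[_ctl.CtlFormula]
    name: str = "model"
    warnings: List[Tuple[int, str]] = field(default_factory=list)

    def slots(self) -> Tuple[ParameterSlot, ...]:
        return parameter_slots(self.network, self.para_restrictions)


def _split_statements(text: str) -> List[Tuple[int, str, str]]:
    """Return (line, section, statement) triples; statements end at ';'.

    Section header lines are returned with an empty statement so ordering
    can be validated.
    """
    out: List[Tuple[int, str, str]] = []
    section: Optional[str] = None
    buf: List[str] = []
    buf_line = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        stripped = line.strip()
        if stripped.upper() in _SECTIONS and not buf:
            section = stripped.upper()
            out.append((lineno, section, ""))
            continue
        if not stripped:
            continue
        if section is None:
            raise ModelFileError(
                f"statement {stripped!r} before any section header", line=lineno
            )
        if not buf:
            buf_line = lineno
        buf.append(stripped)
        while ";" in " ".join(buf):
            joined = " ".join(buf)
            stmt, _, rest = joined.partition(";")
            out.append((buf_line, section, stmt.strip()))
            buf = [rest.strip()] if rest.strip() else []
            if buf:
                buf_line = lineno
            else:
                break
    if buf:
        raise ModelFileError(
            f"unterminated statement {' '.join(buf)!r} (missing ';')",
            line=buf_line, section=section,
        )
    return out


_VAR_RE = re.compile(r"^(?P<name>[A-Za-z_][A-Za-z0-9_]*)\s*=\s*(?P<lo>\d+)\s*\.\.\s*(?P<hi>\d+)$")
_REG_RE = re.compile(
    r"^(?P<source>[A-Za-z_][A-Za-z0-9_]*)\s*\[\s*(?P<tau>\d+)\s*\]\s*->\s*"
    r"(?P<sign>[+-])\s*(?P<target>[A-Za-z_][A-Za-z0-9_]*)$"
)
_PARA_RE = re.compile(
    r"^K_(?P<entity>[A-Za-z_][A-Za-z0-9_]*)\s*:\s*\{(?P<members>[^}]*)\}\s*=\s*(?P<spec>.+)$"
)


def _parse_value_spec(spec: str, line: int) -> Tuple[int, ...]:
    spec = spec.strip()
    m = re.match(r"^(\d+)\s*\.\.\s*(\d+)$", spec)
    if m:
        lo, hi = int(m.group(1)), int(m.group(2))
        if hi < lo:
            raise ModelFileError(f"empty value range {spec!r}", line=line, section="PARA")
        return tuple(range(lo, hi + 1))
    parts = [p.strip() for p in spec.split(",")]
    if all(re.fullmatch(r"\d+", p) for p in parts):
        return tuple(sorted({int(p) for p in parts}))
    raise ModelFileError(f"cannot parse value specification {spec!r}",
                         line=line, section="PARA")


def parse_model_file(text: str, name: str = "model", compat: bool = False) -> ModelDocument:
    """Parse a four-section model file into a validated :class:`ModelDocument`.

    VAR, REG and CTL are mandatory, PARA optional; sections must appear in
    that order.  Every error names the offending line and section.  With
    ``compat=True``, statements this dialect does not recognize are
    recorded in ``warnings`` instead of aborting the parse.
    """
    statements = _split_statements(text)
    seen_order: List[str] = []
    for lineno, section, stmt in statements:
        if stmt == "" and (not seen_order or seen_order[-1] != section):
            if section in seen_order:
                raise ModelFileError(f"duplicate section {section}", line=lineno)
            seen_order.append(section)
    for required in ("VAR", "REG", "CTL"):
        if required not in seen_order:
            raise ModelFileError(f"missing mandatory section {required}")
    expected = [s for s in _SECTIONS if s in seen_order]
    if seen_order != expected:
        raise ModelFileError(
            f"sections out of order: found {seen_order}, expected {expected}"
        )

    warnings: List[Tuple[int, str]] = []
    entities: List[Entity] = []
    interactions: List[Interaction] = []
    para_raw: List[Tuple[int, str, Tuple[str, ...], Tuple[int, ...]]] = []
    ctl_raw: List[Tuple[int, str]] = []

    def unrecognized(lineno: int, section: str, stmt: str, why: str) -> None:
        if compat:
            warnings.append((lineno, f"{section}: unrecognized statement {stmt!r} ({why})"))
        else:
            raise ModelFileError(why, line=lineno, section=section)

    for lineno, section, stmt in statements:
        if not stmt:
            continue
        if section == "VAR":
            m = _VAR_RE.match(stmt)
            if not m:
                unrecognized(lineno, section, stmt, f"cannot parse entity declaration {stmt!r}")
                continue
            if int(m.group("lo")) != 0:
                raise ModelFileError(
                    f"entity {m.group('name')!r}: level range must start at 0",
                    line=lineno, section="VAR",
                )
            if any(e.name == m.group("name") for e in entities):
                raise ModelFileError(
                    f"duplicate entity {m.group('name')!r}", line=lineno, section="VAR"
                )
            try:
                entities.append(Entity(m.group("name"), int(m.group("hi"))))
            except ModelError as exc:
                raise ModelFileError(str(exc), line=lineno, section="VAR") from exc
        elif section == "REG":
            m = _REG_RE.match(stmt)
            if not m:
                unrecognized(lineno, section, stmt, f"cannot parse interaction {stmt!r}")
                continue
            try:
                interactions.append(
                    Interaction(m.group("source"), m.group("target"),
                                int(m.group("tau")), m.group("sign"))
                )
            except ModelError as exc:
                raise ModelFileError(str(exc), line=lineno, section="REG") from exc
        elif section == "PARA":
            m = _PARA_RE.match(stmt)
            if not m:
                unrecognized(lineno, section, stmt, f"cannot parse PARA restriction {stmt!r}")
                continue
            members = tuple(
                p.strip() for p in m.group("members").split(",") if p.strip()
            )
            values = _parse_value_spec(m.group("spec"), lineno)
            para_raw.append((lineno, m.group("entity"), members, values))
        elif section == "CTL":
            ctl_raw.append((lineno, stmt))

    try:
        network = RegulatoryNetwork(entities, interactions)
    except ModelError as exc:
        raise ModelFileError(str(exc), section="REG") from exc

    para_restrictions: Dict[ResourceKey, Tuple[int, ...]] = {}
    for lineno, entity, members, values in para_raw:
        try:
            preds = network.predecessors(entity)
        except ModelError as exc:
            raise ModelFileError(str(exc), line=lineno, section="PARA") from exc
        unknown = [p for p in members if p not in preds]
        if unknown:
            raise ModelFileError(
                f"K_{entity}: {unknown[0]!r} is not a regulator of {entity!r}",
                line=lineno, section="PARA",
            )
        canonical = tuple(p for p in preds if p in members)
        key = (entity, canonical)
        if key in para_restrictions:
            raise ModelFileError(
                f"duplicate PARA restriction for K_{entity}:{{{','.join(canonical)}}}",
                line=lineno, section="PARA",
            )
        para_restrictions[key] = values

    formulas: List[_ctl.CtlFormula] = []
    formula_sources: List[str] = []
    for lineno, src in ctl_raw:
        try:
            formulas.append(_ctl.parse_ctl(src, network))
        except ModelError as exc:
            raise ModelFileError(str(exc), line=lineno, section="CTL") from exc
        formula_sources.append(src)
    if not formulas:
        raise ModelFileError("CTL section contains no formulas", section="CTL")

    doc = ModelDocument(
        network=network,
        para_restrictions=para_restrictions,
        formula_sources=formula_sources,
        formulas=formulas,
        name=name,
        warnings=warnings,
    )
    # validate PARA value ranges against the network (raises on bad values)
    try:
        doc.slots()
    except ModelError as exc:
        raise ModelFileError(str(exc), section="PARA") from exc
    return doc


def write_model_file(document: ModelDocument) -> str:
    """Serialize a document back to the four-section format (round-trip safe)."""
    lines = [f"# model: {document.name}", "VAR"]
    for e in document.network.entities:
        lines.append(f"{e.name} = 0..{e.max_level} ;")
    lines.append("REG")
    for ia in document.network.interactions:
        lines.append(f"{ia.source} [{ia.threshold}] -> {ia.sign} {ia.target} ;")
    if document.para_restrictions:
        lines.append("PARA")
        for (entity, members), values in sorted(document.para_restrictions.items()):
            spec = ",".join(str(v) for v in values)
            lines.append(f"K_{entity}:{{{','.join(members)}}} = {spec} ;")
    lines.append("CTL")
    for src in document.formula_sources:
        lines.append(f"{src.strip()} ;")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Results files
# ---------------------------------------------------------------------------

def write_results(result: EstimationResult, document: ModelDocument) -> str:
    """Serialize an estimation result: header, then one block per model.

    Each block lists every K value in canonical slot order, so the file is
    stable across runs and worker counts and can be re-parsed losslessly.
    """
    slots = document.slots()
    lines = [
        f"# model: {document.name}",
        f"# parameter-space: {total_count(slots)}",
        f"# evaluated: {result.total_evaluated}",
        f"# accepted: {len(result.accepted)}",
    ]
    if result.formula_failures is not None:
        for src, n in sorted(result.formula_failures.items()):
            lines.append(f"# failing \"{src}\": {n}")
    for index, parametrization in result.accepted:
        lines.append(f"MODEL {index}")
        for slot in slots:
            k = parametrization.k(slot.entity, slot.resources)
            lines.append(f"K_{slot.entity}:{{{','.join(slot.resources)}}} = {k}")
    return "\n".join(lines) + "\n"


def parse_results(text: str, document: ModelDocument) -> List[Tuple[int, Parametrization]]:
    """Re-read a results file into ``(index, Parametrization)`` pairs."""
    slots = document.slots()
    out: List[Tuple[int, Parametrization]] = []
    current_index: Optional[int] = None
    current: Dict[ResourceKey, int] = {}

    def flush(line: int) -> None:
        nonlocal current_index, current
        if current_index is None:
            return
        p = Parametrization(current)
        recomputed = parametrization_to_index(slots, p)
        if recomputed != current_index:
            raise ModelFileError(
                f"MODEL {current_index}: K values correspond to index {recomputed}",
                line=line,
            )
        out.append((current_index, p))
        current_index, current = None, {}

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("MODEL"):
            flush(lineno)
            try:
                current_index = int(line.split()[1])
            except (IndexError, ValueError):
                raise ModelFileError(f"malformed MODEL header {line!r}", line=lineno)
            continue
        m = _PARA_RE.match(line)
        if not m or current_index is None:
            raise ModelFileError(f"unexpected line {line!r} in results file", line=lineno)
        members = tuple(p.strip() for p in m.group("members").split(",") if p.strip())
        current[(m.group("entity"), members)] = int(m.group("spec"))
    flush(len(text.splitlines()))
    return out


# ---------------------------------------------------------------------------
# State-graph exports
# ---------------------------------------------------------------------------

def _state_label(state: Sequence[int]) -> str:
    return ",".join(str(v) for v in state)


def export_state_graph(graph: StateGraph, format: str = "dot") -> str:
    """Render a state graph as DOT or GraphML text.

    Nodes are labeled with the comma-separated level tuple in declaration
    order (e.g. ``1,0,1,1,1,1,1,0,1``); deadlocks carry a ``deadlock``
    attribute.  Node and edge order is deterministic.
    """
    fmt = format.lower()
    states = sorted(graph.states)
    edges = sorted(graph.transitions)
    if fmt == "dot":
        lines = ["digraph stategraph {"]
        for s in states:
            label = _state_label(s)
            if s in graph.deadlocks:
                lines.append(f'  "{label}" [label="{label}", deadlock="true", shape="doublecircle"];')
            else:
                lines.append(f'  "{label}" [label="{label}"];')
        for s, t in edges:
            lines.append(f'  "{_state_label(s)}" -> "{_state_label(t)}";')
        lines.append("}")
        return "\n".join(lines) + "\n"
    if fmt == "graphml":
        g = nx.DiGraph()
        for s in states:
            g.add_node(_state_label(s), deadlock=(s in graph.deadlocks))
        for s, t in edges:
            g.add_edge(_state_label(s), _state_label(t))
        return "\n".join(nx.generate_graphml(g)) + "\n"
    raise ModelError(f"unknown export format {format!r} (use 'dot' or 'graphml')")
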