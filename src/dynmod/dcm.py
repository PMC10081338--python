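"""Canalyzing maps and the dynamics canalization map (DCM).

The DCM is a threshold-network redescription of an entire Boolean network.
It contains one *s-unit* per node state (``x-0`` and ``x-1``, so ``2n``
s-units in total) and one *t-unit* per two-symbol schema of every node.
A t-unit has threshold tau equal to the number of enputs of its schema and
fires when it receives tau simultaneous signals; fixed schema positions
contribute single-source fibres, group-invariant enputs contribute merged
fibre bundles that deliver at most ``m`` signals.  Signals travel from
s-units to t-units instantly (dt=0) and from t-units to their target
s-unit with a one-step delay (dt=1); the asymmetry preserves the timing of
the original synchronous dynamics.

Canonical firing semantics are defined by schema matching on the current
firing partial configuration; the threshold representation is kept for
structure and export and is asserted equivalent in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

from .canalization import TwoSymbolSchema, prime_implicants, two_symbol
from .network import BooleanNetwork, BooleanNode

__all__ = ["SUnit", "TUnit", "DCM", "build_cm", "build_dcm"]


class SUnit(NamedTuple):
    """A node variable in one of its Boolean states, written ``x-0``/``x-1``."""

    variable: str
    state: int

    @property
    def label(self) -> str:
        return f"{self.variable}-{self.state}"

    @property
    def negation(self) -> "SUnit":
        return SUnit(self.variable, 1 - self.state)

    @classmethod
    def parse(cls, label: str) -> "SUnit":
        var, _, state = label.rpartition("-")
        if state not in ("0", "1") or not var:
            raise ValueError(f"not an s-unit label: {label!r}")
        return cls(var, int(state))


@dataclass(frozen=True)
class TUnit:
    """One two-symbol schema as a threshold unit targeting an s-unit."""

    id: str
    target: SUnit
    schema: TwoSymbolSchema

    @property
    def tau(self) -> int:
        return self.schema.tau

    @property
    def single_fibres(self) -> tuple[SUnit, ...]:
        """One single-source fibre per fixed schema position."""
        return tuple(
            SUnit(self.schema.inputs[pos], state)
            for pos, state in self.schema.fixed
        )

    @property
    def fibre_bundles(self) -> tuple[tuple[frozenset[SUnit], int], ...]:
        """One merged fibre bundle per group-invariant enput:
        (source s-units, required signal count m)."""
        out = []
        for positions, syms in self.schema.bundles:
            sources = frozenset(
                SUnit(self.schema.inputs[p], int(s))
                for p in positions
                for s in set(syms)
                if s != "#"
            )
            m = sum(1 for s in syms if s != "#")
            out.append((sources, m))
        return tuple(out)

    @property
    def sources(self) -> frozenset[SUnit]:
        srcs = set(self.single_fibres)
        for sources, _ in self.fibre_bundles:
            srcs |= sources
        return frozenset(srcs)

    def fires(self, pc: Mapping[str, int]) -> bool:
        """Canonical semantics: fire iff the schema is guaranteed by the
        firing partial configuration."""
        return self.schema.matches(pc)

    def fires_by_threshold(self, fired: Iterable[SUnit]) -> bool:
        """Structural semantics: count incoming signals against tau.

        Single fibres deliver one signal each; a merged bundle delivers one
        signal per required state realized by a distinct firing source, up
        to ``m``.
        """
        fired = set(fired)
        signals = sum(1 for s in self.single_fibres if s in fired)
        for positions, syms in self.schema.bundles:
            for state in (0, 1):
                need = sum(1 for s in syms if s == str(state))
                have = sum(
                    1 for p in positions
                    if SUnit(self.schema.inputs[p], state) in fired
                )
                signals += min(need, have)
        return signals >= self.tau


@dataclass
class DCM:
    """The dynamics canalization map of a Boolean network."""

    variables: tuple[str, ...]
    t_units: list[TUnit]
    f_double_prime: dict[str, list[TwoSymbolSchema]] = field(default_factory=dict)

    @property
    def s_units(self) -> list[SUnit]:
        return [SUnit(v, st) for v in self.variables for st in (0, 1)]

    @property
    def n(self) -> int:
        return len(self.variables)

    def t_units_targeting(self, s: SUnit) -> list[TUnit]:
        return [t for t in self.t_units if t.target == s]

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "t_units": [
                {
                    "id": t.id,
                    "target": t.target.label,
                    "inputs": list(t.schema.inputs),
                    "output": t.schema.output,
                    "fixed": [[p, s] for p, s in t.schema.fixed],
                    "bundles": [
                        [list(pos), list(syms)] for pos, syms in t.schema.bundles
                    ],
                }
                for t in self.t_units
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, data: dict) -> "DCM":
        t_units = []
        for td in data["t_units"]:
            schema = TwoSymbolSchema(
                inputs=tuple(td["inputs"]),
                output=td["output"],
                fixed=tuple((p, s) for p, s in td["fixed"]),
                bundles=tuple(
                    (tuple(pos), tuple(syms)) for pos, syms in td["bundles"]
                ),
            )
            t_units.append(TUnit(td["id"], SUnit.parse(td["target"]), schema))
        dcm = cls(tuple(data["variables"]), t_units)
        for t in t_units:
            dcm.f_double_prime.setdefault(t.target.variable, []).append(t.schema)
        return dcm

    @classmethod
    def from_json(cls, text: str) -> "DCM":
        return cls.from_dict(json.loads(text))

    def __eq__(self, other) -> bool:
        if not isinstance(other, DCM):
            return NotImplemented
        return self.variables == other.variables and [
            (t.target, t.schema) for t in self.t_units
        ] == [(t.target, t.schema) for t in other.t_units]

    # -- graph exports ---------------------------------------------------

    def _display_t_units(self, simplify: bool) -> list[TUnit]:
        if not simplify:
            return list(self.t_units)
        return [t for t in self.t_units if t.tau > 1 or t.fibre_bundles]

    def to_networkx(self, simplify: bool = False):
        """Typed graph: s-unit and t-unit vertices, fibre edges (delay 0)
        and t-to-s edges (delay 1)."""
        import networkx as nx

        g = nx.DiGraph()
        for s in self.s_units:
            g.add_node(s.label, kind="s-unit", variable=s.variable, state=s.state)
        shown = self._display_t_units(simplify)
        for t in shown:
            g.add_node(t.id, kind="t-unit", tau=t.tau, target=t.target.label)
            for s in t.single_fibres:
                g.add_edge(s.label, t.id, delay=0, bundle=-1, required=1)
            for bi, (sources, m) in enumerate(t.fibre_bundles):
                for s in sources:
                    g.add_edge(s.label, t.id, delay=0, bundle=bi, required=m)
            g.add_edge(t.id, t.target.label, delay=1, bundle=-1, required=0)
        if simplify:
            for t in self.t_units:
                if t not in shown and t.single_fibres:
                    g.add_edge(t.single_fibres[0].label, t.target.label,
                               delay=1, bundle=-1, required=1)
        return g

    def to_graphml(self, simplify: bool = False) -> str:
        import io

        import networkx as nx

        buf = io.BytesIO()
        nx.write_graphml(self.to_networkx(simplify=simplify), buf)
        return buf.getvalue().decode()

    def to_dot(self, simplify: bool = False) -> str:
        lines = ["digraph DCM {"]
        for s in self.s_units:
            fill = "black" if s.state else "white"
            font = "white" if s.state else "black"
            lines.append(
                f'  "{s.label}" [shape=circle style=filled fillcolor={fill} '
                f"fontcolor={font}];"
            )
        shown = self._display_t_units(simplify)
        for t in shown:
            lines.append(f'  "{t.id}" [shape=diamond label="τ={t.tau}"];')
            for s in t.single_fibres:
                lines.append(f'  "{s.label}" -> "{t.id}";')
            for bi, (sources, _) in enumerate(t.fibre_bundles):
                for s in sorted(sources):
                    lines.append(f'  "{s.label}" -> "{t.id}" [style=dashed];')
            lines.append(f'  "{t.id}" -> "{t.target.label}";')
        if simplify:
            for t in self.t_units:
                if t not in shown and t.single_fibres:
                    lines.append(
                        f'  "{t.single_fibres[0].label}" -> "{t.target.label}";'
                    )
        lines.append("}")
        return "\n".join(lines) + "\n"


def export_dcm(dcm: DCM, format: str, simplify: bool = False) -> str:
    """Serialize a DCM as ``json`` (lossless round-trip), ``graphml`` or
    ``dot``."""
    if format == "json":
        return dcm.to_json(indent=2)
    if format == "graphml":
        return dcm.to_graphml(simplify=simplify)
    if format == "dot":
        return dcm.to_dot(simplify=simplify)
    raise ValueError(f"unknown export format {format!r}")


def build_cm(node: BooleanNode, f2: list[TwoSymbolSchema] | None = None):
    """Canalyzing map of one node: its two s-units and one t-unit per
    two-symbol schema."""
    if f2 is None:
        f2 = two_symbol(prime_implicants(node))
    s_pair = (SUnit(node.name, 0), SUnit(node.name, 1))
    t_units = []
    counters = {0: 0, 1: 0}
    for schema in f2:
        idx = counters[schema.output]
        counters[schema.output] += 1
        target = SUnit(node.name, schema.output)
        t_units.append(TUnit(f"{target.label}:{idx}", target, schema))
    return s_pair, t_units


def build_dcm(net: BooleanNetwork) -> DCM:
    """Assemble the DCM: the union of all per-node canalyzing maps over the
    shared set of ``2n`` s-units."""
    t_units: list[TUnit] = []
    f2_map: dict[str, list[TwoSymbolSchema]] = {}
    for node in net.nodes:
        f2 = two_symbol(prime_implicants(node))
        f2_map[node.name] = f2
        _, ts = build_cm(node, f2)
        t_units.extend(ts)
    return DCM(tuple(net.names), t_units, f2_map)
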