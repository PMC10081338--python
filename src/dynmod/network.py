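"""Boolean automata networks: parsing, simulation, composition, generation.

A Boolean network is a directed graph of named automata.  Each automaton
(node) carries an ordered tuple of input node names and a look-up table
(LUT) giving its next state for every combination of input states.  The
network updates synchronously: at every discrete time step all nodes read
their inputs and transition simultaneously.

Configurations are plain dictionaries mapping node names to 0/1.  A
*partial* configuration simply omits the unknown variables (they are in
the wildcard state ``#``).

The module also provides the exhaustive-simulation oracle
:func:`brute_force_stabilization`, which certifies which node states are
guaranteed to hold in every attractor reachable under a pinning
perturbation, by enumerating every completion of the unpinned variables.
"""

from __future__ import annotations

import ast
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "BooleanNode",
    "BooleanNetwork",
    "LatticeSpec",
    "RuleError",
    "parse_rules",
    "parse_lut_table",
    "write_rules",
    "write_lut_table",
    "synchronous_step",
    "attractor_from",
    "brute_force_stabilization",
    "compose_lattice",
    "generate_random_bn",
]

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


class RuleError(ValueError):
    """Raised for malformed rule files or inconsistent network definitions."""


@dataclass(frozen=True)
class BooleanNode:
    """One automaton: ``name``, ordered ``inputs`` and a LUT.

    ``lut[r]`` is the output for input row ``r``, where rows count in
    binary over the inputs with ``inputs[0]`` as the most significant bit.
    ``k = len(inputs)`` may be zero (a constant node with a 1-row LUT).
    """

    name: str
    inputs: tuple[str, ...]
    lut: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.lut) != 2 ** len(self.inputs):
            raise RuleError(
                f"node {self.name}: LUT has {len(self.lut)} rows, "
                f"expected {2 ** len(self.inputs)}"
            )
        if any(v not in (0, 1) for v in self.lut):
            raise RuleError(f"node {self.name}: LUT entries must be 0/1")
        if len(set(self.inputs)) != len(self.inputs):
            raise RuleError(f"node {self.name}: duplicate inputs")

    @property
    def k(self) -> int:
        return len(self.inputs)

    def evaluate(self, values: Mapping[str, int]) -> int:
        """LUT output for a full assignment of this node's inputs."""
        row = 0
        for v in self.inputs:
            row = (row << 1) | values[v]
        return self.lut[row]

    def row_bits(self, row: int) -> tuple[int, ...]:
        """Input states of LUT row ``row`` in input order."""
        k = self.k
        return tuple((row >> (k - 1 - i)) & 1 for i in range(k))


@dataclass
class BooleanNetwork:
    """A synchronous Boolean network ``B=(X, E)``."""

    nodes: list[BooleanNode] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [nd.name for nd in self.nodes]
        if len(set(names)) != len(names):
            raise RuleError("duplicate node names")
        defined = set(names)
        for nd in self.nodes:
            for v in nd.inputs:
                if v not in defined:
                    raise RuleError(
                        f"node {nd.name}: input {v!r} is not defined in the network"
                    )
        self._by_name = {nd.name: nd for nd in self.nodes}

    def __len__(self) -> int:
        return len(self.nodes)

    def __getitem__(self, name: str) -> BooleanNode:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [nd.name for nd in self.nodes]

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Directed edges (source, target): source is an input of target."""
        return {(v, nd.name) for nd in self.nodes for v in nd.inputs}

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.names)
        g.add_edges_from(self.edges)
        return g


# ---------------------------------------------------------------------------
# rule-file parsing


_ALLOWED_AST = (ast.Expression, ast.BoolOp, ast.And, ast.Or, ast.UnaryOp,
                ast.Not, ast.Name, ast.Load, ast.Constant)


def _parse_expression(expr: str, context: str) -> tuple[ast.Expression, list[str]]:
    """Parse a boolean expression; return the AST and variables in order of
    first appearance."""
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as exc:
        raise RuleError(f"{context}: cannot parse expression {expr!r}: {exc}") from None
    names: list[str] = []

    def visit(node: ast.AST) -> None:  # depth-first: source order of names
        if not isinstance(node, _ALLOWED_AST):
            raise RuleError(
                f"{context}: unsupported syntax {type(node).__name__} in {expr!r} "
                "(only and/or/not, parentheses, names and 0/1 are allowed)"
            )
        if isinstance(node, ast.Constant) and node.value not in (0, 1, True, False):
            raise RuleError(f"{context}: constant {node.value!r} is not boolean")
        if isinstance(node, ast.Name) and node.id not in names:
            names.append(node.id)
        for child in ast.iter_child_nodes(node):
            visit(child)

    visit(tree)
    return tree, names


def _tabulate(tree: ast.Expression, variables: Sequence[str]) -> list[int]:
    code = compile(tree, "<rule>", "eval")
    k = len(variables)
    out = []
    for row in range(2 ** k):
        env = {v: (row >> (k - 1 - i)) & 1 for i, v in enumerate(variables)}
        out.append(1 if eval(code, {"__builtins__": {}}, env) else 0)
    return out


def _prune_fictitious(variables: Sequence[str], lut: Sequence[int]):
    """Drop inputs whose state never affects the output; re-tabulate."""
    k = len(variables)
    essential = []
    for i in range(k):
        stride = 1 << (k - 1 - i)
        dep = any(
            lut[r] != lut[r | stride]
            for r in range(2 ** k)
            if not r & stride
        )
        if dep:
            essential.append(i)
    if len(essential) == k:
        return tuple(variables), tuple(lut)
    new_vars = tuple(variables[i] for i in essential)
    m = len(new_vars)
    new_lut = []
    for row in range(2 ** m):
        full = 0
        for j, i in enumerate(essential):
            bit = (row >> (m - 1 - j)) & 1
            full |= bit << (k - 1 - i)
        new_lut.append(lut[full])
    return new_vars, tuple(new_lut)


def parse_rules(text: str) -> BooleanNetwork:
    """Parse a rule file: one ``name* = expression`` per line.

    Expressions use ``and``/``or``/``not``, parentheses, node names and the
    constants 0/1.  ``#`` starts a comment.  Inputs whose value never
    affects the output (fictitious inputs) are pruned during tabulation so
    that the wiring reflects only essential dependencies.
    """
    rules: dict[str, str] = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise RuleError(f"not a rule: {raw!r}")
        lhs, rhs = line.split("=", 1)
        name = lhs.strip()
        if name.endswith("*"):
            name = name[:-1].strip()
        if not _NAME_RE.match(name):
            raise RuleError(f"invalid node name {name!r}")
        if name in rules:
            raise RuleError(f"duplicate rule for node {name!r}")
        rules[name] = rhs.strip()

    nodes = []
    for name, expr in rules.items():
        tree, variables = _parse_expression(expr, f"rule for {name}")
        for v in variables:
            if v not in rules:
                raise RuleError(f"rule for {name}: undefined variable {v!r}")
        lut = _tabulate(tree, variables)
        variables, lut = _prune_fictitious(variables, lut)
        nodes.append(BooleanNode(name, tuple(variables), tuple(lut)))
    return BooleanNetwork(nodes)


def _term_string(inputs: Sequence[str], pattern: str) -> str:
    lits = []
    for v, sym in zip(inputs, pattern):
        if sym == "1":
            lits.append(v)
        elif sym == "0":
            lits.append(f"not {v}")
    return " and ".join(lits)


def write_rules(net: BooleanNetwork) -> str:
    """Serialize a network to rule-file text.

    Each rule is the disjunction of the node's ON prime implicants with
    literals in input order.  When the order of first appearance of the
    variables in that disjunction would differ from the node's input
    order, a (redundant) fully specified ON row is prepended so that
    re-parsing recovers the exact same input order; serialization is then
    idempotent.
    """
    from .canalization import prime_patterns

    lines = []
    for nd in net.nodes:
        if nd.k == 0:
            lines.append(f"{nd.name}* = {nd.lut[0]}")
            continue
        onset = [r for r, v in enumerate(nd.lut) if v == 1]
        if not onset:
            lines.append(f"{nd.name}* = 0")
            continue
        if len(onset) == 2 ** nd.k:
            lines.append(f"{nd.name}* = 1")
            continue
        pats = prime_patterns(nd.k, onset)
        pats.sort(key=lambda p: (p.index("0") if "0" in p else nd.k,
                                 p.index("1") if "1" in p else nd.k, p))
        pats.sort(key=lambda p: min(i for i, s in enumerate(p) if s != "#"))
        appearance = []
        for p in pats:
            for i, s in enumerate(p):
                if s != "#" and i not in appearance:
                    appearance.append(i)
        essential = sorted(appearance)
        if appearance != essential:
            # anchor the input order with one fully specified ON row
            anchor = format(onset[0], f"0{nd.k}b")
            pats.insert(0, anchor)
        terms = [_term_string(nd.inputs, p) for p in pats]
        if len(terms) > 1:
            terms = [f"({t})" if " " in t else t for t in terms]
        lines.append(f"{nd.name}* = " + " or ".join(terms))
    return "\n".join(lines) + "\n"


def parse_lut_table(text: str) -> BooleanNetwork:
    """Parse an explicit LUT table: TSV with columns node, inputs, output bits.

    ``inputs`` is a comma-separated list (empty for constants); the output
    column is the LUT as a 0/1 string in binary-counting row order.
    """
    nodes = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise RuleError(f"LUT table row needs 3 tab-separated columns: {raw!r}")
        name, inputs_s, bits = (p.strip() for p in parts)
        inputs = tuple(v.strip() for v in inputs_s.split(",") if v.strip())
        if not set(bits) <= {"0", "1"}:
            raise RuleError(f"node {name}: output column must be 0/1 bits")
        nodes.append(BooleanNode(name, inputs, tuple(int(b) for b in bits)))
    return BooleanNetwork(nodes)


def write_lut_table(net: BooleanNetwork) -> str:
    rows = []
    for nd in net.nodes:
        rows.append(f"{nd.name}\t{','.join(nd.inputs)}\t{''.join(map(str, nd.lut))}")
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# simulation


def synchronous_step(net: BooleanNetwork, config: Mapping[str, int]) -> dict[str, int]:
    """One synchronous update of a full configuration."""
    for name in net.names:
        if config.get(name) not in (0, 1):
            raise ValueError(f"partial configuration: {name!r} is unknown")
    return {nd.name: nd.evaluate(config) for nd in net.nodes}


def attractor_from(net: BooleanNetwork, config: Mapping[str, int]):
    """Iterate the synchronous dynamics to the reached attractor.

    Returns ``(transient_length, cycle)`` where ``cycle`` is the list of
    configurations of the attractor in visiting order.
    """
    seen: dict[tuple[int, ...], int] = {}
    names = net.names
    trajectory = []
    cfg = dict(config)
    while True:
        key = tuple(cfg[x] for x in names)
        if key in seen:
            start = seen[key]
            return start, trajectory[start:]
        seen[key] = len(trajectory)
        trajectory.append(cfg)
        cfg = synchronous_step(net, cfg)


def _transition_table(net: BooleanNetwork, pinned: Mapping[str, int]):
    """Vectorized transition map over all completions of the unpinned
    variables, with pinned variables held fixed each step."""
    names = net.names
    n = len(names)
    pos = {x: i for i, x in enumerate(names)}
    free = [x for x in names if x not in pinned]
    f = len(free)
    m = 2 ** f
    codes = np.arange(m, dtype=np.int64)
    bits = np.zeros((m, n), dtype=np.int8)
    for j, x in enumerate(free):
        bits[:, pos[x]] = (codes >> (f - 1 - j)) & 1
    for x, v in pinned.items():
        bits[:, pos[x]] = v
    nxt = np.zeros((m, n), dtype=np.int8)
    for nd in net.nodes:
        if nd.name in pinned:
            nxt[:, pos[nd.name]] = pinned[nd.name]
            continue
        row = np.zeros(m, dtype=np.int64)
        for v in nd.inputs:
            row = (row << 1) | bits[:, pos[v]]
        nxt[:, pos[nd.name]] = np.asarray(nd.lut, dtype=np.int8)[row]
    trans = np.zeros(m, dtype=np.int64)
    for j, x in enumerate(free):
        trans |= nxt[:, pos[x]].astype(np.int64) << (f - 1 - j)
    return trans, free, f


def brute_force_stabilization(
    net: BooleanNetwork, pinned: Mapping[str, int], cap: int = 20
) -> set[tuple[str, int]]:
    """Exhaustive-simulation oracle for pinning perturbations.

    Simulates every completion of the unpinned variables (pinned variables
    held fixed each step) to its attractor, and returns exactly the
    ``(variable, state)`` pairs that hold at every time step of every
    reached attractor.  Pinned variables themselves are not reported.
    """
    for x, v in pinned.items():
        if x not in net:
            raise ValueError(f"unknown pinned variable {x!r}")
        if v not in (0, 1):
            raise ValueError(f"pinned value for {x!r} must be 0/1")
    free_count = len(net) - len(pinned)
    if free_count > cap:
        raise ValueError(
            f"{free_count} free variables exceed the exhaustive cap of {cap}"
        )
    trans, free, f = _transition_table(net, pinned)
    # after 2^f steps every trajectory is inside its attractor cycle
    land = trans.copy()
    for _ in range(max(f, 1)):
        land = land[land]
    cycle_states: set[int] = set()
    for code in np.unique(land):
        c = int(code)
        if c in cycle_states:
            continue
        walk = []
        while c not in cycle_states:
            walk.append(c)
            cycle_states.add(c)
            c = int(trans[c])
            if c in walk:
                break
    stable: set[tuple[str, int]] = set()
    states = sorted(cycle_states)
    for j, x in enumerate(free):
        vals = {(s >> (f - 1 - j)) & 1 for s in states}
        if len(vals) == 1:
            stable.add((x, vals.pop()))
    return stable


# ---------------------------------------------------------------------------
# lattice composition


@dataclass
class LatticeSpec:
    """Replicate a single-cell template over a 1-D lattice of cells.

    ``coupling`` maps a template input node to an expression over
    neighbor-cell nodes written with relative offsets, e.g.
    ``"WG[-1] or WG[+1]"``.  Coupled inputs are removed from each cell and
    every reference to them is replaced by the resolved expression.
    """

    template: BooleanNetwork
    cells: int
    coupling: dict[str, str] = field(default_factory=dict)
    boundary: str = "periodic"

    def __post_init__(self) -> None:
        if self.cells < 1:
            raise ValueError("cells must be >= 1")
        if self.boundary not in ("periodic", "open"):
            raise ValueError("boundary must be 'periodic' or 'open'")
        for name in self.coupling:
            if name not in self.template:
                raise RuleError(f"coupling references missing template node {name!r}")


_TOKEN_RE = re.compile(
    r"([A-Za-z_][A-Za-z0-9_]*)(\s*\[\s*([+-]?\d+)\s*\])?"
)


def _resolve_cell(name: str, offset: int, cell: int, spec: LatticeSpec) -> str:
    idx = cell + offset
    if spec.boundary == "periodic":
        idx = (idx - 1) % spec.cells + 1
    elif not 1 <= idx <= spec.cells:
        raise RuleError(
            f"offset {offset:+d} from cell {cell} escapes the open boundary"
        )
    return f"{name}_{idx}"


def _coupling_expression(expr: str, cell: int, spec: LatticeSpec) -> str:
    """Resolve ``name[offset]`` tokens (and bare names, offset 0) to
    absolute cell indices in one pass."""

    def repl(m: re.Match) -> str:
        name = m.group(1)
        if name in ("and", "or", "not"):
            return name
        if name not in spec.template:
            raise RuleError(f"coupling references missing template node {name!r}")
        off = int(m.group(3)) if m.group(2) else 0
        return _resolve_cell(name, off, cell, spec)

    return _TOKEN_RE.sub(repl, expr)


def compose_lattice(spec: LatticeSpec) -> BooleanNetwork:
    """Build the lattice network from a single-cell template.

    Every uncoupled template node is replicated per cell with a ``_<cell>``
    suffix; references to coupled inputs are substituted by the coupling
    expression resolved to absolute cell indices, and all LUTs are
    re-tabulated.
    """
    template_rules = write_rules(spec.template)
    per_node = {}
    for raw in template_rules.splitlines():
        lhs, rhs = raw.split("=", 1)
        per_node[lhs.strip().rstrip("*").strip()] = rhs.strip()

    lines = []
    for cell in range(1, spec.cells + 1):
        for nd in spec.template.nodes:
            if nd.name in spec.coupling:
                continue
            expr = per_node[nd.name]
            tree, variables = _parse_expression(expr, f"template rule {nd.name}")
            sub = {}
            for v in variables:
                if v in spec.coupling:
                    sub[v] = "(" + _coupling_expression(spec.coupling[v], cell, spec) + ")"
                else:
                    sub[v] = f"{v}_{cell}"
            rewritten = re.sub(
                r"\b([A-Za-z_][A-Za-z0-9_]*)\b",
                lambda m: sub.get(m.group(1), m.group(1)),
                expr,
            )
            lines.append(f"{nd.name}_{cell}* = {rewritten}")
    return parse_rules("\n".join(lines))


# ---------------------------------------------------------------------------
# random networks


def generate_random_bn(n: int, k: int, bias: float, seed: int) -> BooleanNetwork:
    """Random Boolean network: ``n`` nodes, each with ``k`` distinct random
    inputs and i.i.d. Bernoulli(``bias``) LUT outputs.  Same seed, same
    network."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 <= bias <= 1.0:
        raise ValueError("bias must be in [0, 1]")
    rng = np.random.default_rng(seed)
    names = [f"v{i + 1}" for i in range(n)]
    nodes = []
    for name in names:
        inputs = tuple(names[j] for j in sorted(rng.choice(n, size=k, replace=False)))
        lut = tuple(int(b) for b in rng.random(2 ** k) < bias)
        nodes.append(BooleanNode(name, inputs, lut))
    return BooleanNetwork(nodes)
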