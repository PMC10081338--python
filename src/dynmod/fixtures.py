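"""Bundled example networks and their self-tests.

Two fixtures are small didactic networks whose full modularity analysis is
known exactly and used throughout the test suite:

* ``or_gate`` — a three-node network whose output node is a logical OR of
  two free inputs; the minimal example of input symmetry (one ON input
  suffices to switch ON, both OFF inputs are needed to switch OFF).
* ``example_grn`` — a six-node gene-regulatory toy model: two constant
  inputs (i1, i2), two genes (g1, g2) and two proteins (P1, P2) with a
  negative feedback loop (P1 activates g2, whose product P2 represses P1).
  P1 requires g1 and the absence of P2; P2 requires g2 and i2.

``example_grn_lattice4`` replicates the toy model over a periodic 4-cell
lattice (each cell's inputs read the neighboring cells' P2 protein) to
exercise lattice composition, and ``random:<params>`` builds seeded random
networks for property testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .canalization import prime_implicants
from .dcm import build_dcm
from .modularity import (
    candidate_pool,
    characteristic_seed_number,
    minimal_cover,
    optimal_cover_exact,
)
from .module_algebra import ModuleSpace
from .network import (
    BooleanNetwork,
    LatticeSpec,
    brute_force_stabilization,
    compose_lattice,
    generate_random_bn,
    parse_rules,
)

__all__ = ["Fixture", "FIXTURES", "load_fixture", "run_selftest"]

OR_GATE_RULES = """\
# three-node OR-gate automaton: two free inputs and the OR output
x1* = x1
x2* = x2
x* = x1 or x2
"""

EXAMPLE_GRN_RULES = """\
# six-node example GRN: inputs i1,i2; genes g1,g2; proteins P1,P2
i1* = i1
i2* = i2
g1* = i1
g2* = P1
P1* = g1 and not P2
P2* = g2 and i2
"""


@dataclass
class Fixture:
    name: str
    rules: str
    provenance: str
    expected: dict = field(default_factory=dict)
    build: Callable[[], BooleanNetwork] | None = None

    def network(self) -> BooleanNetwork:
        if self.build is not None:
            return self.build()
        return parse_rules(self.rules)


def _lattice4() -> BooleanNetwork:
    template = parse_rules(EXAMPLE_GRN_RULES)
    spec = LatticeSpec(
        template=template,
        cells=4,
        coupling={"i1": "P2[-1]", "i2": "P2[+1]"},
        boundary="periodic",
    )
    return compose_lattice(spec)


FIXTURES: dict[str, Fixture] = {
    "or_gate": Fixture(
        name="or_gate",
        rules=OR_GATE_RULES,
        provenance="didactic OR automaton with two free inputs",
        expected={
            "n": 3,
            "f_prime_x": {("1#", 1), ("#1", 1), ("00", 0)},
            "tau_on": 1,
            "tau_off": 2,
        },
    ),
    "example_grn": Fixture(
        name="example_grn",
        rules=EXAMPLE_GRN_RULES,
        provenance="six-node toy GRN with a negative feedback loop",
        expected={
            "n": 6,
            "s_units": 12,
            "complex_s1": 6,
            "core_complex_s2": 2,
            "dbar_s1": 0.71,
            "dbar_minimal_s2": 0.60,
            "dbar_s2": 0.83,
            "minimal_cover_size_s2": 3,
            "s_star": 2,
        },
    ),
    "example_grn_lattice4": Fixture(
        name="example_grn_lattice4",
        rules="",
        provenance="toy GRN composed over a periodic 4-cell lattice "
                   "(cell inputs read the neighbors' P2)",
        expected={"n": 16},
        build=_lattice4,
    ),
}


def load_fixture(name: str) -> BooleanNetwork:
    """Load a bundled fixture network.

    ``random:n=8,k=2,bias=0.5,seed=7`` builds a seeded random network;
    other names index the bundled table.
    """
    if name.startswith("random:"):
        params = dict(
            item.split("=", 1) for item in name[len("random:"):].split(",") if item
        )
        return generate_random_bn(
            n=int(params.get("n", 8)),
            k=int(params.get("k", 2)),
            bias=float(params.get("bias", 0.5)),
            seed=int(params.get("seed", 0)),
        )
    try:
        return FIXTURES[name].network()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)} "
            "or random:<params>"
        ) from None


def run_selftest(name: str) -> list[tuple[str, bool, str]]:
    """Run the full pipeline on a fixture and compare against its
    expected-values table.  Returns (check, passed, detail) entries."""
    report: list[tuple[str, bool, str]] = []

    def check(label: str, got, want) -> None:
        report.append((label, got == want, f"got {got!r}, expected {want!r}"))

    if name.startswith("random:"):
        net = load_fixture(name)
        dcm = build_dcm(net)
        space = ModuleSpace(dcm)
        ok = True
        detail = ""
        for pm in space.pathway_modules(1):
            stable = brute_force_stabilization(
                net, {u.variable: u.state for u in pm.seed_units}
            )
            derived = {
                (u.variable, u.state)
                for u in pm.module_set - pm.seed_units
            }
            if not derived <= stable:
                ok = False
                detail = f"unsound module {pm!r}"
                break
        report.append(("pinning soundness vs exhaustive oracle", ok, detail))
        return report

    fx = FIXTURES[name]
    net = fx.network()
    exp = fx.expected
    check("node count", len(net), exp["n"])

    if name == "or_gate":
        node = net["x"]
        fp = {(ws.pattern, ws.output) for ws in prime_implicants(node)}
        check("F' of the OR node", fp, exp["f_prime_x"])
        dcm = build_dcm(net)
        taus = {
            t.target.state: t.tau for t in dcm.t_units if t.target.variable == "x"
        }
        check("ON threshold", taus[1], exp["tau_on"])
        check("OFF threshold", taus[0], exp["tau_off"])
    elif name == "example_grn":
        dcm = build_dcm(net)
        check("s-unit count", len(dcm.s_units), exp["s_units"])
        space = ModuleSpace(dcm)
        from .module_algebra import core_filter

        check("complex modules at s=1", len(space.complex_modules(1)),
              exp["complex_s1"])
        core2 = core_filter(space.complex_modules(2), space.maximal_modules(1))
        check("core complex modules at s=2", len(core2), exp["core_complex_s2"])
        universe = frozenset(dcm.s_units)
        pool1 = candidate_pool(dcm, 1, space=space)
        _, rep1 = optimal_cover_exact(pool1, universe, s=1)
        check("mean modularity of the s=1 optimal cover",
              rep1.mean_rounded(), exp["dbar_s1"])
        pool2 = candidate_pool(dcm, 2, space=space)
        cmin, repmin = minimal_cover(pool2, universe, s=2)
        check("minimal cover size at s=2", cmin.size,
              exp["minimal_cover_size_s2"])
        check("mean modularity of the minimal s=2 cover",
              repmin.mean_rounded(), exp["dbar_minimal_s2"])
        _, rep2 = optimal_cover_exact(pool2, universe, s=2)
        check("mean modularity of the s=2 optimal cover",
              rep2.mean_rounded(), exp["dbar_s2"])
        curve = characteristic_seed_number(dcm, s_max=3)
        check("characteristic seed number", curve.s_star, exp["s_star"])
    elif name == "example_grn_lattice4":
        dcm = build_dcm(net)
        check("s-unit count", len(dcm.s_units), 2 * exp["n"])
    return report
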