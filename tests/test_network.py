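"""Rule parsing, simulation, the exhaustive oracle, and composition."""

import numpy as np
import pytest

from dynmod import (
    LatticeSpec,
    brute_force_stabilization,
    compose_lattice,
    generate_random_bn,
    parse_lut_table,
    parse_rules,
    synchronous_step,
    write_lut_table,
    write_rules,
)
from dynmod.network import RuleError, attractor_from

from conftest import random_networks


class TestParseRules:
    def test_or_gate_lut(self, or_gate_net):
        node = or_gate_net["x"]
        assert node.inputs == ("x1", "x2")
        assert node.lut == (0, 1, 1, 1)  # rows 00, 01, 10, 11

    def test_identity_self_edge(self):
        net = parse_rules("i1* = i1")
        assert net["i1"].lut == (0, 1)
        assert ("i1", "i1") in net.edges

    def test_example_grn_wiring(self, grn_net):
        assert len(grn_net) == 6
        assert len(grn_net.edges) == 8
        assert grn_net["P1"].inputs == ("g1", "P2")
        assert grn_net["P1"].lut == (0, 0, 1, 0)  # g1 and not P2

    def test_fictitious_inputs_pruned(self):
        net = parse_rules("a* = a\nb* = (a and b) or (a and not b)")
        assert net["b"].inputs == ("a",)
        assert net["b"].lut == (0, 1)

    def test_constants_and_comments(self):
        net = parse_rules("# a constant\nc* = 1\nd* = c and 0")
        assert net["c"].lut == (1,)
        assert net["d"].lut == (0,)

    @pytest.mark.parametrize(
        "text",
        ["x* = y", "x* = x\nx* = not x", "x* = x +"],
        ids=["undefined-variable", "duplicate-rule", "unparseable"],
    )
    def test_errors(self, text):
        with pytest.raises(RuleError):
            parse_rules(text)


class TestRoundTrip:
    def test_fixture_round_trip_exact(self, or_gate_net, grn_net):
        for net in (or_gate_net, grn_net):
            again = parse_rules(write_rules(net))
            for name in net.names:
                assert again[name].inputs == net[name].inputs
                assert again[name].lut == net[name].lut

    def test_random_round_trip_semantics(self):
        for net in random_networks(10, n_range=(4, 7)):
            again = parse_rules(write_rules(net))
            assert {nd.name for nd in again.nodes} == set(net.names)
            for name in net.names:
                a, b = net[name], again[name]
                # after fictitious-input pruning the functions must agree
                assert set(b.inputs) <= set(a.inputs)
                for row in range(2 ** a.k):
                    values = dict(zip(a.inputs, a.row_bits(row)))
                    assert b.evaluate(values) == a.lut[row]
            # a second round trip is a fixed point of the serialization
            twice = parse_rules(write_rules(again))
            for name in net.names:
                assert twice[name].inputs == again[name].inputs
                assert twice[name].lut == again[name].lut

    def test_lut_table_round_trip(self, grn_net):
        again = parse_lut_table(write_lut_table(grn_net))
        for name in grn_net.names:
            assert again[name].inputs == grn_net[name].inputs
            assert again[name].lut == grn_net[name].lut


class TestSimulation:
    def test_or_gate_step(self, or_gate_net):
        nxt = synchronous_step(or_gate_net, {"x1": 1, "x2": 0, "x": 0})
        assert nxt["x"] == 1

    def test_grn_all_zero_fixed_point(self, grn_net):
        zero = {x: 0 for x in grn_net.names}
        assert synchronous_step(grn_net, zero) == zero

    def test_partial_configuration_rejected(self, grn_net):
        with pytest.raises(ValueError):
            synchronous_step(grn_net, {"i1": 1})

    def test_attractor_reached_within_state_count(self):
        for net in random_networks(5, n_range=(4, 6)):
            rng = np.random.default_rng(1)
            config = {x: int(rng.integers(2)) for x in net.names}
            transient, cycle = attractor_from(net, config)
            assert transient + len(cycle) <= 2 ** len(net)
            assert synchronous_step(net, cycle[-1]) == cycle[0]


class TestBruteForceStabilization:
    def test_grn_pin_i1_off(self, grn_net):
        stable = brute_force_stabilization(grn_net, {"i1": 0})
        assert stable == {("g1", 0), ("P1", 0), ("g2", 0), ("P2", 0)}

    def test_grn_pin_p1_and_i2_on(self, grn_net):
        stable = brute_force_stabilization(grn_net, {"P1": 1, "i2": 1})
        assert {("g2", 1), ("P2", 1)} <= stable

    def test_free_input_nothing_stabilizes(self):
        net = parse_rules("a* = a\nb* = a")
        assert brute_force_stabilization(net, {}) == set()

    def test_never_both_states(self):
        for net in random_networks(5, n_range=(4, 8)):
            stable = brute_force_stabilization(net, {net.names[0]: 1})
            variables = [v for v, _ in stable]
            assert len(variables) == len(set(variables))

    def test_cap_enforced(self, grn_net):
        with pytest.raises(ValueError):
            brute_force_stabilization(grn_net, {}, cap=3)


class TestComposeLattice:
    def test_uncoupled_is_disjoint_union(self):
        template = parse_rules("a* = a\nb* = a and b")
        net = compose_lattice(LatticeSpec(template=template, cells=4))
        assert len(net) == 8
        assert all(("_" in name) for name in net.names)
        assert ("a_1", "b_1") in net.edges and ("a_1", "b_2") not in net.edges

    def test_copy_ring_attractors(self):
        # x copies its left neighbor: a 3-cycle of copy nodes
        template = parse_rules("x_left* = x_left\nx* = x_left")
        spec = LatticeSpec(template=template, cells=3,
                           coupling={"x_left": "x[-1]"}, boundary="periodic")
        net = compose_lattice(spec)
        assert len(net) == 3
        cycles = set()
        for code in range(8):
            config = {f"x_{c + 1}": (code >> c) & 1 for c in range(3)}
            _, cycle = attractor_from(net, config)
            key = frozenset(tuple(sorted(cfg.items())) for cfg in cycle)
            cycles.add((len(cycle), key))
        lengths = sorted(l for l, _ in cycles)
        assert lengths == [1, 1, 3, 3]  # two constants plus the two rotations

    def test_open_boundary_offset_error(self):
        template = parse_rules("x_left* = x_left\nx* = x_left")
        spec = LatticeSpec(template=template, cells=3,
                           coupling={"x_left": "x[-1]"}, boundary="open")
        with pytest.raises(RuleError):
            compose_lattice(spec)

    def test_missing_template_node_error(self):
        template = parse_rules("x* = x")
        with pytest.raises(RuleError):
            LatticeSpec(template=template, cells=2, coupling={"nope": "x[-1]"})

    def test_grn_lattice_size(self):
        from dynmod import load_fixture

        net = load_fixture("example_grn_lattice4")
        assert len(net) == 16  # 4 uncoupled template nodes x 4 cells


class TestGenerateRandom:
    def test_lut_row_count(self):
        net = generate_random_bn(n=5, k=2, bias=0.5, seed=3)
        assert all(len(nd.lut) == 4 for nd in net.nodes)

    def test_determinism_byte_identical(self):
        a = write_rules(generate_random_bn(n=8, k=2, bias=0.5, seed=7))
        b = write_rules(generate_random_bn(n=8, k=2, bias=0.5, seed=7))
        assert a == b

    @pytest.mark.parametrize("kwargs", [dict(k=9), dict(bias=1.5)])
    def test_parameter_validation(self, kwargs):
        params = dict(n=5, k=2, bias=0.5, seed=0)
        params.update(kwargs)
        with pytest.raises(ValueError):
            generate_random_bn(**params)
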