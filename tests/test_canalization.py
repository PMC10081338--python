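"""Schemata redescription: prime implicants, two-symbol regrouping, matching."""

import numpy as np
import pytest

from dynmod import parse_rules, prime_implicants, schema_match, two_symbol
from dynmod.canalization import eval_f_double_prime, eval_f_prime
from dynmod.network import BooleanNode


def _node(expr_net, name):
    return parse_rules(expr_net)[name]


OR = "a* = a\nb* = a\nx* = a or b"
AND = "a* = a\nb* = a\nx* = a and b"
XOR = "a* = a\nb* = a\nx* = (a and not b) or (b and not a)"


class TestPrimeImplicants:
    def test_or_gate(self):
        fp = {(w.pattern, w.output) for w in prime_implicants(_node(OR, "x"))}
        assert fp == {("1#", 1), ("#1", 1), ("00", 0)}

    def test_and_gate(self):
        fp = {(w.pattern, w.output) for w in prime_implicants(_node(AND, "x"))}
        assert fp == {("11", 1), ("0#", 0), ("#0", 0)}

    def test_xor_gate(self):
        fp = {(w.pattern, w.output) for w in prime_implicants(_node(XOR, "x"))}
        assert fp == {("10", 1), ("01", 1), ("00", 0), ("11", 0)}

    def test_constant_single_wildcard_schema(self):
        node = BooleanNode("c", (), (1,))
        fp = prime_implicants(node)
        assert [(w.pattern, w.output) for w in fp] == [("", 1)]

    def test_prime_patterns_are_prime(self):
        # widening any specified position must cover an opposite-output row
        rng = np.random.default_rng(42)
        for _ in range(30):
            k = int(rng.integers(1, 6))
            lut = tuple(int(b) for b in rng.integers(0, 2, size=2 ** k))
            node = BooleanNode("r", tuple(f"v{i}" for i in range(k)), lut)
            for w in prime_implicants(node):
                opposite = {
                    r for r, v in enumerate(lut) if v != w.output
                }
                for i, sym in enumerate(w.pattern):
                    if sym == "#":
                        continue
                    widened = w.pattern[:i] + "#" + w.pattern[i + 1:]
                    covered = {
                        r for r in range(2 ** k)
                        if all(
                            s == "#" or int(s) == (r >> (k - 1 - j)) & 1
                            for j, s in enumerate(widened)
                        )
                    }
                    assert covered & opposite


class TestTwoSymbol:
    def test_or_on_schemata_merge_into_one_bundle(self):
        f2 = two_symbol(prime_implicants(_node(OR, "x")))
        on = [t for t in f2 if t.output == 1]
        assert len(on) == 1
        (positions, syms), = on[0].bundles
        assert positions == (0, 1) and sorted(syms) == ["#", "1"]
        assert on[0].expansion() == frozenset({"1#", "#1"})

    def test_xor_on_schemata_merge(self):
        f2 = two_symbol(prime_implicants(_node(XOR, "x")))
        on = [t for t in f2 if t.output == 1]
        assert len(on) == 1
        (positions, syms), = on[0].bundles
        assert sorted(syms) == ["0", "1"]
        assert on[0].expansion() == frozenset({"10", "01"})

    def test_asymmetric_schema_is_pass_through(self):
        node = _node("a* = a\nb* = a\nx* = a and not b", "x")
        f2 = two_symbol(prime_implicants(node))
        on = [t for t in f2 if t.output == 1]
        assert len(on) == 1 and not on[0].bundles
        assert dict(on[0].fixed) == {0: 1, 1: 0}

    def test_lossless_regrouping_on_random_luts(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            k = int(rng.integers(1, 6))
            lut = tuple(int(b) for b in rng.integers(0, 2, size=2 ** k))
            node = BooleanNode("r", tuple(f"v{i}" for i in range(k)), lut)
            fp = prime_implicants(node)
            f2 = two_symbol(fp)
            for output in (0, 1):
                flattened = set()
                for t in (t for t in f2 if t.output == output):
                    flattened |= t.expansion()
                assert flattened == {w.pattern for w in fp if w.output == output}
            expansions = [(t.output, t.expansion()) for t in f2]
            assert len(expansions) == len(set(expansions))


class TestSchemaMatch:
    def test_wildcard_ignores_unknown(self):
        ws = [w for w in prime_implicants(_node(OR, "x")) if w.pattern == "1#"][0]
        assert schema_match(ws, {"a": 1})
        assert schema_match(ws, {"a": 1, "b": "#"})

    def test_unknown_cannot_certify_required_state(self):
        ws = [w for w in prime_implicants(_node(OR, "x")) if w.pattern == "00"][0]
        assert not schema_match(ws, {"a": 0})
        assert schema_match(ws, {"a": 0, "b": 0})

    def test_bundle_injective_assignment(self):
        on = [t for t in two_symbol(prime_implicants(_node(XOR, "x")))
              if t.output == 1][0]
        assert schema_match(on, {"a": 0, "b": 1})
        assert schema_match(on, {"a": 1, "b": 0})
        assert not schema_match(on, {"a": 1})
        assert not schema_match(on, {"a": 1, "b": 1})


class TestSemanticEquivalence:
    """F, F' and F'' agree on every full input configuration."""

    @pytest.mark.parametrize("seed", range(6))
    def test_random_luts_exhaustive(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            k = int(rng.integers(0, 7))
            bias = rng.choice([0.25, 0.5, 0.75])
            lut = tuple(int(b) for b in rng.random(2 ** k) < bias)
            node = BooleanNode("r", tuple(f"v{i}" for i in range(k)), lut)
            fp = prime_implicants(node)
            f2 = two_symbol(fp)
            for row in range(2 ** k):
                values = dict(zip(node.inputs, node.row_bits(row)))
                assert eval_f_prime(fp, values) == lut[row]
                assert eval_f_double_prime(f2, values) == lut[row]

    def test_schema_disjointness_on_partial_configs(self):
        # no partial configuration certifies both an ON and an OFF schema
        rng = np.random.default_rng(11)
        for _ in range(20):
            k = int(rng.integers(1, 6))
            lut = tuple(int(b) for b in rng.integers(0, 2, size=2 ** k))
            node = BooleanNode("r", tuple(f"v{i}" for i in range(k)), lut)
            fp = prime_implicants(node)
            for _ in range(30):
                states = rng.integers(0, 3, size=k)
                pc = {f"v{i}": int(s) for i, s in enumerate(states) if s < 2}
                matched = {w.output for w in fp if schema_match(w, pc)}
                assert matched != {0, 1}
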