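"""Schemata redescription of Boolean automata.

A node's look-up table F is redescribed in two stages that strip the two
kinds of redundancy a transition function can carry:

* **Input redundancy** — the Quine-McCluskey algorithm reduces the rows of
  F (separately for the ON output and the OFF output) to their prime
  implicants, the *wildcard schemata* F'.  Positions marked ``#`` are
  redundant: the remaining *enputs* (essential inputs) alone guarantee the
  transition.
* **Input symmetry** — wildcard schemata that are permutations of one
  another over a set of positions are regrouped into *two-symbol
  schemata* F''.  The permutable positions form a group-invariant enput
  (written with the position-free symbol ``°``): the schema requires the
  multiset of states to appear over those positions in any order.

All prime implicants are retained (no minimal-cover step), which maximizes
the canalization detectable from partial configurations.  Matching is
defined so that a schema is satisfied only when the *known* entries of a
partial configuration guarantee it regardless of the unknown ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Mapping, Sequence

__all__ = [
    "WildcardSchema",
    "TwoSymbolSchema",
    "prime_patterns",
    "prime_implicants",
    "two_symbol",
    "schema_match",
    "eval_f_prime",
    "eval_f_double_prime",
]


def prime_patterns(k: int, onset: Iterable[int]) -> list[str]:
    """All prime implicants of the given set of LUT rows.

    Rows count in binary with position 0 as the most significant bit.
    Returns patterns over ``{0,1,#}`` of length ``k``, sorted.
    """
    rows = sorted(set(onset))
    if not rows:
        return []
    full_mask = (1 << k) - 1
    if k == 0:
        return [""]
    current = {(r, full_mask) for r in rows}
    primes: set[tuple[int, int]] = set()
    while current:
        combined: set[tuple[int, int]] = set()
        used: set[tuple[int, int]] = set()
        by_mask: dict[int, list[int]] = {}
        for bits, mask in current:
            by_mask.setdefault(mask, []).append(bits)
        for mask, group in by_mask.items():
            bucket: dict[int, list[int]] = {}
            for bits in group:
                bucket.setdefault(bin(bits).count("1"), []).append(bits)
            for c in sorted(bucket):
                for b1 in bucket[c]:
                    for b2 in bucket.get(c + 1, ()):
                        diff = b1 ^ b2
                        if diff & mask == diff and bin(diff).count("1") == 1:
                            combined.add((b1 & ~diff, mask & ~diff))
                            used.add((b1, mask))
                            used.add((b2, mask))
        primes |= current - used
        current = combined
    out = []
    for bits, mask in primes:
        out.append(
            "".join(
                "#" if not mask >> (k - 1 - i) & 1
                else str(bits >> (k - 1 - i) & 1)
                for i in range(k)
            )
        )
    return sorted(out)


def _known(value) -> bool:
    return value in (0, 1)


@dataclass(frozen=True)
class WildcardSchema:
    """A prime implicant: pattern over ``{0,1,#}`` with its output state."""

    inputs: tuple[str, ...]
    pattern: str
    output: int

    def __post_init__(self) -> None:
        if len(self.pattern) != len(self.inputs):
            raise ValueError("pattern length must equal the number of inputs")

    @property
    def n_enputs(self) -> int:
        return sum(1 for s in self.pattern if s != "#")

    def matches(self, pc: Mapping[str, int]) -> bool:
        """True iff the known entries of ``pc`` guarantee this schema."""
        for v, sym in zip(self.inputs, self.pattern):
            if sym != "#" and (not _known(pc.get(v)) or pc[v] != int(sym)):
                return False
        return True

    def __str__(self) -> str:
        return f"{self.pattern} -> {self.output}"


@dataclass(frozen=True)
class TwoSymbolSchema:
    """A group-invariant schema: fixed positions, permutable bundles and
    wildcards.

    ``fixed`` maps an input position to its required state.  Each bundle is
    ``(positions, symbols)``: the multiset ``symbols`` (over ``{0,1,#}``)
    must be realized over ``positions`` in some order.  Positions in
    neither are wildcards.
    """

    inputs: tuple[str, ...]
    output: int
    fixed: tuple[tuple[int, int], ...]
    bundles: tuple[tuple[tuple[int, ...], tuple[str, ...]], ...]

    @property
    def tau(self) -> int:
        """Number of enputs: fixed positions plus non-# bundle requirements."""
        return len(self.fixed) + sum(
            1 for _, syms in self.bundles for s in syms if s != "#"
        )

    def expansion(self) -> frozenset[str]:
        """All wildcard-schema patterns this schema regroups."""
        k = len(self.inputs)
        base = ["#"] * k
        for pos, state in self.fixed:
            base[pos] = str(state)
        pats = {tuple(base)}
        for positions, syms in self.bundles:
            new = set()
            for pat in pats:
                for arrangement in set(permutations(syms)):
                    cur = list(pat)
                    for p, s in zip(positions, arrangement):
                        cur[p] = s
                    new.add(tuple(cur))
            pats = new
        return frozenset("".join(p) for p in pats)

    def matches(self, pc: Mapping[str, int]) -> bool:
        """True iff the known entries of ``pc`` guarantee the schema.

        Fixed positions must be known and equal; each bundle needs, for
        every state it requires, at least as many known positions in that
        state (an injective assignment of the non-# requirements).
        """
        for pos, state in self.fixed:
            v = pc.get(self.inputs[pos])
            if not _known(v) or v != state:
                return False
        for positions, syms in self.bundles:
            for state in (0, 1):
                need = sum(1 for s in syms if s == str(state))
                have = sum(
                    1 for p in positions if _known(pc.get(self.inputs[p]))
                    and pc[self.inputs[p]] == state
                )
                if have < need:
                    return False
        return True

    def __str__(self) -> str:
        k = len(self.inputs)
        syms = ["#"] * k
        for pos, state in self.fixed:
            syms[pos] = str(state)
        marks = [""] * k
        for bi, (positions, bsyms) in enumerate(self.bundles):
            ordered = sorted(bsyms, reverse=True)
            for p, s in zip(positions, ordered):
                syms[p] = s
                marks[p] = "°" * (bi + 1)
        body = "".join(s + m for s, m in zip(syms, marks))
        return f"{body} -> {self.output}"


def prime_implicants(node) -> list[WildcardSchema]:
    """Wildcard schemata F' of a node: prime implicants of the ON rows and,
    separately, of the OFF rows (both output polarities are redescribed)."""
    schemas = []
    for output in (0, 1):
        rows = [r for r, v in enumerate(node.lut) if v == output]
        for pat in prime_patterns(node.k, rows):
            schemas.append(WildcardSchema(tuple(node.inputs), pat, output))
    return schemas


def _distinct_arrangements(syms: Sequence[str]) -> set[tuple[str, ...]]:
    return set(permutations(syms))


def _partition_expansion(groups, k: int) -> set[str]:
    pats = {("#",) * k}
    for positions, syms in groups:
        new = set()
        for pat in pats:
            for arrangement in _distinct_arrangements(syms):
                cur = list(pat)
                for p, s in zip(positions, arrangement):
                    cur[p] = s
                new.add(tuple(cur))
        pats = new
    return {"".join(p) for p in pats}


def two_symbol(
    f_prime: Sequence[WildcardSchema], max_k: int = 12
) -> list[TwoSymbolSchema]:
    """Regroup wildcard schemata into two-symbol schemata F''.

    For every F' schema, input positions are greedily merged into
    permutation groups: a merge is accepted only when every pattern in the
    resulting expansion is itself in F' (so the regrouping is lossless).
    Beyond ``max_k`` inputs the search is skipped and each F' schema
    becomes its own two-symbol schema.
    """
    if not f_prime:
        return []
    inputs = f_prime[0].inputs
    k = len(inputs)
    out: list[TwoSymbolSchema] = []
    seen: set[tuple[int, frozenset[str]]] = set()
    for output in (0, 1):
        pool = {ws.pattern for ws in f_prime if ws.output == output}
        for ws in f_prime:
            if ws.output != output:
                continue
            groups = [((i,), (s,)) for i, s in enumerate(ws.pattern)]
            if k <= max_k:
                merged = True
                while merged:
                    merged = False
                    for i in range(len(groups)):
                        for j in range(i + 1, len(groups)):
                            positions = groups[i][0] + groups[j][0]
                            syms = tuple(sorted(groups[i][1] + groups[j][1]))
                            if len(set(syms)) < 2:
                                continue
                            cand = (
                                groups[:i] + groups[i + 1:j] + groups[j + 1:]
                                + [(positions, syms)]
                            )
                            if _partition_expansion(cand, k) <= pool:
                                groups = cand
                                merged = True
                                break
                        if merged:
                            break
            fixed = []
            bundles = []
            for positions, syms in groups:
                if len(positions) == 1:
                    if syms[0] != "#":
                        fixed.append((positions[0], int(syms[0])))
                else:
                    bundles.append((tuple(sorted(positions)), syms))
            schema = TwoSymbolSchema(
                inputs,
                output,
                tuple(sorted(fixed)),
                tuple(sorted(bundles)),
            )
            key = (output, schema.expansion())
            if key not in seen:
                seen.add(key)
                out.append(schema)
    return out


def schema_match(schema, pc: Mapping[str, int]) -> bool:
    """Does the partial configuration ``pc`` of the node's inputs guarantee
    the schema?  Unknown entries (missing, ``None`` or ``'#'``) never
    satisfy a required state."""
    return schema.matches(pc)


def eval_f_prime(schemas: Sequence[WildcardSchema], values: Mapping[str, int]) -> int:
    """Evaluate a node on a full input assignment via its F' schemata."""
    matched = {ws.output for ws in schemas if ws.matches(values)}
    if len(matched) != 1:
        raise ValueError(f"F' schemata match outputs {sorted(matched)} (expected one)")
    return matched.pop()


def eval_f_double_prime(
    schemas: Sequence[TwoSymbolSchema], values: Mapping[str, int]
) -> int:
    """Evaluate a node on a full input assignment via its F'' schemata."""
    matched = {ts.output for ts in schemas if ts.matches(values)}
    if len(matched) != 1:
        raise ValueError(f"F'' schemata match outputs {sorted(matched)} (expected one)")
    return matched.pop()
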