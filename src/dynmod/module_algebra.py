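"""Interactions between pathway modules; maximal, complex and core modules.

Two pathway modules can be combined by unfolding the union of their seed
sets.  Comparing the combined module set with the union of the separate
ones classifies the pair:

* **synergy** — the combination fires s-units that neither fires alone;
* **logical obstruction** — the combination suppresses s-units that one
  of them fires alone (only possible via a state contradiction);
* **decoupled** — no overlap, no obstruction, no synergy: the combined
  unfolding is exactly the disjoint union.

A module is *maximal* (member of Lambda_s) when its module set is not a
proper subset of any module with the same or smaller seed set size; it is
*complex* (member of I_s) when it is maximal and every bipartition of its
seed set is synergistic — every seed contributes an interaction that no
combination of smaller modules reproduces.  *Core* complex modules
additionally require each individual seed to generate a maximal
single-seed module (the maximal seed heuristic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterable, Sequence

from .dcm import DCM, SUnit
from .unfolding import PathwayModule, unfold

__all__ = [
    "InteractionResult",
    "ModuleCatalog",
    "ModuleSpace",
    "classify_interaction",
    "enumerate_pathway_modules",
    "maximal_modules",
    "complex_modules",
    "core_filter",
]


@dataclass(frozen=True)
class InteractionResult:
    """Classification of the pair (M_i, M_j); set flags are symmetric,
    subsumption flags describe M_i relative to M_j."""

    flags: frozenset[str]
    synergy_witness: frozenset[SUnit] = frozenset()
    obstruction_witness: frozenset[SUnit] = frozenset()
    temporal_shift: int | None = None
    seed_contradiction: bool = False

    def __contains__(self, flag: str) -> bool:
        return flag in self.flags


class ModuleSpace:
    """Memoized unfolding of all pathway modules of a DCM in one mode."""

    def __init__(self, dcm: DCM, mode: str = "pin", cap: int = 2_000_000):
        self.dcm = dcm
        self.mode = mode
        self.cap = cap
        self._memo: dict[frozenset[SUnit], PathwayModule] = {}
        self._per_s: dict[int, list[PathwayModule]] = {}

    def module(self, seed_units: Iterable[SUnit]) -> PathwayModule:
        key = frozenset(seed_units)
        pm = self._memo.get(key)
        if pm is None:
            pm = unfold(self.dcm, key, mode=self.mode)
            self._memo[key] = pm
        return pm

    def pathway_modules(self, s: int) -> list[PathwayModule]:
        """P_s: one module per consistent seed set of size s
        (2^s * C(n, s) of them)."""
        if s < 1:
            raise ValueError("seed set size must be >= 1")
        if s in self._per_s:
            return self._per_s[s]
        n = self.dcm.n
        count = 2 ** s * _binom(n, s)
        if count > self.cap:
            raise ValueError(
                f"{count} seed sets of size {s} exceed the cap of {self.cap}"
            )
        out = []
        for variables in combinations(self.dcm.variables, s):
            for states in product((0, 1), repeat=s):
                units = frozenset(
                    SUnit(v, st) for v, st in zip(variables, states)
                )
                out.append(self.module(units))
        self._per_s[s] = out
        return out

    def maximal_modules(self, s: int) -> list[PathwayModule]:
        """Lambda_s: modules of P_s whose set is not a proper subset of any
        module set with seed size <= s."""
        pool: list[frozenset[SUnit]] = []
        for x in range(1, s + 1):
            pool.extend(pm.module_set for pm in self.pathway_modules(x))
        distinct = set(pool)
        by_unit: dict[SUnit, set[frozenset[SUnit]]] = {}
        for ms in distinct:
            for u in ms:
                by_unit.setdefault(u, set()).add(ms)
        has_superset: dict[frozenset[SUnit], bool] = {}
        for S in distinct:
            base = min((by_unit[u] for u in S), key=len, default=set())
            has_superset[S] = any(len(c) > len(S) and S < c for c in base)
        return [
            pm for pm in self.pathway_modules(s)
            if not has_superset[pm.module_set]
        ]

    def synergistic(self, a: frozenset[SUnit], b: frozenset[SUnit]) -> bool:
        """Synergy between the modules seeded by two disjoint consistent
        seed sets: the combined unfolding fires extra s-units."""
        combined = self.module(a | b).module_set
        separate = self.module(a).module_set | self.module(b).module_set
        return bool(combined - separate)

    def complex_modules(self, s: int) -> list[PathwayModule]:
        """I_s: maximal modules in which every seed-set bipartition is
        synergistic.  At s=1 every maximal module is complex."""
        out = []
        for pm in self.maximal_modules(s):
            seeds = sorted(pm.seed_units)
            ok = True
            for r in range(1, len(seeds) // 2 + 1):
                for part in combinations(seeds, r):
                    a = frozenset(part)
                    b = frozenset(seeds) - a
                    if 2 * r == len(seeds) and seeds[0] not in a:
                        continue  # count unordered even bipartitions once
                    if not self.synergistic(a, b):
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                out.append(pm)
        return out

    def core_complex_modules(self, s_max: int) -> list[PathwayModule]:
        """Core complex modules over all seed sizes 1..s_max."""
        lam1 = self.maximal_modules(1)
        out = []
        for s in range(1, s_max + 1):
            out.extend(core_filter(self.complex_modules(s), lam1))
        return out


def _binom(n: int, k: int) -> int:
    from math import comb

    return comb(n, k)


@dataclass
class ModuleCatalog:
    """Snapshot of the module hierarchy at one seed set size."""

    s: int
    all: list[PathwayModule]
    maximal: list[PathwayModule]
    complex: list[PathwayModule]
    core: list[PathwayModule]

    @classmethod
    def build(cls, dcm: DCM, s: int, mode: str = "pin",
              space: ModuleSpace | None = None) -> "ModuleCatalog":
        space = space or ModuleSpace(dcm, mode)
        lam1 = space.maximal_modules(1)
        cplx = space.complex_modules(s)
        return cls(
            s=s,
            all=space.pathway_modules(s),
            maximal=space.maximal_modules(s),
            complex=cplx,
            core=core_filter(cplx, lam1),
        )


# ---------------------------------------------------------------------------
# spec-surface operations


def classify_interaction(
    mi: PathwayModule, mj: PathwayModule, dcm: DCM
) -> InteractionResult:
    """Classify the interaction between two pathway modules.

    Both modules must use the same perturbation mode.  If the union of the
    seed sets is itself contradictory the pair is marked as obstruction by
    seed contradiction and the combined unfolding is not attempted.
    """
    mode_i = {s.mode for s in mi.seeds}
    mode_j = {s.mode for s in mj.seeds}
    if mode_i != mode_j or len(mode_i) != 1:
        raise ValueError("modules must be unfolded with one common mode")
    mode = mode_i.pop()

    flags: set[str] = set()
    si, sj = mi.module_set, mj.module_set
    if si <= sj:
        flags.add("subsumed")
    elif si & sj:
        flags.add("partially_subsumed")
    if mi.seed_units < mj.seed_units:
        flags.add("submodule")
    shift = _temporal_shift(mi, mj)
    if shift is not None:
        flags.add("temporally_subsumed")

    seed_union = mi.seed_units | mj.seed_units
    variables = [u.variable for u in seed_union]
    if len(set(variables)) != len(variables):
        flags.add("obstruction")
        return InteractionResult(
            frozenset(flags),
            obstruction_witness=frozenset(
                u for u in seed_union if u.negation in seed_union
            ),
            temporal_shift=shift,
            seed_contradiction=True,
        )

    combined = unfold(dcm, seed_union, mode=mode).module_set
    synergy = combined - (si | sj)
    obstruction = (si | sj) - combined
    if synergy:
        flags.add("synergy")
    if obstruction:
        flags.add("obstruction")
    if not synergy and not obstruction and not si & sj:
        flags.add("decoupled")
    return InteractionResult(
        frozenset(flags),
        synergy_witness=frozenset(synergy),
        obstruction_witness=frozenset(obstruction),
        temporal_shift=shift,
    )


def _slice_at(pm: PathwayModule, t: int):
    """Slice at time t, extending past T by fixpoint or cycle repetition."""
    T = pm.length
    if t <= T:
        return pm.slices[t]
    if pm.termination == "repeat" and pm.period:
        idx = pm.repeat_of + (t - pm.repeat_of) % pm.period
        return pm.slices[idx]
    if pm.termination == "empty":
        return None
    return pm.slices[T]


def _temporal_shift(mi: PathwayModule, mj: PathwayModule) -> int | None:
    """Smallest k >= 0 such that M_i^t is contained in M_j^{t+k} for all t."""
    horizon = mj.length + (mj.period or 0) + 1
    for k in range(horizon):
        ok = True
        for sl in mi.slices:
            other = _slice_at(mj, sl.t + k)
            if other is None or not (
                sl.s_fired <= other.s_fired and sl.t_fired <= other.t_fired
            ):
                ok = False
                break
        if ok:
            return k
    return None


def enumerate_pathway_modules(
    dcm: DCM, s: int, mode: str = "pin", cap: int = 2_000_000
) -> list[PathwayModule]:
    """P_s: all pathway modules from consistent seed sets of size s."""
    return ModuleSpace(dcm, mode, cap=cap).pathway_modules(s)


def maximal_modules(catalog: ModuleCatalog) -> list[PathwayModule]:
    """Lambda_s from a built catalog."""
    return catalog.maximal


def complex_modules(dcm: DCM, s: int, mode: str = "pin") -> list[PathwayModule]:
    """I_s: complex modules of seed set size s."""
    return ModuleSpace(dcm, mode).complex_modules(s)


def core_filter(
    i_s: Sequence[PathwayModule], lambda_1: Sequence[PathwayModule]
) -> list[PathwayModule]:
    """Keep complex modules whose every single seed generates a maximal
    s=1 module (the maximal seed heuristic)."""
    maximal_units = {next(iter(pm.seed_units)) for pm in lambda_1}
    return [pm for pm in i_s if pm.seed_units <= maximal_units]
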