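"""Covers of the DCM and the mean dynamical modularity statistic.

A *cover* is a set of pathway modules whose module sets jointly contain
every s-unit of the DCM.  The *independence* of a module within a cover is
the fraction of its s-units that no other member fires,

    ind(M_i, Sigma) = |S_i - S_Sigma| / |S_i|,

and the mean dynamical modularity of a cover is the arithmetic mean of the
member independences.  The *optimal cover* at maximum seed size s is the
full cover of maximum mean dynamical modularity built from (core) complex
modules with seed sets of size <= s; it is found exactly by depth-first
branch and bound, or estimated from below by greedy selection of the most
independent module.  The *characteristic seed number* s* is the smallest s
at which the optimal-cover modularity stops increasing.

All scores are computed in exact rational arithmetic so that cover
comparisons and printed roundings are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from .dcm import DCM, SUnit
from .module_algebra import ModuleSpace, core_filter
from .unfolding import PathwayModule

__all__ = [
    "Cover",
    "ModularityReport",
    "InfeasibleCoverError",
    "independence",
    "mean_dynamical_modularity",
    "candidate_pool",
    "optimal_cover_exact",
    "minimal_cover",
    "greedy_cover",
    "characteristic_seed_number",
]

PLATEAU_EPSILON = Fraction(1, 10 ** 9)


class InfeasibleCoverError(ValueError):
    """The candidate pool cannot cover all s-units of the DCM."""

    def __init__(self, uncovered: Iterable[SUnit]):
        self.uncovered = frozenset(uncovered)
        labels = ", ".join(u.label for u in sorted(self.uncovered))
        super().__init__(f"pool cannot cover s-units: {labels}")


def independence(mi: PathwayModule, sigma: Sequence[PathwayModule]) -> Fraction:
    """ind(M_i, Sigma): fraction of M_i's s-units outside the union of
    Sigma's module sets."""
    si = mi.module_set
    if not si:
        raise ValueError("independence is undefined for an empty module set")
    union: set[SUnit] = set()
    for mj in sigma:
        union |= mj.module_set
    return Fraction(len(si - union), len(si))


@dataclass(frozen=True)
class Cover:
    """A candidate cover of the DCM's s-units."""

    modules: tuple[PathwayModule, ...]
    universe: frozenset[SUnit]

    @property
    def union_set(self) -> frozenset[SUnit]:
        out: set[SUnit] = set()
        for pm in self.modules:
            out |= pm.module_set
        return frozenset(out)

    @property
    def is_full(self) -> bool:
        return self.union_set >= self.universe

    @property
    def size(self) -> int:
        return len(self.modules)


@dataclass(frozen=True)
class ModularityReport:
    """Per-module independence scores and their mean (exact rationals)."""

    scores: tuple[Fraction, ...]
    solver: str = "direct"
    s: int | None = None
    q: int | None = None

    @property
    def distribution(self) -> tuple[float, ...]:
        return tuple(float(x) for x in self.scores)

    @property
    def mean(self) -> Fraction:
        return sum(self.scores, Fraction(0)) / len(self.scores)

    @property
    def mean_float(self) -> float:
        return float(self.mean)

    def mean_rounded(self, ndigits: int = 2) -> float:
        """Half-up decimal rounding of the exact mean."""
        scale = 10 ** ndigits
        return float((self.mean * scale + Fraction(1, 2)).__floor__()) / scale


def mean_dynamical_modularity(cover: Cover, solver: str = "direct",
                              s: int | None = None, q: int | None = None
                              ) -> ModularityReport:
    """Mean of ind(M_i, Pi - {M_i}) over the members of the cover."""
    modules = cover.modules
    if not modules:
        raise ValueError("modularity of an empty cover is undefined")
    scores = tuple(
        independence(mi, [mj for j, mj in enumerate(modules) if j != i])
        for i, mi in enumerate(modules)
    )
    return ModularityReport(scores, solver=solver, s=s, q=q)


# ---------------------------------------------------------------------------
# candidate pools


def _seed_key(pm: PathwayModule) -> tuple[str, ...]:
    return tuple(sorted(u.label for u in pm.seed_units))


def candidate_pool(dcm: DCM, s: int, mode: str = "pin", core: bool = True,
                   space: ModuleSpace | None = None) -> list[PathwayModule]:
    """Complex modules with seed size <= s (core-filtered by default),
    deduplicated by module set keeping the lexicographically smallest seed
    set."""
    space = space or ModuleSpace(dcm, mode)
    lam1 = space.maximal_modules(1)
    pool: list[PathwayModule] = []
    for x in range(1, s + 1):
        cplx = space.complex_modules(x)
        pool.extend(core_filter(cplx, lam1) if core else cplx)
    best: dict[frozenset[SUnit], PathwayModule] = {}
    for pm in pool:
        cur = best.get(pm.module_set)
        if cur is None or _seed_key(pm) < _seed_key(cur):
            best[pm.module_set] = pm
    return sorted(best.values(), key=_seed_key)


def _check_feasible(pool: Sequence[PathwayModule], universe: frozenset[SUnit]):
    covered: set[SUnit] = set()
    for pm in pool:
        covered |= pm.module_set
    if not covered >= universe:
        raise InfeasibleCoverError(universe - covered)


# ---------------------------------------------------------------------------
# exact optimal cover


def _sum_independence(chosen: Sequence[PathwayModule], counts: dict[SUnit, int]
                      ) -> Fraction:
    total = Fraction(0)
    for pm in chosen:
        unique = sum(1 for u in pm.module_set if counts[u] == 1)
        total += Fraction(unique, len(pm.module_set))
    return total


def optimal_cover_exact(
    pool: Sequence[PathwayModule],
    universe: frozenset[SUnit],
    s: int | None = None,
    q: int | None = None,
) -> tuple[Cover, ModularityReport]:
    """Exhaustive depth-first branch-and-bound search for the full cover of
    maximum mean dynamical modularity, over subsets of the pool of size at
    most ``q``.

    Candidates are explored largest module set first; branches are pruned
    when the remaining candidates cannot complete the coverage and when an
    optimistic bound (every further module assumed fully independent)
    cannot beat the incumbent.  Ties are broken deterministically: higher
    mean, then fewer modules, then lexicographic seed sets.
    """
    _check_feasible(pool, universe)
    cands = sorted(pool, key=lambda pm: (-len(pm.module_set), _seed_key(pm)))
    q_eff = len(cands) if q is None else min(q, len(cands))
    suffix_union: list[frozenset[SUnit]] = [frozenset()] * (len(cands) + 1)
    for i in range(len(cands) - 1, -1, -1):
        suffix_union[i] = suffix_union[i + 1] | cands[i].module_set

    best: dict = {"mean": Fraction(-1), "cover": None}
    chosen: list[PathwayModule] = []
    counts: dict[SUnit, int] = {}

    def evaluate():
        scores = tuple(
            Fraction(sum(1 for u in pm.module_set if counts[u] == 1),
                     len(pm.module_set))
            for pm in chosen
        )
        mean = sum(scores, Fraction(0)) / len(scores)
        key = (mean, -len(chosen), tuple(sorted(_seed_key(pm) for pm in chosen)))
        if best["cover"] is None or key > best["key"]:
            best.update(mean=mean, key=key,
                        cover=tuple(chosen), scores=scores)

    def dfs(i: int, covered: set[SUnit]):
        if chosen and covered >= universe:
            evaluate()
        if i == len(cands) or len(chosen) == q_eff:
            return
        if not covered | suffix_union[i] >= universe:
            return
        if chosen:
            r = q_eff - len(chosen)
            ub = (_sum_independence(chosen, counts) + r) / (len(chosen) + r)
            if ub < best["mean"] or (ub == best["mean"] and r == 0):
                return
        pm = cands[i]
        # include cands[i]
        chosen.append(pm)
        for u in pm.module_set:
            counts[u] = counts.get(u, 0) + 1
        dfs(i + 1, covered | pm.module_set)
        chosen.pop()
        for u in pm.module_set:
            counts[u] -= 1
        # exclude cands[i]
        dfs(i + 1, covered)

    dfs(0, set())
    if best["cover"] is None:
        raise InfeasibleCoverError(universe)  # unreachable after feasibility check
    cover = Cover(best["cover"], universe)
    report = ModularityReport(best["scores"], solver="exact", s=s, q=q)
    return cover, report


def minimal_cover(
    pool: Sequence[PathwayModule],
    universe: frozenset[SUnit],
    s: int | None = None,
) -> tuple[Cover, ModularityReport]:
    """Minimum-cardinality full cover (ties broken by higher mean
    dynamical modularity, then lexicographic seed sets)."""
    _check_feasible(pool, universe)
    cands = sorted(pool, key=lambda pm: (-len(pm.module_set), _seed_key(pm)))
    best: dict = {"size": len(cands) + 1, "cover": None}
    chosen: list[PathwayModule] = []
    suffix_union: list[frozenset[SUnit]] = [frozenset()] * (len(cands) + 1)
    for i in range(len(cands) - 1, -1, -1):
        suffix_union[i] = suffix_union[i + 1] | cands[i].module_set

    def dfs(i: int, covered: set[SUnit]):
        if chosen and covered >= universe:
            cover = Cover(tuple(chosen), universe)
            rep = mean_dynamical_modularity(cover)
            key = (-len(chosen), rep.mean,
                   tuple(sorted(_seed_key(pm) for pm in chosen)))
            if best["cover"] is None or key > best["key"]:
                best.update(size=len(chosen), key=key, cover=cover, report=rep)
            return
        if i == len(cands) or len(chosen) + 1 > best["size"]:
            return
        if not covered | suffix_union[i] >= universe:
            return
        chosen.append(cands[i])
        dfs(i + 1, covered | cands[i].module_set)
        chosen.pop()
        dfs(i + 1, covered)

    dfs(0, set())
    rep = best["report"]
    return best["cover"], ModularityReport(rep.scores, solver="minimal", s=s)


# ---------------------------------------------------------------------------
# greedy estimate


def greedy_cover(
    pool: Sequence[PathwayModule],
    universe: frozenset[SUnit],
    s: int | None = None,
    q: int | None = None,
) -> tuple[Cover, ModularityReport]:
    """Iteratively add the candidate with the highest independence from the
    current selection until the cover is full (a lower bound on the exact
    optimum).  Ties: larger module set, then smaller seed set, then
    lexicographic seed names.  ``q`` optionally stops the selection early.
    """
    _check_feasible(pool, universe)
    remaining = list(pool)
    chosen: list[PathwayModule] = []
    covered: set[SUnit] = set()
    while covered < universe and remaining:
        if q is not None and len(chosen) >= q:
            break

        def key(pm: PathwayModule):
            ind = Fraction(len(pm.module_set - covered), len(pm.module_set))
            return (-ind, -len(pm.module_set), len(pm.seed_units), _seed_key(pm))

        pick = min(remaining, key=key)
        remaining.remove(pick)
        chosen.append(pick)
        covered |= pick.module_set
    cover = Cover(tuple(chosen), universe)
    report = mean_dynamical_modularity(cover, solver="greedy", s=s, q=q)
    return cover, report


# ---------------------------------------------------------------------------
# characteristic seed number


@dataclass
class ModularityCurve:
    """Mean dynamical modularity of the optimal cover as a function of the
    maximum seed set size."""

    s_values: tuple[int, ...]
    means: tuple[Fraction, ...]
    s_star: int
    plateau_found: bool
    covers: tuple[Cover, ...] = ()
    reports: tuple[ModularityReport, ...] = ()


def characteristic_seed_number(
    dcm: DCM,
    s_max: int,
    solver: str = "exact",
    mode: str = "pin",
    q: int | None = None,
    core: bool = True,
    epsilon: Fraction = PLATEAU_EPSILON,
) -> ModularityCurve:
    """Smallest s at which the optimal-cover modularity stops increasing.

    Computes the optimal (or greedy) cover for s = 1..s_max and returns the
    whole curve; if no plateau is reached by s_max, s* is reported as s_max
    with ``plateau_found=False``.
    """
    space = ModuleSpace(dcm, mode)
    universe = frozenset(dcm.s_units)
    means: list[Fraction] = []
    covers: list[Cover] = []
    reports: list[ModularityReport] = []
    s_star = None
    for s in range(1, s_max + 1):
        pool = candidate_pool(dcm, s, mode=mode, core=core, space=space)
        if solver == "exact":
            cover, report = optimal_cover_exact(pool, universe, s=s, q=q)
        elif solver == "greedy":
            cover, report = greedy_cover(pool, universe, s=s, q=q)
        else:
            raise ValueError(f"unknown solver {solver!r}")
        means.append(report.mean)
        covers.append(cover)
        reports.append(report)
        if s_star is None and s >= 2 and means[-1] - means[-2] <= epsilon:
            s_star = s - 1
    return ModularityCurve(
        s_values=tuple(range(1, s_max + 1)),
        means=tuple(means),
        s_star=s_star if s_star is not None else s_max,
        plateau_found=s_star is not None,
        covers=tuple(covers),
        reports=tuple(reports),
    )
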