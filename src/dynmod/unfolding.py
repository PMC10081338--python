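"""Dynamical unfolding of pathway modules on the DCM.

A *seed set* is a consistent set of s-units perturbed at t=0.  Each seed
is either **pinned** (fires at every step: the perturbation is sustained)
or **pulsed** (fires only at t=0 unless the canalized dynamics re-derives
it).  At every step the firing s-units form a partial configuration; a
t-unit fires when that partial configuration guarantees its schema (dt=0),
and its target s-unit fires at the next step (dt=1).  The time-ordered
sequence of firing slices is the *pathway module*; the union of all firing
s-units is its module set — node states guaranteed to occur, barring
outside interference.

Pinning dynamics is a monotone closure: a pinned seed blocks its opposite
s-unit forever and, among derived s-units, the first-fired state of a
variable wins.  Under pulse or mixed perturbation different states of a
variable may fire at different steps (never within one step), so limit
cycles can appear as repeating slice sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

from .dcm import DCM, SUnit, TUnit
from .network import BooleanNetwork, synchronous_step

__all__ = [
    "Seed",
    "ModuleSlice",
    "PathwayModule",
    "UnfoldingError",
    "unfold",
    "is_attractor_resolving",
    "module_size",
    "module_length",
    "timeline_tsv",
]


class UnfoldingError(RuntimeError):
    """Inconsistent seed set or a violated consistency invariant."""


@dataclass(frozen=True, order=True)
class Seed:
    """One perturbed s-unit with its perturbation mode."""

    unit: SUnit
    mode: str = "pin"

    def __post_init__(self) -> None:
        if self.mode not in ("pin", "pulse"):
            raise ValueError(f"seed mode must be 'pin' or 'pulse', got {self.mode!r}")


class ModuleSlice(NamedTuple):
    """The s-units and t-units firing at one time step."""

    t: int
    s_fired: frozenset[SUnit]
    t_fired: frozenset[TUnit]


@dataclass
class PathwayModule:
    """The unfolding M(S0): slices M^0..M^T plus the module set."""

    seeds: tuple[Seed, ...]
    slices: list[ModuleSlice]
    first_fire: dict[SUnit, int]
    termination: str  # 'fixpoint' | 'repeat' | 'empty'
    repeat_of: int | None = None

    @property
    def seed_units(self) -> frozenset[SUnit]:
        return frozenset(s.unit for s in self.seeds)

    @property
    def module_set(self) -> frozenset[SUnit]:
        """All s-units that fire in at least one slice."""
        return frozenset(self.first_fire)

    @property
    def length(self) -> int:
        """T: the index of the last novel slice."""
        return len(self.slices) - 1

    @property
    def size(self) -> int:
        return len(self.module_set)

    @property
    def period(self) -> int | None:
        """Cycle length of a repeating slice sequence (None otherwise)."""
        if self.repeat_of is None:
            return None
        return len(self.slices) - self.repeat_of

    @property
    def is_pinning(self) -> bool:
        return all(s.mode == "pin" for s in self.seeds)

    def __repr__(self) -> str:
        seeds = ",".join(
            s.unit.label + ("" if s.mode == "pin" else "~") for s in self.seeds
        )
        return (
            f"PathwayModule(M({seeds}), size={self.size}, length={self.length}, "
            f"{self.termination})"
        )


def _normalize_seeds(seeds, mode: str) -> tuple[Seed, ...]:
    out: list[Seed] = []
    if isinstance(seeds, Mapping):
        items = [(k, v) for k, v in seeds.items()]
    else:
        items = [(s, None) for s in seeds]
    for item, m in items:
        if isinstance(item, Seed):
            out.append(item)
            continue
        unit = SUnit.parse(item) if isinstance(item, str) else SUnit(*item)
        out.append(Seed(unit, m or mode))
    variables = [s.unit.variable for s in out]
    if len(set(variables)) != len(variables):
        raise UnfoldingError(f"contradictory or duplicate seed set: {sorted(out)}")
    return tuple(sorted(out))


def _partial_configuration(fired: Iterable[SUnit]) -> dict[str, int]:
    pc: dict[str, int] = {}
    for s in fired:
        if pc.get(s.variable, s.state) != s.state:
            raise UnfoldingError(
                f"both states of {s.variable!r} firing in one slice"
            )
        pc[s.variable] = s.state
    return pc


def unfold(dcm: DCM, seeds, mode: str = "pin", step_cap: int | None = None) -> PathwayModule:
    """Unfold the pathway module of a seed set on the DCM.

    ``seeds`` may be s-unit labels ("P2-1"), ``SUnit``/(name, state) pairs,
    ``Seed`` objects, or a mapping from any of those to a per-seed mode;
    ``mode`` is the default perturbation mode.  Unfolding stops at a
    fixpoint (pinning), at the repetition of an earlier slice (pulse or
    mixed) or at an empty slice.
    """
    seed_tuple = _normalize_seeds(seeds, mode)
    known = set(dcm.variables)
    for s in seed_tuple:
        if s.unit.variable not in known:
            raise UnfoldingError(f"seed variable {s.unit.variable!r} not in the DCM")
    if step_cap is None:
        step_cap = 10 * 2 * dcm.n

    pinned = frozenset(s.unit for s in seed_tuple if s.mode == "pin")
    blocked = {u.negation for u in pinned}
    pure_pinning = len(pinned) == len(seed_tuple)

    if pure_pinning:
        return _unfold_pinning(dcm, seed_tuple, pinned, blocked, step_cap)
    return _unfold_general(dcm, seed_tuple, pinned, blocked, step_cap)


def _matched_t_units(dcm: DCM, pc: Mapping[str, int]) -> list[TUnit]:
    return [t for t in dcm.t_units if t.fires(pc)]


def _check_derivation_consistency(targets: Iterable[SUnit]) -> None:
    seen: dict[str, int] = {}
    for u in targets:
        if seen.get(u.variable, u.state) != u.state:
            raise UnfoldingError(
                f"contradictory derivations for {u.variable!r} in one step"
            )
        seen[u.variable] = u.state


def _unfold_pinning(dcm, seed_tuple, pinned, blocked, step_cap) -> PathwayModule:
    fired: set[SUnit] = set(pinned)
    pc = _partial_configuration(fired)
    first_fire = {u: 0 for u in pinned}
    slices: list[ModuleSlice] = []
    unmatched = list(dcm.t_units)
    theta: set[TUnit] = set()
    t = 0
    while True:
        newly = [tu for tu in unmatched if tu.fires(pc)]
        theta |= set(newly)
        unmatched = [tu for tu in unmatched if tu not in theta]
        slices.append(ModuleSlice(t, frozenset(fired), frozenset(theta)))
        targets = {tu.target for tu in theta}
        new_units = {
            u for u in targets
            if u not in fired and u not in blocked and u.negation not in fired
        }
        _check_derivation_consistency(new_units | fired)
        if not new_units:
            return PathwayModule(
                seed_tuple, slices, first_fire, termination="fixpoint"
            )
        t += 1
        if t > step_cap:
            raise UnfoldingError("step cap exceeded: unfolding bookkeeping bug")
        for u in new_units:
            fired.add(u)
            pc[u.variable] = u.state
            first_fire[u] = t


def _unfold_general(dcm, seed_tuple, pinned, blocked, step_cap) -> PathwayModule:
    current: frozenset[SUnit] = frozenset(s.unit for s in seed_tuple)
    first_fire: dict[SUnit, int] = {}
    slices: list[ModuleSlice] = []
    seen: dict[frozenset[SUnit], int] = {}
    t = 0
    while True:
        if not current:
            return PathwayModule(seed_tuple, slices, first_fire, termination="empty")
        if current in seen:
            idx = seen[current]
            termination = "fixpoint" if idx == len(slices) - 1 else "repeat"
            return PathwayModule(
                seed_tuple, slices, first_fire, termination, repeat_of=idx
            )
        pc = _partial_configuration(current)
        theta = frozenset(_matched_t_units(dcm, pc))
        seen[current] = t
        slices.append(ModuleSlice(t, current, theta))
        for u in current:
            first_fire.setdefault(u, t)
        targets = {tu.target for tu in theta if tu.target not in blocked}
        _check_derivation_consistency(targets)
        current = frozenset(targets | pinned)
        t += 1
        if t > step_cap:
            raise UnfoldingError("step cap exceeded: unfolding bookkeeping bug")


def module_size(pm: PathwayModule) -> int:
    """|S|: the number of distinct s-units that ever fire (seeds included)."""
    return pm.size


def module_length(pm: PathwayModule) -> int:
    """T: the number of time steps the module takes to unfold."""
    return pm.length


def is_attractor_resolving(pm: PathwayModule, net: BooleanNetwork) -> bool:
    """Does a pinning module resolve the state of every variable?

    When it does, the implied full configuration is verified to be a fixed
    point of the synchronous dynamics (a violation would indicate an
    unfolding bug and raises).
    """
    if not pm.is_pinning:
        raise ValueError("attractor resolution is defined for pinning modules")
    if len(pm.module_set) < len(net):
        return False
    config = {u.variable: u.state for u in pm.module_set}
    nxt = synchronous_step(net, config)
    if nxt != config:
        raise UnfoldingError(
            "module resolves all variables but the implied configuration "
            "is not a fixed point"
        )
    return True


def timeline_tsv(pm: PathwayModule, variables: Iterable[str] | None = None) -> str:
    """Timeline table: rows are variables, columns time steps, cells 0/1/#."""
    if variables is None:
        variables = sorted({u.variable for u in pm.module_set})
    header = "variable\t" + "\t".join(str(s.t) for s in pm.slices)
    rows = [header]
    for v in variables:
        cells = []
        for s in pm.slices:
            states = {u.state for u in s.s_fired if u.variable == v}
            cells.append(str(states.pop()) if len(states) == 1 else "#")
        rows.append(v + "\t" + "\t".join(cells))
    return "\n".join(rows) + "\n"
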