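"""Module interactions, maximality, complex and core modules."""

import pytest

from dynmod import (
    ModuleCatalog,
    ModuleSpace,
    SUnit,
    build_dcm,
    classify_interaction,
    core_filter,
    enumerate_pathway_modules,
    load_fixture,
    unfold,
)

from conftest import random_networks


def seeds_of(pm):
    return tuple(sorted(u.label for u in pm.seed_units))


class TestClassifyInteraction:
    def test_subsumption(self, grn_dcm, grn_space):
        res = classify_interaction(
            grn_space.module({SUnit("P1", 0)}),
            grn_space.module({SUnit("i1", 0)}),
            grn_dcm,
        )
        assert "subsumed" in res and "synergy" not in res

    def test_decoupled(self, grn_dcm, grn_space):
        res = classify_interaction(
            grn_space.module({SUnit("P1", 1)}),
            grn_space.module({SUnit("i1", 1)}),
            grn_dcm,
        )
        assert "decoupled" in res
        assert "synergy" not in res and "obstruction" not in res

    def test_obstruction(self, grn_dcm, grn_space):
        res = classify_interaction(
            grn_space.module({SUnit("P1", 1)}),
            grn_space.module({SUnit("P2", 1)}),
            grn_dcm,
        )
        assert "obstruction" in res
        assert res.obstruction_witness  # the suppressed s-units are reported

    def test_synergy_witness(self, grn_dcm, grn_space):
        res = classify_interaction(
            grn_space.module({SUnit("P1", 1)}),
            grn_space.module({SUnit("i2", 1)}),
            grn_dcm,
        )
        assert "synergy" in res
        assert SUnit("P2", 1) in res.synergy_witness

    def test_seed_contradiction(self, grn_dcm, grn_space):
        res = classify_interaction(
            grn_space.module({SUnit("i1", 1)}),
            grn_space.module({SUnit("i1", 0)}),
            grn_dcm,
        )
        assert res.seed_contradiction and "obstruction" in res

    def test_symmetry_of_set_flags(self, grn_dcm, grn_space):
        symmetric = {"synergy", "obstruction", "decoupled"}
        mods = grn_space.pathway_modules(1)
        for i, mi in enumerate(mods):
            for mj in mods[i + 1:]:
                a = classify_interaction(mi, mj, grn_dcm)
                b = classify_interaction(mj, mi, grn_dcm)
                assert a.flags & symmetric == b.flags & symmetric

    def test_temporal_subsumption_shift(self, grn_dcm, grn_space):
        # M_{g1-0} unfolds inside M_{i1-0} one step later
        res = classify_interaction(
            grn_space.module({SUnit("g1", 0)}),
            grn_space.module({SUnit("i1", 0)}),
            grn_dcm,
        )
        assert "temporally_subsumed" in res and res.temporal_shift == 1

    def test_mode_mismatch(self, grn_dcm):
        pin = unfold(grn_dcm, ["P1-1"], mode="pin")
        pulse = unfold(grn_dcm, ["i1-1"], mode="pulse")
        with pytest.raises(ValueError):
            classify_interaction(pin, pulse, grn_dcm)


class TestCatalog:
    def test_pathway_module_count(self, grn_dcm):
        assert len(enumerate_pathway_modules(grn_dcm, 1)) == 12
        assert len(enumerate_pathway_modules(grn_dcm, 2)) == 60  # 4 * C(6,2)

    def test_lambda1(self, grn_space):
        lam1 = {seeds_of(pm) for pm in grn_space.maximal_modules(1)}
        assert lam1 == {
            ("i1-1",), ("i1-0",), ("i2-1",), ("i2-0",), ("P1-1",), ("P2-1",),
        }

    def test_non_maximal_is_proper_subset(self, grn_space):
        g1 = grn_space.module({SUnit("g1", 1)})
        i1 = grn_space.module({SUnit("i1", 1)})
        assert g1.module_set < i1.module_set
        assert g1 not in grn_space.maximal_modules(1)

    def test_complex_s1_equals_lambda1(self, grn_space):
        assert grn_space.complex_modules(1) == grn_space.maximal_modules(1)

    def test_core_complex_s2(self, grn_space):
        core = core_filter(
            grn_space.complex_modules(2), grn_space.maximal_modules(1)
        )
        assert {seeds_of(pm) for pm in core} == {
            ("P1-1", "i2-1"), ("i1-1", "i2-0"),
        }

    def test_catalog_hierarchy(self, grn_dcm):
        cat = ModuleCatalog.build(grn_dcm, 2)
        ids = lambda pms: {seeds_of(pm) for pm in pms}
        assert ids(cat.core) <= ids(cat.complex) <= ids(cat.maximal) <= ids(cat.all)


class TestSetAlgebraIdentities:
    def _check_pairs(self, dcm, space):
        mods = space.pathway_modules(1)
        for i, mi in enumerate(mods):
            for mj in mods[i + 1:]:
                if mi.seed_units == {u.negation for u in mj.seed_units}:
                    continue
                res = classify_interaction(mi, mj, dcm)
                combined = space.module(mi.seed_units | mj.seed_units).module_set
                union = mi.module_set | mj.module_set
                if "obstruction" not in res and "synergy" not in res:
                    assert combined <= union
                if "synergy" in res and "obstruction" not in res:
                    assert combined > union
                if "decoupled" in res:
                    assert len(combined) == len(mi.module_set) + len(mj.module_set)

    def test_example_grn_pairs(self, grn_dcm, grn_space):
        self._check_pairs(grn_dcm, grn_space)

    def test_random_network_pairs(self):
        for net in random_networks(6, n_range=(4, 8), seed0=100):
            dcm = build_dcm(net)
            self._check_pairs(dcm, ModuleSpace(dcm))


class TestLatticeSymmetry:
    def test_per_cell_complex_modules_are_translations(self):
        net = load_fixture("example_grn_lattice4")
        space = ModuleSpace(build_dcm(net))
        by_cell = {}
        for pm in space.complex_modules(1):
            (unit,) = pm.seed_units
            base, cell = unit.variable.rsplit("_", 1)
            key = (base, unit.state,
                   frozenset(
                       (u.variable.rsplit("_", 1)[0], u.state,
                        (int(u.variable.rsplit("_", 1)[1]) - int(cell)) % 4)
                       for u in pm.module_set
                   ))
            by_cell.setdefault(key, set()).add(cell)
        # every complex module recurs in all four cells with shifted indices
        assert all(cells == {"1", "2", "3", "4"} for cells in by_cell.values())
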