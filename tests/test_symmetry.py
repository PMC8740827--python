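import numpy as np
import pandas as pd
import pytest

from minidials.reflections import ReflectionTable
from minidials.simulate import (
    SimConfig,
    simulate_intensity_tables,
    _DEFAULT_CELLS,
)
from minidials.symmetry import (
    SymmetryElement,
    SymmetryElementScore,
    choose_subgroup,
    cosym_align,
    enumerate_subgroups,
    lattice_group_elements,
    point_group_symbol,
    score_all_elements,
    score_element,
    apply_symmetry,
)


def table_from_intensities(hkl, I):
    df = pd.DataFrame({
        "h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2],
        "intensity_sum_value": I,
        "intensity_sum_variance": np.maximum(I, 1.0),
        "d": np.full(len(I), 3.0),
    })
    return ReflectionTable(df)


class TestLatticeGroupElements:
    def test_cubic_element_census(self):
        els = lattice_group_elements((48, 48, 48, 90, 90, 90))
        orders = sorted(e.order for e in els)
        # identity + 9 twofolds + 8 threefold rotations + 6 fourfold
        assert len(els) == 24
        assert orders.count(2) == 9
        assert orders.count(3) == 8
        assert orders.count(4) == 6
        # distinct axes: 3 fourfold, 4 threefold, 9 twofold
        assert len({e.axis for e in els if e.order == 4}) == 3
        assert len({e.axis for e in els if e.order == 3}) == 4
        assert len({e.axis for e in els if e.order == 2}) == 9

    def test_triclinic_identity_only(self):
        els = lattice_group_elements((38, 44, 52, 83, 97, 105))
        assert len(els) == 1 and els[0].order == 1

    def test_tetragonal_census(self):
        els = lattice_group_elements((45, 45, 55, 90, 90, 90))
        orders = sorted(e.order for e in els)
        assert orders == [1, 2, 2, 2, 2, 2, 4, 4]


class TestScoreElement:
    def test_z_cc_is_cc_over_sigma(self):
        # Z_CC = CC / 0.1 exactly for the default sigma_cc
        rng = np.random.default_rng(0)
        hkl = np.column_stack([np.arange(1, 101), np.arange(2, 102),
                               np.arange(3, 103)])
        hkl = np.vstack([hkl, hkl @ np.diag([-1, -1, 1])])
        I = np.concatenate([rng.exponential(100, 100)] * 2)
        I = I + rng.normal(0, 5, len(I))
        t = table_from_intensities(hkl, I)
        el = SymmetryElement(matrix=np.diag([-1, -1, 1]).astype(np.int64),
                             order=2, axis=(0, 0, 1))
        s = score_element(t, el, sigma_cc=0.1, cc_true=0.95)
        assert s.z_cc == pytest.approx(s.cc / 0.1)

    def test_random_intensities_score_zero(self):
        rng = np.random.default_rng(1)
        hkl = rng.integers(-8, 9, size=(4000, 3))
        hkl = hkl[np.any(hkl != 0, axis=1)]
        I = rng.exponential(100, len(hkl))
        t = table_from_intensities(hkl, I)
        el = SymmetryElement(matrix=np.diag([-1, -1, 1]).astype(np.int64),
                             order=2, axis=(0, 0, 1))
        s = score_element(t, el, sigma_cc=0.1, cc_true=0.95)
        assert abs(s.cc) < 0.15
        assert s.stars == 0

    def test_inverse_element_same_score(self):
        cfg = SimConfig(space_group="P4", n_images=60)
        tables, truth = simulate_intensity_tables(cfg, seed=3)
        els = lattice_group_elements(truth.cell)
        four = [e for e in els if e.order == 4]
        # the two order-4 rotations about c are mutual inverses
        m1, m2 = four[0].matrix, four[1].matrix
        assert np.array_equal(m1 @ m2, np.eye(3, dtype=np.int64))
        s1 = score_element(tables[0], four[0], cc_true=0.95, seed=5)
        s2 = score_element(tables[0], four[1], cc_true=0.95, seed=5)
        assert s1.n == s2.n
        assert s1.cc == pytest.approx(s2.cc, abs=1e-12)


class TestSubgroups:
    def test_cubic_subgroup_count_includes_identity_and_full(self):
        els = lattice_group_elements((48, 48, 48, 90, 90, 90))
        subs = enumerate_subgroups(els)
        sizes = sorted(len(s) for s in subs)
        assert sizes[0] == 1 and sizes[-1] == 24

    def test_table1_pattern_selects_tetrahedral_group(self):
        # threefolds and one twofold class present, fourfolds absent:
        # the winner is 23, not 432
        els = lattice_group_elements((48, 48, 48, 90, 90, 90))
        present_two = {(1, 1, 0), (1, 0, 1), (0, 1, 1)}  # face diagonals? no:
        # in the tetrahedral subgroup of the cubic lattice group the
        # twofolds are the coordinate axes
        present_two = {(1, 0, 0), (0, 1, 0), (0, 0, 1)}
        scores = []
        for e in els:
            if e.order == 1:
                like, cc = 0.95, 0.98
            elif e.order == 3:
                like, cc = 0.95, 0.97
            elif e.order == 2 and e.axis in present_two:
                like, cc = 0.95, 0.97
            else:
                like, cc = 0.1, 0.44
            scores.append(SymmetryElementScore(
                element=e, cc=cc, n=1000, z_cc=cc / 0.1, likelihood=like,
                stars=3 if like > 0.9 else 0))
        sub = choose_subgroup(scores)
        assert sub.symbol == "23"

    def test_all_high_takes_highest_order(self):
        els = lattice_group_elements((48, 48, 48, 90, 90, 90))
        scores = [SymmetryElementScore(element=e, cc=0.98, n=1000, z_cc=9.8,
                                       likelihood=0.95, stars=3) for e in els]
        assert choose_subgroup(scores).symbol == "432"

    def test_all_low_takes_identity(self):
        els = lattice_group_elements((48, 48, 48, 90, 90, 90))
        scores = [SymmetryElementScore(
            element=e, cc=(0.98 if e.order == 1 else 0.05), n=1000,
            z_cc=0.5, likelihood=(0.95 if e.order == 1 else 0.05), stars=0)
            for e in els]
        assert choose_subgroup(scores).symbol == "1"

    @pytest.mark.parametrize("sg,expect", [
        ("P222", "222"), ("P4", "4"), ("P23", "23"), ("P3", "3"),
    ])
    def test_recovery_on_simulation(self, sg, expect):
        cfg = SimConfig(space_group=sg, n_images=90)
        tables, truth = simulate_intensity_tables(cfg, seed=17)
        scores = score_all_elements(tables[0], cell=truth.cell, seed=17)
        assert choose_subgroup(scores).symbol == expect


class TestApplySymmetry:
    def test_p1_unchanged(self):
        cfg = SimConfig(space_group="P1", n_images=60)
        tables, truth = simulate_intensity_tables(cfg, seed=2)
        scores = score_all_elements(tables[0], cell=truth.cell, seed=2)
        sub = choose_subgroup(scores)
        from minidials.model import A_from_cell_orientation, Crystal

        cr = Crystal(A=A_from_cell_orientation(truth.cell, truth.U_list[0]))
        t2, c2, laue, acentric = apply_symmetry(tables[0], cr, sub)
        assert (laue, acentric) == ("-1", "1")
        assert np.array_equal(t2.hkl, tables[0].hkl)

    def test_p222_symbols_and_merge_quality(self):
        from minidials.model import A_from_cell_orientation, Crystal
        from minidials.simulate import canonical_hkl, laue_ops

        cfg = SimConfig(space_group="P222", n_images=90)
        tables, truth = simulate_intensity_tables(cfg, seed=4)
        scores = score_all_elements(tables[0], cell=truth.cell, seed=4)
        sub = choose_subgroup(scores)
        cr = Crystal(A=A_from_cell_orientation(truth.cell, truth.U_list[0]))
        t2, c2, laue, acentric = apply_symmetry(tables[0], cr, sub)
        assert laue == "mmm" and acentric == "222"
        # equivalents merge consistently under the chosen group
        canon = canonical_hkl(t2.hkl, laue_ops("P222"))
        df = pd.DataFrame({"key": list(map(tuple, canon)),
                           "I": t2["intensity_sum_value"]})
        grp = df.groupby("key")["I"]
        big = grp.mean()[grp.size() >= 2]
        rng = np.random.default_rng(0)
        # split each group's observations: correlation of group means with
        # individual observations is near one on clean data
        resid = df.join(grp.mean().rename("m"), on="key")
        cc = np.corrcoef(resid["I"], resid["m"])[0, 1]
        assert cc > 0.95


class TestCosym:
    def test_consistent_datasets_identity(self):
        cfg = SimConfig(space_group="P4", n_images=60)
        tables, truth = simulate_intensity_tables(cfg, n_datasets=3, seed=6,
                                                  ambiguity=False)
        ops, obj = cosym_align(tables, cell=truth.cell, seed=6)
        for op in ops:
            assert np.array_equal(op, np.eye(3, dtype=np.int64))

    def test_gauge_invariance(self):
        cfg = SimConfig(space_group="P4", n_images=60)
        tables, truth = simulate_intensity_tables(cfg, n_datasets=3, seed=8,
                                                  ambiguity=True)
        els = lattice_group_elements(truth.cell)
        ops, obj = cosym_align(tables, elements=els, seed=8)
        # applying one global operator to every dataset leaves the
        # objective unchanged
        from minidials.index import reindex
        from minidials.model import A_from_cell_orientation, Crystal

        g = [e for e in els if e.order == 2][0].matrix
        cr = Crystal(A=A_from_cell_orientation(truth.cell, np.eye(3)))
        tables2 = [reindex(t, cr, g)[0] for t in tables]
        ops2, obj2 = cosym_align(tables2, elements=els, seed=8)
        assert obj2 == pytest.approx(obj, abs=1e-6)

    def test_too_few_datasets(self):
        cfg = SimConfig(space_group="P4", n_images=30)
        tables, truth = simulate_intensity_tables(cfg, n_datasets=1, seed=0)
        with pytest.raises(ValueError):
            cosym_align(tables, cell=truth.cell)


class TestPointGroupSymbols:
    def test_known_groups(self):
        from minidials.simulate import point_group_ops

        for sg, symbol in (("P1", "1"), ("P2", "2"), ("P222", "222"),
                           ("P4", "4"), ("P422", "422"), ("P3", "3"),
                           ("P23", "23"), ("P432", "432")):
            assert point_group_symbol(point_group_ops(sg)) == symbol
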