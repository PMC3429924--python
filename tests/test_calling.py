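"""Scoring rules: mwh cell identification, clone merging, hinge masking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wingmosaic import (
    SimulationConfig,
    apply_hinge_mask,
    call_mwh_cells,
    call_wing,
    merge_clones,
    simulate_cohort,
)
from wingmosaic.calling import EmptyScreenError, MalformedCellError
from wingmosaic.records import WingRecord


def make_wing(cells, wing_id="w0", group="g"):
    """Build a wing from (surface, x, y, orientations) tuples."""
    rows = [
        {
            "surface": s,
            "x": x,
            "y": y,
            "n_trichomes": len(o),
            "orientations": tuple(o),
            "true_label": -1,
            "true_clone_id": -1,
        }
        for s, x, y, o in cells
    ]
    return WingRecord(wing_id=wing_id, group=group, cells=pd.DataFrame(rows))


def brute_force_partition(coords, max_gap):
    """Oracle: all-pairs link relation closed transitively by iteration."""
    n = len(coords)
    labels = list(range(n))
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(i + 1, n):
                dx = abs(coords[i][0] - coords[j][0])
                dy = abs(coords[i][1] - coords[j][1])
                if max(dx, dy) - 1 <= max_gap and labels[i] != labels[j]:
                    new = min(labels[i], labels[j])
                    old = max(labels[i], labels[j])
                    labels = [new if l == old else l for l in labels]
                    changed = True
    groups = {}
    for i, l in enumerate(labels):
        groups.setdefault(l, set()).add(tuple(coords[i]))
    return {frozenset(g) for g in groups.values()}


class TestCellCalling:
    def test_two_trichomes_divergent_sectors_is_mwh(self):
        wing = make_wing([("D", 0, 0, (0, 4))])
        assert len(call_mwh_cells(wing)["D"]) == 1

    def test_two_trichomes_same_sector_is_wild_type(self):
        wing = make_wing([("D", 0, 0, (3, 3))])
        assert len(call_mwh_cells(wing)["D"]) == 0

    def test_single_trichome_is_wild_type(self):
        wing = make_wing([("D", 0, 0, (2,))])
        assert len(call_mwh_cells(wing)["D"]) == 0

    def test_three_trichomes_called_regardless_of_orientation(self):
        wing = make_wing([("D", 0, 0, (5, 5, 5))])
        assert len(call_mwh_cells(wing)["D"]) == 1

    def test_zero_trichomes_rejected(self):
        wing = make_wing([("D", 0, 0, ())])
        with pytest.raises(MalformedCellError):
            call_mwh_cells(wing)


class TestMerging:
    def test_three_intervening_cells_merge(self):
        cells = {"D": np.array([[0, 0], [4, 0]])}
        clones = merge_clones(cells, max_gap=3)
        assert [c.size for c in clones] == [2]

    def test_four_intervening_cells_split(self):
        cells = {"D": np.array([[0, 0], [5, 0]])}
        clones = merge_clones(cells, max_gap=3)
        assert sorted(c.size for c in clones) == [1, 1]

    def test_surfaces_never_merge(self):
        cells = {"D": np.array([[0, 0]]), "V": np.array([[0, 0]])}
        clones = merge_clones(cells, max_gap=3)
        assert len(clones) == 2
        assert {c.surface for c in clones} == {"D", "V"}

    @given(
        st.lists(
            st.tuples(st.integers(0, 14), st.integers(0, 14)),
            min_size=0,
            max_size=25,
            unique=True,
        ),
        st.integers(0, 4),
        st.randoms(use_true_random=False),
    )
    def test_partition_matches_bruteforce_and_is_order_invariant(
        self, coords, max_gap, rand
    ):
        expected = brute_force_partition(coords, max_gap)
        shuffled = list(coords)
        rand.shuffle(shuffled)
        for arrangement in (coords, shuffled):
            arr = np.array(arrangement, dtype=np.int64).reshape(-1, 2)
            clones = merge_clones({"D": arr}, max_gap=max_gap)
            got = {frozenset(c.cells) for c in clones}
            assert got == expected

    @given(
        st.lists(
            st.tuples(st.integers(0, 20), st.integers(0, 20)),
            min_size=1,
            max_size=20,
            unique=True,
        ),
        st.integers(0, 4),
    )
    def test_merging_monotone_in_gap(self, coords, gap):
        """The partition at gap g refines the partition at gap g+1."""
        arr = np.array(coords, dtype=np.int64)
        fine = merge_clones({"D": arr}, max_gap=gap)
        coarse = merge_clones({"D": arr}, max_gap=gap + 1)
        coarse_sets = [set(c.cells) for c in coarse]
        for clone in fine:
            containing = [s for s in coarse_sets if set(clone.cells) <= s]
            assert len(containing) == 1


class TestGroundTruthRecovery:
    def test_noise_free_calls_equal_truth(self, small_cohort):
        """Patch gaps exceed the merge rule, so calls match truth exactly."""
        for wing in small_cohort:
            truth = sorted(wing.true_clone_sizes().values())
            called = sorted(c.size for c in call_wing(wing))
            assert called == truth

    def test_noisy_doublets_never_called(self):
        config = SimulationConfig(
            n0=150, rounds=3, p_loss=0.01, blade_fraction=1.0,
            screened_cells=2400, noise_rate=0.3, seed=21,
        )
        wings = simulate_cohort(config, 4, seed=22)
        for wing in wings:
            truth = sorted(wing.true_clone_sizes().values())
            called = sorted(c.size for c in call_wing(wing))
            assert called == truth


class TestHingeMask:
    def test_empty_mask_is_identity(self, small_cohort):
        wing = small_cohort[0]
        assert [c.cells for c in call_wing(wing, hinge_mask=None)] == [
            c.cells for c in call_wing(wing)
        ]

    def test_mask_removes_whole_clone(self):
        # two size-2 clones far apart on one surface, wild-type elsewhere
        wing = make_wing(
            [("D", 0, 0, (0, 4)), ("D", 1, 0, (1, 5))]
            + [("D", 20, 0, (2, 6)), ("D", 21, 0, (3, 7))]
            + [("D", x, 5, (0,)) for x in range(25)]
        )
        masked = apply_hinge_mask(wing, 10)  # x < 10 excluded
        assert sorted(c.size for c in call_wing(wing)) == [2, 2]
        assert [c.size for c in call_wing(masked)] == [2]
        assert masked.screened_cells == wing.n_cells - 2 - 10

    def test_partial_mask_truncates_clone(self):
        wing = make_wing(
            [("D", x, 0, (0, 4)) for x in range(4)]  # one size-4 clone
        )
        masked = apply_hinge_mask(wing, 2)  # x < 2 excluded
        clones = call_wing(masked)
        assert [c.size for c in clones] == [2]

    def test_mask_everything_signals_empty_screen(self):
        wing = make_wing([("D", 0, 0, (0,)), ("D", 1, 0, (1,))])
        with pytest.raises(EmptyScreenError):
            apply_hinge_mask(wing, 10)
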