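"""Hotspot criteria, TMC score, and the diagonal coldfield search."""

import statistics

import numpy as np
import pytest

from conftest import sparse_map
from tepair.contacts import BinnedContactMap
from tepair.spotcaller import (
    Grid,
    HotspotCall,
    call_all,
    extract_grid,
    find_coldfield,
    is_hotspot,
    retained_cell_count,
    search_span_bp,
    tmc,
)

CORNERS = {(0, 0), (0, 4), (4, 0), (4, 4)}


def grid_from(values) -> Grid:
    return Grid(np.asarray(values, dtype=int).reshape(5, 5))


def grid_with(center=0, others=0, corner=None) -> Grid:
    v = np.full((5, 5), others, dtype=int)
    v[2, 2] = center
    if corner is not None:
        v[0, 0] = corner
    return Grid(v)


# independent brute-force re-statements of the published criteria

def oracle_is_hotspot(cells_5x5, min_center=5, excess=1.2, median_frac=0.4):
    center = cells_5x5[2][2]
    others = [
        cells_5x5[r][c]
        for r in range(5)
        for c in range(5)
        if (r, c) not in CORNERS and (r, c) != (2, 2)
    ]
    return (
        center >= min_center
        and center >= excess * max(others)
        and statistics.median(others) < median_frac * center
    )


def oracle_tmc(cells_5x5, exponent=1.3):
    flat = [x for row in cells_5x5 for x in row]
    if max(flat) == 0:
        return 0.0
    return max(flat) ** exponent * statistics.median(flat)


class TestGridGeometry:
    def test_hotspot_evaluation_uses_21_cells(self):
        assert retained_cell_count() == 21
        assert grid_with(center=1).noncenter_retained().size == 20

    def test_corner_value_present_but_masked(self):
        g = grid_with(center=7, corner=99)
        assert g.values[0, 0] == 99
        assert 99 not in g.retained()
        assert is_hotspot(g)  # corner cannot veto the call

    def test_extract_grid_reads_missing_keys_as_zero(self):
        cmap = BinnedContactMap(chrom_sizes={"c": 600 * 100})
        g = extract_grid(cmap, "c", 10, 40)
        assert g is not None and g.values.sum() == 0

    def test_extract_grid_single_center_key(self):
        cmap = BinnedContactMap(
            counts={("c", 10, 40): 3}, chrom_sizes={"c": 600 * 100}
        )
        g = extract_grid(cmap, "c", 10, 40)
        assert g.center == 3 and g.values.sum() == 3

    def test_extract_grid_is_none_near_chromosome_edges(self):
        cmap = BinnedContactMap(chrom_sizes={"c": 600 * 100})
        assert extract_grid(cmap, "c", 1, 40) is None
        assert extract_grid(cmap, "c", 10, 98) is None
        assert extract_grid(cmap, "c", 2, 97) is not None

    def test_grid_reflects_upper_triangular_storage(self):
        # a key below the diagonal is read through its mirrored storage key
        cmap = BinnedContactMap(
            counts={("c", 48, 50): 2}, chrom_sizes={"c": 600 * 100}
        )
        g = extract_grid(cmap, "c", 50, 50)
        assert g.values[0, 2] == 2 and g.values[2, 0] == 2


class TestHotspotCriteria:
    @pytest.mark.parametrize(
        "center,others,expect",
        [
            (10, 0, True),  # all criteria maximally satisfied
            (4, 0, False),  # fails >= 5
            (5, 4, False),  # median 4 not < 0.4*5
        ],
    )
    def test_printed_examples(self, center, others, expect):
        assert is_hotspot(grid_with(center=center, others=others)) is expect

    def test_twenty_percent_excess_is_inclusive(self):
        v = np.zeros((5, 5), dtype=int)
        v[2, 2], v[2, 3] = 5, 4
        assert is_hotspot(Grid(v))  # 5 >= 1.2 * 4 = 4.8
        v[2, 2], v[2, 3] = 6, 5
        assert is_hotspot(Grid(v))  # 6 >= 1.2 * 5 = 6.0 exactly
        v[2, 2], v[2, 3] = 5, 5
        assert not is_hotspot(Grid(v))  # 5 < 6.0

    def test_median_bound_is_strict(self):
        v = np.full((5, 5), 4, dtype=int)
        v[2, 2] = 10
        assert not is_hotspot(Grid(v))  # median 4 == 0.4 * 10, not <

    def test_agrees_with_brute_force_on_random_grids(self, rng):
        for _ in range(1_500):
            cells = rng.integers(0, 12, size=(5, 5))
            assert is_hotspot(Grid(cells)) == oracle_is_hotspot(cells.tolist())


class TestTMC:
    def test_all_zero_grid_scores_zero(self):
        assert tmc(grid_with()) == 0.0

    def test_all_ones_grid_scores_one(self):
        assert tmc(Grid(np.ones((5, 5), dtype=int))) == 1.0

    def test_power_median_value(self):
        v = np.full((5, 5), 2, dtype=int)
        v[1, 1] = 10
        assert tmc(Grid(v)) == pytest.approx(10**1.3 * 2)

    def test_uses_all_25_cells_including_corners(self):
        v = np.zeros((5, 5), dtype=int)
        v[0, 0] = 7  # corner is the max here
        assert tmc(Grid(v)) == pytest.approx(0.0)  # median still 0
        v[:, :] = 1
        v[0, 0] = 7
        assert tmc(Grid(v)) == pytest.approx(7**1.3 * 1)

    def test_agrees_with_brute_force_on_random_grids(self, rng):
        for _ in range(1_500):
            cells = rng.integers(0, 9, size=(5, 5))
            assert tmc(Grid(cells)) == pytest.approx(oracle_tmc(cells.tolist()))


def dense_map_with_zero_blocks(zero_offsets, hot=(50, 80), n_bins=200):
    """Uniform count-1 map with 5x5 all-zero blocks at the given diagonal
    offsets from the hotspot center."""
    counts = {}
    for bi in range(n_bins):
        for bj in range(bi, n_bins):
            counts[("c", bi, bj)] = 1
    for d in zero_offsets:
        ci, cj = hot[0] + d, hot[1] + d
        for r in range(ci - 2, ci + 3):
            for c in range(cj - 2, cj + 3):
                key = ("c", min(r, c), max(r, c))
                counts.pop(key, None)
    return BinnedContactMap(
        counts=counts, total_records=sum(counts.values()),
        chrom_sizes={"c": 600 * n_bins},
    )


class TestColdfieldSearch:
    def test_search_span_is_57kb(self):
        assert search_span_bp() == 57_000
        assert search_span_bp() // 600 == 95

    def test_far_zero_grid_wins_on_otherwise_empty_map(self):
        counts = {("c", 50, 80): 9}
        cmap = BinnedContactMap(counts=counts, chrom_sizes={"c": 600 * 400})
        hot = HotspotCall("c", 50, 80, 9, 0, 0.0)
        cold = find_coldfield(cmap, hot)
        assert cold.tmc == 0.0
        assert cold.offset_bins == -5  # nearest tie, negative preferred

    def test_tie_break_prefers_smaller_then_negative_offset(self):
        cmap = dense_map_with_zero_blocks([-5, 10])
        hot = HotspotCall("c", 50, 80, 1, 1, 1.0)
        cold = find_coldfield(cmap, hot)
        assert cold.tmc == 0.0 and cold.offset_bins == -5
        cmap2 = dense_map_with_zero_blocks([5, -10])
        cold2 = find_coldfield(cmap2, hot)
        assert cold2.offset_bins == 5

    def test_hotspot_position_not_eligible_as_its_own_coldfield(self):
        cmap = dense_map_with_zero_blocks([])  # uniform: every candidate tmc=1
        hot = HotspotCall("c", 50, 80, 1, 1, 1.0)
        cold = find_coldfield(cmap, hot)
        assert cold.offset_bins != 0

    def test_returned_minimum_matches_exhaustive_rescan(self, rng):
        from tepair.spotcaller import extract_grid, tmc as tmc_fn

        cmap = sparse_map(rng, n_bins=300, density=0.25, max_count=5)
        for _ in range(40):
            bi = int(rng.integers(100, 150))
            bj = bi + int(rng.integers(14, 60))
            hot = HotspotCall("chrS1", bi, bj, 5, 0, 0.0)
            cold = find_coldfield(cmap, hot)
            assert abs(cold.offset_bins) <= 95 and cold.offset_bins % 5 == 0
            scores = []
            for d in range(-95, 96, 5):
                if d == 0:
                    continue
                g = extract_grid(cmap, "chrS1", bi + d, bj + d)
                if g is not None:
                    scores.append(tmc_fn(g))
            assert cold.tmc == pytest.approx(min(scores))

    def test_all_candidates_off_chromosome_gives_none(self):
        cmap = BinnedContactMap(
            counts={("c", 5, 20): 9}, chrom_sizes={"c": 600 * 25}
        )
        hot = HotspotCall("c", 5, 20, 9, 0, 0.0)
        assert find_coldfield(cmap, hot) is None


class TestCallAll:
    def test_empty_map_gives_no_calls(self):
        assert call_all(BinnedContactMap(chrom_sizes={"c": 600 * 100})) == []

    def test_uniform_map_has_no_focal_structure(self):
        n = 120
        counts = {("c", i, j): 5 for i in range(n) for j in range(i, n)}
        cmap = BinnedContactMap(
            counts=counts, total_records=5 * len(counts),
            chrom_sizes={"c": 600 * n},
        )
        assert call_all(cmap) == []

    def test_isolated_spike_called_and_paired(self):
        cmap = BinnedContactMap(
            counts={("c", 120, 150): 8}, chrom_sizes={"c": 600 * 400}
        )
        pairs = call_all(cmap)
        assert len(pairs) == 1
        assert (pairs[0].hotspot.bin_i, pairs[0].hotspot.bin_j) == (120, 150)
        assert pairs[0].coldfield.tmc == 0.0

    def test_calls_invariant_to_contacts_outside_all_neighbourhoods(self):
        base = {("c", 120, 150): 8}
        far = {("c", 300, 330): 2, ("c", 350, 390): 1}
        cmap1 = BinnedContactMap(counts=dict(base), chrom_sizes={"c": 600 * 800})
        cmap2 = BinnedContactMap(counts={**base, **far}, chrom_sizes={"c": 600 * 800})
        calls1 = {(p.hotspot.bin_i, p.hotspot.bin_j) for p in call_all(cmap1)}
        calls2 = {(p.hotspot.bin_i, p.hotspot.bin_j) for p in call_all(cmap2)}
        assert calls1 <= calls2 and (120, 150) in calls1 and (120, 150) in calls2

    def test_raising_min_center_never_adds_hotspots(self, rng):
        cmap = sparse_map(rng, n_bins=250, density=0.05, max_count=9)
        sizes = [len(call_all(cmap, min_center=m)) for m in (3, 5, 7, 9)]
        assert sizes == sorted(sizes, reverse=True)
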