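"""Window geometry, pairing counts, per-family metrics and summaries."""

import math

import numpy as np
import pytest

from tepair.pairing import (
    COLD,
    HOT,
    PairingTable,
    age_correlation,
    all_family_metrics,
    assign_windows,
    count_pairings,
    family_metrics,
    make_windows,
    orientation_ratio,
    specificity_matrix,
)
from tepair.te_catalog import TERecord


class TestWindowGeometry:
    def test_twenty_one_windows(self):
        assert make_windows().n_windows == 21

    def test_center_window_covers_plus_minus_1kb(self):
        spec = make_windows()
        assert spec.bounds(spec.center_index) == (-1_000, 1_000)

    def test_outermost_edges_at_plus_minus_11kb(self):
        spec = make_windows()
        assert spec.bounds(0)[0] == -11_000
        assert spec.bounds(spec.n_windows - 1)[1] == 11_000

    def test_fifty_percent_overlap(self):
        spec = make_windows()
        lo0, hi0 = spec.bounds(0)
        lo1, hi1 = spec.bounds(1)
        assert hi0 - lo1 == spec.width // 2


def te_at(center, family="MIRb", strand="+", chrom="c"):
    return TERecord(chrom, center - 100, center + 100, family, strand)


class TestAssignWindows:
    def test_center_element_lands_in_center_window_and_boundary_neighbours(self):
        spec = make_windows()
        out = assign_windows([te_at(50_000)], 50_000, spec)
        # center 0 lies inside [-1k,1k] and on the boundaries of [-2k,0], [0,2k]
        assert set(out) == {spec.center_index - 1, spec.center_index, spec.center_index + 1}

    def test_element_outside_flank_unassigned(self):
        out = assign_windows([te_at(61_500)], 50_000, make_windows())
        assert out == {}

    def test_empty_te_list(self):
        assert assign_windows([], 50_000, make_windows()) == {}

    def test_matches_brute_force_interval_membership(self, rng):
        spec = make_windows()
        for _ in range(300):
            tes = [
                te_at(int(rng.integers(30_000, 70_000)), family=f"F{i % 3}")
                for i in range(10)
            ]
            got = assign_windows(tes, 50_000, spec)
            for i in range(spec.n_windows):
                lo, hi = spec.bounds(i)
                expect = [
                    (t.family, t.strand)
                    for t in tes
                    if lo <= t.center - 50_000 <= hi
                ]
                assert sorted(got.get(i, [])) == sorted(expect)


def one_window_map(families_strands, w=10):
    return {w: list(families_strands)}


class TestCountPairings:
    def test_same_family_counts_homotypic(self):
        t = PairingTable()
        count_pairings(one_window_map([("MIRb", "+")]), one_window_map([("MIRb", "-")]), HOT, t)
        assert t.get(HOT, "MIRb", "MIRb", 10) == 1

    def test_different_families_count_heterotypic_unordered(self):
        t = PairingTable()
        count_pairings(one_window_map([("MIRb", "+")]), one_window_map([("L2a", "+")]), HOT, t)
        assert t.counts == {(HOT, "L2a", "MIRb", 10): 1}

    def test_empty_side_contributes_nothing(self):
        t = PairingTable()
        count_pairings({}, one_window_map([("AluY", "+")]), HOT, t)
        assert t.counts == {} and t.n_contacts[HOT] == 1

    def test_presence_based_ignores_copy_number(self):
        t = PairingTable()
        side1 = one_window_map([("AluY", "+"), ("AluY", "-"), ("AluY", "+")])
        side2 = one_window_map([("AluY", "+")])
        count_pairings(side1, side2, HOT, t)
        assert t.get(HOT, "AluY", "AluY", 10) == 1

    def test_product_counting_counts_element_pairs(self):
        t = PairingTable()
        side1 = one_window_map([("AluY", "+"), ("AluY", "-")])
        side2 = one_window_map([("AluY", "+")])
        count_pairings(side1, side2, HOT, t, product_counting=True)
        assert t.get(HOT, "AluY", "AluY", 10) == 2

    def test_symmetric_under_anchor_swap(self, rng):
        fams = ["MIRb", "L2a", "AluY"]
        for _ in range(200):
            s1 = {
                w: [(fams[rng.integers(3)], "+-"[rng.integers(2)]) for _ in range(rng.integers(4))]
                for w in rng.choice(21, size=3, replace=False)
            }
            s2 = {
                w: [(fams[rng.integers(3)], "+-"[rng.integers(2)]) for _ in range(rng.integers(4))]
                for w in rng.choice(21, size=3, replace=False)
            }
            ta, tb = PairingTable(), PairingTable()
            count_pairings(s1, s2, HOT, ta)
            count_pairings(s2, s1, HOT, tb)
            assert ta.counts == tb.counts

    def test_matches_set_product_enumeration(self, rng):
        fams = ["MIRb", "L2a", "AluY", "L1M"]
        for _ in range(300):
            s1 = [fams[i] for i in rng.integers(0, 4, size=rng.integers(1, 5))]
            s2 = [fams[i] for i in rng.integers(0, 4, size=rng.integers(1, 5))]
            t = PairingTable()
            count_pairings(
                one_window_map([(f, "+") for f in s1]),
                one_window_map([(f, "+") for f in s2]),
                HOT,
                t,
            )
            expect = {tuple(sorted((a, b))) for a in set(s1) for b in set(s2)}
            got = {(a, b) for (_, a, b, _), n in t.counts.items() if n == 1}
            assert got == expect

    def test_unknown_context_rejected(self):
        with pytest.raises(ValueError):
            count_pairings({}, {}, "warm", PairingTable())


def table_with(hot_homo, cold_homo, hot_het=10, cold_het=10, fam="MIRb", other="L2a"):
    t = PairingTable()
    w = t.windows.center_index
    t.counts[(HOT, fam, fam, w)] = hot_homo
    t.counts[(COLD, fam, fam, w)] = cold_homo
    t.counts[(HOT,) + tuple(sorted((fam, other))) + (w,)] = hot_het
    t.counts[(COLD,) + tuple(sorted((fam, other))) + (w,)] = cold_het
    return t


class TestFamilyMetrics:
    def test_equal_hot_cold_gives_unit_metrics(self):
        m = family_metrics(table_with(10, 10), "MIRb")
        assert (m.hot_cold_ratio, m.heterotypic_ratio, m.specificity_index) == (1, 1, 1)

    def test_arithmetic(self):
        m = family_metrics(table_with(20, 10), "MIRb")
        assert m.hot_cold_ratio == 2 and m.specificity_index == 2

    def test_zero_cold_homotypic_flags_undefined(self):
        m = family_metrics(table_with(20, 0), "MIRb")
        assert math.isnan(m.hot_cold_ratio) and not m.defined

    def test_unknown_family_raises(self):
        with pytest.raises(KeyError):
            family_metrics(table_with(1, 1), "SVA")

    def test_heterotypic_denominator_sums_partners(self):
        t = table_with(5, 5, hot_het=6, cold_het=3)
        w = t.windows.center_index
        t.counts[(HOT, "AluY", "MIRb", w)] = 4
        t.counts[(COLD, "AluY", "MIRb", w)] = 2
        m = family_metrics(t, "MIRb")
        assert m.heterotypic_ratio == pytest.approx((6 + 4) / (3 + 2))


class TestSpecificityMatrix:
    def test_identical_contexts_give_all_ones(self):
        t = PairingTable()
        w = t.windows.center_index
        for ctx in (HOT, COLD):
            for a, b in [("A", "A"), ("A", "B"), ("B", "B")]:
                t.counts[(ctx, a, b, w)] = 7
        mat = specificity_matrix(t, top_k=5)
        assert np.allclose(mat.values.to_numpy(), 1.0)

    def test_symmetric_and_sorted_by_diagonal(self):
        t = PairingTable()
        w = t.windows.center_index
        data = {("A", "A"): (2, 1), ("B", "B"): (9, 1), ("A", "B"): (3, 1)}
        for (a, b), (h, c) in data.items():
            t.counts[(HOT, a, b, w)] = h
            t.counts[(COLD, a, b, w)] = c
        mat = specificity_matrix(t, top_k=2)
        assert mat.families == ["B", "A"]  # descending diagonal 9, 2
        v = mat.values
        assert v.loc["A", "B"] == v.loc["B", "A"] == 3

    def test_undefined_cells_are_nan(self):
        t = PairingTable()
        w = t.windows.center_index
        t.counts[(HOT, "A", "A", w)] = 4  # no cold counterpart
        mat = specificity_matrix(t, top_k=1)
        assert math.isnan(mat.values.loc["A", "A"])


class TestOrientationRatio:
    def test_arithmetic(self):
        t = PairingTable()
        t.head_head[HOT] = 47
        t.head_tail[HOT] = 50
        assert orientation_ratio(t) == pytest.approx(0.94)

    def test_all_opposite_strand_is_undefined(self, caplog):
        t = PairingTable()
        t.head_head[HOT] = 12
        with caplog.at_level("WARNING"):
            assert math.isnan(orientation_ratio(t))

    def test_strand_classification_from_elements(self):
        t = PairingTable()
        count_pairings(
            one_window_map([("MIRb", "+")]),
            one_window_map([("MIRb", "-")]),
            HOT,
            t,
        )
        count_pairings(
            one_window_map([("MIRb", "+")]),
            one_window_map([("MIRb", "+")]),
            HOT,
            t,
        )
        assert t.head_head[HOT] == 1 and t.head_tail[HOT] == 1


class TestAgeCorrelation:
    def test_exact_linear_function_of_age_gives_unit_correlation(self):
        import pandas as pd

        ages = {"A": 20.0, "B": 60.0, "C": 100.0, "D": 140.0}
        metrics = pd.DataFrame(
            {"family": list(ages), "hot_cold_ratio": [0.5 + 0.01 * a for a in ages.values()]}
        )
        r, n = age_correlation(metrics, ages)
        assert r == pytest.approx(1.0) and n == 4

    def test_four_point_set_matches_covariance_formula(self):
        import pandas as pd

        ages = {"A": 10.0, "B": 50.0, "C": 90.0, "D": 130.0}
        ys = [1.4, 0.8, 1.9, 2.2]
        metrics = pd.DataFrame({"family": list(ages), "hot_cold_ratio": ys})
        x = np.array(list(ages.values()))
        y = np.array(ys)
        expect = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        r, _ = age_correlation(metrics, ages)
        assert r == pytest.approx(expect)

    def test_identical_ages_flagged_nan(self):
        import pandas as pd

        ages = {"A": 50.0, "B": 50.0, "C": 50.0}
        metrics = pd.DataFrame({"family": list(ages), "hot_cold_ratio": [1.0, 2.0, 3.0]})
        r, _ = age_correlation(metrics, ages)
        assert math.isnan(r)

    def test_fewer_than_three_points_raises(self):
        import pandas as pd

        metrics = pd.DataFrame({"family": ["A", "B"], "hot_cold_ratio": [1.0, 2.0]})
        with pytest.raises(ValueError):
            age_correlation(metrics, {"A": 10.0, "B": 20.0})


def test_all_family_metrics_covers_every_family():
    t = table_with(4, 2)
    df = all_family_metrics(t)
    assert set(df["family"]) == {"MIRb", "L2a"}
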