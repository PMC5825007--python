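"""Representation tables, stratified comparisons and network geometry."""

import numpy as np
import pytest

from floraplan.gap_report import (
    compare_stratified,
    elevation_summary,
    network_overlap,
    perimeter_area_ratio,
    pu_mask_to_fine,
    representation,
    stratify,
    wilcoxon_rank_sum,
)
from floraplan.planning_io import AmountMatrix, PlanningGrid


def _amounts():
    counts = np.array(
        [
            [10, 0, 0, 0],   # a: all in PU 1
            [5, 5, 0, 0],    # b: split PU 1/2
            [0, 0, 8, 2],    # c: PUs 3,4
        ]
    )
    return AmountMatrix(["a", "b", "c"], counts, cell_area=0.1)


class TestRepresentation:
    def test_full_coverage_is_100(self):
        rep = representation(_amounts(), np.array([1, 1, 1, 1], bool))
        assert rep.table["percent_inside"].tolist() == [100.0, 100.0, 100.0]

    def test_disjoint_network_is_0(self):
        rep = representation(_amounts(), np.array([0, 0, 1, 1], bool))
        assert rep.percent("a") == 0.0 and rep.percent("b") == 0.0
        assert rep.percent("c") == 100.0

    def test_three_species_hand_computed(self):
        rep = representation(_amounts(), np.array([1, 0, 0, 1], bool))
        assert rep.percent("a") == pytest.approx(100.0)
        assert rep.percent("b") == pytest.approx(50.0)
        assert rep.percent("c") == pytest.approx(20.0)
        assert rep.group_means["all"] == pytest.approx((100 + 50 + 20) / 3)

    def test_group_means_weighted_consistency(self):
        """The all-species mean equals the member-count-weighted mean of
        disjoint subgroup means."""
        flags = {"a": frozenset({"endangered"}), "b": frozenset({"endemic"}),
                 "c": frozenset({"endemic"})}
        rep = representation(_amounts(), np.array([1, 0, 0, 1], bool), flags)
        combined = (1 * rep.group_means["endangered"] + 2 * rep.group_means["endemic"]) / 3
        assert rep.group_means["all"] == pytest.approx(combined)

    def test_monotone_in_network(self):
        rng = np.random.default_rng(0)
        amounts = AmountMatrix(
            ["x", "y"], rng.integers(0, 9, (2, 6)), cell_area=0.1
        )
        base = rng.random(6) < 0.5
        grown = base | (rng.random(6) < 0.5)
        rep0 = representation(amounts, base)
        rep1 = representation(amounts, grown)
        for s in ["x", "y"]:
            assert rep1.percent(s) >= rep0.percent(s)


class TestStratify:
    def test_ten_evenly_spread_species(self):
        cls = stratify(np.arange(1.0, 11.0), 10)
        assert sorted(cls.tolist()) == list(range(10))

    def test_degenerate_single_class(self):
        cls = stratify([5.0, 5.0, 5.0], 10)
        assert cls.tolist() == [0, 0, 0]

    def test_boundary_values_go_low_but_max_goes_top(self):
        # edges at 0,1,2,...,10: an exact internal edge belongs to the class below
        vals = [0.0, 1.0, 9.999, 10.0]
        cls = stratify(vals, 10)
        assert cls.tolist() == [0, 0, 9, 9]

    def test_matches_histogram_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.random(200) * 50
        cls = stratify(vals, 10)
        lo, hi = vals.min(), vals.max()
        edges = np.linspace(lo, hi, 11)
        for v, c in zip(vals, cls):
            expected = min(int(np.searchsorted(edges, v, side="left") - 1), 9)
            assert c == max(expected, 0)


class TestWilcoxon:
    def test_identical_constant_samples(self):
        w, p = wilcoxon_rank_sum([3.0, 3.0], [3.0, 3.0, 3.0])
        assert p == 1.0

    def test_small_sample_exact_value(self):
        # most extreme of the 6 orderings, doubled -> 1/3
        _, p = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(1 / 3)

    @pytest.mark.parametrize("na,nb", [(6, 6), (5, 7)])
    def test_normal_approximation_tracks_exact(self, na, nb):
        """For balanced 12-observation splits without ties the continuity-
        corrected normal p is within 0.02 of the exact permutation p (the
        worst case over all rank-sum values is 0.0155)."""
        rng = np.random.default_rng(0)
        for _ in range(30):
            a = rng.random(na) * 10
            b = rng.random(nb) * 10
            _, p_exact = wilcoxon_rank_sum(a, b, method="exact")
            _, p_norm = wilcoxon_rank_sum(a, b, method="normal")
            assert abs(p_exact - p_norm) <= 0.02

    def test_tie_corrected_variance_matches_scipy(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(3)
        a = rng.choice(np.arange(6.0), size=15)
        b = rng.choice(np.arange(6.0), size=18)
        _, p = wilcoxon_rank_sum(a, b)  # normal path (N > 12)
        ref = mannwhitneyu(a, b, method="asymptotic").pvalue
        assert p == pytest.approx(ref, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_compare_stratified_emits_stars(self):
        amounts = _amounts()
        rep_a = representation(amounts, np.array([1, 1, 1, 1], bool))
        rep_b = representation(amounts, np.array([0, 0, 0, 0], bool))
        cmp_ = compare_stratified(
            rep_a, rep_b, {"a": 1.0, "b": 2.0, "c": 3.0}, n_classes=1
        )
        row = cmp_.table.iloc[0]
        assert row["n_species"] == 3
        assert row["mean_a"] == 100.0 and row["mean_b"] == 0.0
        assert row["p"] <= 1.0


class TestGeometry:
    def test_single_pu_ratio(self):
        grid = PlanningGrid(n_rows=1, n_cols=1, pu_side_km=2.0, cost=None, status=None)
        sel = np.array([True])
        assert perimeter_area_ratio(sel, grid) == pytest.approx(8.0 / 4.0)

    def test_two_adjacent_pus(self):
        grid = PlanningGrid(n_rows=1, n_cols=2, pu_side_km=2.0, cost=None, status=None)
        assert perimeter_area_ratio(np.array([True, True]), grid) == pytest.approx(
            12.0 / 8.0
        )

    def test_block_ratio_shrinks_with_size(self):
        ratios = []
        for k in (1, 2, 4):
            grid = PlanningGrid(n_rows=4, n_cols=4, pu_side_km=2.0, cost=None, status=None)
            sel = np.zeros((4, 4), bool)
            sel[:k, :k] = True
            ratios.append(perimeter_area_ratio(sel.ravel(), grid))
        assert ratios[0] > ratios[1] > ratios[2]

    def test_empty_network_rejected(self):
        grid = PlanningGrid(n_rows=1, n_cols=2, pu_side_km=2.0, cost=None, status=None)
        with pytest.raises(ValueError):
            perimeter_area_ratio(np.array([False, False]), grid)

    def test_overlap_examples_and_oracle(self):
        a = np.array([1, 1, 0, 0], bool)
        assert network_overlap(a, a) == 100.0
        assert network_overlap(a, ~a) == 0.0
        rng = np.random.default_rng(4)
        x, y = rng.random(20) < 0.5, rng.random(20) < 0.5
        if x.any():
            expected = 100 * sum(xi and yi for xi, yi in zip(x, y)) / sum(x)
            assert network_overlap(x, y) == pytest.approx(expected)

    def test_overlap_empty_a_rejected(self):
        with pytest.raises(ValueError):
            network_overlap(np.zeros(4, bool), np.ones(4, bool))


class TestElevationSummary:
    def test_constant_elevation_sd_zero(self, env40):
        from floraplan.grids import EnvStack

        env = EnvStack(cell_area=1.0, layers={"elevation": np.full((2, 2), 700.0)})
        grid = PlanningGrid(n_rows=2, n_cols=2, pu_side_km=1.0, cost=None, status=None)
        mean, sd = elevation_summary(np.ones(4, bool), grid, env, 1)
        assert mean == 700.0 and sd == 0.0

    def test_two_cell_formula(self):
        from floraplan.grids import EnvStack

        env = EnvStack(cell_area=1.0, layers={"elevation": np.array([[100.0, 300.0]])})
        grid = PlanningGrid(n_rows=1, n_cols=2, pu_side_km=1.0, cost=None, status=None)
        mean, sd = elevation_summary(np.ones(2, bool), grid, env, 1)
        assert mean == 200.0
        assert sd == pytest.approx(141.42, abs=0.01)

    def test_matches_pooled_loop_oracle(self, env40):
        grid = PlanningGrid(n_rows=10, n_cols=10, pu_side_km=4 * env40.cell_side_km,
                            cost=None, status=None)
        rng = np.random.default_rng(5)
        sel = rng.random(100) < 0.4
        mean, sd = elevation_summary(sel, grid, env40, 4)
        fine = pu_mask_to_fine(sel, grid, 4)
        vals = [
            env40["elevation"][r, c]
            for r in range(40)
            for c in range(40)
            if fine[r, c]
        ]
        assert mean == pytest.approx(np.mean(vals))
        assert sd == pytest.approx(np.std(vals, ddof=1))
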