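"""Detachment-assay analysis: curves, histograms, W, subpopulations, filtering."""

import numpy as np
import pandas as pd
import pytest

from integrinkd import (
    DetachmentCurve,
    InvalidDataError,
    PressureSchedule,
    ReplicateCounts,
    ConditionDataset,
    build_histogram,
    heatmap,
    proximity_filter,
    remaining_fraction_averaged,
    remaining_fraction_pooled,
    subpopulations,
    weighted_average,
)

from conftest import dataset_from_pressures, percell_midpoints


def make_dataset(replicates, schedule, q=100.0):
    reps = tuple(ReplicateCounts(initial=r[0], remaining=tuple(r[1:])) for r in replicates)
    return ConditionDataset(q=q, schedule=schedule, replicates=reps)


class TestRemainingFractions:
    def test_identical_ratios_average_with_zero_stderr(self):
        sched = PressureSchedule(pressures=(0.07,))
        ds = make_dataset([(10, 5), (100, 50), (50, 25)], sched)
        curve = remaining_fraction_averaged(ds)
        assert curve.fractions[0] == pytest.approx(0.5)
        assert curve.stderr[0] == pytest.approx(0.0)

    def test_averaged_is_mean_of_per_replicate_ratios(self):
        sched = PressureSchedule(pressures=(0.07,))
        ds = make_dataset([(10, 5), (100, 90), (50, 40)], sched)
        curve = remaining_fraction_averaged(ds)
        assert curve.fractions[0] == pytest.approx((0.5 + 0.9 + 0.8) / 3)

    def test_pooled_weights_by_initial_count(self):
        sched = PressureSchedule(pressures=(0.07,))
        ds = make_dataset([(10, 5), (100, 90), (50, 40)], sched)
        curve = remaining_fraction_pooled(ds)
        assert curve.fractions[0] == pytest.approx(135 / 160)  # 0.84375

    def test_single_replicate_has_no_stderr_and_pooled_equals_averaged(self):
        sched = PressureSchedule(pressures=(0.07, 0.10))
        ds = make_dataset([(40, 30, 10)], sched)
        avg = remaining_fraction_averaged(ds)
        pooled = remaining_fraction_pooled(ds)
        assert avg.stderr is None
        np.testing.assert_allclose(avg.fractions, pooled.fractions)

    def test_pooled_equals_averaged_iff_equal_initial_counts(self, schedule):
        rng = np.random.default_rng(11)
        for trial in range(20):
            n0 = int(rng.integers(50, 150))
            equal = []
            for base in (n0, n0, n0):
                drops = np.sort(rng.integers(0, base + 1, size=6))[::-1]
                equal.append((base, *[int(d) for d in drops]))
            ds_eq = make_dataset(equal, schedule)
            np.testing.assert_allclose(
                remaining_fraction_averaged(ds_eq).fractions,
                remaining_fraction_pooled(ds_eq).fractions,
                atol=1e-12,
            )
        # the fixed arithmetic example where they differ
        sched1 = PressureSchedule(pressures=(0.07,))
        ds = make_dataset([(10, 5), (100, 90), (50, 40)], sched1)
        assert remaining_fraction_averaged(ds).fractions[0] != pytest.approx(
            remaining_fraction_pooled(ds).fractions[0]
        )

    def test_zero_initial_count_rejected(self):
        sched = PressureSchedule(pressures=(0.07,))
        ds = make_dataset([(0, 0)], sched)
        with pytest.raises(InvalidDataError):
            remaining_fraction_averaged(ds)


class TestHistogram:
    def test_differencing_example(self, schedule):
        curve = DetachmentCurve(
            fractions=np.array([0.6, 0.5, 0.5, 0.4, 0.35, 0.35]), mode="pooled"
        )
        hist = build_histogram(curve, schedule)
        np.testing.assert_allclose(hist.masses, [0.4, 0.1, 0.0, 0.1, 0.05, 0.0])
        assert hist.terminal_mass == pytest.approx(0.35)

    def test_everyone_detaches_first_round(self, schedule):
        curve = DetachmentCurve(fractions=np.zeros(6), mode="pooled")
        hist = build_histogram(curve, schedule)
        np.testing.assert_allclose(hist.masses, [1, 0, 0, 0, 0, 0])
        assert hist.terminal_mass == 0.0

    def test_nobody_detaches(self, schedule):
        curve = DetachmentCurve(fractions=np.ones(6), mode="pooled")
        hist = build_histogram(curve, schedule)
        np.testing.assert_allclose(hist.masses, np.zeros(6))
        assert hist.terminal_mass == 1.0

    def test_increasing_curve_rejected(self, schedule):
        with pytest.raises(InvalidDataError):
            DetachmentCurve(fractions=np.array([0.5, 0.6, 0.6, 0.6, 0.6, 0.6]), mode="pooled")

    def test_masses_conserved_on_random_datasets(self, schedule):
        rng = np.random.default_rng(5)
        for _ in range(50):
            pstars = [rng.lognormal(np.log(0.12), 1.0, size=rng.integers(5, 60))
                      for _ in range(3)]
            ds = dataset_from_pressures(pstars, schedule)
            for curve in (remaining_fraction_averaged(ds), remaining_fraction_pooled(ds)):
                hist = build_histogram(curve, schedule)
                assert np.all(hist.masses >= 0)
                assert hist.masses.sum() + hist.terminal_mass == pytest.approx(1.0, abs=1e-12)


class TestWeightedAverage:
    def test_all_mass_in_first_bin(self):
        sched = PressureSchedule(pressures=(0.07,))
        curve = DetachmentCurve(fractions=np.array([0.0]), mode="pooled")
        assert weighted_average(build_histogram(curve, sched)) == pytest.approx(0.035)

    def test_all_mass_terminal_uses_extrapolated_midpoint(self, schedule):
        curve = DetachmentCurve(fractions=np.ones(6), mode="pooled")
        assert weighted_average(build_histogram(curve, schedule)) == pytest.approx(0.235)

    def test_single_round_terminal_midpoint_is_one_and_a_half_p1(self):
        sched = PressureSchedule(pressures=(0.07,))
        curve = DetachmentCurve(fractions=np.array([1.0]), mode="pooled")
        assert weighted_average(build_histogram(curve, sched)) == pytest.approx(0.105)

    def test_uniform_mass_equals_mean_of_midpoints(self, schedule):
        # one cell per bin, including the terminal bin
        pstar = [0.05, 0.09, 0.12, 0.15, 0.18, 0.21, 0.5]
        ds = dataset_from_pressures([pstar], schedule)
        hist = build_histogram(remaining_fraction_pooled(ds), schedule)
        expected = percell_midpoints(pstar, schedule).mean()
        assert weighted_average(hist) == pytest.approx(expected, rel=1e-12)

    def test_equals_mean_per_cell_midpoint_on_random_datasets(self, schedule):
        """W from binned masses == population mean of per-cell bin midpoints."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            pstars = [rng.lognormal(np.log(0.1), 0.9, size=rng.integers(3, 80))
                      for _ in range(rng.integers(1, 4))]
            ds = dataset_from_pressures(pstars, schedule)
            hist = build_histogram(remaining_fraction_pooled(ds), schedule)
            oracle = percell_midpoints(np.concatenate(pstars), schedule).mean()
            assert weighted_average(hist) == pytest.approx(oracle, rel=1e-12)


class TestSubpopulations:
    def test_direct_partition(self, schedule):
        curve = DetachmentCurve(
            fractions=np.array([0.2, 0.1, 0.05, 0.05, 0.05, 0.05]), mode="pooled"
        )
        sub = subpopulations(build_histogram(curve, schedule))
        assert sub.weak == pytest.approx(0.8)
        assert sub.moderate == pytest.approx(0.15)
        assert sub.strong == pytest.approx(0.05)

    def test_all_terminal(self, schedule):
        curve = DetachmentCurve(fractions=np.ones(6), mode="pooled")
        sub = subpopulations(build_histogram(curve, schedule))
        assert (sub.weak, sub.moderate, sub.strong) == (0.0, 0.0, 1.0)

    def test_partition_of_differencing_example(self, schedule):
        curve = DetachmentCurve(
            fractions=np.array([0.6, 0.5, 0.5, 0.4, 0.35, 0.35]), mode="pooled"
        )
        sub = subpopulations(build_histogram(curve, schedule))
        assert sub.weak == pytest.approx(0.4)
        assert sub.strong == pytest.approx(0.35)
        assert sub.moderate == pytest.approx(0.25)
        assert sub.weak + sub.moderate + sub.strong == pytest.approx(1.0, abs=1e-12)


class TestHeatmap:
    def test_single_condition(self, schedule):
        curve = DetachmentCurve(fractions=np.linspace(0.9, 0.4, 6), mode="pooled")
        hist = build_histogram(curve, schedule)
        hm = heatmap([(1000.0, hist)])
        assert hm.values.shape == (1, 7)
        np.testing.assert_allclose(hm.values[0], hist.all_masses())

    def test_rows_sorted_by_density(self, schedule):
        c1 = build_histogram(DetachmentCurve(fractions=np.full(6, 0.5), mode="pooled"), schedule)
        c2 = build_histogram(DetachmentCurve(fractions=np.full(6, 0.8), mode="pooled"), schedule)
        hm = heatmap([(5000.0, c1), (100.0, c2)])
        np.testing.assert_allclose(hm.rho_numbers, [100.0, 5000.0])
        np.testing.assert_allclose(hm.values[0], c2.all_masses())

    def test_mismatched_schedules_rejected(self, schedule):
        other = PressureSchedule(pressures=(0.05, 0.1))
        h1 = build_histogram(DetachmentCurve(fractions=np.full(6, 0.5), mode="pooled"), schedule)
        h2 = build_histogram(DetachmentCurve(fractions=np.full(2, 0.5), mode="pooled"), other)
        with pytest.raises(InvalidDataError):
            heatmap([(1.0, h1), (2.0, h2)])


def cells_df(coords):
    return pd.DataFrame(
        {"cell_id": [f"c{i}" for i in range(len(coords))],
         "x_um": [c[0] for c in coords], "y_um": [c[1] for c in coords],
         "round_detached": [np.nan] * len(coords)}
    )


def brute_force_filter(df, min_sep=70.0):
    xy = df[["x_um", "y_um"]].to_numpy(float)
    keep = []
    for i in range(len(xy)):
        ok = True
        for j in range(len(xy)):
            if i != j and np.hypot(*(xy[i] - xy[j])) < min_sep:
                ok = False
        keep.append(ok)
    return df[np.array(keep, dtype=bool)]


class TestProximityFilter:
    def test_pair_below_threshold_both_removed(self):
        out = proximity_filter(cells_df([(0, 0), (69.9, 0)]))
        assert len(out) == 0

    def test_pair_above_threshold_both_kept(self):
        out = proximity_filter(cells_df([(0, 0), (70.1, 0)]))
        assert len(out) == 2

    def test_boundary_tie_kept(self):
        out = proximity_filter(cells_df([(0, 0), (70.0, 0)]))
        assert len(out) == 2

    def test_collinear_chain_all_removed(self):
        out = proximity_filter(cells_df([(0, 0), (60, 0), (120, 0)]))
        assert len(out) == 0

    def test_empty_input(self):
        out = proximity_filter(cells_df([]))
        assert len(out) == 0

    @pytest.mark.parametrize("n", [10, 100, 500])
    def test_agrees_with_brute_force_on_random_scenes(self, n):
        rng = np.random.default_rng(n)
        df = cells_df(list(map(tuple, rng.uniform(0, 800, size=(n, 2)))))
        fast = proximity_filter(df)
        slow = brute_force_filter(df)
        assert list(fast["cell_id"]) == list(slow["cell_id"])
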