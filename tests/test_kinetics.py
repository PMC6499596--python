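import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import focikit as fk
from focikit import kinetics as kin


def records_from_points(points):
    return pd.DataFrame({
        "label": np.arange(1, len(points) + 1),
        "centroid_row": [p[0] for p in points],
        "centroid_col": [p[1] for p in points],
    })


class TestMatchCells:
    def test_identical_sets_identity(self):
        pts = [(10, 10), (50, 80), (90, 30)]
        m = kin.match_cells(records_from_points(pts), records_from_points(pts),
                            max_displacement_px=5)
        assert (m["label_t0"] == m["label_t1"]).all() and len(m) == 3
        assert (m["displacement_px"] == 0).all()

    def test_displaced_nucleus_unmatched(self):
        a = records_from_points([(10, 10), (50, 50)])
        b = records_from_points([(10, 10), (90, 90)])
        m = kin.match_cells(a, b, max_displacement_px=10)
        assert len(m) == 1

    def test_mutual_matches_exhaustive_assignment(self):
        """On jittered point sets (jitter << spacing) mutual-nearest matching
        equals the globally optimal assignment found by brute force."""
        rng = np.random.default_rng(12)
        base = np.array([(r, c) for r in range(10, 100, 22)
                         for c in range(10, 100, 22)], dtype=float)[:6]
        jit = base + rng.uniform(-2, 2, base.shape)
        perm = rng.permutation(len(base))
        m = kin.match_cells(records_from_points(base),
                            records_from_points(jit[perm]),
                            max_displacement_px=8)
        # brute-force optimal assignment over all permutations
        best, best_cost = None, np.inf
        for p in itertools.permutations(range(len(base))):
            cost = sum(np.hypot(*(base[i] - jit[perm][j]))
                       for i, j in enumerate(p))
            if cost < best_cost:
                best, best_cost = p, cost
        expected = {(i + 1, j + 1) for i, j in enumerate(best)}
        got = set(zip(m["label_t0"], m["label_t1"]))
        assert got == expected

    def test_optimal_mode_agrees_on_jittered_sets(self):
        rng = np.random.default_rng(3)
        base = np.array([(r, c) for r in range(20, 480, 60)
                         for c in range(20, 480, 60)], dtype=float)[:50]
        jit = base + rng.uniform(-4, 4, base.shape)
        a, b = records_from_points(base), records_from_points(jit)
        m1 = kin.match_cells(a, b, 15, method="mutual")
        m2 = kin.match_cells(a, b, 15, method="optimal")
        assert set(zip(m1.label_t0, m1.label_t1)) == set(zip(m2.label_t0, m2.label_t1))

    def test_empty_input(self):
        assert kin.match_cells(records_from_points([]), records_from_points([]),
                               5).empty


class TestResolutionFraction:
    @pytest.mark.parametrize("c0,c1,expected", [(10, 7, 0.30), (20, 2, 0.90),
                                                (10, 12, -0.2)])
    def test_arithmetic(self, c0, c1, expected):
        assert kin.resolution_fraction(c0, c1) == pytest.approx(expected)

    def test_zero_initial_count_undefined(self):
        assert np.isnan(kin.resolution_fraction(0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            kin.resolution_fraction(-1, 2)

    @given(c0=st.integers(1, 50), c1=st.integers(0, 49))
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_final_count(self, c0, c1):
        assert kin.resolution_fraction(c0, c1) \
            > kin.resolution_fraction(c0, c1 + 1)


class TestClassifyFast:
    def test_threshold_is_strict(self):
        assert kin.classify_fast(0.90) is True
        assert kin.classify_fast(0.85) is False
        assert kin.classify_fast(0.25) is False


class TestSummarize:
    def test_degenerate_sample(self):
        s = kin.summarize({45: np.array([10, 10, 10])})
        row = s.stats.iloc[0]
        assert (row["mean"], row["sd"], row["median"]) == (10, 0, 10)

    def test_histogram_mass_is_one(self):
        rng = np.random.default_rng(0)
        s = kin.summarize({45: rng.poisson(9, 400)})
        assert s.histograms[45.0]["probability"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_smoothing_preserves_interior_mean(self):
        """Gaussian smoothing of the count histogram is symmetric, so the
        histogram mean stays within O(bandwidth^2) of the sample mean for
        interior-supported samples."""
        rng = np.random.default_rng(5)
        counts = rng.integers(8, 16, 500)
        h = kin.smoothed_histogram(counts, bandwidth=1.0)
        hist_mean = (h["focus_count"] * h["probability"]).sum()
        assert abs(hist_mean - counts.mean()) < 0.05

    def test_generator_counts_recovered(self):
        params = fk.KineticsParams()
        traj = fk.sample_kinetics(params, 2000, seed=9)
        s = kin.summarize({45: traj["count_t45"].to_numpy()})
        m = s.stats.iloc[0]["mean"]
        se = traj["count_t45"].std() / np.sqrt(2000)
        assert abs(m - params.initial_count_mean) < 3 * se + 0.15

    def test_empty_timepoint_raises(self):
        with pytest.raises(ValueError):
            kin.summarize({45: np.array([])})


class TestCompareTtest:
    def test_identical_samples(self):
        t, p = kin.compare_ttest([5, 5, 5, 5], [5, 5, 5, 5])
        assert (t, p) == (0.0, 1.0)

    def test_separated_samples(self):
        a = np.zeros(6) + np.linspace(0, 1e-3, 6)
        b = 10 + np.linspace(0, 1e-3, 6)
        _, p = kin.compare_ttest(a, b)
        assert p < 1e-6

    def test_matches_closed_form_oracle(self):
        """Frozen values computed from the pooled-variance formula and the
        Student-t CDF by hand."""
        a = [3.0, 5.0, 4.0, 6.0, 2.0]
        b = [7.0, 9.0, 6.0, 8.0, 10.0]
        t, p = kin.compare_ttest(a, b)
        assert t == pytest.approx(-4.0, abs=1e-12)
        assert p == pytest.approx(0.003949772803445323, abs=1e-12)


class TestIntensityCountCorrelation:
    @staticmethod
    def _table(x, y):
        return pd.DataFrame({"mean_nuclear_intensity": x, "focus_count": y})

    def test_perfect_linear(self):
        x = np.arange(1, 8, dtype=float)
        assert kin.intensity_count_correlation(self._table(x, 2 * x)) \
            == pytest.approx(1.0)
        assert kin.intensity_count_correlation(self._table(x, -x)) \
            == pytest.approx(-1.0)

    def test_independent_generator_uncorrelated(self, small_course):
        """Nuclear background level is drawn independently of focus count,
        so detected intensity carries no count information."""
        params = fk.KineticsParams()
        traj = fk.sample_kinetics(params, 1000, seed=2)
        rng = np.random.default_rng(3)
        tbl = self._table(rng.normal(2000, 200, 1000),
                          traj["count_t45"].to_numpy())
        assert abs(kin.intensity_count_correlation(tbl)) < 0.1

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning):
            r = kin.intensity_count_correlation(self._table([1., 1., 1.],
                                                            [1., 2., 3.]))
        assert np.isnan(r)


class TestSpeedRatio:
    def test_median_matching_ratio(self):
        """A population whose 60-min median equals the reference's 90-min
        median resolves 1.5x faster."""
        ref_t = [45, 60, 75, 90, 120]
        ref_m = [24, 20, 18, 15, 10]
        pop_m = [25, 15, 12, 9, 5]  # 25 outside ref range; 15 matches t=90
        assert kin.speed_ratio(ref_t, ref_m, ref_t, pop_m) == pytest.approx(1.5)

    def test_identical_curves_ratio_one(self):
        t = [45, 60, 90]
        m = [20, 15, 10]
        assert kin.speed_ratio(t, m, t, m) == pytest.approx(1.0)

    def test_hand_interpolation(self):
        # reference hits median 13 at t = 75 + 15*(14-13)/(14-10) = 78.75
        ratio = kin.speed_ratio([60, 75, 90], [18, 14, 10], [50, 70], [13, 8])
        assert ratio == pytest.approx(78.75 / 50)

    def test_time_rescaling_invariance(self):
        ref_t = np.array([45., 60., 90.])
        ref_m = [20, 15, 10]
        r1 = kin.speed_ratio(ref_t, ref_m, [50, 70], [14, 11])
        r2 = kin.speed_ratio(3 * ref_t, ref_m, [150, 210], [14, 11])
        assert r1 == pytest.approx(r2)

    def test_no_crossing_flagged(self):
        with pytest.warns(UserWarning):
            r = kin.speed_ratio([45, 60], [20, 15], [45, 60], [30, 25])
        assert np.isnan(r)

    def test_increasing_curve_rejected(self):
        with pytest.raises(ValueError):
            kin.speed_ratio([45, 60], [10, 15], [45, 60], [20, 10])


class TestBuildTracks:
    def test_zero_initial_count_excluded_from_classification(self):
        matches = pd.DataFrame({"label_t0": [1, 2], "label_t1": [1, 2],
                                "displacement_px": [0.0, 0.0]})
        t0 = pd.DataFrame({"nucleus_label": [1, 2], "focus_count": [0, 20]})
        t1 = pd.DataFrame({"nucleus_label": [1, 2], "focus_count": [0, 1]})
        tracks = kin.build_tracks(matches, t0, t1)
        assert not tracks.iloc[0]["classifiable"]
        assert not tracks.iloc[0]["fast_resolver"]
        assert tracks.iloc[1]["fast_resolver"]
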