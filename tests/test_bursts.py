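"""Burst-analysis tests: EM fit, intersection threshold, segmentation, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from caburst import synthetic as syn
from caburst.bursts import (
    Burst,
    BurstDefinition,
    DegenerateFitError,
    EMSettings,
    IntervalMixture,
    NoIntersectionError,
    compute_metrics,
    fit_interval_mixture,
    mixture_intersection,
    segment_bursts,
)

TI_MIX = IntervalMixture(w_g=0.7545, mu_s=2.0, sigma_s=1.5, rate_per_s=1 / 15)
ANGII_MIX = IntervalMixture(w_g=0.6644, mu_s=2.0, sigma_s=1.5, rate_per_s=1 / 15)


def grid_scan_intersection(mix, resolution=1e-4):
    """Dense-grid oracle for the weighted-density crossing above the mean."""
    x = np.arange(mix.mu_s, mix.mu_s + 10 * mix.sigma_s, resolution)
    g, e = mix.component_densities(x)
    d = g - e
    idx = np.flatnonzero(np.sign(d[:-1]) != np.sign(d[1:]))[0]
    return 0.5 * (x[idx] + x[idx + 1])


class TestMixtureIntersection:
    @pytest.mark.parametrize(
        "mix, printed",
        [(TI_MIX, 5.6), (ANGII_MIX, 5.3)],
        ids=["TI", "AngII"],
    )
    def test_printed_thresholds_reproduced(self, mix, printed):
        x = mixture_intersection(mix)
        assert round(x, 1) == printed
        assert x == pytest.approx(grid_scan_intersection(mix), abs=1e-3)

    def test_crossing_is_exact_root(self):
        x = mixture_intersection(TI_MIX)
        g, e = TI_MIX.component_densities(np.asarray(x))
        assert abs(g - e) < 1e-10
        assert x > TI_MIX.mu_s

    def test_single_component_no_intersection(self):
        with pytest.raises(NoIntersectionError):
            mixture_intersection(
                IntervalMixture(w_g=1.0, mu_s=2.0, sigma_s=1.5, rate_per_s=1 / 15)
            )


class TestFitIntervalMixture:
    def test_parameters_recovered_from_generated_sample(self):
        rng = np.random.default_rng(42)
        iv, _ = syn.sample_interval_mixture(0.7545, 2.0, 1.5, 1 / 15, 50_000, rng)
        fit = fit_interval_mixture(iv)
        assert fit.w_g == pytest.approx(0.7545, rel=0.05)
        assert fit.mu_s == pytest.approx(2.0, rel=0.05)
        assert fit.sigma_s == pytest.approx(1.5, rel=0.05)
        assert fit.rate_per_s == pytest.approx(1 / 15, rel=0.05)

    def test_pure_exponential_gets_tiny_gaussian_weight(self):
        rng = np.random.default_rng(7)
        iv = rng.exponential(10.0, 20_000)
        fit = fit_interval_mixture(iv)
        # no Gaussian bump to find: either the weight collapses or the
        # "Gaussian" absorbs a sliver of the exponential bulk
        assert fit.w_g < 0.05 or fit.sigma_s > 2 * fit.mu_s

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError):
            fit_interval_mixture(np.linspace(1, 10, 20))

    def test_identical_intervals_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_interval_mixture(np.full(100, 2.0))

    def test_untruncated_em_path(self):
        rng = np.random.default_rng(3)
        iv, _ = syn.sample_interval_mixture(
            0.6, 8.0, 1.0, 1 / 30, 20_000, rng, interval_floor_s=0.2
        )
        fit = fit_interval_mixture(iv, EMSettings(truncation_floor_s=0.0))
        assert fit.mu_s == pytest.approx(8.0, rel=0.05)
        assert fit.w_g == pytest.approx(0.6, rel=0.05)


class TestSegmentBursts:
    def test_worked_example(self):
        t = np.array([0, 1, 2, 10, 11, 12, 13, 30], dtype=float)
        bursts = segment_bursts(t, BurstDefinition(5.6, 3))
        assert len(bursts) == 2
        assert (bursts[0].onset_s, bursts[0].offset_s, bursts[0].n_events) == (0, 2, 3)
        assert bursts[0].duration_s == 2
        assert (bursts[1].onset_s, bursts[1].offset_s, bursts[1].n_events) == (
            10, 13, 4,
        )

    def test_too_few_events_no_burst(self):
        assert segment_bursts(np.array([1.0, 2.0]), BurstDefinition(5.6)) == []

    def test_all_gaps_above_threshold_no_burst(self):
        t = np.arange(0, 100, 10.0)
        assert segment_bursts(t, BurstDefinition(5.6)) == []

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            segment_bursts(np.array([3.0, 1.0, 2.0]), BurstDefinition(5.6))

    @staticmethod
    def brute_force(times, thr, min_events):
        """Exhaustive scan: from every start index, extend while gaps stay
        below threshold; keep runs that are maximal on both sides."""
        out = []
        n = len(times)
        for i in range(n):
            if i > 0 and times[i] - times[i - 1] < thr:
                continue  # not maximal on the left
            j = i
            while j + 1 < n and times[j + 1] - times[j] < thr:
                j += 1
            if j - i + 1 >= min_events:
                out.append((i, j))
        return out

    def test_matches_exhaustive_oracle_on_random_trains(self):
        n_trains = 10_000
        rng = np.random.default_rng(0)
        for _ in range(n_trains):
            n = int(rng.integers(0, 51))
            times = np.sort(rng.uniform(0, 100, n))
            times = np.unique(times)
            thr = float(rng.uniform(1, 15))
            got = segment_bursts(times, BurstDefinition(thr, 3))
            want = self.brute_force(times, thr, 3)
            assert len(got) == len(want)
            for b, (i, j) in zip(got, want):
                assert b.onset_s == times[i] and b.offset_s == times[j]

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 500), min_size=0, max_size=40),
        st.floats(0.5, 20),
    )
    def test_conservation_properties(self, times, thr):
        t = np.unique(np.asarray(times))
        bursts = segment_bursts(t, BurstDefinition(thr, 3))
        assigned = np.concatenate(
            [b.event_times_s for b in bursts]
        ) if bursts else np.empty(0)
        # every event belongs to at most one burst
        assert len(assigned) == len(np.unique(assigned))
        for b in bursts:
            assert np.diff(b.event_times_s).sum() == pytest.approx(b.duration_s)
            assert np.all(np.diff(b.event_times_s) < thr)

    def test_threshold_monotonicity(self):
        # raising the threshold can merge two bursts into one (so the burst
        # count itself is not monotone), but the number of events assigned
        # to some burst can only grow
        rng = np.random.default_rng(5)
        for _ in range(200):
            t = np.unique(np.sort(rng.uniform(0, 100, rng.integers(3, 40))))
            assigned = []
            for thr in [1.0, 3.0, 5.0, 10.0, 20.0]:
                bursts = segment_bursts(t, BurstDefinition(thr, 3))
                assigned.append(sum(b.n_events for b in bursts))
            assert assigned == sorted(assigned)


class TestComputeMetrics:
    def test_worked_example(self):
        t = np.array([0, 1, 2, 10, 11, 12, 13, 30], dtype=float)
        bursts = segment_bursts(t, BurstDefinition(5.6, 3))
        m = compute_metrics({0: t}, {0: bursts}, duration_s=60.0)
        row = m.per_roi.iloc[0]
        assert row["fraction_active"] == pytest.approx(5 / 60)
        assert row["intraburst_period_s"] == pytest.approx(1.0)
        assert row["n_transients"] == 8 and row["n_bursts"] == 2

    def test_no_bursts_reports_missing_not_zero(self):
        m = compute_metrics({0: np.array([1.0, 20.0])}, {0: []}, duration_s=60.0)
        row = m.per_roi.iloc[0]
        assert row["fraction_active"] == 0
        assert np.isnan(row["mean_burst_duration_s"])
        assert np.isnan(row["intraburst_period_s"])

    def test_active_cell_density(self):
        events = {i: np.array([1.0, 2.0, 3.0]) for i in range(12)}
        events.update({i: np.array([1.0]) for i in range(12, 15)})
        m = compute_metrics(
            events, {i: [] for i in events}, duration_s=600.0,
            zg_area_um2=4000.0,
        )
        assert m.n_active_rois == 12
        assert m.active_cell_density_per_um2 == pytest.approx(0.003)

    def test_binned_rates(self):
        events = {0: np.array([10.0, 20.0, 70.0])}
        m = compute_metrics(events, {0: []}, duration_s=120.0)
        assert m.binned_rate_hz[0] == pytest.approx(2 / 60)
        assert m.binned_rate_hz[1] == pytest.approx(1 / 60)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_metrics({}, {}, duration_s=0.0)
        with pytest.raises(ValueError):
            compute_metrics({}, {}, duration_s=10.0, zg_area_um2=-1.0)
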