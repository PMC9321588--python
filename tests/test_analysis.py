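"""Mixing metrics, regime classification, filters and visit statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lagcomp.analysis import (
    AnalysisError,
    classify_regimes,
    com_curve,
    com_tau95,
    com_value,
    filter_lifeline,
    hysteresis_labels,
    moving_average,
    pool_histograms,
    probe_tau95,
    regime_fractions,
    residence_time_stats,
)


class TestCoM:
    def test_uniform_field_zero(self):
        assert com_value(np.full(10, 0.7), np.ones(10)) == 0.0

    def test_point_mass_equal_volumes(self):
        """All tracer in one of Nc equal boxes -> CoM = sqrt(Nc - 1)."""
        for nc in (4, 156):
            c = np.zeros(nc)
            c[2] = 1.0
            assert com_value(c, np.ones(nc)) == pytest.approx(np.sqrt(nc - 1), rel=1e-12)
        assert com_value(np.eye(156)[0], np.ones(156)) == pytest.approx(12.449, abs=1e-3)

    def test_two_box_five_percent(self):
        assert com_value(np.array([1.05, 0.95]), np.ones(2)) == pytest.approx(0.05)

    def test_zero_mean_flagged(self):
        with pytest.raises(AnalysisError):
            com_value(np.zeros(3), np.ones(3))

    def test_curve_matches_pointwise(self):
        rng = np.random.default_rng(0)
        c = rng.uniform(0.5, 1.5, (5, 8))
        v = rng.uniform(0.5, 2.0, 8)
        curve = com_curve(c, v)
        for k in range(5):
            assert curve[k] == pytest.approx(com_value(c[k], v), rel=1e-12)

    def test_tau95_first_sustained_drop(self):
        t = np.arange(0.0, 10.0, 0.1)
        com = 2.0 * np.exp(-t)  # crosses 0.0283 at t = ln(2/0.0283)
        tau, ok = com_tau95(t, com)
        assert ok and tau == pytest.approx(np.log(2.0 / 0.0283), abs=0.01)
        tau, ok = com_tau95(t, np.full_like(t, 1.0))
        assert not ok and np.isnan(tau)


class TestProbeTau95:
    def test_flat_series_zero(self):
        t = np.linspace(0, 10, 50)
        tau, ok = probe_tau95(t, np.ones(50))
        assert ok and tau == 0.0

    def test_exponential_band_entry(self):
        """1 + 0.2 exp(-t/10) enters the band at 10 ln(0.2/0.05)."""
        t = np.linspace(0, 60, 6001)
        s = 1.0 + 0.2 * np.exp(-t / 10.0)
        tau, ok = probe_tau95(t, s)
        assert ok and tau == pytest.approx(-10 * np.log(0.05 / 0.2), abs=0.02)

    def test_last_crossing_vs_scan_oracle(self):
        """Oscillatory decay: reported time equals brute-force last exit."""
        t = np.linspace(0, 80, 8001)
        s = 1.0 + 0.3 * np.exp(-t / 15.0) * np.cos(t / 2.0)
        tau, ok = probe_tau95(t, s)
        out = (s < 0.95) | (s > 1.05)
        k = np.flatnonzero(out)[-1]
        assert ok and t[k] <= tau <= t[k + 1]

    def test_never_settles_flagged(self):
        t = np.linspace(0, 10, 100)
        tau, ok = probe_tau95(t, 1.2 * np.ones(100))
        assert not ok and np.isnan(tau)


class TestClassification:
    def test_threshold_values(self):
        labels = classify_regimes(np.array([0.96, 0.50, 0.04]))
        assert list(labels) == ["E", "L", "S"]

    def test_boundaries_are_strict(self):
        labels = classify_regimes(np.array([0.95, 0.05]))
        assert list(labels) == ["L", "L"]

    def test_constant_starvation_single_interval(self):
        labels = classify_regimes(np.full(100, 0.01))
        assert np.all(labels == "S")


class TestFilters:
    def test_constant_series_unchanged(self):
        r = np.full(50, 0.5)
        smooth, labels = filter_lifeline(r, dt_sample=0.06)
        np.testing.assert_array_equal(smooth, r)
        assert np.all(labels == "L")

    def test_window_is_seven_points_at_default_sampling(self):
        r = np.zeros(21)
        r[10] = 7.0
        smooth = moving_average(r, dt_sample=0.06)
        # a unit impulse spreads over exactly 7 samples of height 1
        assert np.count_nonzero(smooth) == 7
        np.testing.assert_allclose(smooth[7:14], 1.0)

    def test_single_sample_spike_removed(self):
        """0.90 baseline with one 0.955 sample: no Excess visit survives."""
        r = np.full(40, 0.90)
        r[20] = 0.955
        assert "E" in classify_regimes(r)  # unfiltered sees the spike
        smooth, labels = filter_lifeline(r, dt_sample=0.06)
        assert smooth.max() <= 0.96
        assert "E" not in labels

    def test_clean_step_one_transition(self):
        r = np.concatenate([np.full(50, 0.5), np.full(50, 1.0)])
        _, labels = filter_lifeline(r, dt_sample=0.06)
        runs = [labels[0]]
        for lab in labels[1:]:
            if lab != runs[-1]:
                runs.append(lab)
        assert runs == ["L", "E"]

    def test_hysteresis_blocks_subthreshold_reentry(self):
        """Oscillation between 0.945 and 0.955 never enters Excess."""
        r = np.where(np.arange(100) % 2 == 0, 0.945, 0.955)
        labels = hysteresis_labels(r)
        assert "E" not in labels

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(AnalysisError):
            moving_average(np.ones(3), dt_sample=0.06)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=20, max_size=200))
    def test_filtering_never_creates_regime_visits(self, vals):
        """Filtered E/S visits only exist where the raw series has them."""
        r = np.array(vals)
        raw = classify_regimes(r)
        _, filtered = filter_lifeline(r, dt_sample=0.06)
        for reg in ("E", "S"):
            if reg in filtered:
                assert reg in raw


class TestResidenceStats:
    def test_hand_counted_sle_visit(self):
        """Sequence S,L,L,E at 0.06 s sampling: one SLE visit of 0.12 s."""
        labels = np.array(list("SLLE"))
        stats = residence_time_stats(labels, dt_sample=0.06)
        assert stats.count("SLE") == 1
        assert stats.mean("SLE") == pytest.approx(0.12)
        assert sum(stats.count(p) for p in stats.durations) == 1

    def test_square_wave_all_ele(self):
        labels = np.array((["E"] * 5 + ["L"] * 5) * 10)
        stats = residence_time_stats(labels, dt_sample=0.06)
        assert set(stats.durations) == {"ELE", "LEL"}
        assert stats.mean("ELE") == pytest.approx(5 * 0.06)
        assert stats.mean("LEL") == pytest.approx(5 * 0.06)

    def test_truncated_runs_discarded(self):
        labels = np.array(list("EEELLLSSS"))  # first and last runs truncated
        stats = residence_time_stats(labels, dt_sample=0.06)
        assert stats.count("ELS") == 1
        assert stats.count("LEL") == 0

    def test_random_markov_labels_match_run_oracle(self):
        """Pattern means agree with a brute-force run enumeration."""
        rng = np.random.default_rng(4)
        labels = np.array(["E", "L", "S"])[rng.integers(0, 3, 3000)]
        stats = residence_time_stats(labels, dt_sample=1.0)
        # oracle: explicit scan
        from collections import defaultdict

        acc = defaultdict(list)
        runs = []
        start = 0
        for k in range(1, len(labels) + 1):
            if k == len(labels) or labels[k] != labels[start]:
                runs.append((labels[start], k - start))
                start = k
        for k in range(1, len(runs) - 1):
            acc[runs[k - 1][0] + runs[k][0] + runs[k + 1][0]].append(runs[k][1])
        for pat, durations in acc.items():
            assert stats.count(pat) == len(durations)
            assert stats.mean(pat) == pytest.approx(np.mean(durations))


class TestFractions:
    def test_all_starvation(self):
        labels = np.full(1000, "S")
        frac = regime_fractions(labels, dt_sample=0.06, window_s=6.0)
        assert frac["S"]["percent"] == 100.0
        assert frac["E"]["percent"] == 0.0

    def test_partition_sums_to_hundred(self):
        rng = np.random.default_rng(1)
        labels = np.array(["E", "L", "S"])[rng.integers(0, 3, 5000)]
        frac = regime_fractions(labels, dt_sample=0.06, window_s=10.0)
        total = sum(frac[r]["percent"] for r in "ELS")
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_two_window_margin(self):
        """Windows at 8 % and 10 % E give mean 9 and 2 SD = 2 sqrt(2)."""
        win = 100
        labels = np.array(["E"] * 8 + ["L"] * 92 + ["E"] * 10 + ["L"] * 90)
        frac = regime_fractions(labels, dt_sample=1.0, window_s=float(win))
        assert frac["E"]["percent"] == pytest.approx(9.0)
        assert frac["E"]["margin_2sd"] == pytest.approx(2 * np.sqrt(2.0), rel=1e-6)


class TestPoolHistograms:
    def test_two_parcel_mean_and_sd(self):
        out = pool_histograms(np.array([[1.0], [3.0]]), pool_names=["X"])
        assert out["X"]["mean"] == 2.0
        assert out["X"]["sd"] == 1.0  # population SD

    def test_identical_parcels_zero_sd(self):
        out = pool_histograms(np.tile([[2.0, 5.0]], (10, 1)))
        assert out["pool_0"]["sd"] == 0.0
        assert out["pool_1"]["sd"] == 0.0

    def test_single_parcel_rejected(self):
        with pytest.raises(AnalysisError):
            pool_histograms(np.array([[1.0]]))
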