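import numpy as np
import pytest

from leverhold import peth as P
from leverhold.core import Group, UnitRecording
from leverhold.simulate import BehaviorParams, UnitParams, simulate_behavior, simulate_unit

from conftest import make_session


def brute_force_peth(spikes, events, window, bin_width):
    """Independent per-event, per-spike counting loop."""
    start, stop = window
    n_bins = int(round((stop - start) / bin_width))
    counts = np.zeros(n_bins)
    for e in events:
        for s in spikes:
            rel = s - e
            if start <= rel < stop:
                b = int((rel - start) // bin_width)
                if b == n_bins:  # guard float edge
                    continue
                counts[b] += 1
    return counts / (len(events) * bin_width / 1000.0)


class TestBinSpikes:
    def test_single_event_hand_computed(self):
        u = UnitRecording("u", "s", np.array([5.0, 25.0]))
        peth = P.bin_spikes(u, [0.0], window_ms=(-40.0, 40.0), bin_width_ms=20.0)
        np.testing.assert_allclose(peth.rate_per_bin, [0.0, 0.0, 50.0, 50.0])

    def test_duplicate_events_average_invariance(self):
        u = UnitRecording("u", "s", np.array([5.0, 25.0]))
        once = P.bin_spikes(u, [0.0], window_ms=(-40.0, 40.0), bin_width_ms=20.0)
        twice = P.bin_spikes(u, [0.0, 0.0], window_ms=(-40.0, 40.0), bin_width_ms=20.0)
        np.testing.assert_allclose(once.rate_per_bin, twice.rate_per_bin)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(25):
            spikes = np.sort(rng.uniform(0, 60_000, size=rng.integers(0, 200)))
            events = rng.uniform(5000, 55_000, size=rng.integers(1, 10))
            u = UnitRecording("u", "s", spikes)
            got = P.bin_spikes(
                u, events, window_ms=(-2000.0, 2000.0), bin_width_ms=20.0
            )
            expected = brute_force_peth(spikes, events, (-2000.0, 2000.0), 20.0)
            np.testing.assert_array_equal(got.rate_per_bin, expected)

    def test_zero_events_rejected(self):
        u = UnitRecording("u", "s", np.array([5.0]))
        with pytest.raises(ValueError, match="no events"):
            P.bin_spikes(u, [])

    def test_default_window_has_1000_bins(self):
        u = UnitRecording("u", "s", np.array([5.0]))
        assert P.bin_spikes(u, [0.0]).n_bins == 1000


class TestSmoothPeth:
    def _peth(self, rates):
        return P.Peth(
            unit_id="u",
            event_type="press_onset",
            window_ms=(0.0, 20.0 * len(rates)),
            rate_per_bin=np.asarray(rates, float),
            n_events=1,
        )

    def test_constant_preserved(self):
        out = P.smooth_peth(self._peth([7.0] * 50))
        np.testing.assert_allclose(out.rate_per_bin, 7.0)

    def test_impulse_response(self):
        out = P.smooth_peth(self._peth([0.0] * 5 + [1.0] + [0.0] * 5))
        w = np.exp(-1.0 / (2 * 0.4**2))
        expected_center = 1.0 / (1 + 2 * w)
        expected_side = w / (1 + 2 * w)
        np.testing.assert_allclose(
            out.rate_per_bin[4:7], [expected_side, expected_center, expected_side]
        )
        # frozen values from the kernel arithmetic:
        # w = exp(-3.125) = 0.0439369; [w, 1, w] / (1 + 2w)
        np.testing.assert_allclose(
            out.rate_per_bin[4:7], [0.0403877, 0.9192246, 0.0403877], atol=5e-7
        )

    def test_interior_sum_preserved(self, rng):
        # away from the edges the normalized kernel conserves total rate
        rates = rng.uniform(0, 10, size=100)
        rates[:2] = rates[-2:] = 0.0
        out = P.smooth_peth(self._peth(rates))
        assert out.rate_per_bin.sum() == pytest.approx(rates.sum())


class TestBaselineStats:
    def _onset_peth(self, rates):
        return P.Peth(
            unit_id="u",
            event_type="press_onset",
            rate_per_bin=np.asarray(rates, float),
            n_events=10,
            smoothed=True,
        )

    def test_constant_baseline(self):
        b = P.baseline_stats(self._onset_peth([5.0] * 1000))
        assert (b.mean_hz, b.sd_hz) == (5.0, 0.0)
        assert (b.lower95_hz, b.upper95_hz) == (5.0, 5.0)
        assert b.n_bins == 400

    def test_two_point_distribution(self):
        rates = np.zeros(1000)
        rates[:400] = np.where(np.arange(400) % 2 == 0, 4.0, 6.0)
        b = P.baseline_stats(self._onset_peth(rates))
        assert b.mean_hz == pytest.approx(5.0)
        assert b.lower95_hz == pytest.approx(4.0)
        assert b.upper95_hz == pytest.approx(6.0)

    def test_percentile_interval_covers_95pct_of_bins(self, rng):
        rates = np.zeros(1000)
        rates[:400] = rng.poisson(10, size=400).astype(float)
        b = P.baseline_stats(self._onset_peth(rates))
        inside = np.mean(
            (rates[:400] >= b.lower95_hz) & (rates[:400] <= b.upper95_hz)
        )
        assert inside >= 0.95


class TestDetectModulation:
    def _make(self, window_rates, baseline_val=5.0):
        """PETH with constant baseline and given rates over [-2000, 3000)."""
        rates = np.full(1000, baseline_val)
        idx0 = 400  # left edge -2000 ms
        rates[idx0 : idx0 + len(window_rates)] = window_rates
        peth = P.Peth(
            unit_id="u",
            event_type="press_onset",
            rate_per_bin=rates,
            n_events=10,
            smoothed=True,
        )
        base = P.BaselineStats(
            mean_hz=baseline_val, sd_hz=0.5,
            lower95_hz=baseline_val - 1, upper95_hz=baseline_val + 1,
        )
        return peth, base

    def test_flat_trace_is_unmodulated(self):
        peth, base = self._make([5.0] * 250)
        assert P.detect_modulation(peth, base).direction == "none"

    def test_four_bins_above_is_up_with_onset(self):
        rates = [5.0] * 250
        start = int((100 - (-2000)) / 20)  # bin with left edge +100 ms
        for i in range(4):
            rates[start + i] = 8.0
        peth, base = self._make(rates)
        res = P.detect_modulation(peth, base)
        assert res.direction == "up"
        assert res.onset_latency_ms == 100.0

    def test_three_bins_insufficient(self):
        rates = [5.0] * 250
        for i in range(3):
            rates[100 + i] = 8.0
        peth, base = self._make(rates)
        assert P.detect_modulation(peth, base).direction == "none"

    def test_earlier_run_wins_and_both_flags_kept(self):
        rates = [5.0] * 250
        for i in range(4):
            rates[10 + i] = 2.0  # down run first
        for i in range(4):
            rates[50 + i] = 9.0
        peth, base = self._make(rates)
        res = P.detect_modulation(peth, base)
        assert res.direction == "down"
        assert res.has_up_run and res.has_down_run
        assert res.onset_latency_ms == -2000.0 + 10 * 20.0

    def test_boundary_values_not_significant(self):
        # bins exactly at the interval bound do not count (strict rule)
        rates = [6.0] * 250  # equals upper bound
        peth, base = self._make(rates)
        assert P.detect_modulation(peth, base).direction == "none"


class TestZScore:
    def _peth(self, rates):
        return P.Peth(
            unit_id="u", event_type="press_onset",
            rate_per_bin=np.asarray(rates, float), n_events=5, smoothed=True,
        )

    def test_hand_computed(self):
        base = P.BaselineStats(5.0, 1.0, 3.0, 7.0)
        z = P.zscore_peth(self._peth([7.0] * 1000), base)
        np.testing.assert_allclose(z.z_per_bin, 2.0)

    def test_rate_equal_mean_gives_zero(self):
        base = P.BaselineStats(5.0, 0.0, 5.0, 5.0)
        z = P.zscore_peth(self._peth([5.0] * 1000), base)
        np.testing.assert_allclose(z.z_per_bin, 0.0)
        assert not z.undefined

    def test_degenerate_baseline_flagged(self):
        base = P.BaselineStats(5.0, 0.0, 5.0, 5.0)
        z = P.zscore_peth(self._peth([5.0] * 999 + [6.0]), base)
        assert z.undefined

    def test_own_baseline_bins_standardized(self, rng):
        rates = np.abs(rng.normal(8, 2, size=1000))
        peth = self._peth(rates)
        base = P.baseline_stats(peth)
        z = P.zscore_peth(peth, base)
        zb = z.z_per_bin[peth.slice_bins(-10_000, -2000)]
        assert zb.mean() == pytest.approx(0.0, abs=1e-12)
        assert zb.std(ddof=1) == pytest.approx(1.0, rel=1e-12)


class TestSplitByOutcome:
    def test_all_success_drops_failure_peth(self):
        s = make_session([2000.0] * 6, criterion_ms=1600)
        u = UnitRecording("u", "s1", np.sort(np.linspace(0, 30_000, 300)))
        zs, zf = P.split_by_outcome(u, s, "press_offset")
        assert zs is not None and zf is None

    def test_weighted_average_recovers_all_press_peth(self, rng):
        s = make_session([2000.0, 800.0, 2500.0, 400.0, 1900.0], criterion_ms=1600)
        spikes = np.sort(rng.uniform(0, s.session_end_ms, 400))
        u = UnitRecording("u", "s1", spikes)
        from leverhold.core import success_mask

        mask = success_mask(s)
        all_p = P.bin_spikes(u, s.press_offsets)
        succ = P.bin_spikes(u, s.press_offsets[mask])
        fail = P.bin_spikes(u, s.press_offsets[~mask])
        weighted = (
            succ.rate_per_bin * succ.n_events + fail.rate_per_bin * fail.n_events
        ) / (succ.n_events + fail.n_events)
        np.testing.assert_allclose(weighted, all_p.rate_per_bin)

    def test_success_gain_separates_outcome_epoch(self):
        s = simulate_behavior(BehaviorParams(), seed=21)
        u = simulate_unit(
            UnitParams(base_rate_hz=8.0, outcome_gain_success=2.0),
            s, seed=22,
        )
        zs, zf = P.split_by_outcome(u, s, "press_offset")
        sel = zs.bin_left_edges_ms
        post = (sel >= 0) & (sel < 1000)
        assert zs.z_per_bin[post].mean() > zf.z_per_bin[post].mean()


class TestClassifyUnitEvents:
    def _r(self, event, direction):
        return P.ModulationResult("u", event, direction)

    def test_single_event(self):
        cat = P.classify_unit_events([self._r("press_onset", "up")])
        assert cat == frozenset({"press_onset"})

    def test_direction_agnostic_all_three(self):
        cat = P.classify_unit_events(
            [
                self._r("press_onset", "up"),
                self._r("press_offset", "down"),
                self._r("reward", "up"),
            ]
        )
        assert cat == frozenset({"press_onset", "press_offset", "reward"})

    def test_unmodulated_is_empty(self):
        cat = P.classify_unit_events(
            [self._r(e, "none") for e in ("press_onset", "press_offset", "reward")]
        )
        assert cat == frozenset()


class TestEpochSummary:
    def _z(self, values):
        return P.ZScoredPeth(
            unit_id="u", event_type="press_onset",
            z_per_bin=np.asarray(values, float),
            baseline=P.BaselineStats(0, 1, -2, 2),
        )

    def test_constant(self):
        s = P.epoch_summary(self._z([2.0] * 1000), "pre_onset")
        assert s.bin_means == (2.0, 2.0, 2.0, 2.0)

    def test_linear_ramp_monotone(self):
        z = np.zeros(1000)
        pre = slice(450, 500)  # [-1000, 0)
        z[pre] = np.linspace(0, 1, 50)
        s = P.epoch_summary(self._z(z), "pre_onset")
        assert list(s.bin_means) == sorted(s.bin_means)

    def test_matches_brute_force_bin_means(self, rng):
        z = rng.normal(size=1000)
        s = P.epoch_summary(self._z(z), "post_offset")
        edges = -10_000 + 20.0 * np.arange(1000)
        for k in range(4):
            sel = (edges >= k * 250.0) & (edges < (k + 1) * 250.0)
            assert s.bin_means[k] == pytest.approx(z[sel].mean())
            assert sel.sum() in (12, 13)

    def test_epoch_outside_window_rejected(self):
        z = P.ZScoredPeth(
            unit_id="u", event_type="press_onset",
            z_per_bin=np.zeros(10),
            baseline=P.BaselineStats(0, 1, -2, 2),
            window_ms=(-100.0, 100.0),
        )
        with pytest.raises(ValueError, match="outside"):
            P.epoch_summary(z, "pre_onset")


class TestGroupAverage:
    def _z(self, values, uid="u"):
        return P.ZScoredPeth(
            unit_id=uid, event_type="press_onset",
            z_per_bin=np.asarray(values, float),
            baseline=P.BaselineStats(0, 1, -2, 2),
        )

    def test_mean_of_two_traces(self):
        out = P.group_average(
            [self._z([1.0, 3.0]), self._z([3.0, 1.0])], ["air", "air"]
        )
        np.testing.assert_allclose(out["air"].mean, [2.0, 2.0])

    def test_single_unit_identity(self):
        out = P.group_average([self._z([1.0, 2.0])], ["CIE"])
        np.testing.assert_allclose(out["CIE"].mean, [1.0, 2.0])
        np.testing.assert_allclose(out["CIE"].sem, 0.0)

    def test_identical_traces_zero_sem(self):
        zs = [self._z([1.0, 2.0], uid=f"u{i}") for i in range(5)]
        out = P.group_average(zs, ["air"] * 5)
        np.testing.assert_allclose(out["air"].sem, 0.0)

    def test_no_units_rejected(self):
        with pytest.raises(ValueError, match="no units"):
            P.group_average([], [])
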