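import math

import numpy as np
import pytest
from scipy import stats

from leverhold.core import Group, Outcome
from leverhold.simulate import (
    BehaviorParams,
    GainKernel,
    GroupEffect,
    HoldSuppression,
    RateModel,
    UnitParams,
    UnitPrior,
    apply_group_effect,
    simulate_behavior,
    simulate_cohort,
    simulate_unit,
)

from conftest import make_session


class TestSimulateBehavior:
    def test_degenerate_distribution_all_rewarded(self):
        # sigma -> 0 with median 2000 above the 1600-ms criterion: every
        # press is a success and the session stops at exactly 60 rewards
        p = BehaviorParams(
            criterion_ms=1600,
            log_duration_mu=math.log(2000.0),
            log_duration_sigma=0.0,
            mean_ipi_ms=3000.0,
        )
        s = simulate_behavior(p, seed=0)
        assert s.n_rewards == 60
        assert s.n_presses == 60
        assert all(o is Outcome.SUCCESS for o in s.press_outcomes)
        assert s.session_end_ms == s.press_offsets[-1]

    def test_short_presses_never_rewarded(self):
        p = BehaviorParams(
            criterion_ms=1600,
            log_duration_mu=math.log(100.0),
            log_duration_sigma=0.1,
            mean_ipi_ms=2000.0,
            max_session_ms=120_000.0,
        )
        s = simulate_behavior(p, seed=0)
        assert s.n_rewards == 0
        assert s.n_presses > 0

    def test_success_fraction_matches_lognormal_tail(self):
        # empirical success fraction vs the closed-form log-normal tail
        # probability, at the 95% binomial interval
        p = BehaviorParams(max_rewards=10_000)  # avoid reward truncation
        s = simulate_behavior(p, seed=42)
        n = s.n_presses
        k = sum(o is Outcome.SUCCESS for o in s.press_outcomes)
        lo, hi = stats.binom.interval(0.95, n, p.success_probability)
        assert lo <= k <= hi

    def test_invariants_and_determinism(self):
        p = BehaviorParams()
        a = simulate_behavior(p, seed=7)
        b = simulate_behavior(p, seed=7)
        a.validate()
        np.testing.assert_array_equal(a.press_onsets, b.press_onsets)
        np.testing.assert_array_equal(a.reward_times, b.reward_times)
        assert np.all(a.press_onsets % 10 == 0)
        assert np.all(a.durations_ms >= 10)


class TestSimulateUnit:
    def test_homogeneous_rate_within_poisson_interval(self):
        # all gains 1: spike count within the 99% Poisson interval
        s = simulate_behavior(BehaviorParams(), seed=3)
        u = simulate_unit(UnitParams(base_rate_hz=8.0), s, seed=4)
        expected = 8.0 * s.session_end_ms / 1000.0
        lo, hi = stats.poisson.interval(0.99, expected)
        assert lo <= u.n_spikes <= hi

    def test_full_suppression_silences_presses(self):
        s = simulate_behavior(BehaviorParams(), seed=5)
        u = simulate_unit(
            UnitParams(
                base_rate_hz=20.0, hold_suppression=HoldSuppression(depth=0.0)
            ),
            s,
            seed=6,
        )
        for on, off in zip(s.press_onsets, s.press_offsets):
            inside = (u.spike_times > on) & (u.spike_times < off)
            assert not inside.any()

    def test_onset_kernel_peak_matches_analytic_rate(self):
        # 200 isolated events, onset kernel peak 3 x base: the averaged
        # PETH peak matches the analytic rate profile within counting error
        from leverhold.peth import bin_spikes

        s = make_session([1000.0] * 200, gaps_ms=np.full(200, 4000.0))
        params = UnitParams(
            base_rate_hz=8.0,
            kernels=(GainKernel("press_onset", 0.0, 100.0, 3.0),),
        )
        u = simulate_unit(params, s, seed=8)
        peth = bin_spikes(
            u, s.press_onsets, window_ms=(-1000.0, 1000.0), bin_width_ms=20.0
        )
        peak_idx = np.argmax(peth.rate_per_bin)
        peak_time = peth.bin_centers_ms[peak_idx]
        assert abs(peak_time) <= 60.0
        expected_peak = 8.0 * 3.0
        # Poisson SE of the peak bin of a 200-event average
        se = math.sqrt(expected_peak / (200 * 0.02))
        assert abs(peth.rate_per_bin[peak_idx] - expected_peak) < 4 * se

    def test_rate_ceiling_enforced(self):
        s = make_session([1000.0] * 3)
        params = UnitParams(
            base_rate_hz=300.0,
            kernels=(GainKernel("press_onset", 0.0, 100.0, 3.0),),
        )
        with pytest.raises(ValueError, match="ceiling"):
            simulate_unit(params, s, seed=0)

    def test_deterministic(self):
        s = simulate_behavior(BehaviorParams(), seed=9)
        p = UnitParams(
            base_rate_hz=6.0, kernels=(GainKernel("reward", 0, 150, 2.0),)
        )
        a = simulate_unit(p, s, seed=10)
        b = simulate_unit(p, s, seed=10)
        np.testing.assert_array_equal(a.spike_times, b.spike_times)


class TestRateModel:
    def test_outcome_gain_applies_only_after_successes(self):
        s = make_session([2000.0, 1000.0], criterion_ms=1600)
        params = UnitParams(
            base_rate_hz=10.0, outcome_gain_success=3.0, outcome_gain_failure=1.0
        )
        m = RateModel(params, s)
        t_after_success = s.press_offsets[0] + 500.0
        t_after_failure = s.press_offsets[1] + 500.0
        t_late = s.press_offsets[1] + 1500.0
        r = m.rate_at(np.sort([t_after_success, t_after_failure, t_late]))
        lookup = dict(
            zip(np.sort([t_after_success, t_after_failure, t_late]), r)
        )
        assert lookup[t_after_success] == pytest.approx(30.0)
        assert lookup[t_after_failure] == pytest.approx(10.0)
        assert lookup[t_late] == pytest.approx(10.0)

    def test_hold_profile_depth_and_ramp(self):
        s = make_session([1000.0])
        hs = HoldSuppression(depth=0.5, prerelease_ramp_gain=2.0, ramp_fraction=0.25)
        m = RateModel(UnitParams(base_rate_hz=10.0, hold_suppression=hs), s)
        onset = s.press_onsets[0]
        t = np.array([onset + 100.0, onset + 999.0])
        r = m.rate_at(t)
        assert r[0] == pytest.approx(5.0)
        # at the very end of the ramp the gain approaches depth * ramp_gain
        assert r[1] == pytest.approx(10.0 * 0.5 * 2.0, rel=0.01)


class TestGroupEffect:
    def test_excess_gain_scaling_preserves_direction(self):
        params = UnitParams(
            base_rate_hz=5.0,
            kernels=(
                GainKernel("press_onset", 0, 100, 3.0),
                GainKernel("press_onset", 0, 100, 0.5),
                GainKernel("reward", 0, 100, 2.0),
            ),
            outcome_gain_success=2.0,
        )
        out = apply_group_effect(
            params, GroupEffect(press_gain_multiplier=1.5, outcome_gain_multiplier=0.5)
        )
        assert out.kernels[0].peak_gain == pytest.approx(4.0)  # 1 + 2*1.5
        assert out.kernels[1].peak_gain == pytest.approx(0.25)  # 1 - 0.5*1.5
        assert out.kernels[2].peak_gain == pytest.approx(1.5)  # 1 + 1*0.5
        assert out.outcome_gain_success == pytest.approx(1.5)


class TestSimulateCohort:
    def test_shapes_and_determinism(self):
        ds, gt = simulate_cohort(n_mice_per_group=1, units_per_mouse=1, seed=2)
        assert len(ds.sessions) == 2 and len(ds.units) == 2
        ds.validate()
        ds2, _ = simulate_cohort(n_mice_per_group=1, units_per_mouse=1, seed=2)
        for a, b in zip(ds.units, ds2.units):
            np.testing.assert_array_equal(a.spike_times, b.spike_times)

    def test_substreams_stable_under_growth(self):
        ds1, _ = simulate_cohort(n_mice_per_group=1, units_per_mouse=1, seed=3)
        ds2, _ = simulate_cohort(n_mice_per_group=1, units_per_mouse=2, seed=3)
        np.testing.assert_array_equal(
            ds1.units[0].spike_times, ds2.units[0].spike_times
        )

    def test_ground_truth_records_group_scaling(self):
        # mean injected press excess gain for CIE = 1.5 x air, by construction
        prior = UnitPrior(p_kernel=1.0, p_up=1.0, up_gain_range=(2.0, 2.0))
        effects = {
            Group.AIR: GroupEffect(1.0, 1.0),
            Group.CIE: GroupEffect(1.5, 0.5),
        }
        _, gt = simulate_cohort(
            n_mice_per_group=2, units_per_mouse=2, unit_prior=prior,
            effects=effects, seed=4,
        )
        def mean_excess(group):
            vals = [
                k.peak_gain - 1.0
                for u in gt.units
                if u.group == group
                for k in u.params.kernels
                if k.anchor == "press_onset"
            ]
            return np.mean(vals)

        assert mean_excess(Group.CIE) / mean_excess(Group.AIR) == pytest.approx(1.5)

    def test_ground_truth_reproduces_rate_profiles(self):
        ds, gt = simulate_cohort(n_mice_per_group=1, units_per_mouse=1, seed=6)
        u = ds.units[0]
        info = gt.unit(u.unit_id)
        session = ds.session(u.session_id)
        m = RateModel(info.params, session)
        t = np.linspace(0, session.session_end_ms, 1000)
        r = m.rate_at(t)
        assert np.all(np.isfinite(r)) and np.all(r >= 0)
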