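"""Sleep scoring against a brute-force scanner, plus conservation laws."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flysleeplab.sleep_core import (
    PeriodMetrics,
    activity_while_awake,
    all_period_metrics,
    average_across_days,
    period_architecture,
    score_sleep,
    sleep_profile_binned,
)
from flysleeplab.validation import minute_timeline

from conftest import brute_force_sleep_scan


def make_timeline(n_days):
    return minute_timeline(n_days)


class TestScoreSleep:
    def test_short_run_not_sleep(self):
        rec = score_sleep([1, 0, 0, 0, 0, 1])
        assert rec.sleep.sum() == 0
        assert rec.episodes == ()

    def test_nine_minute_episode(self):
        rec = score_sleep([1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1])
        assert rec.episodes == ((1, 9),)
        assert rec.sleep.sum() == 9

    def test_edge_runs_count(self):
        rec = score_sleep([0] * 6 + [2] + [0] * 5)
        assert rec.episodes == ((0, 6), (7, 5))

    def test_missing_minutes_break_runs(self):
        counts = [0] * 10
        mask = np.zeros(10, dtype=bool)
        mask[5] = True
        rec = score_sleep(counts, missing_mask=mask)
        assert rec.episodes == ((0, 5),)  # trailing run only 4 min

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            score_sleep([1, -1, 0])

    @given(st.lists(st.integers(0, 1), min_size=0, max_size=40))
    @settings(max_examples=200, derandomize=True)
    def test_matches_brute_force_scanner(self, bits):
        rec = score_sleep(bits)
        sleep, episodes = brute_force_sleep_scan(bits)
        assert np.array_equal(rec.sleep, sleep)
        assert list(rec.episodes) == episodes

    @given(st.lists(st.integers(0, 5), min_size=6, max_size=60))
    @settings(max_examples=100, derandomize=True)
    def test_zeroing_a_minute_never_decreases_sleep(self, counts):
        base = score_sleep(counts).sleep.sum()
        nz = [i for i, c in enumerate(counts) if c > 0]
        for i in nz[:3]:
            mod = list(counts)
            mod[i] = 0
            assert score_sleep(mod).sleep.sum() >= base


class TestProfile:
    def test_all_sleep_day_saturates_bins(self):
        tl = make_timeline(1)
        rec = score_sleep([0] * 1440)
        prof = sleep_profile_binned(rec, tl, 30)
        assert len(prof) == 48
        assert (prof["sleep_min"] == 30).all()

    def test_no_sleep_day_all_zero(self):
        tl = make_timeline(1)
        rec = score_sleep([1] * 1440)
        prof = sleep_profile_binned(rec, tl, 30)
        assert (prof["sleep_min"] == 0).all()

    def test_bin_sums_equal_daily_totals(self, small_sim):
        fly = small_sim.fly_ids[0]
        ch = small_sim.fly_channels[fly]
        counts = small_sim.counts[:, ch - 1]
        tl = make_timeline(small_sim.design.n_days)
        rec = score_sleep(counts)
        prof = sleep_profile_binned(rec, tl, 30)
        per_day = prof.groupby("day_index")["sleep_min"].sum()
        for d, total in per_day.items():
            sel = tl["day_index"].to_numpy() == d
            assert total == rec.sleep[sel].sum()

    def test_bad_bin_size_rejected(self):
        tl = make_timeline(1)
        rec = score_sleep([0] * 1440)
        with pytest.raises(ValueError):
            sleep_profile_binned(rec, tl, 7)


class TestPeriodArchitecture:
    def test_boundary_spanning_episode_attribution(self):
        """A 20-min episode starting 10 min before lights-off: the dark
        window gains 10 sleep minutes; the episode itself (duration 20)
        belongs to the light window where it starts."""
        counts = np.ones(1440, dtype=int)
        counts[710:730] = 0
        tl = make_timeline(1)
        rec = score_sleep(counts)
        light = period_architecture(rec, counts, tl, 0, "L")
        dark = period_architecture(rec, counts, tl, 0, "D")
        assert light.total_sleep_min == 10
        assert dark.total_sleep_min == 10
        assert light.n_episodes == 1 and light.max_episode_min == 20
        assert dark.n_episodes == 0
        assert np.isnan(dark.mean_episode_min)

    def test_zero_sleep_window(self):
        counts = np.ones(1440, dtype=int)
        tl = make_timeline(1)
        rec = score_sleep(counts)
        m = period_architecture(rec, counts, tl, 0, "L")
        assert m.total_sleep_min == 0 and m.n_episodes == 0
        assert np.isnan(m.mean_episode_min)

    def test_metrics_match_brute_force_on_sim(self, small_sim):
        tl = make_timeline(small_sim.design.n_days)
        for fly in small_sim.fly_ids[:3]:
            ch = small_sim.fly_channels[fly]
            counts = small_sim.counts[:, ch - 1]
            rec = score_sleep(counts, fly_id=fly)
            sleep, episodes = brute_force_sleep_scan(counts)
            for m in all_period_metrics(rec, counts, tl):
                sel = (tl["day_index"].to_numpy() == m.day_index) & (
                    tl["light"].to_numpy() == m.light
                )
                idx = np.nonzero(sel)[0]
                assert m.total_sleep_min == sleep[idx].sum()
                eps = [e for e in episodes if idx[0] <= e[0] <= idx[-1]]
                assert m.n_episodes == len(eps)
                if eps:
                    assert m.max_episode_min == max(d for _, d in eps)

    def test_conservation_sleep_plus_wake(self, small_sim):
        tl = make_timeline(small_sim.design.n_days)
        for fly in small_sim.fly_ids[:4]:
            ch = small_sim.fly_channels[fly]
            counts = small_sim.counts[:, ch - 1]
            rec = score_sleep(counts)
            for m in all_period_metrics(rec, counts, tl):
                sel = (tl["day_index"].to_numpy() == m.day_index) & (
                    tl["light"].to_numpy() == m.light
                )
                n_wake = int((~rec.sleep[sel]).sum())
                assert m.total_sleep_min + n_wake == 720


class TestActivityWhileAwake:
    def test_simple_rate(self):
        counts = np.full(1440, 2, dtype=int)  # never asleep
        tl = make_timeline(1)
        rec = score_sleep(counts)
        m = period_architecture(rec, counts, tl, 0, "L")
        assert m.activity_while_awake == pytest.approx(2.0)

    def test_fully_asleep_window_is_nan(self):
        counts = np.zeros(1440, dtype=int)
        tl = make_timeline(1)
        rec = score_sleep(counts)
        m = period_architecture(rec, counts, tl, 0, "D")
        assert np.isnan(m.activity_while_awake)

    def test_poisson_rate_recovered(self):
        """Waking counts ~ Poisson(3): the per-waking-minute estimate
        lands within 3 SE of 3 (approximate: zero-count wake minutes can
        be scored as sleep and drop from the denominator)."""
        rng = np.random.default_rng(0)
        counts = rng.poisson(3.0, size=1440 * 4)
        tl = make_timeline(4)
        rec = score_sleep(counts)
        awake = ~rec.sleep
        est = counts[awake].sum() / awake.sum()
        se = np.sqrt(3.0 / awake.sum())
        assert abs(est - 3.0) < 3 * se


class TestAverageAcrossDays:
    @staticmethod
    def _pm(day, total, n_ep=2, mean_ep=50.0):
        return PeriodMetrics(
            fly_id="f", day_index=day, light="D", total_sleep_min=total,
            n_episodes=n_ep, mean_episode_min=mean_ep, max_episode_min=90.0,
            activity_while_awake=2.0,
        )

    def test_identical_days_idempotent(self):
        ms = [self._pm(d, 400.0) for d in range(3)]
        out = average_across_days(ms)
        assert out["total_sleep_min"] == 400.0

    def test_arithmetic_mean(self):
        ms = [self._pm(0, 300.0), self._pm(1, 360.0), self._pm(2, 420.0)]
        assert average_across_days(ms)["total_sleep_min"] == 360.0

    def test_nan_excluded_pairwise(self):
        ms = [self._pm(0, 300.0, n_ep=0, mean_ep=float("nan")),
              self._pm(1, 360.0, n_ep=2, mean_ep=40.0)]
        out = average_across_days(ms)
        assert out["total_sleep_min"] == 330.0
        assert out["mean_episode_min"] == 40.0

    def test_day_selector(self):
        ms = [self._pm(d, 100.0 * (d + 1)) for d in range(4)]
        out = average_across_days(ms, which_days=[1, 2])
        assert out["total_sleep_min"] == 250.0

    def test_no_selected_windows_raises(self):
        with pytest.raises(ValueError):
            average_across_days([self._pm(0, 100.0)], which_days=[5])

    def test_matches_brute_force_table_mean(self, small_sim):
        tl = make_timeline(small_sim.design.n_days)
        fly = small_sim.fly_ids[0]
        ch = small_sim.fly_channels[fly]
        counts = small_sim.counts[:, ch - 1]
        rec = score_sleep(counts)
        ms = all_period_metrics(rec, counts, tl)
        dark = [m for m in ms if m.light == "D"]
        out = average_across_days(ms, light="D")
        assert out["total_sleep_min"] == pytest.approx(
            np.mean([m.total_sleep_min for m in dark])
        )
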