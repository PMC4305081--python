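"""Sleep scoring and sleep-architecture metrics for fly actigraphy.

Sleep is scored by the field-standard inactivity rule: a minute is asleep
iff it lies in a maximal run of consecutive zero-count minutes lasting
five or more minutes. Architecture metrics (total sleep, episode count,
mean/max episode duration, activity while awake) are computed per 12-hr
light or dark window and averaged across days.

Window-attribution convention: sleep *minutes* are credited to the window
they occur in, so minute totals are conserved; an *episode* is counted
(with its full duration) in the window containing its first minute. Runs
touching the edges of the recording count as episodes when long enough.
Missing minutes break inactivity runs — they never fabricate sleep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MIN_SLEEP_MINUTES = 5
DAY_MINUTES = 1440
HALF_DAY = 720

__all__ = [
    "SleepRecord",
    "PeriodMetrics",
    "score_sleep",
    "sleep_profile_binned",
    "period_architecture",
    "activity_while_awake",
    "average_across_days",
    "METRIC_COLUMNS",
]


@dataclass(frozen=True)
class SleepRecord:
    """Scored sleep for one fly: per-minute boolean vector plus episodes.

    episodes is a list of (start_minute_index, duration_minutes), each
    a maximal zero-activity run of length >= 5.
    """

    fly_id: str
    sleep: np.ndarray  # bool, aligned to the activity minutes
    episodes: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        total = int(np.sum(self.sleep))
        ep_total = sum(d for _, d in self.episodes)
        if total != ep_total:
            raise ValueError(
                f"episode durations ({ep_total}) inconsistent with sleep "
                f"vector ({total})"
            )


@dataclass
class PeriodMetrics:
    """Sleep architecture of one fly over one 12-hr light/dark window."""

    fly_id: str
    day_index: int
    light: str  # "L" or "D"
    total_sleep_min: float
    n_episodes: int
    mean_episode_min: float  # NaN when no episodes start in the window
    max_episode_min: float  # NaN when no episodes start in the window
    activity_while_awake: float  # NaN when no waking minutes
    complete: bool = True


METRIC_COLUMNS = (
    "total_sleep_min",
    "n_episodes",
    "mean_episode_min",
    "max_episode_min",
    "activity_while_awake",
)


def _zero_runs(is_zero: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean vector, as (start, length)."""
    if is_zero.size == 0:
        return []
    padded = np.concatenate([[False], is_zero, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def score_sleep(
    counts: Sequence[int],
    missing_mask: np.ndarray | None = None,
    fly_id: str = "",
    min_minutes: int = MIN_SLEEP_MINUTES,
) -> SleepRecord:
    """Score sleep from minute activity counts by the >=5-min zero-run rule.

    A minute is sleep iff it lies in a maximal run of consecutive
    zero-count minutes of length >= min_minutes. Missing minutes (where
    missing_mask is True) break runs and are never scored as sleep.
    """
    c = np.asarray(counts)
    if c.size and np.any(c < 0):
        raise ValueError("activity counts must be non-negative")
    inactive = c == 0
    if missing_mask is not None:
        mask = np.asarray(missing_mask, dtype=bool)
        if mask.shape != inactive.shape:
            raise ValueError("missing_mask shape mismatch")
        inactive = inactive & ~mask
    episodes = [(s, d) for s, d in _zero_runs(inactive) if d >= min_minutes]
    sleep = np.zeros(c.size, dtype=bool)
    for s, d in episodes:
        sleep[s : s + d] = True
    return SleepRecord(fly_id=fly_id, sleep=sleep, episodes=tuple(episodes))


def sleep_profile_binned(
    record: SleepRecord,
    timeline: pd.DataFrame,
    bin_minutes: int = 30,
) -> pd.DataFrame:
    """Sleep minutes per ZT-aligned bin, one row per (day_index, bin).

    bin_minutes must divide 1440 and the recording must start at a bin
    boundary (ZT-aligned), so bins never straddle days. Columns:
    day_index, bin_index, zt_start_min, sleep_min.
    """
    if DAY_MINUTES % bin_minutes != 0:
        raise ValueError(f"bin_minutes={bin_minutes} does not divide 1440")
    zt = timeline["zt_minute"].to_numpy()
    if len(zt) != record.sleep.size:
        raise ValueError("timeline length does not match sleep vector")
    if len(zt) and zt[0] % bin_minutes != 0:
        raise ValueError("recording does not start on a bin boundary")
    df = pd.DataFrame(
        {
            "day_index": timeline["day_index"].to_numpy(),
            "bin_index": zt // bin_minutes,
            "sleep": record.sleep.astype(int),
        }
    )
    out = (
        df.groupby(["day_index", "bin_index"], as_index=False)["sleep"]
        .sum()
        .rename(columns={"sleep": "sleep_min"})
    )
    out["zt_start_min"] = out["bin_index"] * bin_minutes
    return out[["day_index", "bin_index", "zt_start_min", "sleep_min"]]


def _window_indices(
    timeline: pd.DataFrame, day_index: int, light: str
) -> np.ndarray:
    sel = (timeline["day_index"].to_numpy() == day_index) & (
        timeline["light"].to_numpy() == light
    )
    return np.nonzero(sel)[0]


def activity_while_awake(
    counts: Sequence[int],
    record: SleepRecord,
    window_idx: np.ndarray,
    missing_mask: np.ndarray | None = None,
) -> float:
    """Beam-break counts per waking minute inside a window.

    NaN when the window contains no waking minutes (never zero): a fully
    asleep fly has undefined waking activity, not zero activity.
    """
    c = np.asarray(counts)
    awake = ~record.sleep[window_idx]
    if missing_mask is not None:
        awake &= ~np.asarray(missing_mask, dtype=bool)[window_idx]
    n_awake = int(np.sum(awake))
    if n_awake == 0:
        return float("nan")
    return float(np.sum(c[window_idx][awake]) / n_awake)


def period_architecture(
    record: SleepRecord,
    counts: Sequence[int],
    timeline: pd.DataFrame,
    day_index: int,
    light: str,
    missing_mask: np.ndarray | None = None,
) -> PeriodMetrics:
    """Architecture metrics for one 12-hr window of one day.

    total_sleep_min counts in-window sleep minutes (boundary-spanning
    episodes contribute only their in-window part); episode statistics
    use full durations of episodes starting inside the window.
    """
    idx = _window_indices(timeline, day_index, light)
    if idx.size == 0:
        raise ValueError(f"window (day {day_index}, {light}) not in timeline")
    complete = idx.size == HALF_DAY
    total_sleep = int(np.sum(record.sleep[idx]))
    lo, hi = int(idx[0]), int(idx[-1])
    starts_in = [(s, d) for s, d in record.episodes if lo <= s <= hi]
    n_ep = len(starts_in)
    durs = [d for _, d in starts_in]
    return PeriodMetrics(
        fly_id=record.fly_id,
        day_index=day_index,
        light=light,
        total_sleep_min=float(total_sleep),
        n_episodes=n_ep,
        mean_episode_min=float(np.mean(durs)) if durs else float("nan"),
        max_episode_min=float(max(durs)) if durs else float("nan"),
        activity_while_awake=activity_while_awake(
            counts, record, idx, missing_mask
        ),
        complete=complete,
    )


def all_period_metrics(
    record: SleepRecord,
    counts: Sequence[int],
    timeline: pd.DataFrame,
    missing_mask: np.ndarray | None = None,
) -> list[PeriodMetrics]:
    """period_architecture over every (day, L/D) window in the timeline."""
    pairs = (
        timeline[["day_index", "light"]]
        .drop_duplicates()
        .sort_values(["day_index", "light"], ascending=[True, False])
    )
    return [
        period_architecture(
            record, counts, timeline, int(day), str(light), missing_mask
        )
        for day, light in pairs.itertuples(index=False)
    ]


def average_across_days(
    metrics: Iterable[PeriodMetrics],
    which_days: Sequence[int] | None = None,
    light: str | None = None,
    include_partial: bool = False,
) -> dict[str, float]:
    """Per-fly day-averaged metrics over selected complete windows.

    Missing (NaN) values are excluded metric-wise; a metric missing on
    every selected day stays NaN. Raises if no window is selected.
    """
    rows = [
        m
        for m in metrics
        if (which_days is None or m.day_index in which_days)
        and (light is None or m.light == light)
        and (include_partial or m.complete)
    ]
    if not rows:
        raise ValueError("no complete windows selected for day averaging")
    out: dict[str, float] = {"n_days": float(len(rows))}
    for col in METRIC_COLUMNS:
        vals = np.array([getattr(m, col) for m in rows], dtype=float)
        vals = vals[~np.isnan(vals)]
        out[col] = float(np.mean(vals)) if vals.size else float("nan")
    return out


def metrics_to_frame(metrics: Iterable[PeriodMetrics]) -> pd.DataFrame:
    """Tidy DataFrame of PeriodMetrics rows."""
    return pd.DataFrame(
        [
            {
                "fly_id": m.fly_id,
                "day_index": m.day_index,
                "light": m.light,
                **{col: getattr(m, col) for col in METRIC_COLUMNS},
                "complete": m.complete,
            }
            for m in metrics
        ]
    )
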