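"""Trikinetics DAM monitor file parsing and experimental-timeline annotation.

A DAM (Drosophila Activity Monitor) file is tab-delimited text with one
row per minute: a block of metadata fields (record index, date, time,
status code, ...) followed by 32 integer beam-break counts, one per
channel. The default dialect expects 10 metadata fields, date as
``D Mon YY`` and time as ``HH:MM:SS`` in fields 2-3, and status code 1
for a valid reading; DAMSystem versions differ, so the dialect is
explicit configuration rather than sniffed.

Timestamp gaps are an error by default: silently zero-filling a gap
would fabricate sleep. Gap-tolerant mode fills gaps with zero counts
plus a missing mask that downstream scoring excludes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

N_CHANNELS = 32
DAY_MINUTES = 1440
HALF_DAY = 720

__all__ = [
    "DamDialect",
    "ExperimentDesign",
    "ChannelSeries",
    "DamParseError",
    "TimelineError",
    "CoverageError",
    "parse_dam_file",
    "parse_dam_files",
    "annotate_timeline",
    "filter_dead_flies",
    "series_to_frame",
]


class DamParseError(ValueError):
    """Malformed DAM file content (field counts, non-integer counts)."""


class TimelineError(ValueError):
    """Non-monotone or gapped timestamps."""


class CoverageError(ValueError):
    """Experiment design not covered by the recording."""


@dataclass(frozen=True)
class DamDialect:
    """DAM file format options.

    n_metadata: fields preceding the 32 counts. valid_status: the status
    code of a good reading; rows with other codes are dropped or raise
    per on_bad_status. date/time field positions are 0-based indices
    into the metadata block.
    """

    n_metadata: int = 10
    date_field: int = 1
    time_field: int = 2
    status_field: int = 3
    valid_status: int = 1
    on_bad_status: str = "drop"  # "drop" | "error"
    on_gap: str = "error"  # "error" | "fill"
    date_format: str = "%d %b %y"


@dataclass(frozen=True)
class ExperimentDesign:
    """Lights-on time, phase schedule, and channel-to-fly mapping.

    phase_schedule: ordered (phase_label, n_days, temperature_c) blocks;
    channel_map: 1-based channel number -> (fly_id, genotype, role) with
    role in {experimental, gal4_control, uas_control}.
    """

    lights_on: time
    phase_schedule: tuple[tuple[str, int, float], ...]
    channel_map: Mapping[int, tuple[str, str, str]]

    ROLES = ("experimental", "gal4_control", "uas_control")

    def __post_init__(self) -> None:
        labels = [p[0] for p in self.phase_schedule]
        if len(labels) != len(set(labels)):
            raise ValueError("phase labels must be unique")
        for ch, (fly, geno, role) in self.channel_map.items():
            if ch < 1:
                raise ValueError(f"channel {ch} must be >= 1")
            if role not in self.ROLES:
                raise ValueError(f"unknown role {role!r} for fly {fly!r}")

    @property
    def n_monitors(self) -> int:
        """Monitors needed: global channel k lives on monitor (k-1)//32."""
        if not self.channel_map:
            return 1
        return (max(self.channel_map) + N_CHANNELS - 1) // N_CHANNELS

    @property
    def n_days(self) -> int:
        return sum(n for _, n, _ in self.phase_schedule)

    def phase_of_day(self, day_index: int) -> str:
        d = day_index
        for label, n, _ in self.phase_schedule:
            if d < n:
                return label
            d -= n
        raise CoverageError(
            f"day_index {day_index} beyond the {self.n_days}-day schedule"
        )


@dataclass
class ChannelSeries:
    """One fly's minute-resolution counts with timeline annotations.

    timeline columns: timestamp, zt_minute (0..1439, 0 at lights-on),
    light ("L" for zt < 720 else "D"), phase, day_index.
    """

    fly_id: str
    genotype: str
    role: str
    minutes: np.ndarray
    timeline: pd.DataFrame
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.timeline) != self.minutes.size:
            raise ValueError("minutes and timeline length mismatch")


def parse_dam_file(
    text: str, dialect: DamDialect = DamDialect()
) -> tuple[list[datetime], np.ndarray, np.ndarray]:
    """Parse DAM monitor text into timestamps and a (n_minutes, 32) matrix.

    Returns (timestamps, counts, missing_mask). With on_gap="fill",
    minute gaps are filled with zero counts flagged in missing_mask;
    otherwise any gap raises TimelineError. Rows whose status code is
    not valid_status are dropped or raise per the dialect.
    """
    timestamps: list[datetime] = []
    rows: list[list[int]] = []
    expected = dialect.n_metadata + N_CHANNELS
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != expected:
            raise DamParseError(
                f"line {lineno}: expected {expected} fields, got {len(fields)}"
            )
        meta = fields[: dialect.n_metadata]
        try:
            status = int(meta[dialect.status_field])
        except ValueError as exc:
            raise DamParseError(f"line {lineno}: bad status field") from exc
        if status != dialect.valid_status:
            if dialect.on_bad_status == "error":
                raise DamParseError(
                    f"line {lineno}: status code {status} "
                    f"(expected {dialect.valid_status})"
                )
            continue
        try:
            ts = datetime.strptime(
                f"{meta[dialect.date_field]} {meta[dialect.time_field]}",
                f"{dialect.date_format} %H:%M:%S",
            )
        except ValueError as exc:
            raise DamParseError(f"line {lineno}: bad timestamp") from exc
        try:
            counts = [int(v) for v in fields[dialect.n_metadata :]]
        except ValueError as exc:
            raise DamParseError(
                f"line {lineno}: non-integer count field"
            ) from exc
        if any(c < 0 for c in counts):
            raise DamParseError(f"line {lineno}: negative count")
        timestamps.append(ts)
        rows.append(counts)

    if not timestamps:
        return [], np.zeros((0, N_CHANNELS), dtype=int), np.zeros(0, dtype=bool)

    out_ts: list[datetime] = [timestamps[0]]
    out_rows: list[list[int]] = [rows[0]]
    missing: list[bool] = [False]
    one_min = timedelta(minutes=1)
    for ts, row in zip(timestamps[1:], rows[1:]):
        prev = out_ts[-1]
        if ts <= prev:
            raise TimelineError(f"non-monotone timestamp at {ts}")
        gap = int((ts - prev) / one_min) - 1
        if gap > 0:
            if dialect.on_gap == "error":
                raise TimelineError(
                    f"{gap}-minute gap between {prev} and {ts}"
                )
            for k in range(1, gap + 1):
                out_ts.append(prev + k * one_min)
                out_rows.append([0] * N_CHANNELS)
                missing.append(True)
        out_ts.append(ts)
        out_rows.append(row)
        missing.append(False)

    return out_ts, np.asarray(out_rows, dtype=int), np.asarray(missing)


def parse_dam_files(
    texts: Sequence[str], dialect: DamDialect = DamDialect()
) -> tuple[list[datetime], np.ndarray, np.ndarray]:
    """Parse several monitor files of one experiment side by side.

    Monitor i contributes global channels 32*i+1 .. 32*(i+1). All files
    must share identical timestamps. A row is flagged missing if it was
    gap-filled in any monitor.
    """
    if not texts:
        raise ValueError("no monitor files given")
    parsed = [parse_dam_file(t, dialect) for t in texts]
    ts0 = parsed[0][0]
    for ts, _, _ in parsed[1:]:
        if ts != ts0:
            raise TimelineError("monitor files have mismatched timestamps")
    counts = np.hstack([p[1] for p in parsed])
    missing = np.any(np.stack([p[2] for p in parsed]), axis=0) if ts0 else (
        np.zeros(0, dtype=bool)
    )
    return ts0, counts, missing


def build_timeline(
    timestamps: Sequence[datetime], design: ExperimentDesign
) -> pd.DataFrame:
    """Per-minute ZT/light/phase/day annotations for a timestamp vector.

    Day 0 starts at the lights-on transition on or before the first
    timestamp; zt_minute = 0 at lights-on, light is "L" on the half-open
    window [0, 720) and "D" on [720, 1440).
    """
    if not timestamps:
        return pd.DataFrame(
            columns=["timestamp", "zt_minute", "light", "phase", "day_index"]
        )
    first = timestamps[0]
    anchor = datetime.combine(first.date(), design.lights_on)
    if anchor > first:
        anchor -= timedelta(days=1)
    elapsed = np.array(
        [int((ts - anchor).total_seconds() // 60) for ts in timestamps]
    )
    zt = elapsed % DAY_MINUTES
    day = elapsed // DAY_MINUTES
    max_day = int(day.max())
    if max_day >= design.n_days:
        raise CoverageError(
            f"recording spans day index {max_day} but the schedule covers "
            f"{design.n_days} day(s)"
        )
    phases = [design.phase_of_day(int(d)) for d in day]
    return pd.DataFrame(
        {
            "timestamp": list(timestamps),
            "zt_minute": zt,
            "light": np.where(zt < HALF_DAY, "L", "D"),
            "phase": phases,
            "day_index": day,
        }
    )


def annotate_timeline(
    timestamps: Sequence[datetime],
    counts: np.ndarray,
    design: ExperimentDesign,
    missing_mask: np.ndarray | None = None,
) -> list[ChannelSeries]:
    """Attach the experimental timeline to every mapped channel.

    Unmapped channels are omitted. The recording must fit inside the
    design's phase schedule (CoverageError otherwise).
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[1] % N_CHANNELS != 0:
        raise ValueError(f"counts must be (n, k*{N_CHANNELS})")
    if design.channel_map and max(design.channel_map) > counts.shape[1]:
        raise ValueError(
            f"channel map references channel {max(design.channel_map)} but "
            f"only {counts.shape[1]} channels are present"
        )
    if counts.shape[0] != len(timestamps):
        raise ValueError("timestamps and counts length mismatch")
    n_schedule_min = design.n_days * DAY_MINUTES
    if counts.shape[0] < n_schedule_min:
        missing_days = [
            d
            for d in range(design.n_days)
            if d * DAY_MINUTES >= counts.shape[0]
        ]
        raise CoverageError(
            f"recording has {counts.shape[0]} minutes but the schedule needs "
            f"{n_schedule_min}; days {missing_days} are absent"
        )
    timeline = build_timeline(timestamps, design)
    out = []
    for ch in sorted(design.channel_map):
        fly_id, genotype, role = design.channel_map[ch]
        out.append(
            ChannelSeries(
                fly_id=fly_id,
                genotype=genotype,
                role=role,
                minutes=counts[:, ch - 1].copy(),
                timeline=timeline,
                missing_mask=None
                if missing_mask is None
                else np.asarray(missing_mask, dtype=bool),
            )
        )
    return out


def filter_dead_flies(
    series: Sequence[ChannelSeries], window_hours: float = 24.0
) -> tuple[list[ChannelSeries], pd.DataFrame]:
    """Drop flies with zero activity over the final window_hours.

    A dead fly stops breaking the beam, so trailing all-zero activity is
    the standard actigraphy exclusion. Returns (retained, report) where
    report lists excluded fly_ids with the reason.
    """
    window = int(round(window_hours * 60))
    retained: list[ChannelSeries] = []
    excluded: list[dict] = []
    for s in series:
        if window > s.minutes.size:
            raise ValueError(
                f"window_hours={window_hours} exceeds recording length"
            )
        tail = s.minutes[-window:]
        if tail.sum() == 0:
            excluded.append(
                {
                    "fly_id": s.fly_id,
                    "genotype": s.genotype,
                    "reason": f"zero counts over final {window_hours} h",
                }
            )
        else:
            retained.append(s)
    report = pd.DataFrame(excluded, columns=["fly_id", "genotype", "reason"])
    return retained, report


def series_to_frame(series: Sequence[ChannelSeries]) -> pd.DataFrame:
    """Tidy per-minute table across flies (fly_id, timestamp, ..., counts)."""
    frames = []
    for s in series:
        df = s.timeline.copy()
        df.insert(0, "fly_id", s.fly_id)
        df["counts"] = s.minutes
        if s.missing_mask is not None:
            df["missing"] = s.missing_mask
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
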