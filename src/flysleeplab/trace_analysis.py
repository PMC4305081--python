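"""ROI fluorescence trace analysis: dF/F, FRET ratios, response extraction.

Intensity sensors (GCaMP, synapto-pHluorin, Arclight) are quantified as
percent fluorescence change dF/F = (Fn - F0)/F0 x 100 with F0 the first
frame. The per-trace response is the extremum of that series with
sensor-appropriate polarity: maximum for sensors that brighten with
signal, minimum for Arclight, whose fluorescence falls on
depolarization.

Ratiometric FRET sensors (Epac1-camps for cAMP, SuperClomeleon for
chloride) lose FRET on ligand binding: donor (CFP) emission rises,
acceptor (YFP) emission falls. The per-frame CFP/YFP ratio normalized
to the first frame therefore reads positive for rising signal, and is
reported as a percent change; the raw YFP/CFP orientation is available
as an option.

Group comparisons follow a gated scheme: a Kruskal-Wallis test across
the experimental group and the negative controls, with pairwise
Mann-Whitney tests against each control only when the omnibus test is
significant, reporting the most conservative pairwise p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import conservative_p, kruskal_wallis, mann_whitney_u, mean_sem

__all__ = [
    "FluorTrace",
    "ResponseStat",
    "SENSOR_POLARITY",
    "compute_dff",
    "extract_max_response",
    "fret_ratio_trace",
    "group_response_summary",
]

# positive_up: signal raises fluorescence (report the series maximum);
# negative_up: signal lowers it (report the minimum; Arclight).
SENSOR_POLARITY: dict[str, str] = {
    "GCaMP": "positive_up",
    "SpH": "positive_up",
    "Arclight": "negative_up",
    "EPAC": "positive_up",
    "SuperClomeleon": "positive_up",
    "other": "positive_up",
}


@dataclass
class FluorTrace:
    """One ROI's fluorescence time series (1 or 2 channels).

    values has shape (n_frames,) for intensity sensors or (2, n_frames)
    for FRET pairs with row 0 = donor CFP, row 1 = acceptor YFP.
    """

    roi_id: str
    sensor: str
    values: np.ndarray
    sample_rate: float = 2.0
    stimulus_onset_s: float = 30.0
    stimulus_duration_s: float = 30.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (1, 2):
            raise ValueError("values must be 1-D or (2, n) 2-D")
        if self.values.ndim == 2 and self.values.shape[0] != 2:
            raise ValueError("two-channel trace must have shape (2, n)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite intensity values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[-1]

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sample_rate


@dataclass(frozen=True)
class ResponseStat:
    roi_id: str
    polarity: str
    max_change_pct: float
    percent_change_series: np.ndarray = field(repr=False, default=None)


def compute_dff(trace: FluorTrace, f0_mode: str = "first") -> np.ndarray:
    """Percent fluorescence change series for a single-channel trace.

    f0_mode "first" uses the first frame as F0 (so the series starts at
    exactly 0); "prestim_mean" averages all frames before stimulus
    onset. F0 must be positive.
    """
    if trace.values.ndim != 1:
        raise ValueError("compute_dff expects a single-channel trace")
    f = trace.values
    if f0_mode == "first":
        f0 = f[0]
    elif f0_mode == "prestim_mean":
        n_pre = int(round(trace.stimulus_onset_s * trace.sample_rate))
        if n_pre < 1:
            raise ValueError("no pre-stimulus frames for prestim_mean")
        f0 = float(np.mean(f[:n_pre]))
    else:
        raise ValueError(f"unknown f0_mode {f0_mode!r}")
    if f0 <= 0:
        raise ValueError(f"F0 must be positive, got {f0}")
    return (f - f0) / f0 * 100.0


def extract_max_response(
    series: np.ndarray,
    polarity: str = "positive_up",
    search_window: tuple[float, float] | None = None,
    sample_rate: float = 2.0,
) -> float:
    """Signed extremum of a percent-change series.

    polarity positive_up takes the maximum, negative_up the minimum
    (for sensors whose fluorescence falls with signal). By default the
    whole recording is searched; search_window=(t0, t1) in seconds
    restricts it.
    """
    s = np.asarray(series, dtype=float)
    if s.size == 0:
        raise ValueError("empty series")
    if search_window is not None:
        lo = int(np.floor(search_window[0] * sample_rate))
        hi = int(np.ceil(search_window[1] * sample_rate))
        s = s[max(lo, 0) : hi]
        if s.size == 0:
            raise ValueError("search_window excludes every frame")
    if polarity == "positive_up":
        return float(np.max(s))
    if polarity == "negative_up":
        return float(np.min(s))
    raise ValueError(f"unknown polarity {polarity!r}")


def fret_ratio_trace(
    trace: FluorTrace, orientation: str = "cfp_over_yfp"
) -> np.ndarray:
    """Normalized FRET ratio series as percent change from the first frame.

    Default orientation cfp_over_yfp: r = CFP/YFP, series =
    100 * (r/r0 - 1), which reads positive when the sensed signal rises
    (FRET loss raises CFP and lowers YFP). orientation "yfp_over_cfp"
    emits the raw FRET-ratio orientation instead.
    """
    if trace.values.ndim != 2:
        raise ValueError("fret_ratio_trace expects a two-channel trace")
    cfp, yfp = trace.values
    if np.any(cfp <= 0) or np.any(yfp <= 0):
        raise ValueError("channel intensities must be positive")
    if orientation == "cfp_over_yfp":
        r = cfp / yfp
    elif orientation == "yfp_over_cfp":
        r = yfp / cfp
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return 100.0 * (r / r[0] - 1.0)


def analyze_trace(
    trace: FluorTrace,
    f0_mode: str = "first",
    search_window: tuple[float, float] | None = None,
    orientation: str = "cfp_over_yfp",
) -> ResponseStat:
    """Percent-change series and polarity-aware response for one ROI."""
    if trace.values.ndim == 2:
        series = fret_ratio_trace(trace, orientation)
        polarity = "positive_up"
    else:
        series = compute_dff(trace, f0_mode)
        polarity = SENSOR_POLARITY.get(trace.sensor, "positive_up")
    peak = extract_max_response(
        series, polarity, search_window, trace.sample_rate
    )
    return ResponseStat(trace.roi_id, polarity, peak, series)


def group_response_summary(
    responses: Mapping[str, Sequence[float]],
    experimental: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group means +/- SEM with the Kruskal-Wallis-gated pairwise scheme.

    responses maps condition label -> per-ROI max response values;
    `experimental` names the experimental condition, every other key is
    a negative control. Pairwise Mann-Whitney tests (experimental vs
    each control) run only when the omnibus KW p < alpha. Returns one
    row per condition with mean, sem, n, kw_p, pairwise p (NaN for the
    experimental row and when gated off), and the conservative
    (greatest) pairwise p on every row when tests ran.
    """
    if experimental not in responses:
        raise ValueError(f"experimental group {experimental!r} not present")
    if len(responses) < 2:
        raise ValueError("need the experimental group and >= 1 control")
    for label, vals in responses.items():
        if len(vals) == 0:
            raise ValueError(f"empty group: {label}")
    labels = [experimental] + [k for k in responses if k != experimental]
    kw = kruskal_wallis([responses[k] for k in labels])
    pairwise: dict[str, float] = {}
    if kw.p_value < alpha:
        for label in labels[1:]:
            pairwise[label] = mann_whitney_u(
                responses[experimental], responses[label]
            ).p_value
    cons = conservative_p(list(pairwise.values())) if pairwise else float("nan")
    rows = []
    for label in labels:
        mean, sem = mean_sem(responses[label])
        rows.append(
            {
                "condition": label,
                "role": "experimental" if label == experimental else "control",
                "n": len(responses[label]),
                "mean_max_change_pct": mean,
                "sem": sem,
                "kw_p": kw.p_value,
                "pairwise_p": pairwise.get(label, float("nan")),
                "conservative_p": cons,
            }
        )
    return pd.DataFrame(rows)


def traces_from_frame(
    df: pd.DataFrame,
    sensor: str,
    sample_rate: float = 2.0,
    stimulus_onset_s: float = 30.0,
    stimulus_duration_s: float = 30.0,
) -> list[FluorTrace]:
    """Build FluorTrace objects from a tidy CSV table.

    Expected columns: roi_id, frame, intensity, and optionally channel
    (values "CFP"/"YFP" mark a two-channel FRET recording).
    """
    traces = []
    has_channel = "channel" in df.columns and df["channel"].notna().any()
    for roi_id, grp in df.groupby("roi_id", sort=True):
        grp = grp.sort_values("frame")
        if has_channel:
            cfp = grp[grp["channel"] == "CFP"]["intensity"].to_numpy()
            yfp = grp[grp["channel"] == "YFP"]["intensity"].to_numpy()
            if cfp.size != yfp.size or cfp.size == 0:
                raise ValueError(f"ROI {roi_id}: unmatched CFP/YFP frames")
            values = np.stack([cfp, yfp])
        else:
            values = grp["intensity"].to_numpy()
        traces.append(
            FluorTrace(
                roi_id=str(roi_id),
                sensor=sensor,
                values=values,
                sample_rate=sample_rate,
                stimulus_onset_s=stimulus_onset_s,
                stimulus_duration_s=stimulus_duration_s,
            )
        )
    return traces
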