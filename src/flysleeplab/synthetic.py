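"""Synthetic data generators with known ground truth.

Every pipeline stage can be exercised without external data:

* ``simulate_dam_experiment`` emits a Trikinetics-format monitor file
  from a per-minute two-state (wake/sleep) Markov chain per fly. Sleep
  minutes emit zero counts; wake minutes emit Poisson counts, so some
  wake minutes are coincidentally inactive, exactly the ambiguity the
  5-minute scoring rule faces on real data. The ground-truth bundle
  reports both the latent sleep states and the rule-scored sleep of the
  emitted counts, so estimator error and scoring-rule behavior can be
  told apart.
* ``simulate_fluorescence_trace`` builds ROI traces as baseline x
  optional photobleach decay x (1 +/- A/100 * kernel) + noise, with a
  double-exponential response kernel normalized so its sampled peak is
  exactly 1 — a noiseless trace recovers the programmed amplitude
  exactly.
* ``simulate_image_pair`` builds two-channel stacks from shared
  (colocalized) Gaussian blobs, channel-private blobs, a smooth
  background gradient and noise, with a per-pixel truth label map.

Effects in the sleep simulator (e.g. "90 minutes of night sleep lost on
shift days") are programmed by solving for the wake-to-sleep rate that
moves the chain's stationary sleep fraction by the target amount; the
mapping is exact for the stationary fraction, and finite-day realized
sleep fluctuates around it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, time, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dam_io import DAY_MINUTES, HALF_DAY, N_CHANNELS, ExperimentDesign
from .sleep_core import score_sleep
from .trace_analysis import FluorTrace

__all__ = [
    "SleepRates",
    "SleepSimParams",
    "DamSimResult",
    "TraceSimParams",
    "ImageSimParams",
    "rates_with_sleep_shift",
    "make_tempshift_params",
    "simulate_dam_experiment",
    "simulate_fluorescence_trace",
    "simulate_image_pair",
]


@dataclass(frozen=True)
class SleepRates:
    """Per-minute Markov rates for one (genotype, phase, light) cell.

    p_ws: wake->sleep transition probability per minute; p_sw:
    sleep->wake; lambda_wake: mean Poisson beam-break counts per waking
    minute. Stationary sleep fraction is p_ws / (p_ws + p_sw).
    """

    p_ws: float
    p_sw: float
    lambda_wake: float = 2.0

    def __post_init__(self) -> None:
        for name in ("p_ws", "p_sw"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.lambda_wake <= 0:
            raise ValueError("lambda_wake must be positive")

    @property
    def sleep_fraction(self) -> float:
        tot = self.p_ws + self.p_sw
        return self.p_ws / tot if tot > 0 else 0.0


# Realistic wild-type-like defaults: ~520 min night sleep (mean bout
# ~15 min), ~200 min day sleep (mean bout ~10 min). Within-fly
# window-to-window variability under these rates gives baseline-
# subtracted delta SDs near 40 min, matching the repeatability the
# paired-baseline design assumes.
DEFAULT_NIGHT = SleepRates(p_ws=0.1707, p_sw=0.0667, lambda_wake=2.0)
DEFAULT_DAY = SleepRates(p_ws=0.0389, p_sw=0.1, lambda_wake=2.0)


def rates_with_sleep_shift(base: SleepRates, delta_min: float) -> SleepRates:
    """Rates whose stationary sleep fraction differs by delta_min/720.

    Keeps p_sw (bout-ending rate) fixed and solves p_ws for the target
    fraction, so the effect changes sleep amount primarily through
    sleep initiation. Raises if the target fraction leaves (0, 1).
    """
    target = base.sleep_fraction + delta_min / HALF_DAY
    if not 0.0 < target < 1.0:
        raise ValueError(
            f"target sleep fraction {target:.3f} outside (0, 1)"
        )
    p_ws = target * base.p_sw / (1.0 - target)
    if p_ws > 1.0:
        raise ValueError("required p_ws exceeds 1; reduce delta_min")
    return replace(base, p_ws=p_ws)


@dataclass
class SleepSimParams:
    """Cohort layout and Markov rates for a DAM simulation.

    genotypes maps genotype -> role (experimental / gal4_control /
    uas_control); rates maps (genotype, phase_label, light) -> rates.
    deaths maps fly_id -> minute index after which the fly emits no
    counts (emulating death in the monitor).
    """

    genotypes: Mapping[str, str]
    n_flies: int
    rates: Mapping[tuple[str, str, str], SleepRates]
    deaths: Mapping[str, int] = field(default_factory=dict)

    def rate_for(self, genotype: str, phase: str, light: str) -> SleepRates:
        try:
            return self.rates[(genotype, phase, light)]
        except KeyError:
            raise KeyError(
                f"no rates for ({genotype!r}, {phase!r}, {light!r})"
            ) from None


@dataclass
class DamSimResult:
    """Simulated monitor file(s) plus the complete ground truth.

    texts holds one DAM file per 32-channel monitor; global channel k
    lives on monitor (k-1)//32 as local channel ((k-1) % 32) + 1.
    """

    texts: list[str]
    design: ExperimentDesign
    timestamps: list[datetime]
    counts: np.ndarray  # (n_minutes, 32)
    fly_ids: list[str]
    fly_channels: dict[str, int]
    latent_sleep: dict[str, np.ndarray]  # bool per minute
    truth_windows: pd.DataFrame
    expected_sleep_fraction: pd.DataFrame

    @property
    def text(self) -> str:
        if len(self.texts) != 1:
            raise ValueError("multi-monitor simulation; use .texts")
        return self.texts[0]


def _phase_by_day(design: ExperimentDesign) -> list[str]:
    return [design.phase_of_day(d) for d in range(design.n_days)]


def make_tempshift_params(
    n_flies: int = 16,
    night_effect_min: float = -90.0,
    day_effect_min: float = 0.0,
    heat_night_min: float = -30.0,
    heat_day_min: float = 40.0,
    night: SleepRates = DEFAULT_NIGHT,
    day: SleepRates = DEFAULT_DAY,
    phases: Sequence[tuple[str, int, float]] = (
        ("baseline", 1, 22.0),
        ("shift", 1, 31.0),
    ),
) -> tuple[SleepSimParams, ExperimentDesign]:
    """Standard three-genotype temperature-shift experiment.

    All genotypes share baseline rates and a genotype-independent heat
    response on shift days (heat_day_min / heat_night_min, emulating
    the strong temperature sensitivity of fly sleep); the experimental
    genotype additionally gets the programmed night/day effect. Channel
    assignment is experimental first, gal4 control next, uas control
    last, on consecutive global channels; cohorts beyond 32 flies span
    additional monitors.
    """
    genotypes = {
        "exp": "experimental",
        "gal4": "gal4_control",
        "uas": "uas_control",
    }
    rates: dict[tuple[str, str, str], SleepRates] = {}
    phase_labels = [p[0] for p in phases]
    for geno in genotypes:
        for phase_label in phase_labels:
            if phase_label == "baseline" or phase_label == "recovery":
                rates[(geno, phase_label, "L")] = day
                rates[(geno, phase_label, "D")] = night
            else:  # heated phase
                d_l = heat_day_min + (day_effect_min if geno == "exp" else 0.0)
                d_d = heat_night_min + (
                    night_effect_min if geno == "exp" else 0.0
                )
                rates[(geno, phase_label, "L")] = rates_with_sleep_shift(day, d_l)
                rates[(geno, phase_label, "D")] = rates_with_sleep_shift(
                    night, d_d
                )
    channel_map = {}
    ch = 1
    for geno, role in genotypes.items():
        for i in range(n_flies):
            channel_map[ch] = (f"{geno}_{i:02d}", geno, role)
            ch += 1
    design = ExperimentDesign(
        lights_on=time(8, 0),
        phase_schedule=tuple(phases),
        channel_map=channel_map,
    )
    params = SleepSimParams(
        genotypes=genotypes, n_flies=n_flies, rates=rates
    )
    return params, design


def _simulate_counts(
    params: SleepSimParams,
    design: ExperimentDesign,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[str], dict[str, int]]:
    """Markov simulation for all mapped flies.

    Returns (counts (n_min, 32 * n_monitors), latent asleep
    (n_min, n_flies), fly_ids, fly->channel). The recording starts at
    lights-on of day 0.
    """
    n_min = design.n_days * DAY_MINUTES
    n_cols = design.n_monitors * N_CHANNELS
    channels = sorted(design.channel_map)
    fly_ids = [design.channel_map[ch][0] for ch in channels]
    genotypes = [design.channel_map[ch][1] for ch in channels]
    n_flies = len(channels)
    phases = _phase_by_day(design)

    # per-fly per-minute rate arrays
    p_ws = np.empty((n_min, n_flies))
    p_sw = np.empty((n_min, n_flies))
    lam = np.empty((n_min, n_flies))
    for d in range(design.n_days):
        for half, light in ((0, "L"), (1, "D")):
            sl = slice(
                d * DAY_MINUTES + half * HALF_DAY,
                d * DAY_MINUTES + (half + 1) * HALF_DAY,
            )
            for j, geno in enumerate(genotypes):
                r = params.rate_for(geno, phases[d], light)
                p_ws[sl, j] = r.p_ws
                p_sw[sl, j] = r.p_sw
                lam[sl, j] = r.lambda_wake

    asleep = np.zeros((n_min, n_flies), dtype=bool)
    counts = np.zeros((n_min, n_cols), dtype=int)
    ch_idx = np.asarray(channels) - 1
    state = rng.random(n_flies) < p_ws[0] / np.maximum(p_ws[0] + p_sw[0], 1e-12)
    for t in range(n_min):
        asleep[t] = state
        wake = ~state
        c = np.zeros(n_flies, dtype=int)
        if wake.any():
            c[wake] = rng.poisson(lam[t, wake])
        counts[t, ch_idx] = c
        u = rng.random(n_flies)
        state = np.where(state, u >= p_sw[t], u < p_ws[t])

    for fly_id, death_min in params.deaths.items():
        if fly_id in fly_ids:
            j = fly_ids.index(fly_id)
            counts[death_min:, channels[j] - 1] = 0
            asleep[death_min:, j] = False
    return counts, asleep, fly_ids, dict(zip(fly_ids, channels))


def simulate_counts(
    params: SleepSimParams,
    design: ExperimentDesign,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, list[str], dict[str, int]]:
    """Markov simulation without file rendering (fast path).

    Returns (counts (n_min, 32), latent asleep (n_min, n_flies),
    fly_ids, fly->channel map).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return _simulate_counts(params, design, rng)


def _format_dam_text(
    timestamps: Sequence[datetime], counts: np.ndarray
) -> str:
    lines = []
    for i, (ts, row) in enumerate(zip(timestamps, counts), start=1):
        meta = [
            str(i),
            ts.strftime("%d %b %y"),
            ts.strftime("%H:%M:%S"),
            "1",  # status: valid
            "1", "0", "0", "0", "0", "0",  # unused device fields
        ]
        lines.append("\t".join(meta + [str(int(v)) for v in row]))
    return "\n".join(lines) + "\n"


def simulate_dam_experiment(
    params: SleepSimParams,
    design: ExperimentDesign,
    seed: int | np.random.Generator = 0,
    start_date: datetime | None = None,
) -> DamSimResult:
    """Simulate a full DAM experiment and render the monitor file.

    The emitted text round-trips bit-exactly through the parser. The
    truth table reports, per fly and 12-hr window, the latent sleep
    minutes and the 5-min-rule scored sleep of the emitted counts (the
    two differ where Poisson zeros merge or extend inactivity runs).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    counts, asleep, fly_ids, fly_channels = _simulate_counts(
        params, design, rng
    )
    n_min = counts.shape[0]
    if start_date is None:
        start_date = datetime(2024, 1, 1)
    t0 = datetime.combine(start_date.date(), design.lights_on)
    timestamps = [t0 + timedelta(minutes=k) for k in range(n_min)]
    texts = [
        _format_dam_text(
            timestamps, counts[:, m * N_CHANNELS : (m + 1) * N_CHANNELS]
        )
        for m in range(design.n_monitors)
    ]

    phases = _phase_by_day(design)
    rows = []
    for j, fly_id in enumerate(fly_ids):
        ch = fly_channels[fly_id]
        scored = score_sleep(counts[:, ch - 1], fly_id=fly_id)
        # the 5-min rule applied to the latent states themselves:
        # isolates Poisson-zero run merging from short-bout censoring
        rule_latent = score_sleep((~asleep[:, j]).astype(int))
        for d in range(design.n_days):
            for half, light in ((0, "L"), (1, "D")):
                sl = slice(
                    d * DAY_MINUTES + half * HALF_DAY,
                    d * DAY_MINUTES + (half + 1) * HALF_DAY,
                )
                geno = design.channel_map[ch][1]
                rows.append(
                    {
                        "fly_id": fly_id,
                        "genotype": geno,
                        "day_index": d,
                        "phase": phases[d],
                        "light": light,
                        "latent_sleep_min": int(asleep[sl, j].sum()),
                        "rule_latent_sleep_min": int(
                            rule_latent.sleep[sl].sum()
                        ),
                        "scored_sleep_min": int(scored.sleep[sl].sum()),
                    }
                )
    truth_windows = pd.DataFrame(rows)

    exp_rows = []
    for (geno, phase, light), r in params.rates.items():
        exp_rows.append(
            {
                "genotype": geno,
                "phase": phase,
                "light": light,
                "stationary_sleep_fraction": r.sleep_fraction,
                "expected_sleep_min": r.sleep_fraction * HALF_DAY,
            }
        )
    return DamSimResult(
        texts=texts,
        design=design,
        timestamps=timestamps,
        counts=counts,
        fly_ids=fly_ids,
        fly_channels=fly_channels,
        latent_sleep={
            fly_id: asleep[:, j].copy() for j, fly_id in enumerate(fly_ids)
        },
        truth_windows=truth_windows,
        expected_sleep_fraction=pd.DataFrame(exp_rows),
    )


@dataclass
class TraceSimParams:
    """Parameters for a simulated fluorescence recording.

    amplitude_pct is the response amplitude A as percent of baseline;
    polarity +1 brightens with signal, -1 dims (Arclight-like). For
    FRET pairs the donor (CFP) carries +A and the acceptor (YFP) -A.
    bleach_tau_s None disables photobleaching (recordings are
    pre-exposed to stabilize baseline); set a time constant to emulate
    residual bleaching.
    """

    n_frames: int = 240
    sample_rate: float = 2.0
    baseline: float = 1000.0
    amplitude_pct: float = 20.0
    polarity: int = 1
    stimulus_onset_s: float = 30.0
    stimulus_duration_s: float = 30.0
    rise_tau_s: float = 5.0
    decay_tau_s: float = 20.0
    noise_sd: float = 0.0
    bleach_tau_s: float | None = None
    fret_pair: bool = False
    sensor: str = "GCaMP"

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.n_frames < self.stimulus_onset_s * self.sample_rate:
            raise ValueError("recording shorter than the stimulus window")


def _response_kernel(p: TraceSimParams) -> np.ndarray:
    """Double-exponential kernel, 0 before onset, sampled peak exactly 1."""
    t = np.arange(p.n_frames) / p.sample_rate
    dt = t - p.stimulus_onset_s
    k = np.where(
        dt >= 0,
        np.exp(-dt / p.decay_tau_s) - np.exp(-dt / p.rise_tau_s),
        0.0,
    )
    peak = k.max()
    return k / peak if peak > 0 else k


def simulate_fluorescence_trace(
    params: TraceSimParams,
    seed: int | np.random.Generator = 0,
    roi_id: str = "roi_0",
) -> tuple[FluorTrace, dict]:
    """Simulate one ROI trace (single-channel or FRET pair) with truth.

    F_c(t) = B * bleach_c(t) * (1 + s_c * (A/100) * k(t)) + noise, with
    k the normalized response kernel. The truth dict carries the
    programmed amplitude, the kernel peak frame, and (for FRET) the
    closed-form peak of the normalized CFP/YFP series,
    100 * ((1 + a)/(1 - a) - 1) with a = A/100.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    p = params
    t = np.arange(p.n_frames) / p.sample_rate
    k = _response_kernel(p)
    a = p.amplitude_pct / 100.0
    bleach = (
        np.ones_like(t)
        if p.bleach_tau_s is None
        else np.exp(-t / p.bleach_tau_s)
    )
    if p.fret_pair:
        cfp = p.baseline * bleach * (1 + a * k)
        yfp = p.baseline * bleach * (1 - a * k)
        values = np.stack([cfp, yfp])
        if p.noise_sd > 0:
            values = values + rng.normal(0, p.noise_sd, values.shape)
        expected_peak = 100.0 * ((1 + a) / (1 - a) - 1.0)
        sensor = p.sensor if p.sensor in ("EPAC", "SuperClomeleon") else "EPAC"
    else:
        sgn = 1 if p.polarity >= 0 else -1
        values = p.baseline * bleach * (1 + sgn * a * k)
        if p.noise_sd > 0:
            values = values + rng.normal(0, p.noise_sd, values.shape)
        expected_peak = sgn * p.amplitude_pct
        sensor = p.sensor
    trace = FluorTrace(
        roi_id=roi_id,
        sensor=sensor,
        values=values,
        sample_rate=p.sample_rate,
        stimulus_onset_s=p.stimulus_onset_s,
        stimulus_duration_s=p.stimulus_duration_s,
    )
    truth = {
        "amplitude_pct": p.amplitude_pct,
        "expected_peak_pct": expected_peak,
        "peak_frame": int(np.argmax(k)),
        "kernel": k,
    }
    return trace, truth


@dataclass
class ImageSimParams:
    """Parameters for a simulated two-channel confocal stack."""

    shape: tuple[int, int] = (128, 128)
    n_slices: int = 5
    n_shared: int = 10
    n_private: int = 5  # per channel
    shared_amplitude: float = 100.0
    private_amplitude: float = 100.0
    blob_sigma: float = 3.0
    gradient_amplitude: float = 20.0
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if min(self.shape) < 32:
            raise ValueError("image shape must be at least 32 x 32")
        for name in ("shared_amplitude", "private_amplitude",
                     "gradient_amplitude", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _blob_field(
    shape: tuple[int, int],
    centers: np.ndarray,
    amplitude: float,
    sigma: float,
) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    out = np.zeros(shape)
    for cy, cx in centers:
        out += amplitude * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)
        )
    return out


def simulate_image_pair(
    params: ImageSimParams, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Two-channel stack with shared and channel-private structure.

    Returns (stack_r, stack_g) of shape (n_slices, h, w) and a truth
    dict with the per-pixel label map (0 background, 1 shared, 2
    private-R, 3 private-G) and the noise-free projected fields. Blob
    energy is split evenly across slices so a sum projection recovers
    the 2-D fields plus accumulated noise.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    p = params
    h, w = p.shape
    margin = int(4 * p.blob_sigma)

    def draw_centers(n: int) -> np.ndarray:
        if n == 0:
            return np.zeros((0, 2))
        return np.column_stack(
            [
                rng.uniform(margin, h - margin, n),
                rng.uniform(margin, w - margin, n),
            ]
        )

    shared_c = draw_centers(p.n_shared)
    priv_r_c = draw_centers(p.n_private)
    priv_g_c = draw_centers(p.n_private)

    yy, xx = np.mgrid[:h, :w]
    gradient = p.gradient_amplitude * (xx / max(w - 1, 1))
    shared = _blob_field(p.shape, shared_c, p.shared_amplitude, p.blob_sigma)
    field_r = shared + _blob_field(
        p.shape, priv_r_c, p.private_amplitude, p.blob_sigma
    ) + gradient
    field_g = shared + _blob_field(
        p.shape, priv_g_c, p.private_amplitude, p.blob_sigma
    ) + gradient

    labels = np.zeros(p.shape, dtype=np.uint8)
    rad2 = (2 * p.blob_sigma) ** 2
    for centers, code in ((priv_r_c, 2), (priv_g_c, 3), (shared_c, 1)):
        for cy, cx in centers:
            labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= rad2] = code

    def to_stack(field2d: np.ndarray) -> np.ndarray:
        stack = np.repeat(field2d[None] / p.n_slices, p.n_slices, axis=0)
        if p.noise_sd > 0:
            stack = stack + rng.normal(0, p.noise_sd, stack.shape)
        return np.clip(stack, 0.0, None)

    stack_r = to_stack(field_r)
    stack_g = to_stack(field_g)
    truth = {
        "labels": labels,
        "field_r": field_r,
        "field_g": field_g,
        "shared_centers": shared_c,
        "private_r_centers": priv_r_c,
        "private_g_centers": priv_g_c,
    }
    return stack_r, stack_g, truth
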