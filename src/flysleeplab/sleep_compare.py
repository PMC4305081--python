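"""Temperature-shift sleep-change analysis and genotype comparisons.

The thermogenetic protocol records baseline sleep at the rearing
temperature, shifts to 31 degrees C for one or more days, then returns
for recovery. Heat itself changes fly sleep, so the analysis is doubly
differenced: first each fly's baseline window is subtracted from the
same fly's shift (or recovery) window of the same light/dark type, then
the mean per-fly delta of each single-transgene control genotype is
subtracted from the experimental genotype's mean delta, yielding minutes
of sleep gained or lost vs controls. Two pairwise Mann-Whitney tests
(experimental vs GAL4 control, experimental vs UAS control) give two p
values of which only the most conservative (numerically greatest) is
reported.

For constitutive (e.g. RNAi) experiments with no temperature shift, the
same three-genotype machinery runs directly on day-averaged raw metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sleep_core import PeriodMetrics
from .stats import RankTestResult, conservative_p, mann_whitney_u, mean_sem

__all__ = [
    "FlyDelta",
    "GroupComparison",
    "SleepChangeResult",
    "per_fly_baseline_delta",
    "paired_day_deltas",
    "genotype_sleep_change",
    "compare_to_controls",
]


@dataclass(frozen=True)
class FlyDelta:
    """Within-fly sleep change: target window minus baseline window."""

    fly_id: str
    target_day: int
    light: str
    delta_sleep_min: float


@dataclass(frozen=True)
class GroupComparison:
    """Experimental-vs-one-control comparison for one window."""

    ctrl_label: str
    minutes_gained: float  # mean(exp) - mean(ctrl); negative = sleep lost
    sem: float  # quadrature-combined SEMs
    n_exp: int
    n_ctrl: int
    u_statistic: float
    p_value: float


@dataclass(frozen=True)
class SleepChangeResult:
    """Both control comparisons for one window, plus the reported max p."""

    target_day: int
    light: str
    vs_gal4: GroupComparison
    vs_uas: GroupComparison
    conservative_p: float


def _metric_lookup(
    metrics: Sequence[PeriodMetrics], metric: str
) -> dict[tuple[int, str], float]:
    return {
        (m.day_index, m.light): getattr(m, metric)
        for m in metrics
        if m.complete
    }


def per_fly_baseline_delta(
    metrics_by_fly: Mapping[str, Sequence[PeriodMetrics]],
    baseline_day: int,
    target_day: int,
    light: str,
    metric: str = "total_sleep_min",
) -> tuple[list[FlyDelta], list[str]]:
    """Within-fly deltas target_day - baseline_day for one L/D window type.

    Flies missing either window (or with a NaN metric) are omitted;
    their ids are returned as the second element. Raises when no fly
    has both windows.
    """
    deltas: list[FlyDelta] = []
    omitted: list[str] = []
    for fly_id, metrics in metrics_by_fly.items():
        table = _metric_lookup(metrics, metric)
        base = table.get((baseline_day, light))
        target = table.get((target_day, light))
        if base is None or target is None or math.isnan(base) or math.isnan(target):
            omitted.append(fly_id)
            continue
        deltas.append(FlyDelta(fly_id, target_day, light, target - base))
    if not deltas:
        raise ValueError(
            f"no fly has complete ({light}) windows on days "
            f"{baseline_day} and {target_day}"
        )
    return deltas, omitted


def paired_day_deltas(
    metrics_by_fly: Mapping[str, Sequence[PeriodMetrics]],
    pairing: Sequence[tuple[int, int]],
    light: str,
    metric: str = "total_sleep_min",
) -> dict[tuple[int, int], list[FlyDelta]]:
    """Deltas for an explicit list of (baseline_day, target_day) pairs.

    Supports multi-cycle designs where alternating days serve as their
    own baselines (day 1 baseline for day 2, day 3 for day 4, ...).
    Target days may not repeat across pairs.
    """
    targets = [t for _, t in pairing]
    if len(targets) != len(set(targets)):
        raise ValueError("overlapping target days in pairing")
    out: dict[tuple[int, int], list[FlyDelta]] = {}
    for base_day, target_day in pairing:
        try:
            deltas, _ = per_fly_baseline_delta(
                metrics_by_fly, base_day, target_day, light, metric
            )
        except ValueError as exc:
            raise ValueError(
                f"pair (baseline {base_day}, target {target_day}): {exc}"
            ) from exc
        out[(base_day, target_day)] = deltas
    return out


def genotype_sleep_change(
    exp_deltas: Sequence[float],
    ctrl_deltas: Sequence[float],
    ctrl_label: str,
) -> GroupComparison:
    """Minutes gained/lost by the experimental group vs one control.

    Point estimate mean(exp) - mean(ctrl); SEM combined in quadrature;
    p from a two-sided Mann-Whitney test on the per-fly values. With
    fewer than 2 flies in a group the estimate is still reported but
    SEM and p are NaN/1.
    """
    exp = np.asarray(exp_deltas, dtype=float)
    ctrl = np.asarray(ctrl_deltas, dtype=float)
    if exp.size == 0 or ctrl.size == 0:
        raise ValueError("both groups must be non-empty")
    mean_e, sem_e = mean_sem(exp)
    mean_c, sem_c = mean_sem(ctrl)
    estimate = mean_e - mean_c
    if exp.size < 2 or ctrl.size < 2:
        return GroupComparison(
            ctrl_label, estimate, float("nan"), exp.size, ctrl.size,
            float("nan"), 1.0,
        )
    sem = math.sqrt(sem_e**2 + sem_c**2)
    test: RankTestResult = mann_whitney_u(exp, ctrl)
    return GroupComparison(
        ctrl_label, estimate, sem, exp.size, ctrl.size,
        test.statistic, test.p_value,
    )


def compare_to_controls(
    exp: Sequence[float],
    gal4: Sequence[float],
    uas: Sequence[float],
    target_day: int = 0,
    light: str = "D",
) -> SleepChangeResult:
    """Both pairwise control comparisons with the conservative-p rule.

    Values may be per-fly baseline-subtracted deltas (shift designs) or
    day-averaged raw metrics (constitutive designs); the machinery is
    identical.
    """
    for name, grp in (("gal4_control", gal4), ("uas_control", uas)):
        if len(grp) == 0:
            raise ValueError(f"missing control group: {name}")
    if len(exp) == 0:
        raise ValueError("missing experimental group")
    vs_gal4 = genotype_sleep_change(exp, gal4, "gal4_control")
    vs_uas = genotype_sleep_change(exp, uas, "uas_control")
    return SleepChangeResult(
        target_day=target_day,
        light=light,
        vs_gal4=vs_gal4,
        vs_uas=vs_uas,
        conservative_p=conservative_p([vs_gal4.p_value, vs_uas.p_value]),
    )


def results_to_frame(results: Sequence[SleepChangeResult]) -> pd.DataFrame:
    """One row per window x control comparison."""
    rows = []
    for r in results:
        for cmp_ in (r.vs_gal4, r.vs_uas):
            rows.append(
                {
                    "target_day": r.target_day,
                    "light": r.light,
                    "control": cmp_.ctrl_label,
                    "minutes_gained": cmp_.minutes_gained,
                    "sem": cmp_.sem,
                    "n_exp": cmp_.n_exp,
                    "n_ctrl": cmp_.n_ctrl,
                    "U": cmp_.u_statistic,
                    "p": cmp_.p_value,
                    "conservative_p": r.conservative_p,
                }
            )
    return pd.DataFrame(rows)
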