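"""Reusable validation experiments composing the real pipeline stages.

These run the package's own operations end to end on synthetic cohorts
with known ground truth — the same compositions the pipelines perform,
minus file I/O — so recovery of programmed effects can be measured
cheaply and repeatedly.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd

from .dam_io import DAY_MINUTES, HALF_DAY
from .sleep_compare import compare_to_controls, per_fly_baseline_delta
from .sleep_core import all_period_metrics, score_sleep
from .synthetic import make_tempshift_params, simulate_counts

__all__ = ["minute_timeline", "tempshift_replicate"]


@lru_cache(maxsize=8)
def minute_timeline(n_days: int) -> pd.DataFrame:
    """ZT-aligned per-minute timeline starting at lights-on of day 0."""
    minutes = np.arange(n_days * DAY_MINUTES)
    zt = minutes % DAY_MINUTES
    return pd.DataFrame(
        {
            "zt_minute": zt,
            "light": np.where(zt < HALF_DAY, "L", "D"),
            "day_index": minutes // DAY_MINUTES,
        }
    )


def tempshift_replicate(
    seed: int,
    n_flies: int = 16,
    night_effect_min: float = -90.0,
    light: str = "D",
) -> dict:
    """One full temperature-shift recovery experiment.

    Simulates the standard three-genotype design (one baseline day, one
    31 C shift day, programmed night effect in the experimental
    genotype only), scores sleep with the 5-min rule, computes per-fly
    baseline-subtracted deltas, and compares the experimental genotype
    to both controls. Returns the two minutes-gained estimates with
    SEMs, the conservative p, and the programmed truth (the
    genotype-independent heat response cancels in the control
    subtraction, so truth = the programmed effect).
    """
    params, design = make_tempshift_params(
        n_flies=n_flies, night_effect_min=night_effect_min
    )
    counts, _asleep, fly_ids, fly_ch = simulate_counts(params, design, seed)
    timeline = minute_timeline(design.n_days)

    role_of = {
        fly: design.channel_map[fly_ch[fly]][2] for fly in fly_ids
    }
    metrics_by_fly = {}
    for fly in fly_ids:
        vec = counts[:, fly_ch[fly] - 1]
        rec = score_sleep(vec, fly_id=fly)
        metrics_by_fly[fly] = all_period_metrics(rec, vec, timeline)

    deltas_by_role: dict[str, list[float]] = {}
    for role in ("experimental", "gal4_control", "uas_control"):
        sub = {f: metrics_by_fly[f] for f in fly_ids if role_of[f] == role}
        deltas, _ = per_fly_baseline_delta(sub, 0, 1, light)
        deltas_by_role[role] = [d.delta_sleep_min for d in deltas]

    res = compare_to_controls(
        deltas_by_role["experimental"],
        deltas_by_role["gal4_control"],
        deltas_by_role["uas_control"],
        target_day=1,
        light=light,
    )
    return {
        "estimate_vs_gal4": res.vs_gal4.minutes_gained,
        "sem_vs_gal4": res.vs_gal4.sem,
        "estimate_vs_uas": res.vs_uas.minutes_gained,
        "sem_vs_uas": res.vs_uas.sem,
        "conservative_p": res.conservative_p,
        "truth_minutes": night_effect_min,
    }
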