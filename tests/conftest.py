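import numpy as np
import pytest

from flysleeplab.synthetic import (
    make_tempshift_params,
    simulate_dam_experiment,
)


@pytest.fixture(scope="session")
def small_sim():
    """4-fly-per-genotype, 2-day temperature-shift simulation."""
    params, design = make_tempshift_params(n_flies=4)
    return simulate_dam_experiment(params, design, seed=42)


def brute_force_sleep_scan(counts, min_minutes=5):
    """Independent maximal-run scanner: per-minute sleep + episodes.

    Walks the vector once in pure Python, marking maximal runs of
    zero-count minutes of length >= min_minutes.
    """
    sleep = [False] * len(counts)
    episodes = []
    run_start = None
    for i, c in enumerate(list(counts) + [1]):  # sentinel ends final run
        if c == 0:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None:
                length = i - run_start
                if length >= min_minutes:
                    episodes.append((run_start, length))
                    for j in range(run_start, i):
                        sleep[j] = True
                run_start = None
    return np.array(sleep), episodes
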