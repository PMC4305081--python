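"""Generator ground-truth properties: determinism, closed forms."""

import numpy as np
import pytest

from flysleeplab.dam_io import HALF_DAY, parse_dam_files
from flysleeplab.sleep_core import score_sleep
from flysleeplab.synthetic import (
    DEFAULT_DAY,
    DEFAULT_NIGHT,
    ImageSimParams,
    SleepRates,
    SleepSimParams,
    TraceSimParams,
    make_tempshift_params,
    rates_with_sleep_shift,
    simulate_dam_experiment,
    simulate_fluorescence_trace,
    simulate_image_pair,
)


def one_genotype_params(rates: SleepRates, n_flies=8, n_days=1):
    genotypes = {"wt": "experimental"}
    rate_map = {
        ("wt", "baseline", "L"): rates,
        ("wt", "baseline", "D"): rates,
    }
    from datetime import time

    from flysleeplab.dam_io import ExperimentDesign

    design = ExperimentDesign(
        lights_on=time(8, 0),
        phase_schedule=(("baseline", n_days, 22.0),),
        channel_map={
            i + 1: (f"wt_{i:02d}", "wt", "experimental")
            for i in range(n_flies)
        },
    )
    return SleepSimParams(genotypes=genotypes, n_flies=n_flies,
                          rates=rate_map), design


class TestDamSimulator:
    def test_identical_seeds_bit_identical(self):
        params, design = make_tempshift_params(n_flies=3)
        a = simulate_dam_experiment(params, design, seed=123)
        b = simulate_dam_experiment(params, design, seed=123)
        assert a.texts == b.texts
        assert np.array_equal(a.counts, b.counts)
        assert a.truth_windows.equals(b.truth_windows)

    def test_absorbing_wake_means_no_sleep(self):
        params, design = one_genotype_params(
            SleepRates(p_ws=0.0, p_sw=0.1, lambda_wake=2.0)
        )
        sim = simulate_dam_experiment(params, design, seed=0)
        assert sim.truth_windows["latent_sleep_min"].sum() == 0

    def test_absorbing_sleep_one_full_episode(self):
        """p_sw=0 with certain sleep onset: every fly sleeps the whole
        recording in a single edge-to-edge episode."""
        params, design = one_genotype_params(
            SleepRates(p_ws=1.0, p_sw=0.0, lambda_wake=2.0)
        )
        sim = simulate_dam_experiment(params, design, seed=0)
        for fly in sim.fly_ids:
            ch = sim.fly_channels[fly]
            rec = score_sleep(sim.counts[:, ch - 1])
            assert rec.episodes == ((0, 1440),)

    def test_stationary_sleep_fraction_recovered(self):
        """Empirical latent sleep fraction within 3 SE of
        p_ws/(p_ws+p_sw) over 64 fly-days."""
        rates = SleepRates(p_ws=0.1, p_sw=0.05, lambda_wake=2.0)
        params, design = one_genotype_params(rates, n_flies=16, n_days=4)
        sim = simulate_dam_experiment(params, design, seed=11)
        total = sum(v.sum() for v in sim.latent_sleep.values())
        n_min = 16 * 4 * 1440
        frac = total / n_min
        # effective sample size ~ n_min / correlation time
        tau = 1.0 / (rates.p_ws + rates.p_sw)
        f = rates.sleep_fraction
        se = np.sqrt(f * (1 - f) * 2 * tau / n_min)
        assert abs(frac - f) < 3 * se

    def test_scored_close_to_rule_latent_at_high_lambda(self):
        """lambda=5: Poisson zeros are rare, so sleep scored from the
        emitted counts differs from the 5-min-rule scoring of the
        latent states by < 2% of minutes (the scoring rule's own
        short-bout censoring is shared by both sides and cancels)."""
        rates = SleepRates(
            p_ws=DEFAULT_NIGHT.p_ws, p_sw=DEFAULT_NIGHT.p_sw, lambda_wake=5.0
        )
        params, design = one_genotype_params(rates, n_flies=16, n_days=2)
        sim = simulate_dam_experiment(params, design, seed=21)
        diff = (
            sim.truth_windows["scored_sleep_min"]
            - sim.truth_windows["rule_latent_sleep_min"]
        ).abs().sum()
        n_min = 16 * 2 * 1440
        assert diff / n_min < 0.02

    def test_roundtrip_through_parser(self):
        params, design = make_tempshift_params(n_flies=2)
        sim = simulate_dam_experiment(params, design, seed=3)
        _, counts, _ = parse_dam_files(sim.texts)
        assert np.array_equal(counts, sim.counts)

    def test_rates_with_sleep_shift_targets_fraction(self):
        shifted = rates_with_sleep_shift(DEFAULT_NIGHT, -90.0)
        assert shifted.sleep_fraction * HALF_DAY == pytest.approx(
            DEFAULT_NIGHT.sleep_fraction * HALF_DAY - 90.0
        )
        with pytest.raises(ValueError):
            rates_with_sleep_shift(DEFAULT_NIGHT, -10_000.0)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SleepRates(p_ws=1.5, p_sw=0.1)


class TestTraceSimulator:
    def test_flat_trace_without_effect(self):
        params = TraceSimParams(amplitude_pct=0.0, noise_sd=0.0)
        trace, _ = simulate_fluorescence_trace(params, seed=0)
        assert np.allclose(trace.values, params.baseline)

    def test_noiseless_peak_equals_amplitude(self):
        params = TraceSimParams(amplitude_pct=50.0, noise_sd=0.0)
        trace, truth = simulate_fluorescence_trace(params, seed=0)
        dff = (trace.values - trace.values[0]) / trace.values[0] * 100
        assert dff.max() == pytest.approx(50.0, abs=1e-9)
        assert np.argmax(dff) == truth["peak_frame"]

    def test_negative_polarity_dips(self):
        params = TraceSimParams(
            amplitude_pct=8.0, polarity=-1, noise_sd=0.0, sensor="Arclight"
        )
        trace, truth = simulate_fluorescence_trace(params, seed=0)
        dff = (trace.values - trace.values[0]) / trace.values[0] * 100
        assert dff.min() == pytest.approx(-8.0, abs=1e-9)
        assert truth["expected_peak_pct"] == -8.0

    def test_determinism(self):
        params = TraceSimParams(noise_sd=5.0)
        a, _ = simulate_fluorescence_trace(params, seed=9)
        b, _ = simulate_fluorescence_trace(params, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError):
            TraceSimParams(n_frames=10, stimulus_onset_s=30.0)


class TestImageSimulator:
    def test_determinism(self):
        a = simulate_image_pair(ImageSimParams(), seed=4)
        b = simulate_image_pair(ImageSimParams(), seed=4)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_no_shared_structure_mean_pdm_near_zero(self):
        from flysleeplab.coloc_ica import (
            TwoChannelImage,
            compute_pdm,
            pdm_summary,
            z_project,
        )

        params = ImageSimParams(
            n_shared=0, n_private=0, gradient_amplitude=0.0, noise_sd=5.0,
            shared_amplitude=0.0,
        )
        stack_r, stack_g, _ = simulate_image_pair(params, seed=5)
        r = z_project(stack_r, "sum")
        g = z_project(stack_g, "sum")
        s = pdm_summary(compute_pdm(TwoChannelImage(r, g)))
        var = 5.0**2 * params.n_slices  # summed-noise variance per channel
        se = var / np.sqrt(r.size)
        assert abs(s["mean_pdm"]) < 3 * se

    def test_pure_shared_structure_nonnegative_pdm(self):
        from flysleeplab.coloc_ica import TwoChannelImage, compute_pdm, z_project

        params = ImageSimParams(
            n_private=0, noise_sd=0.0, gradient_amplitude=0.0
        )
        stack_r, stack_g, _ = simulate_image_pair(params, seed=12)
        m = compute_pdm(
            TwoChannelImage(z_project(stack_r, "sum"), z_project(stack_g, "sum"))
        )
        assert np.nanmin(m.pdm) >= -1e-9

    def test_too_small_shape_rejected(self):
        with pytest.raises(ValueError):
            ImageSimParams(shape=(16, 16))
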