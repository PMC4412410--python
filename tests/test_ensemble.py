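"""Spike detection, segmentation, U/M construction, and deciles."""

import logging

import numpy as np
import pytest

from motorpls import (
    DegenerateDataError,
    GeneratorConfig,
    InputError,
    MotorSignals,
    SpikeTable,
    WaveformEnsemble,
    build_ensemble,
    build_motor_signals,
    decile_partition,
    detect_spikes,
    filter_trials,
    generate_ensemble,
    hilbert_phase,
    intersect_cycles,
)

FS = 10_000.0


class TestDetectSpikes:
    def test_recovers_known_pulse_times(self):
        times = np.arange(20) * 0.05 + 0.012
        x = np.zeros(int(1.1 * FS))
        x[np.round(times * FS).astype(int)] = 1.0
        table = detect_spikes(x, FS, threshold=0.5, refractory_ms=5.0)
        got = table["ch0"]
        assert got.size == 20
        assert np.all(np.abs(got - times) <= 1.0 / FS)

    def test_all_zero_signal_with_fixed_threshold_is_empty(self):
        table = detect_spikes(np.zeros(1000), FS, threshold=0.5)
        assert table["ch0"].size == 0

    def test_refractory_suppresses_second_pulse(self):
        x = np.zeros(1000)
        x[100] = x[110] = 1.0  # 1 ms apart
        table = detect_spikes(x, FS, threshold=0.5, refractory_ms=5.0)
        assert table["ch0"].size == 1

    def test_flat_signal_auto_threshold_errors(self):
        with pytest.raises(DegenerateDataError):
            detect_spikes(np.ones(1000), FS, threshold=None)


class TestFilterTrials:
    @pytest.mark.parametrize(
        "n_spikes, duration, expected_pass, expected_rate",
        [(100, 5.0, True, 20.0), (50, 5.0, False, 10.0), (90, 5.0, False, 18.0)],
    )
    def test_strict_rate_threshold(self, n_spikes, duration, expected_pass, expected_rate):
        # a trial exactly at 18 spikes/s fails: the rate must *exceed* it
        spikes = SpikeTable({"right": np.linspace(0.01, duration - 0.01, n_spikes)})
        passed, rate = filter_trials(spikes, duration, min_rate=18.0, channel="right")
        assert passed is expected_pass
        assert rate == pytest.approx(expected_rate)


class TestHilbertPhase:
    def test_pure_tone_crossings_are_period_spaced(self):
        t = np.arange(int(2.0 * FS)) / FS
        _, crossings = hilbert_phase(np.sin(2 * np.pi * 20.0 * t), FS)
        assert crossings.size >= 38
        spacing = np.diff(crossings)
        assert np.all(np.abs(spacing - 0.05) <= 1.0 / FS)

    def test_out_of_band_harmonic_does_not_disturb_crossings(self):
        t = np.arange(int(2.0 * FS)) / FS
        x = np.sin(2 * np.pi * 20.0 * t) + 0.3 * np.sin(2 * np.pi * 80.0 * t)
        _, crossings = hilbert_phase(x, FS)
        spacing = np.diff(crossings)
        assert np.all(np.abs(spacing - 0.05) <= 1.0 / FS)

    def test_too_short_series_raises(self):
        with pytest.raises(InputError):
            hilbert_phase(np.zeros(100), FS)


class TestBuildEnsemble:
    def test_constant_torque_is_degenerate_with_unit_scale(self, caplog):
        onsets = np.arange(5) * 0.05
        with caplog.at_level(logging.WARNING, logger="motorpls.ensemble"):
            ens = build_ensemble(np.full(int(0.3 * FS), 3.3), FS, onsets,
                                 n_samples=400)
        assert np.allclose(ens.M, 0.0)
        assert ens.s == 1.0
        assert "degenerate" in caplog.text

    def test_rows_match_generator_ground_truth(self):
        cfg = GeneratorConfig(n_cycles=20)
        from motorpls import generate_experiment

        exp = generate_experiment(cfg, seed=4)
        ens = build_ensemble(exp.torque, FS, exp.onsets, n_samples=500)
        assert np.allclose(ens.raw_rows(), exp.rows)
        assert np.allclose(ens.sta, exp.rows.mean(axis=0))
        assert np.allclose(ens.mean_torque, exp.rows.mean(axis=1))

    def test_overrunning_window_is_dropped_and_counted(self):
        onsets = np.array([0.0, 0.05, 0.28])  # last window overruns a 0.3 s record
        ens = build_ensemble(np.random.default_rng(0).normal(size=int(0.3 * FS)),
                             FS, onsets, n_samples=500)
        assert ens.n_cycles == 2
        assert ens.n_dropped == 1

    def test_centering_and_scale_invariants(self, default_cycles):
        ens, _, _ = default_cycles
        assert np.abs(ens.M.mean(axis=0)).max() < 1e-10
        assert ens.s > 0
        # s is the RMS of the centred ensemble, so the scaled M has unit RMS
        assert np.sqrt(np.mean(ens.M**2)) == pytest.approx(1.0, abs=1e-12)


class TestMotorSignals:
    def test_two_cycle_hand_computed_standardization(self):
        spikes = SpikeTable(
            {"left": np.array([0.010, 0.064]), "right": np.array([0.012, 0.058])}
        )
        sig = build_motor_signals(spikes, np.array([0.0, 0.05]), window_s=0.05)
        assert np.allclose(sig.raw, [[10.0, 12.0], [14.0, 8.0]])
        assert np.allclose(sig.U, [[-1.0, 1.0], [1.0, -1.0]])

    def test_spikes_exactly_at_onsets_are_degenerate(self):
        onsets = np.arange(5) * 0.05
        spikes = SpikeTable({"left": onsets, "right": onsets + 0.002})
        with pytest.raises(DegenerateDataError):
            build_motor_signals(spikes, onsets, window_s=0.05)

    def test_generator_timings_recovered(self, default_cycles):
        from motorpls import generate_experiment

        exp = generate_experiment(GeneratorConfig(n_cycles=30), seed=2)
        sig = build_motor_signals(exp.spikes, exp.onsets, window_s=0.05)
        assert sig.n_cycles == 30
        assert np.allclose(sig.raw, exp.timings_ms, atol=1e-9)

    def test_cycles_missing_spikes_are_dropped(self):
        onsets = np.arange(4) * 0.05
        spikes = SpikeTable(
            {
                "left": np.array([0.010, 0.060, 0.110, 0.160]),
                "right": np.array([0.012, 0.112, 0.162]),  # cycle 1 missing
            }
        )
        sig = build_motor_signals(spikes, onsets, window_s=0.05)
        assert sig.n_cycles == 3
        assert list(sig.cycle_index) == [0, 2, 3]

    def test_standardization_is_idempotent(self, rng):
        raw = rng.normal(size=(40, 2)) * 3 + 5
        once = MotorSignals.from_raw(raw, ("left", "right"))
        twice = MotorSignals.from_raw(once.U, ("left", "right"))
        assert np.allclose(once.U, twice.U)
        assert np.allclose(twice.U.std(axis=0), 1.0)

    def test_unsorted_spike_times_rejected(self):
        with pytest.raises(InputError):
            SpikeTable({"left": np.array([0.2, 0.1])})


class TestDeciles:
    def _ensemble(self, mean_values, rng):
        b = 50
        rows = mean_values[:, None] + rng.normal(0, 1e-6, size=(mean_values.size, b))
        return WaveformEnsemble.from_rows(rows, sample_rate=1000.0)

    def test_equal_groups_with_monotone_means(self, rng):
        ens = self._ensemble(rng.permutation(100).astype(float), rng)
        part = decile_partition(ens)
        sizes = np.bincount(part.labels)
        assert np.all(sizes == 10)
        assert np.all(np.diff(part.group_mean_torque) >= 0)

    def test_remainder_goes_to_lowest_deciles(self, rng):
        ens = self._ensemble(rng.permutation(103).astype(float), rng)
        part = decile_partition(ens)
        sizes = np.bincount(part.labels)
        assert list(sizes) == [11, 11, 11, 10, 10, 10, 10, 10, 10, 10]

    def test_all_equal_means_fall_back_to_index_order(self, caplog, rng):
        ens = self._ensemble(np.zeros(20), rng)
        object.__setattr__(ens, "mean_torque", np.zeros(20))
        with caplog.at_level(logging.WARNING, logger="motorpls.ensemble"):
            part = decile_partition(ens)
        assert np.all(part.labels == np.repeat(np.arange(10), 2))

    def test_too_few_cycles_raises(self, rng):
        ens = self._ensemble(np.arange(5).astype(float), rng)
        with pytest.raises(InputError):
            decile_partition(ens)

    def test_group_means_are_uncentred(self, default_cycles):
        ens, _, _ = default_cycles
        part = decile_partition(ens)
        raw = ens.raw_rows()
        g0 = part.rows_in_group(0)
        assert np.allclose(part.group_means[0], raw[g0].mean(axis=0))


class TestAlignmentConsistency:
    def test_phase_and_spike_ensembles_share_cycles(self):
        # with one reference spike per cycle both alignments keep every cycle
        from motorpls import generate_experiment
        from motorpls.cli import RunConfig, align_recording

        exp = generate_experiment(GeneratorConfig(n_cycles=40), seed=9)
        tau = exp.torque
        ens_p, sig_p = align_recording(tau, FS, exp.spikes,
                                       RunConfig(alignment="phase"), onsets=exp.onsets)
        ens_s, sig_s = align_recording(tau, FS, exp.spikes,
                                       RunConfig(alignment="spike"), onsets=exp.onsets)
        assert ens_p.n_cycles == ens_s.n_cycles

    def test_intersect_cycles_restandardizes(self, default_cycles):
        ens, sig, _ = default_cycles
        sub_e, sub_s = intersect_cycles(ens, sig.take(np.arange(0, 400)))
        assert sub_e.n_cycles == sub_s.n_cycles == 400
        assert np.allclose(sub_s.U.mean(axis=0), 0.0, atol=1e-10)
        assert np.abs(sub_e.M.mean(axis=0)).max() < 1e-10
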