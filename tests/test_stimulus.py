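"""Synthetic stimulus generation and chemosensor preprocessing."""

import numpy as np
import pytest

from mgcsim.dynamics import LIFParams, LIFState, lif_step
from mgcsim.stimulus import (
    RatioTrainSpec,
    SAWRSyntheticSpec,
    SensorTrace,
    TABLE1_VOLUMES_UL,
    TRAIN_AMPLITUDE_PAIRS,
    calibrate_beta,
    differential_current,
    make_ratio_pulse_train,
    make_synthetic_sawr,
    resample_to_grid,
    trace_from_csv,
    trace_to_csv,
)


class TestRatioPulseTrain:
    def test_epoch_has_ten_labelled_segments_tiling_the_grid(self):
        ep = make_ratio_pulse_train(RatioTrainSpec(), seed=0)
        assert len(ep.segments) == 10
        assert ep.grid.n_steps == 10 * 200
        # segments tile [0, n_steps)
        edges = [s for s, _, _ in ep.segments] + [ep.segments[-1][1]]
        assert edges == list(range(0, 2001, 200))
        expected = sorted(f"{a:g}:{b:g}" for a, b in TRAIN_AMPLITUDE_PAIRS)
        assert sorted(ep.labels) == expected

    def test_noiseless_pulse_is_first_order_step_response(self):
        spec = RatioTrainSpec(noise_sigma=0.0, amplitude_scale=1.0)
        ep = make_ratio_pulse_train(spec, seed=1, randomize_order=False)
        # first pair is 0:0; second pulse segment starts at step 200
        a, b = TRAIN_AMPLITUDE_PAIRS[1]
        seg = ep.orn_currents[200:300, 0]
        t = np.arange(1, 101)
        np.testing.assert_allclose(seg, a * (1 - np.exp(-t / 10.0)), rtol=1e-12)

    def test_zero_pair_segment_is_silent_without_noise(self):
        spec = RatioTrainSpec(noise_sigma=0.0)
        ep = make_ratio_pulse_train(spec, seed=1, randomize_order=False)
        assert np.all(ep.orn_currents[:200] == 0.0)

    def test_reproducible_and_order_randomized_per_seed(self):
        spec = RatioTrainSpec()
        a = make_ratio_pulse_train(spec, seed=5)
        b = make_ratio_pulse_train(spec, seed=5)
        c = make_ratio_pulse_train(spec, seed=6)
        np.testing.assert_array_equal(a.orn_currents, b.orn_currents)
        assert a.labels == b.labels
        assert a.labels != c.labels  # different permutation w.h.p.


class TestSyntheticSAWR:
    def test_class_counts_and_labels(self):
        spec = SAWRSyntheticSpec(trials_per_class=3)
        traces = make_synthetic_sawr(spec, seed=0)
        assert len(traces) == 15
        labels = sorted({t.label for t in traces})
        assert labels == ["R1", "R2", "R3", "R4", "R5"]
        for tr in traces:
            assert tr.f_coated.shape == tr.f_uncoated.shape

    def test_equal_volumes_give_equal_noiseless_steady_amplitudes(self):
        spec = SAWRSyntheticSpec(
            noise_sigma_hz=0.0,
            amp_jitter=0.0,
            tau_jitter=0.0,
            trials_per_class=1,
            tau_rise_s=(60.0, 60.0),  # equal kinetics isolates the amplitudes
        )
        # R3 is the 1:1 class (10 ul : 10 ul)
        a = spec.steady_amplitude_hz(2)
        assert a[0] == pytest.approx(a[1])
        traces = make_synthetic_sawr(spec, seed=0)
        r3 = [t for t in traces if t.label == "R3"][0]
        diff = r3.f_uncoated - r3.f_coated
        pre_vent = np.searchsorted(r3.time_s, spec.vent_s) - 1
        assert diff[pre_vent, 0] == pytest.approx(diff[pre_vent, 1], rel=1e-9)

    def test_steady_amplitude_ordering_follows_volumes(self):
        spec = SAWRSyntheticSpec()
        amps_ch1 = [spec.steady_amplitude_hz(i)[0] for i in range(5)]
        assert amps_ch1 == sorted(amps_ch1)  # R1 < R2 < R3 < R4 < R5 for analyte 1
        vols = [v[0] for v in TABLE1_VOLUMES_UL.values()]
        assert vols == sorted(vols)

    def test_no_analyte_no_drift_no_noise_gives_flat_identical_channels(self):
        spec = SAWRSyntheticSpec(
            noise_sigma_hz=0.0,
            drift_hz_per_s=0.0,
            amp_jitter=0.0,
            tau_jitter=0.0,
            sensitivity_hz_per_ul=(0.0, 0.0),
            trials_per_class=1,
        )
        tr = make_synthetic_sawr(spec, seed=0)[0]
        np.testing.assert_allclose(tr.f_coated, tr.f_uncoated)
        np.testing.assert_allclose(tr.f_coated, spec.baseline_hz)

    def test_deterministic_given_seed(self):
        spec = SAWRSyntheticSpec(trials_per_class=2)
        t1 = make_synthetic_sawr(spec, seed=9)
        t2 = make_synthetic_sawr(spec, seed=9)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.f_coated, b.f_coated)


class TestDifferentialCurrent:
    def _trace(self, coated, uncoated):
        n = coated.shape[0]
        return SensorTrace(np.arange(n, dtype=float), coated, uncoated)

    def test_identical_channels_give_zero_current(self):
        f = np.full((50, 2), 262e6)
        tr = self._trace(f, f.copy())
        np.testing.assert_array_equal(differential_current(tr, 2.0), 0.0)

    def test_linearity_in_beta(self):
        rng = np.random.default_rng(0)
        unc = 262e6 + rng.uniform(0, 100, (40, 2))
        tr = self._trace(np.full((40, 2), 262e6), unc)
        i1 = differential_current(tr, 1.5)
        i2 = differential_current(tr, 3.0)
        np.testing.assert_allclose(i2, 2 * i1, rtol=1e-12)

    def test_common_mode_rejection(self):
        rng = np.random.default_rng(1)
        coated = 262e6 - rng.uniform(0, 500, (60, 2))
        uncoated = np.full((60, 2), 262e6)
        base = differential_current(self._trace(coated, uncoated), 1e-4)
        common = rng.uniform(-50, 50, (60, 1))
        shifted = differential_current(
            self._trace(coated + common, uncoated + common), 1e-4
        )
        np.testing.assert_allclose(shifted, base, rtol=1e-10)

    def test_negative_differential_clamped(self):
        tr = self._trace(np.full((5, 2), 10.0), np.full((5, 2), 4.0))
        assert np.all(differential_current(tr, 1.0) == 0.0)


class TestBetaCalibration:
    def test_calibrated_maximum_fires_at_target_rate(self):
        traces = make_synthetic_sawr(SAWRSyntheticSpec(trials_per_class=2), seed=3)
        lif = LIFParams(tau_m=10.0, delta=1.0)
        beta = calibrate_beta(traces, lif, target_rate=50.0)
        max_diff = max(float(np.max(t.f_uncoated - t.f_coated)) for t in traces)
        s, spikes = LIFState(), 0
        for _ in range(2000):
            s = lif_step(s, lif, beta * max_diff)
            spikes += s.spiked
        assert spikes / 2.0 == pytest.approx(50.0, rel=0.05)

    def test_beta_inverse_to_trace_scale(self):
        traces = make_synthetic_sawr(SAWRSyntheticSpec(trials_per_class=1), seed=3)
        beta1 = calibrate_beta(traces)
        doubled = [
            SensorTrace(
                t.time_s,
                t.f_uncoated - 2 * (t.f_uncoated - t.f_coated),
                t.f_uncoated,
                t.label,
            )
            for t in traces
        ]
        assert calibrate_beta(doubled) == pytest.approx(beta1 / 2, rel=1e-12)

    def test_zero_differential_raises(self):
        f = np.full((10, 2), 262e6)
        tr = SensorTrace(np.arange(10.0), f, f.copy())
        with pytest.raises(ValueError):
            calibrate_beta([tr])


class TestResampling:
    def test_default_mapping_is_ten_steps_per_sensor_second(self):
        t = np.arange(0.0, 150.0, 0.5)
        f = np.full((t.size, 2), 262e6)
        tr = SensorTrace(t, f - 100.0, f)
        ep = resample_to_grid(tr, beta=1.0)
        assert ep.grid.n_steps == int(149.5 * 10) + 1

    def test_identity_when_sampling_matches_grid(self):
        t = np.arange(0.0, 1.0, 0.001)  # 1 kHz sensor sampling
        rng = np.random.default_rng(0)
        unc = 262e6 + rng.uniform(0, 10, (t.size, 2))
        tr = SensorTrace(t, np.full((t.size, 2), 262e6), unc)
        ep = resample_to_grid(tr, beta=1.0, compression_ms_per_s=1000.0, delta=1.0)
        np.testing.assert_allclose(
            ep.orn_currents, unc - 262e6, rtol=1e-9, atol=1e-7
        )

    def test_piecewise_constant_preserved(self):
        t = np.arange(0.0, 20.0, 0.5)
        diff = np.where(t < 10, 100.0, 300.0)[:, None] * np.ones((1, 2))
        tr = SensorTrace(t, 262e6 - diff, np.full((t.size, 2), 262e6))
        ep = resample_to_grid(tr, beta=0.01)
        # constant plateaus survive interpolation exactly
        assert np.all(ep.orn_currents[:95] == 1.0)
        assert np.all(ep.orn_currents[105:] == 3.0)

    def test_empty_trace_rejected(self):
        tr = SensorTrace(np.array([]), np.empty((0, 2)), np.empty((0, 2)))
        with pytest.raises(ValueError):
            resample_to_grid(tr)


def test_trace_csv_round_trip(tmp_path):
    tr = make_synthetic_sawr(SAWRSyntheticSpec(trials_per_class=1), seed=2)[0]
    path = tmp_path / "trace.csv"
    trace_to_csv(tr, path)
    back = trace_from_csv(path, label=tr.label, trial=tr.trial)
    np.testing.assert_allclose(back.f_coated, tr.f_coated)
    np.testing.assert_allclose(back.f_uncoated, tr.f_uncoated)
    np.testing.assert_allclose(back.time_s, tr.time_s)
    assert back.label == tr.label
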