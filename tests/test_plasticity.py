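"""Asymmetric STDP rule, training loop, stability and LN tuning."""

import numpy as np
import pytest

import mgcsim as m
from mgcsim.plasticity import (
    STDPParams,
    SpikeMemory,
    apply_stdp_step,
    ln_tuning,
    stdp_delta,
    train,
)
from mgcsim.readout import RateEstimatorParams, estimate_rates
from tests.conftest import TRAINED_DIRECTIONS


class TestKernel:
    def test_coincident_pair_potentiates_at_half_magnitude(self):
        # dW+ * tau+/(tau- + tau+) = 150 * 0.5 at dt = 0
        assert stdp_delta(0.0) == pytest.approx(75.0)

    def test_pre_20ms_before_post(self):
        assert stdp_delta(-20.0) == pytest.approx(75.0 * np.exp(-1), abs=0.01)
        assert stdp_delta(-20.0) == pytest.approx(27.59, abs=0.01)

    def test_pre_after_post_depresses(self):
        assert stdp_delta(10.0) < 0
        assert stdp_delta(10.0) == pytest.approx(-75.0 * np.exp(-0.5), rel=1e-9)

    def test_kernel_decays_with_separation(self):
        assert abs(stdp_delta(-40.0)) < abs(stdp_delta(-10.0))
        assert abs(stdp_delta(40.0)) < abs(stdp_delta(10.0))

    def test_ltd_prefactor_as_printed(self):
        p = STDPParams(tau_plus=20.0, tau_minus=10.0)
        assert p.ltd_prefactor == pytest.approx(150.0 * (1 - 10.0 / 30.0))

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            STDPParams(tau_plus=0.0)
        with pytest.raises(ValueError):
            STDPParams(w_min=5.0, w_max=5.0)
        with pytest.raises(ValueError):
            STDPParams(pairing="random")


class TestStepwiseUpdates:
    def _setup(self):
        conn = m.build_mgc(m.MGCConfig.lca(), seed=0)
        mem = SpikeMemory.empty(2, 30)
        params = STDPParams()
        return conn, mem, params

    def test_no_spikes_no_change(self):
        conn, mem, params = self._setup()
        before = conn.w_orn_ln.copy()
        change = apply_stdp_step(
            conn, 10, np.zeros(2, bool), np.zeros(30, bool), params, mem
        )
        assert change == 0.0
        np.testing.assert_array_equal(conn.w_orn_ln, before)

    def test_pre_before_post_potentiates_that_synapse(self):
        conn, mem, params = self._setup()
        sp0 = np.array([True, False])
        none = np.zeros(30, bool)
        apply_stdp_step(conn, 0, sp0, none, params, mem)  # ORN 1 spikes at t=0
        before = conn.w_orn_ln[:, 0].copy()
        post = np.zeros(30, bool)
        post[3] = True
        apply_stdp_step(conn, 5, np.zeros(2, bool), post, params, mem)
        got = conn.w_orn_ln[3, 0] - before[3]
        assert got == pytest.approx(stdp_delta(-5.0))
        # other LNs' weights untouched
        mask = np.ones(30, bool)
        mask[3] = False
        np.testing.assert_array_equal(conn.w_orn_ln[mask, 0], before[mask])

    def test_post_before_pre_depresses(self):
        conn, mem, params = self._setup()
        post = np.zeros(30, bool)
        post[7] = True
        apply_stdp_step(conn, 0, np.zeros(2, bool), post, params, mem)
        before = conn.w_orn_ln[7, 1]
        apply_stdp_step(conn, 8, np.array([False, True]), np.zeros(30, bool),
                        params, mem)
        assert conn.w_orn_ln[7, 1] - before == pytest.approx(stdp_delta(8.0))

    def test_saturated_weight_stays_at_bound(self):
        conn, mem, params = self._setup()
        conn.w_orn_ln[:] = params.w_max
        apply_stdp_step(conn, 0, np.ones(2, bool), np.zeros(30, bool), params, mem)
        apply_stdp_step(conn, 1, np.zeros(2, bool), np.ones(30, bool), params, mem)
        assert np.all(conn.w_orn_ln <= params.w_max)
        assert np.all(conn.w_orn_ln == params.w_max)

    def test_inhibitory_efficacy_floor_is_zero(self):
        conn, mem, params = self._setup()
        conn.w_ln_ln[:] = -1.0 * conn.ln_ln_mask  # tiny efficacies
        post = np.zeros(30, bool)
        post[0] = True
        apply_stdp_step(conn, 0, np.zeros(2, bool), post, params, mem)
        pre = np.zeros(30, bool)
        pre[1] = True
        apply_stdp_step(conn, 5, np.zeros(2, bool), pre, params, mem)
        assert np.all(conn.w_ln_ln <= 0)  # efficacy clipped at 0, sign preserved

    def test_all_pairs_traces_match_nearest_for_isolated_pair(self):
        """For a single isolated pre/post pair, the all-pairs trace update
        equals the nearest-pairing increment."""
        for pairing in ("nearest", "all"):
            conn = m.build_mgc(m.MGCConfig.lca(), seed=0)
            mem = SpikeMemory.empty(2, 30)
            params = STDPParams(pairing=pairing)
            w0 = conn.w_orn_ln[4, 0]
            sp_pre = np.array([True, False])
            post = np.zeros(30, bool)
            post[4] = True
            apply_stdp_step(conn, 0, sp_pre, np.zeros(30, bool), params, mem)
            for k in range(1, 6):
                apply_stdp_step(conn, k, np.zeros(2, bool),
                                post if k == 5 else np.zeros(30, bool), params, mem)
            assert conn.w_orn_ln[4, 0] - w0 == pytest.approx(
                stdp_delta(-5.0), rel=1e-9
            )


class TestTraining:
    def test_zero_epochs_returns_initial_snapshot_only(self):
        conn = m.build_mgc(m.MGCConfig.lca(), seed=0)
        hist = train(conn, m.RatioTrainSpec(), epochs=0, seed=0, reinit=False)
        assert hist.snapshot_epochs == [0]
        assert hist.per_epoch_change.size == 0
        np.testing.assert_array_equal(hist.orn_ln[0], conn.w_orn_ln)

    def test_negative_epochs_rejected(self):
        conn = m.build_mgc(m.MGCConfig.lca(), seed=0)
        with pytest.raises(ValueError):
            train(conn, m.RatioTrainSpec(), epochs=-1)

    def test_reinit_draws_from_pretraining_ranges(self):
        conn = m.build_mgc(m.MGCConfig.lca(), seed=0)
        hist = train(conn, m.RatioTrainSpec(), epochs=0)
        w0_orn, w0_ln = hist.initial
        assert w0_orn.min() >= 1000 and w0_orn.max() <= 3000
        eff = -w0_ln[conn.ln_ln_mask]
        assert eff.min() >= 100 and eff.max() <= 400

    def test_weights_bounded_throughout(self, trained_results):
        for res in trained_results:
            p = res.stdp
            for w in res.history.orn_ln:
                assert np.all(w >= p.clip_lo) and np.all(w <= p.w_max)
            for w in res.history.ln_ln:
                assert np.all(-w >= p.clip_lo) and np.all(-w <= p.w_max)

    def test_stability_reached_and_absorbing(self, trained_results):
        """Once an epoch realises zero change, repeating a noise-free episode
        keeps the weights frozen."""
        res = trained_results[0]
        assert res.stability_epoch is not None
        conn = res.model.connectome.copy()
        spec = m.RatioTrainSpec(noise_sigma=0.0)
        episode = m.make_ratio_pulse_train(spec, seed=1, randomize_order=False)
        conn.config = m.MGCConfig.lca(noise_sigma=0.0)
        hist = train(conn, episode, epochs=5, seed=0, reinit=False)
        zeros = np.nonzero(hist.per_epoch_change == 0.0)[0]
        assert zeros.size > 0  # the frozen state is reached
        assert np.all(hist.per_epoch_change[zeros[0] :] == 0.0)  # and absorbing

    def test_symmetry_breaking_spreads_preferred_ratios(self, trained_results):
        """Training increases the spread (CV) of normalised ORN-1 weights."""
        improved = 0
        for res in trained_results:
            post = res.tunings.w_norm[:, 0]
            pre = ln_tuning(res.pretrained.connectome).w_norm[:, 0]
            cv = lambda x: np.nanstd(x) / np.nanmean(x)
            improved += cv(post) > cv(pre)
        assert improved >= 4  # majority of seeds (5)

    def test_ln_tunings_cover_trained_ratio_directions(self, trained_results):
        """Pooled over seeds, every trained nonzero ratio direction has an LN
        tuning within 10 degrees (exhaustive nearest-angle search)."""
        angles = np.concatenate(
            [res.tunings.angles_deg for res in trained_results]
        )
        angles = angles[np.isfinite(angles)]
        for direction in TRAINED_DIRECTIONS:
            assert np.min(np.abs(angles - direction)) <= 10.0

    def test_template_separation_amplified_by_training(self, trained_results):
        """Mean inter-class template distance for ratios 1:3/1:1/3:1 grows
        from pre- to post-training."""
        from mgcsim.classify import mean_class_trajectory

        pairs = [(0.5, 1.5), (1.0, 1.0), (1.5, 0.5)]

        def separation(model, seed):
            ts = model.probe_trajectories(pairs, n_trials=3, seed=seed)
            labs = sorted(set(ts.labels))
            tm = [mean_class_trajectory(ts, lab).mean for lab in labs]
            return np.mean(
                [
                    np.linalg.norm(a - b, axis=1).mean()
                    for i, a in enumerate(tm)
                    for b in tm[i + 1 :]
                ]
            )

        wins = 0
        for i, res in enumerate(trained_results):
            wins += separation(res.model, 100 + i) > separation(
                res.pretrained, 100 + i
            )
        assert wins == len(trained_results)

    def test_ln_rate_decorrelation_in_surviving_regime(self, surviving_results):
        """Where LNs remain active after training (raised afferent gain), their
        rate traces on a probe episode decorrelate relative to pre-training."""
        res = surviving_results
        episode = m.make_ratio_pulse_train(
            m.RatioTrainSpec(), seed=99, randomize_order=False
        )

        def mean_corr(model):
            rec = model.simulate(episode, seed=7)
            rates = estimate_rates(
                rec.ln_spikes, RateEstimatorParams(d=20), episode.grid
            )
            active = rates[:, rates.std(axis=0) > 0]
            assert active.shape[1] >= 2
            cc = np.corrcoef(active.T)
            return cc[np.triu_indices(cc.shape[0], 1)].mean()

        assert mean_corr(res.model) < mean_corr(res.pretrained)


class TestTuning:
    def test_symmetric_weights_normalise_to_half(self):
        conn = m.build_mgc(m.MGCConfig.lca(), seed=0)
        conn.w_orn_ln[:] = 2000.0
        tun = ln_tuning(conn)
        np.testing.assert_allclose(tun.w_norm, 0.5)
        np.testing.assert_allclose(tun.preferred_ratio, 1.0)

    def test_three_to_one_weights(self):
        conn = m.build_mgc(m.MGCConfig.lca(), seed=0)
        conn.w_orn_ln[:, 0] = 3000.0
        conn.w_orn_ln[:, 1] = 1000.0
        tun = ln_tuning(conn)
        np.testing.assert_allclose(tun.w_norm[:, 0], 0.75)
        np.testing.assert_allclose(tun.preferred_ratio, 3.0)

    def test_untuned_ln_flagged(self):
        conn = m.build_mgc(m.MGCConfig.lca(), seed=0)
        conn.w_orn_ln[5] = 0.0
        tun = ln_tuning(conn)
        assert tun.untuned[5]
        assert np.isnan(tun.w_norm[5]).all()
        assert not tun.untuned[[i for i in range(30) if i != 5]].any()
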