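"""Model/results facade over the simulator modules.

:class:`MGCModel` bundles a sampled connectome with the simulation,
plasticity and readout machinery; ``fit()`` runs STDP training and returns an
:class:`STDPResults` object carrying the trained connectome, the weight
history, stability diagnostics, the LN ratio tunings and a ``summary()``
table.  The underlying modules (:mod:`mgcsim.network`,
:mod:`mgcsim.plasticity`, ...) remain the functional API.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import TimeGrid
from .network import Connectome, MGCConfig, SimRecord, build_mgc, simulate
from .plasticity import LNTuning, STDPParams, WeightHistory, ln_tuning, train
from .readout import RateEstimatorParams, TrajectorySet, estimate_rates
from .stimulus import RatioTrainSpec, StimulusEpisode, make_ratio_pulse_train

__all__ = ["MGCModel", "STDPResults"]


class MGCModel:
    """An instantiated MGC antennal-lobe model.

    Parameters
    ----------
    config : MGCConfig, optional
        Structural/biophysical parameters; defaults to the LCA regime.
    seed : int
        Connectome sampling seed.
    connectome : Connectome, optional
        Use an existing connectome instead of sampling one.
    """

    def __init__(
        self,
        config: MGCConfig | None = None,
        seed: int = 0,
        connectome: Connectome | None = None,
    ):
        if connectome is not None:
            self.connectome = connectome
            self.config = connectome.config
        else:
            self.config = config or MGCConfig()
            self.connectome = build_mgc(self.config, seed)
        self.seed = self.connectome.seed

    # -- simulation ---------------------------------------------------------
    def simulate(
        self, episode: StimulusEpisode, seed: int = 0, record_v: bool = False
    ) -> SimRecord:
        return simulate(self.connectome, episode, seed=seed, record_v=record_v)

    def pn_rates(self, record: SimRecord) -> np.ndarray:
        """PN firing-rate trajectories (Hz), kernel width matched to tau_m."""
        d = self.config.tau_m_pn / self.config.delta
        return estimate_rates(record.pn_spikes, RateEstimatorParams(d=d), record.grid)

    def ln_rates(self, record: SimRecord) -> np.ndarray:
        d = self.config.tau_m_ln / self.config.delta
        return estimate_rates(record.ln_spikes, RateEstimatorParams(d=d), record.grid)

    def probe_trajectories(
        self,
        pairs: list[tuple[float, float]],
        n_trials: int = 5,
        seed: int = 0,
        spec: RatioTrainSpec | None = None,
    ) -> TrajectorySet:
        """PN trajectories in response to single ratio pulses.

        Per trial and amplitude pair, one RC-filtered square pulse (the
        training-pulse protocol) drives the model; the PN raster is smoothed
        into a rate trajectory.  Labels are ``"a1:a2"`` amplitude strings.
        """
        spec = spec or RatioTrainSpec()
        probe = RatioTrainSpec(
            pulse_ms=spec.pulse_ms,
            gap_ms=spec.gap_ms,
            rc_tau_ms=spec.rc_tau_ms,
            amplitude_pairs=tuple(pairs),
            amplitude_scale=spec.amplitude_scale,
            noise_sigma=spec.noise_sigma,
            delta=spec.delta,
        )
        trajs, labels = [], []
        grid = None
        for trial in range(n_trials):
            s1, s2 = (
                int(x)
                for x in np.random.SeedSequence([seed, trial]).generate_state(2) // 2
            )
            episode = make_ratio_pulse_train(probe, seed=s1, randomize_order=False)
            record = self.simulate(episode, seed=s2)
            rates = self.pn_rates(record)
            seg_len = episode.segments[0][1] - episode.segments[0][0]
            for start, end, lab in episode.segments:
                trajs.append(rates[start : start + seg_len])
                labels.append(lab)
            grid = TimeGrid(delta=episode.grid.delta, n_steps=seg_len)
        return TrajectorySet(
            trajectories=np.stack(trajs), labels=labels, grid=grid,
            meta={"seed": seed, "kind": "pn_probe"},
        )

    # -- training -----------------------------------------------------------
    def fit(
        self,
        training: RatioTrainSpec | StimulusEpisode | None = None,
        epochs: int = 3000,
        stdp: STDPParams | None = None,
        seed: int = 0,
        **train_kwargs,
    ) -> "STDPResults":
        """STDP-train a copy of the connectome on the ratio pulse sequence.

        The model itself is left untouched; the trained network is available
        as ``results.model``.
        """
        training = training if training is not None else RatioTrainSpec()
        stdp = stdp or STDPParams()
        trained = self.connectome.copy()
        history = train(
            trained, training, epochs=epochs, params=stdp, seed=seed, **train_kwargs
        )
        # pre-training reference = the state training actually started from
        # (after any re-initialisation), not the operating weights of `self`
        pre = trained.copy()
        pre.w_orn_ln = history.orn_ln[0].copy()
        pre.w_ln_ln = history.ln_ln[0].copy()
        return STDPResults(
            model=MGCModel(connectome=trained),
            pretrained=MGCModel(connectome=pre),
            history=history,
            stdp=stdp,
            training=training,
        )


@dataclass
class STDPResults:
    """Outcome of one STDP training run."""

    model: MGCModel
    pretrained: MGCModel
    history: WeightHistory
    stdp: STDPParams
    training: RatioTrainSpec | StimulusEpisode

    @property
    def stability_epoch(self) -> int | None:
        return self.history.stability_epoch

    @property
    def stability_epoch_relaxed(self) -> int | None:
        return self.history.stability_epoch_relaxed

    @property
    def tunings(self) -> LNTuning:
        return ln_tuning(self.model.connectome)

    def summary(self) -> str:
        h = self.history
        w0_orn, w0_ln = h.initial
        w1_orn, w1_ln = h.final
        tun = self.tunings
        finite = np.isfinite(tun.preferred_ratio)
        lines = [
            "STDP training results",
            "=" * 54,
            f"epochs run                 {h.epochs_run}",
            f"stability epoch (strict)   {h.stability_epoch}",
            f"stability epoch (relaxed)  {h.stability_epoch_relaxed}"
            f"   (tol {h.relaxed_tol:g} of total |w|)",
            f"final epoch |dw|           {h.per_epoch_change[-1]:.1f}"
            if h.per_epoch_change.size
            else "final epoch |dw|           n/a",
            "-" * 54,
            "weights (16-bit units)      initial            final",
            f"  ORN->LN mean          {w0_orn.mean():10.1f}   {w1_orn.mean():14.1f}",
            f"  LN->LN mean           {w0_ln.mean():10.1f}   {w1_ln.mean():14.1f}",
            "-" * 54,
            f"LN tunings: {int((~tun.untuned).sum())}/{tun.w_norm.shape[0]} tuned, "
            f"preferred-ratio CV "
            f"{np.std(tun.preferred_ratio[finite]) / max(np.mean(tun.preferred_ratio[finite]), 1e-12):.2f}",
        ]
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------------
    def plot_weight_convergence(self, ax=None):
        """Per-epoch summed |weight change| on a log scale."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.history
        ax.semilogy(np.arange(1, h.per_epoch_change.size + 1), h.per_epoch_change)
        ax.set_xlabel("epoch")
        ax.set_ylabel("summed |Δw| (16-bit units)")
        ax.set_title("STDP weight convergence")
        return ax

    def plot_tunings(self, ax=None):
        """Normalised ORN->LN weight pairs on the unit simplex segment."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tun = self.tunings
        ax.plot([0, 1], [1, 0], "k--", lw=0.5)
        ax.scatter(tun.w_norm[:, 0], tun.w_norm[:, 1], c="tab:blue")
        ax.set_xlabel("normalised w(ORN1)")
        ax.set_ylabel("normalised w(ORN2)")
        ax.set_title("LN input tunings after STDP")
        return ax
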