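"""Desk-scale experiment pipelines: regimes, STDP training, ratiometric classification.

Each pipeline is a plain function taking an :class:`ExperimentConfig` and
returning a JSON-serialisable metrics report (plus artifact paths when an
output directory is given).  The CLI wraps these 1:1.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as _io
from .classify import classification_curve, greedy_select, normalize_trajectories
from .dynamics import LIFParams
from .model import MGCModel
from .network import MGCConfig, build_mgc, regime_statistics, simulate
from .plasticity import STDPParams
from .readout import RateEstimatorParams, TrajectorySet, estimate_rates, project_pca
from .stimulus import (
    RatioTrainSpec,
    SAWRSyntheticSpec,
    StimulusEpisode,
    calibrate_beta,
    make_synthetic_sawr,
    resample_to_grid,
)
from .dynamics import TimeGrid

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "square_ratio_episode",
    "run_regimes",
    "run_stdp_train",
    "run_ratiometric",
    "sensor_and_model_trajectories",
]

PIPELINES = ("regimes", "stdp-train", "ratiometric")


def _sub_seeds(seed: int, *keys: int) -> list[int]:
    return [int(x) for x in np.random.SeedSequence([seed, *keys]).generate_state(8) // 2]


@dataclass
class ExperimentConfig:
    """Validated configuration tree for one pipeline run.

    Section dictionaries mirror the constructor arguments of the underlying
    spec objects; unknown keys are rejected with their field path.
    """

    pipeline: str = "regimes"
    seed: int = 0
    out_dir: str | None = None
    network: dict = field(default_factory=dict)
    stdp: dict = field(default_factory=dict)
    stimulus: dict = field(default_factory=dict)
    sawr: dict = field(default_factory=dict)
    readout: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pipeline not in PIPELINES:
            raise ValueError(
                f"pipeline: unknown pipeline {self.pipeline!r}; choose from {PIPELINES}"
            )
        _check_keys("network", self.network, MGCConfig)
        _check_keys("stdp", self.stdp, STDPParams)
        _check_keys("stimulus", self.stimulus, RatioTrainSpec)
        _check_keys("sawr", self.sawr, SAWRSyntheticSpec)
        allowed_classify = {"n_times", "epochs", "n_trials", "pool_size", "compression_ms_per_s"}
        for key in self.classify:
            if key not in allowed_classify:
                raise ValueError(f"classify.{key}: unknown key")
        for key in self.readout:
            if key not in {"d", "half_width", "causal"}:
                raise ValueError(f"readout.{key}: unknown key")

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        for key in raw:
            if key not in known:
                raise ValueError(f"{key}: unknown top-level key")
        raw = dict(raw)
        for section in ("network", "stdp", "stimulus", "sawr"):
            if section in raw and raw[section]:
                raw[section] = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in raw[section].items()
                }
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)


def _check_keys(section: str, values: dict, target) -> None:
    known = {f.name for f in dataclasses.fields(target)}
    for key, val in values.items():
        if key not in known:
            raise ValueError(f"{section}.{key}: unknown key")
    # construct once so range/invariant violations surface with a field path
    try:
        target(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in values.items()})
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{section}: {exc}") from exc


def square_ratio_episode(
    pair: tuple[float, float],
    onset_ms: float = 100.0,
    stim_ms: float = 500.0,
    total_ms: float = 800.0,
    amplitude_scale: float = 0.25,
    delta: float = 1.0,
) -> StimulusEpisode:
    """Square ratio pulse: stimulus from ``onset_ms`` for ``stim_ms``.

    The protocol used for the regime comparison: a 500 ms pulse starting at
    100 ms on an 800 ms grid (noise is added inside the simulation).
    """
    n = int(round(total_ms / delta))
    cur = np.zeros((n, 2))
    a, b = int(round(onset_ms / delta)), int(round((onset_ms + stim_ms) / delta))
    cur[a:b, 0] = pair[0] * amplitude_scale
    cur[a:b, 1] = pair[1] * amplitude_scale
    grid = TimeGrid(delta=delta, n_steps=n)
    lab = f"{pair[0]:g}:{pair[1]:g}"
    return StimulusEpisode(grid=grid, orn_currents=cur, segments=[(0, n, lab)])


def run_regimes(cfg: ExperimentConfig) -> dict:
    """FPA vs LCA comparison: winner-switch counts under a constant ratio pulse."""
    report: dict = {"pipeline": "regimes", "seed": cfg.seed, "regimes": {}}
    episode = square_ratio_episode((1.0, 2.0))
    for name, maker in (("fpa", MGCConfig.fpa), ("lca", MGCConfig.lca)):
        config = maker(**cfg.network)
        conn = build_mgc(config, seed=_sub_seeds(cfg.seed, 0)[0])
        record = simulate(conn, episode, seed=_sub_seeds(cfg.seed, 1)[0])
        summary = regime_statistics(record)
        report["regimes"][name] = {
            "p_ln_ln": config.p_ln_ln,
            "switch_count": summary.switch_count,
            "no_activity": summary.no_activity,
            "pn_spike_count": int(record.pn_spikes.sum()),
            "ln_spike_count": int(record.ln_spikes.sum()),
        }
        if cfg.out_dir:
            out = Path(cfg.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            _io.save_record(record, out / f"record_{name}.h5")
            _io.record_to_csv(record, out / f"raster_{name}.csv")
    return report


def run_stdp_train(cfg: ExperimentConfig) -> dict:
    """STDP training with stability detection, tuning and separation metrics."""
    epochs = int(cfg.classify.get("epochs", 300))
    spec = RatioTrainSpec(**cfg.stimulus)
    model = MGCModel(MGCConfig.lca(**cfg.network), seed=_sub_seeds(cfg.seed, 0)[0])
    res = model.fit(
        spec,
        epochs=epochs,
        stdp=STDPParams(**cfg.stdp),
        seed=_sub_seeds(cfg.seed, 1)[0],
    )
    pairs = [(0.5, 1.5), (1.0, 1.0), (1.5, 0.5)]
    seeds = _sub_seeds(cfg.seed, 2)
    post = res.model.probe_trajectories(pairs, n_trials=5, seed=seeds[0], spec=spec)
    _, var_frac = project_pca(post, n_components=3)
    report = {
        "pipeline": "stdp-train",
        "seed": cfg.seed,
        "epochs_run": res.history.epochs_run,
        "stability_epoch_strict": res.stability_epoch,
        "stability_epoch_relaxed": res.stability_epoch_relaxed,
        "final_epoch_change": float(res.history.per_epoch_change[-1]),
        "top3_variance_fraction": float(var_frac.sum()),
        "n_tuned_lns": int((~res.tunings.untuned).sum()),
    }
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _io.save_weight_history(
            res.history, out / "weight_history.h5", out / "epoch_change.csv"
        )
        tun = res.tunings
        import pandas as pd

        pd.DataFrame(
            {
                "ln_id": np.arange(tun.w_norm.shape[0]),
                "w1_norm": tun.w_norm[:, 0],
                "w2_norm": tun.w_norm[:, 1],
            }
        ).to_csv(out / "ln_tunings.csv", index=False)
        (out / "summary.txt").write_text(res.summary() + "\n")
    return report


def sensor_and_model_trajectories(
    connectome,
    traces,
    compression_ms_per_s: float = 10.0,
    seed: int = 0,
) -> tuple[TrajectorySet, TrajectorySet]:
    """Build the paired (raw-sensor, model-output) trajectory sets.

    Calibrates beta on the trace set, converts each trace into an ORN-current
    episode on the model grid, runs the model, and returns the normalised raw
    differential-current trajectories alongside the PN rate trajectories.
    """
    cfg = connectome.config
    beta = calibrate_beta(traces, LIFParams(tau_m=cfg.tau_m_orn, delta=cfg.delta))
    raw_list, model_list, labels = [], [], []
    grid = None
    d = cfg.tau_m_pn / cfg.delta
    for i, tr in enumerate(traces):
        ep = resample_to_grid(
            tr, beta=beta, compression_ms_per_s=compression_ms_per_s, delta=cfg.delta,
            grid=grid,
        )
        grid = ep.grid
        record = simulate(connectome, ep, seed=_sub_seeds(seed, i)[0])
        rates = estimate_rates(record.pn_spikes, RateEstimatorParams(d=d), ep.grid)
        raw_list.append(ep.orn_currents)
        model_list.append(rates)
        labels.append(tr.label)
    raw = TrajectorySet(np.stack(raw_list), labels, grid, meta={"kind": "sensor"})
    model = TrajectorySet(np.stack(model_list), labels, grid, meta={"kind": "pn"})
    return normalize_trajectories(raw), model


def run_ratiometric(cfg: ExperimentConfig) -> dict:
    """Synthetic-SAWR five-ratio classification: model output vs raw sensor."""
    sawr = SAWRSyntheticSpec(**cfg.sawr)
    seeds = _sub_seeds(cfg.seed, 0)
    traces = make_synthetic_sawr(sawr, seed=seeds[0])
    pool_size = int(cfg.classify.get("pool_size", 5))
    n_times = int(cfg.classify.get("n_times", 20))
    compression = float(cfg.classify.get("compression_ms_per_s", 10.0))
    config = MGCConfig.sensor_matched(**cfg.network)

    candidates = [build_mgc(config, seed=seeds[1] + i) for i in range(pool_size)]
    cache: dict[int, TrajectorySet] = {}
    raw_cache: dict[int, TrajectorySet] = {}

    def fn(conn):
        raw, mod = sensor_and_model_trajectories(
            conn, traces, compression_ms_per_s=compression, seed=seeds[2]
        )
        cache[id(conn)] = mod
        raw_cache[id(conn)] = raw
        return mod

    best, scores = greedy_select(candidates, fn, seed=seeds[3])
    model_ts = cache[id(best)]
    raw_ts = raw_cache[id(best)]
    curve_model = classification_curve(model_ts, n_times=n_times, seed=seeds[4])
    curve_raw = classification_curve(raw_ts, n_times=n_times, seed=seeds[4])
    report = {
        "pipeline": "ratiometric",
        "seed": cfg.seed,
        "n_trials": model_ts.n_trials,
        "candidate_scores": [float(s) for s in scores],
        "model": {
            "mean_accuracy": float(curve_model.p_correct.mean()),
            "final_accuracy": float(curve_model.p_correct[-1]),
            "first_above_chance_ms": curve_model.first_above_chance(),
        },
        "raw_sensor": {
            "mean_accuracy": float(curve_raw.p_correct.mean()),
            "final_accuracy": float(curve_raw.p_correct[-1]),
            "first_above_chance_ms": curve_raw.first_above_chance(),
        },
        "chance": curve_model.chance,
    }
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        curve_model.to_dataframe().to_csv(out / "curve_model.csv", index=False)
        curve_raw.to_dataframe().to_csv(out / "curve_raw.csv", index=False)
        _io.save_trajectories(model_ts, out / "model_trajectories.h5")
        _io.save_connectome(best, out / "best_connectome.h5")
    return report


_RUNNERS = {
    "regimes": run_regimes,
    "stdp-train": run_stdp_train,
    "ratiometric": run_ratiometric,
}


def run_experiment(cfg: ExperimentConfig, log=None) -> dict:
    """Dispatch a pipeline and write the JSON metrics report.

    The report is a pure function of (config, seed): timing goes to ``log``
    (a callable, e.g. ``print``), never into the report, so identical runs
    produce byte-identical ``report.json`` files.
    """
    t0 = time.perf_counter()
    report = _RUNNERS[cfg.pipeline](cfg)
    if log is not None:
        log(f"[mgcsim] pipeline={cfg.pipeline} seed={cfg.seed} "
            f"elapsed={time.perf_counter() - t0:.2f}s")
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
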