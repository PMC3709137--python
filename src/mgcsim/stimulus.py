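"""Synthetic input generation and chemosensor preprocessing.

Two kinds of input drive the antennal-lobe model:

* randomized ratio pulse trains — square concentration pulses, RC-filtered and
  noise-perturbed, used to train the plastic synapses on a fixed set of
  ORN1:ORN2 amplitude ratios;
* dual-channel chemosensor traces — surface-acoustic-wave-resonator-like
  resonant-frequency time series, one polymer-coated (responding) and one
  uncoated (reference) device per analyte channel.  Analyte sorption lowers
  the coated device's resonant frequency over a slow (tens of seconds)
  first-order transient; the uncoated device carries only common-mode drift
  and noise.  The differential signal ``beta * (f_uncoated - f_coated)`` is
  the current driving each ORN; ``beta`` is calibrated so that the largest
  differential in a dataset maps to a target ORN firing rate (~50 Hz).

The synthetic trace generator stands in for undeposited laboratory recordings:
it emulates the five volumetric ratio classes of the binary fruit-volatile
blend experiment (3-methylbutan-1-ol : ethyl acetate at 1:4, 1:2, 1:1, 2:1,
4:1) with configurable cross-sensitivity, drift and noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .dynamics import LIFParams, TimeGrid, lif_current_for_rate

__all__ = [
    "StimulusEpisode",
    "RatioTrainSpec",
    "SensorTrace",
    "SAWRSyntheticSpec",
    "TABLE1_VOLUMES_UL",
    "make_ratio_pulse_train",
    "make_synthetic_sawr",
    "differential_current",
    "calibrate_beta",
    "resample_to_grid",
    "trace_to_csv",
    "trace_from_csv",
]

#: Volumetric ratio classes: liquid volumes (microlitres) of
#: (3-methylbutan-1-ol, ethyl acetate) released per class.
TABLE1_VOLUMES_UL: dict[str, tuple[float, float]] = {
    "R1": (4.0, 16.0),  # 1:4
    "R2": (6.7, 13.3),  # 1:2
    "R3": (10.0, 10.0),  # 1:1
    "R4": (13.3, 6.7),  # 2:1
    "R5": (16.0, 4.0),  # 4:1
}

#: Training-set amplitude pairs (ORN1:ORN2 ratio units), fixed 10-element set.
TRAIN_AMPLITUDE_PAIRS: tuple[tuple[float, float], ...] = (
    (0.0, 0.0),
    (0.5, 0.5),
    (0.5, 1.0),
    (0.5, 1.5),
    (1.0, 0.5),
    (1.0, 1.0),
    (1.0, 1.5),
    (1.5, 0.5),
    (1.5, 1.0),
    (1.5, 1.5),
)


@dataclass
class StimulusEpisode:
    """Time-gridded ORN input currents with ground-truth ratio labels.

    ``orn_currents`` has shape ``(n_steps, n_orn)``.  ``segments`` is a list of
    ``(start_step, end_step, label)`` half-open intervals tiling the episode.
    """

    grid: TimeGrid
    orn_currents: np.ndarray
    segments: list[tuple[int, int, str]] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.orn_currents = np.asarray(self.orn_currents, dtype=float)
        if self.orn_currents.ndim != 2:
            raise ValueError("orn_currents must be 2-D (n_steps, n_orn)")
        if self.orn_currents.shape[0] != self.grid.n_steps:
            raise ValueError("orn_currents length does not match grid")
        if not np.all(np.isfinite(self.orn_currents)):
            raise ValueError("orn_currents must be finite")

    @property
    def n_orn(self) -> int:
        return self.orn_currents.shape[1]

    @property
    def labels(self) -> list[str]:
        return [lab for _, _, lab in self.segments]


@dataclass(frozen=True)
class RatioTrainSpec:
    """Randomized ratio pulse-train specification (one epoch = 10 pulses).

    Square pulses of ``pulse_ms`` separated by ``gap_ms``, low-pass filtered by
    a first-order RC response (``rc_tau_ms``), one pulse per amplitude pair in
    randomized order, Gaussian noise per step.  ``amplitude_scale`` converts
    ratio units to model current units; its default is chosen so the smallest
    nonzero training amplitude drives an ORN at ~60 Hz (see docs).
    ``noise_sigma`` defaults to 2% of the largest pulse amplitude (in current
    units) when None.
    """

    pulse_ms: float = 100.0
    gap_ms: float = 100.0
    rc_tau_ms: float = 10.0
    amplitude_pairs: tuple[tuple[float, float], ...] = TRAIN_AMPLITUDE_PAIRS
    amplitude_scale: float = 0.25
    noise_sigma: float | None = None
    delta: float = 1.0

    def __post_init__(self) -> None:
        if self.pulse_ms <= 0 or self.gap_ms <= 0:
            raise ValueError("pulse_ms and gap_ms must be positive")
        if self.rc_tau_ms <= 0:
            raise ValueError("rc_tau_ms must be positive")

    @property
    def resolved_noise_sigma(self) -> float:
        if self.noise_sigma is not None:
            return self.noise_sigma
        max_amp = max(max(p) for p in self.amplitude_pairs)
        return 0.02 * max_amp * self.amplitude_scale


def _rc_filter(x: np.ndarray, tau_ms: float, delta: float) -> np.ndarray:
    """Exact first-order low-pass on the grid: y[k] = a*y[k-1] + (1-a)*x[k]."""
    a = np.exp(-delta / tau_ms)
    return _sig.lfilter([1.0 - a], [1.0, -a], x, axis=0)


def _pair_label(pair: tuple[float, float]) -> str:
    return f"{pair[0]:g}:{pair[1]:g}"


def make_ratio_pulse_train(
    spec: RatioTrainSpec,
    seed: int,
    randomize_order: bool = True,
    repeats: int = 1,
) -> StimulusEpisode:
    """Generate one training epoch: the 10 amplitude pairs in randomized order.

    Each pulse occupies ``pulse_ms`` followed by a ``gap_ms`` silent interval;
    the square waveform is RC-filtered and Gaussian noise is added per step.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    delta = spec.delta
    pulse_n = int(round(spec.pulse_ms / delta))
    gap_n = int(round(spec.gap_ms / delta))
    seg_n = pulse_n + gap_n

    order: list[tuple[float, float]] = []
    for _ in range(repeats):
        pairs = list(spec.amplitude_pairs)
        if randomize_order:
            pairs = [pairs[i] for i in rng.permutation(len(pairs))]
        order.extend(pairs)

    n_steps = seg_n * len(order)
    square = np.zeros((n_steps, 2))
    segments: list[tuple[int, int, str]] = []
    for i, pair in enumerate(order):
        start = i * seg_n
        square[start : start + pulse_n, 0] = pair[0] * spec.amplitude_scale
        square[start : start + pulse_n, 1] = pair[1] * spec.amplitude_scale
        segments.append((start, start + seg_n, _pair_label(pair)))

    currents = _rc_filter(square, spec.rc_tau_ms, delta)
    sigma = spec.resolved_noise_sigma
    if sigma > 0:
        currents = currents + rng.normal(0.0, sigma, size=currents.shape)
    grid = TimeGrid(delta=delta, n_steps=n_steps)
    return StimulusEpisode(grid=grid, orn_currents=currents, segments=segments, seed=seed)


@dataclass
class SensorTrace:
    """Dual-pair resonant-frequency time series for one trial.

    ``f_coated`` and ``f_uncoated`` have shape ``(n_samples, 2)`` — one
    coated/uncoated device pair per analyte channel.  ``label`` is the ratio
    class (R1–R5 for the synthetic generator; free-form for user data).
    """

    time_s: np.ndarray
    f_coated: np.ndarray
    f_uncoated: np.ndarray
    label: str = ""
    trial: int = 0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f_coated = np.atleast_2d(np.asarray(self.f_coated, dtype=float))
        self.f_uncoated = np.atleast_2d(np.asarray(self.f_uncoated, dtype=float))
        if self.f_coated.shape != self.f_uncoated.shape:
            raise ValueError("coated/uncoated shapes differ")
        if self.f_coated.shape[0] != self.time_s.shape[0]:
            raise ValueError("frequency series length does not match time axis")

    @property
    def n_channels(self) -> int:
        return self.f_coated.shape[1]


@dataclass(frozen=True)
class SAWRSyntheticSpec:
    """Synthetic dual-channel SAWR trace generator settings.

    Coated-device frequency drops by a first-order transient toward a steady
    depression proportional to the channel's analyte volume (plus a
    cross-sensitivity leak from the other analyte), recovers after venting.
    Time constants default inside the 50–80 s band of slow sorption
    transients.  All frequencies in Hz, times in seconds.
    """

    baseline_hz: float = 262e6
    sensitivity_hz_per_ul: tuple[float, float] = (100.0, 100.0)
    cross_sensitivity: float = 0.1
    tau_rise_s: tuple[float, float] = (55.0, 75.0)
    tau_decay_s: tuple[float, float] = (60.0, 80.0)
    onset_s: float = 10.0
    vent_s: float = 110.0
    duration_s: float = 150.0
    dt_s: float = 0.5
    drift_hz_per_s: float = 0.5
    noise_sigma_hz: float = 10.0
    trials_per_class: int = 10
    amp_jitter: float = 0.05
    tau_jitter: float = 0.05
    classes: tuple[str, ...] = ("R1", "R2", "R3", "R4", "R5")
    volumes_ul: tuple[tuple[float, float], ...] = tuple(TABLE1_VOLUMES_UL.values())

    def __post_init__(self) -> None:
        if min(self.tau_rise_s) <= 0 or min(self.tau_decay_s) <= 0:
            raise ValueError("time constants must be positive")
        if len(self.classes) != len(self.volumes_ul):
            raise ValueError("classes and volumes_ul must have equal length")
        if not (0 <= self.onset_s < self.vent_s <= self.duration_s):
            raise ValueError("require 0 <= onset < vent <= duration")

    def steady_amplitude_hz(self, class_index: int) -> np.ndarray:
        """Analytic steady-state frequency depression per channel (Hz)."""
        v = np.asarray(self.volumes_ul[class_index], dtype=float)
        sens = np.asarray(self.sensitivity_hz_per_ul, dtype=float)
        own = v
        other = v[::-1]
        return sens * (own + self.cross_sensitivity * other)


def make_synthetic_sawr(spec: SAWRSyntheticSpec, seed: int) -> list[SensorTrace]:
    """Generate ``trials_per_class`` traces per ratio class, deterministically.

    Per trial, amplitudes and time constants are jittered multiplicatively
    (lognormal-free Gaussian factors) to emulate run-to-run variability, a
    common-mode linear drift is added to both devices of each pair, and iid
    Gaussian noise to every device.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, spec.duration_s, spec.dt_s)
    traces: list[SensorTrace] = []
    for ci, label in enumerate(spec.classes):
        amp0 = spec.steady_amplitude_hz(ci)
        for trial in range(spec.trials_per_class):
            amp = amp0 * (1.0 + spec.amp_jitter * rng.standard_normal(2))
            tau_r = np.asarray(spec.tau_rise_s) * (
                1.0 + spec.tau_jitter * rng.standard_normal(2)
            )
            tau_d = np.asarray(spec.tau_decay_s) * (
                1.0 + spec.tau_jitter * rng.standard_normal(2)
            )
            resp = np.zeros((t.size, 2))
            stim = (t >= spec.onset_s) & (t < spec.vent_s)
            post = t >= spec.vent_s
            for ch in range(2):
                resp[stim, ch] = amp[ch] * (
                    1.0 - np.exp(-(t[stim] - spec.onset_s) / tau_r[ch])
                )
                r_vent = amp[ch] * (
                    1.0 - np.exp(-(spec.vent_s - spec.onset_s) / tau_r[ch])
                )
                resp[post, ch] = r_vent * np.exp(-(t[post] - spec.vent_s) / tau_d[ch])
            drift = spec.drift_hz_per_s * t[:, None]
            f_coated = spec.baseline_hz + drift - resp
            f_uncoated = spec.baseline_hz + drift + np.zeros_like(resp)
            if spec.noise_sigma_hz > 0:
                f_coated = f_coated + rng.normal(0, spec.noise_sigma_hz, resp.shape)
                f_uncoated = f_uncoated + rng.normal(0, spec.noise_sigma_hz, resp.shape)
            traces.append(
                SensorTrace(
                    time_s=t,
                    f_coated=f_coated,
                    f_uncoated=f_uncoated,
                    label=label,
                    trial=trial,
                )
            )
    return traces


def differential_current(trace: SensorTrace, beta: float) -> np.ndarray:
    """ORN drive from a trace: ``beta * (f_uncoated - f_coated)``, floored at 0.

    Sorption lowers the coated-device frequency, so the uncoated-minus-coated
    difference is positive during stimulation; common-mode drift cancels.
    Negative excursions (noise) are clamped — there is no inhibitory sensory
    drive.  Returns shape ``(n_samples, n_channels)``.
    """
    if trace.f_coated.shape != trace.f_uncoated.shape:
        raise ValueError("coated/uncoated length mismatch")
    return np.clip(beta * (trace.f_uncoated - trace.f_coated), 0.0, None)


def calibrate_beta(
    traces: list[SensorTrace],
    lif: LIFParams | None = None,
    target_rate: float = 50.0,
) -> float:
    """Scale constant mapping the dataset-maximum differential to ``target_rate``.

    Finds the maximum of ``f_uncoated - f_coated`` across all traces and
    channels and returns ``beta`` such that this maximum, applied as a constant
    current to the ORN LIF, fires at ``target_rate`` Hz (closed-form
    first-passage inversion on the grid).
    """
    if not traces:
        raise ValueError("no traces to calibrate on")
    lif = lif or LIFParams(tau_m=10.0)
    max_diff = max(float(np.max(tr.f_uncoated - tr.f_coated)) for tr in traces)
    if max_diff <= 0:
        raise ValueError("all-zero (or negative) differentials; cannot calibrate")
    return lif_current_for_rate(target_rate, lif) / max_diff


def resample_to_grid(
    trace: SensorTrace,
    beta: float = 1.0,
    compression_ms_per_s: float = 10.0,
    delta: float = 1.0,
    grid: TimeGrid | None = None,
) -> StimulusEpisode:
    """Map a sensor trace onto the model time grid as an ORN-current episode.

    One sensor second occupies ``compression_ms_per_s`` model milliseconds
    (clock matching between the slow chemosensor and the fast neuronal model);
    the differential current is linearly interpolated onto the grid.
    """
    if compression_ms_per_s <= 0:
        raise ValueError("compression must be positive")
    if trace.time_s.size == 0:
        raise ValueError("empty trace")
    current = differential_current(trace, beta)
    t_model_ms = trace.time_s * compression_ms_per_s
    if grid is None:
        n_steps = int(np.floor(t_model_ms[-1] / delta)) + 1
        grid = TimeGrid(delta=delta, n_steps=n_steps)
    tq = np.arange(grid.n_steps) * grid.delta
    out = np.column_stack(
        [np.interp(tq, t_model_ms, current[:, ch]) for ch in range(current.shape[1])]
    )
    return StimulusEpisode(
        grid=grid,
        orn_currents=out,
        segments=[(0, grid.n_steps, trace.label)],
    )


_CSV_COLUMNS = ("time_s", "f_coated_1", "f_uncoated_1", "f_coated_2", "f_uncoated_2")


def trace_to_csv(trace: SensorTrace, path) -> None:
    """Write a two-pair trace as delimited text (columns time_s, f_coated_1, ...)."""
    if trace.n_channels != 2:
        raise ValueError("CSV schema covers exactly two channel pairs")
    df = pd.DataFrame(
        {
            "time_s": trace.time_s,
            "f_coated_1": trace.f_coated[:, 0],
            "f_uncoated_1": trace.f_uncoated[:, 0],
            "f_coated_2": trace.f_coated[:, 1],
            "f_uncoated_2": trace.f_uncoated[:, 1],
        }
    )
    df.to_csv(path, index=False)


def trace_from_csv(path, label: str = "", trial: int = 0) -> SensorTrace:
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    return SensorTrace(
        time_s=df["time_s"].to_numpy(),
        f_coated=df[["f_coated_1", "f_coated_2"]].to_numpy(),
        f_uncoated=df[["f_uncoated_1", "f_uncoated_2"]].to_numpy(),
        label=label,
        trial=trial,
    )
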