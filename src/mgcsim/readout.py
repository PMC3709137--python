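"""Firing-rate estimation and low-dimensional trajectory projection.

Spike trains are smoothed with the discrete Gaussian kernel

    T(n, d) = exp(-d) * I_n(d),

where ``I_n`` is the modified Bessel function of integer order.  This kernel
is the discrete-time analogue of a Gaussian of variance ``d`` (in steps), is
normalised (``sum_n T(n, d) = 1``) and symmetric, so convolving the 0/1 spike
indicator with it conserves spike mass.  ``d`` defaults to the cell's
membrane time constant expressed in steps, matching the smoothing to the
cell's integration timescale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special as _sp

from .dynamics import TimeGrid

__all__ = [
    "RateEstimatorParams",
    "TrajectorySet",
    "rate_kernel",
    "estimate_rates",
    "project_pca",
]


def _min_half_width(d: float, mass: float = 0.999) -> int:
    """Smallest truncation radius holding at least ``mass`` of the kernel."""
    if d == 0:
        return 0
    half = max(1, int(np.ceil(np.sqrt(d))))
    while True:
        n = np.arange(-half, half + 1)
        if _sp.ive(n, d).sum() >= mass:
            return half
        half *= 2


@dataclass(frozen=True)
class RateEstimatorParams:
    """Kernel width ``d`` (variance in steps) and truncation radius.

    ``half_width=None`` selects the smallest radius retaining >= 99.9% of the
    kernel mass.  ``causal=True`` uses the one-sided (n >= 0) kernel,
    renormalised, for real-time semantics; the symmetric kernel is the default
    for offline analysis.
    """

    d: float = 10.0
    half_width: int | None = None
    causal: bool = False

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError(f"d must be non-negative, got {self.d}")
        if self.half_width is None:
            object.__setattr__(self, "half_width", _min_half_width(self.d))


def rate_kernel(params: RateEstimatorParams) -> np.ndarray:
    """Kernel values ``T(n, d)`` for ``|n| <= half_width``.

    Returns an array of length ``2*half_width + 1`` centred on ``n = 0``
    (symmetric mode), or the renormalised one-sided half in causal mode
    (length ``half_width + 1``, index = lag).
    """
    n = np.arange(-params.half_width, params.half_width + 1)
    # ive(n, d) = I_n(d) * exp(-|d|) — the kernel directly, overflow-free.
    t = _sp.ive(n, params.d)
    if params.d == 0:
        t = (n == 0).astype(float)
    if params.causal:
        half = t[params.half_width :]
        return half / half.sum()
    return t


@dataclass
class TrajectorySet:
    """Per-trial multichannel rate trajectories with class labels.

    ``trajectories`` has shape ``(n_trials, n_steps, n_channels)``; rates are
    in Hz and non-negative.
    """

    trajectories: np.ndarray
    labels: list[str]
    grid: TimeGrid
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trajectories = np.asarray(self.trajectories, dtype=float)
        if self.trajectories.ndim != 3:
            raise ValueError("trajectories must be 3-D (trials, steps, channels)")
        if len(self.labels) != self.trajectories.shape[0]:
            raise ValueError("one label per trial required")

    @property
    def n_trials(self) -> int:
        return self.trajectories.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trajectories.shape[2]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def subset(self, indices) -> "TrajectorySet":
        idx = np.asarray(indices)
        return TrajectorySet(
            trajectories=self.trajectories[idx],
            labels=[self.labels[i] for i in idx],
            grid=self.grid,
            meta=dict(self.meta),
        )


def estimate_rates(
    spikes: np.ndarray,
    params: RateEstimatorParams,
    grid: TimeGrid,
) -> np.ndarray:
    """Convolve a spike raster with the discrete Gaussian kernel.

    ``spikes`` is a boolean/0-1 array of shape ``(n_steps, n_channels)``.
    Returns rates in Hz (spikes per step scaled by ``1000 / delta``), same
    shape.  In causal mode only past spikes contribute to each estimate.
    """
    spikes = np.asarray(spikes)
    if spikes.ndim == 1:
        spikes = spikes[:, None]
    if spikes.shape[0] != grid.n_steps:
        raise ValueError("raster length does not match grid")
    kern = rate_kernel(params)
    scale = 1000.0 / grid.delta
    x = spikes.astype(float)
    out = np.empty_like(x)
    if params.causal:
        # y[k] = sum_{n>=0} T(n) x[k-n]
        for c in range(x.shape[1]):
            out[:, c] = np.convolve(x[:, c], kern)[: x.shape[0]]
    else:
        hw = params.half_width
        for c in range(x.shape[1]):
            out[:, c] = np.convolve(x[:, c], kern, mode="full")[hw : hw + x.shape[0]]
    return out * scale


def project_pca(
    trajectories: TrajectorySet, n_components: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component projection of pooled, mean-centred rate samples.

    All time points of all trials are pooled as samples (channels are the
    variables); returns the projected trajectories with shape
    ``(n_trials, n_steps, n_components)`` and the per-component explained
    variance fractions (descending).  Raises if the pooled data carry no
    variance.
    """
    from sklearn.decomposition import PCA

    n_trials, n_steps, n_ch = trajectories.trajectories.shape
    if n_ch < n_components:
        raise ValueError("fewer channels than requested components")
    x = trajectories.trajectories.reshape(n_trials * n_steps, n_ch)
    if x.shape[0] < n_components:
        raise ValueError("fewer pooled samples than requested components")
    if np.allclose(x.var(axis=0), 0):
        raise ValueError("degenerate input: zero variance in every channel")
    pca = PCA(n_components=n_components)
    z = pca.fit_transform(x)
    return z.reshape(n_trials, n_steps, n_components), pca.explained_variance_ratio_
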