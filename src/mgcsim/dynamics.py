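"""Leaky integrate-and-fire and exponential-synapse primitives with exact integration.

The simulator advances all state with the forward-Euler recursion

    v[k+1] = v[k] * (1 - delta/tau_c) + (delta/C_m) * I[k]

where ``tau_c`` is the *corrected* time constant chosen so that
``1 - delta/tau_c == exp(-delta/tau)``.  With that substitution the recursion
reproduces the exact solution of the underlying linear ODE on the grid
("exact integration"), so the subthreshold trajectory is independent of the
step size and carries no systematic discretisation error.

All potentials and currents are in arbitrary units normalised to the spike
threshold (``v_theta = 1``) and unit membrane capacitance; time constants and
step sizes are in milliseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeGrid",
    "LIFParams",
    "LIFState",
    "SynapseParams",
    "SynapseState",
    "FixedPointSpec",
    "correct_time_constant",
    "lif_step",
    "synapse_step",
    "lif_rate",
    "lif_current_for_rate",
    "decay_error_lsb",
]


@dataclass(frozen=True)
class TimeGrid:
    """Uniform discrete time grid: ``n_steps`` steps of ``delta`` ms each."""

    delta: float = 1.0
    n_steps: int = 0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        if self.n_steps < 0:
            raise ValueError(f"n_steps must be non-negative, got {self.n_steps}")

    @property
    def duration(self) -> float:
        """Total grid span in ms."""
        return self.delta * self.n_steps

    def times(self) -> np.ndarray:
        """Step times in ms (step k occurs at k * delta)."""
        return np.arange(self.n_steps) * self.delta


def correct_time_constant(tau: float, delta: float) -> float:
    """Exact-integration correction of a decay time constant.

    Returns ``tau_c = delta / (1 - exp(-delta/tau))`` so that the forward-Euler
    decay factor ``1 - delta/tau_c`` equals ``exp(-delta/tau)`` exactly.

    Parameters
    ----------
    tau : float
        True time constant (ms), > 0.
    delta : float
        Step duration (ms), > 0.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    # expm1 keeps the delta -> 0 limit (tau_c -> tau) accurate.
    return delta / -math.expm1(-delta / tau)


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire soma parameters.

    ``tau_m`` is the membrane time constant (ms); the input resistance is
    ``R_m = tau_m / c_m``.  ``v_theta`` and ``v_ahp`` are the spike threshold
    and after-hyperpolarisation (reset) potential.
    """

    tau_m: float = 10.0
    c_m: float = 1.0
    v_theta: float = 1.0
    v_ahp: float = 0.0
    delta: float = 1.0
    tau_m_corrected: float = field(init=False)

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError(f"tau_m must be positive, got {self.tau_m}")
        if self.c_m <= 0:
            raise ValueError(f"c_m must be positive, got {self.c_m}")
        if self.v_theta <= self.v_ahp:
            raise ValueError("v_theta must exceed v_ahp")
        object.__setattr__(
            self, "tau_m_corrected", correct_time_constant(self.tau_m, self.delta)
        )

    @property
    def decay(self) -> float:
        """Per-step subthreshold decay factor, equal to exp(-delta/tau_m)."""
        return 1.0 - self.delta / self.tau_m_corrected

    @property
    def r_m(self) -> float:
        return self.tau_m / self.c_m


@dataclass
class LIFState:
    """Membrane potential plus the spike flag of the current step."""

    v: float = 0.0
    spiked: bool = False


@dataclass(frozen=True)
class SynapseParams:
    """Exponential-decay synapse: a spike injects a pulse of magnitude ``b*w``.

    ``w`` is the signed efficacy (negative for inhibitory synapses); ``tau_syn``
    is the EPSC/IPSC decay constant (tau_e or tau_i).
    """

    tau_syn: float = 5.0
    b: float = 1.0
    w: float = 1.0
    delta: float = 1.0
    tau_syn_corrected: float = field(init=False)

    def __post_init__(self) -> None:
        if self.tau_syn <= 0:
            raise ValueError(f"tau_syn must be positive, got {self.tau_syn}")
        object.__setattr__(
            self, "tau_syn_corrected", correct_time_constant(self.tau_syn, self.delta)
        )

    @property
    def decay(self) -> float:
        return 1.0 - self.delta / self.tau_syn_corrected


@dataclass
class SynapseState:
    """Instantaneous postsynaptic current."""

    i: float = 0.0


def lif_step(state: LIFState, params: LIFParams, input_current: float) -> LIFState:
    """Advance a LIF soma by one step.

    Update then threshold: ``v' = v*decay + (delta/c_m)*I``; if ``v' >= v_theta``
    the soma spikes and ``v`` resets to ``v_ahp`` on the same step.  No
    refractory period.
    """
    v = state.v * params.decay + (params.delta / params.c_m) * input_current
    if v >= params.v_theta:
        return LIFState(v=params.v_ahp, spiked=True)
    return LIFState(v=v, spiked=False)


def synapse_step(
    state: SynapseState, params: SynapseParams, presyn_spike: bool
) -> SynapseState:
    """Advance an exponential synapse by one step.

    ``i' = b*w*[spike] + i*decay`` — a presynaptic spike injects the full pulse
    during its step, superimposed on the exponential decay.
    """
    i = state.i * params.decay + (params.b * params.w if presyn_spike else 0.0)
    return SynapseState(i=i)


def lif_rate(current: float, params: LIFParams) -> float:
    """Closed-form steady firing rate (Hz) of a LIF driven by constant current.

    ``f = [tau_m * ln(I R_m / (I R_m - v_theta))]^-1`` above rheobase, 0 below.
    Uses the membrane potential span from ``v_ahp``.
    """
    drive = current * params.r_m
    span = params.v_theta - params.v_ahp
    if drive <= params.v_ahp + span:
        return 0.0
    period_ms = params.tau_m * math.log(
        (drive - params.v_ahp) / (drive - params.v_theta)
    )
    return 1000.0 / period_ms


def lif_current_for_rate(rate_hz: float, params: LIFParams) -> float:
    """Constant current producing a given steady rate on the discrete grid.

    Inverts the exact-integration first-passage relation: with period
    ``n = round(1000 / (rate * delta))`` steps, the current satisfying
    ``v(n*delta) = v_theta`` on the grid is returned with a +1e-9 relative
    nudge so the threshold comparison at step ``n`` is robust to floating-point
    rounding.  This converges to the continuous f–I relation as delta -> 0;
    at finite delta the rectangle-rule current integration makes the forced
    gain ``tau_m_corrected`` rather than ``tau_m``.
    """
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    n = max(1, round(1000.0 / (rate_hz * params.delta)))
    q = params.decay
    # the discrete forced response has gain tau_m_corrected (rectangle-rule
    # current integration): from reset, v_n = I*tau_c*(1 - q^n) + v_ahp*q^n
    tau_c = params.tau_m_corrected / params.c_m
    current = (params.v_theta - params.v_ahp * q**n) / (tau_c * (1.0 - q**n))
    return current * (1.0 + 1e-9)


@dataclass(frozen=True)
class FixedPointSpec:
    """Signed fixed-point representation used by the quantised verification mode.

    ``full_scale`` maps to the largest representable magnitude, so one LSB is
    ``full_scale / 2**(word_length - 1)``.  Rounding is round-half-even.
    """

    word_length: int = 32
    full_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.word_length not in (16, 32):
            raise ValueError(f"word_length must be 16 or 32, got {self.word_length}")
        if self.full_scale <= 0:
            raise ValueError("full_scale must be positive")

    @property
    def lsb(self) -> float:
        return self.full_scale / 2 ** (self.word_length - 1)

    def quantize(self, x: np.ndarray | float) -> np.ndarray:
        """Round a real value to the LSB grid (half-even), in LSB units."""
        return np.round(np.asarray(x, dtype=float) / self.lsb)


def decay_error_lsb(
    params: LIFParams,
    spec: FixedPointSpec,
    horizon: int,
    corrected: bool = True,
    propagate_quantized: bool = False,
) -> float:
    """Max deviation (in LSB) of the quantised free decay from the closed form.

    Starts the membrane at full scale with zero input and compares the
    word-length-quantised recursion state against ``round(v0 * exp(-k*delta/tau))``
    over ``k <= horizon``.

    By default the recursion accumulates with guard bits (full-precision
    datapath, state observed on the LSB grid), which is the regime in which the
    exact-integration correction bounds the error by half an LSB; with
    ``corrected=False`` the raw forward-Euler factor ``1 - delta/tau`` is used
    instead and a systematic, growing error appears.  ``propagate_quantized``
    instead feeds the rounded register value back into the recursion each step,
    which adds an unbiased random-walk rounding error of a few LSB.
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    decay = params.decay if corrected else 1.0 - params.delta / params.tau_m
    v0_lsb = float(2 ** (spec.word_length - 1) - 1)
    exact_decay = params.decay  # equals exp(-delta/tau_m)

    worst = 0.0
    v = v0_lsb
    ref = v0_lsb
    for _ in range(horizon):
        if propagate_quantized:
            v = float(np.round(v * decay))
        else:
            v = v * decay
        ref *= exact_decay
        err = abs(float(np.round(v)) - float(np.round(ref)))
        worst = max(worst, err)
    return worst
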