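"""Asymmetric STDP on the LN-afferent synapses, training loop and tuning analysis.

Plasticity acts only on synapses targeting local interneurons: the excitatory
ORN->LN afferents and the inhibitory LN->LN lateral connections.  The update
for a pre/post spike pair with timing difference ``dt = t_pre - t_post`` is

    dt <= 0 (pre before post):  dw = +dw_plus  * tau_p/(tau_m+tau_p) * exp(-|dt|/tau_p)
    dt >  0 (pre after post):   dw = -dw_minus * (1 - tau_m/(tau_m+tau_p)) * exp(-dt/tau_m)

with nearest-spike pairing: each postsynaptic spike pairs with the most recent
presynaptic spike (potentiation) and each presynaptic spike with the most
recent postsynaptic spike (depression); a coincident pair (same step) counts
once, as dt = 0 potentiation.

Weights are positive efficacies on a signed-16-bit-like scale; the pathway
sign (inhibitory for LN->LN) is applied at current delivery, so potentiation
of an inhibitory synapse *strengthens* inhibition.  Updates are clipped to
``[max(w_min, 0), w_max]``.

Repeated exposure to the randomized ratio pulse train drives the weights from
their randomized initial state to a stable asymptotic configuration in which
individual LNs become tuned to distinct ORN1:ORN2 input ratios, covering the
trained ratio space through mutual competition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import Connectome, simulate
from .stimulus import RatioTrainSpec, StimulusEpisode, make_ratio_pulse_train

__all__ = [
    "STDPParams",
    "SpikeMemory",
    "WeightHistory",
    "LNTuning",
    "stdp_delta",
    "apply_stdp_step",
    "OnlineSTDP",
    "train",
    "ln_tuning",
]


@dataclass(frozen=True)
class STDPParams:
    """Kernel magnitudes, time constants and clipping bounds.

    ``dw_plus``/``dw_minus`` are the LTP/LTD magnitudes (16-bit weight units);
    ``tau_plus``/``tau_minus`` the kernel time constants (ms).  Pairs farther
    apart than ``window_ms`` are ignored (the kernel there is < 1e-3 of its
    peak at the defaults).  ``pairing`` is ``"nearest"`` (per-neuron last-spike
    memory) or ``"all"`` (every spike within the window pairs; computed from
    the same memory of all spikes in the window).
    """

    dw_plus: float = 150.0
    dw_minus: float = 150.0
    tau_plus: float = 20.0
    tau_minus: float = 20.0
    w_min: float = -32768.0
    w_max: float = 32767.0
    window_ms: float = 140.0
    pairing: str = "nearest"

    def __post_init__(self) -> None:
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("STDP time constants must be positive")
        if self.w_min >= self.w_max:
            raise ValueError("w_min must be below w_max")
        if self.pairing not in ("nearest", "all"):
            raise ValueError(f"unknown pairing scheme {self.pairing!r}")

    @property
    def ltp_prefactor(self) -> float:
        return self.dw_plus * self.tau_plus / (self.tau_minus + self.tau_plus)

    @property
    def ltd_prefactor(self) -> float:
        # (1 - tau_-/(tau_- + tau_+)) as printed; equals tau_+/(tau_- + tau_+)
        return self.dw_minus * (1.0 - self.tau_minus / (self.tau_minus + self.tau_plus))

    @property
    def clip_lo(self) -> float:
        """Effective efficacy floor: efficacies are magnitudes, never negative."""
        return max(self.w_min, 0.0)


def stdp_delta(delta_t: float, params: STDPParams | None = None) -> float:
    """Weight increment for one pre/post pair, ``delta_t = t_pre - t_post`` (ms).

    Non-positive ``delta_t`` (pre before or with post) potentiates, positive
    depresses; both branches decay exponentially in ``|delta_t|``.
    """
    params = params or STDPParams()
    if delta_t <= 0:
        return params.ltp_prefactor * float(np.exp(-abs(delta_t) / params.tau_plus))
    return -params.ltd_prefactor * float(np.exp(-delta_t / params.tau_minus))


@dataclass
class SpikeMemory:
    """Recent-spike state: last-spike steps (nearest pairing) and exponential
    spike traces (all-pairs pairing)."""

    last_orn: np.ndarray
    last_ln: np.ndarray
    trace_pre_orn: np.ndarray
    trace_pre_ln: np.ndarray
    trace_post_ln: np.ndarray

    @classmethod
    def empty(cls, n_orn: int, n_ln: int) -> "SpikeMemory":
        far = -(10**9)
        return cls(
            last_orn=np.full(n_orn, far, dtype=np.int64),
            last_ln=np.full(n_ln, far, dtype=np.int64),
            trace_pre_orn=np.zeros(n_orn),
            trace_pre_ln=np.zeros(n_ln),
            trace_post_ln=np.zeros(n_ln),
        )


def _bump_excitatory(w: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                     dw: np.ndarray, lo: float, hi: float) -> float:
    """Add dw (per col) to w[rows, cols], clip, return summed |realised change|."""
    block = w[np.ix_(rows, cols)]
    new = np.clip(block + dw[None, :], lo, hi)
    w[np.ix_(rows, cols)] = new
    return float(np.abs(new - block).sum())


def _bump_inhibitory(w: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                     dw: np.ndarray, mask: np.ndarray, lo: float, hi: float) -> float:
    """Same on an inhibitory (non-positive) matrix: efficacy = -w, edge-masked."""
    block = -w[np.ix_(rows, cols)]
    m = mask[np.ix_(rows, cols)]
    new = np.where(m, np.clip(block + dw[None, :], lo, hi), block)
    w[np.ix_(rows, cols)] = -new
    return float(np.abs(new - block).sum())


def apply_stdp_step(
    connectome: Connectome,
    step: int,
    sp_orn: np.ndarray,
    sp_ln: np.ndarray,
    params: STDPParams,
    memory: SpikeMemory,
) -> float:
    """Process one step's spike events; mutates the plastic weights in place.

    Returns the summed absolute weight change realised this step (after
    clipping).  ``sp_orn``/``sp_ln`` are this step's boolean spike vectors.
    """
    c = connectome.config
    delta = c.delta
    lo, hi = params.clip_lo, params.w_max
    total = 0.0

    if params.pairing == "all":
        return _apply_stdp_all_pairs(connectome, sp_orn, sp_ln, params, memory)

    memory.last_orn[sp_orn] = step  # so coincident ORN/LN pairs see dt = 0
    pre_ln_now = np.where(sp_ln, step, memory.last_ln)

    if sp_ln.any():
        posts = np.nonzero(sp_ln)[0]
        # potentiation: most recent spike of every presynaptic partner
        dt = (step - memory.last_orn) * delta
        pres = np.nonzero(dt <= params.window_ms)[0]
        if pres.size:
            dw = params.ltp_prefactor * np.exp(-dt[pres] / params.tau_plus)
            total += _bump_excitatory(connectome.w_orn_ln, posts, pres, dw, lo, hi)
        dt = (step - pre_ln_now) * delta
        pres = np.nonzero(dt <= params.window_ms)[0]
        if pres.size:
            dw = params.ltp_prefactor * np.exp(-dt[pres] / params.tau_plus)
            total += _bump_inhibitory(
                connectome.w_ln_ln, posts, pres, dw, connectome.ln_ln_mask, lo, hi
            )

    # depression: presynaptic spike arriving after the post's last spike
    dt_post = (step - memory.last_ln) * delta
    dep = (dt_post > 0) & (dt_post <= params.window_ms) & ~sp_ln
    if dep.any():
        posts = np.nonzero(dep)[0]
        fall = np.exp(-dt_post[posts] / params.tau_minus)
        if sp_orn.any():
            pres = np.nonzero(sp_orn)[0]
            dw = -params.ltd_prefactor * fall
            # depression depends on the *post* timing: row-wise increments
            block = connectome.w_orn_ln[np.ix_(posts, pres)]
            new = np.clip(block + dw[:, None], lo, hi)
            connectome.w_orn_ln[np.ix_(posts, pres)] = new
            total += float(np.abs(new - block).sum())
        if sp_ln.any():
            pres = np.nonzero(sp_ln)[0]
            eff = -connectome.w_ln_ln[np.ix_(posts, pres)]
            m = connectome.ln_ln_mask[np.ix_(posts, pres)]
            new = np.where(
                m, np.clip(eff - params.ltd_prefactor * fall[:, None], lo, hi), eff
            )
            connectome.w_ln_ln[np.ix_(posts, pres)] = -new
            total += float(np.abs(new - eff).sum())

    memory.last_ln[sp_ln] = step
    return total


def _apply_stdp_all_pairs(
    connectome: Connectome,
    sp_orn: np.ndarray,
    sp_ln: np.ndarray,
    params: STDPParams,
    memory: SpikeMemory,
) -> float:
    """All-pairs pairing via exponential spike traces (every pair contributes)."""
    c = connectome.config
    lo, hi = params.clip_lo, params.w_max
    total = 0.0
    dec_p = np.exp(-c.delta / params.tau_plus)
    dec_m = np.exp(-c.delta / params.tau_minus)
    memory.trace_pre_orn *= dec_p
    memory.trace_pre_ln *= dec_p
    memory.trace_post_ln *= dec_m
    memory.trace_pre_orn[sp_orn] += 1.0
    memory.trace_pre_ln[sp_ln] += 1.0

    if sp_ln.any():
        posts = np.nonzero(sp_ln)[0]
        dw = params.ltp_prefactor * memory.trace_pre_orn
        total += _bump_excitatory(
            connectome.w_orn_ln, posts, np.arange(c.n_orn), dw, lo, hi
        )
        dw = params.ltp_prefactor * memory.trace_pre_ln
        total += _bump_inhibitory(
            connectome.w_ln_ln, posts, np.arange(c.n_ln), dw,
            connectome.ln_ln_mask, lo, hi,
        )
    # depression against post spikes strictly in the past
    if sp_orn.any():
        pres = np.nonzero(sp_orn)[0]
        block = connectome.w_orn_ln[:, pres]
        new = np.clip(
            block - params.ltd_prefactor * memory.trace_post_ln[:, None], lo, hi
        )
        connectome.w_orn_ln[:, pres] = new
        total += float(np.abs(new - block).sum())
    if sp_ln.any():
        pres = np.nonzero(sp_ln)[0]
        eff = -connectome.w_ln_ln[:, pres]
        m = connectome.ln_ln_mask[:, pres]
        new = np.where(
            m,
            np.clip(eff - params.ltd_prefactor * memory.trace_post_ln[:, None], lo, hi),
            eff,
        )
        connectome.w_ln_ln[:, pres] = -new
        total += float(np.abs(new - eff).sum())

    memory.trace_post_ln[sp_ln] += 1.0
    return total


class OnlineSTDP:
    """Simulation hook accumulating STDP updates across one episode."""

    def __init__(self, connectome: Connectome):
        c = connectome.config
        self.memory = SpikeMemory.empty(c.n_orn, c.n_ln)
        self.total_abs_change = 0.0

    def __call__(self, step, sp_orn, sp_ln, connectome, params) -> None:
        self.total_abs_change += apply_stdp_step(
            connectome, step, sp_orn, sp_ln, params, self.memory
        )


@dataclass
class WeightHistory:
    """Epoch-indexed weight snapshots with stability metadata.

    ``snapshot_epochs[i]`` is the number of completed epochs at snapshot ``i``
    (0 = initial state).  ``per_epoch_change[e]`` is the summed absolute *net*
    weight change over epoch ``e`` (end minus start of the epoch) — the
    convergence measure; ``per_epoch_turnover[e]`` is the summed magnitude of
    every realised update event, a churn diagnostic that stays positive as
    long as cells fire.  ``stability_epoch`` is the first epoch (1-based) with
    strictly zero net change, ``stability_epoch_relaxed`` the first with net
    change below ``relaxed_tol`` times the total absolute weight; either is
    None if never reached.
    """

    snapshot_epochs: list[int]
    orn_ln: list[np.ndarray]
    ln_ln: list[np.ndarray]
    per_epoch_change: np.ndarray
    per_epoch_turnover: np.ndarray
    stability_epoch: int | None
    stability_epoch_relaxed: int | None
    relaxed_tol: float
    params: STDPParams
    seed: int
    epochs_run: int

    @property
    def initial(self) -> tuple[np.ndarray, np.ndarray]:
        return self.orn_ln[0], self.ln_ln[0]

    @property
    def final(self) -> tuple[np.ndarray, np.ndarray]:
        return self.orn_ln[-1], self.ln_ln[-1]

    def change_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, self.per_epoch_change.size + 1),
                "summed_abs_change": self.per_epoch_change,
            }
        )


def train(
    connectome: Connectome,
    training: RatioTrainSpec | StimulusEpisode,
    epochs: int,
    params: STDPParams | None = None,
    seed: int = 0,
    snapshot_every: int | None = None,
    stop_at_stability: bool = False,
    stability_mode: str = "strict",
    relaxed_tol: float = 1e-3,
    reinit: bool = True,
    init_orn_ln: tuple[float, float] = (1000.0, 3000.0),
    init_ln_ln: tuple[float, float] = (100.0, 400.0),
) -> WeightHistory:
    """Run the STDP training loop; mutates ``connectome`` weights in place.

    With ``reinit`` (default) the plastic weights are first redrawn from the
    randomized pre-training ranges — ORN->LN efficacies uniform on
    ``init_orn_ln``, LN->LN efficacies uniform on ``init_ln_ln`` (on the
    existing adjacency) — so training always starts from the weak randomized
    state regardless of the operating weights the connectome was built with.

    Each epoch presents one ratio pulse-train episode with plasticity active.
    When ``training`` is a :class:`RatioTrainSpec`, a fresh episode (new pulse
    order, new noise) is generated per epoch from a seed derived from
    ``seed``; a fixed :class:`StimulusEpisode` is repeated verbatim (noise in
    the network input still varies per epoch through the derived seed).

    ``stop_at_stability`` ends training at the first epoch meeting the chosen
    stability criterion (``"strict"``: zero realised change; ``"relaxed"``:
    change below ``relaxed_tol`` of total absolute weight — the appropriate
    criterion for floating-point weights).
    """
    if epochs < 0:
        raise ValueError("epochs must be non-negative")
    params = params or STDPParams()
    if snapshot_every is None:
        snapshot_every = max(1, epochs // 50) if epochs else 1

    if reinit:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))
        connectome.w_orn_ln[:] = rng.uniform(
            *init_orn_ln, size=connectome.w_orn_ln.shape
        )
        connectome.w_ln_ln[:] = (
            -rng.uniform(*init_ln_ln, size=connectome.w_ln_ln.shape)
            * connectome.ln_ln_mask
        )

    snap_epochs = [0]
    snaps_orn = [connectome.w_orn_ln.copy()]
    snaps_ln = [connectome.w_ln_ln.copy()]
    changes = []
    turnovers = []
    stab_strict: int | None = None
    stab_relaxed: int | None = None

    for epoch in range(1, epochs + 1):
        ep_seed, sim_seed = (
            int(x) for x in np.random.SeedSequence([seed, epoch]).generate_state(2) // 2
        )
        if isinstance(training, RatioTrainSpec):
            episode = make_ratio_pulse_train(training, seed=ep_seed)
        else:
            episode = training
        w_orn_before = connectome.w_orn_ln.copy()
        w_ln_before = connectome.w_ln_ln.copy()
        hook = OnlineSTDP(connectome)
        simulate(connectome, episode, seed=sim_seed, stdp=hook, stdp_params=params)
        # net drift of the weight configuration over the epoch; the realised
        # per-event turnover (which never vanishes while cells fire) is kept
        # separately as a diagnostic
        change = float(
            np.abs(connectome.w_orn_ln - w_orn_before).sum()
            + np.abs(connectome.w_ln_ln - w_ln_before).sum()
        )
        changes.append(change)
        turnovers.append(hook.total_abs_change)

        total_w = np.abs(connectome.w_orn_ln).sum() + np.abs(connectome.w_ln_ln).sum()
        if stab_strict is None and change == 0.0:
            stab_strict = epoch
        if stab_relaxed is None and change < relaxed_tol * max(total_w, 1e-300):
            stab_relaxed = epoch

        if epoch % snapshot_every == 0 or epoch == epochs:
            snap_epochs.append(epoch)
            snaps_orn.append(connectome.w_orn_ln.copy())
            snaps_ln.append(connectome.w_ln_ln.copy())

        reached = stab_strict if stability_mode == "strict" else stab_relaxed
        if stop_at_stability and reached is not None:
            if snap_epochs[-1] != epoch:
                snap_epochs.append(epoch)
                snaps_orn.append(connectome.w_orn_ln.copy())
                snaps_ln.append(connectome.w_ln_ln.copy())
            break

    return WeightHistory(
        snapshot_epochs=snap_epochs,
        orn_ln=snaps_orn,
        ln_ln=snaps_ln,
        per_epoch_change=np.asarray(changes),
        per_epoch_turnover=np.asarray(turnovers),
        stability_epoch=stab_strict,
        stability_epoch_relaxed=stab_relaxed,
        relaxed_tol=relaxed_tol,
        params=params,
        seed=seed,
        epochs_run=len(changes),
    )


@dataclass
class LNTuning:
    """Normalised ORN-afferent weight pair per LN.

    ``w_norm[i] = (w1, w2) / (w1 + w2)`` lies on the unit simplex segment;
    ``preferred_ratio[i] = w1 / w2`` (inf for w2 = 0); ``untuned`` flags LNs
    whose afferent weights are both zero.
    """

    w_norm: np.ndarray
    preferred_ratio: np.ndarray
    untuned: np.ndarray

    @property
    def angles_deg(self) -> np.ndarray:
        """Direction of each LN's (w1, w2) tuning vector, degrees from ORN-1 axis."""
        return np.degrees(np.arctan2(self.w_norm[:, 1], self.w_norm[:, 0]))


def ln_tuning(connectome: Connectome) -> LNTuning:
    """Normalised ORN->LN weight pairs (the LN ratio tunings)."""
    w = connectome.w_orn_ln
    tot = w.sum(axis=1)
    untuned = tot == 0
    safe = np.where(untuned, 1.0, tot)
    w_norm = w / safe[:, None]
    w_norm[untuned] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = np.where(w[:, 1] > 0, w[:, 0] / w[:, 1], np.inf)
    pref = np.where(untuned, np.nan, pref)
    return LNTuning(w_norm=w_norm, preferred_ratio=pref, untuned=untuned)
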