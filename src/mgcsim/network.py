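"""Probabilistic MGC connectome construction and spiking simulation.

The macroglomerular-complex circuit: two ORN types drive two glomeruli of 15
projection neurons each (glomerulus-specific excitation) and a shared pool of
30 inhibitory local interneurons (every LN receives both ORNs).  LNs inhibit
each other and the PNs; PNs excite each other within a glomerulus.  There is
no PN->LN feedback and no spontaneous activity.

Two dynamical regimes arise from the LN<->LN inhibitory wiring:

* FPA (fixed-point attractor) — all-to-all, symmetric LN inhibition
  (``p_ln_ln = 1`` with equal weights) yields a winner-takes-all competition:
  one LN dominates for the whole stimulus;
* LCA (limit-cycle attractor) — sparse, asymmetric inhibition
  (``p_ln_ln = 0.25``, independently drawn weights) yields winnerless
  competition: dominance switches slowly among LNs, imposing rich
  spatiotemporal patterning on the PN output.

All somata advance with the exact-integration forward-Euler recursion of
:mod:`mgcsim.dynamics`; synapses are per-pathway exponential-decay currents.
Weights live on a signed 16-bit-like integer scale and are converted to
current units by the pulse constant ``b`` (default ``2**-15``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import TimeGrid, correct_time_constant
from .stimulus import StimulusEpisode

__all__ = ["MGCConfig", "Connectome", "SimRecord", "build_mgc", "simulate",
           "regime_statistics", "RegimeSummary"]


@dataclass(frozen=True)
class MGCConfig:
    """Structural and biophysical parameters of one MGC instance.

    Connection probabilities are per directed edge; weight ranges are uniform
    draw bounds on the 16-bit efficacy scale.  ``p_ln_ln = 0.25`` gives the
    LCA regime; ``p_ln_ln = 1`` with ``symmetric_ln_ln = True`` gives FPA.
    ``noise_sigma`` is the s.d. of the Gaussian noise added to the ORN drive
    each step (current units); default is 5% of the unit-ratio pulse
    amplitude used by the training stimulus.
    """

    n_orn: int = 2
    n_glom: int = 2
    n_pn_per_glom: int = 15
    n_ln: int = 30
    p_ln_ln: float = 0.25
    p_ln_pn: float = 0.5
    p_pn_pn: float = 0.5
    symmetric_ln_ln: bool = False
    w_orn_ln_range: tuple[float, float] = (1000.0, 3000.0)
    w_orn_pn_range: tuple[float, float] = (4000.0, 8000.0)
    w_ln_ln_range: tuple[float, float] = (2000.0, 6000.0)
    w_ln_pn_range: tuple[float, float] = (1000.0, 3000.0)
    w_pn_pn_range: tuple[float, float] = (500.0, 1500.0)
    tau_m_orn: float = 10.0
    tau_m_pn: float = 10.0
    tau_m_ln: float = 20.0
    tau_e: float = 5.0
    tau_i: float = 10.0
    b: float = 2.0**-15
    # per-pathway pulse-constant multipliers for the plastic pathways: the
    # pulse constant of Eq-style exponential synapses is free per synapse
    # type, and the paper's fixed initial ranges (1000-3000 / 100-400) only
    # set the weight scale, not the current scale
    g_orn_ln: float = 1.0
    g_ln_ln: float = 1.0
    v_theta: float = 1.0
    v_ahp: float = 0.0
    c_m: float = 1.0
    noise_sigma: float = 0.0125
    delta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("p_ln_ln", "p_ln_pn", "p_pn_pn"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        for name in ("n_orn", "n_glom", "n_pn_per_glom", "n_ln"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_orn != self.n_glom:
            raise ValueError("one ORN type per glomerulus is required")

    @classmethod
    def fpa(cls, **kwargs) -> "MGCConfig":
        """All-to-all symmetric LN inhibition (winner-takes-all regime)."""
        kwargs.setdefault("p_ln_ln", 1.0)
        kwargs.setdefault("symmetric_ln_ln", True)
        return cls(**kwargs)

    @classmethod
    def lca(cls, **kwargs) -> "MGCConfig":
        """Sparse asymmetric LN inhibition (winnerless-competition regime)."""
        kwargs.setdefault("p_ln_ln", 0.25)
        kwargs.setdefault("symmetric_ln_ln", False)
        return cls(**kwargs)

    @classmethod
    def sensor_matched(cls, **kwargs) -> "MGCConfig":
        """LCA regime rescaled for chemosensor drive with a ~50 Hz ORN ceiling.

        The training-regime defaults assume ORN rates of 60-450 Hz; calibrated
        sensor input caps ORN firing near 50 Hz, so afferent coupling is
        strengthened and the ORN noise raised to soften the rheobase (still no
        spontaneous firing: threshold sits >10 noise s.d. from rest).
        """
        kwargs.setdefault("g_orn_ln", 4.0)
        kwargs.setdefault("w_orn_pn_range", (24000.0, 48000.0))
        kwargs.setdefault("w_ln_pn_range", (300.0, 900.0))
        kwargs.setdefault("noise_sigma", 0.1)
        return cls.lca(**kwargs)

    @property
    def n_pn(self) -> int:
        return self.n_glom * self.n_pn_per_glom


@dataclass
class Connectome:
    """One sampled MGC instance: pathway weight matrices plus parameters.

    Matrices are ``(n_post, n_pre)``; inhibitory pathways (``ln_ln``,
    ``ln_pn``) are stored non-positive, excitatory ones non-negative, on the
    16-bit efficacy scale.  ``*_mask`` arrays give the sampled adjacency
    (an edge may carry zero weight yet exist for plasticity purposes).
    """

    config: MGCConfig
    seed: int
    w_orn_ln: np.ndarray
    w_orn_pn: np.ndarray
    w_ln_ln: np.ndarray
    w_ln_pn: np.ndarray
    w_pn_pn: np.ndarray
    ln_ln_mask: np.ndarray
    ln_pn_mask: np.ndarray
    pn_pn_mask: np.ndarray

    def copy(self) -> "Connectome":
        return Connectome(
            config=self.config,
            seed=self.seed,
            w_orn_ln=self.w_orn_ln.copy(),
            w_orn_pn=self.w_orn_pn.copy(),
            w_ln_ln=self.w_ln_ln.copy(),
            w_ln_pn=self.w_ln_pn.copy(),
            w_pn_pn=self.w_pn_pn.copy(),
            ln_ln_mask=self.ln_ln_mask,
            ln_pn_mask=self.ln_pn_mask,
            pn_pn_mask=self.pn_pn_mask,
        )

    @property
    def glomerulus_of_pn(self) -> np.ndarray:
        c = self.config
        return np.repeat(np.arange(c.n_glom), c.n_pn_per_glom)

    def validate(self) -> None:
        if np.any(np.diagonal(self.w_ln_ln) != 0) or np.any(
            np.diagonal(self.w_pn_pn) != 0
        ):
            raise ValueError("self-connections are forbidden")
        if np.any(self.w_ln_ln > 0) or np.any(self.w_ln_pn > 0):
            raise ValueError("inhibitory weights must be non-positive")
        if np.any(self.w_orn_ln < 0) or np.any(self.w_orn_pn < 0) or np.any(
            self.w_pn_pn < 0
        ):
            raise ValueError("excitatory weights must be non-negative")


def build_mgc(config: MGCConfig, seed: int) -> Connectome:
    """Sample a connectome: independent Bernoulli edges, uniform weights.

    ORN ``g`` excites every LN and only the PNs of glomerulus ``g``.  With
    ``symmetric_ln_ln`` every existing LN->LN edge carries the midpoint of the
    LN-LN weight range (the symmetric FPA wiring); otherwise weights are drawn
    independently per edge.  Deterministic given ``seed``.
    """
    c = config
    rng = np.random.default_rng(seed)
    n_pn = c.n_pn

    def _uniform(lo_hi, shape):
        lo, hi = lo_hi
        return rng.uniform(lo, hi, size=shape)

    w_orn_ln = _uniform(c.w_orn_ln_range, (c.n_ln, c.n_orn))

    glom = np.repeat(np.arange(c.n_glom), c.n_pn_per_glom)
    w_orn_pn = _uniform(c.w_orn_pn_range, (n_pn, c.n_orn))
    w_orn_pn *= glom[:, None] == np.arange(c.n_orn)[None, :]

    off_diag = ~np.eye(c.n_ln, dtype=bool)
    ln_ln_mask = (rng.random((c.n_ln, c.n_ln)) < c.p_ln_ln) & off_diag
    if c.symmetric_ln_ln:
        mid = 0.5 * (c.w_ln_ln_range[0] + c.w_ln_ln_range[1])
        w_ln_ln = -mid * ln_ln_mask
    else:
        w_ln_ln = -_uniform(c.w_ln_ln_range, (c.n_ln, c.n_ln)) * ln_ln_mask

    ln_pn_mask = rng.random((n_pn, c.n_ln)) < c.p_ln_pn
    w_ln_pn = -_uniform(c.w_ln_pn_range, (n_pn, c.n_ln)) * ln_pn_mask

    same_glom = glom[:, None] == glom[None, :]
    pn_pn_mask = (
        (rng.random((n_pn, n_pn)) < c.p_pn_pn)
        & same_glom
        & ~np.eye(n_pn, dtype=bool)
    )
    w_pn_pn = _uniform(c.w_pn_pn_range, (n_pn, n_pn)) * pn_pn_mask

    conn = Connectome(
        config=c,
        seed=seed,
        w_orn_ln=w_orn_ln,
        w_orn_pn=w_orn_pn,
        w_ln_ln=w_ln_ln,
        w_ln_pn=w_ln_pn,
        w_pn_pn=w_pn_pn,
        ln_ln_mask=ln_ln_mask,
        ln_pn_mask=ln_pn_mask,
        pn_pn_mask=pn_pn_mask,
    )
    conn.validate()
    return conn


@dataclass
class SimRecord:
    """Spike rasters (boolean step x neuron arrays) from one episode.

    ``orn_spikes``: (n_steps, n_orn); ``ln_spikes``: (n_steps, n_ln);
    ``pn_spikes``: (n_steps, n_pn).  Membrane traces are recorded only when
    requested.
    """

    grid: TimeGrid
    orn_spikes: np.ndarray
    ln_spikes: np.ndarray
    pn_spikes: np.ndarray
    v_traces: np.ndarray | None = None
    episode_seed: int | None = None

    def spike_table(self):
        """Long-format (neuron_id, spike_step) table, 0-based; ORNs first,
        then LNs, then PNs."""
        import pandas as pd

        blocks = []
        offset = 0
        for arr in (self.orn_spikes, self.ln_spikes, self.pn_spikes):
            steps, cells = np.nonzero(arr)
            blocks.append(
                pd.DataFrame({"neuron_id": cells + offset, "spike_step": steps})
            )
            offset += arr.shape[1]
        out = pd.concat(blocks, ignore_index=True)
        return out.sort_values(["neuron_id", "spike_step"], ignore_index=True)


def simulate(
    connectome: Connectome,
    episode: StimulusEpisode,
    seed: int = 0,
    record_v: bool = False,
    stdp=None,
    stdp_params=None,
) -> SimRecord:
    """Run the full synchronous spiking simulation of one episode.

    Per step, all synapses advance first (using the previous step's spikes),
    then all somata; ORN somata receive the episode current plus seeded
    Gaussian noise, LN/PN somata the summed synaptic currents at their
    integration node.  Deterministic given (connectome, episode, seed).

    ``stdp``/``stdp_params`` hook the online plasticity rule into the loop
    (used by :func:`mgcsim.plasticity.train`); weights in ``connectome`` are
    then modified in place.
    """
    c = connectome.config
    if episode.n_orn != c.n_orn:
        raise ValueError(
            f"episode drives {episode.n_orn} ORNs but model has {c.n_orn}"
        )
    if abs(episode.grid.delta - c.delta) > 1e-12:
        raise ValueError("episode grid step does not match model delta")

    rng = np.random.default_rng(seed)
    n_steps = episode.grid.n_steps
    n_ln, n_pn, n_orn = c.n_ln, c.n_pn, c.n_orn
    delta = c.delta

    dec_m_orn = 1.0 - delta / correct_time_constant(c.tau_m_orn, delta)
    dec_m_ln = 1.0 - delta / correct_time_constant(c.tau_m_ln, delta)
    dec_m_pn = 1.0 - delta / correct_time_constant(c.tau_m_pn, delta)
    dec_e = 1.0 - delta / correct_time_constant(c.tau_e, delta)
    dec_i = 1.0 - delta / correct_time_constant(c.tau_i, delta)

    v_orn = np.zeros(n_orn)
    v_ln = np.zeros(n_ln)
    v_pn = np.zeros(n_pn)
    # per-postsynaptic-neuron aggregated pathway currents (current units)
    i_orn_ln = np.zeros(n_ln)
    i_ln_ln = np.zeros(n_ln)
    i_orn_pn = np.zeros(n_pn)
    i_ln_pn = np.zeros(n_pn)
    i_pn_pn = np.zeros(n_pn)

    sp_orn = np.zeros(n_orn, dtype=bool)
    sp_ln = np.zeros(n_ln, dtype=bool)
    sp_pn = np.zeros(n_pn, dtype=bool)

    orn_raster = np.zeros((n_steps, n_orn), dtype=bool)
    ln_raster = np.zeros((n_steps, n_ln), dtype=bool)
    pn_raster = np.zeros((n_steps, n_pn), dtype=bool)
    v_rec = np.zeros((n_steps, n_orn + n_ln + n_pn)) if record_v else None

    b = c.b
    w_orn_ln = connectome.w_orn_ln
    w_orn_pn = connectome.w_orn_pn
    w_ln_ln = connectome.w_ln_ln
    w_ln_pn = connectome.w_ln_pn
    w_pn_pn = connectome.w_pn_pn
    drive = episode.orn_currents
    sigma = c.noise_sigma
    scale = delta / c.c_m
    v_theta, v_ahp = c.v_theta, c.v_ahp

    noise = rng.normal(0.0, sigma, size=(n_steps, n_orn)) if sigma > 0 else None

    for k in range(n_steps):
        # synapses first: decay, then inject pulses from last step's spikes
        i_orn_ln *= dec_e
        i_orn_pn *= dec_e
        i_pn_pn *= dec_e
        i_ln_ln *= dec_i
        i_ln_pn *= dec_i
        if sp_orn.any():
            i_orn_ln += b * c.g_orn_ln * w_orn_ln[:, sp_orn].sum(axis=1)
            i_orn_pn += b * w_orn_pn[:, sp_orn].sum(axis=1)
        if sp_ln.any():
            i_ln_ln += b * c.g_ln_ln * w_ln_ln[:, sp_ln].sum(axis=1)
            i_ln_pn += b * w_ln_pn[:, sp_ln].sum(axis=1)
        if sp_pn.any():
            i_pn_pn += b * w_pn_pn[:, sp_pn].sum(axis=1)

        # somata
        i_orn = drive[k] if noise is None else drive[k] + noise[k]
        v_orn = v_orn * dec_m_orn + scale * i_orn
        v_ln = v_ln * dec_m_ln + scale * (i_orn_ln + i_ln_ln)
        v_pn = v_pn * dec_m_pn + scale * (i_orn_pn + i_ln_pn + i_pn_pn)

        sp_orn = v_orn >= v_theta
        sp_ln = v_ln >= v_theta
        sp_pn = v_pn >= v_theta
        v_orn[sp_orn] = v_ahp
        v_ln[sp_ln] = v_ahp
        v_pn[sp_pn] = v_ahp

        orn_raster[k] = sp_orn
        ln_raster[k] = sp_ln
        pn_raster[k] = sp_pn
        if v_rec is not None:
            v_rec[k] = np.concatenate([v_orn, v_ln, v_pn])

        if stdp is not None:
            stdp(k, sp_orn, sp_ln, connectome, stdp_params)

    return SimRecord(
        grid=episode.grid,
        orn_spikes=orn_raster,
        ln_spikes=ln_raster,
        pn_spikes=pn_raster,
        v_traces=v_rec,
        episode_seed=episode.seed,
    )


@dataclass
class RegimeSummary:
    """Windowed LN dominance summary."""

    window_ms: float
    winners: np.ndarray  # winning LN per window; -1 for silent windows
    switch_count: int | None  # None when the raster carries no LN activity
    no_activity: bool


def regime_statistics(
    record: SimRecord, window: float = 50.0, settle_ms: float = 200.0
) -> RegimeSummary:
    """Winner-per-window summary of the LN competition.

    Splits the episode into consecutive windows of ``window`` ms; the winner
    of a window is the LN with the highest spike count in it (ties to the
    lowest index).  The switch count is the number of winner changes across
    active windows after the settling period.  A raster with no LN spikes is
    flagged ``no_activity`` with an undefined switch count.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    ln = record.ln_spikes
    if not ln.any():
        return RegimeSummary(window, np.array([], dtype=int), None, True)
    steps_per_win = max(1, int(round(window / record.grid.delta)))
    n_win = ln.shape[0] // steps_per_win
    winners = np.full(n_win, -1, dtype=int)
    for w in range(n_win):
        counts = ln[w * steps_per_win : (w + 1) * steps_per_win].sum(axis=0)
        if counts.max() > 0:
            winners[w] = int(np.argmax(counts))
    first_win = int(np.ceil(settle_ms / window))
    active = winners[first_win:][winners[first_win:] >= 0]
    switches = int(np.count_nonzero(np.diff(active))) if active.size > 1 else 0
    return RegimeSummary(window, winners, switches, False)
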