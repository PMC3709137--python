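# mgcsim

A spiking-network simulator of the insect antennal lobe's **macroglomerular
complex (MGC)** — the male moth's pheromone-processing circuit — together
with the signal chain that turns slow dual-channel chemosensor transients
into rapid **blend-ratio** classifications. It is aimed at computational
neuroscientists and machine-olfaction researchers who want a tested,
reproducible software counterpart to neuromorphic MGC implementations.

## The model

The circuit contains two olfactory receptor neuron (ORN) types, a pool of 30
inhibitory local interneurons (LNs), and two glomeruli of 15 projection
neurons (PNs) each. Every LN receives both ORNs; the PNs of glomerulus *g*
are excited only by ORN *g*; LNs inhibit each other and the PNs; PNs excite
each other within a glomerulus. There is no PN→LN feedback and no
spontaneous activity.

All somata are leaky integrate-and-fire (LIF) units advanced with the
forward-Euler recursion

```
V[k+1] = V[k] · (1 − Δ/τ_c) + (Δ/C_m) · I[k],     spike & reset when V ≥ V_θ
```

where the corrected time constant `τ_c = Δ / (1 − e^(−Δ/τ))` makes the
recursion reproduce the exact exponential solution on the grid (*exact
integration*), so the subthreshold dynamics carry no systematic
discretisation error — verifiable to within ±½ LSB of a 32-bit fixed-point
state. Synapses are exponential-decay current pulses `I[k+1] = b·w·δ_spike +
I[k](1 − Δ/τ_syn,c)`. Membrane constants are 10 ms (ORN, PN) and 20 ms (LN).

Two dynamical regimes emerge from the LN↔LN wiring:

* **FPA** (fixed-point attractor): all-to-all symmetric inhibition
  (`p = 1`) → a single winner-takes-all LN;
* **LCA** (limit-cycle attractor): sparse asymmetric inhibition
  (`p = 0.25`) → winnerless competition with slow dominance switching.

On top of this sit:

* **asymmetric STDP** on the ORN→LN and LN→LN synapses
  (`ΔW± = 150`, `τ± = 20 ms`, signed-16-bit weight clipping), trained on a
  randomized sequence of RC-filtered ratio pulses
  (`0:0, 0.5:0.5, …, 1.5:1.5`);
* a firing-rate readout convolving PN spikes with the discrete Gaussian
  kernel `T(n, d) = e^(−d) I_n(d)` (`I_n`: modified Bessel function);
* the **ratiometric detection core**: mean class trajectories, the
  time-averaged Euclidean trajectory distance
  `D_x(T) = (1/T) ∫₀ᵀ ‖r(t) − r̄_x(t)‖ dt`, nearest-mean classification,
  leave-one-out decision-time sweeps and greedy model selection;
* a synthetic dual-channel SAWR-like chemosensor generator (five volumetric
  ratio classes, 50–80 s first-order transients) with differential
  preprocessing `I(t) = β (f_uncoated − f_coated)` and β calibrated so the
  dataset-maximum differential drives an ORN at ~50 Hz.

## Worked example

```python
import mgcsim as m

model = m.MGCModel(m.MGCConfig.lca(), seed=0)
results = model.fit(m.RatioTrainSpec(), epochs=300, seed=0)
print(results.summary())
```

```
STDP training results
======================================================
epochs run                 300
stability epoch (strict)   4
stability epoch (relaxed)  4   (tol 0.001 of total |w|)
final epoch |dw|           0.0
------------------------------------------------------
weights (16-bit units)      initial            final
  ORN->LN mean              2063.5            346.1
  LN->LN mean                -55.7            -66.7
------------------------------------------------------
LN tunings: 30/30 tuned, preferred-ratio CV 1.43
```

The weight configuration freezes after four epochs (a *stable* epoch is one
in which no net weight change occurs); the normalised ORN→LN weight pairs of
the 30 LNs spread across the space of input ratios (coefficient of variation
1.43 versus ~0.2 before training), and the post-training PN trajectories for
probe ratios 1:3 / 1:1 / 3:1 are amplified and more widely separated (their
top three principal components capture ≈98% of the variance). See
`docs/methods.md` for why stability at the published plasticity magnitudes
is reached through silencing of the plastic pathway.

The regime dichotomy, from the command line:

```bash
mgcsim run regimes --seed 1 --out out/regimes
```

reports `switch_count: 0` for the FPA network and `switch_count: 5` for the
LCA network — the same stimulus, differing only in LN↔LN wiring. Other
subcommands: `build`, `simulate`, `train`, `classify`, `make-fixtures`
(example configs under `configs/`).

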