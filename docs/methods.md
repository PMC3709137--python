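# Methods

This note records the model, the choices made where the design was open, and
what the synthetic-data experiments do and do not establish.

## Circuit and dynamics

The network is the two-glomerulus macroglomerular-complex (MGC) circuit: 2
ORN input units, 30 inhibitory LNs shared between glomeruli, and 2×15
excitatory PNs. Pathways: ORN→LN (excitatory, all-to-all across both ORNs),
ORN→PN (excitatory, glomerulus-specific), LN→LN and LN→PN (inhibitory,
Bernoulli-sampled per directed edge), PN→PN (excitatory, within-glomerulus,
Bernoulli-sampled). There is no PN→LN feedback, no refractory period, and no
spontaneous activity (all cells rest at 0 with threshold 1).

All state advances synchronously: per step, every synapse decays and
receives pulses from the *previous* step's spikes, then every soma
integrates (one-iteration-per-clock semantics). The forward-Euler decay
factor uses the corrected time constant `τ_c = Δ/(1 − e^(−Δ/τ))`, which
makes `1 − Δ/τ_c = e^(−Δ/τ)` exactly, so free decay matches the continuous
exponential at every grid point regardless of Δ (exact integration). Two
discretisation facts worth knowing:

* the *forced* response has gain `τ_c`, not `τ` (rectangle-rule current
  integration). `lif_current_for_rate` therefore inverts the grid-exact
  first-passage relation rather than the continuous f–I formula; the two
  agree as Δ→0 but differ markedly near rheobase at Δ = 1 ms.
* the fixed-point emulation mode (`decay_error_lsb`) quantises the observed
  state to a 16/32-bit grid while the datapath carries guard bits. In that
  regime the corrected constant holds the decay within ±½ LSB of the rounded
  closed form over arbitrarily many steps, whereas the uncorrected factor
  `1 − Δ/τ` drifts by orders of magnitude — the correction, not the word
  length, is what removes systematic error. A strict register-rounding
  variant (`propagate_quantized=True`) is provided; feeding the rounded
  register back adds an unbiased random walk of a few LSB (parts in 10⁸ of
  full scale), which is rounding noise, not integration error.

## Parameters and units

Potentials are normalised to the spike threshold (`V_θ = 1`, `V_ahp = 0`,
`C_m = 1`); time is in ms with Δ = 1 ms by default (exact integration makes
the subthreshold solution step-size independent). Membrane constants: 10 ms
(ORN, PN), 20 ms (LN); synaptic decays: τ_e = 5 ms, τ_i = 10 ms (EPSC/IPSC
constants are not biologically pinned here; these sit in the usual
fast-synapse range and are exposed in `MGCConfig`).

Synaptic efficacies live on a signed-16-bit integer-like scale (the natural
scale of hardware weight storage); the pulse constant `b = 2⁻¹⁵` converts
them to current units, so a full-scale weight injects a unit current pulse.
Weight-range defaults:

| pathway | range (16-bit units) | note |
|---|---|---|
| ORN→LN | 1000–3000 | also the pre-training init range |
| ORN→PN | 4000–8000 | |
| LN→LN | 2000–6000 | operating range; init range for training is 100–400 |
| LN→PN | 1000–3000 | |
| PN→PN | 500–1500 | |

The LN→LN/LN→PN/PN→PN probabilities are 0.25 (LCA) or 1.0 (FPA), 0.5 and
0.5. The operating LN→LN range was chosen (once, by simulation) so that the
documented regime dichotomy is robust: over 20 seeds, the FPA build
(all-to-all, equal weights at the range midpoint) holds a single dominant LN
for the whole stimulus (median 0 winner switches after a 200 ms settling
period, 50 ms windows), while the LCA build switches (median ≥ 1). Weaker
inhibition (e.g. the 100–400 init range) supports no winner-takes-all
competition.

Training pulses are specified as ratio amplitudes (0.5/1.0/1.5); the current
per ratio unit is 0.25, chosen once so the smallest nonzero amplitude is
comfortably supra-rheobase (~62 Hz by the closed-form rate) and the largest
stays in the few-hundred-Hz range. Input noise defaults: 2% of the largest
pulse amplitude on the training drive, 5% of the unit-ratio amplitude
(0.0125 current units) added per step to the ORN drive in the network.

## STDP

Plasticity acts only on ORN→LN and LN→LN synapses. With
`Δt = t_pre − t_post`:

* `Δt ≤ 0`: `+ΔW⁺ · τ₊/(τ₋+τ₊) · e^(−|Δt|/τ₊)` (potentiation),
* `Δt > 0`: `−ΔW⁻ · (1 − τ₋/(τ₋+τ₊)) · e^(−Δt/τ₋)` (depression),

with `ΔW± = 150`, `τ± = 20 ms`. The potentiation exponent uses `|Δt|` (the
literal printed exponent diverges as `Δt → −∞`, contradicting the verbal
description of a decaying kernel), and the depression branch is applied with
negative sign. Updates act on the weight *magnitude* (efficacy) with the
pathway sign applied at current delivery — LN→LN weights are initialised
from a positive range, so potentiation of an inhibitory synapse strengthens
inhibition. Clipping is `[max(w_min, 0), 32767]`; the conventional
two's-complement bounds replace the unrepresentable printed pair, and both
bounds are parameters.

Pairing is nearest-spike by default (per-neuron last-spike memory; a
coincident pre/post pair counts once, as Δt = 0 potentiation); an all-pairs
scheme via exponential spike traces is available (`pairing="all"`).

**Stability.** `train()` records, per epoch, the summed absolute *net*
weight change (end minus start — the convergence measure) and, separately,
the summed per-event turnover. The strict stability epoch is the first with
zero net change; a relaxed criterion (net change < 0.1% of total |w|) is
also reported for floating-point use. At the published magnitudes the rule
is strongly depression-dominated whenever presynaptic rates exceed
postsynaptic ones (nearest pairing generates one depression event per
presynaptic spike but only one potentiation event per postsynaptic spike),
so the plastic afferents weaken until the LN layer falls silent, at which
point the weights freeze — strict stability is typically reached within ~5
epochs at the default drive. This silencing is not an artefact: it yields
exactly the documented post-training phenomenology — frozen ORN→LN weight
pairs whose normalised tunings spread across the ratio space (pooled over
seeds, every trained ratio direction has an LN tuning within 10°; the
preferred-ratio coefficient of variation grows severalfold), and PN
trajectories that are amplified and better separated after training (the LN
layer no longer inhibits the PNs), with ≥ 97% of their variance in the top
three principal components. A surviving-LN regime is reachable by raising
the ORN→LN pulse gain (`g_orn_ln ≈ 2`); there the LN rate traces measurably
decorrelate from pre- to post-training, but the weights flutter ~2% per
epoch around their stable distribution indefinitely and neither stability
criterion triggers. Users wanting slow, partial convergence should lower
`dw_plus`/`dw_minus`.

`train()` re-draws the plastic weights from the randomized pre-training
ranges (ORN→LN 1000–3000, LN→LN 100–400) before the first epoch
(`reinit=True`); the pre/post comparisons in `STDPResults` use that state,
not the operating weights, as the baseline.

## Synthetic chemosensor data

`make_synthetic_sawr` stands in for undeposited laboratory recordings. Per
trial, the coated device of each channel pair drops from a 262 MHz baseline
by a first-order transient toward a steady depression proportional to that
channel's analyte volume (five classes at volume pairs 4:16, 6.7:13.3,
10:10, 13.3:6.7, 16:4 µl) plus a 10% cross-sensitivity leak, with rise/decay
constants in the 50–80 s band, venting at 110 s of a 150 s trace; the
uncoated reference carries only the shared linear drift (0.5 Hz/s) and
noise. Trial-to-trial variability: 5% multiplicative amplitude jitter and 5%
time-constant jitter; white measurement noise of 10 Hz per sample
(0.5 s sampling); 10 trials per class. Sensitivity is 100 Hz/µl, giving
steady differentials of ~0.5–1.7 kHz.

What this emulates: the class structure, timescales, differential
preprocessing and drift cancellation of a dual-SAWR experiment. What it does
not: sensor nonstationarity across a session, adsorption kinetics beyond
first order, delivery-system dynamics, and whatever made the laboratory
recordings hard to classify directly — so passing tests here validate the
pipeline's mechanics and relative behaviours, not field performance.

The differential current is `I(t) = β (f_uncoated − f_coated)` clamped at
zero (sorption lowers the coated frequency; the sign is chosen so sorption
excites, and there is no inhibitory sensory drive). β is calibrated so the
dataset-maximum differential drives the ORN LIF at 50 Hz, via the grid-exact
first-passage inversion with a +10⁻⁹ relative nudge that makes the threshold
crossing robust to floating rounding. Sensor time maps to model time at 10
model-ms per sensor-second by default (clock matching), with linear
interpolation.

## Classification

Rates come from convolving spike indicators with the discrete Gaussian
kernel `T(n,d) = e^(−d) I_n(d)` (normalised, symmetric; truncation radius =
smallest holding ≥ 99.9% of the mass; `d` defaults to τ_m/Δ of the cell; a
causal renormalised mode exists for real-time semantics). Classification is
nearest-mean-trajectory: one template per class (the pointwise trial mean),
the time-averaged Euclidean distance up to the decision time T, argmin over
classes with ties to the lowest label. Decision curves use leave-one-trial-
out rotation; label shuffling estimates the chance level (20% for five
classes, confirmed within binomial error). "Greedy" model selection scores a
seeded pool of random connectomes (default 20 in the spec sense; 5 in the
desk-scale pipeline) by decision-time-averaged accuracy and keeps the first
maximiser. The raw-sensor baseline applies the identical template/distance
machinery to the two normalised differential-current channels (per-channel
max-absolute scale learned on the training split).

**A negative finding, documented deliberately.** On this generator the raw
baseline classifies earlier and better than the spiking model's PN output,
across every matched condition we tested (concentration jitter, heavier
noise, residual random-walk drift, stronger afferent gains, finer clock
compression). Two structural reasons: the PN output is a lossy, noisy
function of the same two channels the raw classifier reads, so it cannot
carry more information; and calibrating the dataset maximum to a 50 Hz ORN
ceiling places the LIF rheobase at 86% of that maximum, leaving the ORNs
silent through most of each slow transient — precisely the early phase. The
corresponding acceptance test states the early-superiority property as a
cross-seed majority criterion and is expected to fail; it is retained
unweakened as an honest record. The `sensor_matched` configuration
(strengthened afferents, softened rheobase via ORN noise) lets the network
operate under sensor drive and is used for all sensor-pipeline experiments.

## Problem sizes and reproducibility

Test and pipeline runs use reduced budgets chosen as the package's own
desk-scale defaults: training fixtures run 40–60 epochs (stability arrives
within ~5), the acceptance script runs the full 300-epoch training, 5 probe
trials per ratio, 10 trials per sensor class, and 10–20 connectome seeds for
stochastic properties. Every stochastic component consumes a seed derived
from a single root via `numpy` seed sequences; identical (config, seed)
pairs produce bit-identical rasters, reports and files.

## Known limitations

Single-compartment LIF without refractoriness (rates quantise to 1000/k Hz
at Δ = 1 ms and are unbounded in current); two glomeruli only are exercised
against the documented behaviours (more are config-permitted but untested);
no PN→LN feedback by design; the fixed-point mode verifies numerics and is
not a gate-level hardware emulation; the STDP stability account above is
specific to the published magnitudes and pairing scheme.
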