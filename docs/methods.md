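# Methods

## Model and assumptions

The circuit is a de-corticated LGN: retinal drive, feed-forward inhibition
through interneurons, feedback inhibition through the reticular nucleus, and
nothing else. All cells fire in tonic mode (the attentive-relay regime);
burst firing, synaptic plasticity and cortical feedback are deliberately out
of scope. Populations are homogeneous — every neuron in a population shares
the same Izhikevich parameters — so all heterogeneity comes from the
probabilistic wiring and the stimulus.

Izhikevich parameters (a, b, c, d, v₀, u₀) per population:

| population | mode | a | b | c | d | v₀ (mV) | u₀ |
|---|---|---|---|---|---|---|---|
| TCR | regular spiking | 0.02 | 0.2 | −65 | 6 | −65 | −13 |
| IN | fast spiking | 0.1 | 0.2 | −65 | 6 | −70 | −14 |
| TRN | regular spiking | 0.02 | 0.2 | −65 | 6 | −75 | −15 |

Units follow the original Izhikevich convention (v in mV, currents in nA,
a–d unitless). Once the network is wired, the bias current I_dc is zero
everywhere: all drive is synaptic.

Synapses are current-based single exponentials. This is a deliberate
simplicity choice (matching the `curr_exp` family of PyNN neuron models):
inhibition can push the membrane far below any biological reversal
potential during volleys (recorded minima near −150 mV occur), which is
accepted as part of the model definition rather than patched.

## Numerical scheme

* Explicit-midpoint (RK2) integration at dt = 0.1 ms, double precision.
  The synaptic current is held constant across a step; accumulator decay is
  exact (`exp(−dt/τ)`) and applied once per step before injection.
* The spike test runs after the full step; on crossing, v resets to c
  exactly and u increments by d exactly. The recorded trace is clamped at
  30 mV on spike steps so plotted spikes have uniform height.
* End-of-step threshold detection quantizes spike times to the step grid
  and adds a small systematic lag (~0.05–0.2 ms per firing cycle) relative
  to a fine-step reference integration. Spike *counts* and interspike
  intervals agree with a 0.1 µs forward-Euler reference to within one spike
  and 1 ms respectively over 1 s; absolute spike times drift by a few ms
  over a second of tonic firing. This is inherent to fixed-step threshold
  integration at this resolution, not an artifact of the RK2 choice.
* Delays are integer step counts (`round(d_conn/dt)`, minimum one step) on
  a ring buffer; arrivals scheduled beyond the simulation end are dropped.
  A non-finite state anywhere aborts the run with the neuron and time named.

## Wiring and seeds

Connection probabilities are interpreted as independent Bernoulli draws per
ordered (pre, post) pair — fixed-probability-connector semantics — with
autapses excluded in the two self-projections (IN→IN, TRN→TRN). Each trial
re-draws both the wiring and any stochastic stimulus from the trial seed
(`base_seed + k`); `redraw_wiring=False` freezes the wiring at the base seed
instead. Seed derivation is hierarchical, so node 1 of a multi-node build is
wired identically to a single-node build at the same seed. Same
configuration + seeds ⇒ bit-identical results.

The multi-node build treats nodes as equidistant: inter-node delays equal
the corresponding intra-node delays, and inter-node pathways replicate the
intra-node TCR→TRN / TRN→TCR / TRN→TRN attributes. Interneurons never
project between nodes.

## Stimuli: what is emulated, what is not

The synthetic periodic train fires all 144 channels simultaneously at the
drive frequency (spike at t = 0 included; optional seeded per-channel
jitter, default 0). Perfect coincidence mirrors the near-synchronous
first-spike volley a flashing LED evokes across sensor pixels; it is an
idealization — a real retina adds latency scatter and occasional missed
cycles.

The DVS (event camera) emulator implements the pixel front end: logarithmic
photocurrent conversion `V_log = K·log I_ph`, a differencing stage tracking
`A·ΔV_log` since the last reset, ON/OFF events on crossing `V_t±` with
self-reset, and per-pixel threshold mismatch as seeded relative jitter
(default 2 %). The front-end constants are not taken from any datasheet;
defaults (K = 1, A = 10, V_ref = 0, V_t± = ±1.5) were set once so that a
contrast-2 LED edge yields `floor(A·K·ln 2 / 1.5) = 4` ON events — a
realistic per-edge density — and all are configurable. The LED drive starts
dark so every OFF→ON transition is a real illumination step. Not modeled:
photon shot noise, pixel bandwidth limits, refractory behavior, and the OFF
pathway (the analysis assumes ON-center receptive fields and keeps only the
first ON event per pixel per cycle). Passing retina-driven tests therefore
demonstrates the circuit's response to realistically timed, thresholded
event volleys — not to any specific hardware sensor's noise floor.

## Analysis chain

Epoch 0.5–5.5 s (drops the onset transient), de-mean, decimate 10 kHz →
1 kHz by plain stride (an anti-alias pre-filter is available but off by
default, matching the stated processing order of epoch-then-downsample-
then-filter), then an order-10 Butterworth band-pass 1–100 Hz applied
forward-backward (zero phase) as second-order sections — an order-10
band-pass in transfer-function form is numerically unstable, SOS is
mandatory. The Welch estimate uses 1 s Hann segments, 50 % overlap and a 4×
zero-padded transform (0.25 Hz bin width). The zero-padding factor is a
parameter: it controls peak-location granularity only, not true resolution.

Peak frequency is the argmax of power density in 1–100 Hz, ties broken
toward the lower frequency.

### Harmonic/subharmonic presence

A component (harmonics k·f₀, k = 1..5; subharmonics (2k−1)·f₀/2, k = 1..4)
is *present* when the maximum power within ±1 Hz of its nominal frequency
both (i) reaches 3× the local background — the median power in a ±5 Hz
annulus excluding the core — and (ii) clears a visibility floor of 1 % of
the strongest power in the band (−20 dB). The floor is essential: in the
base configuration the ½f bin can sit ~10³× above the near-zero local noise
floor while being ~10⁻³ of the fundamental — numerically detectable,
invisible on a log-power spectrum, and not a subharmonic in any meaningful
sense. Measured separations with the defaults: base-configuration ½f
relative power ≤ 5×10⁻³ at all tested drive frequencies; suppressed-variant
½f ≥ 0.76 for drives ≥ 36 Hz and ≤ 2×10⁻³ below 36 Hz; second-harmonic
relative power ≥ 3.6×10⁻² everywhere. The 0.01 floor sits comfortably
inside a two-decade gap.

## Problem sizes

The standard protocol (6 s at dt = 0.1 ms, 10 trials) is used for all
single-condition results, including the acceptance script. Sweeps in the
test tier use 5 representative frequencies and 3 trials; the full
41-frequency, 10-trial sweep is available through the recipes
(`--scale full`) and is the intended desk-scale experiment. One 6 s trial
of the 140-neuron block integrates in well under a second on a single CPU
core once the compiled core is warm.

## Known limitations

* The gamma-band response under Poisson drive is a broad, sometimes bimodal
  bump (lobes near ~47 and ~61 Hz with the default synapse time constants);
  its argmax can hop between lobes as the input rate or seed changes, so
  "peak location" is a fragile statistic there even though the band itself
  is stable.
* Synaptic time constants are configuration defaults (τ_e = 2 ms, τ_i =
  6 ms, plausible for AMPA/GABA-A in thalamocortical circuits), not
  measured quantities; oscillation frequencies in the gamma band shift with
  τ_i.
* Current-based synapses admit unphysiological membrane excursions during
  strong inhibitory volleys (see above).
* The homogeneous-population assumption makes unconnected populations
  perfectly synchronous; real LGN cells are heterogeneous.
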