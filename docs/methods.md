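# Methods

This note documents the model equations as implemented, the parameters
that matter, the numerical choices, and what the reduced-scale test
conditions do and do not show.

## Neuron and synapse dynamics

Membrane potentials follow the conductance-based LIF equation

    τ_v dV/dt = (V_rest − V) − V·g_e + (−85 mV − V)·g_i

with dimensionless conductances that jump by the synaptic weight on an
afferent spike and decay exponentially (τ_ge = 5 ms, τ_gi = 10 ms).
Excitatory neurons use −65/−65/−52 mV (rest/reset/threshold) and
τ_v = 20 ms, inhibitory neurons −60/−45/−40 mV and τ_v = 10 ms.  There
is no refractory period and no adaptive threshold.

Integration is forward Euler at dt = 0.5 ms for V; conductances and
STDP traces decay by the exact exponential factor per step (the linear
decay has a closed form, and using it removes dt-sensitivity from the
decay while leaving the membrane integration explicitly Eulerian).  The
update order within a global step is fixed and documented: (1) decay
conductances and traces, (2) integrate V, (3) detect V ≥ V_thresh and
reset, (4) deliver spikes — conductance increments, then pre-side
depression, then post-side potentiation, then traces set to 1.  A spike
therefore influences its targets from the next step on (one-step axonal
delay).  When a synapse's source and target fire in the same step, the
depression is applied before the potentiation; both use the decayed
trace values.

STDP parameters: ν_pre = 0.0005, ν_post = 0.0025, η = 0.2 on both
sides, w_max = 0.5, τ_r = 20 ms; τ_o = 40 ms for synapses between
excitatory neurons and 20 ms for inhibitory→excitatory synapses, so each
plastic connection keeps its own o vector (two decay constants cannot
share one state).  Inhibitory→excitatory STDP uses the same rates and
exponents — no separate values are published.  Each connection type caps
weights at w_max = max(initialization ceiling, 0.5); for types whose
initialization ceiling exceeds 0.5 (input→exc in the single-population
network, inh→exc) the cap equals the ceiling, so initial weights are
never truncated.

Synaptic scaling — the homeostatic mechanism the model relies on — is a
multiplicative per-column normalization of every structurally plastic
(excitatory→excitatory type) matrix back to its column sums at
initialization, applied at each structural-plasticity interval and
clipped at w_max.  The normalization constant is a design choice; the
initialization column sum keeps total excitatory input budget constant
while pruning concentrates it on fewer synapses.

## Networks

A computation population holds 1600 excitatory and 400 inhibitory
neurons; an input population 1600 Poisson units.  All four recurrent
connection types exist; 10% of possible synapses are chosen per
connection with *exactly* equal counts per column (target neuron), and
weights drawn uniformly below the per-type ceiling (input→exc 1.0
single-population / 0.5 three-way, input→inh 0.2, exc→exc 0.2, exc→inh
0.2, inh→exc 1.0, inh→inh 0.4).  Structural plasticity ("P+S") applies
to all matrices between excitatory neurons (input→exc, recurrent
exc→exc, long-range); inh→exc is STDP-only ("P"); exc→inh and inh→inh
are static.

The three-way network couples populations A, B, C (driven by inputs X,
Y, Z) to a hub population H that receives no direct input; long-range
matrices (ceiling 0.5) exist only between H and each of A, B, C, in both
directions but sampled independently per direction.  A
`peripheral_cross_links` switch can add direct A–B/B–C/A–C coupling; it
is off by default, the minimal reading of a hub topology.

A `scale` factor shrinks all populations together (4:1 exc:inh
preserved, densities unchanged).  The tested desk scale is 0.125
(200/200/50 per population, 20 synapses per column).

Column sorting orders each population's excitatory neurons by preferred
stimulus (circular mean of the input weight profile), applied once
before training to matrices, traces and counters consistently.
Preferences are snapped at 1e-12 before sorting so a preference of
exactly zero cannot land at 1−ε through floating-point sign noise.

## Structural plasticity

All rules run every 50 training examples, after synaptic scaling, and
only ever create synapses in the column where synapses were removed (no
target neuron is starved).  Defaults: weakness threshold
θ_w = 0.1·w_max of the connection type, deletion count threshold
θ_c = 3, grace g = 2, new-synapse weight w_new = θ_w (at the threshold,
so the grace period decides its fate).  None of these numbers are
published; all are config-exposed.

The pruning target per column is kept as a float and multiplied by λ at
each application, clamped at the floor (half the initial count); the
effective integer target is max(round(c₀·λᵏ), floor).  Keeping the float
internally makes the count follow the exponential exactly — iterated
integer rounding drifts and can stick at half-integers.  In the
mode-comparison experiments λ is derived so the floor is reached after
two thirds of the configured training examples (λ = 0.5^(1/(⅔·N/50))),
mirroring a decreasing pruning rate.  Pruning deletions (weakest
synapses of over-full columns) bypass the bookkeeping counters.

Spatial placement computes P = exp(W ∗ G) with a unit-peak wrapped 2-D
Gaussian (σ = 10 along sources, 5 along targets; wrapped borders match
the circular stimulus), implemented as circulant matrix products — exact
torus convolution without kernel truncation, verified elementwise
against a direct O(n⁴) oracle.  Raw weights enter the convolution; a
synapse of weight w contributes w at its own location.  Occupied
positions are zeroed and columns renormalized; under simultaneous
circular shifts of sources and targets the distribution is equivariant
to floating-point rounding (summation order changes, so bitwise equality
is not guaranteed).

## Coding and noise estimation

Rates: rate_j = r_max·exp(−d(j/n, x)²/(2σ²)) with circular distance d
and σ = 1/12; spikes are per-step Bernoulli draws (rate·dt, valid while
rate·dt < 1), regenerated independently each presentation.  Decoding
uses 0-based indices with phase 2πj/n; activities are spike counts in
one 250 ms presentation.

The peak rate r_max is not published.  With the literal weight ceilings,
strong input ignites a self-sustained saturated state — the excitatory
driving force (reversal 0 mV) grows with hyperpolarization while the
inhibitory one vanishes at −85 mV, so a large enough g_e always wins,
and potentiation (ν_post = 5ν_pre) locks it in.  The default is
therefore chosen by a stability rule: the highest integer peak rate for
which all desk-scale training runs (3 seeds × all modes at scale 0.125)
stay inside the instability guard.  That gives r_max = 4 Hz.  The guard
itself flags divergence when the mean excitatory rate exceeds 200 Hz for
5 consecutive examples; single hot examples occur transiently and are
quenched by inhibitory potentiation within a few examples, while genuine
divergence saturates indefinitely.

Inference probes of the three-way network (X, Y driven, Z silent) use a
40 Hz probe drive: activity has to propagate through two synaptic stages
before C can be decoded, which the 4 Hz training rate cannot sustain at
reduced scale.  Noise probes of the single-population network use the
training rate, since they measure the response to the code the network
was trained on.

The noise fit minimizes least squares of
a·exp(−(x−μ)²/2σ²) + max(0, o) over x = j/n on the unit-area normalized
density (the clamp is inside the model the optimizer sees).  Initial
guesses: a = 1/(σ_input√2π), μ = circular mean of the density (0.5 if
undefined), σ = σ_input, o = 0.  Responses centered within 2σ_input of
the wrap seam are rolled to 0.5 before fitting and the mean rolled back,
keeping the non-circular model well posed.  Tolerances 1e-8, at most
2000 function evaluations, with a coarse grid of restarts before a fit
failure is declared; σ is reported as |σ| and o_noise clamped at 0.

## Experiments

Training presents 250 ms examples continuously (membrane, conductance
and trace state carry over between examples) at dt = 0.5 ms.
Evaluations freeze all plasticity, reset the dynamic state, present 5
evenly spaced probe stimuli (single presentations), record the mean
fitted offset and decoding error, and restore the training state
exactly — probing is side-effect-free.  The metric cadence is every 250
examples.  A run is a pure function of (configuration, seed); matched
comparisons build one network per seed and copy it per mode, so initial
matrices are bit-identical across modes.

The hot loop is a numba kernel operating on the same weight/mask/trace
buffers as the library objects; a pure-numpy reference composed from the
module-level operations reproduces it spike for spike (state equal to
floating-point rounding — the two use different `pow` implementations
that may differ in the last ulp).

Desk-scale study conditions: scale 0.125, 2000 examples, 3 seeds,
comparing STDP-only against bookkeeping-with-pruning (seed-averaged
o_noise over the final third of training).  The untrained three-way
baseline uses 200 random probe pairs.  Problem sizes were chosen so the
full comparison completes in minutes on one CPU core.

## What the desk scale does and does not show

At scale 0.125 with r_max = 4 Hz the network operates in a sparse,
fluctuation-driven regime (mean excitatory rates of a few Hz).  Two
consequences:

- The postsynaptic trace o has usually decayed to ~0 by the next spike
  of the same neuron, so STDP weight changes are small and
  receptive-field sharpening over 2000 examples is modest — much weaker
  than in the full-scale, higher-rate published regime.  The measured
  desk-scale denoising ordering arises mostly from pruning and synaptic
  scaling concentrating the fixed weight budget on fewer synapses,
  which strengthens responses relative to the sampling-noise floor of a
  single 250 ms probe.
- Quantitative full-scale results (fitted response parameters after
  15,000 examples, the relative speed-up of noise reduction) are *not*
  asserted by the test suite; the full-scale configuration is exposed
  for multi-hour reproduction runs instead.

Other known limitations: the synthetic stimulus stream is uniform on
the circle with no temporal correlations; Poisson inputs are
conditionally independent across neurons; the offset fit assumes a
single response bump; no refractory period means firing rates are
bounded only by the time step; and the model neglects silent-synapse /
receptor-expression dynamics entirely — newly created synapses behave
like ordinary weak synapses from the first step.
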