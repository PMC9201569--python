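# Methods

This note records the modelling conventions, parameter choices and known
limitations of `spikebench`. It is the place where genuinely open design
decisions are stated as such.

## Reference simulator

The engine is a clock-driven integrator in the tradition of fast digital
SNN simulators. Within each step of width `dt` (default 0.1 ms) it:
delivers spikes due this step (axonal delay ≥ one step), adds them to the
exponentially decaying synaptic state, advances the membrane with the exact
closed-form solution of the LIF equation under input held constant over the
step, tests the threshold at the step boundary, and applies reset and
refractoriness. Spike times are end-of-step times. This convention was
chosen over error-controlled Runge–Kutta integration because it makes
determinism trivial and matches the integration scheme of the platforms the
reference backend stands in for; an adaptive integrator remains a possible
alternative profile, not implemented.

Consequences worth knowing:

* a self-firing neuron (resting potential above threshold — an explicitly
  supported configuration) spikes every `tau_refrac + dt`, so the maximal
  output rate benchmark has the closed-form oracle `1000/(tau_refrac+dt)` Hz;
* spike times are quantized to `dt`; halving `dt` moves threshold crossings
  by at most one step each, which bounds the spike-count change under
  constant drive to about one per hundred;
* during refractoriness the membrane is clamped to `v_reset` but synaptic
  state keeps integrating. Substrates differ on this point and the
  literature the benchmarks descend from does not fix it; clamped-membrane /
  integrating-synapse is the common software-simulator default and is used
  throughout.

Current-based synapses sum nA directly; conductance synapses (µS) drive the
membrane toward their reversal potentials, with the conductances likewise
held constant over a step. Both decay exponentially with their `tau_syn`.

Randomness: one root seed per run; each source population draws from a
child stream derived by stable hashing of its population id, so adding or
removing a population never changes the noise any other population
receives. Connection realizations (`fixed_probability`) use per-connection
child streams of the same root.

STDP is the additive spike-pair rule with hard bounds: pre-before-post
potentiates by `a_plus * exp(-Δt/tau_plus)`, post-before-pre depresses by
`a_minus * exp(Δt/tau_minus)`, coincident pairs apply neither branch, and
pairing is nearest-neighbour per synapse. The pair lag is formed from
emission times, ignoring the axonal delay; with the millisecond-scale
delays used here the distinction is far below the plasticity time
constants. All-to-all pairing is the main untested alternative.

## Backend constraint profiles

Profiles describe what a substrate accepts: supported neuron models,
neuron budget, synaptic fan-in per neuron, weight resolution, and whether a
population may project only one receptor type (Dale-style separation, the
property that forces the mirror-population workarounds below). The
`reference` profile is unconstrained; `spikey-like` models a small
accelerated analogue chip (conductance LIF only, 384 neurons, 256 synaptic
inputs, separated excitation/inhibition, 4-bit weights); `spinnaker-like`
models a digital many-core system. Violations are returned as data so a
runner can report "not mappable" instead of failing.

## Benchmarks and their parameters

**Maximal output rate.** Self-firing population; default parameters place
the resting potential 20 mV above threshold with `tau_m` = 1 ms so the
neuron re-crosses threshold in the first step after refractoriness, making
the refractory bound tight.

**Spike insertion.** All neurons receive simultaneous input spikes
(default ten per neuron, spaced ≥ 5·tau_m). A sharp synapse
(`tau_syn` = 1 ms) with a 5 ms refractory period guarantees exactly one
output spike per sufficiently strong input spike, so the reference backend
is lossless by construction; a probe neuron asserts the weight is above
threshold before the population runs. Hardware spike-loss curves are a
property of physical substrates and are deliberately not modelled.

**ReLU similarity.** One Poisson source per sampled input rate drives a
group of neurons one-to-all; the metric is the mean absolute deviation of
the mean response from a target line, normalized by the corridor's maximum
mean response, plus the neuron-to-neuron standard deviation averaged over
the corridor. The target line is not uniquely fixed by the benchmark's
ancestry; the default here is the least-squares line over the corridor
clamped at zero, and an explicit target can be supplied instead (the
deviation formula is tested against a supplied target).

**WTA kernels.** Two (or more) populations with private Poisson noise,
self-excitation, and mutual inhibition wired in one of three styles. The
winner of each 15 ms bin is the population with strictly most spikes; ties
and silence are undecided. Undecided bins break winning streaks and do not
count as state changes — the metrics' edge semantics are a package choice,
stated here because the three metrics themselves do not fix them. The
noise rates and weights of these networks are configuration, not
publication: the defaults (150 Hz noise, 0.8 nA noise weight, 0.15 nA
self-excitation, 0.6 nA inhibition on 0.25 nF / 10 ms membranes) were fixed
once, by hand, to give robust competition on the reference backend, and
live in `data/benchmark_defaults.json`.

**Sudoku.** Every (cell, digit) hypothesis is a population of
`pop_size` = 4 neurons (configurable; the size index scales it); the
constraint graph — built with networkx over cell, row, column and box
conflicts — is wired as mutual inhibition; every neuron has its own Poisson
source. Clues are encoded by multiplying the clue population's noise rate
by 4 (the mechanism is not fixed by the benchmark's ancestry; elevated
input rates are the simplest that works and the factor is configurable).
Winner extraction uses 20 ms bins; the time to solution is the END time of
the first bin whose complete assignment matches the stored solution, so the
smallest reportable value is one bin. The default 4×4 puzzle has 8 clues
(half the grid) with a verified-unique completion. The `simple` and
`single_population` styles build the logically identical network (tested:
bit-identical winner traces under a shared seed); `mirror` routes
inhibition through mirror populations and, built with conductance neurons
at `pop_size` = 2, passes the Dale-separated profile.

**Binary associative memory.** Training ORs outer products of sparse
binary pattern pairs; boolean recall thresholds column dot products at the
full input weight `k_in`. Spiking recall uses the matrix as synapses onto
one LIF neuron per output bit, with the weight calibrated from a measured
peak depolarization so that `k_in` coincident spikes fire a neuron and
`k_in − 1` do not; equivalence with the boolean route is asserted
exhaustively for n ≤ 16. Retrieved information per sample with `fp` false
positives and `fn` false negatives against a weight-`d` pattern in `n` bits
is

    I = log2 C(n,d) − log2[ C(d−fn+fp, fp) · C(n−(d−fn+fp), fn) ],

floored at zero — the log-count of stored patterns compatible with the
recalled vector. The formula is a stated, testable choice: it reduces to
`m·log2 C(n,d)` under perfect recall and to 0 for an all-ones recall, and
those endpoint identities are what the tests pin down. For larger networks
recall is evaluated on a subset of stored samples and capacity extrapolated
linearly.

**Function approximation.** Inputs in [0,1] are encoded linearly to a
Poisson rate (≤ 300 Hz); responses are decoded against a 150 Hz maximum and
clipped to the unit interval. Neurons are diversified by random-sign,
random-magnitude input weights and private fixed-rate Poisson biases, both
frozen per benchmark instance so that the fit and test runs share the
tuning structure and differ only in noise. Coefficients are least-squares
on 40 fit points (32 neurons); evaluation is on the 79-point midpoint grid
decoded from an independently seeded second run. Because the tuning-curve
basis is collinear and carries Poisson counting noise, the plain normal
equations amplify noise into large alternating coefficients; the decode
therefore truncates singular values below 1 % of the largest (standard
regularization for noisy rank-deficient least squares, exposed as `rcond`).
At these sizes one benchmark run takes a few seconds on one CPU.

**ANN→SNN conversion.** Bias-free dense ReLU stacks become one LIF
population per layer; weight sign selects the receptor, magnitude is scaled
by a single `weight_scale` knob (a coarse grid-sweep utility is provided,
not auto-run). Rate coding presents each sample for 500 ms by default and
classifies by output spike count (ties break to the lowest index,
documented); TTFS coding emits one spike per input at `(1−x)·T` and
classifies by the earliest output spike, with the response time measured
from the first input spike. The TTFS path is first-spike classification
over standard LIF dynamics with conductance synapses — an approximation of
dedicated TTFS conversion schemes that manage hidden-layer reset/ramp
dynamics explicitly, and labelled as such. The test fixtures are
constructed (not trained) tiny classifiers; external digit datasets are
supported through the same interfaces but no shipped result depends on one.

**Map learning (SLAM-style).** A position-only state machine: one source
and one neuron per grid cell driven along the agent's trail (20 ms per
step); a bumper neuron fires on collisions; map neurons fire when the
bumper does; plastic one-to-one position→map synapses potentiate on the
position/bump coincidence. STDP constants (`a_plus` 0.8, `tau` 5 ms,
`a_minus` 0.01 against w_max = 1) are chosen so a single coincidence at
~1 ms pair lag clears the `(w_min+w_max)/2` read-out threshold while spikes
one trail step away contribute ≈ 1.5 % of `w_max`. A bump is attributed to
the blocked target cell. Heading populations and WTA position tracking are
intentionally out of scope — the scored metric (pixel-wise FP/FN against
the true obstacle set) depends only on the learnt map, and obstacles never
bumped on the trail are expected false negatives.

## Energy model

`E = P_idle·T_wall + P_neuron·N·T_wall + e_src·S + e_spike·K + e_trans·Σ(spikes×fan-out) + [P_stdp·T_wall + e_stdp·U]`,
with `T_wall = model duration × realtime factor` (10⁻⁴ for accelerated
analogue systems, 1 or 10 for realtime/slowed digital ones). Placement,
congestion, DVFS and thermal effects are explicitly unmodelled — which is
precisely why the model transfers counts measured on one backend to
another's coefficients, and why its projections for modern GPUs should not
be trusted beyond order of magnitude.

Coefficient extraction follows a staged protocol (each stage's power an
average of ≥ 20 readings): idle system, idle neurons, self-firing neurons,
source events, transmissions, and optionally plasticity. Each stage
exposes one new coefficient as the residual after subtracting what the
previously derived coefficients predict; a synthetic protocol generator
makes the decomposition exactly invertible, which the tests exploit as a
round-trip identity. Because static STDP power and per-update energy are
two unknowns, the plasticity measurement is split into two stages (enabled
with zero updates, then with updates). Negative residuals are kept and
flagged rather than clamped: they are measurement noise and clamping would
bias sums of coefficients.

The biological comparison multiplies per-process ATP rates (resting
maintenance; action-potential generation, stated at a 4 Hz reference rate
and scaled linearly with rate; and three per-synaptic-event items scaled by
fan-out × rate) by 5·10⁻²⁰ J/ATP, within the reported 4.65–5.56·10⁻²⁰
bracket. Housekeeping adds 33 % of the signaling cost (total minus
resting). The action-potential line item must be read as ATP/s at 4 Hz —
the only reading under which the per-neuron total, the watt column and the
per-event rows are mutually consistent, as the tests verify numerically.
Whole-brain figures multiply per-neuron watts by 8.61·10¹⁰ neurons; this is
a naive upscaling that ignores connectivity infrastructure, and is labelled
as such. Technology scaling divides by a fixed factor or by
`2^(years/period)` for performance-per-watt doubling every 3–4 years.

Shipped per-platform rows (`data/platform_presets.json`) are per-neuron
normalized costs for composing scale-up comparisons; raw machine
coefficients are user-supplied via the measurement protocol CSV.

## What the synthetic fixtures do and do not show

The generators emulate the *structure* of the benchmark inputs — puzzle
constraint density, pattern sparsity, trail coverage statistics, class
separability — under exact reproducibility. They do not emulate analogue
device mismatch, trial-to-trial drift, bandwidth saturation or spike loss;
the reference backend is noiseless and lossless by construction. Passing
tests therefore certify the correctness of the network constructions,
metrics and energy arithmetic, and the behaviour of the algorithms under
Poisson input noise — not the performance any physical substrate would
achieve. Hardware-only quantities (wall-clock columns, measured millijoule
budgets, loss-versus-size curves) are out of scope by design.

## Numerical and testing choices

Default problem sizes keep a full test run within about a minute on one
CPU: ten 2-second Sudoku simulations, two 1.5-second function-approximation
runs at 40–79 input points, sub-second unit simulations elsewhere; the same
sizes are used by `scripts/acceptance.py`. The engine is cross-checked
against an independent scalar per-step reimplementation on a two-neuron
chain (dual-route test) rather than against an external simulator.
Degenerate inputs have defined behaviour: empty networks simulate to empty
results, an all-silent ReLU corridor reports zero deviation against the
zero line, a silent output layer classifies as UNDECIDED and counts as
wrong, unsolved Sudoku runs contribute the full simulation duration to the
mean (conservative censoring) and are reported separately.
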