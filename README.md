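# spikebench

Cross-platform benchmarks for spiking neural networks, with a deterministic
reference simulator and an additive per-event energy model.

Neuromorphic substrates — analogue LIF circuitry, digital many-core systems,
GPU/CPU simulators — differ in which networks they can execute at all
(neuron models, fan-in, separation of excitation and inhibition) and in how
fast and how efficiently they execute them. `spikebench` is for researchers
who want to characterize such substrates with a common set of workloads: it
ships the network descriptions, the metrics, a reference backend to run them
on, and an energy model that turns event counts into joules so that
performance and efficiency can be compared on the same footing, including
against the biological benchmark of the human brain.

## What is in the box

**Reference simulator** (`spikebench.simulator`). A clock-driven
integrator for current- and conductance-based LIF neurons using the exact
closed-form membrane update with input held constant over each step
(default `dt` = 0.1 ms), Poisson and spike-array sources, delayed
excitatory/inhibitory projections, and additive spike-pair STDP with
nearest-neighbour pairing. Runs are bit-reproducible given
`(network, duration, dt, seed)`. Backend constraint profiles
(`spikebench.constraints`) check whether a network is mappable to a
Dale-separated analogue chip or a many-core digital system before you try.

**Three benchmark tiers**, from substrate characterization to full
applications:

* *Low level*: maximal output rate of self-firing neurons (bounded by
  `1000 / tau_refrac` Hz), lossless simultaneous spike insertion, and the
  similarity of the activation curve to the ReLU line that rate-coded
  ANN-to-SNN conversion assumes.
* *Kernels*: three winner-take-all wirings (direct cross-inhibition, global
  inhibitory pool, mirror populations) scored by winning streak, state
  changes, and undecided time on a 15 ms-binned winner trace.
* *Applications*: a Sudoku solver that encodes the puzzle's constraints as
  mutual inhibition between cell-digit populations (metric: bio time to
  solution); a Willshaw-style binary associative memory recalled both as a
  boolean matrix product and as a spiking network (metric: retrieved
  information in bits); function approximation from LIF tuning curves with
  least-squares decoders, f(x) ≈ Σᵢ aᵢ gᵢ(x); conversion of bias-free dense
  ReLU stacks to spiking networks with rate or time-to-first-spike coding
  (f(x) = (1−x)·T); and STDP-based map learning from a bumper sensor on a
  15×15 grid world (metric: pixel-wise false positives/negatives).

**Energy model** (`spikebench.energy`). Total energy of a run is modelled
as a sum over six contributions: idle system power, idle power per neuron,
energy per emitted spike, per source event, per spike transmission
(spikes × fan-out, placement-independent), and STDP costs. Coefficients are
derived from a staged measurement protocol by successive subtraction (idle →
idle neurons → self-firing → sources → transmission → plasticity). On the
biological side, per-process ATP budgets are converted to watts at
5·10⁻²⁰ J/ATP and scaled with a 4 Hz mean rate, a fan-out of 2000, and a
housekeeping surcharge of 33 % of signaling cost; scaling the per-neuron
power to 8.61·10¹⁰ neurons yields a whole-brain figure of ≈ 21.5 W against
which per-platform rows are composed and compared, including projections to
newer fabrication processes.

**Fixtures and CLI** (`spikebench.fixtures`, `spikebench.cli`). Every
benchmark runs on seeded synthetic inputs: generated Sudoku puzzles with
verified-unique solutions, sparse binary pattern sets, random-walk grid
worlds, and constructed tiny ReLU classifiers (≥ 95 % on their own data).
No external datasets are required.

## Worked example

Solve a generated 4×4 Sudoku with the mirrored-inhibition network on the
reference backend, three noise seeds:

```bash
$ spikebench run --benchmark sudoku --index 1 --seed 1 --set n_repetitions=3
running 'sudoku' (backend=refsim, index=1, seed=1)
  times_ms: [60.0, 40.0, 60.0]
  mean_time_ms: 53.333333333333336
  std_time_ms: 9.428090415820632
  fraction_solved: 1.0
```

Each repetition reports the end time of the first 20 ms bin in which every
cell's spike-count winner matches the puzzle's solution; here the network
settles within two to three bins of model time, and the independent
constraint checker accepts every reported assignment. The full results JSON
(`--out results.json`) echoes the effective configuration for provenance.
`spikebench list` shows all registered benchmarks; `--backend spikey-like`
validates mappability against a constrained profile instead of crashing on
unmappable networks.

The energy side takes three lines:

```python
>>> from spikebench.energy import ATPBudget, brain_neuron_power, scale_to_brain
>>> p = brain_neuron_power(ATPBudget(), include_housekeeping=True)
>>> print(f"{p:.3e} W/neuron -> {scale_to_brain(p):.1f} W whole brain")
2.488e-10 W/neuron -> 21.4 W whole brain
```

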