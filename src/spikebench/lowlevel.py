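"""Tier-1 characterization benchmarks.

These measure basic substrate properties that bound every higher-level
network: the maximal sustainable output rate of neurons (limited by the
refractory period and the time step), losslessness of simultaneous spike
insertion, and how closely the neuron activation curve tracks the ReLU
line that rate-coded ANN conversion assumes.

All rates are evaluated in the biological time domain (model ms), never in
wall-clock terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .network import (
    Connection,
    Connector,
    NetworkDescription,
    NeuronParameters,
    Population,
)
from .simulator import DEFAULT_DT, simulate

__all__ = [
    "RateCurve",
    "SELF_FIRING_PARAMS",
    "max_output_rate",
    "spike_insertion",
    "relu_similarity",
    "curve_deviation",
]

#: Self-firing configuration: resting potential above threshold, with the
#: membrane time constant small enough that the neuron re-crosses threshold
#: in the first step after its refractory period ends, so the output rate is
#: exactly 1000 / (tau_refrac + dt) Hz on the reference backend.
SELF_FIRING_PARAMS = NeuronParameters(
    v_rest=-40.0,
    v_thresh=-60.0,
    v_reset=-61.0,
    tau_m=1.0,
    tau_refrac=1.0,
)


@dataclass
class RateCurve:
    """Mean/std output rate per sampled input rate (std across neurons)."""

    input_rates: np.ndarray
    mean_output: np.ndarray
    std_output: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "input_rate_hz": self.input_rates,
                "mean_output_hz": self.mean_output,
                "std_output_hz": self.std_output,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def max_output_rate(
    n_neurons: int,
    record_fraction: float = 1.0,
    duration: float = 1000.0,
    params: Optional[NeuronParameters] = None,
    dt: float = DEFAULT_DT,
    seed: int = 0,
) -> np.ndarray:
    """Per-neuron output rate (Hz) of a self-firing population.

    The population fires by itself (``v_rest > v_thresh``); the measurable
    rate is bounded above by ``1000 / tau_refrac`` Hz through the
    configurable refractory state.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    if not 0 < record_fraction <= 1:
        raise ValueError("record_fraction must be in (0, 1]")
    params = params or SELF_FIRING_PARAMS
    n_rec = max(1, int(round(record_fraction * n_neurons)))
    pop = Population(
        "max_rate", n_neurons, "lif_current", params, record=list(range(n_rec))
    )
    net = NetworkDescription().add(pop)
    result = simulate(net, duration, dt=dt, seed=seed)
    return result.rates("max_rate")


def spike_insertion(
    n_neurons: int,
    spikes_per_neuron: int = 10,
    weight: float = 6.0,
    connector: Optional[Connector] = None,
    params: Optional[NeuronParameters] = None,
    dt: float = DEFAULT_DT,
    seed: int = 0,
) -> float:
    """Mean output spikes per neuron under simultaneous spike insertion.

    Every neuron receives ``spikes_per_neuron`` input spikes at identical
    model times via the connector (default one-to-one), with repetitions
    spaced at least ``5 * tau_m`` apart so the membrane relaxes in between.
    A single probe neuron asserts first that one input spike at this weight
    forces one output spike; zero-weight or inhibitory stimulation
    legitimately yields a mean of 0.
    """
    # short synapse plus a refractory period outlasting the residual input
    # current: one inserted spike elicits exactly one output spike
    params = params or NeuronParameters(tau_refrac=5.0, tau_syn_exc=1.0, c_m=0.25)
    connector = connector or Connector.one_to_one()
    gap = max(5.0 * params.tau_m, 5.0 * params.tau_syn_exc, 10.0)
    times = [10.0 + k * gap for k in range(spikes_per_neuron)]
    duration = times[-1] + gap

    if weight > 0:
        probe = NetworkDescription().add(
            Population("src", 1, "source_array", {"spike_times": [times[0]]}),
            Population("probe", 1, "lif_current", params),
            Connection("src", "probe", Connector.one_to_one(), weight),
        )
        probe_res = simulate(probe, 10.0 + gap, dt=dt, seed=seed)
        if len(probe_res.spikes["probe"][0]) < 1:
            raise ValueError(
                "configuration error: weight below firing threshold "
                "(probe neuron silent)"
            )

    net = NetworkDescription().add(
        Population("src", n_neurons, "source_array", {"spike_times": times}),
        Population("pop", n_neurons, "lif_current", params),
        Connection("src", "pop", connector, weight),
    )
    result = simulate(net, duration, dt=dt, seed=seed)
    return float(np.mean(result.spike_counts("pop")))


def spike_insertion_inhibitory(
    n_neurons: int, spikes_per_neuron: int = 10, weight: float = 6.0, **kw
) -> float:
    """Inhibitory variant of :func:`spike_insertion` (mean must be 0)."""
    params = kw.pop("params", None) or NeuronParameters(
        tau_refrac=5.0, tau_syn_exc=1.0, c_m=0.25
    )
    connector = kw.pop("connector", None) or Connector.one_to_one()
    gap = max(5.0 * params.tau_m, 10.0)
    times = [10.0 + k * gap for k in range(spikes_per_neuron)]
    net = NetworkDescription().add(
        Population("src", n_neurons, "source_array", {"spike_times": times}),
        Population("pop", n_neurons, "lif_current", params),
        Connection("src", "pop", connector, weight, receptor="inhibitory"),
    )
    result = simulate(net, times[-1] + gap, seed=kw.pop("seed", 0))
    return float(np.mean(result.spike_counts("pop")))


def _fit_clamped_line(rates: np.ndarray, mean_resp: np.ndarray) -> np.ndarray:
    """Least-squares line over the corridor, clamped at zero (ReLU target)."""
    A = np.column_stack([rates, np.ones_like(rates)])
    coef, *_ = np.linalg.lstsq(A, mean_resp, rcond=None)
    return np.maximum(0.0, A @ coef)


def curve_deviation(
    mean_resp: np.ndarray,
    target: np.ndarray,
    normalize_by: Optional[float] = None,
) -> float:
    """Mean absolute deviation from a target curve, in normalized units.

    ``normalize_by`` defaults to the corridor's maximum mean response; a
    fully silent corridor is degenerate and compared against the zero line
    without normalization.
    """
    mean_resp = np.asarray(mean_resp, dtype=float)
    target = np.asarray(target, dtype=float)
    if normalize_by is None:
        normalize_by = float(np.max(mean_resp))
    if normalize_by <= 0:
        return float(np.mean(np.abs(mean_resp)))
    return float(np.mean(np.abs(mean_resp - target)) / normalize_by)


def measure_rate_curve(
    input_rates: Sequence[float],
    n_neurons: int = 16,
    weight: float = 0.15,
    duration: float = 1000.0,
    params: Optional[NeuronParameters] = None,
    dt: float = DEFAULT_DT,
    seed: int = 0,
) -> RateCurve:
    """Drive a population at each input rate and record the response curve.

    One Poisson source per sampled rate projects one-to-all onto its own
    group of ``n_neurons`` neurons; all corridor points run in a single
    simulation.
    """
    params = params or NeuronParameters(c_m=0.25, tau_refrac=1.0)
    net = NetworkDescription()
    for k, rate in enumerate(input_rates):
        net.add(
            Population(f"in_{k}", 1, "source_poisson", {"rate": float(rate)}),
            Population(f"pop_{k}", n_neurons, "lif_current", params),
            Connection(f"in_{k}", f"pop_{k}", Connector.all_to_all(), weight),
        )
    result = simulate(net, duration, dt=dt, seed=seed)
    means, stds = [], []
    for k in range(len(input_rates)):
        rates = result.rates(f"pop_{k}")
        means.append(float(np.mean(rates)))
        stds.append(float(np.std(rates)))
    return RateCurve(np.asarray(input_rates, float), np.array(means), np.array(stds))


def relu_similarity(
    input_rates: Sequence[float],
    n_neurons: int = 16,
    params: Optional[NeuronParameters] = None,
    weight: float = 0.15,
    duration: float = 1000.0,
    seed: int = 0,
    target: Optional[np.ndarray] = None,
) -> Tuple[float, float]:
    """Similarity of the activation curve to the ReLU line.

    Returns ``(avg_deviation, avg_std)``: the normalized mean absolute
    deviation of the mean response from the target line (default: clamped
    least-squares fit over the corridor), and the mean across frequencies of
    the per-frequency standard deviation across neurons, normalized the same
    way.
    """
    rates = np.asarray(input_rates, dtype=float)
    if len(rates) < 2:
        raise ValueError("need at least two input rates")
    if np.any(rates < 0):
        raise ValueError("input rates must be >= 0")
    curve = measure_rate_curve(
        rates, n_neurons, weight, duration, params, seed=seed
    )
    max_resp = float(np.max(curve.mean_output))
    if max_resp <= 0:
        # degenerate corridor: everything silent, deviation against zero line
        return 0.0, 0.0
    if target is None:
        target = _fit_clamped_line(rates, curve.mean_output)
    avg_dev = curve_deviation(curve.mean_output, target, normalize_by=max_resp)
    avg_std = float(np.mean(curve.std_output) / max_resp)
    return avg_dev, avg_std
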