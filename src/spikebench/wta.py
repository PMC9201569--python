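"""Winner-take-all kernels: three wiring styles and their dynamics metrics.

Mutually inhibiting populations driven by private Poisson noise compete for
activity; one population's firing suppresses the others.  The three styles
trade off directness against hardware mappability:

* ``direct`` -- self-excitation plus direct cross-inhibition; the excitatory
  populations project both receptor types, which violates Dale-separated
  substrates;
* ``global_inhibition`` -- one shared inhibitory pool carries all
  cross-inhibition;
* ``mirror`` -- each population drives its own inhibitory mirror population,
  keeping every population's outgoing sign uniform.

Dynamics are scored on a binned winner trace: the winner of a time bin is
the population with strictly most spikes; ties and silent bins are
undecided (``NONE``), break winning streaks, and never count as a state
change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .network import (
    Connection,
    Connector,
    NetworkDescription,
    NeuronParameters,
    Population,
)
from .simulator import SimulationResult, simulate

__all__ = [
    "NONE",
    "WinnerTrace",
    "WTAWeights",
    "build_wta",
    "winner_sequence",
    "wta_metrics",
    "run_wta_benchmark",
]

NONE = "NONE"

WTA_STYLES = ("direct", "global_inhibition", "mirror")


@dataclass
class WTAWeights:
    """Weight set for the WTA kernels (nA, current-based neurons)."""

    noise: float = 0.8
    self_exc: float = 0.15
    inhibition: float = 0.6
    mirror_drive: float = 0.8


@dataclass
class WinnerTrace:
    bin_width: float
    winners: List[str]

    def to_frame(self) -> pd.DataFrame:
        starts = np.arange(len(self.winners)) * self.bin_width
        return pd.DataFrame(
            {"bin_start_ms": starts, "winner": self.winners}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_wta(
    style: str,
    n_pops: int = 2,
    pop_size: int = 8,
    noise_rate: float = 150.0,
    weights: Optional[WTAWeights] = None,
    params: Optional[NeuronParameters] = None,
    model: str = "lif_current",
) -> NetworkDescription:
    """Construct one of the three WTA topologies.

    Every excitatory neuron gets its own Poisson noise source (one-to-one).
    The shipped weights are tuned for ``lif_current``; building with
    ``lif_conductance`` (weights then in uS) is supported mainly for
    constraint-profile checks of Dale-separated substrates.
    """
    if style not in WTA_STYLES:
        raise ValueError(f"unknown WTA style {style!r}; choose from {WTA_STYLES}")
    if n_pops < 2:
        raise ValueError("a WTA needs at least two competing populations")
    w = weights or WTAWeights()
    params = params or NeuronParameters(tau_refrac=2.0, c_m=0.25, tau_m=10.0)
    net = NetworkDescription()
    exc_ids = [f"exc_{k}" for k in range(n_pops)]
    for k, pid in enumerate(exc_ids):
        net.add(
            Population(pid, pop_size, model, params),
            Population(f"noise_{k}", pop_size, "source_poisson", {"rate": noise_rate}),
            Connection(f"noise_{k}", pid, Connector.one_to_one(), w.noise),
            Connection(pid, pid, Connector.all_to_all(), w.self_exc),
        )
    if style == "direct":
        for a in exc_ids:
            for b in exc_ids:
                if a != b:
                    net.add(
                        Connection(a, b, Connector.all_to_all(), w.inhibition,
                                   receptor="inhibitory")
                    )
    elif style == "global_inhibition":
        net.add(Population("inh", pop_size, model, params))
        for pid in exc_ids:
            net.add(
                Connection(pid, "inh", Connector.all_to_all(), w.mirror_drive),
                Connection("inh", pid, Connector.all_to_all(), w.inhibition,
                           receptor="inhibitory"),
            )
        # global pool inhibits everyone, including the current winner; the
        # winner survives through its self-excitation
    else:  # mirror
        for k, pid in enumerate(exc_ids):
            mid = f"mirror_{k}"
            net.add(
                Population(mid, pop_size, model, params),
                Connection(pid, mid, Connector.one_to_one(), w.mirror_drive),
            )
            for other in exc_ids:
                if other != pid:
                    net.add(
                        Connection(mid, other, Connector.all_to_all(),
                                   w.inhibition, receptor="inhibitory")
                    )
    return net


def winner_sequence(
    result: SimulationResult,
    populations: Sequence[str],
    bin_width: float = 15.0,
) -> WinnerTrace:
    """Per-bin winner labels from recorded spikes.

    The winner of a bin is the population with strictly the most spikes in
    it; ties and all-silent bins map to ``NONE``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    n_bins = int(np.ceil(result.duration / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros((len(populations), n_bins), dtype=int)
    for r, pid in enumerate(populations):
        for train in result.spikes[pid]:
            if train is None or len(train) == 0:
                continue
            hist, _ = np.histogram(train, bins=edges)
            counts[r] += hist
    winners: List[str] = []
    for b in range(n_bins):
        col = counts[:, b]
        best = int(np.argmax(col))
        if col[best] == 0 or np.sum(col == col[best]) > 1:
            winners.append(NONE)
        else:
            winners.append(populations[best])
    return WinnerTrace(bin_width=bin_width, winners=winners)


def wta_metrics(trace: WinnerTrace) -> Tuple[int, int, float]:
    """(max_streak, state_changes, no_winner_time) from a winner trace.

    ``max_streak`` counts the longest run of bins won by a single
    population; ``state_changes`` counts transitions between distinct
    winning populations.  ``NONE`` bins break streaks, do not count as
    changes, and accumulate into ``no_winner_time`` (ms).
    """
    if not trace.winners:
        raise ValueError("trace is empty")
    max_streak = 0
    streak = 0
    prev: Optional[str] = None
    last_winner: Optional[str] = None
    changes = 0
    none_bins = 0
    for label in trace.winners:
        if label == NONE:
            none_bins += 1
            streak = 0
            prev = None
            continue
        if label == prev:
            streak += 1
        else:
            streak = 1
        prev = label
        max_streak = max(max_streak, streak)
        if last_winner is not None and label != last_winner:
            changes += 1
        last_winner = label
    return max_streak, changes, none_bins * trace.bin_width


def run_wta_benchmark(
    style: str = "mirror",
    n_pops: int = 2,
    pop_size: int = 8,
    noise_rate: float = 150.0,
    duration: float = 3000.0,
    bin_width: float = 15.0,
    n_repetitions: int = 10,
    base_seed: int = 1,
    weights: Optional[WTAWeights] = None,
) -> Dict[str, object]:
    """Average the three WTA metrics over repetitions with distinct seeds."""
    exc_ids = [f"exc_{k}" for k in range(n_pops)]
    per_seed = {"max_streak": [], "state_changes": [], "no_winner_time": []}
    for rep in range(n_repetitions):
        net = build_wta(style, n_pops, pop_size, noise_rate, weights)
        result = simulate(net, duration, seed=base_seed + rep)
        trace = winner_sequence(result, exc_ids, bin_width)
        streak, changes, no_win = wta_metrics(trace)
        per_seed["max_streak"].append(streak)
        per_seed["state_changes"].append(changes)
        per_seed["no_winner_time"].append(no_win)
    metrics = {}
    for key, vals in per_seed.items():
        metrics[key] = {
            "values": vals,
            "mean": float(np.mean(vals)),
            "std": float(np.std(vals)),
        }
    return metrics
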