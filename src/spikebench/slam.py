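"""Spiking map learning (SLAM-style) benchmark.

A virtual agent random-walks an occupancy grid with a bumper sensor.  One
position neuron per cell is driven along the trail; a bumper neuron spikes
whenever the agent collides with an obstacle.  Map neurons (one per cell)
are driven by the bumper, and plastic position-to-map synapses (additive
spike-pair STDP) potentiate on the coincidence of "I am pointing at cell c"
and "bump".  The learnt map is read out by thresholding the plastic
weights; the benchmark metric is the pixel-wise count of false positives
(learnt obstacle that does not exist) and false negatives (existing
obstacle not learnt).

The position state machine is position-only: heading populations and WTA
tracking are deliberately not part of the scored benchmark, whose metric
depends only on the learnt map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .network import (
    Connection,
    Connector,
    NetworkDescription,
    NeuronParameters,
    Population,
    STDPParams,
)
from .simulator import simulate

__all__ = ["GridWorld", "slam_run", "extract_map", "DEFAULT_SLAM_STDP"]

HEADINGS = ("N", "E", "S", "W")
_MOVES = {"N": (0, -1), "E": (1, 0), "S": (0, 1), "W": (-1, 0)}


@dataclass
class GridWorld:
    """Occupancy grid with an agent trail and bump events.

    ``trail`` is the time-ordered sequence of (cell, heading) the agent
    occupied, one entry per time step; ``bumps`` lists
    ``(step_index, blocked_cell)`` for every collision, where the blocked
    cell is the obstacle the agent tried to enter.  Cells are (x, y).
    """

    width: int
    height: int
    obstacles: Set[Tuple[int, int]]
    trail: List[Tuple[Tuple[int, int], str]]
    bumps: List[Tuple[int, Tuple[int, int]]] = field(default_factory=list)

    def validate(self) -> None:
        for (x, y), h in self.trail:
            if not (0 <= x < self.width and 0 <= y < self.height):
                raise ValueError(f"trail cell {(x, y)} outside the grid")
            if (x, y) in self.obstacles:
                raise ValueError(f"trail occupies obstacle cell {(x, y)}")
            if h not in HEADINGS:
                raise ValueError(f"unknown heading {h!r}")
        for step, cell in self.bumps:
            if not (0 <= step < len(self.trail)):
                raise ValueError("bump event outside the trail")
            if cell not in self.obstacles:
                raise ValueError(f"bump at non-obstacle cell {cell}")

    def cell_index(self, cell: Tuple[int, int]) -> int:
        x, y = cell
        return y * self.width + x

    @property
    def n_cells(self) -> int:
        return self.width * self.height


#: STDP time constants are short relative to the trail step (20 ms) so that
#: only the position spike coincident with a bump is potentiated
#: appreciably: one coincidence (pair lag ~1 ms) lifts the weight over the
#: (w_min + w_max)/2 read-out threshold, while pre spikes one trail step
#: before a bump contribute only a_plus * exp(-20/tau_plus) ~ 1.5% of w_max.
DEFAULT_SLAM_STDP = STDPParams(
    a_plus=0.8, a_minus=0.01, tau_plus=5.0, tau_minus=5.0, w_min=0.0, w_max=1.0
)


def _build_slam_network(
    world: GridWorld,
    stdp: STDPParams,
    step_ms: float,
    params: NeuronParameters,
) -> Tuple[NetworkDescription, float]:
    n = world.n_cells
    # position drive: at trail step k the source for the pointed-at cell
    # spikes; during a bump the pointed-at cell is the blocked one
    bump_by_step: Dict[int, Tuple[int, int]] = dict(world.bumps)
    pos_times: List[List[float]] = [[] for _ in range(n)]
    bump_times: List[float] = []
    for k, (cell, heading) in enumerate(world.trail):
        t = 5.0 + k * step_ms
        target = bump_by_step.get(k)
        if target is not None:
            pos_times[world.cell_index(target)].append(t)
            bump_times.append(t + 0.5)  # bumper trails the position spike
        else:
            pos_times[world.cell_index(cell)].append(t)
    duration = 5.0 + len(world.trail) * step_ms + 20.0

    strong = 6.0  # nA, reliably forces a spike within one synaptic rise
    net = NetworkDescription().add(
        Population("pos_src", n, "source_array", {"spike_times": pos_times}),
        Population("bumper_src", 1, "source_array", {"spike_times": bump_times}),
        Population("position", n, "lif_current", params),
        Population("bumper", 1, "lif_current", params),
        Population("map", n, "lif_current", params),
        Connection("pos_src", "position", Connector.one_to_one(), strong),
        Connection("bumper_src", "bumper", Connector.one_to_one(), strong),
        Connection("bumper", "map", Connector.all_to_all(), strong),
        Connection(
            "position",
            "map",
            Connector.from_list([(i, i, stdp.w_min) for i in range(n)]),
            0.0,
            plasticity=stdp,
        ),
    )
    return net, duration


def extract_map(
    weights: np.ndarray, world: GridWorld, threshold: float
) -> Set[Tuple[int, int]]:
    """Cells whose learnt position-to-map weight reaches the threshold."""
    learnt = set()
    for idx in np.nonzero(weights >= threshold)[0]:
        learnt.add((int(idx) % world.width, int(idx) // world.width))
    return learnt


def slam_run(
    world: GridWorld,
    network_params: Optional[NeuronParameters] = None,
    stdp: STDPParams = DEFAULT_SLAM_STDP,
    seed: int = 0,
    step_ms: float = 20.0,
    threshold: Optional[float] = None,
) -> Tuple[Set[Tuple[int, int]], int, int]:
    """Learn the obstacle map from the trail and score it pixel-wise.

    Returns ``(learnt_map, false_positives, false_negatives)``.  The map is
    extracted by thresholding the learnt plastic weights at
    ``(w_min + w_max) / 2`` unless an explicit threshold is given.
    """
    if not world.trail:
        raise ValueError("trail is empty")
    world.validate()
    params = network_params or NeuronParameters(
        tau_refrac=2.0, tau_m=5.0, tau_syn_exc=2.0, c_m=0.25
    )
    net, duration = _build_slam_network(world, stdp, step_ms, params)
    result = simulate(net, duration, seed=seed)
    weights = result.plastic_weights[0]
    if threshold is None:
        threshold = 0.5 * (stdp.w_min + stdp.w_max)
    learnt = extract_map(weights, world, threshold)
    fp = len(learnt - world.obstacles)
    fn = len(world.obstacles - learnt)
    return learnt, fp, fn


def map_to_csv(learnt: Set[Tuple[int, int]], world: GridWorld, path) -> None:
    grid = np.zeros((world.height, world.width), dtype=int)
    for x, y in learnt:
        grid[y, x] = 1
    pd.DataFrame(grid).to_csv(path, index=False, header=False)
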