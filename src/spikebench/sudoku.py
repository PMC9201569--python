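"""Spiking Sudoku solver: constraint satisfaction by winner-take-all.

Each (cell, digit) hypothesis is a small population of self-exciting
neurons with private Poisson noise.  Sudoku rules become inhibitory
connections between incompatible hypotheses: the digits within one cell,
and equal digits within a row, column, or sub-box.  Clue digits receive
elevated noise rates.  The network relaxes into a state where, per cell,
the population representing the correct digit wins the spike count within a
time bin; the benchmark metric is the bio time of the first bin whose
complete assignment equals the puzzle's solution.

Three implementation styles are provided: ``simple`` (one population per
hypothesis, direct inhibition), ``single_population`` (the logically
identical network flattened into one population with explicit connection
lists), and ``mirror`` (inhibition routed through mirror neurons so that no
population projects both receptor types, which maps onto Dale-separated
substrates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import networkx as nx
import numpy as np

from .network import (
    Connection,
    Connector,
    NetworkDescription,
    NeuronParameters,
    Population,
)
from .simulator import SimulationResult, simulate
from .wta import NONE

__all__ = [
    "SudokuPuzzle",
    "UNSOLVED",
    "SudokuRates",
    "SudokuWeights",
    "constraint_graph",
    "build_sudoku_network",
    "solve_sudoku",
    "check_solution",
    "run_sudoku_benchmark",
]

UNSOLVED = "UNSOLVED"

SUDOKU_STYLES = ("simple", "single_population", "mirror")


@dataclass
class SudokuPuzzle:
    """A q^2 x q^2 puzzle with clues and its full solution.

    ``clues`` maps (row, col) to a digit in 1..q^2; ``solution`` is the full
    grid as a nested list.
    """

    block: int
    clues: Dict[Tuple[int, int], int]
    solution: List[List[int]]

    @property
    def side(self) -> int:
        return self.block**2

    def validate(self) -> None:
        n = self.side
        if len(self.solution) != n or any(len(r) != n for r in self.solution):
            raise ValueError("solution grid has wrong shape")
        if not check_solution(self.block, self.solution):
            raise ValueError("stored solution violates Sudoku constraints")
        for (r, c), d in self.clues.items():
            if not (0 <= r < n and 0 <= c < n and 1 <= d <= n):
                raise ValueError(f"clue out of range: {(r, c, d)}")
            if self.solution[r][c] != d:
                raise ValueError(f"clue {(r, c, d)} inconsistent with solution")

    # ------------------------------------------------------------- text IO
    def to_text(self) -> str:
        """Plain-text format: q on line 1, clue grid (0 = blank), blank
        line, then the solution grid."""
        n = self.side
        lines = [str(self.block)]
        for r in range(n):
            lines.append(
                " ".join(str(self.clues.get((r, c), 0)) for c in range(n))
            )
        lines.append("")
        for r in range(n):
            lines.append(" ".join(str(self.solution[r][c]) for c in range(n)))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SudokuPuzzle":
        raw = [ln.strip() for ln in text.strip().splitlines()]
        q = int(raw[0])
        n = q * q
        clue_rows = [list(map(int, raw[1 + r].split())) for r in range(n)]
        # the blank separator line was stripped away; solution follows
        sol_lines = [ln for ln in raw[1 + n :] if ln]
        solution = [list(map(int, ln.split())) for ln in sol_lines]
        clues = {
            (r, c): clue_rows[r][c]
            for r in range(n)
            for c in range(n)
            if clue_rows[r][c] != 0
        }
        puzzle = cls(block=q, clues=clues, solution=solution)
        puzzle.validate()
        return puzzle

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def load(cls, path) -> "SudokuPuzzle":
        with open(path) as fh:
            return cls.from_text(fh.read())


def check_solution(block: int, grid: List[List[int]]) -> bool:
    """Independent constraint checker: rows, columns, boxes, cell range."""
    n = block**2
    digits = set(range(1, n + 1))
    for r in range(n):
        if set(grid[r]) != digits:
            return False
    for c in range(n):
        if {grid[r][c] for r in range(n)} != digits:
            return False
    for br in range(block):
        for bc in range(block):
            box = {
                grid[br * block + i][bc * block + j]
                for i in range(block)
                for j in range(block)
            }
            if box != digits:
                return False
    return True


def constraint_graph(block: int) -> nx.Graph:
    """Graph over (row, col, digit) hypotheses; edges join incompatible ones.

    Two hypotheses conflict when they assert different digits in the same
    cell, or the same digit twice in a row, column, or sub-box.
    """
    n = block**2
    g = nx.Graph()
    for r in range(n):
        for c in range(n):
            for d in range(1, n + 1):
                g.add_node((r, c, d))
    for r in range(n):
        for c in range(n):
            for d1 in range(1, n + 1):
                for d2 in range(d1 + 1, n + 1):
                    g.add_edge((r, c, d1), (r, c, d2), kind="cell")
    for d in range(1, n + 1):
        for r in range(n):
            for c1 in range(n):
                for c2 in range(c1 + 1, n):
                    g.add_edge((r, c1, d), (r, c2, d), kind="row")
        for c in range(n):
            for r1 in range(n):
                for r2 in range(r1 + 1, n):
                    g.add_edge((r1, c, d), (r2, c, d), kind="column")
        for br in range(block):
            for bc in range(block):
                cells = [
                    (br * block + i, bc * block + j)
                    for i in range(block)
                    for j in range(block)
                ]
                for a in range(len(cells)):
                    for b in range(a + 1, len(cells)):
                        r1, c1 = cells[a]
                        r2, c2 = cells[b]
                        if not g.has_edge((r1, c1, d), (r2, c2, d)):
                            g.add_edge((r1, c1, d), (r2, c2, d), kind="box")
    return g


@dataclass
class SudokuRates:
    """Poisson noise rates; clue hypotheses get ``clue_factor`` times the
    baseline (the clue-encoding mechanism)."""

    noise: float = 150.0
    clue_factor: float = 4.0


@dataclass
class SudokuWeights:
    """Weight set (nA) for the current-based solver networks."""

    noise: float = 0.8
    self_exc: float = 0.15
    inhibition: float = 0.6
    mirror_drive: float = 0.8


DEFAULT_SUDOKU_PARAMS = NeuronParameters(
    v_rest=-65.0,
    v_thresh=-50.0,
    v_reset=-70.0,
    tau_m=10.0,
    tau_refrac=2.0,
    tau_syn_exc=5.0,
    tau_syn_inh=5.0,
    c_m=0.25,
)


def _unit_id(r: int, c: int, d: int) -> str:
    return f"cd_{r}_{c}_{d}"


def build_sudoku_network(
    puzzle: SudokuPuzzle,
    style: str = "simple",
    pop_size: int = 4,
    rates: Optional[SudokuRates] = None,
    weights: Optional[SudokuWeights] = None,
    params: Optional[NeuronParameters] = None,
    model: str = "lif_current",
) -> NetworkDescription:
    """Wire the WTA solver network for a puzzle.

    Every hypothesis neuron has its own Poisson spike source.  The
    ``single_population`` style produces the logically identical network as
    ``simple`` but flattened into one neuron population with explicit
    connection lists; ``mirror`` adds one mirror population per hypothesis
    to carry the inhibition.  The shipped weights are tuned for
    ``lif_current``; ``model="lif_conductance"`` is available chiefly for
    mappability checks against Dale-separated conductance substrates.
    """
    if style not in SUDOKU_STYLES:
        raise ValueError(f"unknown Sudoku style {style!r}; choose from {SUDOKU_STYLES}")
    puzzle.validate()
    rates = rates or SudokuRates()
    w = weights or SudokuWeights()
    params = params or DEFAULT_SUDOKU_PARAMS
    n = puzzle.side
    graph = constraint_graph(puzzle.block)
    units = [(r, c, d) for r in range(n) for c in range(n) for d in range(1, n + 1)]

    net = NetworkDescription()

    def noise_rate(r, c, d):
        if puzzle.clues.get((r, c)) == d:
            return rates.noise * rates.clue_factor
        return rates.noise

    if style == "single_population":
        # one flat population; explicit from_list connections
        n_units = len(units)
        index = {u: i for i, u in enumerate(units)}
        net.add(Population("grid", n_units * pop_size, model, params))
        for u in units:
            base = index[u] * pop_size
            net.add(
                Population(
                    f"noise_{_unit_id(*u)}",
                    pop_size,
                    "source_poisson",
                    {"rate": noise_rate(*u)},
                ),
                Connection(
                    f"noise_{_unit_id(*u)}",
                    "grid",
                    Connector.from_list(
                        [(i, base + i) for i in range(pop_size)]
                    ),
                    w.noise,
                ),
            )
        exc_pairs = []
        for u in units:
            base = index[u] * pop_size
            exc_pairs.extend(
                (base + i, base + j)
                for i in range(pop_size)
                for j in range(pop_size)
            )
        net.add(
            Connection("grid", "grid", Connector.from_list(exc_pairs), w.self_exc)
        )
        inh_pairs = []
        for u, v in graph.edges():
            bu, bv = index[u] * pop_size, index[v] * pop_size
            for i in range(pop_size):
                for j in range(pop_size):
                    inh_pairs.append((bu + i, bv + j))
                    inh_pairs.append((bv + i, bu + j))
        net.add(
            Connection(
                "grid",
                "grid",
                Connector.from_list(inh_pairs),
                w.inhibition,
                receptor="inhibitory",
            )
        )
        return net

    # population-per-hypothesis styles
    for u in units:
        uid = _unit_id(*u)
        net.add(
            Population(uid, pop_size, model, params),
            Population(
                f"noise_{uid}", pop_size, "source_poisson", {"rate": noise_rate(*u)}
            ),
            Connection(f"noise_{uid}", uid, Connector.one_to_one(), w.noise),
            Connection(uid, uid, Connector.all_to_all(), w.self_exc),
        )
    if style == "simple":
        for u, v in graph.edges():
            uid, vid = _unit_id(*u), _unit_id(*v)
            net.add(
                Connection(uid, vid, Connector.all_to_all(), w.inhibition,
                           receptor="inhibitory"),
                Connection(vid, uid, Connector.all_to_all(), w.inhibition,
                           receptor="inhibitory"),
            )
    else:  # mirror
        for u in units:
            uid = _unit_id(*u)
            net.add(
                Population(f"mirror_{uid}", pop_size, model, params),
                Connection(uid, f"mirror_{uid}", Connector.one_to_one(),
                           w.mirror_drive),
            )
        for u, v in graph.edges():
            uid, vid = _unit_id(*u), _unit_id(*v)
            net.add(
                Connection(f"mirror_{uid}", vid, Connector.all_to_all(),
                           w.inhibition, receptor="inhibitory"),
                Connection(f"mirror_{vid}", uid, Connector.all_to_all(),
                           w.inhibition, receptor="inhibitory"),
            )
    return net


def _bin_counts(
    result: SimulationResult, puzzle: SudokuPuzzle, pop_size: int, bin_width: float
) -> np.ndarray:
    """Spike counts per (cell, digit, bin) from either network layout."""
    n = puzzle.side
    n_bins = int(result.duration // bin_width)
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros((n, n, n, n_bins), dtype=int)
    if "grid" in result.spikes:
        units = [
            (r, c, d) for r in range(n) for c in range(n) for d in range(1, n + 1)
        ]
        for k, (r, c, d) in enumerate(units):
            for i in range(pop_size):
                train = result.spikes["grid"][k * pop_size + i]
                if train is None or len(train) == 0:
                    continue
                hist, _ = np.histogram(train, bins=edges)
                counts[r, c, d - 1] += hist
    else:
        for r in range(n):
            for c in range(n):
                for d in range(1, n + 1):
                    for train in result.spikes[_unit_id(r, c, d)]:
                        if train is None or len(train) == 0:
                            continue
                        hist, _ = np.histogram(train, bins=edges)
                        counts[r, c, d - 1] += hist
    return counts


def solve_sudoku(
    network: NetworkDescription,
    puzzle: SudokuPuzzle,
    duration: float = 2000.0,
    bin_width: float = 20.0,
    seed: int = 1,
    pop_size: int = 4,
) -> Tuple[List[List[List[object]]], Union[float, str]]:
    """Simulate the solver and extract the per-cell winner trace.

    Per bin and per cell the winning digit is the hypothesis population with
    strictly the most spikes (ties and silence are undecided).  The time to
    solution is the END time of the first bin whose full assignment equals
    the stored solution (so the minimum reportable value is one bin), or
    ``UNSOLVED``.  Returns ``(trace, time_to_solution)`` where
    ``trace[bin][row][col]`` is a digit or ``NONE``.
    """
    if duration < bin_width:
        raise ValueError("duration must cover at least one bin")
    result = simulate(network, duration, seed=seed)
    return winners_from_result(result, puzzle, pop_size, bin_width)


def winners_from_result(
    result: SimulationResult,
    puzzle: SudokuPuzzle,
    pop_size: int = 4,
    bin_width: float = 20.0,
) -> Tuple[List[List[List[object]]], Union[float, str]]:
    """Winner extraction from an existing simulation result."""
    n = puzzle.side
    counts = _bin_counts(result, puzzle, pop_size, bin_width)
    n_bins = counts.shape[-1]
    trace: List[List[List[object]]] = []
    time_to_solution: Union[float, str] = UNSOLVED
    for b in range(n_bins):
        grid_b: List[List[object]] = []
        complete = True
        correct = True
        for r in range(n):
            row: List[object] = []
            for c in range(n):
                col = counts[r, c, :, b]
                best = int(np.argmax(col))
                if col[best] == 0 or np.sum(col == col[best]) > 1:
                    row.append(NONE)
                    complete = False
                    correct = False
                else:
                    digit = best + 1
                    row.append(digit)
                    if digit != puzzle.solution[r][c]:
                        correct = False
            grid_b.append(row)
        trace.append(grid_b)
        if complete and correct and time_to_solution == UNSOLVED:
            time_to_solution = (b + 1) * bin_width
    return trace, time_to_solution


def run_sudoku_benchmark(
    puzzle: SudokuPuzzle,
    style: str = "mirror",
    pop_size: int = 4,
    duration: float = 2000.0,
    bin_width: float = 20.0,
    seeds: Optional[List[int]] = None,
    rates: Optional[SudokuRates] = None,
    weights: Optional[SudokuWeights] = None,
) -> Dict[str, object]:
    """Bio time-to-solution averaged over noise seeds.

    Unsolved runs contribute the full duration to the mean (a conservative
    censoring convention) and are reported separately.
    """
    seeds = seeds if seeds is not None else list(range(1, 11))
    times: List[float] = []
    solved: List[bool] = []
    checked: List[bool] = []
    for s in seeds:
        net = build_sudoku_network(puzzle, style, pop_size, rates, weights)
        trace, tts = solve_sudoku(net, puzzle, duration, bin_width, seed=s,
                                  pop_size=pop_size)
        if tts == UNSOLVED:
            times.append(duration)
            solved.append(False)
            checked.append(False)
        else:
            times.append(float(tts))
            solved.append(True)
            b = int(round(tts / bin_width)) - 1
            checked.append(check_solution(puzzle.block, [
                [int(x) for x in row] for row in trace[b]
            ]))
    return {
        "seeds": seeds,
        "times_ms": times,
        "solved": solved,
        "solution_checker_passed": checked,
        "mean_time_ms": float(np.mean(times)),
        "std_time_ms": float(np.std(times)),
        "fraction_solved": float(np.mean(solved)),
    }
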