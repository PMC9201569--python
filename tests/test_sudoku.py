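"""Spiking Sudoku solver: structure, winner extraction, style equivalence."""

import numpy as np
import pytest

from spikebench.fixtures import gen_sudoku
from spikebench.network import NeuronParameters
from spikebench.sudoku import (
    UNSOLVED,
    SudokuPuzzle,
    build_sudoku_network,
    check_solution,
    constraint_graph,
    solve_sudoku,
    winners_from_result,
)
from spikebench.wta import NONE


@pytest.fixture(scope="module")
def puzzle():
    return gen_sudoku(q=2, n_clues=8, seed=1)


def test_network_has_one_population_per_cell_digit(puzzle):
    net = build_sudoku_network(puzzle, style="simple", pop_size=4)
    digit_pops = [p for p in net.populations
                  if p.id.startswith("cd_") and not p.is_source]
    assert len(digit_pops) == 16 * 4  # q=2: 16 cells x 4 digits


def test_every_hypothesis_neuron_has_its_own_noise_source(puzzle):
    net = build_sudoku_network(puzzle, style="simple", pop_size=3)
    sources = [p for p in net.populations if p.is_source]
    hypothesis_neurons = sum(
        p.size for p in net.populations
        if p.id.startswith("cd_") and not p.is_source
    )
    assert sum(s.size for s in sources) == hypothesis_neurons


def test_constraint_graph_edges_cover_all_rule_classes():
    g = constraint_graph(2)
    kinds = {d["kind"] for _, _, d in g.edges(data=True)}
    assert kinds == {"cell", "row", "column", "box"}
    # each hypothesis conflicts with 3 in-cell + 7 same-digit peers
    assert all(g.degree(n) == 10 for n in g.nodes)


def test_simple_and_single_population_are_logically_identical(puzzle):
    """Same constraint set, same neuron count, and with a fixed noise seed
    the binned winner traces coincide bin for bin."""
    net_a = build_sudoku_network(puzzle, "simple", pop_size=4)
    net_b = build_sudoku_network(puzzle, "single_population", pop_size=4)
    n_a = sum(p.size for p in net_a.populations if not p.is_source)
    n_b = sum(p.size for p in net_b.populations if not p.is_source)
    assert n_a == n_b
    trace_a, tts_a = solve_sudoku(net_a, puzzle, 400.0, 20.0, seed=3)
    trace_b, tts_b = solve_sudoku(net_b, puzzle, 400.0, 20.0, seed=3)
    assert tts_a == tts_b
    assert trace_a == trace_b


def test_unknown_style_rejected(puzzle):
    with pytest.raises(ValueError):
        build_sudoku_network(puzzle, style="fancy")


def test_injected_solution_spikes_give_one_bin_solution(puzzle):
    """Synthetic spikes matching the solution from the first bin onwards
    force time_to_solution = bin_width by definition."""

    class Injected:
        duration = 60.0
        dt = 0.1
        spikes = {}

    n = puzzle.side
    for r in range(n):
        for c in range(n):
            for d in range(1, n + 1):
                count = 5 if puzzle.solution[r][c] == d else 0
                trains = [np.repeat([10.0, 30.0, 50.0], count)]
                Injected.spikes[f"cd_{r}_{c}_{d}"] = trains
    trace, tts = winners_from_result(Injected(), puzzle, pop_size=1,
                                     bin_width=20.0)
    assert tts == 20.0
    assert trace[0] == puzzle.solution


def test_silent_cell_means_unsolved(puzzle):
    class Silent:
        duration = 40.0
        dt = 0.1
        spikes = {}

    n = puzzle.side
    for r in range(n):
        for c in range(n):
            for d in range(1, n + 1):
                Silent.spikes[f"cd_{r}_{c}_{d}"] = [np.empty(0)]
    trace, tts = winners_from_result(Silent(), puzzle, pop_size=1,
                                     bin_width=20.0)
    assert tts == UNSOLVED
    assert all(cell == NONE for row in trace[0] for cell in row)


def test_solver_result_passes_independent_checker(puzzle):
    net = build_sudoku_network(puzzle, style="mirror", pop_size=4)
    trace, tts = solve_sudoku(net, puzzle, 1500.0, 20.0, seed=2)
    assert tts != UNSOLVED
    b = int(round(tts / 20.0)) - 1
    grid = [[int(x) for x in row] for row in trace[b]]
    assert check_solution(2, grid)
    assert grid == puzzle.solution


def test_duration_must_cover_a_bin(puzzle):
    net = build_sudoku_network(puzzle, pop_size=1)
    with pytest.raises(ValueError):
        solve_sudoku(net, puzzle, duration=10.0, bin_width=20.0)


def test_puzzle_text_round_trip(tmp_path, puzzle):
    path = tmp_path / "puzzle.txt"
    puzzle.save(path)
    restored = SudokuPuzzle.load(path)
    assert restored.block == puzzle.block
    assert restored.clues == puzzle.clues
    assert restored.solution == puzzle.solution


def test_inconsistent_clue_rejected(puzzle):
    bad = SudokuPuzzle(
        block=2,
        clues={(0, 0): 3 if puzzle.solution[0][0] != 3 else 4},
        solution=puzzle.solution,
    )
    with pytest.raises(ValueError, match="inconsistent"):
        bad.validate()


def test_checker_rejects_duplicate_in_row():
    grid = [[1, 1, 3, 4], [3, 4, 1, 2], [2, 1, 4, 3], [4, 3, 2, 1]]
    assert not check_solution(2, grid)
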