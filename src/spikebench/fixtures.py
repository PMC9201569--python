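"""Synthetic fixture generators for every benchmark.

All generators are seeded and reproducible; nothing in the test suite or
the benchmarks depends on external data.  The grid-world generator defaults
to the 15 x 15 map with four obstacles used by the SLAM benchmark; the tiny
MLP generator constructs (rather than trains) a bias-free dense ReLU
network that reaches at least 95% on its own synthetic dataset, standing in
for externally trained digit classifiers.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Set, Tuple

import numpy as np

from .dnn2snn import DenseReLUStack
from .slam import GridWorld, HEADINGS, _MOVES
from .sudoku import SudokuPuzzle, check_solution

__all__ = [
    "gen_sudoku",
    "count_sudoku_solutions",
    "gen_binam_patterns",
    "gen_gridworld",
    "gen_tiny_mlp",
]


# --------------------------------------------------------------------------
# Sudoku
# --------------------------------------------------------------------------

def _solve_backtrack(
    block: int,
    grid: List[List[int]],
    rng: Optional[np.random.Generator] = None,
    limit: int = 1,
) -> Tuple[int, Optional[List[List[int]]]]:
    """Count completions up to ``limit``; returns (count, first solution)."""
    n = block**2

    def candidates(r: int, c: int) -> List[int]:
        used = set(grid[r]) | {grid[i][c] for i in range(n)}
        br, bc = (r // block) * block, (c // block) * block
        used |= {
            grid[br + i][bc + j] for i in range(block) for j in range(block)
        }
        cand = [d for d in range(1, n + 1) if d not in used]
        if rng is not None:
            rng.shuffle(cand)
        return cand

    def next_cell() -> Optional[Tuple[int, int]]:
        best = None
        best_n = n + 1
        for r in range(n):
            for c in range(n):
                if grid[r][c] == 0:
                    k = len(candidates(r, c))
                    if k < best_n:
                        best, best_n = (r, c), k
                        if k <= 1:
                            return best
        return best

    found: List[List[List[int]]] = []

    def rec() -> int:
        cell = next_cell()
        if cell is None:
            found.append([row[:] for row in grid])
            return 1
        r, c = cell
        total = 0
        for d in candidates(r, c):
            grid[r][c] = d
            total += rec()
            grid[r][c] = 0
            if total >= limit:
                break
        return total

    count = rec()
    return count, (found[0] if found else None)


def count_sudoku_solutions(block: int, clues: Dict[Tuple[int, int], int],
                           limit: int = 2) -> int:
    """Exhaustive (pruned) completion count for uniqueness checks."""
    n = block**2
    grid = [[0] * n for _ in range(n)]
    for (r, c), d in clues.items():
        grid[r][c] = d
    count, _ = _solve_backtrack(block, grid, limit=limit)
    return count


def gen_sudoku(q: int = 2, n_clues: int = 8, seed: int = 1) -> SudokuPuzzle:
    """Random puzzle with a stored, verified-unique solution.

    A full grid is generated by randomized backtracking, then cells are
    removed while completion uniqueness is preserved.  ``n_clues`` below
    what uniqueness permits raises a parameter error.
    """
    if q not in (2, 3):
        raise ValueError("q must be 2 or 3")
    n = q * q
    if not 0 < n_clues <= n * n:
        raise ValueError(f"n_clues must be in 1..{n * n}")
    rng = np.random.default_rng(seed % (2**31))
    grid = [[0] * n for _ in range(n)]
    _, solution = _solve_backtrack(q, grid, rng=rng, limit=1)
    assert solution is not None
    clues = {(r, c): solution[r][c] for r in range(n) for c in range(n)}
    cells = list(clues)
    rng.shuffle(cells)
    for cell in cells:
        if len(clues) <= n_clues:
            break
        removed = clues.pop(cell)
        if count_sudoku_solutions(q, clues) != 1:
            clues[cell] = removed  # removal would break uniqueness
    if len(clues) > n_clues:
        raise ValueError(
            f"infeasible clue count: could not reduce to {n_clues} clues "
            f"while keeping the solution unique (reached {len(clues)})"
        )
    puzzle = SudokuPuzzle(block=q, clues=clues, solution=solution)
    puzzle.validate()
    return puzzle


# --------------------------------------------------------------------------
# BiNAM patterns
# --------------------------------------------------------------------------

def gen_binam_patterns(
    n_in: int, n_out: int, k_in: int, k_out: int, m_samples: int, seed: int = 1
) -> Tuple[np.ndarray, np.ndarray]:
    """Uniformly sampled binary pattern pairs of exact weight k."""
    if k_in > n_in or k_out > n_out:
        raise ValueError("pattern weight k must not exceed pattern length n")
    rng = np.random.default_rng(seed % (2**31))
    x = np.zeros((m_samples, n_in), dtype=np.uint8)
    y = np.zeros((m_samples, n_out), dtype=np.uint8)
    for s in range(m_samples):
        x[s, rng.choice(n_in, size=k_in, replace=False)] = 1
        y[s, rng.choice(n_out, size=k_out, replace=False)] = 1
    return x, y


# --------------------------------------------------------------------------
# grid world
# --------------------------------------------------------------------------

def gen_gridworld(
    width: int = 15,
    height: int = 15,
    n_obstacles: int = 4,
    trail_length: int = 400,
    seed: int = 1,
) -> GridWorld:
    """Random-walk trail through a grid with obstacles and bump events.

    The walk never enters an obstacle; an attempted move into one records a
    bump event (step index plus the blocked cell) and the agent stays put.
    """
    if trail_length <= 0:
        raise ValueError("trail_length must be > 0")
    if n_obstacles >= width * height:
        raise ValueError("obstacles do not fit into the grid")
    rng = np.random.default_rng(seed % (2**31))
    cells = [(x, y) for x in range(width) for y in range(height)]
    obstacle_idx = rng.choice(len(cells), size=n_obstacles, replace=False)
    obstacles: Set[Tuple[int, int]] = {cells[i] for i in obstacle_idx}
    free = [c for c in cells if c not in obstacles]
    pos = free[int(rng.integers(len(free)))]
    heading = HEADINGS[int(rng.integers(4))]
    trail: List[Tuple[Tuple[int, int], str]] = []
    bumps: List[Tuple[int, Tuple[int, int]]] = []
    for step in range(trail_length):
        heading = HEADINGS[int(rng.integers(4))]
        dx, dy = _MOVES[heading]
        nxt = (pos[0] + dx, pos[1] + dy)
        trail.append((pos, heading))
        if not (0 <= nxt[0] < width and 0 <= nxt[1] < height):
            continue  # wall, no bump sensor event
        if nxt in obstacles:
            bumps.append((step, nxt))
            continue
        pos = nxt
    world = GridWorld(width, height, obstacles, trail, bumps)
    world.validate()
    return world


# --------------------------------------------------------------------------
# tiny MLP + dataset
# --------------------------------------------------------------------------

def gen_tiny_mlp(
    layout: Tuple[int, ...] = (16, 8, 2),
    task: str = "separable-blobs",
    n_samples: int = 80,
    seed: int = 1,
) -> Tuple[DenseReLUStack, Tuple[np.ndarray, np.ndarray]]:
    """Constructed bias-free ReLU classifier plus its labelled dataset.

    ``separable-blobs`` places one prototype per class on near-disjoint
    input supports and draws noisy samples around them; ``xor-ish`` uses two
    prototypes per class so no single linear readout of the raw input
    separates the classes.  The weights are constructed from the prototype
    directions (no training) and reach at least 95% accuracy on the
    generated dataset; inputs are normalized to [0, 1].
    """
    if task not in ("separable-blobs", "xor-ish"):
        raise ValueError(f"unknown task {task!r}")
    if len(layout) < 2:
        raise ValueError("layout needs at least input and output sizes")
    n_in, n_out = layout[0], layout[-1]
    n_hidden = layout[1] if len(layout) > 2 else n_out
    rng = np.random.default_rng(seed % (2**31))

    n_proto = n_out if task == "separable-blobs" else 2 * n_out
    supports = np.array_split(np.arange(n_in), n_proto)
    protos = np.zeros((n_proto, n_in))
    for p, sup in enumerate(supports):
        protos[p, sup] = 1.0
    proto_label = (
        np.arange(n_out)
        if task == "separable-blobs"
        else np.tile(np.arange(n_out), 2)
    )

    # hidden units: one detector per prototype (contrast against the mean of
    # the other prototypes keeps the ReLU silent off-class); spare units 0
    w1 = np.zeros((n_in, n_hidden))
    for p in range(min(n_proto, n_hidden)):
        others = np.delete(protos, p, axis=0).mean(axis=0)
        w1[:, p] = protos[p] - others
    w2 = np.zeros((n_hidden, n_out))
    for p in range(min(n_proto, n_hidden)):
        w2[p, proto_label[p]] = 1.0
    if len(layout) > 3:
        raise ValueError("layouts deeper than 3 layers are not generated")
    weights = [w1 @ w2] if len(layout) == 2 else [w1, w2]
    stack = DenseReLUStack(weights)

    labels = rng.integers(n_out, size=n_samples)
    X = np.empty((n_samples, n_in))
    for s in range(n_samples):
        cand = np.nonzero(proto_label == labels[s])[0]
        proto = protos[int(rng.choice(cand))]
        noise = rng.uniform(0.0, 0.25, size=n_in)
        X[s] = np.clip(0.75 * proto + noise, 0.0, 1.0)
    acc = float(np.mean(stack.predict(X) == labels))
    if acc < 0.95:
        raise RuntimeError(
            f"constructed network reached only {acc:.0%} on its dataset"
        )
    return stack, (X, labels)
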