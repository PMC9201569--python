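"""Binary neural associative memory (Willshaw-style) benchmark.

A BiNAM stores sparse binary pattern pairs in a binary matrix by OR-ing
their outer products.  Recall thresholds the matrix-vector product at the
input pattern weight (full-match rule).  The spiking variant uses the
matrix as a synaptic connection matrix: one LIF neuron per output bit,
input bits as synchronized spikes, and a weight calibrated so that exactly
``k_in`` coincident inputs drive a neuron over threshold.  The benchmark
metric is the retrieved information in bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammaln

from .network import (
    Connection,
    Connector,
    NetworkDescription,
    NeuronParameters,
    Population,
)
from .simulator import simulate

__all__ = [
    "BinaryMemory",
    "binam_train",
    "binam_recall",
    "binam_recall_batch",
    "binam_information",
    "calibrate_recall_weight",
]


@dataclass
class BinaryMemory:
    matrix: np.ndarray  # n_in x n_out, entries in {0, 1}
    k_in: int
    k_out: int

    @property
    def n_in(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_out(self) -> int:
        return self.matrix.shape[1]


def binam_train(
    input_patterns: np.ndarray, output_patterns: np.ndarray,
    k_in: Optional[int] = None, k_out: Optional[int] = None,
) -> BinaryMemory:
    """Train by element-wise OR over sample outer products."""
    x = np.atleast_2d(np.asarray(input_patterns, dtype=bool))
    y = np.atleast_2d(np.asarray(output_patterns, dtype=bool))
    if x.size == 0 or y.size == 0:
        if x.shape[0] != y.shape[0]:
            raise ValueError("pattern lists must have equal length")
    elif x.shape[0] != y.shape[0]:
        raise ValueError(
            f"pattern count mismatch: {x.shape[0]} inputs, {y.shape[0]} outputs"
        )
    n_in = x.shape[1]
    n_out = y.shape[1]
    matrix = np.zeros((n_in, n_out), dtype=np.uint8)
    for xi, yi in zip(x, y):
        matrix |= np.outer(xi, yi).astype(np.uint8)
    if k_in is None:
        k_in = int(x[0].sum()) if x.shape[0] else 0
    if k_out is None:
        k_out = int(y[0].sum()) if y.shape[0] else 0
    return BinaryMemory(matrix=matrix, k_in=k_in, k_out=k_out)


def _boolean_recall(memory: BinaryMemory, x: np.ndarray) -> np.ndarray:
    dots = memory.matrix.T.astype(int) @ x.astype(int)
    return (dots >= memory.k_in).astype(np.uint8)


_CAL_PARAMS = NeuronParameters(tau_refrac=5.0, tau_syn_exc=2.0)


def calibrate_recall_weight(k_in: int, params: NeuronParameters = _CAL_PARAMS,
                            dt: float = 0.1) -> float:
    """Synaptic weight such that ``k_in`` coincident spikes fire a neuron
    but ``k_in - 1`` do not.

    The peak depolarization per unit weight is measured on a probe neuron,
    then the weight is set so the threshold falls between the (k-1)- and
    k-fold peaks.
    """
    if k_in < 1:
        raise ValueError("k_in must be >= 1")
    probe = NetworkDescription().add(
        Population("src", 1, "source_array", {"spike_times": [5.0]}),
        Population("probe", 1, "lif_current", params),
        Connection("src", "probe", Connector.one_to_one(), 1e-3),
    )
    res = simulate(probe, 40.0, dt=dt, record_v=["probe"])
    peak_per_unit = (np.max(res.voltages["probe"][0]) - params.v_rest) / 1e-3
    delta = params.v_thresh - params.v_rest
    return delta / (peak_per_unit * (k_in - 0.5))


def binam_recall(
    memory: BinaryMemory,
    input_pattern: Sequence[int],
    spiking: bool = False,
    params: NeuronParameters = _CAL_PARAMS,
    weight: Optional[float] = None,
    dt: float = 0.1,
) -> np.ndarray:
    """Recall one pattern, via thresholded matrix product or a spiking net."""
    x = np.asarray(input_pattern, dtype=np.uint8)
    if x.shape != (memory.n_in,):
        raise ValueError("input pattern length mismatch")
    if not spiking:
        return _boolean_recall(memory, x)
    return binam_recall_batch(memory, x[None, :], params, weight, dt)[0]


def binam_recall_batch(
    memory: BinaryMemory,
    input_patterns: np.ndarray,
    params: NeuronParameters = _CAL_PARAMS,
    weight: Optional[float] = None,
    dt: float = 0.1,
) -> np.ndarray:
    """Spiking recall of many patterns in one simulation.

    Patterns are presented sequentially with a generous gap; an output bit
    is set iff its neuron spikes within the presentation window.
    """
    x = np.atleast_2d(np.asarray(input_patterns, dtype=np.uint8))
    m = x.shape[0]
    if weight is None:
        weight = calibrate_recall_weight(memory.k_in, params, dt)
    gap = 8.0 * max(params.tau_m, params.tau_syn_exc)
    present_times = [5.0 + s * gap for s in range(m)]
    spike_times: List[List[float]] = [
        [present_times[s] for s in range(m) if x[s, i]]
        for i in range(memory.n_in)
    ]
    pre, post = np.nonzero(memory.matrix)
    net = NetworkDescription().add(
        Population("in", memory.n_in, "source_array", {"spike_times": spike_times}),
        Population("out", memory.n_out, "lif_current", params),
        Connection("in", "out", Connector.from_list(list(zip(pre, post))), weight),
    )
    res = simulate(net, present_times[-1] + gap, dt=dt)
    out = np.zeros((m, memory.n_out), dtype=np.uint8)
    for j in range(memory.n_out):
        train = res.spikes["out"][j]
        for s, t0 in enumerate(present_times):
            if np.any((train >= t0) & (train < t0 + gap)):
                out[s, j] = 1
    return out


def _log2_comb(n: int, k: int) -> float:
    if k < 0 or k > n:
        raise ValueError(f"invalid binomial C({n},{k})")
    return (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)) / np.log(2.0)


def binam_information(
    true_patterns: np.ndarray,
    recalled_patterns: np.ndarray,
    n_out: int,
    k_out: int,
) -> float:
    """Retrieved information in bits over a set of recalled patterns.

    Per sample with ``fp`` false positives and ``fn`` false negatives
    against a true pattern of weight ``d = k_out`` in ``n = n_out`` bits::

        I = log2 C(n, d) - log2[ C(d - fn + fp, fp) * C(n - (d - fn + fp), fn) ]

    i.e. the entropy of the stored pattern minus the log-count of stored
    patterns compatible with the recalled vector; each sample's
    contribution is floored at 0 and the total is the sum over samples.
    """
    y_true = np.atleast_2d(np.asarray(true_patterns, dtype=np.uint8))
    y_rec = np.atleast_2d(np.asarray(recalled_patterns, dtype=np.uint8))
    if y_true.shape != y_rec.shape:
        raise ValueError("pattern lists must be aligned")
    total = 0.0
    for t, r in zip(y_true, y_rec):
        if int(t.sum()) != k_out:
            raise ValueError("true pattern weight differs from k_out")
        fp = int(np.sum((r == 1) & (t == 0)))
        fn = int(np.sum((r == 0) & (t == 1)))
        ones = k_out - fn + fp  # weight of the recalled vector
        if fp > ones or fn > n_out - ones:
            raise ValueError("fp/fn inconsistent with pattern weights")
        info = _log2_comb(n_out, k_out) - (
            _log2_comb(ones, fp) + _log2_comb(n_out - ones, fn)
        )
        total += max(0.0, info)
    return total
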