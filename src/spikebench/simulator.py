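"""Deterministic clock-driven reference simulator.

The engine integrates conductance- or current-based LIF neurons with the
closed-form-per-step convention used by the fast digital simulators it
stands in for: synaptic input delivered within a step is held constant over
that step, the membrane equation is then solved exactly for one ``dt``, and
threshold crossings are detected at step boundaries (spike time = end of
step).  Default ``dt`` is 0.1 ms.

Semantics frozen here (see docs/methods.md for rationale):

* refractory neurons are clamped to ``v_reset`` for ``round(tau_refrac/dt)``
  steps while synaptic state keeps integrating, so the minimum inter-spike
  interval of a self-firing neuron is ``tau_refrac + dt``;
* both synapse models decay exponentially with their ``tau_syn``;
* one root seed; every source population draws from a child stream derived
  by stable hashing of its population id, so adding a population never
  perturbs the noise of the others;
* all reported times are model ("bio") time in ms, wall-clock is kept in a
  separate field of the result.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse

from .network import (
    Connection,
    NetworkDescription,
    NetworkStructureError,
    NeuronParameters,
    Population,
    STDPParams,
)

__all__ = [
    "SimulationResult",
    "simulate",
    "lif_step",
    "poisson_train",
    "stdp_update",
    "population_rng",
]

DEFAULT_DT = 0.1


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------

def lif_step(
    v: float,
    syn_state: Tuple[float, float],
    params: NeuronParameters,
    dt: float,
    model: str = "lif_current",
) -> Tuple[float, bool]:
    """Advance one membrane by one step of the closed-form update.

    ``syn_state`` is ``(exc, inh)``: summed synaptic current (nA) per channel
    for the current model, summed conductance (uS) for the conductance model,
    assumed constant over the step.  Returns ``(v_new, spiked)``; on a spike
    the membrane is reset to ``v_reset`` (the refractory clock is the
    caller's responsibility).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not (np.isfinite(v) and all(np.isfinite(s) for s in syn_state)):
        raise FloatingPointError("non-finite membrane or synaptic state")
    exc, inh = syn_state
    if model == "lif_current":
        i_tot = exc - inh + params.i_offset
        v_inf = params.v_rest + i_tot * params.tau_m / params.c_m
        v_new = v_inf + (v - v_inf) * np.exp(-dt / params.tau_m)
    elif model == "lif_conductance":
        a = 1.0 / params.tau_m + (exc + inh) / params.c_m
        b = (
            params.v_rest / params.tau_m
            + (exc * params.e_rev_exc + inh * params.e_rev_inh + params.i_offset)
            / params.c_m
        )
        v_inf = b / a
        v_new = v_inf + (v - v_inf) * np.exp(-a * dt)
    else:
        raise ValueError(f"unknown neuron model {model!r}")
    if v_new >= params.v_thresh:
        return params.v_reset, True
    return float(v_new), False


def poisson_train(rate: float, duration: float, seed) -> np.ndarray:
    """Homogeneous Poisson spike train on ``[0, duration]`` ms.

    ``rate`` is in Hz, ``seed`` is an integer or a ``numpy`` Generator.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0 or duration <= 0:
        return np.empty(0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # draw in blocks of exponential gaps (mean gap in ms = 1000 / rate)
    mean_gap = 1000.0 / rate
    expected = max(8, int(duration / mean_gap * 1.5) + 8)
    times: List[np.ndarray] = []
    t = 0.0
    while t <= duration:
        gaps = rng.exponential(mean_gap, size=expected)
        chunk = t + np.cumsum(gaps)
        times.append(chunk)
        t = chunk[-1]
    all_times = np.concatenate(times)
    return all_times[all_times <= duration]


def stdp_update(w: float, dt_pair: float, params: STDPParams) -> float:
    """Apply the additive spike-pair rule to one weight.

    ``dt_pair`` is post minus pre spike time in ms.  Positive pairs
    potentiate, negative pairs depress, coincident pairs (``dt_pair == 0``)
    apply neither branch; the result is clipped to ``[w_min, w_max]``.
    """
    if dt_pair > 0:
        return min(params.w_max, w + params.a_plus * np.exp(-dt_pair / params.tau_plus))
    if dt_pair < 0:
        return max(params.w_min, w - params.a_minus * np.exp(dt_pair / params.tau_minus))
    return w


def population_rng(root_seed: int, pop_id: str) -> np.random.Generator:
    """Child RNG stream for one population, stable under network edits."""
    digest = hashlib.blake2b(pop_id.encode(), digest_size=4).digest()
    child = int.from_bytes(digest, "little") % (2**31)
    return np.random.default_rng([int(root_seed) % (2**31), child])


# --------------------------------------------------------------------------
# result container
# --------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Spikes (and optionally voltages) from one deterministic run.

    ``spikes[pop_id]`` is a list over the population's neurons; entries are
    ascending arrays of spike times in model ms, or ``None`` for unrecorded
    neurons.  Source events are always recorded.
    """

    spikes: Dict[str, List[Optional[np.ndarray]]]
    duration: float
    dt: float
    seed: int
    wallclock: float = 0.0
    voltages: Dict[str, np.ndarray] = field(default_factory=dict)
    plastic_weights: Dict[int, np.ndarray] = field(default_factory=dict)
    n_stdp_updates: int = 0

    def spike_counts(self, pop_id: str) -> np.ndarray:
        return np.array(
            [len(s) if s is not None else 0 for s in self.spikes[pop_id]]
        )

    def rates(self, pop_id: str) -> np.ndarray:
        """Mean firing rate in Hz of each recorded neuron of a population."""
        counts = [len(s) for s in self.spikes[pop_id] if s is not None]
        return np.array(counts) / self.duration * 1000.0

    def fully_recorded(self, network: NetworkDescription) -> bool:
        for pop in network.populations:
            if pop.is_source:
                continue
            if any(s is None for s in self.spikes[pop.id]):
                return False
        return True


# --------------------------------------------------------------------------
# compilation: description -> flat arrays
# --------------------------------------------------------------------------

def _expand_pairs(
    con: Connection, n_src: int, n_tgt: int, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resolve a connector to (pre, post, weight) index arrays."""
    kind = con.connector.kind
    if kind == "one_to_one":
        pre = np.arange(n_src)
        post = np.arange(n_tgt)
        w = np.full(n_src, con.weight)
    elif kind == "all_to_all":
        pre = np.repeat(np.arange(n_src), n_tgt)
        post = np.tile(np.arange(n_tgt), n_src)
        w = np.full(n_src * n_tgt, con.weight)
    elif kind == "fixed_probability":
        mask = rng.random((n_src, n_tgt)) < con.connector.p
        pre, post = np.nonzero(mask)
        w = np.full(len(pre), con.weight)
    else:  # from_list
        pairs = con.connector.pairs
        pre = np.array([p[0] for p in pairs], dtype=int)
        post = np.array([p[1] for p in pairs], dtype=int)
        w = np.array(
            [p[2] if len(p) > 2 else con.weight for p in pairs], dtype=float
        )
    if np.any(w < 0):
        raise ValueError("weights are magnitudes; receptor carries the sign")
    return pre, post, w


class _Plastic:
    """State of one plastic (STDP) projection."""

    def __init__(self, pre, post, w, channel, delay_steps, params: STDPParams):
        self.pre = pre  # global pre indices
        self.post = post  # LIF indices
        self.w = w.astype(float).copy()
        self.channel = channel
        self.delay_steps = delay_steps
        self.params = params
        n = len(pre)
        self.last_pre = np.full(n, -np.inf)
        self.last_post = np.full(n, -np.inf)


def simulate(
    network: NetworkDescription,
    duration: float,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    record_v: Sequence[str] = (),
) -> SimulationResult:
    """Run the reference clock-driven simulation.

    Identical ``(network, duration, dt, seed)`` produce bit-identical
    results.  ``record_v`` lists population ids whose membrane traces are
    stored at ``dt`` resolution.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    network.validate()
    t_start = time.perf_counter()
    n_steps = int(round(duration / dt))

    lif_pops = [p for p in network.populations if not p.is_source]
    src_pops = [p for p in network.populations if p.is_source]

    # global index layout: sources first, then LIF neurons
    src_offset: Dict[str, int] = {}
    n_src = 0
    for p in src_pops:
        src_offset[p.id] = n_src
        n_src += p.size
    lif_offset: Dict[str, int] = {}
    n_lif = 0
    for p in lif_pops:
        lif_offset[p.id] = n_lif
        n_lif += p.size
    n_pre_total = n_src + n_lif

    # flattened parameter arrays -------------------------------------------
    def _flat(attr):
        if n_lif == 0:
            return np.empty(0)
        return np.concatenate(
            [np.full(p.size, getattr(p.params, attr)) for p in lif_pops]
        )

    v_rest = _flat("v_rest")
    v_thresh = _flat("v_thresh")
    v_reset = _flat("v_reset")
    tau_m = _flat("tau_m")
    c_m = _flat("c_m")
    i_offset = _flat("i_offset")
    e_rev_exc = _flat("e_rev_exc")
    e_rev_inh = _flat("e_rev_inh")
    decay_e = np.exp(-dt / _flat("tau_syn_exc")) if n_lif else np.empty(0)
    decay_i = np.exp(-dt / _flat("tau_syn_inh")) if n_lif else np.empty(0)
    refrac_steps = (
        np.round(_flat("tau_refrac") / dt).astype(int) if n_lif else np.empty(0, int)
    )
    is_cond = (
        np.concatenate(
            [np.full(p.size, p.model == "lif_conductance") for p in lif_pops]
        )
        if n_lif
        else np.empty(0, bool)
    )
    decay_m = np.exp(-dt / tau_m) if n_lif else np.empty(0)
    cond_idx = np.nonzero(is_cond)[0]
    curr_idx = np.nonzero(~is_cond)[0]

    # source spike trains ---------------------------------------------------
    src_trains: Dict[str, List[np.ndarray]] = {}
    for p in src_pops:
        rng = population_rng(seed, p.id)
        if p.model == "source_poisson":
            rate = (p.params or {}).get("rate", 0.0)
            src_trains[p.id] = [
                poisson_train(rate, duration, rng) for _ in range(p.size)
            ]
        else:
            st = p.params["spike_times"]
            if st and isinstance(st[0], (list, tuple, np.ndarray)):
                if len(st) != p.size:
                    raise NetworkStructureError(
                        f"population {p.id!r}: need one spike list per neuron"
                    )
                trains = [np.sort(np.asarray(s, dtype=float)) for s in st]
            else:
                shared = np.sort(np.asarray(st, dtype=float))
                trains = [shared.copy() for _ in range(p.size)]
            src_trains[p.id] = trains

    # per-step source event counts: emission step of a spike at time t is
    # floor(t/dt) - 1 (end-of-step grid; t=0 maps to the virtual step -1 and
    # is delivered in step 0 through the minimum one-step delay)
    ev_step: List[np.ndarray] = []
    ev_idx: List[np.ndarray] = []
    for p in src_pops:
        base = src_offset[p.id]
        for i, train in enumerate(src_trains[p.id]):
            if len(train) == 0:
                continue
            steps = np.floor(train / dt + 1e-9).astype(int) - 1
            steps = steps[steps < n_steps]
            ev_step.append(steps)
            ev_idx.append(np.full(len(steps), base + i))
    if ev_step:
        ev_step_all = np.concatenate(ev_step)
        ev_idx_all = np.concatenate(ev_idx)
    else:
        ev_step_all = np.empty(0, int)
        ev_idx_all = np.empty(0, int)

    # connections -----------------------------------------------------------
    static_groups: Dict[Tuple[int, str], List[Tuple[np.ndarray, np.ndarray, np.ndarray]]] = {}
    plastics: List[_Plastic] = []
    max_delay_steps = 1
    for ci, con in enumerate(network.connections):
        src = network.population(con.source)
        tgt = network.population(con.target)
        if con.delay < dt - 1e-9:
            raise ValueError(
                f"connection {con.source!r}->{con.target!r}: delay {con.delay} ms "
                f"is below dt = {dt} ms"
            )
        delay_steps = max(1, int(round(con.delay / dt)))
        max_delay_steps = max(max_delay_steps, delay_steps)
        rng_con = np.random.default_rng(
            [int(seed) % (2**31), 0x5EED, ci % (2**31)]
        )
        pre, post, w = _expand_pairs(con, src.size, tgt.size, rng_con)
        gpre = pre + (src_offset[con.source] if src.is_source else n_src + lif_offset[con.source])
        gpost = post + lif_offset[con.target]
        channel = 0 if con.receptor == "excitatory" else 1
        if con.plasticity is not None:
            plastics.append(
                _Plastic(gpre, gpost, w, channel, delay_steps, con.plasticity)
            )
        else:
            static_groups.setdefault((delay_steps, con.receptor), []).append(
                (gpre, gpost, w)
            )

    matrices: Dict[Tuple[int, str], sparse.csr_matrix] = {}
    for key, triples in static_groups.items():
        pre = np.concatenate([t[0] for t in triples])
        post = np.concatenate([t[1] for t in triples])
        w = np.concatenate([t[2] for t in triples])
        matrices[key] = sparse.csr_matrix(
            (w, (post, pre)), shape=(n_lif, n_pre_total)
        )

    # state -----------------------------------------------------------------
    v = v_rest.copy()
    syn_e = np.zeros(n_lif)
    syn_i = np.zeros(n_lif)
    refrac = np.zeros(n_lif, dtype=int)
    ring_len = max_delay_steps + 1
    ring = np.zeros((ring_len, n_pre_total))
    # seed the ring with source events of virtual emission step -1
    mask_init = ev_step_all == -1
    if mask_init.any():
        np.add.at(ring[(-1) % ring_len], ev_idx_all[mask_init], 1.0)
    # source events grouped by emission step for the loop
    order = np.argsort(ev_step_all, kind="stable")
    ev_step_sorted = ev_step_all[order]
    ev_idx_sorted = ev_idx_all[order]
    ev_ptr = int(np.searchsorted(ev_step_sorted, 0))

    spike_steps: List[np.ndarray] = []
    spike_ids: List[np.ndarray] = []
    n_stdp_updates = 0

    v_pops = list(record_v)
    v_traces = (
        {pid: np.empty((network.population(pid).size, n_steps)) for pid in v_pops}
        if v_pops
        else {}
    )

    any_plastic = bool(plastics)
    for s in range(n_steps):
        # 1. deliver due spikes
        inc_e = np.zeros(n_lif)
        inc_i = np.zeros(n_lif)
        for (d, receptor), mat in matrices.items():
            vec = ring[(s - d) % ring_len]
            if vec.any():
                if receptor == "excitatory":
                    inc_e += mat.dot(vec)
                else:
                    inc_i += mat.dot(vec)
        if any_plastic:
            for pl in plastics:
                vec = ring[(s - pl.delay_steps) % ring_len]
                fired = vec[pl.pre]
                if fired.any():
                    contrib = pl.w * fired
                    if pl.channel == 0:
                        np.add.at(inc_e, pl.post, contrib)
                    else:
                        np.add.at(inc_i, pl.post, contrib)
        syn_e += inc_e
        syn_i += inc_i

        # 2. closed-form membrane update (input constant over the step)
        active = refrac == 0
        if curr_idx.size:
            idx = curr_idx[active[curr_idx]]
            if idx.size:
                i_tot = syn_e[idx] - syn_i[idx] + i_offset[idx]
                v_inf = v_rest[idx] + i_tot * tau_m[idx] / c_m[idx]
                v[idx] = v_inf + (v[idx] - v_inf) * decay_m[idx]
        if cond_idx.size:
            idx = cond_idx[active[cond_idx]]
            if idx.size:
                a = 1.0 / tau_m[idx] + (syn_e[idx] + syn_i[idx]) / c_m[idx]
                b = (
                    v_rest[idx] / tau_m[idx]
                    + (
                        syn_e[idx] * e_rev_exc[idx]
                        + syn_i[idx] * e_rev_inh[idx]
                        + i_offset[idx]
                    )
                    / c_m[idx]
                )
                v_inf = b / a
                v[idx] = v_inf + (v[idx] - v_inf) * np.exp(-a * dt)

        # 3. threshold, reset, refractory bookkeeping
        spiked = active & (v >= v_thresh)
        fired_idx = np.nonzero(spiked)[0]
        if fired_idx.size:
            v[fired_idx] = v_reset[fired_idx]
            refrac[fired_idx] = refrac_steps[fired_idx]
            spike_steps.append(np.full(fired_idx.size, s))
            spike_ids.append(fired_idx)
        in_refrac = ~active
        if in_refrac.any():
            v[in_refrac] = v_reset[in_refrac]
            refrac[in_refrac] -= 1

        # 4. synaptic decay at the end of the step
        syn_e *= decay_e
        syn_i *= decay_i

        # 5. publish emissions of this step (sources + neuron spikes)
        slot = ring[s % ring_len]
        slot[:] = 0.0
        while ev_ptr < len(ev_step_sorted) and ev_step_sorted[ev_ptr] == s:
            slot[ev_idx_sorted[ev_ptr]] += 1.0
            ev_ptr += 1
        if fired_idx.size:
            slot[n_src + fired_idx] = 1.0

        # 6. STDP pairing on this step's emissions
        if any_plastic:
            t_now = (s + 1) * dt
            pre_fired = slot > 0
            for pl in plastics:
                n_stdp_updates += _stdp_step(
                    pl, pre_fired, fired_idx, n_src, t_now
                )

        for pid in v_pops:
            pop = network.population(pid)
            off = lif_offset[pid]
            v_traces[pid][:, s] = v[off : off + pop.size]

    # assemble result -------------------------------------------------------
    if spike_steps:
        all_steps = np.concatenate(spike_steps)
        all_ids = np.concatenate(spike_ids)
    else:
        all_steps = np.empty(0, int)
        all_ids = np.empty(0, int)
    all_times = (all_steps + 1) * dt
    order = np.argsort(all_ids, kind="stable")  # stable keeps times ascending
    sorted_ids = all_ids[order]
    sorted_times = all_times[order]

    spikes: Dict[str, List[Optional[np.ndarray]]] = {}
    for p in lif_pops:
        off = lif_offset[p.id]
        rec = set(p.recorded_indices())
        per: List[Optional[np.ndarray]] = []
        for i in range(p.size):
            if i in rec:
                lo = np.searchsorted(sorted_ids, off + i, side="left")
                hi = np.searchsorted(sorted_ids, off + i, side="right")
                per.append(sorted_times[lo:hi].copy())
            else:
                per.append(None)
        spikes[p.id] = per
    for p in src_pops:
        spikes[p.id] = [t[t <= duration] for t in src_trains[p.id]]

    result = SimulationResult(
        spikes=spikes,
        duration=duration,
        dt=dt,
        seed=seed,
        wallclock=time.perf_counter() - t_start,
        voltages=v_traces,
        plastic_weights={i: pl.w.copy() for i, pl in enumerate(plastics)},
        n_stdp_updates=n_stdp_updates,
    )
    return result


def _stdp_step(
    pl: _Plastic,
    pre_fired_global: np.ndarray,
    lif_fired_idx: np.ndarray,
    n_src: int,
    t_now: float,
) -> int:
    """Nearest-neighbour pair updates for one plastic projection, one step.

    Returns the number of weight updates applied (for energy accounting).
    """
    p = pl.params
    n_updates = 0
    pre_mask = pre_fired_global[pl.pre]
    if pre_mask.any():
        pl.last_pre[pre_mask] = t_now
    if lif_fired_idx.size:
        post_mask = np.isin(pl.post, lif_fired_idx)
        if post_mask.any():
            dt_pair = t_now - pl.last_pre[post_mask]
            pot = np.isfinite(dt_pair) & (dt_pair > 0)
            if pot.any():
                sel = np.nonzero(post_mask)[0][pot]
                pl.w[sel] = np.minimum(
                    p.w_max,
                    pl.w[sel] + p.a_plus * np.exp(-dt_pair[pot] / p.tau_plus),
                )
                n_updates += int(pot.sum())
            pl.last_post[post_mask] = t_now
    if pre_mask.any():
        dt_pair = pl.last_post[pre_mask] - t_now
        dep = np.isfinite(dt_pair) & (dt_pair < 0)
        if dep.any():
            sel = np.nonzero(pre_mask)[0][dep]
            pl.w[sel] = np.maximum(
                p.w_min,
                pl.w[sel] - p.a_minus * np.exp(dt_pair[dep] / p.tau_minus),
            )
            n_updates += int(dep.sum())
    return n_updates
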