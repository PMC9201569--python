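"""Reference-simulator semantics: closed-form integration, refractoriness,
determinism, spike-pair plasticity, and a dual-route cross-check against an
independent scalar reimplementation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikebench.network import (
    Connection,
    Connector,
    NetworkDescription,
    NetworkStructureError,
    NeuronParameters,
    Population,
    STDPParams,
)
from spikebench.simulator import lif_step, poisson_train, simulate, stdp_update


# ---------------------------------------------------------------- lif_step

def test_membrane_decay_matches_analytic_exponential():
    params = NeuronParameters(tau_m=10.0, v_thresh=0.0)
    v = params.v_rest + 10.0
    for dt in (0.01, 0.1, 1.0, 10.0):
        v_new, spiked = lif_step(v, (0.0, 0.0), params, dt)
        expected = params.v_rest + 10.0 * np.exp(-dt / params.tau_m)
        assert not spiked
        assert abs(v_new - expected) <= 1e-9 * abs(expected)


def test_threshold_crossing_resets_to_v_reset():
    params = NeuronParameters(v_thresh=-50.0, v_reset=-70.0, tau_m=5.0, c_m=1.0)
    # strong constant current drives v past threshold within one step
    v_new, spiked = lif_step(params.v_rest, (10.0, 0.0), params, 5.0)
    assert spiked
    assert v_new == params.v_reset


def test_constant_current_converges_to_fixed_point():
    params = NeuronParameters(tau_m=10.0, c_m=0.5, v_thresh=100.0)
    current = 0.4  # nA
    v = params.v_rest
    for _ in range(2000):
        v, _ = lif_step(v, (current, 0.0), params, 0.1)
    assert v == pytest.approx(params.v_rest + current * params.tau_m / params.c_m,
                              abs=1e-6)


def test_conductance_step_pulls_toward_reversal_potential():
    params = NeuronParameters(v_thresh=0.0, e_rev_exc=0.0, e_rev_inh=-90.0)
    v_exc, _ = lif_step(-65.0, (0.5, 0.0), params, 0.1, model="lif_conductance")
    v_inh, _ = lif_step(-65.0, (0.0, 0.5), params, 0.1, model="lif_conductance")
    assert v_exc > -65.0
    assert v_inh < -65.0


def test_non_finite_state_raises():
    params = NeuronParameters()
    with pytest.raises(FloatingPointError):
        lif_step(float("nan"), (0.0, 0.0), params, 0.1)


# ---------------------------------------------------------------- simulate

def test_empty_network_any_duration_zero_spikes():
    result = simulate(NetworkDescription(), 100.0, seed=0)
    assert result.spikes == {}
    assert result.duration == 100.0


def test_refractory_limited_interspike_interval(single_neuron_net):
    """Self-firing neuron: ISI = tau_refrac + one dt, from first principles.

    The independent oracle walks the update rule step by step: after a
    spike the membrane is clamped for round(tau_refrac/dt) steps, then one
    more update crosses threshold, so spikes recur every 11 steps at
    dt = 0.1 ms.
    """
    dt = 0.1
    result = simulate(single_neuron_net, 1000.0, dt=dt, seed=0)
    train = result.spikes["n"][0]
    isis = np.diff(train)
    assert np.allclose(isis, 1.0 + dt)
    # oracle: expected spike steps are 1, 12, 23, ... (11-step period)
    expected_first = [dt * (1 + 11 * k) for k in range(5)]
    assert np.allclose(train[:5], expected_first)


def test_no_two_spikes_closer_than_tau_refrac(driven_pair_net):
    result = simulate(driven_pair_net, 60.0, seed=0)
    train = result.spikes["n"][0]
    assert len(train) >= 2
    assert np.all(np.diff(train) >= 2.0)


def test_determinism_same_seed_bit_identical(single_neuron_net):
    a = simulate(single_neuron_net, 200.0, seed=42)
    b = simulate(single_neuron_net, 200.0, seed=42)
    assert np.array_equal(a.spikes["n"][0], b.spikes["n"][0])


def test_adding_a_population_does_not_perturb_other_noise():
    def base(extra):
        net = NetworkDescription().add(
            Population("noise_a", 3, "source_poisson", {"rate": 50.0})
        )
        if extra:
            net.add(Population("noise_b", 3, "source_poisson", {"rate": 80.0}))
        return simulate(net, 500.0, seed=7)

    without = base(False)
    with_extra = base(True)
    for i in range(3):
        assert np.array_equal(without.spikes["noise_a"][i],
                              with_extra.spikes["noise_a"][i])


def test_unknown_population_reference_is_structural_error():
    net = NetworkDescription().add(
        Population("a", 1, "lif_current", NeuronParameters()),
        Connection("a", "ghost", Connector.one_to_one(), 0.1),
    )
    with pytest.raises(NetworkStructureError):
        simulate(net, 10.0)


def test_delay_below_dt_is_configuration_error():
    net = NetworkDescription().add(
        Population("a", 1, "lif_current", NeuronParameters()),
        Population("b", 1, "lif_current", NeuronParameters()),
        Connection("a", "b", Connector.one_to_one(), 0.1, delay=0.1),
    )
    with pytest.raises(ValueError, match="delay"):
        simulate(net, 10.0, dt=1.0)


def test_dt_refinement_changes_count_by_at_most_one_percent():
    """Halving dt shifts threshold crossings by at most one step each."""
    params = NeuronParameters(tau_m=10.0, c_m=0.5, tau_refrac=2.0,
                              i_offset=1.0, v_thresh=-50.0)
    net = NetworkDescription().add(Population("n", 1, "lif_current", params))
    coarse = len(simulate(net, 5000.0, dt=0.1, seed=0).spikes["n"][0])
    fine = len(simulate(net, 5000.0, dt=0.05, seed=0).spikes["n"][0])
    assert coarse >= 100
    assert abs(fine - coarse) <= max(1, coarse // 100)


def test_voltage_trace_recording_shape():
    params = NeuronParameters()
    net = NetworkDescription().add(Population("n", 2, "lif_current", params))
    result = simulate(net, 10.0, dt=0.1, record_v=["n"])
    assert result.voltages["n"].shape == (2, 100)


# ------------------------------------------------- independent oracle

def _scalar_reference(net_spec, duration, dt):
    """Independent event-by-step scalar reimplementation for a 2-neuron
    chain: array source -> neuron A -> neuron B (excitatory, delay 1 step).

    Written without reference to the engine: plain python floats, explicit
    queues.
    """
    src_times, w_sa, w_ab, params = net_spec
    n_steps = int(round(duration / dt))
    refrac_steps = int(round(params.tau_refrac / dt))
    decay_m = np.exp(-dt / params.tau_m)
    decay_s = np.exp(-dt / params.tau_syn_exc)
    # emission step of a source spike at time t: floor(t/dt) - 1
    src_steps = sorted(int(np.floor(t / dt + 1e-9)) - 1 for t in src_times)
    spikes = {"A": [], "B": []}
    v = {"A": params.v_rest, "B": params.v_rest}
    syn = {"A": 0.0, "B": 0.0}
    refrac = {"A": 0, "B": 0}
    pending = {"A": {}, "B": {}}  # step -> weight sum
    for s in src_steps:
        pending["A"][s + 1] = pending["A"].get(s + 1, 0.0) + w_sa
    for s in range(n_steps):
        for name in ("A", "B"):
            syn[name] += pending[name].pop(s, 0.0)
            if refrac[name] == 0:
                v_inf = params.v_rest + syn[name] * params.tau_m / params.c_m
                v[name] = v_inf + (v[name] - v_inf) * decay_m
                if v[name] >= params.v_thresh:
                    spikes[name].append((s + 1) * dt)
                    v[name] = params.v_reset
                    refrac[name] = refrac_steps
                    if name == "A":
                        pending["B"][s + 1] = (
                            pending["B"].get(s + 1, 0.0) + w_ab
                        )
            else:
                v[name] = params.v_reset
                refrac[name] -= 1
            syn[name] *= decay_s
    return spikes


def test_two_neuron_chain_matches_independent_reimplementation():
    params = NeuronParameters(tau_refrac=2.0, tau_m=5.0, tau_syn_exc=2.0,
                              c_m=0.25)
    src_times = [5.0, 20.0, 47.3]
    w = 6.0
    net = NetworkDescription().add(
        Population("src", 1, "source_array", {"spike_times": src_times}),
        Population("A", 1, "lif_current", params),
        Population("B", 1, "lif_current", params),
        Connection("src", "A", Connector.one_to_one(), w),
        Connection("A", "B", Connector.one_to_one(), w),
    )
    result = simulate(net, 80.0, dt=0.1, seed=0)
    oracle = _scalar_reference((src_times, w, w, params), 80.0, 0.1)
    for name in ("A", "B"):
        got = result.spikes[name][0]
        want = np.array(oracle[name])
        assert len(got) == len(want) > 0
        assert np.allclose(got, want, atol=0.1 + 1e-12)


# ------------------------------------------------------------- poisson

def test_poisson_zero_rate_is_empty():
    assert len(poisson_train(0.0, 1000.0, 1)) == 0


def test_poisson_negative_rate_rejected():
    with pytest.raises(ValueError):
        poisson_train(-1.0, 100.0, 1)


def test_poisson_count_within_statistical_band():
    counts = [len(poisson_train(100.0, 10_000.0, seed)) for seed in range(10)]
    # expected 1000 events; 4 sigma band on the mean of 10 draws
    assert abs(np.mean(counts) - 1000.0) < 4.0 * np.sqrt(1000.0 / 10)


def test_poisson_different_seeds_differ():
    a = poisson_train(100.0, 1000.0, 1)
    b = poisson_train(100.0, 1000.0, 2)
    assert not np.array_equal(a, b)


def test_poisson_times_sorted_within_duration():
    t = poisson_train(250.0, 500.0, 3)
    assert np.all(np.diff(t) >= 0)
    assert t[0] >= 0 and t[-1] <= 500.0


# ---------------------------------------------------------------- stdp

STDP = STDPParams(a_plus=0.1, a_minus=0.12, tau_plus=20.0, tau_minus=20.0,
                  w_min=0.0, w_max=1.0)


@pytest.mark.parametrize(
    "w, dt_pair, expected",
    [
        (1.0, 5.0, 1.0),  # additive clipping at w_max
        (0.5, 20.0, 0.5 + 0.1 * np.exp(-1.0)),  # potentiation at +tau_plus
        (0.5, -20.0, 0.5 - 0.12 * np.exp(-1.0)),  # depression at -tau_minus
        (0.5, 0.0, 0.5),  # coincident pair applies neither branch
        (0.0, -5.0, 0.0),  # clipping at w_min
    ],
)
def test_stdp_pair_rule_arithmetic(w, dt_pair, expected):
    assert stdp_update(w, dt_pair, STDP) == pytest.approx(expected)


@settings(max_examples=100, derandomize=True)
@given(
    w=st.floats(0.0, 1.0),
    dt_pair=st.floats(-200.0, 200.0, allow_nan=False),
)
def test_stdp_update_stays_within_bounds(w, dt_pair):
    w_new = stdp_update(w, dt_pair, STDP)
    assert STDP.w_min <= w_new <= STDP.w_max
    if dt_pair > 0:
        assert w_new >= w
    elif dt_pair < 0:
        assert w_new <= w


def test_engine_stdp_potentiation_on_pre_post_pairing():
    """A forced pre-then-post pairing potentiates by a_plus*exp(-lag/tau)."""
    params = NeuronParameters(tau_refrac=2.0, tau_m=5.0, tau_syn_exc=2.0,
                              c_m=0.25)
    stdp = STDPParams(a_plus=0.2, a_minus=0.1, tau_plus=20.0, tau_minus=20.0,
                      w_min=0.0, w_max=1.0)
    net = NetworkDescription().add(
        Population("pre_src", 1, "source_array", {"spike_times": [5.0]}),
        Population("post_src", 1, "source_array", {"spike_times": [9.0]}),
        Population("pre", 1, "lif_current", params),
        Population("post", 1, "lif_current", params),
        Connection("pre_src", "pre", Connector.one_to_one(), 6.0),
        Connection("post_src", "post", Connector.one_to_one(), 6.0),
        Connection("pre", "post", Connector.one_to_one(), 0.0, plasticity=stdp),
    )
    result = simulate(net, 30.0, seed=0)
    t_pre = result.spikes["pre"][0][0]
    t_post = result.spikes["post"][0][0]
    lag = t_post - t_pre
    assert lag > 0
    expected = 0.2 * np.exp(-lag / 20.0)
    assert result.plastic_weights[0][0] == pytest.approx(expected)
    assert result.n_stdp_updates == 1
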