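"""Additive energy model: decomposition, accounting, prediction, and the
biological scale-up arithmetic."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikebench.energy import (
    ATPBudget,
    BrainScaleupParams,
    EnergyCoefficients,
    EventCounts,
    MeasurementStage,
    ProtocolError,
    brain_neuron_power,
    count_events,
    decompose_measurements,
    load_platform_presets,
    platform_neuron_power,
    predict_energy,
    protocol_from_csv,
    protocol_to_csv,
    scale_to_brain,
    synthesize_protocol,
    technology_scaling,
)
from spikebench.network import (
    Connection,
    Connector,
    NetworkDescription,
    NeuronParameters,
    Population,
)
from spikebench.simulator import simulate


# ------------------------------------------------------- decomposition

coeff_floats = st.floats(0.0, 10.0, allow_nan=False, allow_infinity=False)


@settings(max_examples=30, derandomize=True)
@given(
    p_idle=coeff_floats, e_src=coeff_floats, p_neuron=coeff_floats,
    e_spike=coeff_floats, e_trans=coeff_floats, p_stdp=coeff_floats,
    e_stdp=coeff_floats,
)
def test_synthesize_then_decompose_is_identity(
    p_idle, e_src, p_neuron, e_spike, e_trans, p_stdp, e_stdp
):
    coeff = EnergyCoefficients(
        p_idle=p_idle, e_source_event=e_src, p_idle_neuron=p_neuron,
        e_spike=e_spike, e_transmission=e_trans, p_stdp_static=p_stdp,
        e_stdp_event=e_stdp, realtime_factor=1.0,
    )
    recovered = decompose_measurements(synthesize_protocol(coeff))
    for field in dataclasses.fields(EnergyCoefficients):
        assert getattr(recovered, field.name) == pytest.approx(
            getattr(coeff, field.name), abs=1e-9
        )


def test_all_stages_equal_power_gives_zero_event_coefficients():
    stages = synthesize_protocol(EnergyCoefficients(p_idle=5.0))
    for s in stages:
        s.power = 5.0
    coeff = decompose_measurements(stages)
    assert coeff.p_idle == 5.0
    assert coeff.e_spike == 0.0
    assert coeff.e_source_event == 0.0
    assert coeff.e_transmission == 0.0


def test_zero_spike_divisor_is_protocol_error():
    stages = synthesize_protocol(EnergyCoefficients(p_idle=1.0))
    for s in stages:
        if s.label == "self_firing":
            s.n_spikes = 0
    with pytest.raises(ProtocolError, match="zero spikes"):
        decompose_measurements(stages)


def test_missing_stage_is_protocol_error():
    stages = [s for s in synthesize_protocol(EnergyCoefficients())
              if s.label != "sources"]
    with pytest.raises(ProtocolError, match="sources"):
        decompose_measurements(stages)


def test_negative_residual_kept_with_warning():
    stages = synthesize_protocol(EnergyCoefficients(p_idle=2.0), include_stdp=False)
    for s in stages:
        if s.label == "self_firing":
            s.power = 1.0  # below the idle-neurons stage: noisy measurement
    coeff = decompose_measurements(stages)
    assert coeff.e_spike < 0
    assert any("negative" in w for w in coeff.warnings)


def test_protocol_csv_round_trip(tmp_path):
    stages = synthesize_protocol(
        EnergyCoefficients(p_idle=3.0, e_spike=1e-6, e_transmission=2e-8)
    )
    path = tmp_path / "protocol.csv"
    protocol_to_csv(stages, path)
    restored = protocol_from_csv(path)
    assert [s.label for s in restored] == [s.label for s in stages]
    assert restored[2].power == pytest.approx(stages[2].power)


# ------------------------------------------------------- event counting

def _counting_network():
    params = NeuronParameters(v_rest=-40.0, v_thresh=-60.0, v_reset=-61.0,
                              tau_m=1.0, tau_refrac=4.0)
    return NetworkDescription().add(
        Population("drive", 2, "source_poisson", {"rate": 50.0}),
        Population("a", 2, "lif_current", params),
        Population("b", 3, "lif_current", NeuronParameters()),
        Connection("drive", "a", Connector.one_to_one(), 0.01),
        Connection("a", "b", Connector.all_to_all(), 0.01),
    )


def test_count_events_matches_brute_force_tally():
    net = _counting_network()
    result = simulate(net, 500.0, seed=3)
    counts = count_events(result, net)
    # independent recount from the raw spike lists
    spikes_a = sum(len(t) for t in result.spikes["a"])
    spikes_b = sum(len(t) for t in result.spikes["b"])
    src = sum(len(t) for t in result.spikes["drive"])
    assert counts.n_spikes == spikes_a + spikes_b
    assert counts.n_source_events == src
    # each drive source feeds 1 neuron, each 'a' neuron fans out to 3
    assert counts.n_transmissions == src * 1 + spikes_a * 3
    assert counts.n_neurons == 5
    assert counts.model_duration == pytest.approx(0.5)


def test_pure_source_network_counts():
    net = NetworkDescription().add(
        Population("only", 4, "source_poisson", {"rate": 100.0})
    )
    result = simulate(net, 1000.0, seed=1)
    counts = count_events(result, net)
    assert counts.n_spikes == 0
    assert counts.n_source_events > 0


def test_partial_recording_rejected():
    net = _counting_network()
    net.population("b").record = [0]
    result = simulate(net, 100.0, seed=1)
    with pytest.raises(ValueError, match="full recording"):
        count_events(result, net)


# ------------------------------------------------------- prediction

def test_zero_duration_zero_events_zero_energy():
    counts = EventCounts(n_neurons=0, model_duration=0.0, n_spikes=0,
                         n_source_events=0, n_transmissions=0)
    assert predict_energy(counts, EnergyCoefficients(p_idle=10.0)) == 0.0


def test_prediction_linear_in_every_count():
    coeff = EnergyCoefficients(p_idle=1.0, e_source_event=1e-6,
                               p_idle_neuron=1e-3, e_spike=2e-6,
                               e_transmission=3e-8, realtime_factor=2.0)
    base = EventCounts(n_neurons=10, model_duration=2.0, n_spikes=100,
                       n_source_events=50, n_transmissions=400)
    e0 = predict_energy(base, coeff)
    doubled = dataclasses.replace(base, n_spikes=200)
    assert predict_energy(doubled, coeff) - e0 == pytest.approx(
        coeff.e_spike * 100
    )
    assert e0 > predict_energy(
        dataclasses.replace(base, model_duration=1.0), coeff
    )


def test_stdp_terms_only_when_enabled():
    coeff = EnergyCoefficients(p_stdp_static=0.5, e_stdp_event=1e-6,
                               realtime_factor=1.0)
    off = EventCounts(5, 1.0, 0, 0, 0, n_stdp_updates=100, stdp_enabled=False)
    on = dataclasses.replace(off, stdp_enabled=True)
    assert predict_energy(off, coeff) == 0.0
    assert predict_energy(on, coeff) == pytest.approx(0.5 + 1e-4)


def test_placement_independence_by_construction():
    """Identical counts give identical energy regardless of how the same
    network would be placed across chips."""
    coeff = EnergyCoefficients(p_idle=1.0, e_transmission=1e-8)
    a = EventCounts(100, 1.0, 1000, 0, 50_000)
    b = EventCounts(100, 1.0, 1000, 0, 50_000)
    assert predict_energy(a, coeff) == predict_energy(b, coeff)


# ------------------------------------------------------- biological side

def test_brain_neuron_power_without_housekeeping():
    watts = brain_neuron_power(ATPBudget())
    assert watts == pytest.approx(2.02e-10, rel=0.01)


def test_brain_neuron_power_with_housekeeping():
    watts = brain_neuron_power(ATPBudget(), include_housekeeping=True)
    assert watts == pytest.approx(2.49e-10, rel=0.01)


def test_resting_only_power_at_zero_rate_limit():
    # rate -> 0: only the resting-potential line item remains
    budget = ATPBudget()
    tiny = BrainScaleupParams(mean_rate=1e-9)
    assert brain_neuron_power(budget, tiny) == pytest.approx(
        budget.resting * budget.j_per_atp, rel=1e-6
    )
    assert budget.resting * budget.j_per_atp == pytest.approx(5.75e-11, rel=1e-3)


def test_housekeeping_adds_exactly_a_third_of_signaling():
    budget = ATPBudget()
    without = brain_neuron_power(budget)
    with_hk = brain_neuron_power(budget, include_housekeeping=True)
    signaling = without - budget.resting * budget.j_per_atp
    assert with_hk - without == pytest.approx(0.33 * signaling)


def test_j_per_atp_outside_reported_bracket_rejected():
    with pytest.raises(ValueError):
        ATPBudget(j_per_atp=6e-20).validate()


@pytest.mark.parametrize(
    "platform, single_neuron, full_brain",
    [
        ("brain", 2.49e-10, 2.15e1),
        ("spikey", 1.49e-6, 1.29e5),
        ("spinnaker", 3.33e-4, 2.87e7),
        ("cpu_r2600x", 9.62e-4, 8.29e7),
        ("cpu_mobile", 3.37e-4, 2.90e7),
        ("gpu_rtx2070", 3.18e-5, 2.74e6),
    ],
)
def test_platform_rows_compose_to_printed_values(platform, single_neuron,
                                                 full_brain):
    presets = load_platform_presets()
    watts = platform_neuron_power(presets[platform])
    assert watts == pytest.approx(single_neuron, rel=0.01)
    assert scale_to_brain(watts) == pytest.approx(full_brain, rel=0.01)


def test_scale_to_brain_of_zero_neurons_is_zero():
    assert scale_to_brain(1e-6, 0) == 0.0


def test_technology_scaling_fixed_factor_and_doubling():
    presets = load_platform_presets()
    spikey_brain = scale_to_brain(platform_neuron_power(presets["spikey"]))
    assert technology_scaling(spikey_brain, factor=50) == pytest.approx(
        2.6e3, rel=0.01
    )
    # doubling every 3.33 years over a decade: more than 8-fold improvement
    assert technology_scaling(8.0, years=10.0, period_years=3.33) \
        == pytest.approx(1.0, rel=0.01)
    assert technology_scaling(7.0, factor=1.0) == 7.0


def test_technology_scaling_invalid_factor():
    with pytest.raises(ValueError):
        technology_scaling(1.0, factor=0.0)
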