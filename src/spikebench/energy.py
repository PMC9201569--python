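"""Additive per-event energy model and the biological comparison.

The energy expenditure of a spiking-network run on a target platform is
modelled as a sum of six contributions: static idle power of the system,
per-neuron idle power, energy per emitted spike, energy per source event,
energy per spike transmission (one per spike per outgoing synapse,
independent of placement), and STDP costs (a static power while plasticity
is active plus an energy per synaptic update).  Coefficients are obtained
by a staged subtraction protocol: measure idle power, then idle neurons,
then self-firing neurons, and so on, each stage exposing exactly one new
coefficient.

For the biological comparison, per-process ATP budgets (molecules per
second or per synaptic event) are converted to watts at 5e-20 J per ATP
molecule and scaled with a mean rate of 4 Hz and a fan-out of 2000 synapses
per neuron; "housekeeping" adds 33% of the signaling cost.  Scaling the
per-neuron power to 8.61e10 neurons gives the full-brain figure of about
21.5 W against which the hardware platforms are compared.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .network import NetworkDescription
from .simulator import SimulationResult

__all__ = [
    "EnergyCoefficients",
    "EventCounts",
    "ATPBudget",
    "BrainScaleupParams",
    "MeasurementStage",
    "ProtocolError",
    "decompose_measurements",
    "synthesize_protocol",
    "count_events",
    "predict_energy",
    "brain_neuron_power",
    "platform_neuron_power",
    "scale_to_brain",
    "technology_scaling",
    "load_platform_presets",
    "protocol_to_csv",
    "protocol_from_csv",
]


class ProtocolError(ValueError):
    """Raised when a measurement protocol is malformed."""


@dataclass
class EnergyCoefficients:
    """Per-platform cost coefficients of the additive model."""

    p_idle: float = 0.0  # W, idle system
    e_source_event: float = 0.0  # J per source event
    p_idle_neuron: float = 0.0  # W per simulated idle neuron
    e_spike: float = 0.0  # J per emitted spike
    e_transmission: float = 0.0  # J per (spike x fan-out) delivery
    p_stdp_static: float = 0.0  # W while plasticity is active
    e_stdp_event: float = 0.0  # J per synaptic update
    realtime_factor: float = 1.0  # wall-clock s per model s

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if name != "realtime_factor" and value < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.realtime_factor <= 0:
            raise ValueError("realtime_factor must be > 0")


@dataclass
class EventCounts:
    """Tallies of the energy-relevant event classes of one simulation."""

    n_neurons: int
    model_duration: float  # s
    n_spikes: int
    n_source_events: int
    n_transmissions: int
    n_stdp_updates: int = 0
    stdp_enabled: bool = False


@dataclass
class ATPBudget:
    """ATP line items of the biological neuron (rat neocortex values scaled
    to human): rates in ATP/s, synaptic items in ATP per event."""

    resting: float = 1.15e9
    action_potential_at_4hz: float = 1.57e9  # ATP/s at the 4 Hz reference rate
    post_synaptic: float = 1.40e5
    transmitter_recycling: float = 1.14e4
    presynaptic: float = 1.20e4
    j_per_atp: float = 5e-20
    housekeeping_fraction: float = 0.33

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if not 4.6495e-20 <= self.j_per_atp <= 5.5628e-20:
            raise ValueError(
                "j_per_atp outside the reported bracket 4.6495e-20..5.5628e-20"
            )


@dataclass
class BrainScaleupParams:
    mean_rate: float = 4.0  # Hz
    fan_out: int = 2000
    n_neurons: float = 8.61e10

    def validate(self) -> None:
        if self.mean_rate <= 0 or self.fan_out <= 0 or self.n_neurons <= 0:
            raise ValueError("scale-up parameters must be positive")


# --------------------------------------------------------------------------
# measurement decomposition
# --------------------------------------------------------------------------

@dataclass
class MeasurementStage:
    """One stage of the subtraction protocol.

    ``power`` is the stage's mean power in W (each an average over at least
    20 readings), ``duration`` the stage length in model seconds, and the
    count fields the events active during the stage.
    """

    label: str
    power: float
    duration: float
    n_neurons: int = 0
    n_spikes: int = 0
    n_source_events: int = 0
    n_transmissions: int = 0
    n_stdp_updates: int = 0
    stdp_enabled: bool = False


STAGE_ORDER = ["idle", "idle_neurons", "self_firing", "sources", "transmission"]
OPTIONAL_STAGES = ["stdp_static", "stdp_events"]


def decompose_measurements(
    protocol: Sequence[MeasurementStage],
    realtime_factor: float = 1.0,
) -> EnergyCoefficients:
    """Derive the cost coefficients from an ordered stage protocol.

    Stages must appear in the order idle -> idle_neurons -> self_firing ->
    sources -> transmission (-> stdp_static -> stdp_events); each stage
    exposes one new coefficient, computed from the residual power after
    subtracting the contributions predicted by the coefficients already
    known.  A negative residual is kept (measurement noise) but flagged via
    a warning attribute on the result; a stage dividing by a zero event
    count is a protocol error.
    """
    stages = {s.label: s for s in protocol}
    labels = [s.label for s in protocol]
    expected = STAGE_ORDER + [s for s in OPTIONAL_STAGES if s in stages]
    for want in STAGE_ORDER:
        if want not in stages:
            raise ProtocolError(f"missing protocol stage {want!r}")
    if labels != expected:
        raise ProtocolError(
            f"stages out of order: got {labels}, expected {expected}"
        )
    coeff = EnergyCoefficients(realtime_factor=realtime_factor)
    warnings: List[str] = []

    def residual(stage: MeasurementStage) -> float:
        counts = EventCounts(
            n_neurons=stage.n_neurons,
            model_duration=stage.duration,
            n_spikes=stage.n_spikes,
            n_source_events=stage.n_source_events,
            n_transmissions=stage.n_transmissions,
            n_stdp_updates=stage.n_stdp_updates,
            stdp_enabled=stage.stdp_enabled,
        )
        # the protocol is defined on the measured machine: durations are
        # wall-clock already, so predict with realtime factor 1
        flat = EnergyCoefficients(**{**asdict(coeff), "realtime_factor": 1.0})
        predicted = predict_energy(counts, flat)
        return stage.power * stage.duration - predicted

    def per_event(stage: MeasurementStage, count: int, what: str) -> float:
        if count <= 0:
            raise ProtocolError(
                f"stage {stage.label!r}: zero {what} in divisor"
            )
        value = residual(stage) / count
        if value < 0:
            warnings.append(
                f"stage {stage.label!r}: negative derived coefficient "
                f"{value:.3e} (kept; measurement noise)"
            )
        return value

    coeff.p_idle = stages["idle"].power
    st = stages["idle_neurons"]
    if st.n_neurons <= 0:
        raise ProtocolError("stage 'idle_neurons': zero neurons in divisor")
    coeff.p_idle_neuron = (st.power - coeff.p_idle) / st.n_neurons
    if coeff.p_idle_neuron < 0:
        warnings.append("stage 'idle_neurons': negative derived coefficient (kept)")
    st = stages["self_firing"]
    coeff.e_spike = per_event(st, st.n_spikes, "spikes")
    st = stages["sources"]
    coeff.e_source_event = per_event(st, st.n_source_events, "source events")
    st = stages["transmission"]
    coeff.e_transmission = per_event(st, st.n_transmissions, "transmissions")
    if "stdp_static" in stages:
        st = stages["stdp_static"]
        if not st.stdp_enabled or st.n_stdp_updates != 0:
            raise ProtocolError(
                "stage 'stdp_static' must have plasticity on and zero updates"
            )
        coeff.p_stdp_static = residual(st) / st.duration
    if "stdp_events" in stages:
        st = stages["stdp_events"]
        if not st.stdp_enabled:
            raise ProtocolError("stage 'stdp_events' must have plasticity on")
        coeff.e_stdp_event = per_event(st, st.n_stdp_updates, "stdp updates")
    coeff.warnings = warnings  # type: ignore[attr-defined]
    return coeff


def synthesize_protocol(
    coeff: EnergyCoefficients,
    duration: float = 10.0,
    n_neurons: int = 100,
    n_spikes: int = 5000,
    n_source_events: int = 4000,
    n_transmissions: int = 60000,
    n_stdp_updates: int = 3000,
    include_stdp: bool = True,
) -> List[MeasurementStage]:
    """Generate the staged protocol a machine with the given coefficients
    would produce (exact inverse of :func:`decompose_measurements`)."""

    def power(**kw) -> float:
        counts = EventCounts(
            n_neurons=kw.get("n_neurons", 0),
            model_duration=duration,
            n_spikes=kw.get("n_spikes", 0),
            n_source_events=kw.get("n_source_events", 0),
            n_transmissions=kw.get("n_transmissions", 0),
            n_stdp_updates=kw.get("n_stdp_updates", 0),
            stdp_enabled=kw.get("stdp_enabled", False),
        )
        flat = EnergyCoefficients(**{**asdict(coeff), "realtime_factor": 1.0})
        return predict_energy(counts, flat) / duration

    stages = [
        MeasurementStage("idle", power(), duration),
        MeasurementStage("idle_neurons", power(n_neurons=n_neurons), duration,
                         n_neurons=n_neurons),
        MeasurementStage("self_firing",
                         power(n_neurons=n_neurons, n_spikes=n_spikes),
                         duration, n_neurons=n_neurons, n_spikes=n_spikes),
        MeasurementStage("sources",
                         power(n_neurons=n_neurons, n_spikes=n_spikes,
                               n_source_events=n_source_events),
                         duration, n_neurons=n_neurons, n_spikes=n_spikes,
                         n_source_events=n_source_events),
        MeasurementStage("transmission",
                         power(n_neurons=n_neurons, n_spikes=n_spikes,
                               n_source_events=n_source_events,
                               n_transmissions=n_transmissions),
                         duration, n_neurons=n_neurons, n_spikes=n_spikes,
                         n_source_events=n_source_events,
                         n_transmissions=n_transmissions),
    ]
    if include_stdp:
        stages.append(
            MeasurementStage("stdp_static",
                             power(n_neurons=n_neurons, n_spikes=n_spikes,
                                   n_source_events=n_source_events,
                                   n_transmissions=n_transmissions,
                                   stdp_enabled=True),
                             duration, n_neurons=n_neurons, n_spikes=n_spikes,
                             n_source_events=n_source_events,
                             n_transmissions=n_transmissions,
                             stdp_enabled=True)
        )
        stages.append(
            MeasurementStage("stdp_events",
                             power(n_neurons=n_neurons, n_spikes=n_spikes,
                                   n_source_events=n_source_events,
                                   n_transmissions=n_transmissions,
                                   n_stdp_updates=n_stdp_updates,
                                   stdp_enabled=True),
                             duration, n_neurons=n_neurons, n_spikes=n_spikes,
                             n_source_events=n_source_events,
                             n_transmissions=n_transmissions,
                             n_stdp_updates=n_stdp_updates,
                             stdp_enabled=True)
        )
    return stages


# --------------------------------------------------------------------------
# event accounting and prediction
# --------------------------------------------------------------------------

def count_events(
    result: SimulationResult, network: NetworkDescription
) -> EventCounts:
    """Tally energy-relevant events of a finished simulation.

    Requires full spike recording of every neuron population (energy
    accounting cannot extrapolate unrecorded neurons).  Transmissions are
    spikes times the static fan-out of the emitting neuron.
    """
    if not result.fully_recorded(network):
        raise ValueError("energy accounting needs full recording")
    fan_out: Dict[str, np.ndarray] = {}
    for pop in network.populations:
        fan_out[pop.id] = np.zeros(pop.size, dtype=int)
    for con in network.connections:
        src = network.population(con.source)
        tgt = network.population(con.target)
        kind = con.connector.kind
        if kind == "one_to_one":
            fan_out[src.id] += 1
        elif kind in ("all_to_all", "fixed_probability"):
            # fixed_probability counts the expected dense fan-out bound;
            # exact per-seed realizations are a simulator internal
            fan_out[src.id] += tgt.size
        else:
            for pair in con.connector.pairs:
                fan_out[src.id][pair[0]] += 1

    n_spikes = 0
    n_source_events = 0
    n_transmissions = 0
    n_neurons = 0
    for pop in network.populations:
        counts = np.array([len(t) for t in result.spikes[pop.id]])
        trans = int(np.sum(counts * fan_out[pop.id]))
        if pop.is_source:
            n_source_events += int(counts.sum())
        else:
            n_neurons += pop.size
            n_spikes += int(counts.sum())
        n_transmissions += trans
    stdp_on = any(c.plasticity is not None for c in network.connections)
    return EventCounts(
        n_neurons=n_neurons,
        model_duration=result.duration / 1000.0,
        n_spikes=n_spikes,
        n_source_events=n_source_events,
        n_transmissions=n_transmissions,
        n_stdp_updates=result.n_stdp_updates,
        stdp_enabled=stdp_on,
    )


def predict_energy(counts: EventCounts, coeff: EnergyCoefficients) -> float:
    """Total energy in J of a simulation on the target platform.

    Wall-clock time is model duration times the platform's realtime factor;
    static terms scale with wall-clock, event terms with their counts.
    Placement plays no role: the same counts give the same energy.
    """
    t_wall = counts.model_duration * coeff.realtime_factor
    energy = coeff.p_idle * t_wall
    energy += coeff.p_idle_neuron * counts.n_neurons * t_wall
    energy += coeff.e_source_event * counts.n_source_events
    energy += coeff.e_spike * counts.n_spikes
    energy += coeff.e_transmission * counts.n_transmissions
    if counts.stdp_enabled:
        energy += coeff.p_stdp_static * t_wall
        energy += coeff.e_stdp_event * counts.n_stdp_updates
    return energy


# --------------------------------------------------------------------------
# biological comparison and scale-up
# --------------------------------------------------------------------------

def brain_neuron_power(
    budget: ATPBudget,
    scale: BrainScaleupParams = BrainScaleupParams(),
    include_housekeeping: bool = False,
) -> float:
    """Power of one biological neuron in W from the ATP line items.

    The action-potential line item is an ATP/s figure at the 4 Hz reference
    rate and is rescaled linearly with the mean rate; synaptic items are
    per event and fire ``fan_out * rate`` times per second.  Housekeeping
    adds ``housekeeping_fraction`` of the signaling cost (total minus
    resting).
    """
    budget.validate()
    scale.validate()
    atp_per_s = (
        budget.resting
        + budget.action_potential_at_4hz * (scale.mean_rate / 4.0)
        + (budget.post_synaptic + budget.transmitter_recycling + budget.presynaptic)
        * scale.fan_out
        * scale.mean_rate
    )
    if include_housekeeping:
        atp_per_s += budget.housekeeping_fraction * (atp_per_s - budget.resting)
    return atp_per_s * budget.j_per_atp


def platform_neuron_power(
    row: Dict[str, float],
    scale: BrainScaleupParams = BrainScaleupParams(),
) -> float:
    """Per-neuron power of a platform from its normalized cost row.

    ``row`` holds ``housekeeping`` (W), ``resting`` (W), ``e_ap`` (J per
    action potential) and ``e_trans`` (J per transmission)::

        W = housekeeping + resting + e_ap * rate + e_trans * fan_out * rate
    """
    scale.validate()
    for key in ("housekeeping", "resting", "e_ap", "e_trans"):
        if row[key] < 0:
            raise ValueError(f"row value {key!r} must be >= 0")
    return (
        row["housekeeping"]
        + row["resting"]
        + row["e_ap"] * scale.mean_rate
        + row["e_trans"] * scale.fan_out * scale.mean_rate
    )


def scale_to_brain(per_neuron_w: float, n_neurons: float = 8.61e10) -> float:
    """Naive scale-up: per-neuron power times the brain's neuron count."""
    if per_neuron_w < 0 or n_neurons < 0:
        raise ValueError("inputs must be non-negative")
    return per_neuron_w * n_neurons


def technology_scaling(
    power: float,
    factor: Optional[float] = None,
    years: Optional[float] = None,
    period_years: Optional[float] = None,
) -> float:
    """Project power to a newer fabrication process.

    Either a fixed improvement ``factor`` (power / factor), or doubling of
    performance per watt every ``period_years`` over ``years``
    (power / 2**(years / period_years)).
    """
    if factor is not None:
        if factor <= 0:
            raise ValueError("factor must be > 0")
        return power / factor
    if years is None or period_years is None or period_years <= 0:
        raise ValueError("give factor, or years and period_years > 0")
    return power / 2.0 ** (years / period_years)


def load_platform_presets() -> Dict[str, Dict[str, float]]:
    """Per-neuron normalized cost rows for the shipped platform columns."""
    text = resources.files("spikebench.data").joinpath(
        "platform_presets.json"
    ).read_text()
    return json.loads(text)["platforms"]


# --------------------------------------------------------------------------
# protocol CSV round trip
# --------------------------------------------------------------------------

_PROTO_COLS = [
    "stage", "label", "power_w", "duration_s", "n_neurons", "n_spikes",
    "n_source_events", "n_transmissions", "n_stdp", "stdp_enabled",
]


def protocol_to_csv(protocol: Sequence[MeasurementStage], path) -> None:
    rows = []
    for k, s in enumerate(protocol):
        rows.append([k, s.label, s.power, s.duration, s.n_neurons, s.n_spikes,
                     s.n_source_events, s.n_transmissions, s.n_stdp_updates,
                     int(s.stdp_enabled)])
    pd.DataFrame(rows, columns=_PROTO_COLS).to_csv(path, index=False)


def protocol_from_csv(path) -> List[MeasurementStage]:
    frame = pd.read_csv(path).sort_values("stage")
    return [
        MeasurementStage(
            label=r.label, power=float(r.power_w), duration=float(r.duration_s),
            n_neurons=int(r.n_neurons), n_spikes=int(r.n_spikes),
            n_source_events=int(r.n_source_events),
            n_transmissions=int(r.n_transmissions),
            n_stdp_updates=int(r.n_stdp), stdp_enabled=bool(r.stdp_enabled),
        )
        for r in frame.itertuples()
    ]
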