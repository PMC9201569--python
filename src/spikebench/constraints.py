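"""Backend constraint profiles and mappability checks.

Neuromorphic substrates restrict which networks they can execute: some
enforce Dale-style separation of excitation and inhibition, cap the synaptic
fan-in per neuron, support only one synapse model, or quantize weights.  A
:class:`ConstraintProfile` captures such restrictions declaratively and
:func:`validate_backend_constraints` reports every violation as data (an
empty list means the network is mappable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .network import NetworkDescription, LIF_MODELS, SOURCE_MODELS

__all__ = ["ConstraintProfile", "PROFILES", "validate_backend_constraints"]


@dataclass
class ConstraintProfile:
    """Declarative description of one backend's restrictions."""

    name: str
    supported_models: Sequence[str] = LIF_MODELS + SOURCE_MODELS
    max_fan_in: Optional[int] = None
    max_neurons: Optional[int] = None
    dale_separation: bool = False
    weight_resolution_bits: Optional[int] = None


#: Shipped profiles.  ``reference`` is the unconstrained software simulator;
#: the two hardware-like profiles model a small accelerated analogue chip
#: (conductance neurons only, 256 synaptic inputs, separated excitation and
#: inhibition, 4-bit weights, 384 neurons) and a digital many-core system.
PROFILES: Dict[str, ConstraintProfile] = {
    "reference": ConstraintProfile(name="reference"),
    "spikey-like": ConstraintProfile(
        name="spikey-like",
        supported_models=("lif_conductance",) + SOURCE_MODELS,
        max_fan_in=256,
        max_neurons=384,
        dale_separation=True,
        weight_resolution_bits=4,
    ),
    "spinnaker-like": ConstraintProfile(
        name="spinnaker-like",
        supported_models=LIF_MODELS + SOURCE_MODELS,
        max_fan_in=None,
        max_neurons=None,
        dale_separation=False,
    ),
}


def _fan_in_counts(network: NetworkDescription) -> Dict[str, List[int]]:
    counts = {
        p.id: [0] * p.size for p in network.populations if not p.is_source
    }
    for con in network.connections:
        src = network.population(con.source)
        tgt = network.population(con.target)
        kind = con.connector.kind
        if kind == "one_to_one":
            for j in range(tgt.size):
                counts[tgt.id][j] += 1
        elif kind == "all_to_all":
            for j in range(tgt.size):
                counts[tgt.id][j] += src.size
        elif kind == "fixed_probability":
            # worst case: the realized fan-in is bounded by the full matrix
            for j in range(tgt.size):
                counts[tgt.id][j] += src.size
        else:
            for pair in con.connector.pairs:
                counts[tgt.id][pair[1]] += 1
    return counts


def validate_backend_constraints(
    network: NetworkDescription, constraint_profile
) -> List[str]:
    """Check a network against a backend profile.

    ``constraint_profile`` is a :class:`ConstraintProfile` or the name of a
    shipped profile.  Returns a list of human-readable violation strings;
    violations are data, not exceptions.
    """
    if isinstance(constraint_profile, str):
        try:
            profile = PROFILES[constraint_profile]
        except KeyError:
            raise ValueError(
                f"unknown constraint profile {constraint_profile!r}; "
                f"declared profiles: {sorted(PROFILES)}"
            ) from None
    else:
        profile = constraint_profile
    network.validate()
    violations: List[str] = []

    for pop in network.populations:
        if pop.model not in profile.supported_models:
            violations.append(
                f"population {pop.id!r}: model {pop.model!r} not supported "
                f"on {profile.name!r}"
            )

    if profile.max_neurons is not None:
        n = sum(p.size for p in network.populations if not p.is_source)
        if n > profile.max_neurons:
            violations.append(
                f"{n} neurons exceed the {profile.max_neurons}-neuron "
                f"capacity of {profile.name!r}"
            )

    if profile.dale_separation:
        sign_by_pop: Dict[str, set] = {}
        for con in network.connections:
            sign_by_pop.setdefault(con.source, set()).add(con.receptor)
        for pop_id, receptors in sign_by_pop.items():
            if len(receptors) > 1:
                violations.append(
                    f"population {pop_id!r}: excitation/inhibition not "
                    f"separated (projects both receptor types)"
                )

    if profile.max_fan_in is not None:
        for pop_id, counts in _fan_in_counts(network).items():
            worst = max(counts, default=0)
            if worst > profile.max_fan_in:
                violations.append(
                    f"population {pop_id!r}: fan-in {worst} exceeds the "
                    f"{profile.max_fan_in} synaptic inputs of {profile.name!r}"
                )

    return violations
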