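"""Backend-agnostic spiking network description.

A network is a set of :class:`Population` objects (leaky integrate-and-fire
neurons or spike sources) wired by :class:`Connection` objects.  The
description deliberately mirrors the PyNN vocabulary (populations,
projections, connectors, receptor types) so that the same network can be
checked against different backend constraint profiles and executed on the
reference simulator.

Units follow the PyNN convention throughout: voltages in mV, times and time
constants in ms, capacitance in nF, currents in nA, conductances in uS.
Synaptic weights are sign-free magnitudes; the ``receptor`` of a connection
("excitatory" / "inhibitory") carries the sign semantics, which is what makes
Dale-style separation a checkable structural property.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple, Union

__all__ = [
    "NeuronParameters",
    "STDPParams",
    "Connector",
    "Population",
    "Connection",
    "NetworkDescription",
    "NetworkStructureError",
    "LIF_MODELS",
    "SOURCE_MODELS",
]

LIF_MODELS = ("lif_current", "lif_conductance")
SOURCE_MODELS = ("source_poisson", "source_array")


class NetworkStructureError(ValueError):
    """Raised for structurally invalid networks (bad references, shapes)."""


@dataclass
class NeuronParameters:
    """LIF neuron parameters (PyNN ``IF_curr_exp`` / ``IF_cond_exp`` style).

    ``v_rest > v_thresh`` is explicitly permitted: it configures a
    self-firing neuron, which the maximal-output-rate benchmark relies on.
    """

    v_rest: float = -65.0
    v_thresh: float = -50.0
    v_reset: float = -65.0
    tau_m: float = 20.0
    tau_refrac: float = 0.1
    tau_syn_exc: float = 5.0
    tau_syn_inh: float = 5.0
    e_rev_exc: float = 0.0
    e_rev_inh: float = -70.0
    c_m: float = 1.0
    i_offset: float = 0.0

    def validate(self, conductance: bool = False) -> None:
        for name in ("tau_m", "tau_syn_exc", "tau_syn_inh", "c_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0 (got {getattr(self, name)})")
        if self.tau_refrac < 0:
            raise ValueError("tau_refrac must be >= 0")
        if conductance and not self.e_rev_inh < self.e_rev_exc:
            raise ValueError("conductance model requires e_rev_inh < e_rev_exc")


@dataclass
class STDPParams:
    """Additive spike-pair STDP with hard weight bounds.

    Pre-before-post (dt > 0) potentiates by ``a_plus * exp(-dt/tau_plus)``,
    post-before-pre depresses by ``a_minus * exp(dt/tau_minus)``; updates are
    clipped to ``[w_min, w_max]``.  Pairing is nearest-neighbour per synapse.
    """

    a_plus: float
    a_minus: float
    tau_plus: float
    tau_minus: float
    w_min: float
    w_max: float

    def validate(self) -> None:
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("STDP time constants must be > 0")
        if self.w_min > self.w_max:
            raise ValueError("w_min must be <= w_max")


@dataclass
class Connector:
    """Wiring pattern between two populations.

    ``kind`` is one of ``one_to_one``, ``all_to_all``, ``fixed_probability``
    (with ``p``), or ``from_list`` (with ``pairs``).  ``from_list`` pairs are
    ``(pre_index, post_index)`` or ``(pre_index, post_index, weight)``; the
    third element overrides the connection-level weight magnitude.
    """

    kind: str
    p: Optional[float] = None
    pairs: Optional[List[Tuple]] = None

    KINDS = ("one_to_one", "all_to_all", "fixed_probability", "from_list")

    def validate(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown connector kind {self.kind!r}")
        if self.kind == "fixed_probability":
            if self.p is None or not 0.0 <= self.p <= 1.0:
                raise ValueError("fixed_probability requires p in [0, 1]")
        if self.kind == "from_list" and self.pairs is None:
            raise ValueError("from_list requires pairs")

    @classmethod
    def one_to_one(cls) -> "Connector":
        return cls("one_to_one")

    @classmethod
    def all_to_all(cls) -> "Connector":
        return cls("all_to_all")

    @classmethod
    def fixed_probability(cls, p: float) -> "Connector":
        return cls("fixed_probability", p=p)

    @classmethod
    def from_list(cls, pairs: Sequence[Tuple]) -> "Connector":
        return cls("from_list", pairs=[tuple(t) for t in pairs])


@dataclass
class Population:
    """A homogeneous group of neurons or spike sources.

    For sources, ``params`` is a plain dict: ``{"rate": Hz}`` for
    ``source_poisson`` or ``{"spike_times": [...]}`` for ``source_array``
    (either one shared list of times in ms, or one list per neuron).
    ``record`` is True (all), False (none) or a list of neuron indices.
    """

    id: str
    size: int
    model: str
    params: Union[NeuronParameters, dict, None] = None
    record: Union[bool, Sequence[int]] = True

    def validate(self) -> None:
        if self.size < 1:
            raise ValueError(f"population {self.id!r}: size must be >= 1")
        if self.model in LIF_MODELS:
            if not isinstance(self.params, NeuronParameters):
                raise NetworkStructureError(
                    f"population {self.id!r}: LIF model needs NeuronParameters"
                )
            self.params.validate(conductance=self.model == "lif_conductance")
        elif self.model in SOURCE_MODELS:
            if isinstance(self.params, NeuronParameters):
                raise NetworkStructureError(
                    f"population {self.id!r}: source populations carry no "
                    "NeuronParameters"
                )
            p = self.params or {}
            if self.model == "source_poisson":
                if p.get("rate", 0.0) < 0:
                    raise ValueError(f"population {self.id!r}: rate must be >= 0")
            else:
                if "spike_times" not in p:
                    raise NetworkStructureError(
                        f"population {self.id!r}: source_array needs spike_times"
                    )
        else:
            raise NetworkStructureError(
                f"population {self.id!r}: unknown model {self.model!r}"
            )
        if not isinstance(self.record, bool):
            idx = list(self.record)
            if any(i < 0 or i >= self.size for i in idx):
                raise ValueError(f"population {self.id!r}: recorded subset outside population")

    @property
    def is_source(self) -> bool:
        return self.model in SOURCE_MODELS

    def recorded_indices(self) -> List[int]:
        if self.record is True:
            return list(range(self.size))
        if self.record is False:
            return []
        return sorted(set(int(i) for i in self.record))


@dataclass
class Connection:
    """A projection between two populations.

    ``weight`` is a non-negative magnitude (nA for current-based targets, uS
    for conductance-based targets); ``receptor`` selects the synapse sign.
    ``delay`` must be at least one simulator step.
    """

    source: str
    target: str
    connector: Connector
    weight: float
    receptor: str = "excitatory"
    delay: float = 0.1
    plasticity: Optional[STDPParams] = None

    def validate(self) -> None:
        self.connector.validate()
        if self.weight < 0:
            raise ValueError("weights are sign-free magnitudes; use receptor for sign")
        if self.receptor not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown receptor {self.receptor!r}")
        if self.delay <= 0:
            raise ValueError("delay must be > 0")
        if self.plasticity is not None:
            self.plasticity.validate()


@dataclass
class NetworkDescription:
    """The backend-agnostic network a benchmark builds."""

    populations: List[Population] = field(default_factory=list)
    connections: List[Connection] = field(default_factory=list)

    def add(self, *items) -> "NetworkDescription":
        for item in items:
            if isinstance(item, Population):
                self.populations.append(item)
            elif isinstance(item, Connection):
                self.connections.append(item)
            else:
                raise TypeError(f"cannot add {type(item).__name__} to a network")
        return self

    def population(self, pop_id: str) -> Population:
        for p in self.populations:
            if p.id == pop_id:
                return p
        raise NetworkStructureError(f"unknown population reference {pop_id!r}")

    def validate(self) -> None:
        seen = set()
        for p in self.populations:
            if p.id in seen:
                raise NetworkStructureError(f"duplicate population id {p.id!r}")
            seen.add(p.id)
            p.validate()
        for c in self.connections:
            c.validate()
            src = self.population(c.source)
            tgt = self.population(c.target)
            if tgt.is_source:
                raise NetworkStructureError(
                    f"connection {c.source!r}->{c.target!r}: sources cannot be targets"
                )
            if c.connector.kind == "one_to_one" and src.size != tgt.size:
                raise NetworkStructureError(
                    f"one_to_one connector {c.source!r}->{c.target!r} requires "
                    f"equal sizes ({src.size} != {tgt.size})"
                )
            if c.connector.kind == "from_list":
                for pair in c.connector.pairs:
                    i, j = pair[0], pair[1]
                    if not (0 <= i < src.size and 0 <= j < tgt.size):
                        raise NetworkStructureError(
                            f"from_list pair {pair} outside populations "
                            f"{c.source!r}/{c.target!r}"
                        )

    # ------------------------------------------------------------------ JSON
    def to_json(self) -> str:
        def pop_dict(p: Population) -> dict:
            d = {"id": p.id, "size": p.size, "model": p.model}
            if isinstance(p.params, NeuronParameters):
                d["params"] = asdict(p.params)
            else:
                d["params"] = p.params
            d["record"] = p.record if isinstance(p.record, bool) else list(p.record)
            return d

        def con_dict(c: Connection) -> dict:
            d = {
                "source": c.source,
                "target": c.target,
                "connector": {"kind": c.connector.kind},
                "weight": c.weight,
                "receptor": c.receptor,
                "delay": c.delay,
            }
            if c.connector.p is not None:
                d["connector"]["p"] = c.connector.p
            if c.connector.pairs is not None:
                d["connector"]["pairs"] = [list(t) for t in c.connector.pairs]
            if c.plasticity is not None:
                d["plasticity"] = asdict(c.plasticity)
            return d

        return json.dumps(
            {
                "populations": [pop_dict(p) for p in self.populations],
                "connections": [con_dict(c) for c in self.connections],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkDescription":
        doc = json.loads(text)
        net = cls()
        for pd in doc["populations"]:
            params = pd.get("params")
            if pd["model"] in LIF_MODELS and params is not None:
                params = NeuronParameters(**params)
            record = pd.get("record", True)
            if not isinstance(record, bool):
                record = list(record)
            net.populations.append(
                Population(pd["id"], pd["size"], pd["model"], params, record)
            )
        for cd in doc["connections"]:
            con = cd["connector"]
            pairs = con.get("pairs")
            connector = Connector(
                con["kind"],
                p=con.get("p"),
                pairs=[tuple(t) for t in pairs] if pairs is not None else None,
            )
            plast = cd.get("plasticity")
            net.connections.append(
                Connection(
                    cd["source"],
                    cd["target"],
                    connector,
                    cd["weight"],
                    cd.get("receptor", "excitatory"),
                    cd.get("delay", 0.1),
                    STDPParams(**plast) if plast else None,
                )
            )
        net.validate()
        return net

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "NetworkDescription":
        with open(path) as fh:
            return cls.from_json(fh.read())
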