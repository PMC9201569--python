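"""Benchmark configuration: JSON files with per-backend sections.

A configuration file maps benchmark names to sections, one per backend plus
a ``default`` fallback::

    {
      "sudoku": {
        "default":  {"pop_size": 4, "duration": 2000.0},
        "refsim":   {"noise_rate": 150.0},
        "spikey-like": {"pop_size": 2}
      }
    }

The effective configuration merges ``default`` < backend section < explicit
overrides (associative, later layers win key-by-key).  Unknown keys are
rejected against the benchmark's declared schema so that typos fail loudly.

Benchmark sizes use a small index instead of raw neuron counts; the four
categories are single core (0), single chip (1), small scale (2) and large
scale (3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional

__all__ = [
    "SIZE_CATEGORIES",
    "BenchmarkConfig",
    "merge_config",
    "load_config_file",
    "default_config",
]

SIZE_CATEGORIES = ("single core", "single chip", "small scale", "large scale")


@dataclass
class BenchmarkConfig:
    """Fully resolved configuration of one benchmark invocation."""

    benchmark: str
    backend: str = "refsim"
    index: int = 0
    seed: int = 1
    params: Dict[str, object] = field(default_factory=dict)

    def validate(self, allowed_keys: Optional[List[str]] = None) -> None:
        if not 0 <= self.index <= 3:
            raise ValueError(
                f"size index {self.index} outside 0..3 "
                f"(categories: {', '.join(SIZE_CATEGORIES)})"
            )
        if allowed_keys is not None:
            unknown = sorted(set(self.params) - set(allowed_keys))
            if unknown:
                raise ValueError(
                    f"unknown configuration keys for {self.benchmark!r}: "
                    f"{unknown}; allowed: {sorted(allowed_keys)}"
                )


def merge_config(*layers: Optional[Dict[str, object]]) -> Dict[str, object]:
    """Key-wise merge; later layers override earlier ones (associative)."""
    out: Dict[str, object] = {}
    for layer in layers:
        if layer:
            out.update(layer)
    return out


def load_config_file(path) -> Dict[str, Dict[str, dict]]:
    with open(path) as fh:
        return json.load(fh)


def default_config() -> Dict[str, Dict[str, dict]]:
    """The shipped benchmark defaults (spikebench/data/benchmark_defaults.json)."""
    text = resources.files("spikebench.data").joinpath(
        "benchmark_defaults.json"
    ).read_text()
    return json.loads(text)


def resolve(
    doc: Dict[str, Dict[str, dict]],
    benchmark: str,
    backend: str,
    overrides: Optional[Dict[str, object]] = None,
) -> Dict[str, object]:
    """Effective parameters: default section < backend section < overrides."""
    section = doc.get(benchmark, {})
    return merge_config(section.get("default"), section.get(backend), overrides)
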