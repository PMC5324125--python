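"""Shipped scenario and probe presets.

Scenario configurations (``awake``, ``anaesthetised``,
``hippocampus_multilayer``) are YAML files bundled with the package; probe
geometries are JSON site maps.  ``scenario()`` returns a plain dict that
``compose.run_scenario`` resolves, optionally deep-merged with user
overrides.
"""

from __future__ import annotations

import copy
import json
from importlib import resources

import numpy as np
import yaml

from .errors import ConfigurationError
from .tissue import ProbeGeometry

_SCENARIOS = "data/scenarios"
_PROBES = "data/probes"


def _pkg_file(rel: str):
    return resources.files(__package__).joinpath(rel)


def list_scenarios() -> list[str]:
    return sorted(
        p.name[: -len(".yaml")]
        for p in _pkg_file(_SCENARIOS).iterdir()
        if p.name.endswith(".yaml")
    )


def scenario(name: str) -> dict:
    """Load a shipped scenario configuration by name."""
    path = _pkg_file(f"{_SCENARIOS}/{name}.yaml")
    if not path.is_file():
        raise ConfigurationError(
            f"unknown scenario {name!r}; available: {', '.join(list_scenarios())}"
        )
    return yaml.safe_load(path.read_text())


def probe_preset(name: str) -> ProbeGeometry:
    """Load a shipped probe geometry by name."""
    path = _pkg_file(f"{_PROBES}/{name}.json")
    if not path.is_file():
        raise ConfigurationError(f"unknown probe preset file {name!r}")
    d = json.loads(path.read_text())
    return ProbeGeometry(
        np.asarray(d["sites"], float), d.get("site_diameter_um", 13.0), d.get("name", name)
    )


def deep_merge(base: dict, override: dict | None) -> dict:
    """Recursively merge ``override`` into a copy of ``base``."""
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out
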