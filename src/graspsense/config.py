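"""Loading and representation of simulation configurations.

A configuration YAML has sections ``motor``, ``gains``, ``object`` (name of
the active object for single-closure runs), ``objects`` (catalog),
``reference`` (per-kind profile defaults) and ``sim``.  The packaged
``hannes_like.yaml`` is the default synthetic parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict

import yaml

from .errors import ConfigurationMissing
from .simulator import ControllerGains, MotorParams, ObjectModel, ReferenceProfile


@dataclass
class SimConfig:
    motor: MotorParams = field(default_factory=MotorParams)
    gains: ControllerGains = field(default_factory=ControllerGains)
    objects: Dict[str, ObjectModel] = field(default_factory=dict)
    references: Dict[str, ReferenceProfile] = field(default_factory=dict)
    active_object: str = "void"
    duration: float = 4.0
    sample_rate: float = 1000.0
    amplitude_jitter_sd: float = 3.0
    seed: int = 0

    def object(self, name: str | None = None) -> ObjectModel:
        name = name or self.active_object
        try:
            return self.objects[name]
        except KeyError:
            raise ConfigurationMissing(
                f"object {name!r} not in configuration catalog "
                f"(available: {sorted(self.objects)})"
            ) from None

    def reference(self, kind: str) -> ReferenceProfile:
        # accept the protocol's 'emg' shorthand
        kind = {"emg": "emg_like"}.get(kind, kind)
        if kind in self.references:
            return self.references[kind]
        return ReferenceProfile(kind=kind)

    def objects_of_class(self, stiffness: str) -> list[str]:
        return sorted(
            name
            for name, obj in self.objects.items()
            if obj.stiffness_class.value == stiffness
        )


def _config_from_dict(raw: dict) -> SimConfig:
    objects = {
        name: ObjectModel(name=name, **spec)
        for name, spec in raw.get("objects", {}).items()
    }
    references = {
        kind: ReferenceProfile(**spec)
        for kind, spec in raw.get("reference", {}).items()
    }
    sim = raw.get("sim", {})
    gains_spec = dict(raw.get("gains", {}))
    sample_rate = float(sim.get("sample_rate", gains_spec.get("sample_rate", 1000.0)))
    gains_spec["sample_rate"] = sample_rate
    return SimConfig(
        motor=MotorParams(**raw.get("motor", {})),
        gains=ControllerGains(**gains_spec),
        objects=objects,
        references=references,
        active_object=raw.get("object", "void"),
        duration=float(sim.get("duration", 4.0)),
        sample_rate=sample_rate,
        amplitude_jitter_sd=float(sim.get("amplitude_jitter_sd", 3.0)),
        seed=int(sim.get("seed", 0)),
    )


def load_config(path) -> SimConfig:
    """Read a simulation configuration from a YAML file."""
    with open(path) as fh:
        return _config_from_dict(yaml.safe_load(fh))


def default_config() -> SimConfig:
    """The packaged synthetic 'hannes_like' parameter set."""
    text = resources.files("graspsense.configs").joinpath("hannes_like.yaml").read_text()
    return _config_from_dict(yaml.safe_load(text))


def default_protocol_path():
    """Path-like handle to the packaged acquisition protocol YAML."""
    return resources.files("graspsense.configs").joinpath("table2.yaml")
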