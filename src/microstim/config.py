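"""Structured configuration files (YAML) for studies and the CLI.

A study file is flat key/value plus lists, e.g.::

    fiber_diameter: 10.0
    cathodic_width: 200.0      # µs
    resistivities: {rho_x: 1211.0, rho_y: 1211.0, rho_z: 175.0}
    electrodes:
      - [0.0, 0.0, 0.0]
      - [0.0, 0.0, 400.0]      # µm
    search: {accuracy: 0.1, amplitude_min: 0.0, amplitude_max: 30.0}
    solver: {dt: 5.0, post_stimulus_time: 400.0, temperature: 36.0}
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .cable import SimulationConfig
from .fields import Electrode, Resistivities, StimulusWaveform
from .thresholds import SearchSettings

__all__ = ["StudyConfig", "load_config"]


@dataclass
class StudyConfig:
    fiber_diameter: float
    waveform: StimulusWaveform
    rho: Resistivities
    electrodes: list[Electrode]
    settings: SearchSettings
    solver: SimulationConfig


def load_config(path) -> StudyConfig:
    raw = yaml.safe_load(Path(path).read_text())
    rho = Resistivities(**raw.get("resistivities", {}))
    wf = StimulusWaveform(cathodic_amplitude=1.0,
                          cathodic_width=float(raw.get("cathodic_width", 200.0)))
    electrodes = [Electrode(tuple(e)) for e in raw.get("electrodes", [[0.0, 0.0, 0.0]])]
    settings = SearchSettings(**raw.get("search", {}))
    solver = SimulationConfig(**raw.get("solver", {}))
    return StudyConfig(fiber_diameter=float(raw.get("fiber_diameter", 10.0)),
                       waveform=wf, rho=rho, electrodes=electrodes,
                       settings=settings, solver=solver)
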