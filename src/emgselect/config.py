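"""Experiment configuration: one YAML file describes one reproducible run.

Every random stream in a run (simulation, rest undersampling, classifier
initialisation and batch order) fans out from the single root ``seed``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .paradigms import SelectionConfig
from .simulate import SimulationConfig

__all__ = ["ExperimentConfig"]


@dataclass
class ExperimentConfig:
    """Fully describes one protocol run; round-trips through YAML."""

    source: str = "simulated"  # "simulated" | path to a directory of .mat sessions
    paradigm: str = "enn"
    classifier: str = "lda"
    mode: str = "retrain"
    vote: bool = False
    seed: int = 0
    output_dir: str = "results"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["simulation"]["band_hz"] = list(d["simulation"]["band_hz"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        sim = d.pop("simulation", {})
        if "band_hz" in sim:
            sim["band_hz"] = tuple(sim["band_hz"])
        sel = d.pop("selection", {})
        return cls(simulation=SimulationConfig(**sim),
                   selection=SelectionConfig(**sel), **d)
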