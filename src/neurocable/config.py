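"""Run-time configuration: library search path, run directory, time step."""

from __future__ import annotations

import importlib.resources
import os
from dataclasses import dataclass, field

import yaml

from .solver import DEFAULT_DT


def shipped_library_dir() -> str:
    """Directory of the model library installed with the package
    (``channels/``, ``cells/``)."""
    return str(importlib.resources.files("neurocable") / "library")


@dataclass
class Config:
    #: ordered library search path; first match wins
    library_paths: list[str] = field(
        default_factory=lambda: [".", shipped_library_dir()])
    #: directory where output files and relative event files live
    run_dir: str = "."
    #: fixed integration step, s
    dt: float = DEFAULT_DT
    #: default output file name inside run_dir
    output_name: str = "output"

    @property
    def output_path(self) -> str:
        if os.path.isabs(self.output_name):
            return self.output_name
        return os.path.join(self.run_dir, self.output_name)

    @classmethod
    def load(cls, filename: str) -> "Config":
        with open(filename) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls()
        if "library_paths" in data:
            cfg.library_paths = [str(p) for p in data["library_paths"]]
        if "run_dir" in data:
            cfg.run_dir = str(data["run_dir"])
        if "dt" in data:
            cfg.dt = float(data["dt"])
        if "output_name" in data:
            cfg.output_name = str(data["output_name"])
        return cfg
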