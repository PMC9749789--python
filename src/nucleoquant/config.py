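"""Run configuration: temperature, segmentation parameters, seeds.

A single :class:`RunConfig` travels through the CLI so that every stage of
a run shares one temperature, one seed and one set of segmentation
defaults, and so that outputs can record the configuration that produced
them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from nucleoquant.constants import T_CELL


@dataclass
class RunConfig:
    """Shared analysis parameters.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin, used both for the RT factor of
        transfer free energies and the kBT factor of surface tension.
        Default 310.15 K (cells at 37 C).
    energy_units : str
        ``"per-mole"`` reports transfer energies in kJ/mol;
        ``"per-molecule"`` reports them in units of kBT.
    nucleus_min_area : float
        Smallest nucleus kept by segmentation, in square micrometres.
    nucleolus_min_area : float
        Smallest nucleolus kept, in square micrometres.
    smoothing_sigma : float
        Gaussian pre-smoothing for nucleus segmentation, in pixels.
    erosion_px : int
        Margin eroded from the nucleus boundary, and dilated around each
        nucleolus, before measuring nucleoplasmic (dilute-phase) intensity.
    exclude_modes : tuple of int
        Angular Fourier modes zeroed by the flicker estimator; mode 0 is
        area/segmentation drift, mode 1 residual translation.
    seed : int
        Seed for every stochastic operation in a run.
    output_dir : str
        Where CLI subcommands write their results.
    """

    temperature: float = T_CELL
    energy_units: str = "per-mole"
    nucleus_min_area: float = 50.0
    nucleolus_min_area: float = 0.2
    smoothing_sigma: float = 2.0
    erosion_px: int = 2
    exclude_modes: tuple = (0, 1)
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if self.energy_units not in ("per-mole", "per-molecule"):
            raise ValueError(f"unknown energy_units {self.energy_units!r}")
        self.exclude_modes = tuple(int(q) for q in self.exclude_modes)
        self.seed = int(self.seed)

    def config_hash(self) -> str:
        """Short stable hash of all parameters, recorded in outputs."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from YAML or JSON; unknown keys are rejected."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path) -> None:
        path = Path(path)
        data = dataclasses.asdict(self)
        data["exclude_modes"] = list(data["exclude_modes"])
        path.write_text(yaml.safe_dump(data, sort_keys=True))
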