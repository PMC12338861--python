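"""Run configuration shared by the CLI subcommands."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field, field_validator

from .anisotropy import DEFAULT_WAVELENGTHS
from .thermal import GRID_TEMPERATURES


class RunConfig(BaseModel):
    """End-to-end analysis settings; all values serialize to JSON."""

    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS
    window_c: float = Field(default=2.0, gt=0)
    bandwidth_c: float = Field(default=12.0, gt=0)
    weighting: Literal["ivar", "none"] = "ivar"
    r_o_mode: Literal["interpolate", "fixed"] = "interpolate"
    photophysics_path: str | None = None
    grid_temperatures: tuple[float, ...] = GRID_TEMPERATURES
    out_dir: str = "."
    seed: int = 0
    verbosity: int = 1

    @field_validator("wavelengths")
    @classmethod
    def _wavelengths_nonempty(cls, v):
        if len(v) == 0:
            raise ValueError("wavelength set must be nonempty")
        return v

    @field_validator("grid_temperatures")
    @classmethod
    def _grid_increasing(cls, v):
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("grid temperatures must be strictly increasing")
        return v

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def to_json(self, path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))
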