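"""Run configuration: one JSON document binding sensor, DAC and analog
parameters plus per-command blocks, with a single master seed.

Load -> dump -> load is the identity, and every source of randomness in a run
is derived from ``seed`` through named substreams, so a config file plus a
seed pins a run exactly.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict

from .cdc import AnalogParams
from .dac import DacConfig
from .sensor import SensorConfig

__all__ = ["SweepBlock", "AssayBlock", "NoiseBlock", "RunConfig", "load_config", "substream_seed"]


class SweepBlock(BaseModel):
    model_config = ConfigDict(frozen=True)
    c_min_fF: float = 0.0
    c_max_fF: float = 16137.0
    step_fF: float = 4.5


class AssayBlock(BaseModel):
    model_config = ConfigDict(frozen=True)
    concentrations_mgL: tuple[float, ...] = (10.0, 5.0, 2.5, 1.25)
    n_reps: int = 3
    replicate_noise_sigma_fF: float = 0.0


class NoiseBlock(BaseModel):
    model_config = ConfigDict(frozen=True)
    points_fF: tuple[float, ...] = tuple(float(c) for c in np.linspace(100.0, 16000.0, 20))
    n_reps: int = 100


class RunConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    sensor: SensorConfig = SensorConfig()
    dac: DacConfig = DacConfig()
    analog: AnalogParams = AnalogParams()
    sweep: SweepBlock = SweepBlock()
    assay: AssayBlock = AssayBlock()
    noise: NoiseBlock = NoiseBlock()
    seed: int = 0
    outdir: str = "."

    def dump_json(self) -> str:
        return self.model_dump_json(indent=2)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a JSON run config, applying dotted-path overrides on top."""
    data: dict = {}
    if path is not None:
        data = json.loads(Path(path).read_text())
    for dotted, value in (overrides or {}).items():
        _set_dotted(data, dotted, value)
    return RunConfig.model_validate(data)


def _set_dotted(tree: dict, dotted: str, value) -> None:
    keys = dotted.split(".")
    node = tree
    for k in keys[:-1]:
        node = node.setdefault(k, {})
        if not isinstance(node, dict):
            raise ValueError(f"override path {dotted!r} conflicts with a scalar")
    node[keys[-1]] = value


def substream_seed(master_seed: int, name: str) -> int:
    """Stable per-command substream seed derived from the master seed."""
    ss = np.random.SeedSequence([master_seed, zlib.crc32(name.encode()) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))
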