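"""Run configuration loading and validation."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Configuration of a serial-dilution run.

    ``inoculation`` is either "equal" (equal biomass per species, total 1/9)
    or a mapping species_id -> biomass.
    """

    seed: int = 0
    n_cycles: int = 10_000
    mortality_factor: float = 10.0
    extinction_threshold: float = 1e-12
    inoculation: str | dict = "equal"
    record: str = "window"
    record_last: int = 2000
    tau_window: float = 0.2

    def __post_init__(self) -> None:
        if self.mortality_factor <= 1.0:
            raise ValueError("mortality_factor must exceed 1")
        if not 0.0 < self.extinction_threshold < 1.0:
            raise ValueError("extinction_threshold must lie in (0, 1)")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = asdict(config)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=1))
    else:
        path.write_text(yaml.safe_dump(data))
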