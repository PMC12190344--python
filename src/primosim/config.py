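"""YAML configuration loading with CLI-over-file-over-defaults precedence."""
from __future__ import annotations

from pathlib import Path

import yaml

from .runner import RunConfig

_SECTIONS = ("abm", "cpm", "metrics")


def load_config(path: str | Path | None = None, **cli_overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus CLI overrides.

    Precedence: CLI flag > config file > built-in default.  Section dicts
    (``abm:``, ``cpm:``, ``metrics:``) merge key-wise.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(loaded)
    for key, value in cli_overrides.items():
        if value is None:
            continue
        if key in _SECTIONS:
            data.setdefault(key, {}).update(value)
        else:
            data[key] = value
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg
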