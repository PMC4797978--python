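"""Plain-text ``config.txt`` parsing for a cross-docking run.

The dialect is ``key = value`` lines with ``#`` comments, matching the
engine config files users already write by hand.  Unknown keys are rejected
with a listing rather than silently ignored — a typo in ``exhaustivness``
must not quietly run a default search.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

__all__ = ["RunConfig", "ConfigError", "parse_config", "serialize_config"]


class ConfigError(ValueError):
    """Malformed or incomplete run configuration."""


@dataclass
class RunConfig:
    """Everything a run needs; defaults reproduce the standard protocol
    (exhaustiveness 8, success threshold 2.0 angstrom, self-docks included
    in column averages)."""

    receptor_dir: str
    ligand_dir: str
    output_dir: str = "crossdock_output"
    size_x: float = 22.0
    size_y: float = 22.0
    size_z: float = 22.0
    num_modes: int = 9
    exhaustiveness: int = 8
    energy_range: float | None = None
    engine: str = "vina"
    engine_path: str | None = None
    seed: int | None = None
    success_threshold: float = 2.0
    include_self_in_averages: bool = True
    band_scope: str = "matrix"

    def __post_init__(self) -> None:
        for key in ("size_x", "size_y", "size_z"):
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key} must be positive, got {getattr(self, key)}")
        if self.success_threshold <= 0:
            raise ConfigError("success_threshold must be positive")
        if self.num_modes < 1 or self.exhaustiveness < 1:
            raise ConfigError("num_modes and exhaustiveness must be >= 1")
        if self.engine not in ("vina", "mock"):
            raise ConfigError(f"engine must be 'vina' or 'mock', got {self.engine!r}")
        if self.band_scope not in ("matrix", "column"):
            raise ConfigError(f"band_scope must be 'matrix' or 'column'")

    @property
    def box_size(self) -> tuple[float, float, float]:
        return (self.size_x, self.size_y, self.size_z)


_BOOL = {"true": True, "yes": True, "1": True,
         "false": False, "no": False, "0": False}


def _convert(key: str, raw: str, typ):
    raw = raw.strip()
    try:
        if typ is bool:
            if raw.lower() not in _BOOL:
                raise ValueError(raw)
            return _BOOL[raw.lower()]
        if raw.lower() in ("none", ""):
            return None
        return typ(raw)
    except ValueError as exc:
        raise ConfigError(f"malformed value for key {key!r}: {raw!r}") from exc


_FIELD_TYPES = {
    "receptor_dir": str, "ligand_dir": str, "output_dir": str,
    "size_x": float, "size_y": float, "size_z": float,
    "num_modes": int, "exhaustiveness": int, "energy_range": float,
    "engine": str, "engine_path": str, "seed": int,
    "success_threshold": float, "include_self_in_averages": bool,
    "band_scope": str,
}


def parse_config(path: str | Path) -> RunConfig:
    """Parse a ``key = value`` config file into a validated RunConfig."""
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"config file not found: {path}")
    values: dict[str, object] = {}
    unknown: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, raw = (s.strip() for s in line.split("=", 1))
        if key not in _FIELD_TYPES:
            unknown.append(key)
            continue
        values[key] = _convert(key, raw, _FIELD_TYPES[key])
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for mandatory in ("receptor_dir", "ligand_dir"):
        if values.get(mandatory) in (None, ""):
            raise ConfigError(f"mandatory key {mandatory!r} missing")
    return RunConfig(**values)  # type: ignore[arg-type]


def serialize_config(config: RunConfig) -> str:
    """Round-trippable text form: parse(serialize(c)) == c."""
    lines = []
    for f in fields(config):
        value = getattr(config, f.name)
        lines.append(f"{f.name} = {'' if value is None else value}")
    return "\n".join(lines) + "\n"
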