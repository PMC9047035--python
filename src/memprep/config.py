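"""Pipeline configuration.

Every constant of the preparation rules is collected here and can be
overridden from a flat key = value config file (one assignment per line,
``#`` comments; ranges as ``A-B``).
"""
from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional

from .errors import ContractError

Range = tuple[int, int]


@dataclass
class PipelineConfig:
    # confidence trimming
    plddt_threshold: float = 70.0
    min_confident_run: int = 3
    # long-sequence fragment windows
    window_length: int = 1400
    window_step: int = 200
    # TM detection
    tm_window: int = 21
    tm_score_threshold: float = -8.0
    tm_min_helix_fraction: float = 0.6
    tm_max_length: int = 35
    idealize_helicity_threshold: float = 0.8
    scale_path: Optional[str] = None
    # membrane positioning
    d_min: float = 10.0
    d_max: float = 20.0
    grid_angle_step: float = 10.0
    grid_offset_step: float = 1.0
    grid_d_step: float = 1.0
    # reassembly
    clearance: float = 3.0
    max_gap: float = 12.0
    # topology / signal annotation
    topology: str = "N_out"
    signal_range: Optional[Range] = None
    # validation
    min_reference_residues: int = 45
    # output
    dum_spacing: float = 10.0

    def __post_init__(self) -> None:
        if not 0 <= self.plddt_threshold <= 100:
            raise ContractError("plddt_threshold must be in [0, 100]")
        if self.window_step <= 0 or self.window_length <= 0:
            raise ContractError("window length and step must be positive")
        if not 5 <= self.d_min <= self.d_max <= 30:
            raise ContractError("implausible half-thickness bounds")
        if self.topology not in ("N_out", "N_in"):
            raise ContractError("topology must be N_out or N_in")


def _parse_value(name: str, raw: str):
    raw = raw.strip().strip('"').strip("'")
    if raw.lower() in ("none", ""):
        return None
    if name == "signal_range" or ("-" in raw and name.endswith("_range")):
        a, b = raw.split("-")
        return (int(a), int(b))
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    return raw


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat key = value file into a PipelineConfig."""
    known = {f.name for f in fields(PipelineConfig)}
    overrides = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ContractError(f"{path}:{lineno}: expected key = value")
        key, raw = (s.strip() for s in line.split("=", 1))
        if key not in known:
            raise ContractError(f"{path}:{lineno}: unknown key {key!r}")
        overrides[key] = _parse_value(key, raw)
    return PipelineConfig(**overrides)


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    lines = []
    for f in fields(PipelineConfig):
        v = getattr(config, f.name)
        if isinstance(v, tuple):
            v = f"{v[0]}-{v[1]}"
        lines.append(f"{f.name} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")
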