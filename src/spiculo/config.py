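"""Run configuration: a flat key/value schema with validated defaults.

The defaults are the study conditions of the phantom experiment: an l=10,
m=5 harmonic of amplitude 10, a d sweep of 11..92 in steps of 3, a 50 mm
base, CT-like spacings of 0.68 x 0.68 x {0.6, 2} mm, isovalue 0.9,
target edge 2 mm, smoothing quantity 5, a 1 mm isotropic resampling grid
and volume fractions 25..150 %.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

__all__ = ["RunConfig", "load_config", "save_config"]


def _floats(text: str) -> tuple[float, ...]:
    return tuple(float(x) for x in text.replace(",", " ").split())


@dataclass
class RunConfig:
    d_start: float = 11.0
    d_stop: float = 92.0
    d_step: float = 3.0
    degree_l: int = 10
    order_m: int = 5
    amplitude_A: float = 10.0
    base_mm: float = 50.0
    n_theta: int = 128
    n_phi: int = 256
    spacings: tuple = ((0.68, 0.68, 0.6), (0.68, 0.68, 2.0))
    methods: tuple = ("M1", "M2", "M3")
    isovalue: float = 0.9
    target_edge: float = 2.0
    smooth_quantity: float = 5.0
    smooth_iterations: int = 1
    resample_grid: tuple = (1.0, 1.0, 1.0)
    volume_fractions: tuple = (0.25, 0.5, 0.75, 1.0, 1.25, 1.5)
    volume_models: tuple = (11.0, 47.0, 92.0)
    out_dir: str = "spiculo_report"
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        if not 0 <= self.order_m <= self.degree_l:
            raise ValueError("require 0 <= order_m <= degree_l")
        if self.d_start <= self.amplitude_A:
            raise ValueError("d_start must exceed amplitude_A")
        if self.d_step <= 0 or self.d_stop < self.d_start:
            raise ValueError("invalid d sweep")
        if not 0 < self.isovalue < 1:
            raise ValueError("isovalue must lie in (0, 1)")
        if self.base_mm <= 0 or self.target_edge <= 0:
            raise ValueError("base_mm and target_edge must be positive")
        if self.smooth_quantity < 0 or self.smooth_iterations < 0:
            raise ValueError("smoothing parameters must be non-negative")
        if self.n_theta < 32 or self.n_phi < 64:
            raise ValueError("n_theta >= 32 and n_phi >= 64 required")
        for sp in list(self.spacings) + [self.resample_grid]:
            if len(sp) != 3 or any(s <= 0 for s in sp):
                raise ValueError(f"spacing must be 3 positive numbers, got {sp}")
        for m in self.methods:
            if m.upper() not in ("M1", "M2", "M3", "M4"):
                raise ValueError(f"unknown meshing method {m!r}")
        if any(f <= 0 for f in self.volume_fractions):
            raise ValueError("volume fractions must be positive")
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ValueError(f"unknown log level {self.log_level!r}")
        return self

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_PARSERS = {
    "d_start": float, "d_stop": float, "d_step": float,
    "degree_l": int, "order_m": int, "amplitude_A": float,
    "base_mm": float, "n_theta": int, "n_phi": int,
    "spacings": lambda s: tuple(_floats(g) for g in s.split(";") if g.strip()),
    "methods": lambda s: tuple(x.strip().upper() for x in s.split(",") if x.strip()),
    "isovalue": float, "target_edge": float,
    "smooth_quantity": float, "smooth_iterations": int,
    "resample_grid": _floats,
    "volume_fractions": _floats,
    "volume_models": _floats,
    "out_dir": str, "log_level": str,
}


def _format_value(key: str, value) -> str:
    if key == "spacings":
        return "; ".join(" ".join(repr(float(x)) for x in sp) for sp in value)
    if key == "methods":
        return ", ".join(value)
    if isinstance(value, tuple):
        return " ".join(repr(float(x)) for x in value)
    return repr(value) if isinstance(value, float) else str(value)


def load_config(path) -> RunConfig:
    """Parse a flat ``key = value`` document; blank lines and ``#`` comments
    are ignored, unknown keys are an error listing the valid schema."""
    kwargs = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in _PARSERS:
            valid = ", ".join(sorted(_PARSERS))
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}; valid keys: {valid}")
        kwargs[key] = _PARSERS[key](value.strip())
    return RunConfig(**kwargs).validate()


def save_config(config: RunConfig, path) -> None:
    lines = [
        f"{f.name} = {_format_value(f.name, getattr(config, f.name))}"
        for f in fields(config)
    ]
    Path(path).write_text("\n".join(lines) + "\n")
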