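"""Run configuration: parsing, validation, defaults, round-tripping."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .lattice import LatticeSpec

__all__ = ["RunConfig", "ConfigError", "load_config"]

EXPERIMENTS = ("impulse", "attenuation", "hopf1d", "dispersion")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated experiment configuration with all defaults made explicit.

    Not every field is consumed by every experiment; the dispatcher uses
    what it needs.  ``t_final=None`` means "derive the horizon from the
    lattice geometry" (see perturbation.default_horizon).
    """

    experiment: str = "attenuation"
    n: int = 64
    g: float = 1.0
    bc: str = "periodic"
    dt: float | None = None  # default 0.01/g, resolved at run time
    seed: int = 0
    eta: float = 0.0
    eta_grid: list[float] = field(default_factory=lambda: [0.0, 0.05, 0.1, 0.2, 0.4])
    realizations: int = 8
    t_final: float | None = None
    burn_in: float | None = None  # default 50/g
    save_stride: int = 10
    window_frac: float = 1.0 / 3.0
    f_grid: list[float] = field(default_factory=lambda: [0.5, 1.0, 2.0, 4.0, 8.0])
    omega0: float = 1.0
    out: str = "critwave-out"
    plot: bool = False

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ConfigError(
                f"unknown experiment {self.experiment!r}; choose from {EXPERIMENTS}"
            )
        try:
            self.lattice_spec()
        except ValueError as err:
            raise ConfigError(str(err)) from err
        if self.eta < 0:
            raise ConfigError(f"eta must be >= 0, got {self.eta}")
        if any(e < 0 for e in self.eta_grid):
            raise ConfigError("eta_grid values must be >= 0")
        if self.eta_grid != sorted(self.eta_grid):
            raise ConfigError("eta_grid must be sorted ascending")
        if self.realizations < 1:
            raise ConfigError(f"realizations must be >= 1, got {self.realizations}")
        if self.save_stride < 1:
            raise ConfigError(f"save_stride must be >= 1, got {self.save_stride}")
        if not (0 < self.window_frac <= 1):
            raise ConfigError(f"window_frac must be in (0, 1], got {self.window_frac}")

    def lattice_spec(self) -> LatticeSpec:
        return LatticeSpec(n=self.n, g=self.g, bc=self.bc)

    @property
    def dt_resolved(self) -> float:
        return self.dt if self.dt is not None else 0.01 / self.g

    def to_dict(self) -> dict:
        return asdict(self)

    def serialize(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def hash(self) -> str:
        """Content hash, stable under key reordering (canonical JSON)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config, apply overrides, validate, fill defaults.

    Unknown keys are an error (no silent typos); invalid values raise a
    :class:`ConfigError` naming the field.
    """
    raw: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        loaded = yaml.safe_load(p.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config must be a mapping, got {type(loaded).__name__}")
        raw.update(loaded)
    if overrides:
        raw.update(overrides)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except ConfigError:
        raise
    except (TypeError, ValueError) as err:
        raise ConfigError(str(err)) from err


def parse_override(text: str):
    """Parse a ``key=value`` override; values go through YAML scalar rules."""
    if "=" not in text:
        raise ConfigError(f"override must look like key=value, got {text!r}")
    key, _, value = text.partition("=")
    return key.strip(), yaml.safe_load(value.strip())
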