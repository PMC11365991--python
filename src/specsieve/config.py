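"""Run configuration: defaults, parsing and cross-field validation.

Defaults reproduce the reference study conditions: wavenumber grid
650–3999.5 cm⁻¹ at step 0.5, J=100 membrane and L=10 clean training spectra
per class, K=50 atoms, λ=1.0, SNR levels 0/−10/−20/−30 dB and 100 test
mixtures per class per level.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["GridSpec", "RunConfig", "validate_config", "ConfigError"]


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


@dataclass(frozen=True)
class GridSpec:
    start: float = 650.0
    stop: float = 3999.5
    step: float = 0.5

    @property
    def n_points(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    def build(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.n_points)


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable pipeline configuration."""

    grid: GridSpec = field(default_factory=GridSpec)
    # synthesis
    models_file: str | None = None  # band models; None → built-in toy library
    seed_replicates: int = 24
    J: int = 100
    L: int = 10
    n_per_class: int = 100
    snr_levels: tuple[float, ...] = (0.0, -10.0, -20.0, -30.0)
    # dictionary
    K: int = 50
    lam: float = 1.0
    budget: int = 10
    n_iter: int = 50
    coder: str = "omp"
    # classification
    references_per_class: int = 10
    # reproducibility
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["snr_levels"] = list(self.snr_levels)
        return d

    def stage_seed(self, offset: int) -> int:
        """Deterministic per-stage seed fan-out from the global seed."""
        return int((self.seed * 9973 + offset) % (2**31 - 1))


_KNOWN_KEYS = {
    "grid",
    "models_file",
    "seed_replicates",
    "J",
    "L",
    "n_per_class",
    "snr_levels",
    "K",
    "lam",
    "budget",
    "n_iter",
    "coder",
    "references_per_class",
    "seed",
}
_GRID_KEYS = {"start", "stop", "step"}


def validate_config(raw: str | dict | Path | None) -> RunConfig:
    """Parse YAML/JSON text (or a dict / file path) into a validated RunConfig.

    Unknown keys, type errors and cross-field violations are aggregated into
    one ConfigError. An empty document yields all defaults.
    """
    if raw is None:
        data: dict = {}
    elif isinstance(raw, dict):
        data = dict(raw)
    else:
        if isinstance(raw, Path) or (
            isinstance(raw, str) and "\n" not in raw and Path(raw).is_file()
        ):
            raw = Path(raw).read_text()
        try:
            data = yaml.safe_load(raw) or {}
        except yaml.YAMLError as exc:
            raise ConfigError([f"unparseable document: {exc}"]) from exc
        if not isinstance(data, dict):
            raise ConfigError(["top level must be a mapping"])

    problems: list[str] = []
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        problems.append(f"unknown keys: {sorted(unknown)}")

    grid_data = data.pop("grid", {}) if isinstance(data.get("grid"), dict) else (
        data.pop("grid", {}) or {}
    )
    if not isinstance(grid_data, dict):
        problems.append("grid must be a mapping of start/stop/step")
        grid_data = {}
    bad_grid = set(grid_data) - _GRID_KEYS
    if bad_grid:
        problems.append(f"unknown grid keys: {sorted(bad_grid)}")
    try:
        grid = GridSpec(**{k: float(v) for k, v in grid_data.items() if k in _GRID_KEYS})
    except (TypeError, ValueError) as exc:
        problems.append(f"grid: {exc}")
        grid = GridSpec()
    if grid.step <= 0:
        problems.append("grid.step must be > 0")
    elif grid.stop <= grid.start:
        problems.append("grid.stop must exceed grid.start")

    defaults = RunConfig()
    values: dict = {"grid": grid}
    int_fields = {
        "seed_replicates",
        "J",
        "L",
        "n_per_class",
        "K",
        "budget",
        "n_iter",
        "references_per_class",
        "seed",
    }
    for name in _KNOWN_KEYS - {"grid"}:
        if name not in data:
            continue
        value = data[name]
        try:
            if name in int_fields:
                if isinstance(value, float) and not value.is_integer():
                    raise TypeError(f"{value!r} is not an integer")
                values[name] = int(value)
            elif name == "lam":
                values[name] = float(value)
            elif name == "snr_levels":
                levels = tuple(float(v) for v in value)
                if not levels:
                    raise TypeError("must be non-empty")
                if not all(np.isfinite(levels)):
                    raise TypeError("levels must be finite")
                values[name] = levels
            elif name == "coder":
                if value not in {"omp", "lasso"}:
                    raise TypeError(f"{value!r} is not one of omp/lasso")
                values[name] = str(value)
            else:  # models_file
                values[name] = None if value is None else str(value)
        except (TypeError, ValueError) as exc:
            problems.append(f"{name}: {exc}")

    cfg = RunConfig(**{**{k: getattr(defaults, k) for k in defaults.__dataclass_fields__}, **values})

    # cross-field checks
    if grid.step > 0 and grid.stop > grid.start:
        if cfg.K >= grid.n_points:
            problems.append(
                f"K={cfg.K} must be smaller than the grid length N={grid.n_points} "
                "(undercomplete dictionary)"
            )
    for name in ("J", "L", "n_per_class", "K", "budget", "n_iter",
                 "references_per_class", "seed_replicates"):
        if getattr(cfg, name) < 1:
            problems.append(f"{name} must be ≥ 1")
    if cfg.lam < 0:
        problems.append("lam must be ≥ 0")
    if cfg.seed < 0:
        problems.append("seed must be ≥ 0")
    if cfg.seed_replicates < 2:
        problems.append("seed_replicates must be ≥ 2 (pair mixing needs 2 seeds)")

    if problems:
        raise ConfigError(problems)
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> Path:
    """Serialize a RunConfig losslessly (YAML by default, JSON by extension)."""
    path = Path(path)
    payload = cfg.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path
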