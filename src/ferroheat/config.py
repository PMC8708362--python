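"""Run configuration: plain-text (YAML) input, validated and SI-normalized.

Quantities may be given either as bare numbers, interpreted in the field's
documented unit, or as strings with an explicit unit ("20 kA/m", "500 kHz",
"16 nm", "1e-9 s"), which are converted to SI on validation. Unknown keys
are rejected by name. Defaults reproduce the study box: the eight anchor
compositions, ε = 0.1, τ0 = 1 ns, T = 300 K, H ∈ {10..50} kA/m,
f ∈ {100, 250, 500} kHz, diameter search 1–20 nm, limit product 5×10⁹.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["RunConfig", "validate_config", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unparseable run configuration."""


# multiplier to SI for every accepted unit spelling
_UNITS = {
    "A/m": 1.0, "kA/m": 1e3,
    "Hz": 1.0, "kHz": 1e3, "MHz": 1e6,
    "m": 1.0, "nm": 1e-9, "um": 1e-6, "µm": 1e-6,
    "s": 1.0, "ms": 1e-3, "us": 1e-6, "µs": 1e-6, "ns": 1e-9,
    "K": 1.0,
    "W/g": 1.0, "W/kg": 1e-3,  # thresholds are carried on the W/g scale
    "AHz/m": 1.0, "A*Hz/m": 1.0, "A.Hz/m": 1.0,
}

_QTY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([^\s]+)\s*$")


def parse_quantity(value: Any, default_unit: str, allowed: tuple[str, ...]) -> float:
    """Convert ``value`` to SI. Bare numbers are taken in ``default_unit``."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value) * _UNITS[default_unit]
    if isinstance(value, str):
        m = _QTY_RE.match(value)
        if not m:
            raise ConfigError(f"cannot parse quantity {value!r}")
        num, unit = m.groups()
        if unit not in allowed:
            raise ConfigError(
                f"unit {unit!r} not valid here (expected one of {allowed})"
            )
        try:
            return float(num) * _UNITS[unit]
        except ValueError as exc:
            raise ConfigError(f"cannot parse number in {value!r}") from exc
    raise ConfigError(f"expected number or 'value unit' string, got {value!r}")


def _qty_list(values: Any, default_unit: str, allowed: tuple[str, ...]) -> list[float]:
    if not isinstance(values, (list, tuple)):
        values = [values]
    return [parse_quantity(v, default_unit, allowed) for v in values]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParticleConfig(_Section):
    epsilon: float = Field(default=0.1, gt=0, le=1)
    tau0_s: float = Field(default=1e-9, gt=0)


class EnvironmentConfig(_Section):
    T_K: float = Field(default=300.0, gt=0)


class FieldConfig(_Section):
    H_A_per_m: list[float] = Field(
        default_factory=lambda: [10e3, 20e3, 30e3, 40e3, 50e3]
    )
    f_Hz: list[float] = Field(default_factory=lambda: [100e3, 250e3, 500e3])

    @field_validator("H_A_per_m", "f_Hz")
    @classmethod
    def _positive(cls, v: list[float]) -> list[float]:
        if not v or any(q <= 0 for q in v):
            raise ValueError("field grids must be non-empty and positive")
        return v


class SearchConfig(_Section):
    D_min_m: float = Field(default=1e-9, gt=0)
    D_max_m: float = Field(default=20e-9, gt=0)

    @field_validator("D_max_m")
    @classmethod
    def _ordered(cls, v: float, info) -> float:
        if "D_min_m" in info.data and v <= info.data["D_min_m"]:
            raise ValueError("D_max must exceed D_min")
        return v


class BioLimitConfig(_Section):
    limit_product_AHz_per_m: float = Field(default=5e9, gt=0)
    threshold_W_per_g: float = Field(default=10.0, gt=0)
    H_cap_A_per_m: float = Field(default=50e3, gt=0)
    saturation_rel_gain: float = Field(default=0.05, gt=0)
    H_grid_A_per_m: list[float] = Field(
        default_factory=lambda: [10e3, 20e3, 30e3, 40e3, 50e3]
    )


class OutputConfig(_Section):
    directory: str = "ferroheat-out"
    formats: list[str] = Field(default_factory=lambda: ["csv", "json"])
    plots: bool = False

    @field_validator("formats")
    @classmethod
    def _known(cls, v: list[str]) -> list[str]:
        unknown = set(v) - {"csv", "json"}
        if unknown:
            raise ValueError(f"unknown output formats: {sorted(unknown)}")
        return v


class RunConfig(_Section):
    """Fully validated, SI-normalized configuration of a study run."""

    compositions: list[float] = Field(
        default_factory=lambda: [0.0, 0.05, 0.1, 0.2, 0.4, 0.67, 0.8, 1.0]
    )
    particle: ParticleConfig = Field(default_factory=ParticleConfig)
    environment: EnvironmentConfig = Field(default_factory=EnvironmentConfig)
    field: FieldConfig = Field(default_factory=FieldConfig)
    search: SearchConfig = Field(default_factory=SearchConfig)
    biolimit: BioLimitConfig = Field(default_factory=BioLimitConfig)
    output: OutputConfig = Field(default_factory=OutputConfig)

    @field_validator("compositions")
    @classmethod
    def _x_domain(cls, v: list[float]) -> list[float]:
        if not v:
            raise ValueError("composition list must not be empty")
        bad = [x for x in v if not (0 <= x <= 1)]
        if bad:
            raise ValueError(
                f"compositions {bad} outside the valid Co2+ fraction range 0–1"
            )
        return v

    def to_dict(self) -> dict:
        return self.model_dump()


# raw-key → (section, SI field, default unit, accepted units)
_QUANTITY_KEYS = {
    ("field", "H"): ("field", "H_A_per_m", "kA/m", ("A/m", "kA/m")),
    ("field", "f"): ("field", "f_Hz", "kHz", ("Hz", "kHz", "MHz")),
    ("search", "D_min"): ("search", "D_min_m", "nm", ("nm", "m")),
    ("search", "D_max"): ("search", "D_max_m", "nm", ("nm", "m")),
    ("particle", "tau0"): ("particle", "tau0_s", "s", ("s", "ns", "us", "µs", "ms")),
    ("environment", "T"): ("environment", "T_K", "K", ("K",)),
    ("biolimit", "limit_product"): (
        "biolimit", "limit_product_AHz_per_m", "AHz/m", ("AHz/m", "A*Hz/m", "A.Hz/m"),
    ),
    ("biolimit", "threshold"): ("biolimit", "threshold_W_per_g", "W/g", ("W/g", "W/kg")),
    ("biolimit", "H_cap"): ("biolimit", "H_cap_A_per_m", "kA/m", ("A/m", "kA/m")),
    ("biolimit", "H_grid"): ("biolimit", "H_grid_A_per_m", "kA/m", ("A/m", "kA/m")),
}


def _normalize_units(raw: dict) -> dict:
    """Rewrite convenience keys with units into their SI counterparts."""
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in raw.items()}
    for (section, key), (sec_to, key_to, default_unit, allowed) in _QUANTITY_KEYS.items():
        sec = out.get(section)
        if isinstance(sec, dict) and key in sec:
            value = sec.pop(key)
            if isinstance(value, (list, tuple)) or key in ("H", "f", "H_grid"):
                sec[key_to] = _qty_list(value, default_unit, allowed)
            else:
                sec[key_to] = parse_quantity(value, default_unit, allowed)
    return out


def validate_config(raw: dict | None) -> RunConfig:
    """Validate a raw key-value document into a :class:`RunConfig`.

    Accepts both SI keys (``H_A_per_m``) and unit-bearing convenience keys
    (``H: ["20 kA/m", 30]`` — bare numbers in the documented default unit).
    Raises :class:`ConfigError` naming the offending key on any violation.
    """
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig.model_validate(_normalize_units(raw))
    except ConfigError:
        raise
    except Exception as exc:  # pydantic ValidationError → uniform ConfigError
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config file; ``None`` yields all defaults."""
    if path is None:
        return RunConfig()
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse YAML config {path}: {exc}") from exc
    return validate_config(raw)
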