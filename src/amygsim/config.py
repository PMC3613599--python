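"""Run configuration: YAML/JSON loading, precedence, and round-tripping.

Precedence (lowest to highest): built-in defaults < preset < config file
< command-line overrides. A resolved-config sidecar written by a run can
be fed back in to reproduce the run byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .circuit import CircuitParameters
from .errors import ConfigurationError, ParameterError
from .plasticity import LesionSpec
from .protocols import PRESET_NAMES, ProtocolSpec, build_preset

__all__ = ["RunConfig", "load_config", "parse_overrides",
           "resolve_protocol", "write_sidecar"]

_PARAM_FIELDS = {f.name for f in fields(CircuitParameters)}
_LESION_FIELDS = {f.name for f in fields(LesionSpec)}
_BIAS_FIELDS = {"f_I", "E_ILd", "E_ILv"}


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation run."""

    preset: str = "normal"
    trials_per_epoch: int = 15
    seed: int = 0
    overrides: dict = field(default_factory=dict)   # CircuitParameters deltas
    bias: dict = field(default_factory=dict)        # f_I / E_ILd / E_ILv
    lesions: dict = field(default_factory=dict)
    trace: bool = False
    plot: bool = False

    def __post_init__(self):
        if self.preset not in PRESET_NAMES:
            raise ConfigurationError(
                f"unknown preset {self.preset!r}; choose from "
                f"{sorted(PRESET_NAMES)}")
        if self.trials_per_epoch < 1:
            raise ConfigurationError("trials_per_epoch must be >= 1")
        bad = set(self.overrides) - _PARAM_FIELDS
        if bad:
            raise ConfigurationError(f"unknown parameter(s): {sorted(bad)}")
        bad = set(self.bias) - _BIAS_FIELDS
        if bad:
            raise ConfigurationError(f"unknown bias field(s): {sorted(bad)}")
        bad = set(self.lesions) - _LESION_FIELDS
        if bad:
            raise ConfigurationError(f"unknown lesion flag(s): {sorted(bad)}")
        # fail fast: parameter overrides must satisfy the invariants
        CircuitParameters().with_overrides(**self.overrides)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        bad = set(d) - known
        if bad:
            raise ConfigurationError(f"unknown config key(s): {sorted(bad)}")
        return cls(**d)


def load_config(path) -> RunConfig:
    """Load a YAML (or JSON — a YAML subset) run configuration."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse config {path}: {exc}")
    if not isinstance(data, dict):
        raise ConfigurationError(f"config {path} must be a mapping")
    return RunConfig.from_dict(data)


def parse_overrides(pairs) -> dict:
    """Parse ``key=value`` strings (CLI ``--override``) into a dict."""
    out = {}
    for pair in pairs:
        if "=" not in pair:
            raise ConfigurationError(
                f"override {pair!r} is not of the form key=value")
        key, _, raw = pair.partition("=")
        key = key.strip()
        try:
            value = float(raw)
        except ValueError:
            raise ConfigurationError(
                f"override {pair!r}: value must be numeric")
        if key == "n_channels":
            value = int(value)
        out[key] = value
    return out


def resolve_protocol(config: RunConfig) -> ProtocolSpec:
    """Build the protocol a RunConfig describes (preset + deltas)."""
    prot = build_preset(config.preset, config.trials_per_epoch, config.seed)
    bias = dict(config.bias)
    # f_I / E_ILd / E_ILv given as parameter overrides act as bias values
    for key in _BIAS_FIELDS & set(config.overrides):
        bias.setdefault(key, config.overrides[key])
    lesions = config.lesions
    if bias or lesions:
        merged = asdict(prot.lesions)
        merged.update(lesions)
        prot = ProtocolSpec(
            epochs=prot.epochs, stimuli=prot.stimuli,
            f_I=bias.get("f_I", prot.f_I),
            E_ILd=bias.get("E_ILd", prot.E_ILd),
            E_ILv=bias.get("E_ILv", prot.E_ILv),
            lesions=LesionSpec(**merged),
            params_override={k: v for k, v in config.overrides.items()
                             if k not in _BIAS_FIELDS},
            seed=config.seed, name=prot.name)
    else:
        prot = ProtocolSpec(
            epochs=prot.epochs, stimuli=prot.stimuli, f_I=prot.f_I,
            E_ILd=prot.E_ILd, E_ILv=prot.E_ILv, lesions=prot.lesions,
            params_override={k: v for k, v in config.overrides.items()
                             if k not in _BIAS_FIELDS},
            seed=config.seed, name=prot.name)
    return prot


def write_sidecar(config: RunConfig, path) -> None:
    """Write the resolved config as a JSON sidecar (re-feedable)."""
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
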