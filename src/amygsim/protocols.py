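"""CS patterns, trial/epoch schedules and the preset experiments.

A conditioning protocol is four consecutive epochs — fear acquisition,
extinction, fear retrieval, extinction retrieval — in which two conditioned
stimuli with overlapping tonotopic representations are presented in strict
alternation. During acquisition/retrieval trials the CS co-occurs with the
US gate ``r_plus`` in a teaching window at the end of the CS-on interval;
during extinction trials the omission gate ``r_minus`` is active in the
same window instead. Intertrial intervals are represented by resetting the
activities to zero (only weights persist), so no wall-clock gap is
simulated.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .circuit import CircuitParameters, StimulusPattern
from .errors import ConfigurationError, ParameterError
from .plasticity import LesionSpec

__all__ = [
    "FrequencyAxis", "TrialSpec", "EpochSpec", "ProtocolSpec",
    "make_cs_pattern", "build_preset", "teaching_timeline",
    "PRESET_NAMES", "preset_table",
]

EPOCH_LABELS = ("acquisition", "extinction", "retrieval",
                "extinction_retrieval")


@dataclass(frozen=True)
class FrequencyAxis:
    """Linear mapping of channels to half-open frequency bins [low, high).

    The default axis spans 0-2500 Hz over 20 channels (125 Hz bins), which
    places a 500-1500 Hz CS on channels 4-11 and a 1000-2000 Hz CS on
    channels 8-15, overlapping on channels 8-11.
    """

    n_channels: int = 20
    f_min: float = 0.0
    f_max: float = 2500.0

    @property
    def bin_width(self) -> float:
        return (self.f_max - self.f_min) / self.n_channels

    def channels_in_band(self, freq_low: float, freq_high: float) -> np.ndarray:
        """Channels whose bin intersects the half-open band [low, high)."""
        if freq_low >= freq_high:
            raise ParameterError("freq_low must be strictly below freq_high")
        lo = np.floor((freq_low - self.f_min) / self.bin_width)
        hi = np.ceil((freq_high - self.f_min) / self.bin_width)
        lo = int(max(lo, 0))
        hi = int(min(hi, self.n_channels))
        if hi <= lo:
            raise ParameterError("frequency band lies outside the axis")
        return np.arange(lo, hi)


def make_cs_pattern(freq_low: float, freq_high: float,
                    axis: FrequencyAxis | None = None,
                    amplitude: float = 1.0,
                    label: str | None = None) -> StimulusPattern:
    """Build a CS pattern active on every channel intersecting the band."""
    axis = axis or FrequencyAxis()
    if amplitude <= 0:
        raise ParameterError("amplitude must be strictly positive")
    drive = np.zeros(axis.n_channels)
    drive[axis.channels_in_band(freq_low, freq_high)] = amplitude
    if label is None:
        label = f"CS[{freq_low:g}-{freq_high:g}Hz]"
    return StimulusPattern(drive, label=label)


@dataclass(frozen=True)
class TrialSpec:
    """One CS presentation with its teaching-signal contingency."""

    cs_label: str
    paired_with_us: bool = False
    omission_signal: bool = False
    t_cs: float = 10.0
    t_teach: float = 2.0

    def __post_init__(self):
        if self.paired_with_us and self.omission_signal:
            raise ParameterError(
                "a trial cannot both pair the US and signal its omission")
        if not (0 < self.t_teach <= self.t_cs):
            raise ParameterError(
                "teaching window must lie within the CS-on interval")


@dataclass(frozen=True)
class EpochSpec:
    label: str
    trials: tuple[TrialSpec, ...]

    def __post_init__(self):
        if self.label not in EPOCH_LABELS:
            raise ConfigurationError(f"unknown epoch label {self.label!r}")
        object.__setattr__(self, "trials", tuple(self.trials))


@dataclass(frozen=True)
class ProtocolSpec:
    """A full experiment: epochs, stimuli, bias inputs, lesions, seed."""

    epochs: tuple[EpochSpec, ...]
    stimuli: dict
    f_I: float = 3.0
    E_ILd: float = 0.0
    E_ILv: float = 2.0
    lesions: LesionSpec = LesionSpec.NONE
    params_override: dict = field(default_factory=dict)
    seed: int = 0
    name: str = "custom"

    def __post_init__(self):
        object.__setattr__(self, "epochs", tuple(self.epochs))
        for epoch in self.epochs:
            for trial in epoch.trials:
                if trial.cs_label not in self.stimuli:
                    raise ConfigurationError(
                        f"trial references unknown stimulus "
                        f"{trial.cs_label!r}")

    @property
    def n_trials(self) -> int:
        return sum(len(e.trials) for e in self.epochs)

    def resolve_params(self, base: CircuitParameters | None = None,
                       ) -> CircuitParameters:
        """Fold protocol-level settings into a CircuitParameters."""
        base = base or CircuitParameters()
        return base.with_overrides(f_I=self.f_I, E_ILd=self.E_ILd,
                                   E_ILv=self.E_ILv,
                                   **self.params_override)


def teaching_timeline(trial: TrialSpec, params: CircuitParameters,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-step (r_plus, r_minus) gate values over the CS-on interval.

    The active gate is 1 during the final ``t_teach`` window of CS-on and
    0 otherwise; both gates are 0 throughout intertrial intervals (which
    are not simulated — activities are simply reset).
    """
    n_steps = int(round(trial.t_cs / params.dt))
    teach_start = n_steps - int(round(trial.t_teach / params.dt))
    r_plus = np.zeros(n_steps)
    r_minus = np.zeros(n_steps)
    if trial.paired_with_us:
        r_plus[teach_start:] = 1.0
    if trial.omission_signal:
        r_minus[teach_start:] = 1.0
    return r_plus, r_minus


# ---------------------------------------------------------------------------
# presets

PRESET_NAMES = (
    "normal", "cautious", "rapid_switch", "lesion_itcd", "lesion_itcv",
    "confusing", "confusing_lesion_itcd", "confusing_lesion_itcv",
    "generalization", "phobic",
)


def preset_table() -> dict:
    """The shipped preset definitions (parsed from the packaged YAML)."""
    ref = importlib.resources.files("amygsim").joinpath(
        "presets/presets.yaml")
    return yaml.safe_load(ref.read_text())


def _alternating(labels, n_trials, make_trial):
    return tuple(make_trial(labels[k % len(labels)]) for k in range(n_trials))


def build_preset(name: str, trials_per_epoch: int = 15,
                 seed: int = 0) -> ProtocolSpec:
    """Construct one of the ten shipped experiments.

    ``trials_per_epoch`` counts CS presentations per epoch; the two CSs
    alternate within it. In "single-CS" (confusing-style) extinction
    epochs only CS1 receives omission trials while CS2 remains paired with
    the US; otherwise both CSs are extinguished.
    """
    table = preset_table()
    if name not in table:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(table)}")
    cfg = table[name]
    axis = FrequencyAxis()
    stimuli = {
        "CS1": make_cs_pattern(500.0, 1500.0, axis, label="CS1"),
        "CS2": make_cs_pattern(1000.0, 2000.0, axis, label="CS2"),
    }
    labels = ("CS1", "CS2")

    def paired(cs):
        return TrialSpec(cs, paired_with_us=True)

    def extinction_trial(cs):
        if cfg["extinction"] == "single_cs" and cs != "CS1":
            return paired(cs)   # CS2 keeps its US contingency
        return TrialSpec(cs, omission_signal=True)

    epochs = (
        EpochSpec("acquisition",
                  _alternating(labels, trials_per_epoch, paired)),
        EpochSpec("extinction",
                  _alternating(labels, trials_per_epoch, extinction_trial)),
        EpochSpec("retrieval",
                  _alternating(labels, trials_per_epoch, paired)),
        EpochSpec("extinction_retrieval",
                  _alternating(labels, trials_per_epoch, extinction_trial)),
    )
    lesions = LesionSpec(**cfg.get("lesions", {}))
    return ProtocolSpec(epochs=epochs, stimuli=stimuli, f_I=cfg["f_I"],
                        E_ILd=cfg["E_ILd"], E_ILv=cfg["E_ILv"],
                        lesions=lesions, seed=seed, name=name)
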