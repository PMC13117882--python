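"""Run configuration: every tunable constant, with documented defaults.

The config file is YAML with the same nesting as the dataclasses below.
Unknown keys are rejected so typos cannot silently fall back to defaults.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigError

__all__ = ["RunConfig", "load_config"]


@dataclass
class TensorConfig:
    """Nitroxide hyperfine principal values in gauss."""

    Axx: float = 6.3
    Ayy: float = 5.8
    Azz: float = 33.6

    def validate(self) -> None:
        if min(self.Axx, self.Ayy) <= 0 or self.Azz <= max(self.Axx, self.Ayy):
            raise ConfigError("tensor requires Azz > Axx, Ayy > 0")


@dataclass
class CalibrationConfig:
    """Constants of the line-shape formulas.

    ``k_B``/``k_C`` are the linewidth-to-correlation-time coefficients in
    s/gauss; ``inner_correction_gauss`` is the additive inner-splitting
    correction applied as ``A_perp_obs + c * (1 - S_app)``.
    """

    k_B: float = 6.51e-10
    k_C: float = 6.51e-10
    inner_correction: bool = True
    inner_correction_gauss: float = 1.4

    def validate(self) -> None:
        if self.k_B <= 0 or self.k_C <= 0:
            raise ConfigError("k_B and k_C must be positive")
        if self.inner_correction_gauss < 0:
            raise ConfigError("inner_correction_gauss must be >= 0")


@dataclass
class SmoothingConfig:
    """Local-polynomial (Savitzky-Golay) smoothing before extremum search."""

    window: int = 11
    polyorder: int = 2

    def validate(self) -> None:
        if self.window < 5 or self.window % 2 == 0:
            raise ConfigError("smoothing window must be odd and >= 5")
        if not 0 < self.polyorder < self.window:
            raise ConfigError("polyorder must be in (0, window)")


@dataclass
class SimulateConfig:
    """Synthetic-generator grid and noise defaults.

    Sweep geometry (100 G centered at 3350 G) is an X-band convention, not a
    measured fact; ``noise_sigma`` is relative to max |signal|.
    """

    sweep_center_G: float = 3350.0
    sweep_width_G: float = 100.0
    n_points: int = 2048
    noise_sigma: float = 0.01
    conv_width_G: float = 1.25
    n_orientations: int = 4000
    sr_n_points: int = 2048

    def validate(self) -> None:
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.n_points < 512:
            raise ConfigError("n_points must be >= 512")
        if self.sr_n_points < 64:
            raise ConfigError("sr_n_points must be >= 64")
        if self.sweep_width_G <= 0 or self.conv_width_G <= 0:
            raise ConfigError("sweep_width_G and conv_width_G must be positive")
        if self.n_orientations < 2000:
            raise ConfigError("n_orientations must be >= 2000")


@dataclass
class BindingConfig:
    use_depletion: bool = True
    n_starts: int = 5

    def validate(self) -> None:
        if self.n_starts < 1:
            raise ConfigError("n_starts must be >= 1")


@dataclass
class SRFitConfig:
    """Saturation-recovery fit options; ``t_cutoff_us`` drops early points."""

    t_cutoff_us: float = 0.0

    def validate(self) -> None:
        if self.t_cutoff_us < 0:
            raise ConfigError("t_cutoff_us must be >= 0")


@dataclass
class QuenchConfig:
    """Thresholds (percentage points) of the depth-localization classifier."""

    threshold_significant: float = 20.0
    threshold_equal: float = 5.0

    def validate(self) -> None:
        if self.threshold_significant <= 0 or self.threshold_equal < 0:
            raise ConfigError("quenching thresholds must be positive")


@dataclass
class RunConfig:
    tensor: TensorConfig = field(default_factory=TensorConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    binding: BindingConfig = field(default_factory=BindingConfig)
    sr: SRFitConfig = field(default_factory=SRFitConfig)
    quenching: QuenchConfig = field(default_factory=QuenchConfig)
    seed: int = 0

    def validate(self) -> None:
        for section in (
            self.tensor,
            self.calibration,
            self.smoothing,
            self.simulate,
            self.binding,
            self.sr,
            self.quenching,
        ):
            section.validate()

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        cfg = cls()
        _apply(cfg, mapping or {}, prefix="")
        cfg.validate()
        return cfg


def _apply(obj, mapping: dict, prefix: str) -> None:
    fields = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in mapping.items():
        if key not in fields:
            raise ConfigError(f"unknown configuration key {prefix + key!r}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current):
            if not isinstance(value, dict):
                raise ConfigError(f"section {prefix + key!r} must be a mapping")
            _apply(current, value, prefix=f"{prefix}{key}.")
        else:
            expected = type(current)
            if expected is float and isinstance(value, int):
                value = float(value)
            if not isinstance(value, expected):
                raise ConfigError(
                    f"key {prefix + key!r} expects {expected.__name__}, "
                    f"got {type(value).__name__}"
                )
            setattr(obj, key, value)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; omitted keys keep documented defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "r", encoding="ascii") as fh:
        payload = yaml.safe_load(fh)
    if payload is None:
        payload = {}
    if not isinstance(payload, dict):
        raise ConfigError("configuration root must be a mapping")
    return RunConfig.from_mapping(payload)
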