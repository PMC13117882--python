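"""Domain records shared by all stages.

Units are fixed package-wide: magnetic field in gauss, time in microseconds,
temperature in kelvin, curcumin concentration in micromolar, lipid
concentration in millimolar, oxygen transport parameter in 1/microsecond,
rotational correlation times in nanoseconds.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "Atmosphere",
    "FieldSpectrum",
    "GroundTruth",
    "MembraneComposition",
    "NitroxideTensor",
    "Regime",
    "SRDecay",
    "SpectrumMeta",
    "SpinLabelPosition",
    "TitrationSeries",
    "celsius_to_kelvin",
    "DEFAULT_TENSOR",
]

#: temperature below which a spectrum is tagged as a rigid-limit (frozen) one
FROZEN_BELOW_K = 200.0


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


class SpinLabelPosition(enum.Enum):
    """Nitroxide attachment point, ordered from headgroup to bilayer center.

    TPC carries the nitroxide on the choline headgroup, C5 on the fifth and
    C16 on the sixteenth acyl carbon; ``depth_rank`` increases monotonically
    toward the bilayer center and orders every depth profile.
    """

    TPC = "TPC"
    C5 = "C5"
    C16 = "C16"

    @property
    def depth_rank(self) -> int:
        return {"TPC": 0, "C5": 1, "C16": 2}[self.value]


class Regime(enum.Enum):
    FAST = "fast"
    SLOW = "slow"
    FROZEN = "frozen"


class Atmosphere(enum.Enum):
    AIR = "air"
    N2 = "N2"


@dataclass(frozen=True)
class MembraneComposition:
    """Host bilayer composition; value-equality makes it a grouping key."""

    host_lipid: str
    curcumin_molpct: float = 0.0
    peg_molpct: float = 0.0
    peg_anchor: Optional[str] = None

    def __post_init__(self) -> None:
        if self.curcumin_molpct < 0 or self.peg_molpct < 0:
            raise ValidationError("mol % fractions must be >= 0")
        if self.curcumin_molpct + self.peg_molpct >= 100:
            raise ValidationError(
                "curcumin_molpct + peg_molpct must stay below 100 mol %"
            )

    def label(self) -> str:
        parts = [self.host_lipid]
        if self.peg_molpct > 0:
            parts.append("PEG")
        if self.curcumin_molpct > 0:
            parts.append("CUR")
        return "-".join(parts)


@dataclass(frozen=True)
class NitroxideTensor:
    """Principal hyperfine values (gauss) of the nitroxide A-tensor."""

    Axx: float
    Ayy: float
    Azz: float

    def __post_init__(self) -> None:
        if min(self.Axx, self.Ayy) <= 0:
            raise ValidationError("Axx and Ayy must be positive")
        if self.Azz <= max(self.Axx, self.Ayy):
            raise ValidationError("Azz must exceed Axx and Ayy")

    @property
    def a0(self) -> float:
        """Isotropic hyperfine average (Axx + Ayy + Azz) / 3."""
        return (self.Axx + self.Ayy + self.Azz) / 3.0

    @property
    def delta(self) -> float:
        """Maximum anisotropy Azz - (Axx + Ayy) / 2, the S denominator."""
        return self.Azz - (self.Axx + self.Ayy) / 2.0


#: typical doxyl-stearate principal values; every routine that needs a tensor
#: accepts an override
DEFAULT_TENSOR = NitroxideTensor(Axx=6.3, Ayy=5.8, Azz=33.6)


@dataclass(frozen=True)
class GroundTruth:
    """True generating parameters stored alongside each synthetic record."""

    params: dict
    seed: int
    noise_sigma: float


@dataclass(frozen=True)
class SpectrumMeta:
    label: Optional[SpinLabelPosition] = None
    temperature_K: Optional[float] = None
    composition: Optional[MembraneComposition] = None
    regime: Optional[Regime] = None

    def __post_init__(self) -> None:
        # a 120 K record is a rigid-limit measurement whatever the caller said
        if (
            self.regime is None
            and self.temperature_K is not None
            and self.temperature_K < FROZEN_BELOW_K
        ):
            object.__setattr__(self, "regime", Regime.FROZEN)


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass
class FieldSpectrum:
    """First-derivative CW-EPR spectrum on a uniform magnetic-field grid."""

    field: np.ndarray
    intensity: np.ndarray
    meta: SpectrumMeta = dc_field(default_factory=SpectrumMeta)
    truth: Optional[GroundTruth] = None

    MIN_POINTS = 512
    GRID_RTOL = 1e-9

    def __post_init__(self) -> None:
        self.field = _as_float_array(self.field, "field")
        self.intensity = _as_float_array(self.intensity, "intensity")
        if self.field.size != self.intensity.size:
            raise ValidationError("field and intensity lengths differ")
        if self.field.size < self.MIN_POINTS:
            raise ValidationError(
                f"spectrum needs >= {self.MIN_POINTS} samples, got {self.field.size}"
            )
        steps = np.diff(self.field)
        if np.any(steps <= 0):
            raise ValidationError("field grid must be strictly increasing")
        mean = steps.mean()
        if np.max(np.abs(steps - mean)) > self.GRID_RTOL * abs(mean):
            raise ValidationError("field grid is not uniform within tolerance")

    @property
    def step(self) -> float:
        return float(self.field[1] - self.field[0])


@dataclass
class SRDecay:
    """Saturation-recovery signal versus time, tagged with the atmosphere."""

    time: np.ndarray
    signal: np.ndarray
    atmosphere: Atmosphere
    meta: SpectrumMeta = dc_field(default_factory=SpectrumMeta)
    truth: Optional[GroundTruth] = None

    MIN_POINTS = 64

    def __post_init__(self) -> None:
        self.time = _as_float_array(self.time, "time")
        self.signal = _as_float_array(self.signal, "signal")
        if self.time.size != self.signal.size:
            raise ValidationError("time and signal lengths differ")
        if self.time.size < self.MIN_POINTS:
            raise ValidationError(
                f"decay needs >= {self.MIN_POINTS} points, got {self.time.size}"
            )
        if self.time[0] < 0:
            raise ValidationError("time must start at >= 0")
        if np.any(np.diff(self.time) <= 0):
            raise ValidationError("time must be strictly increasing")


@dataclass
class TitrationSeries:
    """One replicate of a lipid-into-fluorophore titration."""

    lipid_mM: np.ndarray
    intensity: np.ndarray
    series_id: str = "series-1"
    curcumin_uM: float = 2.0
    composition: Optional[MembraneComposition] = None
    truth: Optional[GroundTruth] = None

    MIN_POINTS = 5

    def __post_init__(self) -> None:
        self.lipid_mM = _as_float_array(self.lipid_mM, "lipid_mM")
        self.intensity = _as_float_array(self.intensity, "intensity")
        if self.lipid_mM.size != self.intensity.size:
            raise ValidationError("lipid_mM and intensity lengths differ")
        if self.lipid_mM.size < self.MIN_POINTS:
            raise ValidationError(
                f"titration needs >= {self.MIN_POINTS} points, got {self.lipid_mM.size}"
            )
        if np.any(self.lipid_mM <= 0):
            raise ValidationError("lipid concentrations must be positive")
        if np.any(self.intensity < 0):
            raise ValidationError("intensities must be >= 0")
        if self.curcumin_uM < 0 or not math.isfinite(self.curcumin_uM):
            raise ValidationError("curcumin_uM must be finite and >= 0")
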