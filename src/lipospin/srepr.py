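"""Saturation-recovery analysis: T1 fits and oxygen transport profiles.

A saturation-recovery signal approaches its equilibrium baseline as
``signal(t) = baseline - amplitude * exp(-t / T1)``.  Comparing the fitted
relaxation rates under air and under nitrogen isolates the oxygen-induced
contribution, the oxygen transport parameter
``W = 1/T1(air) - 1/T1(N2)`` (1/µs), which tracks the local oxygen
collision rate at the depth probed by the spin label.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from lmfit import Model

from .exceptions import FitError, ValidationError
from .types import Atmosphere, MembraneComposition, SpinLabelPosition, SRDecay

__all__ = [
    "T1Fit",
    "OTPResult",
    "DepthProfile",
    "fit_t1",
    "compute_otp",
    "build_profile",
    "compare_profiles",
]


@dataclass(frozen=True)
class T1Fit:
    """Single-exponential recovery fit; T1 in µs."""

    T1: float
    T1_se: float
    amplitude: float
    baseline: float
    residual_rms: float
    converged: bool
    truncated: bool = False
    atmosphere: Optional[Atmosphere] = None
    position: Optional[SpinLabelPosition] = None
    composition: Optional[MembraneComposition] = None

    def __post_init__(self) -> None:
        if self.converged and self.T1 <= 0:
            raise ValidationError("converged fit must report T1 > 0")


@dataclass(frozen=True)
class OTPResult:
    """Oxygen transport parameter W = 1/T1(air) - 1/T1(N2), in 1/µs."""

    W: float
    W_se: float
    T1_air: T1Fit
    T1_N2: T1Fit
    position: Optional[SpinLabelPosition] = None
    composition: Optional[MembraneComposition] = None
    flagged: bool = False


def _recovery(t, baseline, amplitude, T1):
    return baseline - amplitude * np.exp(-t / T1)


def fit_t1(decay: SRDecay, t_cutoff: float = 0.0) -> T1Fit:
    """Fit ``baseline - amplitude * exp(-t/T1)`` by nonlinear least squares.

    Initial values come from the tail mean (baseline) and a log-linear
    regression of the baseline-subtracted early signal (T1).  Decays stored
    inverted (signal decreasing toward the baseline) are handled by letting
    the amplitude take either sign.  A fit whose T1 exceeds the time span is
    flagged truncated; a span below three estimated T1 raises a warning.
    """
    mask = decay.time >= t_cutoff
    t, y = decay.time[mask], decay.signal[mask]
    if t.size < SRDecay.MIN_POINTS:
        raise ValidationError("fewer than 64 points after the cutoff")

    n_tail = max(t.size // 10, 8)
    baseline0 = float(np.mean(y[-n_tail:]))
    amp0 = baseline0 - float(y[0])
    if amp0 == 0:
        amp0 = float(np.ptp(y)) or 1.0
    # log-linear T1 initial from the early baseline-approach
    resid = (baseline0 - y) / amp0
    early = np.where(resid > 0.05)[0]
    if early.size >= 2:
        te, re = t[early], np.log(resid[early])
        slope = np.polyfit(te, re, 1)[0]
        T1_0 = -1.0 / slope if slope < 0 else float(t[-1] - t[0]) / 3.0
    else:
        T1_0 = float(t[-1] - t[0]) / 3.0
    T1_0 = min(max(T1_0, float(t[1] - t[0])), 10.0 * float(t[-1] - t[0]))

    model = Model(_recovery)
    params = model.make_params(baseline=baseline0, amplitude=amp0, T1=T1_0)
    params["T1"].set(min=1e-9)
    result = model.fit(y, params, t=t)
    if not result.success:
        raise FitError(f"T1 fit did not converge: {result.message}")

    T1 = float(result.params["T1"].value)
    stderr = result.params["T1"].stderr
    span = float(t[-1] - t[0])
    truncated = T1 > span
    if span < 3.0 * T1:
        warnings.warn(
            f"time span ({span:.3g} µs) covers less than 3 T1 ({T1:.3g} µs); "
            "the fit may be poorly constrained",
            stacklevel=2,
        )
    return T1Fit(
        T1=T1,
        T1_se=float(stderr) if stderr is not None else float("nan"),
        amplitude=float(result.params["amplitude"].value),
        baseline=float(result.params["baseline"].value),
        residual_rms=float(np.sqrt(np.mean(result.residual**2))),
        converged=True,
        truncated=truncated,
        atmosphere=decay.atmosphere,
        position=decay.meta.label,
        composition=decay.meta.composition,
    )


def compute_otp(fit_air: T1Fit, fit_n2: T1Fit) -> OTPResult:
    """W = 1/T1(air) - 1/T1(N2) with first-order SE propagation."""
    if not (fit_air.converged and fit_n2.converged):
        raise ValidationError("both T1 fits must have converged")
    if fit_air.atmosphere is Atmosphere.N2 or fit_n2.atmosphere is Atmosphere.AIR:
        raise ValidationError("atmosphere tags are swapped")
    if fit_air.position != fit_n2.position or fit_air.composition != fit_n2.composition:
        raise ValidationError("air/N2 fits refer to different samples")
    W = 1.0 / fit_air.T1 - 1.0 / fit_n2.T1
    var = 0.0
    for fit in (fit_air, fit_n2):
        if np.isfinite(fit.T1_se):
            var += (fit.T1_se / fit.T1**2) ** 2
    return OTPResult(
        W=float(W),
        W_se=float(np.sqrt(var)),
        T1_air=fit_air,
        T1_N2=fit_n2,
        position=fit_air.position,
        composition=fit_air.composition,
        flagged=bool(W < 0),
    )


ProfileEntry = Union[OTPResult, Tuple[SpinLabelPosition, float], Tuple[SpinLabelPosition, float, float]]


@dataclass
class DepthProfile:
    """Ordered map of spin-label position to a scalar with uncertainty.

    ``kind`` is ``"otp"`` (W, 1/µs) or ``"polarity"`` (2Az, gauss); entries
    are ordered headgroup -> bilayer center by the position's depth rank.
    """

    values: Dict[SpinLabelPosition, float]
    uncertainties: Dict[SpinLabelPosition, float]
    kind: str
    composition: Optional[MembraneComposition] = None

    @property
    def positions(self) -> List[SpinLabelPosition]:
        return sorted(self.values, key=lambda p: p.depth_rank)

    def value(self, position: SpinLabelPosition) -> float:
        return self.values[position]

    def difference(
        self, pos_a: SpinLabelPosition, pos_b: SpinLabelPosition
    ) -> Tuple[float, float]:
        """(value[pos_b] - value[pos_a], propagated SE)."""
        delta = self.values[pos_b] - self.values[pos_a]
        se = float(np.hypot(self.uncertainties[pos_a], self.uncertainties[pos_b]))
        return float(delta), se


def build_profile(
    results: Sequence[ProfileEntry],
    kind: str = "otp",
    composition: Optional[MembraneComposition] = None,
) -> DepthProfile:
    """Assemble a depth profile from OTP results or (position, value[, se]).

    Input order is irrelevant; duplicate positions with conflicting values
    raise a validation error naming them.
    """
    values: Dict[SpinLabelPosition, float] = {}
    ses: Dict[SpinLabelPosition, float] = {}
    duplicates = []
    for entry in results:
        if isinstance(entry, OTPResult):
            pos, val, se = entry.position, entry.W, entry.W_se
            if composition is None:
                composition = entry.composition
        else:
            pos, val = entry[0], float(entry[1])
            se = float(entry[2]) if len(entry) > 2 else 0.0
        if pos is None:
            raise ValidationError("profile entry lacks a spin-label position")
        if pos in values:
            if not np.isclose(values[pos], val, rtol=1e-9, atol=1e-12):
                duplicates.append(pos.value)
            continue
        values[pos] = float(val)
        ses[pos] = float(se) if np.isfinite(se) else 0.0
    if duplicates:
        raise ValidationError(
            "conflicting duplicate positions: " + ", ".join(sorted(duplicates))
        )
    if len(values) < 2:
        raise ValidationError("a depth profile needs >= 2 distinct positions")
    return DepthProfile(values=values, uncertainties=ses, kind=kind, composition=composition)


def compare_profiles(a: DepthProfile, b: DepthProfile) -> Dict[SpinLabelPosition, Tuple[float, float]]:
    """Per-position ``b - a`` deltas with propagated uncertainty.

    Sign convention: call with ``a=control`` and ``b=treated`` so a curcumin-
    induced reduction appears negative.
    """
    if a.kind != b.kind:
        raise ValidationError(f"profile kinds differ: {a.kind} vs {b.kind}")
    if set(a.values) != set(b.values):
        raise ValidationError("profiles cover different positions")
    out = {}
    for pos in a.positions:
        delta = b.values[pos] - a.values[pos]
        se = float(np.hypot(a.uncertainties[pos], b.uncertainties[pos]))
        out[pos] = (float(delta), se)
    return out
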