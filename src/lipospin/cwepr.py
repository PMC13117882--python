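"""Feature extraction and observables for first-derivative CW-EPR spectra.

Three regimes are handled the way the corresponding spin labels are analyzed
in membrane work:

* fast motion (16-PC-like, three resolved lines): peak-to-peak amplitudes and
  widths give rotational correlation times
  ``tau_2B = k_B * dH0 * (sqrt(h0/h-) - sqrt(h0/h+))`` and
  ``tau_2C = k_C * dH0 * (sqrt(h0/h-) + sqrt(h0/h+) - 2)``;
* slow motion (5-PC-like pseudo-powder): the outer/inner hyperfine extrema
  give ``A_par = 2Amax/2`` and the observed ``A_perp``, corrected by the
  standard ``+1.4 * (1 - S_app)`` gauss for the inner-splitting bias of
  powder patterns, and the order parameter
  ``S = (A_par - A_perp) / (Azz - (Axx + Ayy)/2) * a0/a0'`` with
  ``a0' = (A_par + 2 A_perp)/3`` normalizing out the polarity shift;
* rigid limit (frozen, 120 K): the separation of the outermost extrema reads
  out the maximum hyperfine splitting ``2Az``, a polarity gauge.

All positions are refined below the grid spacing by a parabola through the
three points around each extremum; optional Savitzky-Golay smoothing runs
before any extremum search.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import fsolve
from scipy.signal import find_peaks, savgol_filter

from .exceptions import ComputationError, ExtractionError, ValidationError
from .types import DEFAULT_TENSOR, FieldSpectrum, NitroxideTensor, Regime

__all__ = [
    "LineFeatures",
    "SplittingPair",
    "OrderParameterResult",
    "CorrelationTimes",
    "extract_line_features",
    "tpc_params",
    "extract_outer_inner_splittings",
    "order_parameter",
    "invert_order_parameter",
    "correlation_times",
    "extract_2Az",
]

#: default linewidth-to-correlation-time coefficient, s/gauss
K_TAU = 6.51e-10
#: default additive inner-splitting correction, gauss
INNER_CORRECTION_G = 1.4


@dataclass(frozen=True)
class LineFeatures:
    """Peak-to-peak amplitudes/widths of a three-line fast-motion spectrum.

    ``h_plus``/``h_zero``/``h_minus`` are the low-, central- and high-field
    line amplitudes; ``delta_h0`` the central and ``dh_plus`` the low-field
    peak-to-peak width (gauss); ``centers`` the line center fields.
    """

    h_plus: float
    h_zero: float
    h_minus: float
    delta_h0: float
    dh_plus: float
    dh_minus: float
    centers: Tuple[float, float, float]
    snr: float = float("inf")
    notes: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if min(self.h_plus, self.h_zero, self.h_minus) <= 0:
            raise ValidationError("line amplitudes must be positive")
        if min(self.delta_h0, self.dh_plus, self.dh_minus) <= 0:
            raise ValidationError("line widths must be positive")
        if not (self.centers[0] < self.centers[1] < self.centers[2]):
            raise ValidationError("line centers must be ordered in field")


@dataclass(frozen=True)
class SplittingPair:
    """Outer (2Amax) and inner (2Amin) hyperfine extrema separations, gauss."""

    two_Amax: float
    two_Amin: Optional[float] = None
    notes: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.two_Amax <= 0:
            raise ValidationError("two_Amax must be positive")
        if self.two_Amin is not None and not 0 < self.two_Amin < self.two_Amax:
            raise ValidationError("need two_Amax > two_Amin > 0")

    @property
    def resolved(self) -> bool:
        return self.two_Amin is not None


@dataclass(frozen=True)
class OrderParameterResult:
    S: float
    A_parallel: float
    A_perp_corrected: float
    polarity_factor: float
    tensor: NitroxideTensor
    flagged: bool = False


@dataclass(frozen=True)
class CorrelationTimes:
    tau_2B_ns: float
    tau_2C_ns: float
    flagged: bool = False

    @property
    def anisotropy_gap_ns(self) -> float:
        return self.tau_2C_ns - self.tau_2B_ns


# ---------------------------------------------------------------------------
# low-level helpers


def _smooth(y: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    if window <= 1:
        return y
    window = min(window, len(y) - (1 - len(y) % 2))
    return savgol_filter(y, window_length=window, polyorder=polyorder)


def _refine(x: np.ndarray, y: np.ndarray, i: int, half: int = 1) -> Tuple[float, float]:
    """Sub-grid extremum via a least-squares parabola over ``i -+ half``.

    ``half=1`` reduces to the classic three-point formula; wider footprints
    average noise at the flat extrema of broad powder features.
    """
    if i <= 0 or i >= len(y) - 1:
        raise ExtractionError("extremum at grid boundary")
    lo, hi = max(i - half, 0), min(i + half + 1, len(y))
    coeffs = np.polyfit(x[lo:hi] - x[i], y[lo:hi], 2)
    if coeffs[0] == 0:
        return float(x[i]), float(y[i])
    shift = -coeffs[1] / (2.0 * coeffs[0])
    # keep the vertex inside the fitted footprint; otherwise fall back
    span = x[hi - 1] - x[lo]
    if abs(shift) > span:
        return float(x[i]), float(y[i])
    return float(x[i] + shift), float(np.polyval(coeffs, shift))


def _require_regime(spec: FieldSpectrum, expected: Regime, op: str) -> None:
    actual = spec.meta.regime
    if actual is not None and actual is not expected:
        raise ValidationError(
            f"{op} expects a {expected.value}-regime spectrum, got {actual.value}"
        )


def _outer_extrema(
    spec: FieldSpectrum, window: int, polyorder: int, prominence_frac: float
) -> Tuple[float, float, np.ndarray]:
    """Leftmost significant maximum and rightmost significant minimum."""
    y_s = _smooth(spec.intensity, window, polyorder)
    span = y_s.max() - y_s.min()
    if span <= 0:
        raise ExtractionError("flat spectrum")
    prom = prominence_frac * span
    maxima, _ = find_peaks(y_s, prominence=prom)
    minima, _ = find_peaks(-y_s, prominence=prom)
    if maxima.size == 0 or minima.size == 0:
        raise ExtractionError("no significant extrema found")
    i_lo, i_hi = int(maxima[0]), int(minima[-1])
    edge = max(3, window)
    if i_lo < edge or i_hi > len(y_s) - 1 - edge:
        raise ExtractionError("outer extrema too close to the sweep boundary")
    half = max(window // 2, 1)
    x_lo, _ = _refine(spec.field, y_s, i_lo, half)
    x_hi, _ = _refine(spec.field, y_s, i_hi, half)
    if x_hi <= x_lo:
        raise ExtractionError("outer extrema are not ordered in field")
    return x_lo, x_hi, y_s


# ---------------------------------------------------------------------------
# fast-motion route


def extract_line_features(
    spec: FieldSpectrum,
    window: int = 11,
    polyorder: int = 2,
    prominence_frac: float = 0.05,
    snr_warn: float = 5.0,
) -> LineFeatures:
    """Locate the three derivative lines and measure amplitudes and widths.

    The three most prominent maxima (ordered in field) are paired each with
    the deepest minimum before the next line; amplitude is the refined
    max-min difference and width the refined field distance of the pair.
    """
    _require_regime(spec, Regime.FAST, "extract_line_features")
    y_s = _smooth(spec.intensity, window, polyorder)
    span = y_s.max() - y_s.min()
    if span <= 0:
        raise ExtractionError("flat spectrum")
    maxima, props = find_peaks(y_s, prominence=prominence_frac * span)
    if maxima.size < 3:
        raise ExtractionError(
            f"found {maxima.size} candidate lines, need 3 "
            f"(prominence threshold {prominence_frac:g} of span)"
        )
    order = np.argsort(props["prominences"])[::-1][:3]
    line_max = np.sort(maxima[order])
    minima, _ = find_peaks(-y_s, prominence=prominence_frac * span)

    amplitudes, widths, centers = [], [], []
    half = max(window // 2, 1)
    bounds = list(line_max[1:]) + [len(y_s) - 1]
    for i_max, i_stop in zip(line_max, bounds):
        cand = minima[(minima > i_max) & (minima < i_stop)]
        if cand.size == 0:
            raise ExtractionError("line maximum without a following minimum")
        i_min = int(cand[np.argmin(y_s[cand])])
        x_max, y_max = _refine(spec.field, y_s, int(i_max), half)
        x_min, y_min = _refine(spec.field, y_s, i_min, half)
        amplitudes.append(y_max - y_min)
        widths.append(x_min - x_max)
        centers.append(0.5 * (x_max + x_min))

    noise = float(np.std(spec.intensity - y_s))
    snr = amplitudes[1] / noise if noise > 0 else float("inf")
    notes: Tuple[str, ...] = ()
    if snr < snr_warn:
        warnings.warn(f"low signal-to-noise ratio ({snr:.1f})", stacklevel=2)
        notes = (f"low SNR {snr:.2f}",)
    return LineFeatures(
        h_plus=amplitudes[0],
        h_zero=amplitudes[1],
        h_minus=amplitudes[2],
        delta_h0=widths[1],
        dh_plus=widths[0],
        dh_minus=widths[2],
        centers=(centers[0], centers[1], centers[2]),
        snr=snr,
        notes=notes,
    )


def tpc_params(features: LineFeatures) -> dict:
    """Headgroup mobility readouts: low-field width and h0/h- ratio.

    Both decrease as headgroup motional freedom increases.
    """
    return {
        "dh_plus": features.dh_plus,
        "h0_over_hminus": features.h_zero / features.h_minus,
    }


def correlation_times(
    features: LineFeatures, k_B: float = K_TAU, k_C: float = K_TAU
) -> CorrelationTimes:
    """Rotational correlation times (ns) from relative line amplitudes.

    ``tau_2B = k_B * dH0 * (sqrt(h0/h-) - sqrt(h0/h+))`` and
    ``tau_2C = k_C * dH0 * (sqrt(h0/h-) + sqrt(h0/h+) - 2)`` with the
    coefficients in s/gauss.  Negative values (pathological amplitude
    ordering) are flagged, never clipped.
    """
    r_minus = np.sqrt(features.h_zero / features.h_minus)
    r_plus = np.sqrt(features.h_zero / features.h_plus)
    tau_b = k_B * features.delta_h0 * (r_minus - r_plus) * 1e9
    tau_c = k_C * features.delta_h0 * (r_minus + r_plus - 2.0) * 1e9
    return CorrelationTimes(
        tau_2B_ns=float(tau_b),
        tau_2C_ns=float(tau_c),
        flagged=bool(tau_b < 0 or tau_c < 0),
    )


# ---------------------------------------------------------------------------
# slow-motion route


def extract_outer_inner_splittings(
    spec: FieldSpectrum,
    window: int = 31,
    polyorder: int = 2,
    prominence_frac: float = 0.02,
) -> SplittingPair:
    """Measure 2Amax (outer) and 2Amin (inner) extrema separations.

    2Amax spans the leftmost significant maximum to the rightmost significant
    minimum.  The inner pair is the deepest minimum below the spectrum
    midpoint and the highest maximum above it (the central-line lobes fall on
    the opposite sides of the midpoint and are thereby excluded).  If either
    inner extremum is unresolved the result carries ``two_Amin=None`` and a
    note; the order parameter can then only be estimated from 2Amax, flagged.
    """
    _require_regime(spec, Regime.SLOW, "extract_outer_inner_splittings")
    x_lo, x_hi, y_s = _outer_extrema(spec, window, polyorder, prominence_frac)
    two_Amax = x_hi - x_lo
    b0 = 0.5 * (x_lo + x_hi)
    field = spec.field

    lo_win = np.where((field > x_lo) & (field < b0))[0]
    hi_win = np.where((field > b0) & (field < x_hi))[0]
    notes = []
    two_Amin: Optional[float] = None
    if lo_win.size > 2 and hi_win.size > 2:
        i_min = int(lo_win[np.argmin(y_s[lo_win])])
        i_max = int(hi_win[np.argmax(y_s[hi_win])])
        interior = lo_win[0] < i_min < lo_win[-1] and hi_win[0] < i_max < hi_win[-1]
        if interior:
            half = max(window // 2, 1)
            x_imin, _ = _refine(field, y_s, i_min, half)
            x_imax, _ = _refine(field, y_s, i_max, half)
            if 0 < x_imax - x_imin < two_Amax:
                two_Amin = x_imax - x_imin
    if two_Amin is None:
        notes.append("inner extrema unresolved; two_Amin unavailable")
    return SplittingPair(two_Amax=two_Amax, two_Amin=two_Amin, notes=tuple(notes))


def order_parameter(
    splittings: SplittingPair,
    tensor: NitroxideTensor = DEFAULT_TENSOR,
    inner_correction: bool = True,
    correction_gauss: float = INNER_CORRECTION_G,
) -> OrderParameterResult:
    """Segmental order parameter from hyperfine splittings.

    ``A_par = 2Amax/2``; the observed ``A_perp = 2Amin/2`` is corrected for
    the inner-splitting underestimate of powder patterns by
    ``+correction_gauss * (1 - S_app)`` (on by default); the polarity factor
    ``a0/a0'`` with ``a0' = (A_par + 2 A_perp)/3`` referencing the splittings
    to the crystal tensor.  If the inner splitting is unresolved a fallback
    estimate from ``A_par`` alone is returned, flagged.
    """
    A_par = splittings.two_Amax / 2.0
    delta = tensor.delta
    a0 = tensor.a0
    if not splittings.resolved:
        # fallback: assume the polarity factor is 1 and A_perp tracks A_par
        # through the a0 constraint A_par + 2 A_perp = 3 a0
        A_perp = (3.0 * a0 - A_par) / 2.0
        S = (A_par - A_perp) / delta
        return OrderParameterResult(
            S=float(S),
            A_parallel=float(A_par),
            A_perp_corrected=float(A_perp),
            polarity_factor=1.0,
            tensor=tensor,
            flagged=True,
        )
    A_perp_obs = splittings.two_Amin / 2.0
    S_app = (A_par - A_perp_obs) / delta
    A_perp = A_perp_obs + (correction_gauss * (1.0 - S_app) if inner_correction else 0.0)
    a0_prime = (A_par + 2.0 * A_perp) / 3.0
    if a0_prime <= 0:
        raise ComputationError("a0' <= 0: splittings inconsistent with the tensor")
    S = (A_par - A_perp) / delta * (a0 / a0_prime)
    return OrderParameterResult(
        S=float(S),
        A_parallel=float(A_par),
        A_perp_corrected=float(A_perp),
        polarity_factor=float(a0 / a0_prime),
        tensor=tensor,
        flagged=bool(S < -0.02 or S > 1.02),
    )


def invert_order_parameter(
    S_target: float,
    tensor: NitroxideTensor = DEFAULT_TENSOR,
    inner_correction: bool = True,
    correction_gauss: float = INNER_CORRECTION_G,
) -> SplittingPair:
    """Numerically invert :func:`order_parameter` for target S.

    The inversion pins the polarity factor to 1 (``a0' = a0``), i.e. the
    observed isotropic average matches the reference tensor, and solves the
    two-equation system for ``(A_par, A_perp_obs)`` with a root finder.
    """
    if not 0 <= S_target <= 1:
        raise ValidationError("S_target must lie in [0, 1]")
    delta, a0 = tensor.delta, tensor.a0

    def equations(v):
        A_par, A_perp_obs = v
        pair = SplittingPair(two_Amax=2 * A_par, two_Amin=2 * A_perp_obs)
        res = order_parameter(pair, tensor, inner_correction, correction_gauss)
        a0_prime = (res.A_parallel + 2.0 * res.A_perp_corrected) / 3.0
        return [res.S - S_target, a0_prime - a0]

    guess = [a0 + 2.0 / 3.0 * S_target * delta, a0 - S_target * delta / 3.0]
    solution, info, ier, msg = fsolve(equations, guess, full_output=True)
    if ier != 1:
        raise ComputationError(f"order-parameter inversion failed: {msg}")
    A_par, A_perp_obs = solution
    return SplittingPair(two_Amax=2.0 * float(A_par), two_Amin=2.0 * float(A_perp_obs))


# ---------------------------------------------------------------------------
# rigid limit


def extract_2Az(
    spec: FieldSpectrum,
    window: int = 61,
    polyorder: int = 2,
    prominence_frac: float = 0.02,
) -> float:
    """Maximum hyperfine splitting (gauss) of a rigid-limit powder spectrum.

    Reads the field separation between the global low-field maximum and the
    global high-field minimum, sub-grid refined.  Higher values report higher
    local polarity.
    """
    _require_regime(spec, Regime.FROZEN, "extract_2Az")
    x_lo, x_hi, _ = _outer_extrema(spec, window, polyorder, prominence_frac)
    return float(x_hi - x_lo)
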