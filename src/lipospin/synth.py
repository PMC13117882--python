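"""Synthetic instrument data with stored ground truth.

Every record the pipeline consumes can be generated here: three-line
fast-motion nitroxide spectra (Lorentzian first-derivative lines),
anisotropy-broadened pseudo-powder spectra with resolved outer/inner
extrema, rigid-limit frozen powder patterns, 2048-point saturation-recovery
decays, replicate titration series and control/sample quenching pairs.
Identical parameters and seed give bit-identical output; the generating
parameters travel with each record as a :class:`~lipospin.types.GroundTruth`.

Powder patterns are built by deterministic orientation averaging of
``A(theta) = sqrt(Apar^2 cos^2 theta + Aperp^2 sin^2 theta)`` on a uniform
``cos theta`` grid, convolved with a Gaussian and differentiated.  The
documented inner-splitting bias of such patterns is measured on the
noise-free spectrum and stored with the record; ``*_for_observed`` variants
self-calibrate that bias so the produced spectrum's *measured* splittings
match a requested truth.
"""
from __future__ import annotations

import warnings
from typing import Optional, Sequence, Tuple

import numpy as np

from . import cwepr
from .exceptions import ComputationError, ValidationError
from .types import (
    Atmosphere,
    FieldSpectrum,
    GroundTruth,
    MembraneComposition,
    Regime,
    SpectrumMeta,
    SpinLabelPosition,
    SRDecay,
    TitrationSeries,
)

__all__ = [
    "gen_fast_motion_spectrum",
    "fast_motion_widths_for_taus",
    "gen_slow_motion_spectrum",
    "gen_slow_motion_for_observed",
    "gen_frozen_spectrum",
    "gen_frozen_for_observed",
    "gen_sr_decay",
    "gen_sr_pair",
    "gen_titration",
    "gen_quenching_pair",
    "DEFAULT_LIPID_GRID_MM",
]

SWEEP_CENTER_G = 3350.0
SWEEP_WIDTH_G = 100.0
N_POINTS = 2048

#: eleven-step two-fold dilution from 2 mM, spanning 0.0019-2 mM
DEFAULT_LIPID_GRID_MM = 2.0 / 2.0 ** np.arange(10, -1, -1)


def _grid(center: float, sweep: float, n_points: int) -> np.ndarray:
    if n_points < FieldSpectrum.MIN_POINTS:
        raise ValidationError(f"n_points must be >= {FieldSpectrum.MIN_POINTS}")
    return np.linspace(center - sweep / 2.0, center + sweep / 2.0, n_points)


def _noisy(clean: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    if sigma == 0:
        return clean.copy()
    return clean + sigma * np.max(np.abs(clean)) * rng.standard_normal(clean.size)


def _meta(
    regime: Regime,
    label: Optional[SpinLabelPosition],
    temperature_K: Optional[float],
    composition: Optional[MembraneComposition],
) -> SpectrumMeta:
    return SpectrumMeta(
        label=label, temperature_K=temperature_K, composition=composition, regime=regime
    )


# ---------------------------------------------------------------------------
# fast motion


def _dlorentz(field: np.ndarray, center: float, pp_width: float) -> np.ndarray:
    """First derivative of a unit-area Lorentzian with peak-to-peak width."""
    gamma = np.sqrt(3.0) / 2.0 * pp_width
    x = field - center
    return -(2.0 / np.pi) * gamma * x / (x * x + gamma * gamma) ** 2


def gen_fast_motion_spectrum(
    widths: Tuple[float, float, float],
    splitting: float = 15.2,
    noise_sigma: float = 0.0,
    seed: int = 0,
    center: float = SWEEP_CENTER_G,
    sweep: float = SWEEP_WIDTH_G,
    n_points: int = N_POINTS,
    label: Optional[SpinLabelPosition] = None,
    temperature_K: Optional[float] = None,
    composition: Optional[MembraneComposition] = None,
    k_B: float = cwepr.K_TAU,
    k_C: float = cwepr.K_TAU,
) -> FieldSpectrum:
    """Three equal-area first-derivative Lorentzian lines at ``B0 -+ aN``.

    ``widths`` are the peak-to-peak widths (Gamma_plus, Gamma_0, Gamma_minus)
    of the low-, central- and high-field lines in gauss; equal integrated
    intensity makes the derivative amplitudes scale as ``1/Gamma^2``, which
    encodes the correlation-time truths stored with the record.
    """
    g_plus, g_zero, g_minus = (float(w) for w in widths)
    if min(g_plus, g_zero, g_minus) <= 0 or splitting <= 0:
        raise ValidationError("linewidths and splitting must be positive")
    field = _grid(center, sweep, n_points)
    g_max = max(g_plus, g_zero, g_minus)
    if center - splitting - 3 * g_max < field[0] or center + splitting + 3 * g_max > field[-1]:
        raise ValidationError("sweep too narrow to contain the outer lines")
    clean = (
        _dlorentz(field, center - splitting, g_plus)
        + _dlorentz(field, center, g_zero)
        + _dlorentz(field, center + splitting, g_minus)
    )
    clean = clean / np.max(np.abs(clean))
    rng = np.random.default_rng(seed)
    intensity = _noisy(clean, noise_sigma, rng)
    ratio_minus = (g_minus / g_zero) ** 2
    ratio_plus = (g_plus / g_zero) ** 2
    truth = GroundTruth(
        params={
            "gamma_plus": g_plus,
            "gamma_zero": g_zero,
            "gamma_minus": g_minus,
            "aN": splitting,
            "delta_h0": g_zero,
            "h0_over_hminus": ratio_minus,
            "h0_over_hplus": ratio_plus,
            "tau_2B_ns": k_B * g_zero * (np.sqrt(ratio_minus) - np.sqrt(ratio_plus)) * 1e9,
            "tau_2C_ns": k_C * g_zero * (np.sqrt(ratio_minus) + np.sqrt(ratio_plus) - 2) * 1e9,
        },
        seed=seed,
        noise_sigma=noise_sigma,
    )
    return FieldSpectrum(
        field=field,
        intensity=intensity,
        meta=_meta(Regime.FAST, label, temperature_K, composition),
        truth=truth,
    )


def fast_motion_widths_for_taus(
    tau_2B_ns: float,
    tau_2C_ns: float,
    gamma_zero: float = 2.0,
    k_B: float = cwepr.K_TAU,
    k_C: float = cwepr.K_TAU,
) -> Tuple[float, float, float]:
    """Linewidth triple whose amplitude ratios encode the target tau pair."""
    scale_b = k_B * gamma_zero * 1e9
    scale_c = k_C * gamma_zero * 1e9
    diff = tau_2B_ns / scale_b
    total = 2.0 + tau_2C_ns / scale_c
    a = 0.5 * (total + diff)  # sqrt(h0/h-)
    b = 0.5 * (total - diff)  # sqrt(h0/h+)
    if b <= 0 or a <= 0:
        raise ValidationError("tau pair implies non-physical amplitude ratios")
    return (b * gamma_zero, gamma_zero, a * gamma_zero)


# ---------------------------------------------------------------------------
# powder patterns


def _deposit(out: np.ndarray, field: np.ndarray, positions: np.ndarray, weight: float) -> None:
    step = field[1] - field[0]
    idx = (positions - field[0]) / step
    i0 = np.floor(idx).astype(int)
    frac = idx - i0
    ok = (i0 >= 0) & (i0 < field.size - 1)
    np.add.at(out, i0[ok], weight * (1.0 - frac[ok]))
    np.add.at(out, i0[ok] + 1, weight * frac[ok])


def _pseudo_powder(
    field: np.ndarray, center: float, Apar: float, Aperp: float,
    conv_width: float, n_orientations: int,
) -> np.ndarray:
    from scipy.ndimage import gaussian_filter1d

    cos_theta = (np.arange(n_orientations) + 0.5) / n_orientations
    A = np.sqrt(Aperp**2 + (Apar**2 - Aperp**2) * cos_theta**2)
    absorption = np.zeros_like(field)
    _deposit(absorption, field, center - A, 1.0)          # mI = +1, low field
    _deposit(absorption, field, np.full_like(A, center), 1.0)  # mI = 0
    _deposit(absorption, field, center + A, 1.0)          # mI = -1, high field
    step = field[1] - field[0]
    absorption = gaussian_filter1d(absorption, sigma=conv_width / step, mode="constant")
    deriv = np.gradient(absorption, field)
    return deriv / np.max(np.abs(deriv))


def _powder_spectrum(
    Apar: float, Aperp: float, conv_width: float, noise_sigma: float, seed: int,
    regime: Regime, center: float, sweep: float, n_points: int, n_orientations: int,
    label, temperature_K, composition,
) -> FieldSpectrum:
    if Aperp <= 0 or Apar < Aperp:
        raise ValidationError("need Apar >= Aperp > 0")
    if conv_width <= 0:
        raise ValidationError("conv_width must be positive")
    field = _grid(center, sweep, n_points)
    if center - Apar - 5 * conv_width < field[0] or center + Apar + 5 * conv_width > field[-1]:
        raise ValidationError("sweep too narrow to contain the powder pattern")
    clean = _pseudo_powder(field, center, Apar, Aperp, conv_width, n_orientations)
    rng = np.random.default_rng(seed)
    return FieldSpectrum(
        field=field,
        intensity=_noisy(clean, noise_sigma, rng),
        meta=_meta(regime, label, temperature_K, composition),
        truth=None,  # filled by callers
    )


def gen_slow_motion_spectrum(
    Apar: float,
    Aperp: float,
    conv_width: float = 1.25,
    noise_sigma: float = 0.0,
    seed: int = 0,
    center: float = SWEEP_CENTER_G,
    sweep: float = SWEEP_WIDTH_G,
    n_points: int = N_POINTS,
    n_orientations: int = 4000,
    label: Optional[SpinLabelPosition] = None,
    temperature_K: Optional[float] = None,
    composition: Optional[MembraneComposition] = None,
) -> FieldSpectrum:
    """Anisotropy-broadened pseudo-powder spectrum (5-PC-like).

    Outer extrema sit near ``2 Apar`` apart and inner extrema near
    ``2 Aperp``; the convolution-induced biases of both readouts are measured
    on the noise-free pattern and stored in the ground truth
    (``bias_outer``/``bias_inner``, gauss).  ``Apar == Aperp`` is allowed as
    the degenerate isotropic limit.
    """
    spec = _powder_spectrum(
        Apar, Aperp, conv_width, noise_sigma, seed, Regime.SLOW,
        center, sweep, n_points, n_orientations, label, temperature_K, composition,
    )
    clean = _powder_spectrum(
        Apar, Aperp, conv_width, 0.0, seed, Regime.SLOW,
        center, sweep, n_points, n_orientations, label, temperature_K, composition,
    )
    params = {"Apar": Apar, "Aperp": Aperp, "conv_width": conv_width}
    try:
        pair = cwepr.extract_outer_inner_splittings(clean)
        params["bias_outer"] = pair.two_Amax - 2.0 * Apar
        if pair.resolved:
            params["bias_inner"] = pair.two_Amin - 2.0 * Aperp
    except Exception:  # noqa: BLE001 - bias simply not measurable
        pass
    spec.truth = GroundTruth(params=params, seed=seed, noise_sigma=noise_sigma)
    return spec


def _calibrate(
    target_outer: float,
    target_inner: Optional[float],
    generate,
    extract,
    max_iter: int = 8,
    tol: float = 5e-3,
) -> Tuple[float, Optional[float]]:
    """Fixed-point adjustment of the generating splittings so that the
    noise-free spectrum's *measured* splittings match the targets."""
    Apar = target_outer / 2.0
    Aperp = target_inner / 2.0 if target_inner is not None else None
    for _ in range(max_iter):
        obs = extract(generate(Apar, Aperp))
        err_outer = target_outer - obs[0]
        err_inner = 0.0
        if target_inner is not None:
            if obs[1] is None:
                raise ComputationError("inner extrema unresolved during calibration")
            err_inner = target_inner - obs[1]
            Aperp += err_inner / 2.0
        Apar += err_outer / 2.0
        if abs(err_outer) < tol and abs(err_inner) < tol:
            break
    return Apar, Aperp


def gen_slow_motion_for_observed(
    two_Amax: float,
    two_Amin: float,
    conv_width: float = 1.25,
    noise_sigma: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> FieldSpectrum:
    """Slow-motion spectrum whose *measured* splittings equal the targets.

    The generator's own orientation-averaging/convolution bias is removed by
    a deterministic fixed-point calibration against noise-free extraction,
    so a generate -> extract round trip returns ``(two_Amax, two_Amin)`` up
    to noise and grid interpolation.
    """

    def generate(Apar, Aperp):
        return _powder_spectrum(
            Apar, Aperp, conv_width, 0.0, seed, Regime.SLOW,
            kwargs.get("center", SWEEP_CENTER_G), kwargs.get("sweep", SWEEP_WIDTH_G),
            kwargs.get("n_points", N_POINTS), kwargs.get("n_orientations", 4000),
            kwargs.get("label"), kwargs.get("temperature_K"), kwargs.get("composition"),
        )

    def extract(spec):
        pair = cwepr.extract_outer_inner_splittings(spec)
        return pair.two_Amax, pair.two_Amin

    Apar, Aperp = _calibrate(two_Amax, two_Amin, generate, extract)
    spec = gen_slow_motion_spectrum(
        Apar, Aperp, conv_width=conv_width, noise_sigma=noise_sigma, seed=seed, **kwargs
    )
    spec.truth = GroundTruth(
        params={
            "two_Amax": two_Amax,
            "two_Amin": two_Amin,
            "Apar": Apar,
            "Aperp": Aperp,
            "conv_width": conv_width,
        },
        seed=seed,
        noise_sigma=noise_sigma,
    )
    return spec


def gen_frozen_spectrum(
    Az: float,
    conv_width: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    A_minor: float = 6.05,
    center: float = SWEEP_CENTER_G,
    sweep: float = SWEEP_WIDTH_G,
    n_points: int = N_POINTS,
    n_orientations: int = 4000,
    label: Optional[SpinLabelPosition] = None,
    temperature_K: float = 120.0,
    composition: Optional[MembraneComposition] = None,
) -> FieldSpectrum:
    """Rigid-limit powder pattern read out through its outer extrema (2Az)."""
    if Az <= A_minor:
        raise ValidationError("Az must exceed the minor hyperfine component")
    spec = _powder_spectrum(
        Az, A_minor, conv_width, noise_sigma, seed, Regime.FROZEN,
        center, sweep, n_points, n_orientations, label, temperature_K, composition,
    )
    clean = _powder_spectrum(
        Az, A_minor, conv_width, 0.0, seed, Regime.FROZEN,
        center, sweep, n_points, n_orientations, label, temperature_K, composition,
    )
    params = {"Az": Az, "conv_width": conv_width, "A_minor": A_minor}
    try:
        params["bias_2Az"] = cwepr.extract_2Az(clean) - 2.0 * Az
    except Exception:  # noqa: BLE001
        pass
    spec.truth = GroundTruth(params=params, seed=seed, noise_sigma=noise_sigma)
    return spec


def gen_frozen_for_observed(
    two_Az: float,
    conv_width: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> FieldSpectrum:
    """Frozen spectrum whose *measured* 2Az equals the target, bias-calibrated."""
    A_minor = kwargs.pop("A_minor", 6.05)

    def generate(Az, _):
        return _powder_spectrum(
            Az, A_minor, conv_width, 0.0, seed, Regime.FROZEN,
            kwargs.get("center", SWEEP_CENTER_G), kwargs.get("sweep", SWEEP_WIDTH_G),
            kwargs.get("n_points", N_POINTS), kwargs.get("n_orientations", 4000),
            kwargs.get("label"), kwargs.get("temperature_K", 120.0), kwargs.get("composition"),
        )

    def extract(spec):
        return cwepr.extract_2Az(spec), None

    Az, _ = _calibrate(two_Az, None, generate, extract)
    spec = gen_frozen_spectrum(
        Az, conv_width=conv_width, noise_sigma=noise_sigma, seed=seed,
        A_minor=A_minor, **kwargs,
    )
    spec.truth = GroundTruth(
        params={"two_Az": two_Az, "Az": Az, "conv_width": conv_width},
        seed=seed,
        noise_sigma=noise_sigma,
    )
    return spec


# ---------------------------------------------------------------------------
# saturation recovery


def gen_sr_decay(
    T1: float,
    amplitude: float = 1.0,
    baseline: float = 1.0,
    n_points: int = 2048,
    t_max: Optional[float] = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    atmosphere: Atmosphere = Atmosphere.N2,
    label: Optional[SpinLabelPosition] = None,
    temperature_K: Optional[float] = None,
    composition: Optional[MembraneComposition] = None,
) -> SRDecay:
    """``signal(t) = baseline - amplitude * exp(-t/T1)`` plus Gaussian noise.

    Noise sigma is relative to the recovery amplitude.  A window shorter
    than five T1 raises a truncation warning but still returns the record.
    """
    if T1 <= 0:
        raise ValidationError("T1 must be positive")
    if n_points < SRDecay.MIN_POINTS:
        raise ValidationError(f"n_points must be >= {SRDecay.MIN_POINTS}")
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    if t_max is None:
        t_max = 10.0 * T1
    if t_max < 5.0 * T1:
        warnings.warn(
            f"t_max ({t_max:g} µs) below 5 T1 ({5 * T1:g} µs); decay is truncated",
            stacklevel=2,
        )
    t = np.linspace(0.0, t_max, n_points)
    rng = np.random.default_rng(seed)
    signal = baseline - amplitude * np.exp(-t / T1)
    if noise_sigma > 0:
        signal = signal + noise_sigma * abs(amplitude) * rng.standard_normal(n_points)
    truth = GroundTruth(
        params={"T1": T1, "amplitude": amplitude, "baseline": baseline},
        seed=seed,
        noise_sigma=noise_sigma,
    )
    return SRDecay(
        time=t,
        signal=signal,
        atmosphere=atmosphere,
        meta=_meta(Regime.FAST, label, temperature_K, composition),
        truth=truth,
    )


def gen_sr_pair(
    W: float,
    T1_n2: float = 5.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> Tuple[SRDecay, SRDecay]:
    """Air/N2 decay pair generated from an oxygen transport truth W (1/µs)."""
    if W < 0:
        raise ValidationError("W must be >= 0")
    T1_air = 1.0 / (1.0 / T1_n2 + W)
    seed_air, seed_n2 = (
        int(s) % (2**31 - 1) for s in np.random.SeedSequence(seed).generate_state(2)
    )
    air = gen_sr_decay(
        T1_air, noise_sigma=noise_sigma, seed=seed_air, atmosphere=Atmosphere.AIR, **kwargs
    )
    n2 = gen_sr_decay(
        T1_n2, noise_sigma=noise_sigma, seed=seed_n2, atmosphere=Atmosphere.N2, **kwargs
    )
    for rec in (air, n2):
        rec.truth = GroundTruth(
            params=dict(rec.truth.params, W=W), seed=rec.truth.seed, noise_sigma=noise_sigma
        )
    return air, n2


# ---------------------------------------------------------------------------
# fluorescence


def gen_titration(
    Kd_true: float,
    curcumin_uM: float = 2.0,
    lipid_grid_mM: Optional[Sequence[float]] = None,
    n_series: int = 3,
    F0: float = 10.0,
    Fmax: float = 100.0,
    noise_sigma: float = 0.01,
    scale_jitter: float = 0.02,
    seed: int = 0,
    composition: Optional[MembraneComposition] = None,
) -> list[TitrationSeries]:
    """Replicate titration series from a single-site binding truth.

    Intensity is ``scale * (F0 + (Fmax - F0) * f)`` with ``f`` the exact
    mass-balance bound fraction, a per-series multiplicative scale drawn
    from ``N(1, scale_jitter)`` and additive Gaussian noise of
    ``noise_sigma * (Fmax - F0)``.
    """
    from .binding import bound_fraction

    if Kd_true <= 0:
        raise ValidationError("Kd_true must be positive")
    grid = np.asarray(
        DEFAULT_LIPID_GRID_MM if lipid_grid_mM is None else lipid_grid_mM, dtype=float
    )
    if np.any(grid <= 0):
        raise ValidationError("lipid grid must be positive")
    rng = np.random.default_rng(seed)
    f = bound_fraction(grid, curcumin_uM, Kd_true)
    clean = F0 + (Fmax - F0) * f
    out = []
    for i in range(n_series):
        scale = 1.0 + scale_jitter * rng.standard_normal()
        noise = noise_sigma * (Fmax - F0) * rng.standard_normal(grid.size)
        intensity = np.clip(scale * clean + noise, 0.0, None)
        out.append(
            TitrationSeries(
                lipid_mM=grid,
                intensity=intensity,
                series_id=f"rep-{i + 1}",
                curcumin_uM=curcumin_uM,
                composition=composition,
                truth=GroundTruth(
                    params={"Kd_uM": Kd_true, "F0": F0, "Fmax": Fmax, "scale": scale},
                    seed=seed,
                    noise_sigma=noise_sigma,
                ),
            )
        )
    return out


def gen_quenching_pair(
    true_remaining_fraction: float,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Tuple[float, float]:
    """(F_control, F_sample) with the control pinned at 100 units."""
    if not 0 < true_remaining_fraction <= 1:
        raise ValidationError("remaining fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    control = 100.0
    sample = control * true_remaining_fraction + noise_sigma * control * rng.standard_normal()
    return control, float(max(sample, 0.0))
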