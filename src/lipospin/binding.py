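"""Equilibrium binding of a fluorophore to liposomal lipid.

The model is single-site association of curcumin (total concentration
``Ctot``, micromolar) with lipid treated as independent sites at the total
lipid concentration (``Ltot``, millimolar).  With ligand depletion the bound
fraction solves the mass-balance quadratic exactly; in the dilute-probe limit
it reduces to the hyperbola ``L / (L + Kd)``.  A global fit shares one Kd
across replicate titration series, with per-series intensity end points as
nuisance parameters.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from lmfit import Parameters, minimize

from .exceptions import FitError, ValidationError
from .types import TitrationSeries

__all__ = ["BindingFit", "AffinityRatio", "bound_fraction", "fit_kd_global", "affinity_ratio"]

_KD_MIN_UM = 1e-4
_KD_MAX_UM = 1e7


def bound_fraction(Ltot_mM, Ctot_uM: float, Kd_uM: float, use_depletion: bool = True):
    """Fraction of curcumin bound at total lipid ``Ltot_mM``.

    Exact mass-balance solution
    ``f = [(Ctot + L + Kd) - sqrt((Ctot + L + Kd)^2 - 4 Ctot L)] / (2 Ctot)``
    with ``L`` in micromolar; the limit ``Ctot -> 0`` (or
    ``use_depletion=False``) gives ``L / (L + Kd)``.
    """
    L = np.asarray(Ltot_mM, dtype=float) * 1000.0  # mM lipid -> µM sites
    if np.any(L < 0) or Ctot_uM < 0 or Kd_uM <= 0:
        raise ValidationError("concentrations must be >= 0 and Kd > 0")
    if not use_depletion or Ctot_uM == 0:
        return L / (L + Kd_uM)
    b = Ctot_uM + L + Kd_uM
    disc = b * b - 4.0 * Ctot_uM * L
    f = (b - np.sqrt(disc)) / (2.0 * Ctot_uM)
    return np.clip(f, 0.0, 1.0)


@dataclass
class BindingFit:
    """Result of a (global) single-site fit: shared Kd plus nuisance scales."""

    kd: float
    kd_se: float
    per_series: List[dict]
    n_series: int
    n_points: int
    converged: bool
    at_bound: bool = False
    redchi: float = float("nan")
    residual_rms: float = float("nan")
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged and self.kd <= 0:
            raise ValidationError("converged fit must report Kd > 0")


@dataclass
class AffinityRatio:
    ratio: float
    se: float


def _model(params: Parameters, series: Sequence[TitrationSeries], use_depletion: bool):
    out = []
    for i, rec in enumerate(series):
        f = bound_fraction(rec.lipid_mM, rec.curcumin_uM, params["Kd"].value, use_depletion)
        out.append(params[f"F0_{i}"].value + (params[f"Fmax_{i}"].value - params[f"F0_{i}"].value) * f)
    return out


def _residual(params, series, use_depletion):
    return np.concatenate(
        [model - rec.intensity for model, rec in zip(_model(params, series, use_depletion), series)]
    )


def fit_kd_global(
    series: Sequence[TitrationSeries],
    use_depletion: bool = True,
    n_starts: int = 5,
    kd_inits_uM: Optional[Sequence[float]] = None,
) -> BindingFit:
    """Globally fit one Kd across replicate titrations by least squares.

    Kd is shared; each series gets free ``F0`` (>= 0) and ``Fmax`` end
    points.  The fit restarts from ``n_starts`` log-spaced Kd initials
    spanning the lipid range (the spec default initial, the median lipid
    concentration, is always included) and keeps the lowest-loss converged
    solution.  Standard errors come from the covariance at the optimum.
    """
    if len(series) < 1:
        raise ValidationError("need at least one titration series")
    for rec in series:
        if rec.lipid_mM.size < TitrationSeries.MIN_POINTS:
            raise ValidationError("every series needs >= 5 points")

    all_L_uM = np.concatenate([rec.lipid_mM for rec in series]) * 1000.0
    if kd_inits_uM is None:
        inits = list(np.geomspace(all_L_uM.min(), all_L_uM.max(), max(n_starts - 1, 1)))
        inits.append(float(np.median(all_L_uM)))
    else:
        inits = list(kd_inits_uM)

    best = None
    for kd0 in inits:
        params = Parameters()
        params.add("Kd", value=kd0, min=_KD_MIN_UM, max=_KD_MAX_UM)
        for i, rec in enumerate(series):
            lo, hi = float(rec.intensity.min()), float(rec.intensity.max())
            params.add(f"F0_{i}", value=max(lo, 0.0), min=0.0)
            params.add(f"Fmax_{i}", value=hi if hi > 0 else 1.0, min=0.0)
        try:
            result = minimize(_residual, params, args=(series, use_depletion), method="leastsq")
        except Exception:  # noqa: BLE001 - a failed start is simply skipped
            continue
        if not result.success:
            continue
        if best is None or result.chisqr < best.chisqr:
            best = result

    if best is None:
        raise FitError("global Kd fit failed to converge from every start")

    kd = float(best.params["Kd"].value)
    kd_se = best.params["Kd"].stderr
    kd_se = float(kd_se) if kd_se is not None else float("nan")
    at_bound = kd <= _KD_MIN_UM * (1 + 1e-6) or kd >= _KD_MAX_UM * (1 - 1e-6)
    if at_bound:
        warnings.warn("Kd pinned at a parameter bound; treat the fit as unreliable")
    per_series = []
    for i, rec in enumerate(series):
        entry = {"series_id": rec.series_id}
        for name in ("F0", "Fmax"):
            p = best.params[f"{name}_{i}"]
            entry[name] = float(p.value)
            entry[f"{name}_se"] = float(p.stderr) if p.stderr is not None else float("nan")
        per_series.append(entry)
    residual = best.residual
    return BindingFit(
        kd=kd,
        kd_se=kd_se,
        per_series=per_series,
        n_series=len(series),
        n_points=int(sum(rec.lipid_mM.size for rec in series)),
        converged=True,
        at_bound=at_bound,
        redchi=float(best.redchi),
        residual_rms=float(np.sqrt(np.mean(residual**2))),
        message=str(best.message),
    )


def affinity_ratio(fit_a: BindingFit, fit_b: BindingFit) -> AffinityRatio:
    """Kd_a / Kd_b with first-order (delta-method) error propagation."""
    if not (fit_a.converged and fit_b.converged):
        raise ValidationError("affinity ratio requires two converged fits")
    ratio = fit_a.kd / fit_b.kd
    rel = np.hypot(fit_a.kd_se / fit_a.kd, fit_b.kd_se / fit_b.kd)
    return AffinityRatio(ratio=ratio, se=abs(ratio) * float(rel))


def normalized_bound_fraction(fit: BindingFit, series_index: int, intensity):
    """Convert measured intensities to the bound-fraction axis of the fit."""
    entry = fit.per_series[series_index]
    span = entry["Fmax"] - entry["F0"]
    if span == 0:
        raise ValidationError("degenerate series: Fmax equals F0")
    return (np.asarray(intensity, dtype=float) - entry["F0"]) / span
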