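"""Orchestration: run every analysis over a manifest and emit report tables.

A manifest lists XY-ASCII records (path, kind, optional metadata overrides).
Records are grouped by membrane composition; titrations feed the global Kd
fit, quenching pairs the depth-localization summary, CW spectra the
regime-appropriate observable (T-PC parameters, order parameter,
correlation times, 2Az) and SR decay pairs the oxygen transport profile.
Outputs are pandas tables plus one machine-readable JSON results file.
"""
from __future__ import annotations

import json
import logging
import os
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import binding, cwepr, quenching, srepr, synth
from .config import RunConfig
from .exceptions import LipospinError, ValidationError
from .io import read_manifest, read_xy_table, write_manifest, write_xy_table
from .quenching import QuenchingRecord
from .types import (
    Atmosphere,
    FieldSpectrum,
    MembraneComposition,
    NitroxideTensor,
    Regime,
    SpinLabelPosition,
    SRDecay,
    TitrationSeries,
    celsius_to_kelvin,
)

__all__ = ["ReportBundle", "run_pipeline", "make_demo_dataset"]

log = logging.getLogger("lipospin")


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run plus failure diagnostics."""

    tables: Dict[str, pd.DataFrame] = field(default_factory=dict)
    results: dict = field(default_factory=dict)
    failures: List[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def _comp_key(composition: Optional[MembraneComposition]) -> str:
    return composition.label() if composition is not None else "unknown"


def _load_records(manifest_path) -> list[tuple[str, str, object]]:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    entries = read_manifest(manifest_path)
    missing = [e["path"] for e in entries if not (base / e["path"]).exists()]
    if missing:
        raise ValidationError("manifest references missing files: " + ", ".join(missing))
    records = []
    for entry in entries:
        rec = read_xy_table(base / entry["path"], entry["kind"])
        records.append((entry["path"], entry["kind"], rec))
    return records


def _analyze_binding(groups, cfg: RunConfig, bundle: ReportBundle) -> None:
    rows = []
    fits = {}
    for comp, series in sorted(groups.items()):
        fit = binding.fit_kd_global(
            series, use_depletion=cfg.binding.use_depletion, n_starts=cfg.binding.n_starts
        )
        fits[comp] = fit
        log.info("binding %s: Kd = %.4g +- %.2g µM (converged=%s)", comp, fit.kd, fit.kd_se, fit.converged)
        rows.append(
            {"composition": comp, "Kd_uM": fit.kd, "Kd_se_uM": fit.kd_se,
             "n_series": fit.n_series, "converged": fit.converged}
        )
    bundle.tables["binding"] = pd.DataFrame(rows)
    bundle.results["binding"] = {
        comp: {"Kd_uM": fit.kd, "Kd_se_uM": fit.kd_se} for comp, fit in fits.items()
    }
    ratios = {}
    for plain, peg in (("DMPC", "DMPC-PEG"), ("POPC", "POPC-PEG")):
        if plain in fits and peg in fits:
            r = binding.affinity_ratio(fits[plain], fits[peg])
            ratios[f"{plain}/{peg}"] = {"ratio": r.ratio, "se": r.se}
    if ratios:
        bundle.results["affinity_ratios"] = ratios


def _analyze_quenching(records: List[QuenchingRecord], cfg: RunConfig, bundle: ReportBundle) -> None:
    rows = []
    per_comp: dict = defaultdict(dict)
    for rec in records:
        pos = rec.quencher_position
        rows.append(
            {"composition": _comp_key(rec.composition),
             "position": pos.value if pos else "?",
             "incubation_h": rec.incubation_h,
             "remaining_pct": rec.remaining_pct}
        )
        if pos is not None:
            per_comp[_comp_key(rec.composition)][pos] = rec.remaining_pct
    summary = {}
    for comp, remaining in sorted(per_comp.items()):
        if SpinLabelPosition.C5 in remaining and SpinLabelPosition.C16 in remaining:
            cls = quenching.localization_summary(
                remaining,
                threshold_significant=cfg.quenching.threshold_significant,
                threshold_equal=cfg.quenching.threshold_equal,
            )
            summary[comp] = {
                "C5_remaining_pct": remaining[SpinLabelPosition.C5],
                "C16_remaining_pct": remaining[SpinLabelPosition.C16],
                "localization": cls.value,
            }
            log.info("quenching %s: %s", comp, cls.value)
    bundle.tables["quenching"] = pd.DataFrame(rows)
    if summary:
        bundle.results["quenching"] = summary


def _analyze_cw(spectra: List[FieldSpectrum], cfg: RunConfig, bundle: ReportBundle) -> None:
    tensor = NitroxideTensor(cfg.tensor.Axx, cfg.tensor.Ayy, cfg.tensor.Azz)
    tau_rows, tpc_rows, order_rows, polarity_rows = [], [], [], []
    polarity_by_comp: dict = defaultdict(list)
    for spec in spectra:
        comp = _comp_key(spec.meta.composition)
        label = spec.meta.label.value if spec.meta.label else "?"
        temp = spec.meta.temperature_K
        if spec.meta.regime is Regime.FROZEN:
            two_az = cwepr.extract_2Az(spec)
            polarity_rows.append(
                {"composition": comp, "position": label, "two_Az_G": two_az}
            )
            if spec.meta.label is not None:
                polarity_by_comp[comp].append((spec.meta.label, two_az, 0.0))
            log.info("cw polarity %s/%s: 2Az = %.2f G", comp, label, two_az)
        elif spec.meta.regime is Regime.SLOW:
            pair = cwepr.extract_outer_inner_splittings(
                spec, window=max(cfg.smoothing.window, 31), polyorder=cfg.smoothing.polyorder
            )
            res = cwepr.order_parameter(
                pair, tensor,
                inner_correction=cfg.calibration.inner_correction,
                correction_gauss=cfg.calibration.inner_correction_gauss,
            )
            order_rows.append(
                {"composition": comp, "position": label, "temperature_K": temp,
                 "S": res.S, "flagged": res.flagged}
            )
            log.info("cw order %s/%s: S = %.3f", comp, label, res.S)
        else:
            features = cwepr.extract_line_features(
                spec, window=cfg.smoothing.window, polyorder=cfg.smoothing.polyorder
            )
            if spec.meta.label is SpinLabelPosition.TPC:
                # headgroup probe: report its motional-freedom readouts, not tau
                params = cwepr.tpc_params(features)
                tpc_rows.append(
                    {"composition": comp, "temperature_K": temp,
                     "dh_plus_G": params["dh_plus"],
                     "h0_over_hminus": params["h0_over_hminus"]}
                )
                log.info("cw tpc %s: dh+ = %.3f G", comp, params["dh_plus"])
            else:
                tau = cwepr.correlation_times(features, cfg.calibration.k_B, cfg.calibration.k_C)
                tau_rows.append(
                    {"composition": comp, "position": label, "temperature_K": temp,
                     "tau_2B_ns": tau.tau_2B_ns, "tau_2C_ns": tau.tau_2C_ns,
                     "gap_ns": tau.anisotropy_gap_ns, "flagged": tau.flagged}
                )
                log.info("cw tau %s/%s: tau2B = %.3f ns tau2C = %.3f ns", comp, label, tau.tau_2B_ns, tau.tau_2C_ns)
    for name, rows in (
        ("cw_tau", tau_rows), ("cw_tpc", tpc_rows),
        ("cw_order", order_rows), ("cw_polarity", polarity_rows),
    ):
        if rows:
            bundle.tables[name] = pd.DataFrame(rows)
    if order_rows:
        bundle.results["order_parameters"] = {
            f"{r['composition']}/{r['position']}": r["S"] for r in order_rows
        }
    if tau_rows:
        bundle.results["correlation_times"] = {
            f"{r['composition']}/{r['position']}": {
                "tau_2B_ns": r["tau_2B_ns"], "tau_2C_ns": r["tau_2C_ns"], "gap_ns": r["gap_ns"]
            }
            for r in tau_rows
        }
    if polarity_rows:
        bundle.results["polarity_2Az_G"] = {
            f"{r['composition']}/{r['position']}": r["two_Az_G"] for r in polarity_rows
        }
    profiles = {
        comp: srepr.build_profile(entries, kind="polarity")
        for comp, entries in polarity_by_comp.items()
        if len(entries) >= 2
    }
    if profiles:
        bundle.results["polarity_profiles"] = {
            comp: {p.value: prof.values[p] for p in prof.positions}
            for comp, prof in profiles.items()
        }


def _analyze_sr(decays: List[SRDecay], cfg: RunConfig, bundle: ReportBundle) -> None:
    grouped: dict = defaultdict(dict)
    for decay in decays:
        key = (_comp_key(decay.meta.composition), decay.meta.label)
        grouped[key][decay.atmosphere] = decay
    rows = []
    otp_by_comp: dict = defaultdict(list)
    for (comp, label), pair in sorted(grouped.items(), key=lambda kv: str(kv[0])):
        if Atmosphere.AIR not in pair or Atmosphere.N2 not in pair:
            log.warning("sr %s/%s: incomplete air/N2 pair; skipped", comp, label)
            continue
        fit_air = srepr.fit_t1(pair[Atmosphere.AIR], t_cutoff=cfg.sr.t_cutoff_us)
        fit_n2 = srepr.fit_t1(pair[Atmosphere.N2], t_cutoff=cfg.sr.t_cutoff_us)
        otp = srepr.compute_otp(fit_air, fit_n2)
        rows.append(
            {"composition": comp, "position": label.value if label else "?",
             "T1_air_us": fit_air.T1, "T1_N2_us": fit_n2.T1,
             "W_per_us": otp.W, "W_se_per_us": otp.W_se}
        )
        log.info("sr %s/%s: W = %.3f +- %.3f 1/µs", comp, label.value if label else "?", otp.W, otp.W_se)
        if label is not None:
            otp_by_comp[comp].append(otp)
    if rows:
        bundle.tables["sr_otp"] = pd.DataFrame(rows)
        bundle.results["otp"] = {
            f"{r['composition']}/{r['position']}": {"W_per_us": r["W_per_us"], "W_se_per_us": r["W_se_per_us"]}
            for r in rows
        }
    profiles = {
        comp: srepr.build_profile(entries, kind="otp")
        for comp, entries in otp_by_comp.items()
        if len(entries) >= 2
    }
    if profiles:
        bundle.results["otp_profiles"] = {
            comp: {p.value: prof.values[p] for p in prof.positions}
            for comp, prof in profiles.items()
        }


def run_pipeline(config: RunConfig, manifest_path, out_dir=None) -> ReportBundle:
    """Run every applicable analysis over the manifest's records.

    Deterministic given inputs; partial failures are isolated per analysis
    group and collected in ``bundle.failures`` rather than aborting the run.
    """
    config.validate()
    records = _load_records(manifest_path)
    bundle = ReportBundle()

    titr_groups: dict = defaultdict(list)
    quench_records: List[QuenchingRecord] = []
    spectra: List[FieldSpectrum] = []
    decays: List[SRDecay] = []
    for path, kind, rec in records:
        if isinstance(rec, TitrationSeries):
            titr_groups[_comp_key(rec.composition)].append(rec)
        elif isinstance(rec, QuenchingRecord):
            quench_records.append(rec)
        elif isinstance(rec, FieldSpectrum):
            spectra.append(rec)
        elif isinstance(rec, SRDecay):
            decays.append(rec)

    stages = []
    if titr_groups:
        stages.append(("binding", lambda: _analyze_binding(titr_groups, config, bundle)))
    if quench_records:
        stages.append(("quenching", lambda: _analyze_quenching(quench_records, config, bundle)))
    if spectra:
        stages.append(("cw", lambda: _analyze_cw(spectra, config, bundle)))
    if decays:
        stages.append(("sr", lambda: _analyze_sr(decays, config, bundle)))
    for name, stage in stages:
        try:
            stage()
        except LipospinError as exc:
            log.error("stage %s failed: %s", name, exc)
            bundle.failures.append({"stage": name, "error": str(exc)})

    if out_dir is not None:
        out_dir = Path(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        for name, table in bundle.tables.items():
            table.to_csv(out_dir / f"{name}.csv", index=False)
        with open(out_dir / "results.json", "w", encoding="ascii") as fh:
            json.dump(bundle.results, fh, indent=2, sort_keys=True)
    return bundle


# ---------------------------------------------------------------------------
# shipped synthetic study


def _compositions() -> Dict[str, MembraneComposition]:
    return {
        "DMPC": MembraneComposition("DMPC"),
        "DMPC-PEG": MembraneComposition("DMPC", peg_molpct=7.0, peg_anchor="14:0-PEG2000-PE"),
        "DMPC-CUR": MembraneComposition("DMPC", curcumin_molpct=10.0),
        "POPC": MembraneComposition("POPC"),
        "POPC-PEG": MembraneComposition("POPC", peg_molpct=7.0, peg_anchor="18:0-PEG2000-PE"),
        "POPC-CUR": MembraneComposition("POPC", curcumin_molpct=10.0),
    }


#: generating truths of the shipped demo study (see docs/methods.md)
DEMO_KD_UM = {"DMPC": 263.0, "DMPC-PEG": 88.0, "POPC": 270.0, "POPC-PEG": 156.0}
DEMO_REMAINING = {
    "DMPC": {"C5": 0.63, "C16": 0.78},
    "DMPC-PEG": {"C5": 0.62, "C16": 0.64},
    "POPC": {"C5": 0.46, "C16": 0.58},
    "POPC-PEG": {"C5": 0.55, "C16": 0.71},
}
DEMO_TAUS_NS = {  # 16-PC at 25 °C: (tau_2B, tau_2C)
    "DMPC": (1.19, 1.30), "DMPC-CUR": (1.44, 2.03), "DMPC-PEG": (1.34, 1.50),
    "POPC": (1.07, 1.22), "POPC-CUR": (1.15, 1.33),
}
DEMO_S = {  # 5-PC at 25 °C
    "DMPC": 0.63, "DMPC-PEG": 0.64, "DMPC-CUR": 0.66,
    "POPC": 0.635, "POPC-PEG": 0.645, "POPC-CUR": 0.66,
}
DEMO_2AZ_G = {  # polarity profiles; headgroup values are consistent choices
    "DMPC": {"TPC": 71.0, "C5": 69.0, "C16": 68.25},
    "DMPC-CUR": {"TPC": 73.5, "C5": 69.65, "C16": 68.64},
    "POPC": {"C5": 68.9, "C16": 67.5},
    "POPC-PEG": {"C5": 69.31, "C16": 68.35},
}
DEMO_W_PER_US = {  # oxygen transport profiles; consistent endpoint choices
    "DMPC": {"TPC": 1.0, "C5": 1.2, "C16": 2.7},
    "DMPC-CUR": {"TPC": 0.2, "C5": 0.5, "C16": 1.3},
}


def make_demo_dataset(out_dir, seed: int = 0, noise_sigma: float = 0.01) -> Path:
    """Write the shipped synthetic study and return its manifest path.

    Generating truths are the study conditions of the package's reference
    tables: per-composition Kd values, quenching fractions, correlation
    times, order parameters, polarity (2Az) and oxygen-transport profiles.
    Same seed, same bytes.
    """
    out_dir = Path(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    comps = _compositions()
    entries = []
    truths: dict = {}
    counter = 0

    def next_seed() -> int:
        nonlocal counter
        counter += 1
        return (seed * 1000 + counter) % (2**31 - 1)

    t25 = celsius_to_kelvin(25.0)
    for comp_label, kd in DEMO_KD_UM.items():
        series = synth.gen_titration(
            kd, noise_sigma=noise_sigma, seed=next_seed(), composition=comps[comp_label]
        )
        for i, rec in enumerate(series):
            name = f"titration-{comp_label}-{i}.dat"
            write_xy_table(rec, out_dir / name)
            entries.append({"path": name, "kind": "titration"})
        truths[f"Kd_uM/{comp_label}"] = kd

    for comp_label, fractions in DEMO_REMAINING.items():
        for pos_name, fraction in fractions.items():
            control, sample = synth.gen_quenching_pair(
                fraction, noise_sigma=noise_sigma / 2.0, seed=next_seed()
            )
            rec = QuenchingRecord(
                control_intensity=control,
                sample_intensity=sample,
                quencher_position=SpinLabelPosition(pos_name),
                incubation_h=0.5,
                composition=comps[comp_label],
            )
            name = f"quenching-{comp_label}-{pos_name}.dat"
            write_xy_table(rec, out_dir / name)
            entries.append({"path": name, "kind": "quenching"})
            truths[f"remaining_pct/{comp_label}/{pos_name}"] = 100.0 * fraction

    for comp_label, (tau_b, tau_c) in DEMO_TAUS_NS.items():
        widths = synth.fast_motion_widths_for_taus(tau_b, tau_c)
        spec = synth.gen_fast_motion_spectrum(
            widths, noise_sigma=noise_sigma, seed=next_seed(),
            label=SpinLabelPosition.C16, temperature_K=t25, composition=comps[comp_label],
        )
        name = f"cw-fast-{comp_label}-C16.dat"
        write_xy_table(spec, out_dir / name)
        entries.append({"path": name, "kind": "spectrum"})
        truths[f"tau_ns/{comp_label}/C16"] = [tau_b, tau_c]

    # T-PC headgroup pair: curcumin narrows the low-field line by ~20 %
    # and drops h0/h- by ~5 %
    for comp_label, dh_plus, g_minus in (("DMPC", 1.5, 2.0), ("DMPC-CUR", 1.2, 1.95)):
        spec = synth.gen_fast_motion_spectrum(
            (dh_plus, 1.8, g_minus), noise_sigma=noise_sigma, seed=next_seed(),
            label=SpinLabelPosition.TPC, temperature_K=t25, composition=comps[comp_label],
        )
        name = f"cw-fast-{comp_label}-TPC.dat"
        write_xy_table(spec, out_dir / name)
        entries.append({"path": name, "kind": "spectrum"})
        truths[f"dh_plus_G/{comp_label}/TPC"] = dh_plus

    for comp_label, s_true in DEMO_S.items():
        target = cwepr.invert_order_parameter(s_true)
        spec = synth.gen_slow_motion_for_observed(
            target.two_Amax, target.two_Amin, noise_sigma=noise_sigma, seed=next_seed(),
            label=SpinLabelPosition.C5, temperature_K=t25, composition=comps[comp_label],
        )
        name = f"cw-slow-{comp_label}-C5.dat"
        write_xy_table(spec, out_dir / name)
        entries.append({"path": name, "kind": "spectrum"})
        truths[f"S/{comp_label}/C5"] = s_true

    for comp_label, profile in DEMO_2AZ_G.items():
        for pos_name, two_az in profile.items():
            spec = synth.gen_frozen_for_observed(
                two_az, noise_sigma=noise_sigma, seed=next_seed(),
                label=SpinLabelPosition(pos_name), composition=comps[comp_label],
            )
            name = f"cw-frozen-{comp_label}-{pos_name}.dat"
            write_xy_table(spec, out_dir / name)
            entries.append({"path": name, "kind": "spectrum"})
            truths[f"two_Az_G/{comp_label}/{pos_name}"] = two_az

    for comp_label, profile in DEMO_W_PER_US.items():
        for pos_name, w_true in profile.items():
            air, n2 = synth.gen_sr_pair(
                w_true, noise_sigma=2 * noise_sigma, seed=next_seed(),
                label=SpinLabelPosition(pos_name), composition=comps[comp_label],
            )
            for decay, tag in ((air, "air"), (n2, "N2")):
                name = f"sr-{comp_label}-{pos_name}-{tag}.dat"
                write_xy_table(decay, out_dir / name)
                entries.append({"path": name, "kind": "decay"})
            truths[f"W_per_us/{comp_label}/{pos_name}"] = w_true

    manifest = out_dir / "manifest.yaml"
    write_manifest(entries, manifest)
    with open(out_dir / "truths.yaml", "w", encoding="ascii") as fh:
        yaml.safe_dump({"seed": seed, "noise_sigma": noise_sigma, "truths": truths}, fh)
    return manifest
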