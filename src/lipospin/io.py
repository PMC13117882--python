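"""Plain-text I/O: the XY-ASCII record format and analysis manifests.

A record file is lines of ``# key = value`` metadata followed by two numeric
columns (whitespace- or comma-delimited, decimal point only).  One record per
file.  Round-trips preserve >= 12 significant digits.
"""
from __future__ import annotations

import os
import warnings
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import yaml

from .exceptions import ParseError, ValidationError
from .quenching import QuenchingRecord
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
    "read_xy_table",
    "write_xy_table",
    "read_manifest",
    "write_manifest",
    "write_titration_bundle",
    "read_titration_bundle",
]

_FMT = "%.17g"

Record = Union[FieldSpectrum, SRDecay, TitrationSeries, QuenchingRecord]


def _parse_number(token: str, lineno: int):
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"line {lineno}: non-numeric value {token!r}") from None


def _read_lines(path) -> tuple[dict, np.ndarray, np.ndarray]:
    meta: dict = {}
    xs: List[float] = []
    ys: List[float] = []
    with open(path, "r", encoding="ascii") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            tokens = line.replace(",", " ").split()
            if len(tokens) != 2:
                raise ParseError(
                    f"line {lineno}: expected 2 columns, found {len(tokens)}"
                )
            xs.append(_parse_number(tokens[0], lineno))
            ys.append(_parse_number(tokens[1], lineno))
    return meta, np.asarray(xs), np.asarray(ys)


def _meta_get_float(meta: dict, key: str) -> Optional[float]:
    return float(meta[key]) if key in meta else None


def _composition_from_meta(meta: dict) -> Optional[MembraneComposition]:
    if "host_lipid" not in meta:
        return None
    return MembraneComposition(
        host_lipid=meta["host_lipid"],
        curcumin_molpct=float(meta.get("curcumin_molpct", 0.0)),
        peg_molpct=float(meta.get("peg_molpct", 0.0)),
        peg_anchor=meta.get("peg_anchor") or None,
    )


def _spectrum_meta_from_header(meta: dict) -> SpectrumMeta:
    return SpectrumMeta(
        label=SpinLabelPosition(meta["label"]) if "label" in meta else None,
        temperature_K=_meta_get_float(meta, "temperature_K"),
        composition=_composition_from_meta(meta),
        regime=Regime(meta["regime"]) if "regime" in meta else None,
    )


def _truth_from_header(meta: dict) -> Optional[GroundTruth]:
    params = {
        key[len("truth_") :]: float(value)
        for key, value in meta.items()
        if key.startswith("truth_") and key not in ("truth_seed", "truth_noise_sigma")
    }
    if not params and "truth_seed" not in meta:
        return None
    return GroundTruth(
        params=params,
        seed=int(float(meta.get("truth_seed", -1))),
        noise_sigma=float(meta.get("truth_noise_sigma", 0.0)),
    )


def _sorted_xy(x: np.ndarray, y: np.ndarray, path) -> tuple[np.ndarray, np.ndarray]:
    if np.any(np.diff(x) < 0):
        warnings.warn(f"{path}: rows were not sorted by x; sorting", stacklevel=3)
        order = np.argsort(x, kind="stable")
        return x[order], y[order]
    return x, y


def read_xy_table(path, kind: str) -> Record:
    """Read one XY-ASCII record of the given kind.

    ``kind`` is one of ``spectrum``, ``decay``, ``titration`` or
    ``quenching``.  Metadata in ``# key = value`` header lines populates the
    record; rows are sorted by the x column (with a warning) if needed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta, x, y = _read_lines(path)
    smeta = _spectrum_meta_from_header(meta)
    truth = _truth_from_header(meta)
    if kind == "spectrum":
        x, y = _sorted_xy(x, y, path)
        return FieldSpectrum(field=x, intensity=y, meta=smeta, truth=truth)
    if kind == "decay":
        x, y = _sorted_xy(x, y, path)
        atmosphere = Atmosphere(meta.get("atmosphere", "air"))
        return SRDecay(time=x, signal=y, atmosphere=atmosphere, meta=smeta, truth=truth)
    if kind == "titration":
        x, y = _sorted_xy(x, y, path)
        return TitrationSeries(
            lipid_mM=x,
            intensity=y,
            series_id=meta.get("series_id", path.stem),
            curcumin_uM=float(meta.get("curcumin_uM", 2.0)),
            composition=_composition_from_meta(meta),
            truth=truth,
        )
    if kind == "quenching":
        if x.size != 1:
            raise ParseError(
                f"{path}: quenching record must hold exactly one (control, sample) row"
            )
        return QuenchingRecord(
            control_intensity=float(x[0]),
            sample_intensity=float(y[0]),
            quencher_position=SpinLabelPosition(meta["quencher_position"])
            if "quencher_position" in meta
            else None,
            incubation_h=_meta_get_float(meta, "incubation_h"),
            composition=_composition_from_meta(meta),
        )
    raise ValidationError(f"unknown record kind {kind!r}")


def _header_items(record: Record) -> Iterable[tuple[str, object]]:
    comp = getattr(record, "composition", None)
    meta = getattr(record, "meta", None)
    if meta is not None:
        comp = meta.composition
        if meta.label is not None:
            yield "label", meta.label.value
        if meta.temperature_K is not None:
            yield "temperature_K", meta.temperature_K
        if meta.regime is not None:
            yield "regime", meta.regime.value
    if comp is not None:
        yield "host_lipid", comp.host_lipid
        yield "curcumin_molpct", comp.curcumin_molpct
        yield "peg_molpct", comp.peg_molpct
        if comp.peg_anchor:
            yield "peg_anchor", comp.peg_anchor
    if isinstance(record, SRDecay):
        yield "atmosphere", record.atmosphere.value
    if isinstance(record, TitrationSeries):
        yield "series_id", record.series_id
        yield "curcumin_uM", record.curcumin_uM
    if isinstance(record, QuenchingRecord):
        if record.quencher_position is not None:
            yield "quencher_position", record.quencher_position.value
        if record.incubation_h is not None:
            yield "incubation_h", record.incubation_h
    truth = getattr(record, "truth", None)
    if truth is not None:
        yield "truth_seed", truth.seed
        yield "truth_noise_sigma", truth.noise_sigma
        for key, value in sorted(truth.params.items()):
            yield f"truth_{key}", value


def _xy_of(record: Record) -> tuple[np.ndarray, np.ndarray, str]:
    if isinstance(record, FieldSpectrum):
        return record.field, record.intensity, "spectrum"
    if isinstance(record, SRDecay):
        return record.time, record.signal, "decay"
    if isinstance(record, TitrationSeries):
        return record.lipid_mM, record.intensity, "titration"
    if isinstance(record, QuenchingRecord):
        return (
            np.asarray([record.control_intensity]),
            np.asarray([record.sample_intensity]),
            "quenching",
        )
    raise ValidationError(f"cannot serialize object of type {type(record).__name__}")


def write_xy_table(record: Record, path) -> None:
    """Write a record as XY-ASCII, readable back by :func:`read_xy_table`."""
    x, y, kind = _xy_of(record)
    path = Path(path)
    with open(path, "w", encoding="ascii") as fh:
        fh.write(f"# kind = {kind}\n")
        for key, value in _header_items(record):
            if isinstance(value, float):
                value = _FMT % value
            fh.write(f"# {key} = {value}\n")
        for xi, yi in zip(x, y):
            fh.write(f"{_FMT % xi} {_FMT % yi}\n")


def write_manifest(entries: Sequence[dict], path) -> None:
    """Write a manifest: a YAML list of ``{path, kind}`` entries."""
    with open(path, "w", encoding="ascii") as fh:
        yaml.safe_dump({"records": list(entries)}, fh, sort_keys=False)


def read_manifest(path) -> List[dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "r", encoding="ascii") as fh:
        payload = yaml.safe_load(fh) or {}
    entries = payload.get("records", [])
    for entry in entries:
        if "path" not in entry or "kind" not in entry:
            raise ValidationError("manifest entries need 'path' and 'kind'")
    return entries


def write_titration_bundle(
    series: Sequence[TitrationSeries], directory, prefix: str = "titration"
) -> Path:
    """Write one file per replicate plus a manifest; returns the manifest path."""
    directory = Path(directory)
    os.makedirs(directory, exist_ok=True)
    entries = []
    for i, rec in enumerate(series):
        name = f"{prefix}-{i}.dat"
        write_xy_table(rec, directory / name)
        entries.append({"path": name, "kind": "titration"})
    manifest = directory / f"{prefix}-manifest.yaml"
    write_manifest(entries, manifest)
    return manifest


def read_titration_bundle(manifest_path) -> List[TitrationSeries]:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    out = []
    for entry in read_manifest(manifest_path):
        if entry["kind"] != "titration":
            continue
        out.append(read_xy_table(base / entry["path"], "titration"))
    return out
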