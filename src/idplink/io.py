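"""Readers and writers for the on-disk formats.

Supported formats:

* reduced SAXS 1D profile: whitespace/comma-delimited text, columns
  ``q  I(q)  [sigma]``, ``#`` comment lines (the de facto ``.dat`` standard);
* frame series: one wide CSV (``q`` column plus one intensity column per
  frame) or per-frame ``.dat`` files listed in a manifest (1-based frame
  numbers, beamline convention, converted to 0-based on load);
* UV trace: two-column CSV (time s, A280 AU);
* kinetic and endpoint plates: long-format CSV;
* step-field ion-mobility data: CSV with columns ``delta_v, t_a, intensity``;
* results: JSON via :mod:`idplink.results`;
* configuration: flat YAML mirroring :class:`idplink.datatypes.AnalysisConfig`.

The internal q unit is nm^-1; profiles read with ``q_unit="A^-1"`` are
converted (multiplied by 10) on load.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    AnalysisConfig,
    Instrument,
    KineticTrace,
    PlateData,
    SAXSProfile,
    StepFieldData,
    FrameSeries,
    ValidationError,
)
from .results import FitResult, result_from_dict

__all__ = [
    "read_saxs_profile",
    "write_saxs_profile",
    "read_frame_series",
    "read_kinetic_csv",
    "read_plate_csv",
    "read_stepfield_csv",
    "write_result",
    "read_result",
    "load_config",
]

logger = logging.getLogger("idplink")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


def _q_scale(q_unit: str) -> float:
    if q_unit in ("nm^-1", "nm-1", "1/nm"):
        return 1.0
    if q_unit in ("A^-1", "A-1", "1/A", "angstrom^-1"):
        return 10.0
    raise ValidationError(f"unknown q unit {q_unit!r}")


def read_saxs_profile(path, q_unit: str = "nm^-1", label: str | None = None) -> SAXSProfile:
    """Read a reduced 1D profile; q is converted to nm^-1.

    Rows containing non-finite values are dropped (the count is logged).
    Malformed numeric fields raise :class:`ParseError` naming the line.
    """
    path = Path(path)
    scale = _q_scale(q_unit)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.replace(",", " ").split()
            if len(parts) not in (2, 3):
                raise ParseError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed numeric field: {exc}") from None
    if not rows:
        raise ParseError(f"{path}: no data rows")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ParseError(f"{path}: inconsistent column count")
    arr = np.asarray(rows, dtype=float)
    finite = np.all(np.isfinite(arr), axis=1)
    if not np.all(finite):
        logger.info("%s: dropped %d non-finite rows", path, int((~finite).sum()))
        arr = arr[finite]
    sigma = arr[:, 2] * 1.0 if ncol == 3 else None
    return SAXSProfile(
        q=arr[:, 0] * scale,
        intensity=arr[:, 1],
        sigma=sigma,
        label=label if label is not None else path.stem,
    )


def write_saxs_profile(profile: SAXSProfile, path) -> None:
    cols = [profile.q, profile.intensity]
    header = "q_nm^-1 intensity"
    if profile.sigma is not None:
        cols.append(profile.sigma)
        header += " sigma"
    np.savetxt(path, np.column_stack(cols), header=header, fmt="%.17g")


def _read_uv(uv_path) -> np.ndarray:
    uv = pd.read_csv(uv_path, comment="#")
    if uv.shape[1] < 2:
        raise ParseError(f"{uv_path}: UV trace needs two columns (time, A280)")
    return uv.iloc[:, :2].to_numpy(dtype=float)


def read_frame_series(frames_path, uv_path=None, q_unit: str = "nm^-1") -> FrameSeries:
    """Read a SEC-SAXS/batch frame series.

    ``frames_path`` is either a wide CSV (``q`` column then one intensity
    column per frame, optional ``time_<label>`` naming ignored) or a manifest
    text file listing per-frame ``.dat`` paths, one per line, 1-based order.
    All frames must share one q grid to within a 1e-9 relative tolerance.
    """
    frames_path = Path(frames_path)
    uv = _read_uv(uv_path) if uv_path is not None else None
    if frames_path.suffix.lower() == ".csv":
        df = pd.read_csv(frames_path, comment="#")
        q = df.iloc[:, 0].to_numpy(dtype=float) * _q_scale(q_unit)
        frames = [
            SAXSProfile(q=q, intensity=df[col].to_numpy(dtype=float), label=str(col))
            for col in df.columns[1:]
        ]
        times = np.arange(len(frames), dtype=float)
    else:  # manifest of per-frame .dat files
        names = [
            ln.strip()
            for ln in frames_path.read_text().splitlines()
            if ln.strip() and not ln.strip().startswith("#")
        ]
        frames = [
            read_saxs_profile(frames_path.parent / name, q_unit=q_unit) for name in names
        ]
        times = np.arange(len(frames), dtype=float)
    series = FrameSeries(frames=frames, times=times, uv=uv)
    if uv is not None:
        t0, t1 = series.times[0], series.times[-1]
        if uv[:, 0].min() < t0 or uv[:, 0].max() > t1:
            logger.warning("UV trace times extend outside the frame time span")
    return series


def read_kinetic_csv(path) -> list[KineticTrace]:
    """Read a long-format kinetic plate CSV.

    Columns: ``condition, replicate, time_h, signal``.  Returns one trace per
    (condition, replicate) pair, sorted by time.
    """
    df = pd.read_csv(path, comment="#")
    required = {"condition", "replicate", "time_h", "signal"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: kinetic CSV needs columns {sorted(required)}")
    traces = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=True):
        grp = grp.sort_values("time_h")
        traces.append(
            KineticTrace(
                time=grp["time_h"].to_numpy(dtype=float),
                signal=grp["signal"].to_numpy(dtype=float),
                condition=str(cond),
                replicate=int(rep),
            )
        )
    return traces


def read_plate_csv(path) -> PlateData:
    """Read an endpoint turbidity plate CSV: ``concentration_uM, replicate, absorbance``."""
    df = pd.read_csv(path, comment="#")
    required = {"concentration_uM", "replicate", "absorbance"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: plate CSV needs columns {sorted(required)}")
    return PlateData(
        concentration_um=df["concentration_uM"].to_numpy(dtype=float),
        replicate=df["replicate"].to_numpy(dtype=int),
        absorbance=df["absorbance"].to_numpy(dtype=float),
    )


def read_stepfield_csv(path, instrument: Instrument | None = None) -> StepFieldData:
    """Read step-field IMS data: ``delta_v, t_a, intensity`` long-format CSV."""
    df = pd.read_csv(path, comment="#")
    required = {"delta_v", "t_a", "intensity"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: step-field CSV needs columns {sorted(required)}")
    records = []
    for dv, grp in df.groupby("delta_v", sort=True):
        grp = grp.sort_values("t_a")
        records.append(
            (
                float(dv),
                grp["t_a"].to_numpy(dtype=float),
                grp["intensity"].to_numpy(dtype=float),
            )
        )
    return StepFieldData(records=records, instrument=instrument or Instrument())


def write_result(result: FitResult, path) -> None:
    """Write a fit result as JSON; reading it back reproduces all numeric
    fields exactly for finite doubles."""
    from . import __version__

    record = result.to_dict()
    record["software_version"] = __version__
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=1)


def read_result(path) -> FitResult:
    with open(path) as fh:
        record = json.load(fh)
    return result_from_dict(record)


def load_config(path=None, **overrides) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML; keyword overrides win."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ParseError(f"{path}: config must be a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**values)
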