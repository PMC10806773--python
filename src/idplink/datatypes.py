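"""In-memory containers shared by every analysis stage.

All momentum transfers are stored in nm^-1 and all radii of gyration in nm;
loaders convert on the way in (see :mod:`idplink.io`).  Times are hours for
plate-reader kinetics and milliseconds for ion-mobility arrival times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "SAXSProfile",
    "FrameSeries",
    "KineticTrace",
    "PlateData",
    "Instrument",
    "StepFieldData",
    "AnalysisConfig",
]


class ValidationError(ValueError):
    """An input violates a structural invariant (shape, ordering, sign)."""


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class SAXSProfile:
    """One reduced 1D scattering curve.

    Parameters
    ----------
    q : array
        Momentum transfer in nm^-1; finite, non-negative, strictly increasing.
    intensity : array
        Scattered intensity, arbitrary units.
    sigma : array, optional
        Standard error of the intensity, same units; strictly positive when
        present.  Absent sigma makes downstream fits fall back to unweighted
        least squares.
    label : str
        Free-text identifier carried through reports.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.q = _as_1d(self.q, "q")
        self.intensity = _as_1d(self.intensity, "intensity")
        if not np.all(np.isfinite(self.q)):
            raise ValidationError("q values must be finite")
        if np.any(self.q < 0):
            raise ValidationError("q values must be non-negative")
        if len(self.q) > 1 and not np.all(np.diff(self.q) > 0):
            raise ValidationError("q must be strictly increasing")
        if len(self.intensity) != len(self.q):
            raise ValidationError("intensity length must match q")
        if self.sigma is not None:
            self.sigma = _as_1d(self.sigma, "sigma")
            if len(self.sigma) != len(self.q):
                raise ValidationError("sigma length must match q")
            if not np.all(self.sigma > 0):
                raise ValidationError("sigma must be strictly positive when present")

    def __len__(self) -> int:
        return len(self.q)


@dataclass
class FrameSeries:
    """Time-ordered SAXS frames on one q grid, with an optional UV trace.

    SEC-SAXS data couple a scattering frame series with an in-line A280
    absorbance trace; batch series carry no UV.
    """

    frames: list[SAXSProfile]
    times: np.ndarray
    uv: np.ndarray | None = None  # shape (n, 2): time s, A280 AU

    Q_GRID_RTOL = 1e-9

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValidationError("frame series must contain at least one frame")
        self.times = _as_1d(self.times, "times")
        if len(self.times) != len(self.frames):
            raise ValidationError("times length must match number of frames")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("frame times must be strictly increasing")
        q0 = self.frames[0].q
        for i, fr in enumerate(self.frames[1:], start=1):
            if len(fr.q) != len(q0) or not np.allclose(
                fr.q, q0, rtol=self.Q_GRID_RTOL, atol=0.0
            ):
                raise ValidationError(f"frame {i} q grid differs from frame 0")
        if self.uv is not None:
            self.uv = np.asarray(self.uv, dtype=float)
            if self.uv.ndim != 2 or self.uv.shape[1] != 2:
                raise ValidationError("uv must have shape (n, 2): time, A280")

    @property
    def q(self) -> np.ndarray:
        return self.frames[0].q

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class KineticTrace:
    """One well's signal versus time (hours), with replicate bookkeeping."""

    time: np.ndarray
    signal: np.ndarray
    condition: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.time = _as_1d(self.time, "time")
        self.signal = _as_1d(self.signal, "signal")
        if len(self.time) < 4:
            raise ValidationError("kinetic trace needs at least 4 points")
        if not np.all(np.diff(self.time) > 0):
            raise ValidationError("time must be strictly increasing")
        if len(self.signal) != len(self.time):
            raise ValidationError("signal length must match time")
        if not np.all(np.isfinite(self.signal)):
            raise ValidationError("signal must be finite")


@dataclass
class PlateData:
    """Endpoint turbidity plate: A500 absorbances by concentration/replicate."""

    concentration_um: np.ndarray
    replicate: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.concentration_um = _as_1d(self.concentration_um, "concentration_um")
        self.replicate = np.asarray(self.replicate, dtype=int)
        self.absorbance = _as_1d(self.absorbance, "absorbance")
        n = len(self.concentration_um)
        if len(self.replicate) != n or len(self.absorbance) != n:
            raise ValidationError("plate columns must have equal length")
        if np.any(self.concentration_um < 0):
            raise ValidationError("concentrations must be non-negative")

    def concentrations(self) -> np.ndarray:
        return np.unique(self.concentration_um)

    def absorbances_at(self, conc: float) -> np.ndarray:
        return self.absorbance[np.isclose(self.concentration_um, conc)]


@dataclass
class Instrument:
    """Drift-tube instrument constants for the step-field analysis.

    Defaults are the drift-tube geometry and conditions of a helium DTIMS
    instrument: L = 78.1 cm, T = 297 K, p = 3.89 Torr.
    """

    drift_length_cm: float = 78.1
    temperature_k: float = 297.0
    pressure_torr: float = 3.89
    charge: int = 1
    ion_mass_da: float | None = None
    gas_mass_da: float = 4.002602  # helium
    # 1-sigma instrument uncertainties used for CCS error propagation
    drift_length_err_cm: float = 0.2
    temperature_err_k: float = 1.0
    pressure_err_torr: float = 0.01

    def __post_init__(self) -> None:
        for name in ("drift_length_cm", "temperature_k", "pressure_torr"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.charge <= 0:
            raise ValidationError("charge must be a positive integer")


@dataclass
class StepFieldData:
    """Arrival-time distributions recorded at several drift voltages.

    ``records`` maps each drift-voltage difference (V) to an arrival-time
    grid (ms) and the intensity per bin.
    """

    records: list[tuple[float, np.ndarray, np.ndarray]]  # (delta_v, t_a, counts)
    instrument: Instrument = field(default_factory=Instrument)
    min_voltages: int = 2

    def __post_init__(self) -> None:
        cleaned = []
        for dv, ta, counts in self.records:
            ta = _as_1d(ta, "arrival_times")
            counts = _as_1d(counts, "counts")
            if len(ta) != len(counts):
                raise ValidationError("arrival-time and count grids must match")
            if np.any(ta <= 0):
                raise ValidationError("arrival times must be positive")
            if dv <= 0:
                raise ValidationError("drift voltage must be positive")
            cleaned.append((float(dv), ta, counts))
        self.records = cleaned
        if len({dv for dv, _, _ in self.records}) < self.min_voltages:
            raise ValidationError(
                f"step-field data need >= {self.min_voltages} distinct voltages"
            )

    @property
    def voltages(self) -> np.ndarray:
        return np.array([dv for dv, _, _ in self.records])


@dataclass
class AnalysisConfig:
    """Run-wide configuration mirrored by the YAML config file and CLI flags."""

    q_unit: str = "nm^-1"  # or "A^-1": converted to nm^-1 on load
    guinier_qmin: float | None = None
    guinier_qmax: float | None = None
    histogram_bins: int = 50
    outlier_threshold: float = 2.0
    extinction_coeff: float = 2800.0  # M^-1 cm^-1
    mw_da: float = 20570.0
    uv_path_cm: float = 1.0
    guinier_limit: float = 1.3
    min_window: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.q_unit not in ("nm^-1", "A^-1"):
            raise ValidationError("q_unit must be 'nm^-1' or 'A^-1'")
        for name in (
            "histogram_bins",
            "outlier_threshold",
            "extinction_coeff",
            "mw_da",
            "uv_path_cm",
            "guinier_limit",
            "min_window",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
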