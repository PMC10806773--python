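"""Step-field drift-tube ion mobility: K0, Mason-Schamp CCS, reconstruction.

At each drift voltage difference dV the arrival time of an ion species is

    tA = t0 + L^2 / (K dV),

so an ordinary least-squares regression of tA on 1/dV separates the raw
mobility K (slope = L^2/K) from the time t0 spent outside the drift region.
K reduces to standard conditions, K0 = K (p/760)(273.15/T), and the
Mason-Schamp relation converts K0 to the orientation-averaged collision
cross section

    CCS = 3 z e / (16 N0) * sqrt(2 pi / (mu kB T)) / K0,

with N0 the buffer-gas number density at standard conditions and mu the
ion-gas reduced mass.  The arrival-time distribution at the lowest voltage
maps linearly onto a CCS distribution, CCS(tA) = a (tA - t0), with the
factor a anchored so the ATD peak center lands on the regression CCS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import Instrument, StepFieldData, ValidationError
from .results import FitResult

__all__ = ["CONSTANTS", "CCSResults", "StepFieldModel",
           "fit_stepfield", "mobility_to_ccs", "reconstruct_ccs_distribution",
           "peak_center"]

# CODATA 2018 exact/recommended values, pinned in one table
CONSTANTS = {
    "e_C": 1.602176634e-19,          # elementary charge
    "kb_J_per_K": 1.380649e-23,      # Boltzmann constant
    "da_kg": 1.66053906660e-27,      # unified atomic mass unit
    "n0_per_m3": 101325.0 / (1.380649e-23 * 273.15),  # Loschmidt number density
    "standard_pressure_torr": 760.0,
    "standard_temperature_k": 273.15,
}

CCS_UNCERTAINTY_FLOOR = 0.020  # combined standard uncertainty incl. calibration


@dataclass
class CCSResults(FitResult):
    k0: float                  # reduced mobility, cm^2 V^-1 s^-1
    t0: float                  # ms
    ccs: float                 # A^2
    ccs_nm2: float
    ccs_uncertainty_rel: float # reported: max(propagated, 2.0% floor)
    propagated_rel: float      # first-order L/T/p propagation alone
    slope: float               # ms * V
    intercept: float           # ms
    r_squared: float
    scale_factor: float        # a, A^2/ms (nan until a reconstruction anchors it)
    n_voltages: int
    warnings: list

    _summary_title = "Step-field ion-mobility CCS"


def peak_center(t_a: np.ndarray, counts: np.ndarray, mode: str = "centroid") -> float:
    """ATD peak center: intensity-weighted centroid within the FWHM window
    (default), or the maximum bin with ``mode="max"``."""
    t_a = np.asarray(t_a, dtype=float)
    counts = np.asarray(counts, dtype=float)
    imax = int(np.argmax(counts))
    if mode == "max":
        return float(t_a[imax])
    if mode != "centroid":
        raise ValidationError(f"unknown peak-center mode {mode!r}")
    half = 0.5 * counts[imax]
    lo = imax
    while lo > 0 and counts[lo - 1] >= half:
        lo -= 1
    hi = imax
    while hi < len(counts) - 1 and counts[hi + 1] >= half:
        hi += 1
    window = slice(lo, hi + 1)
    return float((t_a[window] * counts[window]).sum() / counts[window].sum())


def fit_stepfield(peak_centers: list[tuple[float, float]],
                  instrument: Instrument) -> tuple[float, float, dict]:
    """OLS of tA (ms) on 1/dV: slope -> K0, intercept -> t0.

    Returns (k0 cm^2 V^-1 s^-1, t0 ms, regression dict with slope,
    intercept, r_squared).  A non-positive slope (unphysical mobility)
    raises.
    """
    if len({dv for dv, _ in peak_centers}) < 2:
        raise ValidationError("step-field regression needs >= 2 distinct voltages")
    dv = np.array([v for v, _ in peak_centers], dtype=float)
    ta = np.array([t for _, t in peak_centers], dtype=float)
    x = 1.0 / dv
    slope, intercept = np.polyfit(x, ta, 1)
    pred = intercept + slope * x
    ss_res = float(((ta - pred) ** 2).sum())
    ss_tot = float(((ta - ta.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if slope <= 0:
        raise ValidationError("negative step-field slope: unphysical mobility")
    # slope in ms*V; K = L^2/(slope in s*V)
    k_raw = instrument.drift_length_cm**2 / (slope / 1000.0)
    k0 = (k_raw * (instrument.pressure_torr / CONSTANTS["standard_pressure_torr"])
          * (CONSTANTS["standard_temperature_k"] / instrument.temperature_k))
    return float(k0), float(intercept), {
        "slope": float(slope), "intercept": float(intercept), "r_squared": float(r2)
    }


def mobility_to_ccs(k0: float, instrument: Instrument) -> float:
    """Mason-Schamp CCS (A^2) from the reduced mobility (cm^2 V^-1 s^-1)."""
    if k0 <= 0:
        raise ValidationError("k0 must be positive")
    if instrument.ion_mass_da is None or instrument.gas_mass_da is None:
        raise ValidationError("ion and buffer-gas masses are required for CCS")
    m_ion = instrument.ion_mass_da * CONSTANTS["da_kg"]
    m_gas = instrument.gas_mass_da * CONSTANTS["da_kg"]
    mu = m_ion * m_gas / (m_ion + m_gas)
    kbt = CONSTANTS["kb_J_per_K"] * instrument.temperature_k
    k0_si = k0 * 1.0e-4  # cm^2/Vs -> m^2/Vs
    ccs_m2 = (3.0 * instrument.charge * CONSTANTS["e_C"]
              / (16.0 * CONSTANTS["n0_per_m3"])
              * np.sqrt(2.0 * np.pi / (mu * kbt)) / k0_si)
    return float(ccs_m2 * 1.0e20)  # m^2 -> A^2


def propagated_ccs_uncertainty(instrument: Instrument) -> float:
    """First-order relative CCS uncertainty from the L, T, p uncertainties.

    ln CCS = 2 ln L - ... gives d(lnCCS) contributions 2 dL/L, dp/p and
    (1/2) dT/T, combined in quadrature.
    """
    terms = (
        2.0 * instrument.drift_length_err_cm / instrument.drift_length_cm,
        instrument.pressure_err_torr / instrument.pressure_torr,
        0.5 * instrument.temperature_err_k / instrument.temperature_k,
    )
    return float(np.sqrt(sum(t * t for t in terms)))


def reconstruct_ccs_distribution(t_a: np.ndarray, counts: np.ndarray,
                                 t0: float, ccs_peak: float,
                                 center_mode: str = "centroid"
                                 ) -> tuple[np.ndarray, np.ndarray, float]:
    """Map the lowest-voltage ATD onto a CCS axis.

    CCS(tA) = a (tA - t0) with a = ccs_peak / (tA_peak - t0); intensities
    carry over bin for bin.  Returns (ccs grid A^2, intensities, a).
    """
    t_a = np.asarray(t_a, dtype=float)
    counts = np.asarray(counts, dtype=float)
    ta_peak = peak_center(t_a, counts, mode=center_mode)
    if ta_peak <= t0:
        raise ValidationError("ATD peak center does not exceed t0")
    a = ccs_peak / (ta_peak - t0)
    return a * (t_a - t0), counts.copy(), float(a)


class StepFieldModel:
    """Full step-field analysis of one :class:`StepFieldData`.

    ``fit()`` locates the ATD peak center at every voltage, regresses tA on
    1/dV for (K0, t0), converts K0 to a Mason-Schamp CCS and anchors the
    CCS-distribution scale factor at the lowest voltage.
    """

    def __init__(self, data: StepFieldData, center_mode: str = "centroid"):
        self.data = data
        self.center_mode = center_mode
        self.distribution_: tuple[np.ndarray, np.ndarray] | None = None

    def fit(self) -> CCSResults:
        inst = self.data.instrument
        centers = [
            (dv, peak_center(ta, counts, self.center_mode))
            for dv, ta, counts in self.data.records
        ]
        warnings = []
        if len(centers) < 5:
            warnings.append("fewer than the recommended 5 drift voltages")
        k0, t0, reg = fit_stepfield(centers, inst)
        ccs = mobility_to_ccs(k0, inst)
        prop = propagated_ccs_uncertainty(inst)
        rel = max(prop, CCS_UNCERTAINTY_FLOOR)
        # reconstruction at the lowest voltage
        dv_low, ta_low, counts_low = min(self.data.records, key=lambda r: r[0])
        scale = float("nan")
        try:
            ccs_grid, inten, scale = reconstruct_ccs_distribution(
                ta_low, counts_low, t0, ccs, self.center_mode
            )
            self.distribution_ = (ccs_grid, inten)
        except ValidationError as exc:
            warnings.append(f"CCS-distribution reconstruction skipped: {exc}")
        return CCSResults(
            k0=k0, t0=t0, ccs=ccs, ccs_nm2=ccs / 100.0,
            ccs_uncertainty_rel=rel, propagated_rel=prop,
            slope=reg["slope"], intercept=reg["intercept"],
            r_squared=reg["r_squared"], scale_factor=scale,
            n_voltages=len(centers), warnings=warnings,
        )
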