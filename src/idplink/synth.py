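"""Synthetic datasets with the statistical structure each analysis assumes.

Every generator is a pure function of its parameters and seed, and each
dataset can be written with a ``truth`` record of the generating parameters
so that downstream parameter recovery is checkable without external data.
The generators emulate:

* disordered-chain scattering with known Rg (Debye function of an ideal
  Gaussian chain) or known Flory exponent (self-avoiding-walk ensembles);
* SEC-SAXS elution series whose forward intensities follow the virial
  relation K*c/I(0,c) = 1/Mw + 2*A2*c, with a synchronized UV trace;
* sigmoidal ThT aggregation traces with replicate noise;
* endpoint turbidity plates with a step at a known saturation concentration;
* step-field ion-mobility arrival-time distributions with a known reduced
  mobility and dead time.

Noise is Gaussian throughout: reduced SAXS profiles and plate readers report
near-Gaussian errors, and recording the applied sd in the sigma column keeps
chi-square diagnostics meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .datatypes import (
    FrameSeries,
    Instrument,
    KineticTrace,
    PlateData,
    SAXSProfile,
    StepFieldData,
)
from .saw import ChainEnsemble, random_walk_ensemble, saw_ensemble  # noqa: F401

__all__ = [
    "SyntheticTruth",
    "debye_function",
    "debye_profile",
    "saw_ensemble",
    "random_walk_ensemble",
    "scattering_from_ensemble",
    "sec_saxs_series",
    "tht_traces",
    "llps_plate",
    "ims_arrival",
]


@dataclass
class SyntheticTruth:
    """Ground-truth parameters recorded alongside a generated dataset."""

    params: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.params[key]

    def to_dict(self) -> dict:
        return dict(self.params)


def debye_function(x: np.ndarray) -> np.ndarray:
    """Gaussian-chain form factor D(x) = 2(e^-x + x - 1)/x^2, x = (q*Rg)^2.

    D(0) = 1 by the series limit; evaluated by expansion below x = 1e-6.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < 1e-6
    xs = x[small]
    out[small] = 1.0 - xs / 3.0 + xs**2 / 12.0
    xl = x[~small]
    out[~small] = 2.0 * (np.expm1(-xl) + xl) / xl**2
    return out


def debye_profile(rg_nm: float, i0: float, q_grid: np.ndarray,
                  noise_rel: float = 0.0, seed: int = 0,
                  label: str = "debye") -> SAXSProfile:
    """Ideal-chain (theta-solvent) scattering curve with known Rg.

    ``intensity = i0 * D((q*rg)^2)`` plus Gaussian noise of sd
    ``noise_rel * intensity``; the sigma column records the applied sd.
    """
    if rg_nm <= 0:
        raise ValueError("rg_nm must be positive")
    if noise_rel < 0:
        raise ValueError("noise_rel must be non-negative")
    q = np.asarray(q_grid, dtype=float)
    ideal = i0 * debye_function((q * rg_nm) ** 2)
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        sd = noise_rel * ideal
        intensity = ideal + rng.normal(0.0, sd)
        return SAXSProfile(q=q, intensity=intensity, sigma=sd, label=label)
    return SAXSProfile(q=q, intensity=ideal, sigma=None, label=label)


def scattering_from_ensemble(ensemble: ChainEnsemble, q_grid: np.ndarray) -> SAXSProfile:
    """Orientation-averaged Debye-sum scattering of a chain ensemble.

    I(q) = < (1/N^2) sum_ij sin(q r_ij)/(q r_ij) > with the i=j term equal
    to 1, so I(0) = 1 exactly.  q is in nm^-1 and bead separations are
    converted with the ensemble's bead spacing.
    """
    if not ensemble.walks:
        raise ValueError("ensemble must contain at least one walk")
    q = np.asarray(q_grid, dtype=float)
    n = ensemble.n_beads
    accum = np.zeros_like(q)
    for walk in ensemble.walks:
        d = pdist(walk.astype(float)) * ensemble.bead_spacing_nm
        x = np.outer(d, q)  # pairs x q
        # np.sinc(t/pi) = sin(t)/t with the t=0 limit handled
        pair_sum = np.sinc(x / np.pi).sum(axis=0)
        accum += (n + 2.0 * pair_sum) / n**2
    return SAXSProfile(
        q=q, intensity=accum / len(ensemble.walks),
        label=f"ensemble N={n}",
    )


def sec_saxs_series(mw_da: float, a2: float, conc_profile, q_grid,
                    rg_nm: float, noise_rel: float = 0.0, seed: int = 0,
                    k_const: float = 1.0e4, buffer_level: float = 1.0,
                    epsilon: float = 2800.0, path_cm: float = 1.0,
                    n_buffer: int = 10) -> tuple[FrameSeries, SyntheticTruth]:
    """SEC-SAXS elution emulator for the second-virial-coefficient analysis.

    ``conc_profile`` is a list of (time s, concentration g/cm^3) for the
    elution; ``n_buffer`` zero-concentration buffer frames are prepended.
    Per frame the forward intensity obeys the virial relation
    K*c/I(0,c) = 1/Mw + 2*A2*c (K = ``k_const``, recorded in the truth), the
    profile shape is a Debye curve with ``rg_nm`` on top of a flat buffer
    background, and the UV trace is eps*c_molar*path.
    """
    conc_profile = [(float(t), float(c)) for t, c in conc_profile]
    if not any(c > 0 for _, c in conc_profile):
        raise ValueError("elution profile must contain non-zero concentrations")
    q = np.asarray(q_grid, dtype=float)
    rng = np.random.default_rng(seed)

    dt = conc_profile[1][0] - conc_profile[0][0] if len(conc_profile) > 1 else 1.0
    t_start = conc_profile[0][0]
    times = [t_start - dt * (n_buffer - i) for i in range(n_buffer)]
    concs = [0.0] * n_buffer
    for t, c in conc_profile:
        times.append(t)
        concs.append(c)

    frames, uv_rows = [], []
    shape = debye_function((q * rg_nm) ** 2)
    for t, c in zip(times, concs):
        i0 = k_const * c / (1.0 / mw_da + 2.0 * a2 * c) if c > 0 else 0.0
        ideal = buffer_level + i0 * shape
        if noise_rel > 0:
            sd = np.maximum(noise_rel * np.abs(ideal), noise_rel * buffer_level)
            intensity = ideal + rng.normal(0.0, sd)
            sigma = sd
        else:
            intensity, sigma = ideal, None
        frames.append(SAXSProfile(q=q, intensity=intensity, sigma=sigma,
                                  label=f"t={t:g}"))
        c_molar = c * 1000.0 / mw_da  # g/cm^3 -> g/L -> mol/L
        uv_rows.append((t, epsilon * c_molar * path_cm))

    series = FrameSeries(frames=frames, times=np.asarray(times, dtype=float),
                         uv=np.asarray(uv_rows, dtype=float))
    truth = SyntheticTruth({
        "mw_da": mw_da, "a2": a2, "rg_nm": rg_nm, "k_const": k_const,
        "buffer_level": buffer_level, "noise_rel": noise_rel, "seed": seed,
        "epsilon": epsilon, "path_cm": path_cm, "n_buffer": n_buffer,
    })
    return series, truth


def tht_traces(f: float, k_per_h: float, t_half_h: float, t_grid,
               noise_sd: float = 0.0, n_replicates: int = 3, seed: int = 0,
               condition: str = "synthetic") -> list[KineticTrace]:
    """Sigmoidal ThT aggregation traces with independent replicate noise.

    signal(t) = f / (1 + exp(-k (t - t_half))) + N(0, noise_sd).
    """
    if f <= 0 or k_per_h <= 0:
        raise ValueError("f and k must be positive")
    t = np.asarray(t_grid, dtype=float)
    if not (t[0] <= t_half_h <= t[-1]):
        raise ValueError("t_half must lie within the time grid")
    rng = np.random.default_rng(seed)
    clean = f / (1.0 + np.exp(-k_per_h * (t - t_half_h)))
    traces = []
    for rep in range(n_replicates):
        noisy = clean + (rng.normal(0.0, noise_sd, size=t.shape) if noise_sd > 0 else 0.0)
        traces.append(KineticTrace(time=t, signal=noisy,
                                   condition=condition, replicate=rep))
    return traces


def llps_plate(c_sat_um: float | None, conc_list, baseline_au: float,
               jump_au: float, noise_sd: float, n_replicates: int = 3,
               seed: int = 0) -> PlateData:
    """Endpoint turbidity plate with a step at the saturation concentration.

    absorbance = baseline + jump * 1[c >= c_sat] + N(0, noise_sd); a
    ``c_sat_um`` of None (or a jump of 0) produces a null plate with no
    phase separation anywhere.
    """
    conc = np.asarray(conc_list, dtype=float)
    rng = np.random.default_rng(seed)
    rows_c, rows_r, rows_a = [], [], []
    for c in conc:
        dense = c_sat_um is not None and jump_au != 0 and c >= c_sat_um
        mean = baseline_au + (jump_au if dense else 0.0)
        for rep in range(n_replicates):
            rows_c.append(c)
            rows_r.append(rep)
            rows_a.append(mean + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))
    return PlateData(concentration_um=np.array(rows_c),
                     replicate=np.array(rows_r),
                     absorbance=np.array(rows_a))


def ims_arrival(k0_cm2_vs: float, t0_ms: float, voltages,
                peak_rel_width: float = 0.02,
                instrument: Instrument | None = None,
                noise_rel: float = 0.0, seed: int = 0,
                n_bins: int = 200) -> StepFieldData:
    """Step-field arrival-time distributions with known K0 and dead time.

    Peak centers satisfy tA = t0 + L^2/(K * dV) with the raw mobility
    K = K0 * (760/p) * (T/273.15); each ATD is a Gaussian of relative width
    ``peak_rel_width`` around its center.
    """
    if k0_cm2_vs <= 0 or t0_ms <= 0:
        raise ValueError("k0 and t0 must be positive")
    inst = instrument or Instrument()
    k_raw = k0_cm2_vs * (760.0 / inst.pressure_torr) * (inst.temperature_k / 273.15)
    rng = np.random.default_rng(seed)
    records = []
    for dv in voltages:
        center = t0_ms + 1000.0 * inst.drift_length_cm**2 / (k_raw * dv)
        width = peak_rel_width * center
        ta = np.linspace(max(center - 5 * width, 1e-6), center + 5 * width, n_bins)
        counts = np.exp(-0.5 * ((ta - center) / width) ** 2)
        if noise_rel > 0:
            counts = np.clip(counts + rng.normal(0.0, noise_rel, size=counts.shape),
                             0.0, None)
        records.append((float(dv), ta, counts))
    return StepFieldData(records=records, instrument=inst)
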