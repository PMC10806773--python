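"""Frame quality control, averaging, and buffer subtraction.

Batch SAXS acquisitions record a burst of short exposures of the same
sample; frames affected by radiation damage or air bubbles are rejected by a
chi-square-type distance criterion before averaging.  SEC-SAXS series add an
in-line UV trace used both to pick sample/buffer frame windows and to assign
a concentration to each frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import SAXSProfile, FrameSeries, ValidationError
from .results import FitResult

__all__ = [
    "DetectionError",
    "ReductionReport",
    "reject_outlier_frames",
    "average_frames",
    "subtract_buffer",
    "select_sec_frames",
    "uv_to_concentration",
]


class DetectionError(RuntimeError):
    """Automatic peak/feature detection failed on the given data."""


@dataclass
class ReductionReport(FitResult):
    """Outcome of chi-square frame rejection."""

    distances: np.ndarray
    kept: list
    rejected: list
    mean_distance: float
    sd_distance: float
    threshold_sigmas: float
    weighted: bool
    buffer_frames: list = field(default_factory=list)

    _summary_title = "Frame rejection report"


def _common_grid(frames: list[SAXSProfile]) -> None:
    q0 = frames[0].q
    for i, fr in enumerate(frames[1:], start=1):
        if len(fr.q) != len(q0) or not np.allclose(fr.q, q0, rtol=1e-9, atol=0.0):
            raise ValidationError(f"frame {i} q grid differs from frame 0")


def reject_outlier_frames(frames: list[SAXSProfile], threshold_sigmas: float = 2.0,
                          weighted: bool | None = None) -> ReductionReport:
    """Single-pass chi-square-type frame rejection.

    The distance of frame i from the pointwise mean of all frames is
    d_i = sum_q (I_i - Ibar)^2 / sigma_i^2 (sigma-weighted when every frame
    carries errors, plain squared distance otherwise); a frame is rejected
    iff |d_i - mean(d)| > threshold_sigmas * sd(d).  When sd(d) = 0 (all
    frames equivalent) every frame is kept: no dispersion, no outliers.
    """
    if len(frames) < 3:
        raise ValidationError("frame rejection needs at least 3 frames")
    _common_grid(frames)
    if weighted is None:
        weighted = all(fr.sigma is not None for fr in frames)
    intensities = np.stack([fr.intensity for fr in frames])
    mean_profile = intensities.mean(axis=0)
    resid2 = (intensities - mean_profile) ** 2
    if weighted:
        sigmas = np.stack([fr.sigma for fr in frames])
        resid2 = resid2 / sigmas**2
    distances = resid2.sum(axis=1)
    mean_d = float(distances.mean())
    sd_d = float(distances.std(ddof=0))
    if sd_d == 0.0:
        kept = list(range(len(frames)))
        rejected: list[int] = []
    else:
        outlier = np.abs(distances - mean_d) > threshold_sigmas * sd_d
        kept = [i for i in range(len(frames)) if not outlier[i]]
        rejected = [i for i in range(len(frames)) if outlier[i]]
    return ReductionReport(
        distances=distances, kept=kept, rejected=rejected,
        mean_distance=mean_d, sd_distance=sd_d,
        threshold_sigmas=float(threshold_sigmas), weighted=bool(weighted),
    )


def average_frames(frames: list[SAXSProfile], kept: list[int] | None = None,
                   label: str = "average") -> SAXSProfile:
    """Pointwise mean of the kept frames with propagated standard errors.

    With per-frame sigmas the averaged sigma is sqrt(mean(sigma^2)/n); without
    them it is the pointwise sample sd / sqrt(n) (absent for n = 1).
    """
    if kept is None:
        kept = list(range(len(frames)))
    if not kept:
        raise ValidationError("cannot average an empty frame selection")
    sel = [frames[i] for i in kept]
    _common_grid(sel)
    n = len(sel)
    intensities = np.stack([fr.intensity for fr in sel])
    mean_i = intensities.mean(axis=0)
    if all(fr.sigma is not None for fr in sel):
        sigmas = np.stack([fr.sigma for fr in sel])
        sigma = np.sqrt((sigmas**2).mean(axis=0) / n)
    elif n > 1:
        sd = intensities.std(axis=0, ddof=1)
        sigma = sd / np.sqrt(n) if np.all(sd > 0) else None
    else:
        sigma = None
    return SAXSProfile(q=sel[0].q, intensity=mean_i, sigma=sigma, label=label)


def subtract_buffer(sample_avg: SAXSProfile, buffer_avg: SAXSProfile,
                    label: str | None = None) -> SAXSProfile:
    """Intensity difference with sigmas added in quadrature."""
    if len(sample_avg.q) != len(buffer_avg.q) or not np.allclose(
        sample_avg.q, buffer_avg.q, rtol=1e-9, atol=0.0
    ):
        raise ValidationError("sample and buffer q grids differ")
    sigma = None
    if sample_avg.sigma is not None and buffer_avg.sigma is not None:
        sigma = np.sqrt(sample_avg.sigma**2 + buffer_avg.sigma**2)
    elif sample_avg.sigma is not None:
        sigma = sample_avg.sigma.copy()
    return SAXSProfile(
        q=sample_avg.q,
        intensity=sample_avg.intensity - buffer_avg.intensity,
        sigma=sigma,
        label=label if label is not None else f"{sample_avg.label} - buffer",
    )


def uv_at_frames(series: FrameSeries) -> np.ndarray:
    """A280 interpolated onto the frame times (nearest within, linear)."""
    if series.uv is None:
        raise ValidationError("frame series carries no UV trace")
    return np.interp(series.times, series.uv[:, 0], series.uv[:, 1])


def select_sec_frames(series: FrameSeries, mode: str = "auto",
                      sample_indices: list[int] | None = None,
                      buffer_indices: list[int] | None = None,
                      buffer_block: int = 10,
                      uv_threshold: float = 0.5) -> tuple[list[int], list[int]]:
    """Pick sample (elution-peak) and buffer frame windows.

    ``mode="manual"`` passes the explicit index lists through unchanged.
    ``mode="auto"`` selects sample frames where the UV signal rises at least
    ``uv_threshold`` of the way from baseline to peak (default half-max),
    and takes as buffer the contiguous block of up to ``buffer_block``
    frames immediately preceding the peak (buffer just before the sample
    gives the best subtraction).  The virial analysis, which needs
    concentration leverage, lowers the threshold to widen the elution
    window; averaging for a single best profile keeps the half-max default.
    """
    if mode == "manual":
        if sample_indices is None or buffer_indices is None:
            raise ValidationError("manual mode needs explicit index lists")
        return list(sample_indices), list(buffer_indices)
    if mode != "auto":
        raise ValidationError(f"unknown selection mode {mode!r}")
    uv = uv_at_frames(series)
    # baseline from the lowest quartile: robust to peaks spanning most frames
    low = np.sort(uv)[: max(len(uv) // 4, 2)]
    baseline = float(np.median(low))
    noise = 1.4826 * float(np.median(np.abs(low - baseline)))
    peak = float(uv.max())
    if peak - baseline <= 3.0 * noise or peak <= baseline:
        raise DetectionError("no UV peak above 3x baseline noise")
    cut = baseline + uv_threshold * (peak - baseline)
    sample = [i for i, v in enumerate(uv) if v >= cut]
    # peak onset: where the UV first rises clearly above baseline; the
    # buffer block sits just before it (best subtraction placement)
    onset_cut = baseline + max(3.0 * noise, 0.02 * (peak - baseline))
    onset = sample[0]
    for i in range(sample[0], -1, -1):
        if uv[i] <= onset_cut:
            onset = i + 1
            break
        onset = i
    buffer = list(range(max(0, onset - buffer_block), onset))
    if not buffer:
        raise DetectionError("no buffer frames precede the UV peak")
    return sample, buffer


def uv_to_concentration(a280, epsilon: float = 2800.0, path_cm: float = 1.0,
                        mw_da: float | None = None):
    """Concentration from A280 by Beer-Lambert: c = A / (eps * path), mol/L.

    Negative absorbances (baseline noise) are clamped to zero.  With
    ``mw_da`` given, returns (molar, g_per_cm3) instead.
    """
    if epsilon <= 0 or path_cm <= 0:
        raise ValidationError("epsilon and path length must be positive")
    a = np.clip(np.asarray(a280, dtype=float), 0.0, None)
    molar = a / (epsilon * path_cm)
    if mw_da is None:
        return molar
    g_per_cm3 = molar * mw_da / 1000.0  # mol/L * g/mol = g/L; /1000 -> g/cm^3
    return molar, g_per_cm3
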