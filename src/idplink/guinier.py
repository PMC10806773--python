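"""Window-scanned Guinier analysis.

The radius of gyration follows from the low-q linearization
ln I(q) = ln I(0) - (Rg^2/3) q^2.  Rather than a single fit over one
hand-picked window, the fit is repeated on every contiguous subdivision of
the chosen region, from 6 points up to the full region; the window-wise Rg
estimates are collected on a frequency histogram whose count-weighted
average is the reported Rg.  A proper linear Guinier region produces a
narrow, unimodal histogram; a wide histogram flags a poor region choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import SAXSProfile, ValidationError
from .results import FitResult

__all__ = ["EstimationError", "WindowFit", "GuinierResults", "GuinierModel",
           "guinier_fit", "window_scan", "histogram_rg"]

DEFAULT_REGION_POINTS = 40


class EstimationError(RuntimeError):
    """No valid estimate could be produced from the data."""


@dataclass
class WindowFit:
    """One Guinier fit over the index window [start, stop)."""

    start: int
    stop: int
    rg: float
    i0: float
    stderr_rg: float
    valid: bool


@dataclass
class GuinierResults(FitResult):
    rg: float                     # nm, count-weighted histogram average
    rg_uncertainty: float         # nm, count-weighted sd of bin centers
    i0: float                     # forward intensity, input units
    bin_centers: np.ndarray
    counts: np.ndarray
    n_windows: int
    q_min: float
    q_max: float
    wide_histogram: bool          # relative width > 10%: inspect the region
    window_rg: np.ndarray = field(default_factory=lambda: np.empty(0))

    _summary_title = "Guinier window-scan analysis"

    def plot(self, ax=None):
        """Histogram of window-wise Rg estimates."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        width = (self.bin_centers[1] - self.bin_centers[0]
                 if len(self.bin_centers) > 1 else 0.01)
        ax.bar(self.bin_centers, self.counts, width=width, color="C0")
        ax.axvline(self.rg, color="C3", label=f"Rg = {self.rg:.3g} nm")
        ax.set_xlabel("Rg (nm)")
        ax.set_ylabel("window count")
        ax.legend()
        return ax


def auto_region(profile: SAXSProfile, qmax_rg: float = 1.0,
                probe_points: int = 20) -> tuple[float, float]:
    """Two-pass automatic Guinier region: probe Rg on the lowest-q points,
    then bound the region at q*Rg <= ``qmax_rg``.

    The default cap of 1.0 suits disordered chains, whose scattering
    departs from ln-linearity sooner than globular particles; set the
    region explicitly for publication-grade analyses.
    """
    pos = profile.intensity > 0
    q, inten = profile.q[pos], profile.intensity[pos]
    if len(q) < probe_points:
        raise ValidationError("too few positive-intensity points for auto region")
    slope = np.polyfit(q[:probe_points] ** 2, np.log(inten[:probe_points]), 1)[0]
    if slope >= 0:
        raise EstimationError("no decaying low-q region found")
    rg0 = float(np.sqrt(-3.0 * slope))
    return float(q[0]), float(qmax_rg / rg0)


def guinier_fit(profile: SAXSProfile, i_start: int, i_stop: int) -> WindowFit:
    """Weighted linear fit of ln I versus q^2 on the window [i_start, i_stop).

    With sigmas present the log-intensity errors follow from propagation,
    sigma_lnI = sigma_I / I.  A non-negative slope or non-positive intensity
    flags the window invalid instead of raising: the window scan simply
    drops it.
    """
    if i_stop - i_start < 3:
        raise ValidationError("Guinier window needs at least 3 points")
    q = profile.q[i_start:i_stop]
    inten = profile.intensity[i_start:i_stop]
    if np.any(inten <= 0):
        return WindowFit(i_start, i_stop, np.nan, np.nan, np.nan, valid=False)
    x = q**2
    y = np.log(inten)
    if profile.sigma is not None:
        w = (inten / profile.sigma[i_start:i_stop]) ** 2  # 1/sigma_lnI^2
    else:
        w = np.ones_like(y)
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    slope = (w * (x - xbar) * (y - ybar)).sum() / sxx
    intercept = ybar - slope * xbar
    if slope >= 0:
        return WindowFit(i_start, i_stop, np.nan, np.nan, np.nan, valid=False)
    if profile.sigma is not None:
        var_slope = 1.0 / sxx
    else:
        resid = y - (intercept + slope * x)
        dof = max(len(y) - 2, 1)
        var_slope = (resid @ resid) / dof / sxx
    rg = float(np.sqrt(-3.0 * slope))
    stderr_rg = float(3.0 * np.sqrt(var_slope) / (2.0 * rg))
    return WindowFit(i_start, i_stop, rg, float(np.exp(intercept)), stderr_rg, True)


def window_scan(profile: SAXSProfile, region: tuple[float, float] | None = None,
                min_len: int = 6,
                guinier_limit: float | None = 1.3) -> list[WindowFit]:
    """Guinier fits on every contiguous window of the fitting region.

    Window lengths run from ``min_len`` to the full region length, at every
    start position.  Invalid windows (rising intensity) are dropped, as are
    windows whose own q_max * Rg exceeds ``guinier_limit`` (set it to None
    to disable the validity filter and keep every window).
    """
    if region is None:
        lo, hi = 0, min(len(profile), DEFAULT_REGION_POINTS)
    else:
        qmin, qmax = region
        idx = np.nonzero((profile.q >= qmin) & (profile.q <= qmax))[0]
        if len(idx) == 0:
            raise ValidationError("region contains no data points")
        lo, hi = int(idx[0]), int(idx[-1]) + 1
    n = hi - lo
    if n < min_len:
        raise ValidationError(
            f"region has {n} points, fewer than the minimum window {min_len}"
        )
    fits = []
    for length in range(min_len, n + 1):
        for start in range(lo, hi - length + 1):
            fit = guinier_fit(profile, start, start + length)
            if not fit.valid:
                continue
            if guinier_limit is not None:
                if profile.q[start + length - 1] * fit.rg > guinier_limit:
                    continue
            fits.append(fit)
    return fits


def histogram_rg(window_fits: list[WindowFit], n_bins: int = 50,
                 q_range: tuple[float, float] = (np.nan, np.nan)) -> GuinierResults:
    """Frequency histogram of window Rg values and its count-weighted average.

    The reported Rg is sum(center * count)/sum(count) over equal-width bins
    spanning [min, max] of the window estimates; the uncertainty is the
    count-weighted sd of the bin centers.  All windows agreeing exactly
    yields a single-bin histogram with zero uncertainty.
    """
    valid = [f for f in window_fits if f.valid]
    if not valid:
        raise EstimationError("no valid Guinier window (no linear region found)")
    rgs = np.array([f.rg for f in valid])
    i0s = np.array([f.i0 for f in valid])
    lo, hi = float(rgs.min()), float(rgs.max())
    if hi - lo <= 1e-9 * max(abs(hi), 1e-300):  # numerically degenerate spread
        centers = np.array([lo])
        counts = np.array([float(len(rgs))])
    else:
        counts, edges = np.histogram(rgs, bins=n_bins, range=(lo, hi))
        counts = counts.astype(float)
        centers = 0.5 * (edges[:-1] + edges[1:])
    total = counts.sum()
    rg = float((centers * counts).sum() / total)
    var = float((counts * (centers - rg) ** 2).sum() / total)
    unc = float(np.sqrt(var))
    return GuinierResults(
        rg=rg,
        rg_uncertainty=unc,
        i0=float(np.median(i0s)),
        bin_centers=centers,
        counts=counts,
        n_windows=len(valid),
        q_min=float(q_range[0]),
        q_max=float(q_range[1]),
        wide_histogram=bool(unc / rg > 0.10),
        window_rg=rgs,
    )


class GuinierModel:
    """Window-scanned Guinier analysis of one reduced profile.

    Parameters
    ----------
    profile : SAXSProfile
        Buffer-subtracted curve, q in nm^-1.
    region : (qmin, qmax), optional
        Fitting region in nm^-1.  Defaults to the lowest-q 40 points, which
        is only a starting point: set it explicitly for publication use.
    min_len : int
        Smallest window length of the subdivision sweep (default 6 points).
    n_bins : int
        Histogram bin count (default 50).
    guinier_limit : float or None
        Drop windows with q_max * Rg above this (default 1.3, the customary
        validity bound for disordered chains); None keeps all windows.
    """

    def __init__(self, profile: SAXSProfile, region: tuple[float, float] | None = None,
                 min_len: int = 6, n_bins: int = 50,
                 guinier_limit: float | None = 1.3):
        self.profile = profile
        self.region = region
        self.min_len = min_len
        self.n_bins = n_bins
        self.guinier_limit = guinier_limit

    def fit(self) -> GuinierResults:
        fits = window_scan(self.profile, self.region, self.min_len,
                           self.guinier_limit)
        if self.region is not None:
            q_range = self.region
        else:
            hi = min(len(self.profile), DEFAULT_REGION_POINTS)
            q_range = (float(self.profile.q[0]), float(self.profile.q[hi - 1]))
        return histogram_rg(fits, self.n_bins, q_range=q_range)
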