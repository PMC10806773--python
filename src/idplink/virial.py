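"""Second virial coefficient from SEC-SAXS.

Along a size-exclusion elution the protein concentration varies
continuously while the in-line UV trace reports it frame by frame, so a
single injection samples the concentration dependence of the forward
scattering.  The Zimm-type virial relation

    K c / I(0, c) = 1/Mw + 2 A2 c

is fitted in the operational form c/I0 = alpha + beta c, giving
A2 = beta / (2 alpha Mw): the lumped instrument constant K cancels, so the
estimate is invariant under global intensity rescaling.  Positive A2 means
net repulsive protein-protein interactions, negative net attractive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import AnalysisConfig, FrameSeries, ValidationError
from .guinier import guinier_fit
from .reduce import average_frames, subtract_buffer, uv_at_frames, uv_to_concentration
from .results import FitResult

__all__ = ["ConcentrationPoint", "VirialResults", "VirialModel",
           "extract_i0_series", "fit_virial"]


@dataclass
class ConcentrationPoint:
    """One (concentration, forward intensity) pair along the elution."""

    c_g_cm3: float
    c_um: float
    i0: float
    i0_err: float | None = None


@dataclass
class VirialResults(FitResult):
    a2: float                  # cm^3 mol g^-2
    a2_err: float
    k_const: float             # lumped instrument constant K
    mw_used: float             # Da
    n_points: int
    chi2: float
    alpha: float               # intercept of c/I0 vs c
    beta: float                # slope of c/I0 vs c
    alpha_err: float
    beta_err: float

    _summary_title = "SEC-SAXS second virial coefficient"

    def plot(self, points: list[ConcentrationPoint] | None = None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if points:
            c = np.array([p.c_g_cm3 for p in points])
            y = c / np.array([p.i0 for p in points])
            ax.plot(c, y, "o", ms=4, label="frames")
            cf = np.linspace(0, c.max() * 1.05, 50)
            ax.plot(cf, self.alpha + self.beta * cf, "-",
                    label=f"A2 = {self.a2:.3g} cm$^3$ mol g$^{{-2}}$")
        ax.set_xlabel("c (g cm$^{-3}$)")
        ax.set_ylabel("c / I(0, c)")
        ax.legend()
        return ax


def _i0_window(sub, min_pts: int = 8) -> int:
    """Low-q window length for the forward-intensity fit.

    The window ends where the curve has decayed by a factor
    1 + max(0.002, 30 * relative noise) from its forward value: with noise
    the slope needs leverage over the scatter, while noiseless data keep a
    minimal window so the Guinier truncation bias stays negligible.
    """
    inten = sub.intensity
    rel_noise = 0.0
    if sub.sigma is not None:
        head = slice(0, max(len(sub) // 2, min_pts))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = sub.sigma[head] / np.abs(inten[head])
        ratios = ratios[np.isfinite(ratios)]
        if len(ratios):
            rel_noise = float(np.median(ratios))
    target = 1.0 + max(0.002, 30.0 * rel_noise)
    i_ref = float(np.median(inten[:3]))
    below = np.nonzero(inten < i_ref / target)[0]
    n_low = int(below[0]) + 1 if len(below) else len(sub)
    return int(np.clip(n_low, min_pts, len(sub)))


def extract_i0_series(series: FrameSeries, sample_idx: list[int],
                      buffer_idx: list[int],
                      config: AnalysisConfig | None = None,
                      uv_lag_frames: int = 0,
                      n_bins: int | None = 20,
                      guinier_points: int | None = None) -> list[ConcentrationPoint]:
    """Per-frame forward intensities paired with UV-derived concentrations.

    Each sample frame is buffer-subtracted and Guinier-fitted at low q for
    I(0); its concentration comes from the time-aligned UV absorbance
    (``uv_lag_frames`` shifts the UV assignment to compensate detector lag).
    Frames whose concentration falls below 3x the UV baseline noise are
    dropped.  With ``n_bins`` set, frames are grouped into at most that many
    concentration bins and averaged per bin first, which stabilizes the
    per-point I(0) errors; ``n_bins=None`` fits every frame separately.

    The I(0) window is noise-aware unless ``guinier_points`` pins it: it
    extends to the q where the curve has decayed by ~30x the relative noise
    (a noiseless profile keeps a very low-q window, minimizing Guinier
    truncation bias; a noisy one buys slope leverage).  Any residual window
    bias is multiplicative and identical across frames, so it cancels in
    the virial ratio beta/alpha.
    """
    config = config or AnalysisConfig()
    if series.uv is None:
        raise ValidationError("A2 extraction needs a UV trace in the series")
    buffer_avg = average_frames(series.frames, buffer_idx, label="buffer")
    uv = uv_at_frames(series)
    if uv_lag_frames:
        uv = np.roll(uv, -uv_lag_frames)
    buffer_uv = uv[buffer_idx]
    uv_noise = float(buffer_uv.std(ddof=1)) if len(buffer_uv) > 1 else 0.0

    frame_conc = {}
    for i in sample_idx:
        a280 = uv[i]
        if a280 <= 3.0 * uv_noise or a280 <= 0.0:
            continue
        _, c_g = uv_to_concentration(a280, config.extinction_coeff,
                                     config.uv_path_cm, mw_da=config.mw_da)
        frame_conc[i] = float(c_g)
    if not frame_conc:
        raise ValidationError("no sample frame has concentration above UV noise")

    if n_bins is None or len(frame_conc) <= n_bins:
        groups = [[i] for i in frame_conc]
    else:
        concs = np.array(list(frame_conc.values()))
        edges = np.quantile(concs, np.linspace(0, 1, n_bins + 1))
        groups = []
        assigned = np.clip(np.searchsorted(edges, concs, side="right") - 1,
                           0, n_bins - 1)
        idx_list = list(frame_conc)
        for b in range(n_bins):
            grp = [idx_list[j] for j in range(len(idx_list)) if assigned[j] == b]
            if grp:
                groups.append(grp)

    points = []
    for grp in groups:
        avg = average_frames(series.frames, grp)
        sub = subtract_buffer(avg, buffer_avg)
        if guinier_points is not None:
            n_low = min(guinier_points, len(sub))
        else:
            n_low = _i0_window(sub)
        fit = guinier_fit(sub, 0, n_low)
        if not fit.valid:
            continue
        c_g = float(np.mean([frame_conc[i] for i in grp]))
        c_um = c_g / config.mw_da * 1.0e9  # g/cm^3 -> mol/cm^3 -> mol/L*1e3 -> uM
        i0_err = fit.i0 * fit.stderr_rg / max(fit.rg, 1e-12)  # crude scale proxy
        points.append(ConcentrationPoint(c_g_cm3=c_g, c_um=c_um,
                                         i0=fit.i0, i0_err=float(i0_err)))
    return points


def fit_virial(points: list[ConcentrationPoint], mw: float,
               min_span_ratio: float = 2.0) -> VirialResults:
    """Weighted linear fit of c/I0 = alpha + beta*c; A2 = beta/(2 alpha Mw).

    Requires at least 3 distinct concentrations spanning at least
    ``min_span_ratio``-fold.  Errors on alpha and beta come from the fit
    covariance and propagate to A2 by the delta method (including their
    covariance).
    """
    if mw <= 0:
        raise ValidationError("molecular weight must be positive")
    c = np.array([p.c_g_cm3 for p in points], dtype=float)
    i0 = np.array([p.i0 for p in points], dtype=float)
    keep = (c > 0) & (i0 > 0)
    c, i0 = c[keep], i0[keep]
    if len(np.unique(c)) < 3:
        raise ValidationError("need >= 3 distinct concentrations")
    span = c.max() / c.min()
    if span < min_span_ratio:
        raise ValidationError(
            f"concentration span {span:.2f}-fold is below the required "
            f"{min_span_ratio:.2f}-fold"
        )
    y = c / i0
    x = np.column_stack([np.ones_like(c), c])
    coef, residuals, *_ = np.linalg.lstsq(x, y, rcond=None)
    alpha, beta = float(coef[0]), float(coef[1])
    resid = y - x @ coef
    dof = max(len(c) - 2, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(x.T @ x)
    alpha_err, beta_err = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    if alpha <= 0:
        raise ValidationError("non-positive intercept: data violate the virial form")
    a2 = beta / (2.0 * alpha * mw)
    # delta method: grad = (dA2/dalpha, dA2/dbeta)
    grad = np.array([-beta / (2.0 * alpha**2 * mw), 1.0 / (2.0 * alpha * mw)])
    a2_var = float(grad @ cov @ grad)
    k_const = 1.0 / (alpha * mw)  # from K/Mw = ... at c->0: alpha = 1/(K Mw)
    chi2 = float(resid @ resid)
    return VirialResults(
        a2=float(a2), a2_err=float(np.sqrt(max(a2_var, 0.0))),
        k_const=float(k_const), mw_used=float(mw), n_points=int(len(c)),
        chi2=chi2, alpha=alpha, beta=beta,
        alpha_err=alpha_err, beta_err=beta_err,
    )


class VirialModel:
    """Second-virial-coefficient analysis of one SEC-SAXS series.

    Wraps frame selection, per-frame I(0) extraction and the virial fit:

    >>> model = VirialModel(series, sample_idx, buffer_idx, config=cfg)
    >>> res = model.fit()
    """

    def __init__(self, series: FrameSeries, sample_idx: list[int],
                 buffer_idx: list[int], config: AnalysisConfig | None = None,
                 uv_lag_frames: int = 0, n_bins: int | None = 20):
        self.series = series
        self.sample_idx = sample_idx
        self.buffer_idx = buffer_idx
        self.config = config or AnalysisConfig()
        self.uv_lag_frames = uv_lag_frames
        self.n_bins = n_bins
        self.points_: list[ConcentrationPoint] | None = None

    def fit(self) -> VirialResults:
        self.points_ = extract_i0_series(
            self.series, self.sample_idx, self.buffer_idx, self.config,
            uv_lag_frames=self.uv_lag_frames, n_bins=self.n_bins,
        )
        return fit_virial(self.points_, self.config.mw_da)
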