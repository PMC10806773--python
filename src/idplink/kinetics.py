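"""ThT aggregation kinetics: normalization, sigmoid fits, replicate stats.

Thioflavin-T fluorescence reports amyloid formation; each well's trace is
min-max normalized and fitted with the three-parameter logistic

    s(t) = F / (1 + exp(-k (t - t_1/2))),

where F is the final normalized intensity, k the growth rate (h^-1) and
t_1/2 the aggregation halftime (h).  Replicates are fitted independently;
per-condition halftimes are summarized as mean +- sd over the converged
replicates.  A trace that never grows (a non-aggregating control) can be
normalized against another trace's maximum and is reported as "no
aggregation observed" rather than forced through the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .datatypes import KineticTrace, ValidationError
from .results import FitResult

__all__ = ["SigmoidResults", "SigmoidModel", "HalftimeSummary",
           "normalize_trace", "fit_sigmoid", "halftime_stats"]


class NormalizationError(ValueError):
    """A flat trace cannot be normalized against its own extrema."""


def logistic(t, f, k, t_half):
    return f / (1.0 + np.exp(-k * (t - t_half)))


def normalize_trace(trace: KineticTrace, reference_max: float | None = None) -> KineticTrace:
    """Min-max normalize a trace to [0, 1].

    With ``reference_max`` the scale is (reference_max - min) instead of the
    trace's own span: this is how a non-increasing control is normalized
    against an aggregating condition's maximum.
    """
    lo = float(trace.signal.min())
    hi = float(reference_max) if reference_max is not None else float(trace.signal.max())
    if hi == lo:
        raise NormalizationError(
            f"flat trace {trace.condition!r}: supply reference_max to normalize"
        )
    return KineticTrace(
        time=trace.time.copy(),
        signal=(trace.signal - lo) / (hi - lo),
        condition=trace.condition,
        replicate=trace.replicate,
    )


@dataclass
class SigmoidResults(FitResult):
    f: float
    k: float                   # h^-1
    t_half: float              # h
    f_stderr: float
    k_stderr: float
    t_half_stderr: float
    converged: bool
    condition: str
    replicate: int

    _summary_title = "ThT sigmoid fit"

    def plot(self, trace: KineticTrace | None = None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if trace is not None:
            ax.plot(trace.time, trace.signal, ".", ms=3, label="data")
            tf = np.linspace(trace.time[0], trace.time[-1], 300)
            ax.plot(tf, logistic(tf, self.f, self.k, self.t_half), "-",
                    label=f"$t_{{1/2}}$ = {self.t_half:.1f} h")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("normalized ThT")
        ax.legend()
        return ax


class SigmoidModel:
    """Three-parameter logistic fit of one normalized kinetic trace.

    Initialization is data-driven: F from the signal maximum, t_1/2 from the
    first half-maximum crossing, k from the 10-90% rise time (k ~ 4/(t90 -
    t10)).  Failure to converge, or a halftime escaping the observed time
    span, is encoded in ``converged`` rather than raised, so plate-wide
    batch fits never abort.
    """

    def __init__(self, trace: KineticTrace):
        self.trace = trace

    def _initial(self) -> tuple[float, float, float]:
        t, s = self.trace.time, self.trace.signal
        f0 = float(s.max())
        half = 0.5 * f0
        above = np.nonzero(s >= half)[0]
        t_half0 = float(t[above[0]]) if len(above) else float(t[len(t) // 2])
        lo_idx = np.nonzero(s >= 0.1 * f0)[0]
        hi_idx = np.nonzero(s >= 0.9 * f0)[0]
        if len(lo_idx) and len(hi_idx) and t[hi_idx[0]] > t[lo_idx[0]]:
            k0 = 4.0 / float(t[hi_idx[0]] - t[lo_idx[0]])
        else:
            k0 = 4.0 / float(t[-1] - t[0])
        return f0, k0, t_half0

    def fit(self) -> SigmoidResults:
        t, s = self.trace.time, self.trace.signal
        f0, k0, t_half0 = self._initial()
        failed = SigmoidResults(
            f=np.nan, k=np.nan, t_half=np.nan,
            f_stderr=np.nan, k_stderr=np.nan, t_half_stderr=np.nan,
            converged=False, condition=self.trace.condition,
            replicate=self.trace.replicate,
        )
        if f0 <= 0:
            return failed
        try:
            popt, pcov = curve_fit(
                logistic, t, s, p0=[f0, k0, t_half0],
                bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=10000,
            )
        except (RuntimeError, ValueError):
            return failed
        f, k, t_half = (float(v) for v in popt)
        perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
        converged = bool(k > 0 and t[0] <= t_half <= t[-1] and np.isfinite(popt).all())
        return SigmoidResults(
            f=f, k=k, t_half=t_half,
            f_stderr=float(perr[0]), k_stderr=float(perr[1]),
            t_half_stderr=float(perr[2]),
            converged=converged, condition=self.trace.condition,
            replicate=self.trace.replicate,
        )


def fit_sigmoid(trace: KineticTrace) -> SigmoidResults:
    """Functional wrapper around :class:`SigmoidModel`."""
    return SigmoidModel(trace).fit()


@dataclass
class HalftimeSummary(FitResult):
    condition: str
    t_half_mean: float         # h; nan when no aggregation observed
    t_half_sd: float
    n_converged: int
    n_total: int
    aggregated: bool           # False: "no aggregation observed"

    _summary_title = "Aggregation halftime summary"


def halftime_stats(fits_by_condition: dict[str, list[SigmoidResults]]) -> list[HalftimeSummary]:
    """Mean and sample sd of t_1/2 over the converged replicates.

    Conditions with zero converged replicates are marked not aggregating
    (halftime undefined) instead of raising; a single converged replicate
    reports sd = 0 with n = 1.
    """
    out = []
    for condition, fits in fits_by_condition.items():
        conv = [f for f in fits if f.converged]
        if not conv:
            out.append(HalftimeSummary(condition=condition,
                                       t_half_mean=float("nan"),
                                       t_half_sd=float("nan"),
                                       n_converged=0, n_total=len(fits),
                                       aggregated=False))
            continue
        vals = np.array([f.t_half for f in conv])
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out.append(HalftimeSummary(condition=condition,
                                   t_half_mean=float(vals.mean()),
                                   t_half_sd=sd,
                                   n_converged=len(conv), n_total=len(fits),
                                   aggregated=True))
    return out
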