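"""Cross-condition statistics: pairwise OLS correlations and the elbow check.

Once each mutant/condition has been reduced to a handful of scalars (Rg,
Flory exponent, A2, aggregation halftime, Csat), the questions are (i) how
strongly pairs of parameters co-vary across conditions — answered by simple
ordinary least squares with the coefficient of determination R² — and (ii)
whether the conditions fall into distinct groups — answered by k-means with
the elbow rule on the within-cluster sum of squares.  Conditions whose
quantity is undefined (a non-aggregating control has no halftime; a
condition that never phase-separates has no Csat) are excluded with the
reason recorded, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .datatypes import ValidationError
from .results import FitResult

__all__ = ["CorrelationResults", "ElbowResults", "regress", "elbow_k",
           "standard_correlations"]


@dataclass
class CorrelationResults(FitResult):
    slope: float
    intercept: float
    r_squared: float           # nan when SStot = 0 (constant y): undefined
    slope_stderr: float
    p_value: float
    n: int
    x_name: str
    y_name: str
    excluded: dict = field(default_factory=dict)  # condition -> reason

    _summary_title = "Pairwise OLS correlation"

    def plot(self, x=None, y=None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if x is not None and y is not None:
            ax.plot(x, y, "o")
            xf = np.linspace(np.min(x), np.max(x), 50)
            ax.plot(xf, self.intercept + self.slope * xf, "-",
                    label=f"$R^2$ = {self.r_squared:.2f}")
            ax.legend()
        ax.set_xlabel(self.x_name)
        ax.set_ylabel(self.y_name)
        return ax


@dataclass
class ElbowResults(FitResult):
    k_candidates: list
    wcss: np.ndarray
    selected_k: int
    strong_elbow: bool
    selection_rule: str

    _summary_title = "Elbow-method cluster count"

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.k_candidates, self.wcss, "o-")
        ax.axvline(self.selected_k, color="C3", ls="--",
                   label=f"k = {self.selected_k}")
        ax.set_xlabel("k")
        ax.set_ylabel("within-cluster sum of squares")
        ax.legend()
        return ax


def regress(xy_pairs, exclusions: dict | None = None,
            x_name: str = "x", y_name: str = "y") -> CorrelationResults:
    """Ordinary least squares over (x, y) pairs with recorded exclusions.

    ``xy_pairs`` may contain NaNs; such pairs are dropped.  A constant y
    leaves R² undefined (reported as NaN), not an error.
    """
    pairs = np.asarray(list(xy_pairs), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValidationError("xy_pairs must be a sequence of (x, y) pairs")
    finite = np.all(np.isfinite(pairs), axis=1)
    pairs = pairs[finite]
    if len(pairs) < 3:
        raise ValidationError("need >= 3 finite pairs for a regression")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.all(y == y[0]) or np.all(x == x[0]):
        # constant y: SStot = 0, R^2 undefined; constant x: slope undefined
        return CorrelationResults(
            slope=float("nan") if np.all(x == x[0]) else 0.0,
            intercept=float(y[0]) if np.all(y == y[0]) else float("nan"),
            r_squared=float("nan"),
            slope_stderr=float("nan"), p_value=float("nan"),
            n=len(pairs), x_name=x_name, y_name=y_name,
            excluded=dict(exclusions or {}),
        )
    fit = stats.linregress(x, y)
    return CorrelationResults(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2), slope_stderr=float(fit.stderr),
        p_value=float(fit.pvalue), n=len(pairs),
        x_name=x_name, y_name=y_name, excluded=dict(exclusions or {}),
    )


def elbow_k(points, k_max: int = 6, seed: int = 0, n_restarts: int = 10,
            flat_curvature_rel: float = 0.05) -> ElbowResults:
    """k-means elbow scan: WCSS for k = 1..k_max, maximum-curvature pick.

    The selected k maximizes the second difference of the WCSS curve
    (discrete curvature), ties broken toward smaller k.  When the best
    curvature is small relative to the total WCSS drop the elbow is flagged
    weak ("no strong elbow").  The WCSS curve is asserted non-increasing on
    every run.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n_distinct = len(np.unique(pts, axis=0))
    if k_max < 2:
        raise ValidationError("k_max must be >= 2")
    if n_distinct <= k_max:
        k_max = n_distinct - 1
        if k_max < 2:
            raise ValidationError("too few distinct points for an elbow scan")
    ks = list(range(1, k_max + 1))
    wcss = []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        km.fit(pts)
        wcss.append(float(km.inertia_))
    wcss = np.array(wcss)
    # k-means inertia is non-increasing in k up to restart noise
    if np.any(np.diff(wcss) > 1e-9 * max(wcss[0], 1.0)):
        raise RuntimeError("WCSS increased with k: k-means restarts insufficient")
    if len(ks) >= 3:
        curvature = wcss[:-2] - 2 * wcss[1:-1] + wcss[2:]  # at k = 2..k_max-1
        best = int(np.argmax(curvature))
        selected = ks[best + 1]
        total_drop = max(wcss[0] - wcss[-1], 1e-300)
        strong = bool(curvature[best] > flat_curvature_rel * total_drop)
    else:
        selected, strong = ks[-1], False
    return ElbowResults(
        k_candidates=ks, wcss=wcss, selected_k=int(selected),
        strong_elbow=strong, selection_rule="max second difference of WCSS",
    )


STANDARD_PAIRS = [
    ("rg_nm", "t_half_h"),
    ("rg_nm", "c_sat_um"),
    ("rg_nm", "nu"),
    ("nu", "t_half_h"),
    ("a2", "t_half_h"),
]


def standard_correlations(summary_rows: list[dict]) -> dict[str, CorrelationResults]:
    """The cross-condition regression panel.

    ``summary_rows`` are dicts with keys ``condition`` plus any of
    ``rg_nm, nu, a2, t_half_h, c_sat_um``; missing/NaN entries exclude that
    condition from the affected regressions with a recorded reason.
    """
    out = {}
    for x_name, y_name in STANDARD_PAIRS:
        pairs, excluded = [], {}
        for row in summary_rows:
            x = row.get(x_name, float("nan"))
            y = row.get(y_name, float("nan"))
            cond = row.get("condition", "?")
            missing = [n for n, v in ((x_name, x), (y_name, y))
                       if v is None or not np.isfinite(v)]
            if missing:
                excluded[cond] = f"{' and '.join(missing)} undefined"
                continue
            pairs.append((x, y))
        key = f"{y_name}_vs_{x_name}"
        if len(pairs) >= 3:
            out[key] = regress(pairs, excluded, x_name=x_name, y_name=y_name)
    return out
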