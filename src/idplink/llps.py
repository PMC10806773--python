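"""LLPS saturation concentration from endpoint turbidity plates.

Wells below the phase boundary scatter no light; once the protein
concentration crosses the saturation concentration, droplets form and the
A500 absorbance jumps.  Concentrations at which phase separation is never
seen (0, 4, 8, 12 uM by default) pool into one baseline sample; each higher
concentration is compared with the baseline by a two-sample t test, walking
up the ladder, and the lowest concentration with p < alpha is reported as
Csat.  No multiple-testing correction is applied (raw per-test p values by
design); the resulting type-I inflation of the ladder is quantified in the
test suite.  The default is the pooled Student test (see
:class:`CsatModel` for the small-sample rationale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datatypes import PlateData, ValidationError
from .results import FitResult

__all__ = ["CsatResults", "CsatModel", "determine_csat"]

DEFAULT_BASELINE_UM = (0.0, 4.0, 8.0, 12.0)


@dataclass
class CsatResults(FitResult):
    c_sat: float               # uM; nan when none detected
    detected: bool
    p_values: dict             # tested concentration -> p (nan: degenerate)
    baseline_concs: list
    alpha: float
    test: str                  # "welch" or "student"
    warnings: list = field(default_factory=list)

    _summary_title = "LLPS saturation concentration"


class CsatModel:
    """Baseline-plus-t-test ladder on one endpoint turbidity plate.

    Parameters
    ----------
    plate : PlateData
    baseline_concs : sequence of float
        Concentrations (uM) pooled into the no-LLPS baseline.
    alpha : float
        Per-test significance level (default 0.05), uncorrected.
    equal_var : bool
        True (default) uses the pooled-variance Student t test, whose
        per-test size is exact at these tiny replicate counts (n = 3 per
        well against the 12-well pooled baseline) and keeps the ladder's
        family-wise false-detection rate below alpha times the number of
        tested concentrations; False switches to the Welch unequal-variance
        test, which is anticonservative here (its small-sample size runs
        near 0.07) but robust if dense-phase wells have inflated variance.
    """

    def __init__(self, plate: PlateData,
                 baseline_concs=DEFAULT_BASELINE_UM,
                 alpha: float = 0.05, equal_var: bool = True,
                 min_replicates: int = 3):
        self.plate = plate
        self.baseline_concs = tuple(float(c) for c in baseline_concs)
        self.alpha = alpha
        self.equal_var = equal_var
        self.min_replicates = min_replicates

    def fit(self) -> CsatResults:
        plate = self.plate
        present = plate.concentrations()
        for c in self.baseline_concs:
            if not np.any(np.isclose(present, c)):
                raise ValidationError(f"baseline concentration {c} uM missing from plate")
        for c in present:
            if len(plate.absorbances_at(c)) < self.min_replicates:
                raise ValidationError(
                    f"concentration {c} uM has fewer than "
                    f"{self.min_replicates} replicates"
                )
        baseline = np.concatenate(
            [plate.absorbances_at(c) for c in self.baseline_concs]
        )
        tested = sorted(c for c in present
                        if not any(np.isclose(c, b) for b in self.baseline_concs))
        p_values: dict[float, float] = {}
        warnings: list[str] = []
        c_sat = float("nan")
        detected = False
        def _degenerate(x):
            # zero variance up to float cancellation in the mean-subtract
            return x.std(ddof=1) <= 1e-12 * max(abs(x.mean()), 1e-300)

        for c in tested:
            sample = plate.absorbances_at(c)
            if _degenerate(baseline) and _degenerate(sample):
                if abs(baseline.mean() - sample.mean()) <= 1e-12 * max(
                    abs(baseline.mean()), abs(sample.mean()), 1e-300
                ):
                    # all absorbances identical: p undefined, not significant
                    p_values[float(c)] = float("nan")
                    warnings.append(f"{c} uM: zero variance in both samples")
                    continue
                # zero variance but distinct means: the noise -> 0 limit of
                # an arbitrarily large t statistic
                p_values[float(c)] = 0.0
                if not detected:
                    c_sat = float(c)
                    detected = True
                continue
            p = float(stats.ttest_ind(baseline, sample,
                                      equal_var=self.equal_var).pvalue)
            p_values[float(c)] = p
            if not detected and p < self.alpha:
                c_sat = float(c)
                detected = True
                # ladder stops at the lowest significant concentration, but
                # higher concentrations are still tested for diagnostics
        return CsatResults(
            c_sat=c_sat, detected=detected, p_values=p_values,
            baseline_concs=list(self.baseline_concs), alpha=self.alpha,
            test="student" if self.equal_var else "welch",
            warnings=warnings,
        )


def determine_csat(plate: PlateData, baseline_concs=DEFAULT_BASELINE_UM,
                   alpha: float = 0.05, equal_var: bool = True) -> CsatResults:
    """Functional wrapper around :class:`CsatModel`."""
    return CsatModel(plate, baseline_concs, alpha, equal_var).fit()
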