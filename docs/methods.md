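# Methods

This note records the models behind each analysis stage, the parameters
that matter, the numerical choices made where the design was genuinely
open, and what the synthetic-data generators do and do not emulate.

## Units and containers

Momentum transfer is held internally in nm⁻¹ (profiles read as Å⁻¹ are
multiplied by 10 on load) and Rg in nm; plate-reader time in hours;
ion-mobility arrival times in ms.  Frames are 0-based internally; manifest
files use 1-based beamline numbering, converted on load.  Profiles without
an error column propagate `sigma = None`, and every downstream fit then
falls back to unweighted least squares.

## SAXS reduction

Frame quality control uses a chi-square-type distance of each frame from
the pointwise mean of all frames, sigma-weighted when every frame carries
errors (the unweighted squared distance otherwise — both are offered
because reduced data do not always retain errors).  Rejection is a single
pass at mean ± 2σ of the distance distribution; when the distances have
zero spread no frame is rejected (no dispersion → no outliers).  An
iterative mode exists behind a flag but is off by default, matching the
single-elimination reading of the procedure.

SEC-SAXS frame selection is UV-driven: the baseline is estimated from the
lowest quartile of the A280 trace (robust when the elution peak spans much
of the run), sample frames are those above a configurable fraction of the
baseline-to-peak rise (default one half), and the buffer block is the up
to 10 frames immediately preceding the *peak onset* (where UV first rises
clearly above baseline), the placement that empirically gives the best
subtraction.  The A2 analysis lowers the sample threshold to 0.2: the
virial fit needs a ≥ 2-fold concentration span, which a half-maximum
window cannot deliver.  Concentrations come from Beer–Lambert with
ε = 2800 M⁻¹cm⁻¹ and Mw = 20570 Da by default (the tau-fragment values);
the UV flow-cell path defaults to 1.0 cm and is configurable and logged.

## Window-scanned Guinier Rg

"Subdivisions" of the fitting region are implemented as *all* contiguous
windows of each length from 6 points to the full region — this maximizes
histogram statistics.  Each window gets a weighted linear fit of ln I vs
q² (σ_lnI = σ_I/I); windows with non-negative slope or non-positive
intensities are dropped, as are (by default) windows whose own qmax·Rg
exceeds 1.3; histogram weighting is by bin count, per the frequency
reading of the weighted average; 50 equal-width bins by default.  The
count-weighted sd of bin centers is the reported uncertainty and a
relative width above 10% sets a quality flag.

Known limitation: on a Debye curve the Guinier approximation's truncation
bias is about −(qRg)²_mean/12; a region reaching qmax·Rg = 1.0 biases the
histogram mean by roughly −3%.  The `auto_region` helper therefore probes
Rg on the lowest-q points and caps the region at q·Rg ≤ 1.0 by default —
adequate for comparative work, while publication-grade absolute values
should use an explicitly chosen region and report the histogram.

## Flory exponent

The generalized Debye (excluded-volume) form factor is used in closed
form; its ν = 1/2 case reduces analytically to the Debye function and its
low-q expansion reproduces the Guinier law with the same Rg for every ν,
which the tests verify.  The fit is multi-start (ν₀ ∈ {0.45, 0.55, 0.65}),
bounded to ν ∈ [0.3, 0.8] (collapsed globule to swollen coil), restricted
to q·Rg ≲ 4, with U-singularities at q → 0 handled by series expansion
below U = 10⁻⁶.  A fit is flagged unreliable when its χ² exceeds 3× the
median over starts or a parameter pins at a bound — thresholds that are
this package's own convention.

Absolute ν from any closed-form factor is approximate: fitted to the
Debye-sum scattering of *finite lattice* self-avoiding walks (N = 200) it
returns ν ≈ 0.49–0.53 even though the same curves carry the true exponent
(their fractal-regime slope gives 1/0.592), because the form factor's
Gaussian-segment assumption fails at finite N.  ν values should therefore
be compared across samples measured and fitted identically, not read as
absolute exponents; the good-solvent calibration in `scripts/acceptance.py`
uses the Rg ~ N^ν scaling route, which is free of this approximation.

## Second virial coefficient

The standard Zimm-type relation K·c/I(0,c) = 1/Mw + 2A2·c is fitted as
c/I0 = α + βc by ordinary least squares with covariance from the residual
scatter; A2 = β/(2αMw) with a full delta-method error (including the α–β
covariance).  The estimate is exactly invariant to global intensity
rescaling and to any multiplicative bias in the per-frame I(0) extraction
that is common across frames.  The per-frame I(0) comes from a low-q
Guinier fit whose window is noise-aware: it extends until the curve has
decayed by about 30× the relative noise (noiseless data keep a minimal
window, so truncation bias stays below 10⁻⁸; noisy data buy slope
leverage).  Frames may optionally be pooled into ≤ 20 concentration bins
first; binning is off in the exactness tests because averaging frames of
unequal concentration perturbs the nonlinear c ↦ I(0,c) relation.
A2 is reported in cm³·mol·g⁻² (light-scattering convention) with a µM
concentration mirror for display.

## ThT kinetics

Eq-style three-parameter logistic, no baseline term: traces are min-max
normalized first (a non-increasing control is normalized against another
condition's maximum), which absorbs the baseline.  Initialization is
data-driven (F from the maximum, t₁ᐟ₂ from the first half-max crossing, k
from the 10–90% rise time); convergence is policed by bounds (k > 0, t₁ᐟ₂
inside the observed span) rather than exceptions so plate-wide batch runs
never abort.  Halftime statistics are the mean and sample sd over
converged replicates only; zero converged replicates mark the condition
"no aggregation observed" rather than raising.  No lag-time parameter is
extracted — the halftime is the reported summary.

## LLPS saturation concentration

The ladder pools the four no-LLPS concentrations (0, 4, 8, 12 µM) into one
baseline of 12 wells and tests each higher concentration's 3 wells against
it, two-sided, walking upward; the first p < 0.05 is Csat.  No
multiple-testing correction is applied, matching the raw per-test rule;
the resulting family-wise null detection rate (≈ 1 − 0.95⁷ ≈ 0.30 over the
seven tested concentrations) is measured in the test suite.  The default
test is the pooled-variance Student t: at these sample sizes (12 vs 3) the
Welch test's actual size is ≈ 0.07 per test, inflating the family-wise
rate past the α·(number tested) bound the package guarantees, while the
pooled test is exactly sized (and is what the common `ttest_ind` default
computes).  Welch remains available via `equal_var=False` for data whose
dense-phase wells have visibly inflated variance.  Zero-variance
comparisons are decided by the means: identical means are "not
significant" (p undefined), distinct means are the noise → 0 limit of an
arbitrarily large t statistic (p = 0).

## Ion mobility

Peak centers are intensity-weighted centroids within the FWHM window
(maximum-bin mode behind a flag; on synthetic Gaussian distributions the
two differ by less than the reported CCS uncertainty).  The step-field
regression is OLS of tA on 1/ΔV; K0 = K·(p/760)·(273.15/T) with
L = 78.1 cm, T = 297 K, p = 3.89 Torr as instrument defaults.  The
Mason–Schamp conversion pins CODATA 2018 constants in one table; the
reduced mass uses the ion and buffer-gas (helium) masses.  First-order
propagation of ΔL = 0.2 cm, ΔT = 1 K, Δp = 0.01 Torr gives ≈ 0.6%
relative CCS uncertainty; the reported uncertainty applies a 2.0% floor
that accounts for calibration terms outside this propagation.  The CCS
distribution is the linear map CCS = a·(tA − t0) with a anchored so the
lowest-voltage peak center lands on the regression CCS.

## Cross-condition statistics

Correlations are simple OLS (a Deming option exists but is off by
default, matching how such panels are usually presented); conditions with
undefined quantities (no halftime for a non-aggregating control, no Csat
when none was detected) are excluded with the reason recorded in the
result.  Constant-x or constant-y panels report undefined slope/R² rather
than raising.  The elbow rule is the maximum second difference of the
within-cluster sum of squares over k = 1..k_max (10 k-means restarts,
fixed seed), ties toward smaller k, with a "no strong elbow" flag when the
best curvature is under 5% of the total WCSS drop; the WCSS curve is
asserted non-increasing on every run.

## Synthetic data: what it emulates, and what not

Generators are pure functions of their parameters and seed, and every
dataset can be written with a truth record.  They emulate: Debye
scattering with known Rg; pivot-algorithm self-avoiding walks (burn-in
10·N accepted pivots, one sample per N accepted pivots; lattice spacing
0.38 nm, the Cα–Cα distance — it scales absolute Rg only, never ν);
Debye-sum ensemble scattering; SEC-SAXS elutions obeying the virial
relation exactly with a synchronized noiseless UV trace; logistic ThT
traces; step-plate turbidity; and Gaussian arrival-time distributions with
exact tA = t0 + L²/(K·ΔV) centers.  Noise is Gaussian everywhere (reduced
SAXS errors and plate readers are near-Gaussian), recorded in the sigma
columns so χ² diagnostics stay meaningful.

Not emulated: detector geometry and azimuthal integration, radiation
damage beyond what χ² rejection sees, inter-frame drift, UV noise and
detector lag (the lag *correction* is tested by construction), non-Gaussian
plate artifacts, and real charge-state distributions.  Passing tests
therefore certify the estimators against their own generating models —
parameter recovery, invariances, error calibration — not robustness to
every artifact of real beamline or instrument data.

## Problem sizes in tests

The default suite and the acceptance script use desk-scale sizes chosen as
the smallest that make the statistical assertions stable: 200 SAW walks
per chain length at N ≤ 400, 50-seed medians for noisy-recovery checks,
200 seeds for interval coverage, 1000 plates for the null-detection rate.
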