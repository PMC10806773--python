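# idplink

Quantitative analysis chain linking the **monomer conformation of an
intrinsically disordered protein (IDP)** — measured by small-angle X-ray
scattering (SAXS) and native ion-mobility mass spectrometry — to its
**aggregation propensity** (thioflavin-T kinetics) and **liquid–liquid
phase separation** (turbidity assays).  The motivating use case is
single-point mutants of a tau fragment, where subtle changes in monomer
expansion (radius of gyration Rg, Flory exponent ν, second virial
coefficient A2, collision cross section) track the aggregation halftime and
the LLPS saturation concentration across mutants.

The package is written for structural biologists and biophysicists who
have reduced 1D SAXS profiles, SEC-SAXS frame series with an in-line UV
trace, plate-reader kinetic/endpoint CSVs, or step-field drift-tube
arrival-time distributions, and want the full chain — reduction,
per-technique fits, and cross-condition statistics — in one tested,
scriptable toolbox.  A synthetic-data module generates every input type
with known ground truth, so the whole pipeline is verifiable without any
beamline or instrument data.

## Methods at a glance

- **Window-scanned Guinier analysis** (`GuinierModel`): ln I(q) = ln I(0) −
  q²Rg²/3 is fitted on *every* contiguous subdivision of the fitting
  region, from 6 points to the full region; the window-wise Rg estimates
  form a frequency histogram whose count-weighted average is the reported
  Rg.  A narrow histogram certifies a proper linear Guinier region.
- **Flory exponent** (`FloryModel`): the generalized Debye (excluded-volume
  polymer) form factor P(q) = 1/(νU^{1/2ν}) γ(1/2ν, U) − 1/(νU^{1/ν})
  γ(1/ν, U), U = (2ν+1)(2ν+2)q²Rg²/6, fitted over q·Rg ≤ 4 with free
  (I0, Rg, ν).  At ν = 1/2 this is exactly the Debye function of an ideal
  chain; ν ≈ 0.588 is the swollen self-avoiding limit.
- **Second virial coefficient** (`VirialModel`): per-frame forward
  intensities I(0, c) from SEC-SAXS paired with UV-derived concentrations
  obey K·c/I(0,c) = 1/Mw + 2·A2·c; A2 follows from the slope/intercept
  ratio and is invariant to the instrument constant K.  Positive A2 =
  repulsive interactions.
- **Aggregation kinetics** (`SigmoidModel`): normalized ThT traces fitted
  with s(t) = F/(1 + exp(−k(t − t₁ᐟ₂))); replicates fitted independently,
  halftimes summarized as mean ± sd.
- **LLPS saturation concentration** (`CsatModel`): absorbances at 0/4/8/12
  µM pool into a baseline; walking up the plate, the lowest concentration
  whose t test against the baseline gives p < 0.05 is Csat.
- **Collision cross sections** (`StepFieldModel`): step-field regression
  tA = t0 + L²/(K·ΔV) separates the reduced mobility K0 (slope) from the
  dead time t0 (intercept); the Mason–Schamp relation converts K0 to a CCS,
  and the lowest-voltage arrival-time distribution maps linearly onto a CCS
  distribution anchored at the regression CCS.
- **Cross-condition statistics** (`regress`, `elbow_k`): OLS panels
  (halftime vs Rg, Csat vs Rg, ν vs Rg, …) with R², undefined quantities
  excluded with recorded reasons, and a k-means elbow check of how many
  conformational/kinetic groups the conditions form.
- **Self-avoiding-walk reference** (`saw_ensemble`): pivot-algorithm SAWs
  on the cubic lattice provide the ν ≈ 0.59 good-solvent calibration via
  Rg ~ N^ν scaling and Debye-sum scattering.

Every `Model.fit()` returns a results object carrying parameters,
uncertainties and diagnostics, with `summary()`, JSON round-trip
(`idplink.io.write_result`/`read_result`) and, where it helps, `plot()`.

## Worked example

```python
import numpy as np
from idplink import GuinierModel, FloryModel, SigmoidModel
from idplink.guinier import auto_region
from idplink.synth import debye_profile, tht_traces
from idplink.kinetics import halftime_stats

# a noisy ideal-chain curve with known Rg = 4.1 nm
q = np.linspace(0.02, 2.0, 300)                    # nm^-1
profile = debye_profile(rg_nm=4.1, i0=100.0, q_grid=q, noise_rel=0.01, seed=0)

g = GuinierModel(profile, region=auto_region(profile)).fit()
print(f"Rg = {g.rg:.2f} +/- {g.rg_uncertainty:.2f} nm  ({g.n_windows} windows)")

f = FloryModel(profile).fit()
print(f"nu = {f.nu:.3f} +/- {f.nu_stderr:.3f}, Rg = {f.rg:.2f} nm")

t = np.linspace(0.0, 110.0, 100)                   # hours
fits = [SigmoidModel(tr).fit()
        for tr in tht_traces(1.0, 0.25, 40.0, t, 0.05, 3, seed=1)]
s = halftime_stats({"mutant A": fits})[0]
print(f"t1/2 = {s.t_half_mean:.1f} +/- {s.t_half_sd:.1f} h "
      f"over {s.n_converged} replicates")
```

prints

```
Rg = 4.00 +/- 0.35 nm  (435 windows)
nu = 0.498 +/- 0.002, Rg = 4.09 nm
t1/2 = 40.2 +/- 0.1 h over 3 replicates
```

The window-scan Rg of 4.00 ± 0.35 nm recovers the generating 4.1 nm within
its histogram width; the form-factor exponent ν ≈ 0.50 identifies the curve
as an ideal (theta-solvent) chain, as it should for Debye-function input;
and the sigmoid halftime reproduces the generating 40 h to well under the
replicate scatter.

## Command line

`idplink` exposes the stages as subcommands — `synth`, `reduce`, `rg`,
`flory`, `a2`, `tht`, `csat`, `ccs`, `correlate` — and `pipeline`, which
runs everything over a study directory (the layout `synth` writes) and
finishes with the cross-condition correlation panel:

```sh
idplink synth study/ --seed 7
idplink pipeline study/ results/ --seed 7
```

Each output directory contains a `manifest.json` (command, config
snapshot, input hashes, version, seed, timestamp).

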