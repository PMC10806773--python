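"""Step-field regression, Mason-Schamp conversion, CCS reconstruction."""

import numpy as np
import pytest

from idplink.datatypes import Instrument, StepFieldData, ValidationError
from idplink.ims import (
    CONSTANTS,
    StepFieldModel,
    fit_stepfield,
    mobility_to_ccs,
    peak_center,
    propagated_ccs_uncertainty,
    reconstruct_ccs_distribution,
)
from idplink.synth import ims_arrival

INST = Instrument(charge=10, ion_mass_da=20570.0)

# Frozen by two independent evaluations of the Mason-Schamp relation
# (pinned-constants route vs scipy.constants with the raw-mobility/actual-
# density route), agreeing to 7e-10 relative:
# z = 10, m_ion = 20570 Da, helium, T = 297 K, K0 = 1 cm^2 V^-1 s^-1.
CCS_REFERENCE_A2 = 5369.0334006


class TestConstants:
    def test_pinned_codata_literals(self):
        assert CONSTANTS["e_C"] == 1.602176634e-19
        assert CONSTANTS["kb_J_per_K"] == 1.380649e-23
        assert CONSTANTS["da_kg"] == 1.66053906660e-27
        assert CONSTANTS["n0_per_m3"] == pytest.approx(2.6867801e25, rel=1e-7)


class TestFitStepField:
    def test_exact_round_trip(self):
        data = ims_arrival(1.2, 0.7, [400, 500, 600, 700, 800], instrument=INST)
        res = StepFieldModel(data).fit()
        assert res.k0 == pytest.approx(1.2, rel=1e-9)
        assert res.t0 == pytest.approx(0.7, rel=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_voltages_with_warning(self):
        data = ims_arrival(1.0, 0.5, [400, 800], instrument=INST)
        res = StepFieldModel(data).fit()
        assert res.k0 == pytest.approx(1.0, rel=1e-9)
        assert any("5 drift voltages" in w for w in res.warnings)

    def test_input_order_invariance(self):
        centers = [(400.0, 10.0), (800.0, 5.3), (600.0, 6.9)]
        a = fit_stepfield(centers, INST)
        b = fit_stepfield(centers[::-1], INST)
        assert a[0] == pytest.approx(b[0], rel=1e-12)

    def test_negative_slope_rejected(self):
        with pytest.raises(ValidationError):
            fit_stepfield([(400.0, 1.0), (800.0, 5.0)], INST)


class TestMasonSchamp:
    def test_frozen_dual_implementation_value(self):
        assert mobility_to_ccs(1.0, INST) == pytest.approx(CCS_REFERENCE_A2,
                                                           rel=1e-6)

    def test_linear_in_charge(self):
        double_z = Instrument(charge=20, ion_mass_da=20570.0)
        assert mobility_to_ccs(1.0, double_z) == pytest.approx(
            2.0 * mobility_to_ccs(1.0, INST), rel=1e-12)

    def test_heavy_ion_limit(self):
        # m_ion -> inf: mu -> m_gas; CCS scales as sqrt(mu_finite/mu_inf)
        heavy = Instrument(charge=10, ion_mass_da=1e12)
        m_i, m_g = 20570.0, INST.gas_mass_da
        mu_finite = m_i * m_g / (m_i + m_g)
        ratio = mobility_to_ccs(1.0, INST) / mobility_to_ccs(1.0, heavy)
        assert ratio == pytest.approx(np.sqrt(m_g / mu_finite), rel=1e-6)

    def test_missing_mass_rejected(self):
        with pytest.raises(ValidationError):
            mobility_to_ccs(1.0, Instrument(charge=10))


class TestReconstruction:
    def test_anchor_point_maps_to_ccs_peak(self):
        ta = np.linspace(10.0, 14.0, 100)
        counts = np.exp(-0.5 * ((ta - 12.0) / 0.3) ** 2)
        ccs_grid, inten, a = reconstruct_ccs_distribution(ta, counts, 0.5, 5000.0)
        t_peak = peak_center(ta, counts)
        assert a * (t_peak - 0.5) == pytest.approx(5000.0, rel=1e-12)

    def test_symmetric_atd_gives_symmetric_ccs(self):
        ta = np.linspace(10.0, 14.0, 101)
        counts = np.exp(-0.5 * ((ta - 12.0) / 0.4) ** 2)
        ccs_grid, inten, a = reconstruct_ccs_distribution(ta, counts, 0.0, 6000.0)
        np.testing.assert_allclose(inten, inten[::-1], rtol=1e-12)
        mid = ccs_grid[len(ccs_grid) // 2]
        assert mid == pytest.approx(6000.0, rel=1e-9)

    def test_linearity_in_drift_time(self):
        # CCS(tA) = a (tA - t0): doubling every (tA - t0) at fixed scale
        # factor doubles every CCS value
        ta = np.linspace(10.0, 14.0, 50)
        counts = np.exp(-0.5 * ((ta - 12.0) / 0.3) ** 2)
        t0 = 2.0
        g1, _, a = reconstruct_ccs_distribution(ta, counts, t0, 5000.0)
        doubled = a * (2.0 * (ta - t0))
        np.testing.assert_allclose(doubled, 2.0 * g1, rtol=1e-12)

    def test_peak_before_t0_rejected(self):
        ta = np.linspace(1.0, 2.0, 10)
        counts = np.ones(10)
        with pytest.raises(ValidationError):
            reconstruct_ccs_distribution(ta, counts, 5.0, 5000.0)


class TestFullPipeline:
    def test_zero_noise_ccs_round_trip(self):
        k0_true = 0.95
        data = ims_arrival(k0_true, 0.6, [400, 500, 600, 700, 800],
                           instrument=INST)
        res = StepFieldModel(data).fit()
        assert res.ccs == pytest.approx(mobility_to_ccs(k0_true, INST),
                                        rel=1e-9)

    def test_centroid_vs_max_within_uncertainty(self):
        data = ims_arrival(1.0, 0.5, [400, 500, 600, 700, 800],
                           instrument=INST, peak_rel_width=0.03)
        a = StepFieldModel(data, center_mode="centroid").fit()
        b = StepFieldModel(data, center_mode="max").fit()
        assert abs(a.ccs - b.ccs) / a.ccs < a.ccs_uncertainty_rel

    def test_uncertainty_floor_and_propagation(self):
        res = StepFieldModel(
            ims_arrival(1.0, 0.5, [400, 500, 600, 700, 800], instrument=INST)
        ).fit()
        # L, T, p terms: 2*0.2/78.1, 0.01/3.89, 0.5*1/297 in quadrature
        assert res.propagated_rel == pytest.approx(0.00597, rel=0.01)
        assert res.ccs_uncertainty_rel == 0.020
        assert propagated_ccs_uncertainty(INST) == res.propagated_rel
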