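"""Generators: closed forms, determinism, self-avoidance, scaling."""

import numpy as np
import pytest

from idplink.datatypes import Instrument
from idplink.ims import fit_stepfield, peak_center
from idplink.saw import (
    random_walk_ensemble,
    saw_ensemble,
    scaling_exponent,
    walk_rg2,
)
from idplink.synth import (
    debye_function,
    debye_profile,
    ims_arrival,
    llps_plate,
    scattering_from_ensemble,
    sec_saxs_series,
    tht_traces,
)


class TestDebyeProfile:
    def test_normalization_limit(self):
        prof = debye_profile(3.0, 7.5, np.array([1e-8, 0.01]))
        assert prof.intensity[0] == pytest.approx(7.5, rel=1e-9)

    def test_closed_form_at_x_one(self):
        # (q*rg)^2 = 1 -> D = 2/e
        prof = debye_profile(2.0, 1.0, np.array([0.5]))
        assert prof.intensity[0] == pytest.approx(2.0 * np.exp(-1.0), rel=1e-12)

    def test_zero_noise_is_seed_independent(self):
        q = np.linspace(0.01, 1.0, 20)
        a = debye_profile(3.0, 1.0, q, noise_rel=0.0, seed=1)
        b = debye_profile(3.0, 1.0, q, noise_rel=0.0, seed=99)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_invalid_rg(self):
        with pytest.raises(ValueError):
            debye_profile(-1.0, 1.0, np.array([0.1]))


def _simple_sampling_saw(n_beads, n_walks, seed):
    """Rejection-sampled SAWs (non-reversal walk + self-avoidance test).

    Exact uniform sampler over non-reversal SAWs; tractable only for short
    chains, which is what makes it an independent oracle for the pivot
    sampler.
    """
    rng = np.random.default_rng(seed)
    steps = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                      [0, -1, 0], [0, 0, 1], [0, 0, -1]])
    walks = []
    while len(walks) < n_walks:
        pos = [(0, 0, 0)]
        seen = {(0, 0, 0)}
        last = None
        ok = True
        for _ in range(n_beads - 1):
            choices = [i for i in range(6) if last is None or i != last ^ 1]
            i = choices[rng.integers(len(choices))]
            nxt = tuple(np.array(pos[-1]) + steps[i])
            if nxt in seen:
                ok = False
                break
            pos.append(nxt)
            seen.add(nxt)
            last = i
        if ok:
            walks.append(np.array(pos))
    return walks


class TestSAWEnsemble:
    def test_self_avoidance_and_shape(self):
        ens = saw_ensemble(10, 5, seed=7)
        assert len(ens.walks) == 5
        for w in ens.walks:
            assert len({tuple(r) for r in w}) == 10

    def test_determinism(self):
        a = saw_ensemble(20, 4, seed=3)
        b = saw_ensemble(20, 4, seed=3)
        for wa, wb in zip(a.walks, b.walks):
            np.testing.assert_array_equal(wa, wb)

    def test_mean_rg2_matches_rejection_sampling_oracle(self):
        # independent exact sampler at small N; compare <Rg^2> within MC error
        n = 14
        pivot = saw_ensemble(n, 400, seed=11)
        oracle_walks = _simple_sampling_saw(n, 400, seed=12)
        r_pivot = pivot.rg2()
        r_oracle = np.array([walk_rg2(w) for w in oracle_walks])
        se = np.sqrt(r_pivot.var() / len(r_pivot) + r_oracle.var() / len(r_oracle))
        assert abs(r_pivot.mean() - r_oracle.mean()) < 4.0 * se

    def test_scaling_exponent_in_saw_range(self):
        # short-chain sweep: effective exponent slightly above the
        # asymptotic 0.588 is expected at these lengths
        ens = [saw_ensemble(n, 120, seed=100 + n) for n in (40, 80, 160)]
        nu, _ = scaling_exponent(ens)
        assert 0.55 < nu < 0.66


class TestScatteringFromEnsemble:
    def test_collinear_rod_closed_form(self):
        from idplink.saw import ChainEnsemble

        # rod of N beads: I(q) = (1/N^2) sum_ij sinc(q a |i-j|), the N-bead
        # generalization of the two-bead (1 + sinc(qd))/2 identity
        rod = np.array([[i, 0, 0] for i in range(10)])
        ens = ChainEnsemble(walks=[rod], n_beads=10, seed=0, bead_spacing_nm=1.0)
        q = np.array([0.3, 0.7])
        got = scattering_from_ensemble(ens, q).intensity
        n = 10
        expect = np.zeros_like(q)
        for i in range(n):
            for j in range(n):
                d = abs(i - j)
                expect += np.sinc(q * d / np.pi)
        expect /= n**2
        np.testing.assert_allclose(got, expect, rtol=1e-12)

    def test_forward_scattering_is_one(self):
        ens = random_walk_ensemble(20, 3, seed=5)
        prof = scattering_from_ensemble(ens, np.array([0.0, 0.5]))
        assert prof.intensity[0] == pytest.approx(1.0, abs=1e-12)

    def test_ideal_walk_matches_debye_at_matched_rg(self):
        # distributional identity at N=200, 500 walks, 3 q points
        ens = random_walk_ensemble(200, 500, seed=7)
        rg = ens.rg_nm()
        q = np.array([0.5, 1.0, 1.5]) / rg
        ens_i = scattering_from_ensemble(ens, q).intensity
        deb_i = debye_profile(rg, 1.0, q).intensity
        np.testing.assert_allclose(ens_i, deb_i, rtol=0.02)


class TestSecSAXS:
    q = np.geomspace(0.01, 1.5, 80)

    def _series(self, a2, noise=0.0, seed=0):
        t = np.arange(0.0, 30.0)
        c = 8e-4 * np.exp(-0.5 * ((t - 15.0) / 4.0) ** 2)
        c[c < 0.02 * c.max()] = 0.0
        return sec_saxs_series(20570.0, a2, list(zip(t + 10.0, c)), self.q,
                               rg_nm=4.0, noise_rel=noise, seed=seed)

    def test_zero_a2_constant_i0_over_c(self):
        # at A2 = 0 the forward intensity is proportional to c
        series, truth = self._series(0.0)
        buf = series.frames[0].intensity
        uv = series.uv[:, 1]
        cs = uv / (truth["epsilon"] * truth["path_cm"]) * truth["mw_da"] / 1000.0
        i0s = np.array([fr.intensity[0] for fr in series.frames]) - buf[0]
        keep = cs > 0
        r = i0s[keep] / cs[keep]
        np.testing.assert_allclose(r, r[0], rtol=1e-9)

    def test_positive_a2_monotone_c_over_i0(self):
        # ramp elution: strictly distinct concentrations
        t = np.arange(0.0, 20.0)
        c = 8e-4 * (t + 1.0) / 20.0
        series, truth = sec_saxs_series(20570.0, 5e-4, list(zip(t + 10.0, c)),
                                        self.q, rg_nm=4.0)
        buf = series.frames[0].intensity[0]
        uv = series.uv[:, 1]
        cs = uv / (truth["epsilon"] * truth["path_cm"]) * truth["mw_da"] / 1000.0
        i0s = np.array([fr.intensity[0] for fr in series.frames]) - buf
        keep = cs > 0
        order = np.argsort(cs[keep])
        y = (cs[keep] / i0s[keep])[order]
        assert np.all(np.diff(y) > 0)

    def test_all_zero_concentration_rejected(self):
        with pytest.raises(ValueError):
            sec_saxs_series(20570.0, 0.0, [(0.0, 0.0), (1.0, 0.0)], self.q, 4.0)


class TestThTTraces:
    def test_midpoint_and_plateau(self):
        t = np.arange(0.0, 110.5, 0.5)  # grid contains t_half = 40.0 exactly
        tr = tht_traces(2.0, 0.5, 40.0, t, 0.0, 1, 0)[0]
        i_mid = int(np.nonzero(t == 40.0)[0][0])
        assert tr.signal[i_mid] == pytest.approx(1.0, rel=1e-9)  # f/2
        assert tr.signal[-1] == pytest.approx(2.0, rel=1e-9)

    def test_seed_reproducibility(self):
        t = np.linspace(0, 110, 50)
        a = tht_traces(1.0, 0.3, 50.0, t, 0.05, 3, seed=4)
        b = tht_traces(1.0, 0.3, 50.0, t, 0.05, 3, seed=4)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.signal, y.signal)


class TestLLPSPlate:
    def test_structure_and_reproducibility(self):
        conc = np.arange(0.0, 44.0, 4.0)
        a = llps_plate(24.0, conc, 0.05, 0.4, 0.01, seed=2)
        b = llps_plate(24.0, conc, 0.05, 0.4, 0.01, seed=2)
        np.testing.assert_array_equal(a.absorbance, b.absorbance)
        assert len(a.absorbance) == 3 * len(conc)

    def test_step_location(self):
        conc = np.arange(0.0, 44.0, 4.0)
        plate = llps_plate(24.0, conc, 0.05, 0.4, 0.0, seed=0)
        assert plate.absorbances_at(20.0).mean() == pytest.approx(0.05)
        assert plate.absorbances_at(24.0).mean() == pytest.approx(0.45)


class TestIMSArrival:
    def test_noiseless_centers_regress_exactly(self):
        inst = Instrument(charge=10, ion_mass_da=20570.0)
        data = ims_arrival(1.2, 0.7, [400, 500, 600, 700, 800], instrument=inst)
        centers = [(dv, peak_center(ta, c)) for dv, ta, c in data.records]
        k0, t0, reg = fit_stepfield(centers, inst)
        assert k0 == pytest.approx(1.2, rel=1e-9)
        assert t0 == pytest.approx(0.7, rel=1e-9)
        assert reg["r_squared"] == pytest.approx(1.0, abs=1e-12)

    def test_high_voltage_limit_approaches_t0(self):
        inst = Instrument(charge=10, ion_mass_da=20570.0)
        data = ims_arrival(1.0, 0.5, [1e8, 2e8], instrument=inst)
        centers = [peak_center(ta, c) for _, ta, c in data.records]
        assert centers[0] == pytest.approx(0.5, rel=1e-3)
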