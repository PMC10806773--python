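"""Frame rejection, averaging, buffer subtraction, SEC frame selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from idplink.datatypes import FrameSeries, SAXSProfile, ValidationError
from idplink.reduce import (
    DetectionError,
    average_frames,
    reject_outlier_frames,
    select_sec_frames,
    subtract_buffer,
    uv_to_concentration,
)

Q = np.linspace(0.05, 1.0, 30)


def _frame(intensity, sigma=None, label=""):
    return SAXSProfile(q=Q, intensity=np.asarray(intensity, dtype=float),
                       sigma=sigma, label=label)


def _noisy_frames(n, seed, sd=0.02):
    rng = np.random.default_rng(seed)
    base = 10.0 * np.exp(-(Q * 3.0) ** 2 / 3.0)
    return [_frame(base + rng.normal(0, sd, size=Q.shape)) for _ in range(n)]


class TestRejectOutliers:
    def test_identical_frames_all_kept(self):
        frames = [_frame(np.ones_like(Q))] * 10
        rep = reject_outlier_frames(frames)
        assert rep.rejected == [] and len(rep.kept) == 10
        assert rep.sd_distance == 0.0

    def test_spiked_frame_is_unique_rejection(self):
        frames = _noisy_frames(10, seed=0)
        bad = frames[4].intensity.copy()
        bad[10] *= 2.0
        frames[4] = _frame(bad)
        rep = reject_outlier_frames(frames)
        assert rep.rejected == [4]

    def test_threshold_monotonicity(self):
        frames = _noisy_frames(12, seed=3)
        kept2 = set(reject_outlier_frames(frames, 2.0).kept)
        kept3 = set(reject_outlier_frames(frames, 3.0).kept)
        assert kept2 <= kept3

    def test_too_few_frames(self):
        with pytest.raises(ValidationError):
            reject_outlier_frames(_noisy_frames(2, seed=1))

    @given(perm_seed=st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_permutation_equivariance(self, perm_seed):
        frames = _noisy_frames(8, seed=5)
        rng = np.random.default_rng(perm_seed)
        perm = rng.permutation(8)
        rep = reject_outlier_frames(frames)
        rep_p = reject_outlier_frames([frames[i] for i in perm])
        assert {int(perm[i]) for i in range(8)} == set(range(8))
        assert sorted(perm[rep_p.kept]) == sorted(rep.kept)


class TestAverageFrames:
    def test_identical_frames(self):
        frames = [_frame(np.full_like(Q, 2.0))] * 4
        avg = average_frames(frames)
        np.testing.assert_array_equal(avg.intensity, frames[0].intensity)

    def test_mean_of_scaled_frames(self):
        frames = [_frame(np.ones_like(Q)), _frame(3.0 * np.ones_like(Q))]
        avg = average_frames(frames)
        np.testing.assert_allclose(avg.intensity, 2.0)

    def test_averaged_sigma_scales_as_sqrt_n(self):
        # n iid frames with noise sd s: averaged sigma ~ s/sqrt(n)
        n, s = 100, 0.5
        rng = np.random.default_rng(42)
        frames = [_frame(5.0 + rng.normal(0, s, size=Q.shape)) for _ in range(n)]
        avg = average_frames(frames)
        expected = s / np.sqrt(n)
        assert np.median(avg.sigma) == pytest.approx(expected, rel=0.2)

    def test_empty_selection(self):
        with pytest.raises(ValidationError):
            average_frames(_noisy_frames(3, 0), kept=[])


class TestSubtractBuffer:
    def test_self_subtraction_zero(self):
        f = _frame(np.linspace(1, 2, len(Q)))
        sub = subtract_buffer(f, f)
        np.testing.assert_array_equal(sub.intensity, 0.0)

    def test_sigma_quadrature(self):
        a = _frame(np.ones_like(Q), sigma=np.ones_like(Q))
        b = _frame(np.ones_like(Q), sigma=np.ones_like(Q))
        sub = subtract_buffer(a, b)
        np.testing.assert_allclose(sub.sigma, np.sqrt(2.0))

    @given(seed=st.integers(0, 500))
    @settings(max_examples=20, deadline=None)
    def test_subtract_then_add_back(self, seed):
        # dyadic intensities: subtraction and re-addition are exact
        rng = np.random.default_rng(seed)
        sample = _frame(rng.integers(8, 64, size=len(Q)) / 16.0)
        buffer = _frame(rng.integers(1, 8, size=len(Q)) / 16.0)
        sub = subtract_buffer(sample, buffer)
        np.testing.assert_array_equal(sub.intensity + buffer.intensity,
                                      sample.intensity)

    def test_grid_mismatch(self):
        other = SAXSProfile(q=Q * 1.1, intensity=np.ones_like(Q))
        with pytest.raises(ValidationError):
            subtract_buffer(_frame(np.ones_like(Q)), other)


def _uv_series(uv_values):
    frames = [SAXSProfile(q=Q, intensity=np.ones_like(Q))
              for _ in range(len(uv_values))]
    times = np.arange(len(uv_values), dtype=float)
    uv = np.column_stack([times, uv_values])
    return FrameSeries(frames=frames, times=times, uv=uv)


class TestSelectSecFrames:
    def test_gaussian_peak_selection(self):
        t = np.arange(60, dtype=float)
        uv = 0.4 * np.exp(-0.5 * ((t - 40.0) / 4.0) ** 2)
        uv[uv < 1e-4] = 0.0
        series = _uv_series(uv)
        sample, buffer = select_sec_frames(series)
        assert min(sample) <= 40 <= max(sample)
        assert max(buffer) < min(sample)
        assert len(buffer) == 10

    def test_flat_uv_detection_error(self):
        series = _uv_series(np.full(20, 0.1))
        with pytest.raises(DetectionError):
            select_sec_frames(series)

    def test_manual_passthrough(self):
        series = _uv_series(np.zeros(10))
        s, b = select_sec_frames(series, mode="manual",
                                 sample_indices=[5, 6], buffer_indices=[1, 2])
        assert s == [5, 6] and b == [1, 2]


class TestUVToConcentration:
    def test_beer_lambert_20_micromolar(self):
        # A280 = 0.056 with eps = 2800 M^-1 cm^-1 and 1 cm path -> 20 uM
        assert uv_to_concentration(0.056, 2800.0, 1.0) == pytest.approx(20e-6)

    def test_mass_concentration_mirror(self):
        molar, g_cm3 = uv_to_concentration(0.056, 2800.0, 1.0, mw_da=20570.0)
        assert g_cm3 == pytest.approx(4.114e-4, rel=1e-3)

    def test_negative_absorbance_clamped(self):
        assert uv_to_concentration(-0.01) == 0.0
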