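"""Unit tests of the censored-autocovariance PSD route and slope fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from boldslope.cohort import CohortSpec, synthesize_series
from boldslope.spectral import (
    Autocovariance,
    FrameSeries,
    censored_autocovariance,
    compare_spectral_models,
    estimate_ss_matrix,
    fit_spectral_slope,
    psd_via_cosine_transform,
    subject_ss_map,
    PowerSpectrum,
)


def brute_force_acv(values, valid, tr, max_lag):
    """Independent oracle: explicit loop over all valid frame pairs."""
    x = values - values[valid].mean()
    out = np.zeros(max_lag)
    for m in range(1, max_lag + 1):
        s, n = 0.0, 0
        for t in range(len(values) - (m - 1)):
            if valid[t] and valid[t + m - 1]:
                s += x[t] * x[t + m - 1]
                n += 1
        q = (m - 1) * tr / 30.0
        out[m - 1] = s * np.exp(-0.5 * q * q) / n if n else 0.0
    return out


class TestCensoredAutocovariance:
    def test_zero_lag_is_valid_frame_variance(self, rng):
        vals = rng.standard_normal(80)
        valid = rng.random(80) > 0.2
        acv = censored_autocovariance(FrameSeries(vals, 2.0, valid), max_lag=10)
        assert acv.q[0] == 0.0
        expected = np.var(vals[valid])
        assert acv.adjusted[0] == pytest.approx(expected, abs=1e-12)

    def test_full_mask_reduces_to_standard_estimator(self, rng):
        vals = rng.standard_normal(60)
        ts_masked = FrameSeries(vals, 1.5, np.ones(60, bool))
        ts_plain = FrameSeries(vals, 1.5)
        a = censored_autocovariance(ts_masked, max_lag=20)
        b = censored_autocovariance(ts_plain, max_lag=20)
        np.testing.assert_array_equal(a.adjusted, b.adjusted)
        x = vals - vals.mean()
        for m in (1, 5, 20):
            plain = (x[: 60 - (m - 1)] * x[m - 1 :]).sum() / (60 - (m - 1))
            taper = np.exp(-0.5 * ((m - 1) * 1.5 / 30.0) ** 2)
            assert b.adjusted[m - 1] == pytest.approx(plain * taper, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        n=st.integers(20, 100),
        seed=st.integers(0, 10_000),
        tr=st.sampled_from([0.7, 1.97, 3.0]),
    )
    def test_matches_brute_force_pair_enumeration(self, n, seed, tr):
        r = np.random.default_rng(seed)
        vals = r.standard_normal(n)
        valid = r.random(n) > 0.3
        if valid.sum() < 2:
            valid[:2] = True
        max_lag = min(n - 1, 30)
        acv = censored_autocovariance(FrameSeries(vals, tr, valid), max_lag=max_lag)
        oracle = brute_force_acv(vals, valid, tr, max_lag)
        np.testing.assert_allclose(acv.adjusted, oracle, atol=1e-12)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError, match="valid frames"):
            censored_autocovariance(
                FrameSeries(np.ones(10), 1.0, np.zeros(10, bool)), max_lag=3
            )
        with pytest.raises(ValueError, match="max_lag"):
            censored_autocovariance(FrameSeries(np.arange(10.0), 1.0), max_lag=10)


def _acv(adjusted, tr):
    m = np.arange(1, len(adjusted) + 1)
    return Autocovariance(
        lag_m=m,
        q=(m - 1) * tr / 30.0,
        raw_sum=np.asarray(adjusted, float),
        n_pairs=np.ones(len(adjusted), dtype=int),
        adjusted=np.asarray(adjusted, float),
        tr=tr,
    )


class TestCosineTransform:
    def test_delta_acv_gives_flat_spectrum(self):
        adjusted = np.zeros(40)
        adjusted[0] = 2.0
        ps = psd_via_cosine_transform(_acv(adjusted, 1.97))
        assert ps.freq[0] == 0.0
        assert ps.freq[-1] == pytest.approx(1.0 / (2 * 1.97))
        np.testing.assert_allclose(ps.power, 1.97 * 2.0, rtol=1e-12)

    def test_cosine_acv_peaks_at_its_frequency(self):
        tr, f0 = 1.97, 0.08
        m = np.arange(1, 60)
        adjusted = np.cos(2 * np.pi * f0 * (m - 1) * tr)
        ps = psd_via_cosine_transform(_acv(adjusted, tr))
        peak = ps.freq[np.argmax(ps.power)]
        assert abs(peak - f0) <= ps.freq[1] - ps.freq[0]

    def test_agrees_with_direct_matrix_dft(self, rng):
        tr = 2.5
        adjusted = rng.standard_normal(30)
        ps = psd_via_cosine_transform(_acv(adjusted, tr), n_freq=64)
        # independent oracle: explicit cosine-matrix multiplication
        freq = np.arange(65) / (2 * 64 * tr)
        w = np.full(30, 2.0)
        w[0] = 1.0
        oracle = tr * np.cos(
            2 * np.pi * np.outer(freq, np.arange(30) * tr)
        ) @ (w * adjusted)
        floored = np.maximum(oracle, 1e-12 * oracle.max())
        np.testing.assert_allclose(ps.power, floored, atol=1e-10)

    def test_empty_acv_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            psd_via_cosine_transform(_acv(np.empty(0), 1.0))


def _spectrum(freq, power):
    eps = 1e-12 * power.max()
    return PowerSpectrum(freq=freq, power=np.maximum(power, eps))


class TestSlopeFit:
    @pytest.mark.parametrize("s", [5.0, 10.0, 20.0])
    def test_exact_semilog_data_recovered_exactly(self, s):
        freq = np.linspace(0.0, 0.25, 257)
        ps = _spectrum(freq, 10 ** (2.0 - s * freq))
        fit = fit_spectral_slope(ps)
        assert fit.slope == pytest.approx(s, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_flat_spectrum_has_zero_slope(self):
        freq = np.linspace(0.0, 0.25, 257)
        fit = fit_spectral_slope(_spectrum(freq, np.full(257, 3.0)))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_ar1_closed_form_spectrum_matches_independent_fit(self):
        from scipy.stats import linregress

        phi, tr = 0.9, 1.97
        freq = np.arange(257) / (2 * 256 * tr)
        power = tr / (1 - 2 * phi * np.cos(2 * np.pi * freq * tr) + phi**2)
        fit = fit_spectral_slope(_spectrum(freq, power))
        band = (freq >= 0.015) & (freq <= 0.145)
        oracle = linregress(freq[band], np.log10(power[band]))
        assert fit.slope == pytest.approx(-oracle.slope, abs=1e-10)
        assert fit.r2 == pytest.approx(oracle.rvalue**2, abs=1e-10)

    def test_amplitude_invariance(self, rng):
        freq = np.linspace(0.0, 0.25, 257)
        power = 10 ** (1.0 - 8.0 * freq) * (1 + 0.1 * rng.random(257))
        f1 = fit_spectral_slope(_spectrum(freq, power))
        f2 = fit_spectral_slope(_spectrum(freq, 7.3 * power))
        assert f1.slope == pytest.approx(f2.slope, rel=1e-12)

    def test_too_few_inband_points_rejected(self):
        freq = np.linspace(0.0, 0.25, 6)
        with pytest.raises(ValueError, match="grid resolution"):
            fit_spectral_slope(_spectrum(freq, np.ones(6)))


class TestModelComparison:
    def test_exact_semilog_prefers_semilog(self):
        freq = np.linspace(0.0, 0.25, 257)
        r2 = compare_spectral_models(_spectrum(freq, 10 ** (2 - 10 * freq)))
        assert r2["r2_semilog"] == pytest.approx(1.0, abs=1e-12)
        assert r2["r2_semilog"] > r2["r2_loglog"]

    def test_exact_power_law_prefers_loglog(self):
        freq = np.linspace(0.001, 0.25, 257)
        r2 = compare_spectral_models(_spectrum(freq, freq**-1.2))
        assert r2["r2_loglog"] == pytest.approx(1.0, abs=1e-12)
        assert r2["r2_loglog"] > r2["r2_semilog"]


class TestSubjectMap:
    def _series(self, rng, n_parcels=4, n=128):
        spec = CohortSpec(n_frames=n, tr=1.97, noise_floor=0.0, seed=0)
        vals = synthesize_series(np.full(n_parcels, 8.0), spec, rng, noise_floor=0.0)
        return {
            pid + 1: FrameSeries(vals[:, pid], 1.97) for pid in range(n_parcels)
        }

    def test_identical_series_give_constant_map(self, rng):
        base = self._series(rng, n_parcels=1)[1]
        series = {i: FrameSeries(base.values.copy(), base.tr) for i in (1, 2, 3)}
        out = subject_ss_map(series)
        assert out["ss"].nunique() == 1

    def test_scaling_one_parcel_leaves_its_slope_unchanged(self, rng):
        series = self._series(rng)
        out1 = subject_ss_map(series)
        series[2] = FrameSeries(series[2].values * 3.0, series[2].tr)
        out2 = subject_ss_map(series)
        assert out2.loc[2, "ss"] == pytest.approx(out1.loc[2, "ss"], rel=1e-9)

    def test_medial_wall_parcels_absent(self, rng):
        out = subject_ss_map(self._series(rng), medial_wall={2})
        assert list(out.index) == [1, 3, 4]

    def test_cohort_slopes_within_sane_bounds(self, default_ss_maps):
        # flooring caps a semilog fit at ~12 decades over the 0.13 Hz band,
        # so even floored steep spectra cannot exceed ~95 per Hz by much
        vals = default_ss_maps.to_numpy()
        assert np.isfinite(vals).all()
        assert vals.min() > -10 and vals.max() < 120
        assert (np.abs(vals) > 50).mean() < 0.01
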