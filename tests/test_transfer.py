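"""Empirical transfer functions: spectra, H(ω), and transmission features."""

import numpy as np
import pytest
from scipy import signal

from tractgain import (
    TransferFunctionEstimate,
    TransferFunctionEstimator,
    estimate_spectra,
    estimate_transfer_function,
    extract_features,
    pathway_features,
)
from tractgain.containers import BipolarPair, BipolarSession
from tractgain.errors import DataError, EmptyPathwayError, InsufficientDataError


FS = 1000.0


def _noise(n, rng):
    return rng.standard_normal(n)


class TestSpectra:
    def test_self_spectrum_equals_cross_spectrum(self, rng):
        x = _noise(2**16, rng)
        freqs, psd, cpsd = estimate_spectra(x, x, FS, window_len=2048)
        np.testing.assert_allclose(cpsd.real, psd, rtol=1e-10)
        assert np.all(psd >= 0)
        assert np.all(np.diff(freqs) > 0)

    def test_independent_noise_cross_spectrum_decays(self, rng):
        """|CPSD| of independent signals shrinks as averaging increases."""
        x = _noise(2**17, rng)
        y = _noise(2**17, rng)
        ratios = []
        for wl in (16384, 1024):
            _, psd, cpsd = estimate_spectra(x, y, FS, window_len=wl)
            ratios.append(np.median(np.abs(cpsd) / psd))
        assert ratios[1] < ratios[0] / 2  # ~1/sqrt(n_segments) decay

    def test_sinusoid_peak_at_nearest_bin(self, rng):
        t = np.arange(2**15) / FS
        x = np.sin(2 * np.pi * 37.3 * t) + 0.01 * _noise(t.size, rng)
        freqs, psd, _ = estimate_spectra(x, x, FS, window_len=4096)
        assert freqs[np.argmax(psd)] == pytest.approx(37.3, abs=FS / 4096)

    def test_short_record_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            estimate_spectra(_noise(1000, rng), _noise(1000, rng), FS, window_len=800)


class TestTransferFunction:
    def test_static_gain(self, rng):
        x = _noise(2**16, rng)
        tfe = estimate_transfer_function(x, 2.0 * x, FS, window_len=2048)
        np.testing.assert_allclose(np.abs(tfe.H), 2.0, rtol=1e-3)

    def test_pure_delay_unit_magnitude_linear_phase(self, rng):
        d = 25
        x = _noise(2**17, rng)
        y = np.roll(x, d)
        tfe = estimate_transfer_function(x[d:], y[d:], FS, window_len=4096)
        band = (tfe.freqs > 5) & (tfe.freqs < 400)
        np.testing.assert_allclose(np.abs(tfe.H)[band], 1.0, rtol=0.02)
        phase = np.unwrap(np.angle(tfe.H))
        slope = np.polyfit(tfe.freqs[band], phase[band], 1)[0]
        assert slope == pytest.approx(-2 * np.pi * d / FS, rel=0.02)

    @pytest.mark.parametrize("source", ["white", "pink"])
    def test_known_bandpass_matches_analytic_response(self, source, rng):
        """|H| within 5% of the analytic response in the passband, >= 60 averages."""
        b, a = signal.iirpeak(20.0, 2.0, fs=FS)
        sos = signal.tf2sos(5.0 * b, a)
        n = int(130 * FS)  # ~64 Welch segments at 4 s windows, 50% overlap
        x = _noise(n, rng)
        if source == "pink":
            x = signal.lfilter([0.05, -0.096, 0.051, -0.004],
                               [1, -2.495, 2.017, -0.522], x)
            x /= x.std()
        y = signal.sosfilt(sos, x)
        wl = int(4 * FS)
        tfe = estimate_transfer_function(x, y, FS, window_len=wl)
        _, h = signal.sosfreqz(sos, worN=tfe.freqs, fs=FS)
        ana = np.abs(h)
        passband = ana >= ana.max() / np.sqrt(2)
        dev = np.abs(np.abs(tfe.H)[passband] - ana[passband]) / ana[passband]
        assert dev.max() < 0.05
        assert tfe.freqs[np.argmax(np.abs(tfe.H))] == pytest.approx(
            20.0, abs=FS / wl + 1e-9
        )

    def test_regularization_monotone(self, rng):
        x = _noise(2**15, rng)
        y = np.convolve(x, [0.5, 0.3, 0.2], mode="same")
        mags = []
        for eps in (0.0, 1e-3, 1e-1):
            tfe = estimate_transfer_function(x, y, FS, epsilon=eps, window_len=1024)
            mags.append(np.abs(tfe.H))
        assert np.all(mags[1] <= mags[0] + 1e-12)
        assert np.all(mags[2] <= mags[1] + 1e-12)

    def test_scale_covariance(self, rng):
        x = _noise(2**15, rng)
        y = np.convolve(x, [1.0, -0.4], mode="same")
        f1 = TransferFunctionEstimator(fs=FS, window_len=1024).fit(x, y).features()
        f2 = TransferFunctionEstimator(fs=FS, window_len=1024).fit(x, 10 * y).features()
        assert f2.peak_gain_db == pytest.approx(f1.peak_gain_db + 20.0, abs=1e-6)
        if f1.rolloff_defined:
            assert f2.pf_ratio == pytest.approx(f1.pf_ratio, abs=1e-9)

    def test_zero_epsilon_with_zero_power_rejected(self):
        x = np.zeros(2**14)
        with pytest.raises(DataError):
            estimate_transfer_function(x, x, FS, epsilon=0.0, window_len=1024)


class TestFeatureExtraction:
    def test_monotone_response_pf_is_three_twentieths(self):
        """Peak at DC, floor 3 dB below by definition: PF = 3/20 = 0.15."""
        freqs = np.linspace(0, 100, 2001)
        mag = 10.0 * np.exp(-freqs / 10.0)
        feats = extract_features(TransferFunctionEstimate.from_response(freqs, mag))
        assert feats.omega_p == 0.0
        assert feats.pf_ratio == pytest.approx(0.15, abs=1e-12)

    def test_piecewise_response_hand_computed_pf(self):
        """dc gain 4, peak 10: floor = 4·10^(−3/20) ≈ 2.832, PF ≈ 0.548."""
        freqs = np.linspace(0, 50, 501)
        mag = np.full_like(freqs, 4.0)
        mag[(freqs >= 10) & (freqs <= 20)] = 10.0
        mag[freqs > 30] = 1.0
        feats = extract_features(TransferFunctionEstimate.from_response(freqs, mag))
        assert feats.dc_gain == 4.0
        assert feats.peak_gain == 10.0
        assert feats.floor_gain == pytest.approx(4 * 10 ** (-3 / 20), abs=1e-9)
        assert feats.pf_ratio == pytest.approx(
            np.log10(10.0 / (4 * 10 ** (-3 / 20))), abs=1e-9
        )
        assert feats.pf_ratio == pytest.approx(0.548, abs=1e-3)

    def test_flat_response_has_undefined_rolloff(self):
        freqs = np.linspace(0, 100, 401)
        feats = extract_features(
            TransferFunctionEstimate.from_response(freqs, np.ones_like(freqs))
        )
        assert not feats.rolloff_defined
        assert np.isnan(feats.omega_f) and np.isnan(feats.pf_ratio)

    def test_first_order_lowpass_rolloff_at_cutoff(self):
        """−3 dB point of 1/sqrt(1+(f/fc)²) detected at the half-power drop."""
        freqs = np.arange(0, 200.0001, 0.01)
        mag = 1.0 / np.sqrt(1.0 + (freqs / 10.0) ** 2)
        feats = extract_features(TransferFunctionEstimate.from_response(freqs, mag))
        assert feats.rolloff_defined
        drop_db = 20 * np.log10(1.0 / np.interp(feats.omega_f, freqs, mag))
        assert drop_db == pytest.approx(3.0, abs=0.01)

    def test_broadband_gain_leaves_pf_unchanged(self):
        freqs = np.linspace(0, 100, 1001)
        mag = 5.0 / np.sqrt(1.0 + (freqs / 15.0) ** 2)
        f1 = extract_features(TransferFunctionEstimate.from_response(freqs, mag))
        f2 = extract_features(TransferFunctionEstimate.from_response(freqs, 7 * mag))
        assert f2.pf_ratio == pytest.approx(f1.pf_ratio, abs=1e-12)

    def test_all_zero_magnitude_rejected(self):
        freqs = np.linspace(0, 10, 11)
        with pytest.raises(DataError):
            extract_features(
                TransferFunctionEstimate.from_response(freqs, np.zeros_like(freqs))
            )


def _bipolar(signals, regions, fs=FS):
    pairs = [
        BipolarPair(subject="S01", hemisphere="L", lead=f"L{i}", region=r,
                    contact_a=0, contact_b=1)
        for i, r in enumerate(regions)
    ]
    return BipolarSession(samples=np.vstack(signals), fs=fs, pairs=pairs)


class TestPathwayFeatures:
    def test_singleton_aggregate_equals_pair(self, rng):
        x = _noise(2**15, rng)
        y = np.convolve(x, [0.8, 0.2], mode="same")
        sess = _bipolar([x, y], ["GPi", "VoaVop"])
        agg, per = pathway_features(sess, "GPi", "VoaVop", window_len=1024)
        assert len(per) == 1 and len(agg) == 1
        assert agg.iloc[0]["peak_gain"] == pytest.approx(per.iloc[0]["peak_gain"])
        assert agg.iloc[0]["n_pairs"] == 1

    def test_mean_reduction_over_pairs(self, rng):
        x = _noise(2**15, rng)
        sess = _bipolar([x, 2.0 * x, 4.0 * x], ["GPi", "VoaVop", "VoaVop"])
        agg, per = pathway_features(sess, "GPi", "VoaVop", window_len=1024)
        assert len(per) == 2
        assert agg.iloc[0]["peak_gain"] == pytest.approx(
            per["peak_gain"].mean(), rel=1e-9
        )

    def test_missing_region_raises(self, rng):
        sess = _bipolar([_noise(2**14, rng)], ["GPi"])
        with pytest.raises(EmptyPathwayError):
            pathway_features(sess, "GPi", "VoaVop", window_len=1024)
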