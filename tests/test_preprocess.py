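"""Dyadic band selection and the two-pass coefficient-zeroing artifact rule."""

import numpy as np
import pytest

from fcgbnet import EEGRecording, WaveletBandSpec, band_select, dyadic_level, threshold_correct
from fcgbnet.preprocess import threshold_coefficients


def make_rec(data, fs=300.0):
    data = np.atleast_2d(data)
    if data.shape[0] == 1:
        data = np.vstack([data, data])
    return EEGRecording(data, fs=fs, channels=[f"c{i}" for i in range(data.shape[0])])


def spectral_energy_fraction(x, fs, band):
    """FFT oracle: fraction of periodogram energy inside ``band``."""
    freqs = np.fft.rfftfreq(x.size, 1 / fs)
    pxx = np.abs(np.fft.rfft(x)) ** 2
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return pxx[sel].sum() / pxx.sum()


class TestDyadicLevel:
    def test_standard_band_is_level_three(self):
        # Nyquist 150: d1=[75,150], d2=[37.5,75], d3=[18.75,37.5]
        assert dyadic_level(300.0, (18.75, 37.50)) == 3

    @pytest.mark.parametrize("d,band", [(1, (75.0, 150.0)), (2, (37.5, 75.0)), (4, (9.375, 18.75))])
    def test_other_dyadic_bands(self, d, band):
        assert dyadic_level(300.0, band) == d

    def test_non_dyadic_band_rejected(self):
        with pytest.raises(ValueError, match="dyadic"):
            dyadic_level(300.0, (20.0, 40.0))

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            dyadic_level(300.0, (100.0, 200.0))


class TestBandSelect:
    def test_zero_input_zero_output(self):
        rec = make_rec(np.zeros((2, 4096)))
        out = band_select(rec, WaveletBandSpec())
        assert np.all(out.data == 0.0)
        assert out.fs == rec.fs and out.data.shape == rec.data.shape

    def test_white_noise_energy_concentrates_in_band(self, rng):
        x = rng.standard_normal(2**14)
        rec = make_rec(x)
        out = band_select(rec, WaveletBandSpec())
        frac = spectral_energy_fraction(out.data[0], 300.0, (18.75, 37.5))
        assert frac >= 0.90

    def test_in_band_tone_retained_out_of_band_rejected(self):
        t = np.arange(2**13) / 300.0
        spec = WaveletBandSpec()
        tone25 = make_rec(np.sin(2 * np.pi * 25.0 * t))
        tone5 = make_rec(np.sin(2 * np.pi * 5.0 * t))
        out25 = band_select(tone25, spec).data[0]
        out5 = band_select(tone5, spec).data[0]
        e = lambda v: float(np.sum(v**2))
        assert e(out25) >= 0.80 * e(tone25.data[0])
        assert e(out5) <= 0.05 * e(tone5.data[0])

    def test_energy_never_increases(self, rng):
        rec = make_rec(rng.standard_normal((3, 4096)))
        out = band_select(rec, WaveletBandSpec())
        assert np.sum(out.data**2) <= np.sum(rec.data**2) * (1 + 1e-9)

    def test_channel_independence(self, rng):
        data = rng.standard_normal((3, 4096))
        base = band_select(make_rec(data), WaveletBandSpec())
        data2 = data.copy()
        data2[2] = rng.standard_normal(4096)
        out2 = band_select(make_rec(data2), WaveletBandSpec())
        np.testing.assert_array_equal(base.data[0], out2.data[0])
        np.testing.assert_array_equal(base.data[1], out2.data[1])

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            band_select(make_rec(np.ones((2, 64))), WaveletBandSpec())


class TestThresholdRule:
    def test_moderate_outlier_survives(self):
        # mean + 2*std of (1,1,1,100) is ~111.5: nothing exceeds it
        C = np.array([1.0, 1.0, 1.0, 100.0])
        thr = C.mean() + 2 * C.std()
        assert thr == pytest.approx(111.49, abs=0.01)
        np.testing.assert_array_equal(threshold_coefficients(C), C)

    def test_borderline_outlier_survives(self):
        C = np.array([0.0, 0.0, 0.0, 100.0])
        assert C.mean() + 2 * C.std() == pytest.approx(111.60, abs=0.01)
        np.testing.assert_array_equal(threshold_coefficients(C), C)

    def test_extreme_outlier_zeroed(self):
        C = np.concatenate([np.ones(99), [1000.0]])
        assert C.mean() + 2 * C.std() == pytest.approx(209.79, abs=0.01)
        out = threshold_coefficients(C)
        assert out[-1] == 0.0
        np.testing.assert_array_equal(out[:-1], np.ones(99))

    def test_constant_coefficients_unchanged(self):
        # std = 0 and the rule is a strict '>': nothing exceeds mean + 0
        C = np.full(16, 3.3)
        np.testing.assert_array_equal(threshold_coefficients(C), C)

    def test_one_sided_rule_spares_negative_spikes(self):
        C = np.concatenate([np.ones(99), [-1000.0]])
        out = threshold_coefficients(C)
        assert out[-1] == -1000.0  # signed rule: only positive excursions zeroed
        out_abs = threshold_coefficients(C, use_abs=True)
        assert out_abs[-1] == 0.0


class TestThresholdCorrect:
    def test_energy_never_increases(self, rng):
        rec = make_rec(rng.standard_normal((2, 4096)))
        sel = band_select(rec, WaveletBandSpec())
        out = threshold_correct(rec, WaveletBandSpec())
        tol = 1 + 1e-9
        assert np.sum(out.data**2) <= np.sum(sel.data**2) * tol
        assert np.sum(sel.data**2) <= np.sum(rec.data**2) * tol

    def test_third_pass_changes_few_coefficients(self):
        """The two-pass rule is nearly converged on generator-style signals."""
        import pywt

        from fcgbnet import SynthSpec, generate

        rec, _ = generate(
            SynthSpec(n_channels=3, duration_s=30.0, event_times_s=[],
                      artifact_times_s=[10.0, 20.0], seed=3)
        )
        wavelet = pywt.Wavelet("dmey")
        changed = total = 0
        for ch in range(rec.n_channels):
            C = pywt.wavedec(rec.data[ch], wavelet, level=3)[1]
            two = threshold_coefficients(threshold_coefficients(C))
            three = threshold_coefficients(two)
            changed += int(np.sum(two != three))
            total += C.size
        assert changed / total < 0.01

    def test_invalid_parameters_rejected(self, rng):
        rec = make_rec(rng.standard_normal((2, 4096)))
        with pytest.raises(ValueError):
            threshold_correct(rec, WaveletBandSpec(), n_passes=0)
        with pytest.raises(ValueError):
            threshold_correct(rec, WaveletBandSpec(), k_sigma=0.0)
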