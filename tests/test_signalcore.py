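"""Signal-processing primitives: filter contract, resampling, PSD,
cosine similarity, and evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from vidspo2 import signalcore as sc
from vidspo2.exceptions import (DegenerateSignalError, InsufficientLengthError,
                                InvalidParameterError, ShapeError)


def sine(freq, rate=30.0, duration=30.0, amp=1.0, phase=0.0):
    t = np.arange(int(duration * rate)) / rate
    return sc.Waveform(amp * np.sin(2 * np.pi * freq * t + phase), rate)


def central(w, skip_s=9.0):
    # zero-phase edge transients last about one filter length (241 taps
    # = 8 s at the defaults), so amplitude checks use the interior only
    k = int(skip_s * w.rate)
    return w.samples[k:-k]


class TestBandpass:
    def test_designed_response_in_band(self):
        """Independent oracle: the designed filter's |H| at 1.5 Hz."""
        rate, low = 30.0, 0.5
        numtaps = int(round(4 * rate / low)) + 1
        taps = sps.firwin(numtaps, [0.5, 4.0], pass_zero=False, fs=rate)
        _, h = sps.freqz(taps, worN=[1.5], fs=rate)
        assert abs(h[0]) ** 2 >= 0.9        # forward-backward => |H|^2

    @pytest.mark.parametrize("freq,lo,hi", [(1.5, 0.9, 1.1), (8.0, 0.0, 0.1)])
    def test_passband_and_stopband_amplitude(self, freq, lo, hi):
        out = sc.bandpass_fir(sine(freq))
        amp = np.abs(central(out)).max()
        assert lo <= amp <= hi

    def test_dc_removed(self):
        w = sc.Waveform(np.ones(900), 30.0)
        out = sc.bandpass_fir(w)
        assert np.abs(central(out)).max() < 0.05

    def test_invalid_cutoffs_and_short_input(self):
        with pytest.raises(InvalidParameterError):
            sc.bandpass_fir(sine(1.0), low_hz=0.5, high_hz=20.0)
        with pytest.raises(InsufficientLengthError):
            sc.bandpass_fir(sc.Waveform(np.random.default_rng(0).normal(size=50),
                                        30.0))


class TestResample:
    def test_halving_and_identity(self):
        w = sc.Waveform(np.random.default_rng(0).normal(size=600), 60.0)
        out = sc.resample(w, 30.0)
        assert out.rate == 30.0 and len(out) == 300
        same = sc.resample(w, 60.0)
        np.testing.assert_array_equal(same.samples, w.samples)

    def test_psd_peak_preserved(self):
        w = sine(1.0, rate=100.0, duration=20.0)
        out = sc.resample(w, 30.0)
        psd = sc.compute_psd(out)
        assert psd.peak_freq == pytest.approx(1.0, abs=1.0 / out.duration)

    def test_invalid_rate(self):
        with pytest.raises(InvalidParameterError):
            sc.resample(sine(1.0), -1.0)


class TestNormalize:
    def test_standardization_and_idempotence(self):
        w = sc.Waveform([1.0, 2.0, 3.0], 1.0)
        out = sc.normalize(w)
        assert out.samples.mean() == pytest.approx(0.0, abs=1e-9)
        assert out.samples.std() == pytest.approx(1.0, abs=1e-9)
        again = sc.normalize(out)
        np.testing.assert_allclose(again.samples, out.samples, atol=1e-9)

    def test_constant_rejected(self):
        with pytest.raises(DegenerateSignalError):
            sc.normalize(sc.Waveform(np.full(10, 3.0), 1.0))


class TestComputePsd:
    def test_peak_location(self):
        psd = sc.compute_psd(sine(1.2, duration=10.0))
        assert psd.peak_freq == pytest.approx(1.2, abs=0.1)

    def test_l1_normalized(self):
        psd = sc.compute_psd(sine(1.2))
        assert psd.power.sum() == pytest.approx(1.0, abs=1e-9)

    def test_phase_invariance(self):
        a = sc.compute_psd(sine(1.2))
        b = sc.compute_psd(sine(1.2, phase=np.pi / 2))
        assert np.abs(a.power - b.power).sum() < 0.05

    def test_amplitude_invariance(self):
        a = sc.compute_psd(sine(1.2))
        b = sc.compute_psd(sine(1.2, amp=7.5))
        np.testing.assert_allclose(a.power, b.power, atol=1e-12)

    def test_degenerate_and_short(self):
        with pytest.raises(DegenerateSignalError):
            sc.compute_psd(sc.Waveform(np.zeros(600), 30.0))
        with pytest.raises(InsufficientLengthError):
            sc.compute_psd(sine(1.2, duration=2.0))

    def test_noise_after_bandpass_mostly_in_band(self):
        rng = np.random.default_rng(5)
        w = sc.Waveform(rng.normal(size=1800), 30.0)
        filtered = sc.bandpass_fir(w)
        f, p = sps.periodogram(filtered.samples, fs=30.0, window="hann")
        inband = p[(f >= 0.5) & (f <= 4.0)].sum()
        assert inband / p.sum() >= 0.95


class TestCosineSimilarity:
    def test_examples(self):
        x = np.array([1.0, 2.0, 3.0])
        assert sc.cosine_similarity(x, x) == pytest.approx(1.0)
        assert sc.cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        assert sc.cosine_similarity([1, 2, 3], [4, 5, 6]) == pytest.approx(
            0.9746, abs=1e-4)

    @given(st.floats(min_value=0.1, max_value=50.0),
           st.booleans())
    @settings(max_examples=25, deadline=None)
    def test_scaling_law(self, a, negate):
        x = np.array([0.3, -1.2, 2.0, 0.7])
        scale = -a if negate else a
        expected = -1.0 if negate else 1.0
        assert sc.cosine_similarity(x, scale * x) == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(ShapeError):
            sc.cosine_similarity([1, 2], [1, 2, 3])
        with pytest.raises(DegenerateSignalError):
            sc.cosine_similarity([0, 0], [1, 2])


class TestMetrics:
    def test_examples(self):
        r = np.array([95.0, 97.0, 96.0])
        m = sc.metrics(r, r)
        assert (m["mae"], m["rmse"]) == (0.0, 0.0)
        assert m["pearson"] == pytest.approx(1.0)
        m = sc.metrics(r + 1, r)
        assert m["mae"] == pytest.approx(1.0)
        assert m["rmse"] == pytest.approx(1.0)
        m = sc.metrics([95.0, 97.0], [96.0, 96.0], include_pearson=False)
        assert m["mae"] == pytest.approx(1.0)
        assert m["rmse"] == pytest.approx(1.0)

    @given(st.lists(st.floats(min_value=90, max_value=100), min_size=2,
                    max_size=30),
           st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_rmse_dominates_mae(self, ref, seed):
        ref = np.asarray(ref)
        pred = ref + np.random.default_rng(seed).normal(size=ref.size)
        if pred.std() == 0 or ref.std() == 0:
            return
        m = sc.metrics(pred, ref)
        assert m["rmse"] >= m["mae"] - 1e-12

    def test_errors(self):
        with pytest.raises(ShapeError):
            sc.metrics([1, 2], [1, 2, 3])
        with pytest.raises(DegenerateSignalError):
            sc.metrics([96.0, 96.0], [95.0, 97.0])


def test_waveform_csv_round_trip(tmp_path):
    w = sine(1.3, duration=3.0)
    path = tmp_path / "w.csv"
    sc.waveform_to_csv(w, path)
    back = sc.waveform_from_csv(path)
    assert back.rate == pytest.approx(w.rate, rel=1e-6)
    np.testing.assert_allclose(back.samples, w.samples, atol=1e-8)
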