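"""Spindle detector: filters, envelope, event extraction and event metrics."""

import numpy as np
import pytest

import spindlespa as sp
from spindlespa.detection import BANDS
from spindlespa.eeg_io import BipolarRecording, DERIVATIONS

FS = 256.0


def _sine(freq, seconds, amp=1.0, fs=FS):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def _bipolar_with_burst(bursts, seconds=330.0, noise_uv=3.0, seed=0,
                        derivation="C3-O1"):
    """Background noise on every derivation, bursts added to one of them.

    bursts: list of (onset_s, duration_s, freq_hz, amp_uv).
    """
    rng = np.random.default_rng(seed)
    n = int(seconds * FS)
    data = rng.normal(0, noise_uv, size=(len(DERIVATIONS), n))
    i = DERIVATIONS.index(derivation)
    for onset, dur, freq, amp in bursts:
        from scipy.signal.windows import tukey

        m = int(dur * FS)
        t = np.arange(m) / FS
        wave = amp * tukey(m, 0.5) * np.sin(2 * np.pi * freq * t)
        s = int(onset * FS)
        data[i, s:s + wave.size] += wave
    return BipolarRecording("t", list(DERIVATIONS), FS, data)


class TestSigmaFilter:
    @pytest.mark.parametrize("freq,passes", [(13.0, True), (4.0, False)])
    def test_band_selectivity(self, freq, passes):
        x = _sine(freq, 20)
        y = sp.sigma_filter(x, FS)
        mid = slice(int(5 * FS), int(15 * FS))
        gain = np.sqrt(np.mean(y[mid] ** 2) / np.mean(x[mid] ** 2))
        if passes:
            assert abs(gain - 1) < 0.05
        else:
            assert gain < 0.1  # >= 20 dB down

    def test_zero_in_zero_out(self):
        np.testing.assert_array_equal(sp.sigma_filter(np.zeros(1000), FS),
                                      np.zeros(1000))

    def test_band_outside_nyquist(self):
        with pytest.raises(ValueError):
            sp.sigma_filter(np.zeros(1000), fs=30.0)


class TestSigmaEnvelope:
    def test_stationary_sine_envelope_equals_amplitude(self):
        x = _sine(12, 20, amp=7.0)
        env = sp.sigma_envelope(x, FS)
        mid = env[int(5 * FS):int(15 * FS)]
        assert np.all(np.abs(mid - 7.0) / 7.0 < 0.1)

    def test_zero_signal(self):
        assert np.allclose(sp.sigma_envelope(np.zeros(4000), FS), 0)

    def test_amplitude_step_ratio(self):
        x = np.concatenate([_sine(12, 10, amp=5.0), _sine(12, 10, amp=10.0)])
        env = sp.sigma_envelope(x, FS)
        p1 = env[int(3 * FS):int(7 * FS)].mean()
        p2 = env[int(13 * FS):int(17 * FS)].mean()
        assert p2 / p1 == pytest.approx(2.0, rel=0.05)

    def test_smoothing_window_floor(self):
        with pytest.raises(ValueError):
            sp.sigma_envelope(np.zeros(1000), FS, smooth_s=0.05)


class TestDetectSpindles:
    def test_single_burst_detected_with_accurate_onset(self):
        bip = _bipolar_with_burst([(100.0, 1.0, 12.0, 30.0)], noise_uv=2.0)
        events = [e for e in sp.detect_spindles(bip) if e.derivation == "C3-O1"]
        assert len(events) == 1
        assert events[0].onset_s == pytest.approx(100.0, abs=0.25)

    def test_burst_below_min_duration_rejected(self):
        bip = _bipolar_with_burst([(100.0, 0.2, 12.0, 30.0)], noise_uv=2.0)
        assert [e for e in sp.detect_spindles(bip)
                if e.derivation == "C3-O1"] == []

    def test_small_gap_merges_to_one_event(self):
        bip = _bipolar_with_burst([(100.0, 0.6, 12.0, 30.0),
                                   (100.7, 0.6, 12.0, 30.0)], noise_uv=2.0)
        events = [e for e in sp.detect_spindles(bip) if e.derivation == "C3-O1"]
        assert len(events) == 1

    def test_requires_300s_of_data(self):
        bip = _bipolar_with_burst([], seconds=200.0)
        with pytest.raises(ValueError, match="300"):
            sp.detect_spindles(bip)

    def test_excluded_derivation_is_skipped(self):
        bip = _bipolar_with_burst([(100.0, 1.0, 12.0, 30.0)], noise_uv=2.0)
        bip.excluded = {"C3-O1"}
        assert [e for e in sp.detect_spindles(bip)
                if e.derivation == "C3-O1"] == []

    def test_duration_bounds_and_no_overlap(self, symmetric_events):
        params = sp.DetectorParams()
        by_deriv = {}
        for e in symmetric_events:
            assert params.min_dur_s <= e.duration_s <= params.max_dur_s
            by_deriv.setdefault(e.derivation, []).append(e)
        for evs in by_deriv.values():
            evs = sorted(evs, key=lambda e: e.onset_s)
            for a, b in zip(evs, evs[1:]):
                assert a.offset_s <= b.onset_s

    def test_slow_plus_fast_equals_full(self, symmetric_events):
        n_slow = sum(e.band == "slow" for e in symmetric_events)
        n_fast = sum(e.band == "fast" for e in symmetric_events)
        assert n_slow + n_fast == len(symmetric_events)

    def test_amplitude_equivariance(self):
        bip = _bipolar_with_burst([(60.0, 1.2, 12.0, 30.0),
                                   (200.0, 1.0, 13.5, 25.0)], noise_uv=2.0)
        params = sp.DetectorParams()
        ev1 = [e for e in sp.detect_spindles(bip, params)
               if e.derivation == "C3-O1"]
        bip2 = BipolarRecording("t", list(DERIVATIONS), FS, 2.0 * bip.data)
        params2 = sp.DetectorParams(min_abs_amplitude_uv=10.0)
        ev2 = [e for e in sp.detect_spindles(bip2, params2)
               if e.derivation == "C3-O1"]
        assert len(ev1) == len(ev2) == 2
        for a, b in zip(ev1, ev2):
            assert b.mean_power_uv2 == pytest.approx(4 * a.mean_power_uv2,
                                                     rel=1e-6)


class TestEventMetrics:
    def test_pure_burst_frequencies(self):
        for f in (12.0, 14.5):
            burst = sp.synth_spindle(f, 1.0, 30.0, FS)
            est = sp.event_osc_frequency(burst, FS)
            assert est == pytest.approx(f, abs=0.5)
        assert sp.classify_band(sp.event_osc_frequency(
            sp.synth_spindle(14.5, 1.0, 30.0, FS), FS)) == "fast"

    def test_exact_spectral_tie_breaks_low(self):
        # an impulse has an exactly flat magnitude spectrum, so every in-band
        # bin ties; the documented rule reports the lowest tied frequency
        x = np.zeros(int(2.0 * FS))
        x[x.size // 2] = 1.0
        assert sp.event_osc_frequency(x, FS) == pytest.approx(11.0, abs=0.26)

    def test_too_short_event_rejected(self):
        with pytest.raises(ValueError):
            sp.event_osc_frequency(np.zeros(int(0.1 * FS)), FS)

    def test_sinusoid_mean_power(self):
        x = _sine(13.0, 2.0, amp=10.0)
        assert sp.event_mean_power(x, FS) == pytest.approx(50.0, rel=0.1)

    def test_power_quadratic_scaling(self):
        x1 = _sine(13.0, 2.0, amp=10.0)
        x2 = _sine(13.0, 2.0, amp=20.0)
        p1, p2 = sp.event_mean_power(x1, FS), sp.event_mean_power(x2, FS)
        assert p2 / p1 == pytest.approx(4.0, rel=0.05)
        b1 = sp.synth_spindle(12.0, 1.5, 10.0, FS)
        b2 = sp.synth_spindle(12.0, 1.5, 20.0, FS)
        ratio = sp.event_mean_power(b1, FS) / sp.event_mean_power(b2, FS)
        assert ratio == pytest.approx(0.25, rel=0.05)

    @pytest.mark.parametrize("freq,band", [(12.2, "slow"), (13.0, "fast"),
                                           (14.9, "fast")])
    def test_band_classification(self, freq, band):
        assert sp.classify_band(freq) == band

    def test_out_of_band_frequency_rejected(self):
        with pytest.raises(ValueError):
            sp.classify_band(16.0)
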