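"""Accelerometer processing: magnitude, filter design, zero-phase
filtering, RMS binning, Welch PSDs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as ssig
from scipy.spatial.transform import Rotation

from gravseq.accel import (AccelTrace, FilterSpec, design_highpass,
                           filter_order, read_accel_csv, rms_bins,
                           vibration_magnitude, welch_psd, write_accel_csv,
                           zero_phase_filter)
from gravseq.errors import FormatError, InputError

FS = 5000.0


def sinusoid(freq, duration_s, fs=FS, amplitude=1.0):
    t = np.arange(int(duration_s * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t)


class TestMagnitude:
    @pytest.mark.parametrize(
        "axes, expected",
        [((3.0, 4.0, 0.0), 5.0), ((0.0, 0.0, 1.0), 1.0),
         ((1.0, 1.0, 1.0), np.sqrt(3))],
    )
    def test_pythagorean(self, axes, expected):
        trace = AccelTrace(*[np.full(4, a) for a in axes], sample_rate=FS)
        assert vibration_magnitude(trace) == pytest.approx(
            np.full(4, expected), abs=1e-12
        )

    def test_mismatched_axes_rejected(self):
        with pytest.raises(InputError):
            AccelTrace(np.zeros(3), np.zeros(3), np.zeros(4))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_rotation_invariance(self, seed):
        """The magnitude is unchanged by any joint rotation of the axes —
        the sensor's mounting orientation cannot matter."""
        r = np.random.default_rng(seed)
        xyz = r.normal(size=(3, 50))
        rot = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
        rotated = rot @ xyz
        m0 = vibration_magnitude(AccelTrace(*xyz, sample_rate=FS))
        m1 = vibration_magnitude(AccelTrace(*rotated, sample_rate=FS))
        np.testing.assert_allclose(m0, m1, rtol=1e-10)


class TestFilterDesign:
    def test_stopband_attenuation_at_spec(self):
        sos = design_highpass(FilterSpec())
        _, h = ssig.sosfreqz(sos, worN=[5.0], fs=FS)
        assert -20 * np.log10(abs(h[0])) >= 60.0

    def test_deep_stopband_attenuation_not_worse(self):
        sos = design_highpass(FilterSpec())
        _, h = ssig.sosfreqz(sos, worN=[2.0, 5.0], fs=FS)
        atten = -20 * np.log10(np.abs(h))
        assert atten[0] >= atten[1] - 1e-6

    def test_passband_near_unity(self):
        sos = design_highpass(FilterSpec())
        _, h = ssig.sosfreqz(sos, worN=[100.0], fs=FS)
        assert abs(20 * np.log10(abs(h[0]))) <= 1.0

    def test_infeasible_spec_rejected(self):
        with pytest.raises(InputError):
            FilterSpec(stop_hz=10, pass_hz=5)


class TestZeroPhase:
    def test_stopband_sinusoid_annihilated(self):
        """Two passes double the attenuation: a 1 Hz tone comes out at
        least 120 dB down."""
        sos = design_highpass(FilterSpec())
        out = zero_phase_filter(sinusoid(1.0, 60.0), sos)
        # ignore edge transients
        core = out[len(out) // 4: -len(out) // 4]
        assert np.max(np.abs(core)) <= 10 ** (-120 / 20) + 1e-7

    def test_passband_sinusoid_preserved_with_zero_lag(self):
        sos = design_highpass(FilterSpec())
        x = sinusoid(100.0, 10.0)
        y = zero_phase_filter(x, sos)
        core = slice(len(x) // 4, -len(x) // 4)
        amp = np.max(np.abs(y[core]))
        assert amp == pytest.approx(1.0, abs=2 * (1 - 10 ** (-2 * 1.0 / 20)))
        lags = ssig.correlation_lags(len(x), len(x))
        xc = ssig.correlate(x, y)
        assert lags[np.argmax(xc)] == 0

    def test_dc_removed(self):
        sos = design_highpass(FilterSpec())
        out = zero_phase_filter(np.full(30000, 3.7), sos)
        assert np.max(np.abs(out)) < 1e-6

    def test_time_reversal_symmetry(self):
        """Forward-backward filtering commutes with time reversal away
        from the edges (the near-DC cutoff makes the edge transient decay
        over a few seconds, far longer than the pad)."""
        r = np.random.default_rng(0)
        x = r.normal(size=100000)
        sos = design_highpass(FilterSpec())
        a = zero_phase_filter(x[::-1], sos)[::-1]
        b = zero_phase_filter(x, sos)
        core = slice(len(x) // 4, -len(x) // 4)
        np.testing.assert_allclose(a[core], b[core], atol=1e-9)

    def test_too_short_signal_rejected(self):
        sos = design_highpass(FilterSpec())
        with pytest.raises(InputError):
            zero_phase_filter(np.zeros(3 * filter_order(sos)), sos)


class TestRmsBins:
    @pytest.mark.parametrize(
        "x, expected",
        [
            (np.full(5000, -2.5), [2.5]),                 # |constant|
            (sinusoid(10, 1.0), [1 / np.sqrt(2)]),        # integer cycles
            (np.zeros(10000), [0.0, 0.0]),
        ],
    )
    def test_known_rms(self, x, expected):
        starts, rms = rms_bins(x, FS)
        np.testing.assert_allclose(rms, expected, rtol=1e-12)
        np.testing.assert_allclose(starts, np.arange(len(expected)))

    def test_partial_trailing_bin_dropped(self):
        _, rms = rms_bins(np.ones(int(2.7 * FS)), FS)
        assert len(rms) == 2

    def test_empty_signal(self):
        starts, rms = rms_bins(np.empty(0), FS)
        assert len(starts) == len(rms) == 0

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.integers(1, 4))
    def test_identical_bins_give_identical_rms(self, seed, reps):
        one = np.random.default_rng(seed).normal(size=100)
        _, rms = rms_bins(np.tile(one, reps), sample_rate=100.0)
        np.testing.assert_allclose(rms, rms[0])


class TestWelch:
    def test_peak_at_tone_frequency(self):
        psd = welch_psd(sinusoid(250.0, 20.0), FS)
        df = psd.freqs[1] - psd.freqs[0]
        assert abs(psd.freqs[np.argmax(psd.power)] - 250.0) <= df

    def test_two_tones_two_local_maxima(self):
        x = sinusoid(116.0, 30.0) + sinusoid(876.0, 30.0)
        psd = welch_psd(x, FS)
        df = psd.freqs[1] - psd.freqs[0]
        p = psd.power
        local_max = psd.freqs[1:-1][(p[1:-1] > p[:-2]) & (p[1:-1] > p[2:])]
        assert any(abs(f - 116.0) <= df for f in local_max)
        assert any(abs(f - 876.0) <= df for f in local_max)

    def test_parseval_white_noise(self, rng):
        """Integrated PSD approximates the signal variance."""
        sigma = 0.7
        x = rng.normal(0, sigma, 200000)
        psd = welch_psd(x, FS)
        var = np.trapezoid(psd.power, psd.freqs)
        assert var == pytest.approx(sigma**2, rel=0.10)

    def test_too_short_rejected(self):
        with pytest.raises(InputError):
            welch_psd(np.zeros(8), FS)


class TestAccelIO:
    def test_roundtrip(self, tmp_path):
        r = np.random.default_rng(3)
        trace = AccelTrace(*r.normal(size=(3, 500)), sample_rate=100.0)
        path = tmp_path / "trace.csv"
        write_accel_csv(trace, path)
        back = read_accel_csv(path)
        assert back.sample_rate == pytest.approx(100.0, rel=1e-4)
        np.testing.assert_allclose(back.gx, trace.gx, atol=1e-5)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(FormatError):
            read_accel_csv(path)
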