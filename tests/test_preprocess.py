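"""Filtering, re-referencing, ICA artifact removal, and segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from dfhm.errors import ValidationError
from dfhm.io import Block, Recording
from dfhm.preprocess import (
    bandpass_filter,
    design_bandpass,
    remove_artifacts,
    rereference_average,
    segment,
    segment_count,
)
from dfhm.synthetic import BatteryBlock, CohortSpec, generate_recording


def _freq_gain(taps, f, rate=500.0):
    w, h = sps.freqz(taps, worN=2 ** 14, fs=rate)
    return np.abs(h[np.argmin(np.abs(w - f))])


class TestBandpass:
    def test_passband_gain_at_6_hz(self):
        taps = design_bandpass(0.5, 40.0, 100, 500.0)
        assert _freq_gain(taps, 6.0) == pytest.approx(1.0, abs=0.05)
        assert _freq_gain(taps, 10.0) == pytest.approx(1.0, abs=0.05)

    def test_stopband_attenuation_beyond_transition(self):
        # order 100 at 500 Hz has a ~16 Hz transition: strong rejection at 50 Hz
        taps = design_bandpass(0.5, 40.0, 100, 500.0)
        assert _freq_gain(taps, 50.0) < 0.01
        assert _freq_gain(taps, 40.0) == pytest.approx(0.5, abs=0.05)  # -6 dB edge

    def test_sinusoid_amplitude_preserved(self):
        t = np.arange(5000) / 500.0
        rec = Recording(samples=np.sin(2 * np.pi * 6 * t)[None, :], rate=500.0,
                        channels=["Fz"])
        out = bandpass_filter(rec)
        mid = out.samples[0, 1000:4000]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)
        assert out.n_times == rec.n_times  # delay-compensated, same length

    def test_invalid_edges_and_order(self):
        with pytest.raises(ValidationError):
            design_bandpass(40.0, 0.5, 100, 500.0)
        with pytest.raises(ValidationError):
            design_bandpass(0.5, 300.0, 100, 500.0)  # beyond Nyquist
        with pytest.raises(ValidationError):
            design_bandpass(0.5, 40.0, 101, 500.0)  # odd order

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 3000))
        y = rng.normal(size=(2, 3000))
        rec = lambda d: Recording(samples=d, rate=500.0, channels=["a", "b"])
        lhs = bandpass_filter(rec(2.0 * x + 3.0 * y)).samples
        rhs = 2.0 * bandpass_filter(rec(x)).samples + 3.0 * bandpass_filter(rec(y)).samples
        assert np.allclose(lhs, rhs, atol=1e-10)


class TestAverageReference:
    def test_zero_mean_and_idempotence(self):
        rng = np.random.default_rng(1)
        rec = Recording(samples=rng.normal(size=(5, 100)), rate=500.0,
                        channels=list("abcde"))
        out = rereference_average(rec)
        assert np.allclose(out.samples.mean(axis=0), 0.0, atol=1e-12)
        assert out.reference == "average"
        again = rereference_average(out)
        assert np.allclose(again.samples, out.samples, atol=1e-12)

    def test_two_channel_hand_arithmetic(self):
        rec = Recording(samples=np.array([[4.0], [2.0]]), rate=1.0, channels=["a", "b"])
        out = rereference_average(rec)
        assert np.allclose(out.samples, [[1.0], [-1.0]])

    def test_single_channel_rejected(self):
        rec = Recording(samples=np.zeros((1, 10)), rate=500.0, channels=["a"])
        with pytest.raises(ValidationError):
            rereference_average(rec)


class TestSegmentation:
    @pytest.mark.parametrize("duration,expected", [(300, 59), (10, 1), (9, 0), (60, 11)])
    def test_counts(self, duration, expected):
        assert segment_count(duration, 10.0, 5.0) == expected

    def test_segments_respect_blocks(self):
        rec = Recording(samples=np.zeros((2, 500 * 30)), rate=500.0, channels=["a", "b"],
                        blocks=[Block("t1", 0.0, 12.0), Block("t2", 12.0, 30.0)])
        segs = segment(rec)
        assert [s.task_id for s in segs] == ["t1", "t2", "t2"]
        assert all(s.data.shape == (2, 5000) for s in segs)
        assert segs[0].offset_in_block_s == 0.0
        assert segs[2].offset_in_block_s == 5.0

    def test_invalid_window(self):
        rec = Recording(samples=np.zeros((1, 5000)), rate=500.0, channels=["a"])
        with pytest.raises(ValidationError):
            segment(rec, window_s=0.0)
        with pytest.raises(ValidationError):
            segment(rec, step_s=-1.0)

    @given(duration=st.integers(10, 2000), window=st.integers(1, 60),
           step=st.integers(1, 30))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_count_closed_form(self, duration, window, step):
        """Segment count matches floor((T - w)/s) + 1 whenever T >= w."""
        n = segment_count(float(duration), float(window), float(step))
        if duration < window:
            assert n == 0
        else:
            assert n == (duration - window) // step + 1


@pytest.fixture(scope="module")
def blinky():
    spec = CohortSpec(n_subjects=1, seed=42,
                      battery=(BatteryBlock("t", 120.0, "moderate"),),
                      artifact_rate_hz=0.25)
    rec = generate_recording(spec, 0).recording
    return bandpass_filter(rec)


class TestIcaArtifactRemoval:
    @staticmethod
    def _band_amp(rec, channels, lo, hi):
        idx = [rec.channels.index(c) for c in channels]
        f, psd = sps.periodogram(rec.samples[idx], fs=rec.rate, axis=1)
        m = (f >= lo) & (f < hi)
        return np.sqrt(psd[:, m].sum(axis=1) * (f[1] - f[0])).mean()

    def test_blink_removed_oscillation_kept(self, blinky):
        clean = remove_artifacts(blinky, "default")
        fp_before = self._band_amp(blinky, ["Fp1", "Fp2"], 0.5, 4.0)
        fp_after = self._band_amp(clean, ["Fp1", "Fp2"], 0.5, 4.0)
        assert fp_after <= 0.5 * fp_before  # blink band cut by at least half
        pa_before = self._band_amp(blinky, ["Pz", "P3", "P4"], 8.0, 12.0)
        pa_after = self._band_amp(clean, ["Pz", "P3", "P4"], 8.0, 12.0)
        assert abs(pa_after / pa_before - 1.0) < 0.10  # alpha untouched

    def test_policy_none_is_identity(self, blinky):
        out = remove_artifacts(blinky, "none")
        assert np.array_equal(out.samples, blinky.samples)

    def test_single_channel_rejected(self):
        rec = Recording(samples=np.zeros((1, 5000)), rate=500.0, channels=["Fz"])
        with pytest.raises(ValidationError):
            remove_artifacts(rec, "default")
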