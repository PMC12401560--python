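"""Preprocessing contracts: reference, filter, resample, epoch, detrend, artifacts."""

import numpy as np
import pytest

from fastball.preprocess import (
    Recording,
    TrialEpoch,
    detrend_polynomial,
    extract_epoch,
    lowpass_zero_phase,
    preprocess_recording,
    rereference_common_average,
    resample,
    suppress_artifacts,
)


def make_recording(data, fs=500.0):
    labels = tuple(f"ch{i}" for i in range(np.atleast_2d(data).shape[0]))
    return Recording(data=np.atleast_2d(data), fs_hz=fs, channel_labels=labels)


def tone_amplitude(x, fs, freq):
    """Amplitude of a bin-aligned tone via the DFT."""
    n = len(x)
    k = round(freq * n / fs)
    return 2 * abs(np.fft.rfft(x)[k]) / n


class TestRereference:
    def test_zero_mean_input_unchanged(self):
        rec = make_recording(np.array([[1.0, 1.0], [-1.0, -1.0]]))
        out = rereference_common_average(rec)
        assert np.allclose(out.data, rec.data)

    def test_constant_offset_removed(self):
        rec = make_recording(np.full((4, 100), 17.0))
        out = rereference_common_average(rec)
        assert np.allclose(out.data, 0.0)

    def test_column_sums_conserved_to_zero(self, rng):
        rec = make_recording(rng.normal(size=(8, 5000)) * 50)
        out = rereference_common_average(rec)
        assert np.max(np.abs(out.data.sum(axis=0))) <= 1e-9

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            rereference_common_average(make_recording(np.zeros((1, 10))))

    def test_double_rereference_rejected(self):
        rec = rereference_common_average(make_recording(np.zeros((2, 10))))
        with pytest.raises(ValueError):
            rereference_common_average(rec)


class TestLowpass:
    def test_passband_tone_preserved(self):
        fs = 500.0
        t = np.arange(int(60 * fs)) / fs
        rec = make_recording(np.vstack([np.sin(2 * np.pi * 3 * t)] * 2), fs)
        out = lowpass_zero_phase(rec)
        mid = slice(int(10 * fs), int(50 * fs))
        ratio = out.data[0, mid].std() / rec.data[0, mid].std()
        assert abs(ratio - 1) < 0.01

    def test_cutoff_attenuation_minus_6_db(self):
        # two forward-backward passes of a -3 dB Butterworth edge
        fs = 500.0
        t = np.arange(int(60 * fs)) / fs
        rec = make_recording(np.sin(2 * np.pi * 40 * t), fs)
        out = lowpass_zero_phase(rec, cutoff_hz=40.0)
        mid = slice(int(10 * fs), int(50 * fs))
        ratio = out.data[0, mid].std() / rec.data[0, mid].std()
        assert ratio == pytest.approx(0.5, abs=0.01)

    def test_zero_phase_impulse_symmetric(self):
        x = np.zeros(2001)
        x[1000] = 1.0
        out = lowpass_zero_phase(make_recording(x), cutoff_hz=40.0)
        h = out.data[0]
        assert np.allclose(h[1:1000][::-1], h[1001:2000], atol=1e-10)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_zero_phase(make_recording(np.zeros((2, 100)), fs=100.0), cutoff_hz=60.0)


class TestResample:
    def test_sample_count(self):
        rec = make_recording(np.zeros((2, 5000)), fs=500.0)
        out = resample(lowpass_zero_phase(rec), 120.0)
        assert out.data.shape[1] == 1200
        assert out.fs_hz == 120.0

    def test_passband_tone_survives(self):
        fs = 500.0
        t = np.arange(int(120 * fs)) / fs
        rec = make_recording(np.sin(2 * np.pi * 3 * t), fs)
        out = resample(lowpass_zero_phase(rec), 120.0)
        mid = out.data[0, 1200:-1200]
        amp = np.sqrt(2) * mid.std()
        assert abs(amp - 1) < 0.01

    def test_out_of_band_tone_suppressed(self):
        # Butterworth magnitude oracle: two passes of an order-2 filter
        # give |H(55)| = 1 / (1 + (55/40)^4) ~ 0.219; the polyphase
        # resampler's own anti-alias filter can only attenuate further.
        fs = 500.0
        t = np.arange(int(60 * fs)) / fs
        rec = make_recording(np.sin(2 * np.pi * 55 * t), fs)
        out = resample(lowpass_zero_phase(rec), 120.0)
        amp = np.sqrt(2) * out.data[0, 240:-240].std()
        bound = 1 / (1 + (55 / 40) ** 4)
        assert amp <= bound * 1.02
        assert amp < 0.25

    def test_requires_prior_lowpass(self):
        rec = make_recording(np.zeros((2, 1000)), fs=500.0)
        with pytest.raises(ValueError, match="lowpass"):
            resample(rec, 120.0)


class TestExtractEpoch:
    def test_default_epoch_length_and_resolution(self):
        rec = make_recording(np.zeros((2, 22000)), fs=120.0)
        ep = extract_epoch(rec, onset_s=0.0)
        assert ep.n_samples == 20800
        df = ep.fs_hz / ep.n_samples
        assert f"{df:.4f}" == "0.0058"

    def test_single_cycle(self):
        rec = make_recording(np.zeros((2, 500)), fs=120.0)
        ep = extract_epoch(rec, 0.0, n_cycles=1)
        assert ep.n_samples == 200

    def test_too_short_reports_required_length(self):
        rec = make_recording(np.zeros((2, 100)), fs=120.0)
        with pytest.raises(ValueError, match="too short"):
            extract_epoch(rec, 0.0)


def make_epoch(data, fs=120.0, n_cycles=104):
    data = np.atleast_2d(data)
    return TrialEpoch(
        data=data,
        fs_hz=fs,
        onset_s=0.0,
        n_cycles=n_cycles,
        oddball_freq_hz=0.6,
        channel_labels=tuple(f"ch{i}" for i in range(data.shape[0])),
    )


class TestDetrend:
    def test_cubic_removed_exactly(self):
        x = np.linspace(-1, 1, 20800)
        ep = make_epoch(100 * x**3 - 5 * x**2 + 3 * x + 42)
        out = detrend_polynomial(ep, order=3)
        assert np.max(np.abs(out.data)) < 1e-6

    def test_constant_removed(self):
        ep = make_epoch(np.full(20800, 100.0))
        out = detrend_polynomial(ep, order=3)
        assert np.allclose(out.data, 0.0)

    def test_oddball_band_sinusoid_preserved(self):
        t = np.arange(20800) / 120.0
        ep = make_epoch(np.sin(2 * np.pi * 0.6 * t))
        out = detrend_polynomial(ep, order=3)
        amp = tone_amplitude(out.data[0], 120.0, 0.6)
        assert abs(amp - 1) < 0.005

    def test_order_too_high_rejected(self):
        rec = make_epoch(np.zeros(200), n_cycles=1)
        with pytest.raises(ValueError):
            detrend_polynomial(rec, order=200)


class TestArtifactSuppression:
    def test_clean_epoch_identity(self):
        t = np.arange(20800) / 120.0
        ep = make_epoch(10 * np.sin(2 * np.pi * 0.6 * t))
        out = suppress_artifacts(ep)
        assert np.array_equal(out.data, ep.data)
        assert out.fraction_zeroed == 0.0

    def test_pulse_zeroed_with_monotone_ramps(self):
        x = np.full(20800, 100.0)
        x[10000:10010] = 300.0
        out = suppress_artifacts(make_epoch(x))
        assert np.all(out.data[0, 10000:10010] == 0.0)
        # boundary samples adjacent to the run nearly vanish
        assert abs(out.data[0, 9999]) < 0.01 * 100.0
        assert abs(out.data[0, 10010]) < 0.01 * 100.0
        left = out.data[0, 10000 - 670 : 10000]
        right = out.data[0, 10010 : 10010 + 670]
        assert np.all(np.diff(left) <= 1e-12)  # descending into the run
        assert np.all(np.diff(right) >= -1e-12)
        assert out.fraction_zeroed == pytest.approx(10 / 20800)
        assert np.max(np.abs(out.data)) <= 250.0

    def test_whole_epoch_artifact_zeroed(self):
        out = suppress_artifacts(make_epoch(np.full(20800, 300.0)))
        assert np.all(out.data == 0.0)
        assert out.fraction_zeroed == 1.0

    def test_taper_introduces_no_discontinuity(self, rng):
        t = np.arange(20800) / 120.0
        clean = 50 * np.sin(2 * np.pi * 1.2 * t) + rng.normal(0, 5, 20800)
        x = clean.copy()
        x[5000:5050] = 400.0
        out = suppress_artifacts(make_epoch(x))
        max_step_clean = np.max(np.abs(np.diff(clean)))
        assert np.max(np.abs(np.diff(out.data[0]))) <= 1.5 * max_step_clean

    def test_nearby_runs_merge_tapers(self):
        x = np.zeros(20800)
        x[3000:3010] = 300.0
        x[3100:3110] = -300.0
        out = suppress_artifacts(make_epoch(x + 100.0))
        between = out.data[0, 3010:3100]
        assert np.max(np.abs(between)) < 100.0  # still attenuated between runs
        assert np.max(np.abs(out.data)) <= 250.0


class TestPipelineOrder:
    def test_end_to_end_shapes_and_determinism(self, rng):
        data = rng.normal(0, 30, size=(8, int(500 * 176)))
        rec = make_recording(data, fs=500.0)
        eps1 = preprocess_recording(rec, [1.0])
        eps2 = preprocess_recording(rec, [1.0])
        assert len(eps1) == 1
        assert eps1[0].n_samples == 20800
        assert np.array_equal(eps1[0].data, eps2[0].data)
        assert np.max(np.abs(eps1[0].data)) <= 250.0
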