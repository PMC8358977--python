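"""Preprocessing chain: filter responses, channel repair, epoching, masking."""

import numpy as np
import pytest

from rhythmdecode.containers import EpochSet, Recording
from rhythmdecode.preprocess import (
    ChannelQualityReport,
    bandpass,
    detect_bad_channels,
    downsample,
    drop_unused_channels,
    epoch,
    interpolate_channels,
    reject_improbable_epochs,
    rereference_average,
    run_preprocessing,
)
from rhythmdecode.simulate import GeneratorConfig, generate_session, spiral_positions


def _sine_recording(freq, rate=1000.0, seconds=20.0, n_channels=4, dc=0.0):
    t = np.arange(int(seconds * rate)) / rate
    data = np.tile(np.sin(2 * np.pi * freq * t) + dc, (n_channels, 1))
    return Recording(data=data, rate=rate)


def _central_rms(x):
    n = x.shape[-1]
    return np.sqrt(np.mean(x[..., n // 4 : 3 * n // 4] ** 2))


class TestBandpass:
    def test_stopband_50hz(self):
        rec = _sine_recording(50.0)
        out = bandpass(rec)
        assert _central_rms(out.data) <= 0.10 * _central_rms(rec.data)

    def test_rejects_dc(self):
        rec = Recording(data=np.ones((4, 20000)), rate=1000.0)
        out = bandpass(rec)
        assert _central_rms(out.data) <= 0.10

    def test_passband_10hz(self):
        rec = _sine_recording(10.0)
        out = bandpass(rec)
        assert _central_rms(out.data) == pytest.approx(_central_rms(rec.data), rel=0.05)

    def test_invalid_edges_rejected(self):
        rec = _sine_recording(10.0)
        for lo, hi in [(45.0, 0.5), (0.0, 45.0), (0.5, 600.0)]:
            with pytest.raises(ValueError):
                bandpass(rec, lo, hi)


class TestDropChannels:
    def test_64_to_60(self):
        rec = Recording(data=np.random.default_rng(0).standard_normal((64, 100)), rate=100.0)
        out = drop_unused_channels(rec)
        assert out.n_channels == 60
        assert np.array_equal(out.data, rec.data[:60])

    def test_60_identity(self):
        rec = Recording(data=np.zeros((60, 50)), rate=100.0)
        assert drop_unused_channels(rec).n_channels == 60

    def test_too_few_rejected(self):
        rec = Recording(data=np.zeros((32, 50)), rate=100.0)
        with pytest.raises(ValueError):
            drop_unused_channels(rec)


class TestDownsample:
    def test_length_and_event_scaling(self):
        rec = Recording(
            data=np.random.default_rng(0).standard_normal((4, 10000)),
            rate=1000.0,
            event_onsets=np.array([500, 1500]),
            event_labels=np.array(["drum", "drum"], dtype=object),
        )
        out = downsample(rec, 100.0)
        assert out.data.shape[1] == 1000
        assert out.rate == 100.0
        assert list(out.event_onsets) == [50, 150]

    def test_passband_preserved(self):
        rec = _sine_recording(5.0, seconds=30.0)
        out = downsample(rec, 100.0)
        assert _central_rms(out.data) == pytest.approx(_central_rms(rec.data), rel=0.05)

    def test_upsampling_rejected(self):
        rec = _sine_recording(5.0, rate=100.0)
        with pytest.raises(ValueError):
            downsample(rec, 200.0)


class TestBadChannels:
    def test_flat_and_transient_channels_flagged(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((60, 5000))
        data[10] = 1e-3 * rng.standard_normal(5000)  # flat channel
        data[30, ::250] += 20.0  # heavy transients
        rec = Recording(data=data, rate=100.0, channel_positions=spiral_positions(60))
        report = detect_bad_channels(rec)
        assert report.flagged == [10, 30]
        assert report.kurtosis_z[30] > 2
        assert report.improbability_z[10] < -2
        for ch in report.flagged:
            assert len(report.interpolation_map[ch]) == 4
            assert not set(report.interpolation_map[ch]) & {10, 30}

    def test_identical_channels_unflagged(self):
        data = np.tile(np.sin(np.arange(1000) / 7.0), (8, 1))
        rec = Recording(data=data, rate=100.0)
        assert detect_bad_channels(rec).flagged == []

    def test_infinite_threshold_never_flags(self):
        rng = np.random.default_rng(0)
        rec = Recording(data=rng.standard_normal((10, 2000)), rate=100.0)
        assert detect_bad_channels(rec, threshold=np.inf).flagged == []


class TestInterpolation:
    def _rec(self, data):
        return Recording(data=data, rate=100.0, channel_positions=spiral_positions(len(data)))

    def test_mean_of_identical_neighbours(self):
        s = np.sin(np.arange(500) / 11.0)
        data = np.vstack([np.zeros(500)] + [s] * 4)
        report = ChannelQualityReport(
            np.zeros(5), np.zeros(5), flagged=[0], interpolation_map={0: [1, 2, 3, 4]}
        )
        out = interpolate_channels(self._rec(data), report)
        assert np.allclose(out.data[0], s)

    def test_no_flags_identity(self):
        data = np.random.default_rng(0).standard_normal((5, 100))
        report = ChannelQualityReport(np.zeros(5), np.zeros(5), flagged=[])
        out = interpolate_channels(self._rec(data), report)
        assert np.array_equal(out.data, data)

    def test_variance_not_amplified(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((6, 2000))
        report = ChannelQualityReport(
            np.zeros(6), np.zeros(6), flagged=[2], interpolation_map={2: [0, 1, 3, 4]}
        )
        out = interpolate_channels(self._rec(data), report)
        assert out.data[2].var() <= data[[0, 1, 3, 4]].var(axis=1).max()


class TestRereference:
    def test_mean_zero_and_offset_invariance(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((6, 300))
        out = rereference_average(Recording(data=data, rate=100.0))
        assert np.allclose(out.data.mean(axis=0), 0.0, atol=1e-12)
        shifted = rereference_average(Recording(data=data + 7.5, rate=100.0))
        assert np.allclose(out.data, shifted.data)

    def test_two_channel_closed_form(self):
        a = np.sin(np.arange(100) / 5.0)
        b = np.cos(np.arange(100) / 3.0)
        out = rereference_average(Recording(data=np.vstack([a, b]), rate=100.0))
        assert np.allclose(out.data[0], (a - b) / 2)
        assert np.allclose(out.data[1], (b - a) / 2)


class TestEpoching:
    def _session(self, n_onsets=200, rate=100.0, spacing=50):
        rng = np.random.default_rng(0)
        onsets = np.arange(n_onsets) * spacing
        data = rng.standard_normal((60, int(onsets[-1] + spacing)))
        return Recording(
            data=data,
            rate=rate,
            event_onsets=onsets,
            event_labels=np.array(["syllable"] * n_onsets, dtype=object),
        )

    def test_four_beats_per_epoch(self):
        rec = self._session()
        eps = epoch(rec, 2.0)
        # reconstruct epoch starts and count onsets falling inside each window
        starts = np.arange(eps.n_epochs) * 200
        for s in starts:
            inside = (rec.event_onsets >= s) & (rec.event_onsets < s + 200)
            assert inside.sum() == 4

    def test_counts_and_shape(self):
        eps = epoch(self._session(n_onsets=200), 2.0)
        assert eps.data.shape == (50, 60, 200)
        assert set(eps.labels) == {"syllable"}

    def test_short_recording_warns_empty(self):
        rec = Recording(
            data=np.zeros((4, 100)),
            rate=100.0,
            event_onsets=np.array([0]),
            event_labels=np.array(["drum"], dtype=object),
        )
        with pytest.warns(UserWarning, match="shorter"):
            eps = epoch(rec, 2.0)
        assert eps.n_epochs == 0

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            epoch(Recording(data=np.zeros((4, 1000)), rate=100.0), 2.0)


class TestImprobableEpochs:
    def test_injected_transients_flagged(self):
        rng = np.random.default_rng(8)
        data = rng.standard_normal((120, 30, 200))
        hit = rng.choice(120, size=20, replace=False)
        for e in hit:
            ch = rng.integers(0, 30)
            data[e, ch, 50:80] += 10.0  # 10x RMS transient
        eps = EpochSet(data, np.array(["drum"] * 120, dtype=object), 100.0, 2.0)
        out = reject_improbable_epochs(eps)
        truth = np.zeros(120, bool)
        truth[hit] = True
        assert out.reject_mask[truth].mean() >= 0.9
        assert out.reject_mask[~truth].mean() < 0.10

    def test_homogeneous_gaussian_low_false_rate(self):
        rng = np.random.default_rng(0)
        eps = EpochSet(
            rng.standard_normal((300, 60, 200)),
            np.array(["drum"] * 300, dtype=object), 100.0, 2.0,
        )
        out = reject_improbable_epochs(eps)
        assert out.reject_mask.mean() < 0.05

    def test_clean_and_rejected_partition(self):
        rng = np.random.default_rng(1)
        eps = EpochSet(
            rng.standard_normal((40, 8, 200)),
            np.array(["drum"] * 40, dtype=object), 100.0, 2.0,
        )
        out = reject_improbable_epochs(eps)
        assert out.clean().n_epochs + out.rejected().n_epochs == 40

    def test_too_few_epochs_rejected(self):
        eps = EpochSet(
            np.zeros((5, 4, 200)), np.array(["drum"] * 5, dtype=object), 100.0, 2.0
        )
        with pytest.raises(ValueError):
            reject_improbable_epochs(eps)


class TestFullChain:
    def test_specificity_on_clean_session(self):
        cfg = GeneratorConfig(
            n_repetitions=120, snr=0.6, subject_snr_spread=0.0,
            artifact_channel_count=0, artifact_transient_rate=0.0, rng_seed=17,
        )
        rec = generate_session(cfg, "drum")
        result = run_preprocessing(rec)
        eps = result.epochs
        assert eps.data.shape[1:] == (60, 200)
        assert eps.rate == 100.0
        # contamination-free: few epochs masked, channel false flags within
        # the 10% operating bound of a relative 2-SD criterion
        assert result.rejection_rate <= 0.05
        assert len(result.channel_report.flagged) <= 6
        assert set(eps.labels) == {"drum"}
        # every epoch holds exactly 4 beats: epoch count = repetitions / 4
        assert eps.n_epochs == 30
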