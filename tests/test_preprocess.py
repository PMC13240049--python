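"""Filtering, re-referencing and epoching contracts."""

import numpy as np
import pytest
from scipy import signal

from asmconn.preprocess import (
    ChannelInfo,
    NOTCH_BANDS,
    Recording,
    bipolar_reference,
    common_average_reference,
    detect_pulse_onsets,
    epoch_and_baseline,
    ms_to_samples,
    notch_filter,
)

FS = 2048.0


def _rec(data, channels=None, fs=FS):
    if channels is None:
        channels = [
            ChannelInfo(name=f"C{i + 1}", shaft="S", contact_index=i + 1)
            for i in range(data.shape[0])
        ]
    return Recording(samples=data, fs_hz=fs, channels=channels)


def _sine(freq, n=int(4 * FS), fs=FS):
    return np.sin(2 * np.pi * freq * np.arange(n) / fs)


class TestNotch:
    def test_60hz_attenuated_30db(self):
        rec = _rec(_sine(60.0)[None, :])
        out = notch_filter(rec).samples[0]
        mid = slice(int(FS), int(3 * FS))  # avoid filter edges
        atten_db = 20 * np.log10(np.std(rec.samples[0][mid]) / np.std(out[mid]))
        assert atten_db >= 30.0

    def test_designed_response_oracle(self):
        # magnitude response of the designed cascade, squared for the
        # forward-backward application, evaluated at the stop/pass freqs
        h_total = np.ones(3, dtype=complex)
        for band in NOTCH_BANDS:
            sos = signal.butter(3, band, btype="bandstop", output="sos", fs=FS)
            _, h = signal.sosfreqz(sos, worN=[10.0, 60.0, 120.0], fs=FS)
            h_total *= h
        gain = np.abs(h_total) ** 2  # zero-phase = magnitude squared
        assert -20 * np.log10(gain[1]) >= 30.0  # 60 Hz
        assert -20 * np.log10(gain[2]) >= 30.0  # 120 Hz
        assert abs(gain[0] - 1.0) < 0.01  # 10 Hz passband

    def test_passband_10hz_unchanged(self):
        rec = _rec(_sine(10.0)[None, :])
        out = notch_filter(rec).samples[0]
        mid = slice(int(FS), int(3 * FS))
        assert np.abs(out[mid]).max() == pytest.approx(1.0, rel=0.01)

    def test_zero_signal_stays_zero(self):
        out = notch_filter(_rec(np.zeros((2, 1000)))).samples
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_low_fs_drops_highest_band_with_warning(self):
        rec = _rec(np.random.default_rng(0).standard_normal((1, 2000)), fs=360.0)
        with pytest.warns(UserWarning, match="skipped"):
            notch_filter(rec)

    def test_zero_phase_preserves_symmetric_pulse_peak(self):
        x = np.exp(-0.5 * ((np.arange(4096) - 2048) / 10.0) ** 2)
        out = notch_filter(_rec(x[None, :])).samples[0]
        assert np.argmax(out) == np.argmax(x)


class TestBipolar:
    def _shaft(self, n, bad=()):
        return [
            ChannelInfo(name=f"A{i + 1}", shaft="A", contact_index=i + 1,
                        bad=(i + 1) in bad)
            for i in range(n)
        ]

    def test_count_full_shaft(self):
        rec = _rec(np.random.default_rng(0).standard_normal((10, 100)),
                   channels=self._shaft(10))
        out = bipolar_reference(rec)
        assert out.n_channels == 9
        assert out.channel_names[0] == "A1-A2"

    def test_common_mode_rejection(self):
        x = np.random.default_rng(1).standard_normal(100)
        rec = _rec(np.vstack([x, x]), channels=self._shaft(2))
        np.testing.assert_allclose(bipolar_reference(rec).samples, 0.0, atol=1e-12)

    def test_shared_signal_invariance(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((4, 200))
        common = rng.standard_normal(200)
        rec_a = _rec(data.copy(), channels=self._shaft(4))
        rec_b = _rec(data + common, channels=self._shaft(4))
        np.testing.assert_allclose(
            bipolar_reference(rec_a).samples, bipolar_reference(rec_b).samples,
            atol=1e-12,
        )

    def test_bad_contact_excluded_with_its_pairs(self):
        rec = _rec(np.zeros((5, 10)), channels=self._shaft(5, bad=(3,)))
        out = bipolar_reference(rec)
        # pairs 1-2 and 4-5 survive; 2-3 and 3-4 are dropped
        assert out.channel_names == ["A1-A2", "A4-A5"]

    def test_zone_inherits_most_pathological(self):
        chans = [
            ChannelInfo(name="A1", shaft="A", contact_index=1, zone="NIZ"),
            ChannelInfo(name="A2", shaft="A", contact_index=2, zone="SOZ"),
        ]
        out = bipolar_reference(_rec(np.zeros((2, 10)), channels=chans))
        assert out.channels[0].zone == "SOZ"

    def test_short_shaft_yields_nothing(self):
        out = bipolar_reference(_rec(np.zeros((1, 10)), channels=self._shaft(1)))
        assert out.n_channels == 0

    def test_linearity(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((4, 50))
        rec = _rec(data, channels=self._shaft(4))
        rec3 = _rec(3.0 * data, channels=self._shaft(4))
        np.testing.assert_allclose(
            bipolar_reference(rec3).samples, 3.0 * bipolar_reference(rec).samples
        )


class TestCommonAverage:
    def test_included_mean_zero(self):
        rng = np.random.default_rng(4)
        rec = _rec(rng.standard_normal((5, 200)))
        out = common_average_reference(rec, exclude=["C5"])
        np.testing.assert_allclose(out.samples[:4].mean(axis=0), 0.0, atol=1e-9)

    def test_two_channel_hand_computation(self):
        x = np.array([2.0, 4.0, 6.0])
        y = np.array([0.0, 2.0, 2.0])
        out = common_average_reference(_rec(np.vstack([x, y]))).samples
        np.testing.assert_allclose(out[0], (x - y) / 2)
        np.testing.assert_allclose(out[1], (y - x) / 2)

    def test_excluded_channel_does_not_leak(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((4, 100))
        out1 = common_average_reference(_rec(data.copy()), exclude=["C4"]).samples
        data2 = data.copy()
        data2[3] += 100.0
        out2 = common_average_reference(_rec(data2), exclude=["C4"]).samples
        np.testing.assert_allclose(out1[:3], out2[:3])
        assert np.abs(out1[3] - out2[3]).max() > 50

    def test_refuses_single_included(self):
        with pytest.raises(ValueError):
            common_average_reference(_rec(np.zeros((2, 10))), exclude=["C1"])

    def test_linearity(self):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((3, 50))
        out1 = common_average_reference(_rec(data)).samples
        out2 = common_average_reference(_rec(2.5 * data)).samples
        np.testing.assert_allclose(out2, 2.5 * out1)


class TestEpoching:
    def test_constant_channel_zeroed(self):
        rec = _rec(np.full((1, int(10 * FS)), 5.0))
        ep = epoch_and_baseline(rec, [int(2 * FS), int(5 * FS)])
        np.testing.assert_allclose(ep.data, 0.0, atol=1e-12)

    def test_trial_count_and_baseline_mean(self):
        rng = np.random.default_rng(7)
        rec = _rec(rng.standard_normal((3, int(50 * FS))))
        onsets = [int((2 + k) * FS) for k in range(40)]
        ep = epoch_and_baseline(rec, onsets)
        assert ep.n_trials == 40
        bmask = (ep.times_ms >= -215) & (ep.times_ms <= -15)
        np.testing.assert_allclose(
            ep.data[:, :, bmask].mean(axis=2), 0.0, atol=1e-9
        )

    def test_edge_onset_dropped(self, caplog):
        rec = _rec(np.zeros((1, int(2 * FS))))
        ep = epoch_and_baseline(rec, [10, int(FS)])
        assert ep.n_trials == 1  # first onset has no room for the pre-window

    def test_ms_to_samples_rounds_half_away_from_zero(self):
        assert ms_to_samples(0.5, 1000.0) == 1
        assert ms_to_samples(-0.5, 1000.0) == -1
        assert ms_to_samples(1.4, 1000.0) == 1


class TestPipelineLinearity:
    def test_notch_reference_epoch_commute_with_scaling(self):
        rng = np.random.default_rng(8)
        chans = [
            ChannelInfo(name=f"A{i + 1}", shaft="A", contact_index=i + 1)
            for i in range(4)
        ]
        data = rng.standard_normal((4, int(8 * FS)))
        onsets = [int(3 * FS), int(5 * FS)]

        def chain(d):
            rec = _rec(d, channels=chans)
            return epoch_and_baseline(
                bipolar_reference(notch_filter(rec)), onsets
            ).data

        np.testing.assert_allclose(chain(2.0 * data), 2.0 * chain(data), atol=1e-8)


def test_pulse_onset_detector_finds_artifacts():
    rng = np.random.default_rng(9)
    x = rng.standard_normal(int(10 * FS))
    true = [int(2 * FS), int(4 * FS), int(6 * FS)]
    for on in true:
        x[on] += 400.0
        x[on + 1] -= 400.0
    found = detect_pulse_onsets(x, FS)
    assert len(found) == 3
    assert all(abs(f - t) <= 1 for f, t in zip(found, true))
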