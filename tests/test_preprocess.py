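import logging

import numpy as np
import pytest

from cmcoh import (
    ChannelInfo,
    Modality,
    Muscle,
    Recording,
    Side,
    bandpass,
    emg_condition,
    epoch_events,
    flip_to_ipsilesional,
    rereference_average,
    segment_clean,
    surface_laplacian,
)
from cmcoh.core_io import ValidationError


def _rec(data, channels, fs=1000.0, events=()):
    return Recording(data=np.asarray(data, float), fs=fs, channels=channels,
                     events=list(events))


def _eeg_channels(n):
    return [ChannelInfo.eeg(f"E{i+1}") for i in range(n)]


class TestBandpass:
    fs = 1000.0
    t = np.arange(0, 10, 1 / 1000.0)

    def _gain(self, freq, low=0.5, high=50.0):
        """Amplitude gain at `freq` by quadrature projection over the middle
        of the record (rejects the slowly decaying 0.5 Hz edge transient)."""
        x = np.sin(2 * np.pi * freq * self.t)[None, :]
        rec = _rec(x, _eeg_channels(1), self.fs)
        out = bandpass(rec, low, high)
        mid = slice(2000, 8000)
        y = out.data[0, mid]
        tm = self.t[mid]
        s, c = np.sin(2 * np.pi * freq * tm), np.cos(2 * np.pi * freq * tm)
        return 2 * np.hypot((y * s).mean(), (y * c).mean())

    def test_passband_10hz_within_1db(self):
        assert 0.89 <= self._gain(10.0) <= 1.01

    def test_stopband_100hz_at_least_40db(self):
        assert self._gain(100.0) < 10 ** (-40 / 20)

    def test_dc_removed(self):
        rec = _rec(np.full((1, 10_000), 7.3), _eeg_channels(1))
        out = bandpass(rec)
        assert np.abs(out.data[0, 2000:8000]).max() < 1e-3

    def test_bad_edges_rejected(self):
        rec = _rec(np.zeros((1, 1000)), _eeg_channels(1))
        with pytest.raises(ValidationError):
            bandpass(rec, 50.0, 0.5)


class TestRereference:
    def test_mean_subtraction(self):
        rec = _rec([[3.0] * 10, [1.0] * 10], _eeg_channels(2))
        out = rereference_average(rec)
        np.testing.assert_allclose(out.data[0], 1.0)
        np.testing.assert_allclose(out.data[1], -1.0)

    def test_idempotent_and_zero_mean(self):
        rng = np.random.default_rng(0)
        rec = _rec(rng.normal(size=(4, 100)), _eeg_channels(4))
        once = rereference_average(rec)
        np.testing.assert_allclose(once.data.mean(axis=0), 0.0, atol=1e-12)
        twice = rereference_average(once)
        np.testing.assert_allclose(twice.data, once.data)

    def test_emg_untouched(self):
        channels = _eeg_channels(2) + [ChannelInfo.emg(Muscle.FDI, Side.right)]
        rng = np.random.default_rng(1)
        rec = _rec(rng.normal(size=(3, 50)), channels)
        out = rereference_average(rec)
        np.testing.assert_array_equal(out.data[2], rec.data[2])


TOY_ADJ = {  # 5-node star-ish graph: E1 central
    "E1": ["E2", "E3", "E4"],
    "E2": ["E1", "E3"],
    "E3": ["E1", "E2"],
    "E4": ["E1", "E5"],
    "E5": ["E4"],
}


class TestLaplacian:
    def test_constant_potential_maps_to_zero(self):
        rec = _rec(np.full((5, 20), 4.2), _eeg_channels(5))
        out = surface_laplacian(rec, TOY_ADJ)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_single_active_channel_toy_graph(self):
        """E1 = 1, rest 0: out(E1)=1, out(neighbors of E1) = -1/|nbrs|."""
        data = np.zeros((5, 3))
        data[0] = 1.0
        rec = _rec(data, _eeg_channels(5))
        out = surface_laplacian(rec, TOY_ADJ)
        np.testing.assert_allclose(out.data[0], 1.0)  # E1: 1 - 0
        np.testing.assert_allclose(out.data[1], -1 / 2)  # E2: 0 - 1/2
        np.testing.assert_allclose(out.data[2], -1 / 2)  # E3
        np.testing.assert_allclose(out.data[3], -1 / 2)  # E4: nbrs E1,E5
        np.testing.assert_allclose(out.data[4], 0.0)  # E5: nbr E4 only

    def test_linear_gradient_interior_zero(self):
        """On a 1-D chain a linear potential has zero discrete Laplacian at
        interior nodes."""
        n = 9
        adj = {f"E{i}": [f"E{i-1}", f"E{i+1}"] for i in range(2, n)}
        adj["E1"] = ["E2"]
        adj[f"E{n}"] = [f"E{n-1}"]
        data = np.arange(1, n + 1, dtype=float)[:, None] * np.ones((1, 4))
        out = surface_laplacian(_rec(data, _eeg_channels(n)), adj)
        np.testing.assert_allclose(out.data[1 : n - 1], 0.0, atol=1e-12)

    def test_channel_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(5, 30))
        rec = _rec(data, _eeg_channels(5))
        out = surface_laplacian(rec, TOY_ADJ)
        perm = [3, 1, 4, 0, 2]
        rec_p = _rec(data[perm], [rec.channels[i] for i in perm])
        out_p = surface_laplacian(rec_p, TOY_ADJ)
        np.testing.assert_allclose(out_p.data, out.data[perm])

    def test_isolated_channel_rejected(self):
        rec = _rec(np.zeros((2, 5)), _eeg_channels(2))
        with pytest.raises(ValidationError, match="neighbors"):
            surface_laplacian(rec, {"E1": [], "E2": ["E1"]})


class TestEmgCondition:
    fs = 1000.0

    def _emg_rec(self, x):
        channels = [ChannelInfo.eeg("E1"), ChannelInfo.emg(Muscle.FDI, Side.right)]
        return _rec(np.stack([np.zeros_like(x), x]), channels, self.fs)

    def test_am_carrier_envelope_recovered(self):
        t = np.arange(0, 10, 1 / self.fs)
        A = 1.5 + np.sin(2 * np.pi * 0.5 * t)  # slow nonnegative modulation
        rec = self._emg_rec(A * np.sin(2 * np.pi * 60.0 * t))
        out = emg_condition(rec, band=(10.0, 100.0))
        mid = slice(1000, 9000)
        rel_rms = np.sqrt(np.mean((out.data[1, mid] - A[mid]) ** 2)) / np.sqrt(
            np.mean(A[mid] ** 2)
        )
        assert rel_rms < 0.05

    def test_pure_sinusoid_constant_envelope(self):
        t = np.arange(0, 5, 1 / self.fs)
        rec = self._emg_rec(2.0 * np.sin(2 * np.pi * 40.0 * t))
        out = emg_condition(rec)
        np.testing.assert_allclose(out.data[1, 500:4500], 2.0, rtol=0.02)

    def test_envelope_nonnegative_and_eeg_untouched(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=5000)
        rec = self._emg_rec(x)
        out = emg_condition(rec)
        assert (out.data[1] >= 0).all()
        np.testing.assert_array_equal(out.data[0], rec.data[0])


class TestSegmentClean:
    def test_floor_division_count(self):
        rec = _rec(np.zeros((1, 10_500)), _eeg_channels(1))
        assert len(segment_clean(rec)) == 10

    def test_spike_segment_dropped(self):
        data = np.zeros((1, 10_500))
        data[0, 3500] = 500.0  # 500 uV spike in segment 3
        rec = _rec(data, _eeg_channels(1))
        kept = segment_clean(rec, amplitude_uv=200.0)
        assert len(kept) == 9
        assert (3000, 4000) not in kept

    def test_precleaned_hook_skips_thresholding(self):
        data = np.zeros((1, 10_000))
        data[0, 100] = 500.0
        rec = _rec(data, _eeg_channels(1))
        assert len(segment_clean(rec, precleaned=True)) == 10

    def test_artifact_free_drops_nothing(self, small_recording):
        spans = segment_clean(small_recording)
        assert len(spans) == small_recording.n_samples // 1000


class TestEpochEvents:
    def test_window_arithmetic(self):
        data = np.arange(20_000, dtype=float)[None, :]
        rec = _rec(data, _eeg_channels(1), events=[(5000, "go")])
        ep = epoch_events(rec)
        assert ep.data.shape == (1, 1, 5000)
        assert ep.data[0, 0, 0] == 4000.0  # [4000, 9000)
        assert ep.data[0, 0, -1] == 8999.0

    def test_truncated_event_skipped_with_warning(self, caplog):
        rec = _rec(
            np.zeros((1, 20_000)),
            _eeg_channels(1),
            events=[(500, "early"), (5000, "ok")],
        )
        with caplog.at_level(logging.WARNING):
            ep = epoch_events(rec)
        assert ep.n_epochs == 1
        assert any("skipped" in r.message for r in caplog.records)

    def test_no_usable_events_is_error(self):
        rec = _rec(np.zeros((1, 2000)), _eeg_channels(1), events=[(100, "x")])
        with pytest.raises(ValidationError):
            epoch_events(rec)

    def test_all_events_usable(self, small_recording):
        ep = epoch_events(small_recording)
        assert ep.n_epochs == len(small_recording.events)


class TestFlip:
    def _epochs(self, roi_map):
        from cmcoh import EpochSet

        labels = ["E30", "E197", "E6"]  # PMC-left[0], PMC-right[0], SMA
        channels = [ChannelInfo.eeg(lab) for lab in labels]
        channels += [
            ChannelInfo.emg(Muscle.FDI, Side.left),
            ChannelInfo.emg(Muscle.FDI, Side.right),
        ]
        rng = np.random.default_rng(9)
        return EpochSet(
            data=rng.normal(size=(2, 5, 5000)),
            fs=1000.0,
            channels=channels,
            pre_ms=1000,
            post_ms=4000,
        )

    def test_left_lesion_is_identity(self, roi_map):
        ep = self._epochs(roi_map)
        out = flip_to_ipsilesional(ep, Side.left, roi_map)
        assert out.labels == ep.labels
        assert not out.flipped
        np.testing.assert_array_equal(out.data, ep.data)

    def test_right_lesion_swaps_paired_labels(self, roi_map):
        """The signal formerly addressed as E197 (first right PMC electrode)
        becomes E30 (first left PMC electrode); values are untouched."""
        ep = self._epochs(roi_map)
        out = flip_to_ipsilesional(ep, Side.right, roi_map)
        assert out.flipped
        assert out.labels[ep.labels.index("E197")] == "E30"
        assert out.labels[ep.labels.index("E30")] == "E197"
        assert out.labels[ep.labels.index("E6")] == "E6"  # midline fixed
        np.testing.assert_array_equal(
            out.data[out.labels.index("E30")], ep.data[ep.labels.index("E197")]
        )
        # EMG sides swapped
        assert out.labels[3] == "EMG_FDI_R" and out.labels[4] == "EMG_FDI_L"

    def test_involution(self, roi_map):
        ep = self._epochs(roi_map)
        twice = flip_to_ipsilesional(
            flip_to_ipsilesional(ep, Side.right, roi_map), Side.right, roi_map
        )
        assert twice.labels == ep.labels
        assert not twice.flipped
        np.testing.assert_array_equal(twice.data, ep.data)
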