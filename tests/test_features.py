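"""Recording I/O, montage, filtering, windowing and CSD estimation."""

import numpy as np
import pytest

from synaptrack.features import (
    Recording,
    WindowedCSD,
    bandpass,
    bipolar_montage,
    estimate_csd,
    read_recording,
    segment_windows,
    write_recording_text,
)
from synaptrack.spectral import FrequencyGrid, csd_is_hermitian


@pytest.fixture()
def rec4():
    rng = np.random.default_rng(0)
    data = 20.0 * rng.standard_normal((4, 256 * 8))
    return Recording(["LH4", "LH5", "LH6", "LH7"], 256.0, data)


class TestReadRecording:
    def test_text_round_trip(self, rec4, tmp_path):
        path = tmp_path / "rec.csv"
        write_recording_text(rec4, path)
        back = read_recording(path)
        assert back.labels == rec4.labels
        assert back.fs == rec4.fs
        assert np.allclose(back.data, rec4.data)

    def test_edf_fixture(self, edf_path):
        path, data = edf_path
        rec = read_recording(path)
        assert rec.fs == 256.0
        assert rec.labels == ["LH4", "LH5"]
        # 16-bit quantisation over +-1000 uV
        assert np.abs(rec.data - data[:, : rec.data.shape[1]]).max() < 0.1

    def test_missing_sample_rate(self, rec4, tmp_path):
        path = tmp_path / "naked.csv"
        np.savetxt(path, rec4.data.T, delimiter=",", header="a,b,c,d", comments="")
        with pytest.raises(ValueError, match="sampling rate"):
            read_recording(path)

    def test_truncated_edf_errors_with_context(self, edf_path, tmp_path):
        path, _ = edf_path
        broken = tmp_path / "broken.edf"
        broken.write_bytes(path.read_bytes()[:100])
        with pytest.raises(IOError, match="bytes"):
            read_recording(broken)

    def test_unknown_format(self, tmp_path):
        p = tmp_path / "x.csv"
        p.write_text("a,b\n1,2\n3,4\n")
        with pytest.raises(ValueError, match="format"):
            read_recording(p, format="parquet")


class TestBipolarMontage:
    def test_identical_channels_cancel(self, rec4):
        twin = Recording(["a", "b"], 256.0, np.vstack([rec4.data[0], rec4.data[0]]))
        out = bipolar_montage(twin, [("a", "b")])
        assert np.allclose(out.data, 0.0)

    def test_common_mode_rejection(self, rec4):
        shifted = Recording(rec4.labels, rec4.fs, rec4.data + 123.4)
        pairs = [("LH4", "LH5"), ("LH6", "LH7")]
        a = bipolar_montage(rec4, pairs)
        b = bipolar_montage(shifted, pairs)
        assert np.allclose(a.data, b.data)

    def test_labels_and_values(self, rec4):
        out = bipolar_montage(rec4, [("LH4", "LH5"), ("LH6", "LH7")])
        assert out.labels == ["LH4-LH5", "LH6-LH7"]
        assert np.allclose(out.data[0], rec4.data[0] - rec4.data[1])

    def test_unknown_label(self, rec4):
        with pytest.raises(KeyError):
            bipolar_montage(rec4, [("LH4", "nope")])


class TestBandpass:
    fs = 256.0
    t = np.arange(int(256 * 8)) / 256.0

    def _power(self, x):
        return float(np.mean(x**2))

    def test_stopband_attenuation(self):
        tone = np.sin(2 * np.pi * 100 * self.t)
        rec = Recording(["a"], self.fs, tone[None, :])
        out = bandpass(rec, 0.5, 48.0)
        mid = slice(256, -256)  # zero-phase filtering leaves edge transients
        assert self._power(out.data[0, mid]) < 0.01 * self._power(tone[mid])

    def test_passband_preserved(self):
        tone = np.sin(2 * np.pi * 10 * self.t)
        rec = Recording(["a"], self.fs, tone[None, :])
        out = bandpass(rec, 0.5, 48.0)
        mid = slice(256, -256)  # ignore filter edge transients
        amp = np.abs(out.data[0, mid]).max()
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_dc_rejected(self):
        rec = Recording(["a"], self.fs, np.full((1, 2048), 7.0))
        out = bandpass(rec, 0.5, 48.0)
        assert np.abs(out.data).max() < 1e-6

    def test_band_outside_nyquist(self, rec4):
        with pytest.raises(ValueError):
            bandpass(rec4, 0.5, 200.0)

    def test_montage_and_filter_commute(self, rec4):
        pairs = [("LH4", "LH5"), ("LH6", "LH7")]
        a = bandpass(bipolar_montage(rec4, pairs), 0.5, 48.0)
        b = bipolar_montage(bandpass(rec4, 0.5, 48.0), pairs)
        assert np.allclose(a.data, b.data, atol=1e-8)


class TestSegmentWindows:
    def test_canonical_peri_onset_geometry(self):
        """Two 10-s segments of 2-s windows at 50% overlap: 9 + 9 = 18."""
        wins = segment_windows(10.0, 2.0, 0.5)
        assert len(wins) == 9
        assert len(wins) + len(segment_windows(10.0, 2.0, 0.5)) == 18

    def test_single_full_window(self):
        assert segment_windows(10.0, 10.0, 0.0) == [(0.0, 10.0)]

    @pytest.mark.parametrize("duration,wl,ov", [(12.0, 2.0, 0.5), (10.0, 1.0, 0.0), (9.0, 3.0, 2 / 3)])
    def test_uniform_length_and_stride(self, duration, wl, ov):
        wins = np.array(segment_windows(duration, wl, ov))
        assert np.allclose(wins[:, 1] - wins[:, 0], wl)
        if len(wins) > 1:
            assert np.allclose(np.diff(wins[:, 0]), wl * (1 - ov))
        assert wins[-1, 1] <= duration + 1e-9

    def test_infeasible_geometry(self):
        with pytest.raises(ValueError):
            segment_windows(1.0, 2.0, 0.5)
        with pytest.raises(ValueError):
            segment_windows(10.0, 2.0, 1.0)


class TestEstimateCSD:
    fs = 256.0

    def test_duplicated_channel_has_unit_coherence(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(int(self.fs * 10))
        rec = Recording(["a", "b"], self.fs, np.vstack([x, x]))
        grid = FrequencyGrid.default()
        w = estimate_csd(rec, [(0.0, 10.0)], grid, method="var")
        S = w.csd[0]
        coh = np.abs(S[:, 0, 1]) ** 2 / (S[:, 0, 0].real * S[:, 1, 1].real)
        assert np.allclose(coh, 1.0, atol=1e-6)

    def test_independent_white_noise(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((2, int(self.fs * 60)))
        rec = Recording(["a", "b"], self.fs, data)
        grid = FrequencyGrid.default()
        # ~29 tapers give a per-bin sampling sd of ~19%
        w = estimate_csd(rec, [(0.0, 60.0)], grid, method="multitaper", n_tapers=29)
        auto = w.csd[0, :, 0, 0].real
        flat = 2.0 / self.fs  # one-sided density of unit-variance white noise
        assert np.abs(auto / flat - 1).mean() < 0.25
        coh = np.abs(w.csd[0, :, 0, 1]) ** 2 / (auto * w.csd[0, :, 1, 1].real)
        assert coh.mean() < 0.2

    def test_lagged_sinusoid_phase(self):
        lag = 0.025
        t = np.arange(int(self.fs * 60)) / self.fs
        rng = np.random.default_rng(3)
        x1 = np.sin(2 * np.pi * 10 * t) + 0.01 * rng.standard_normal(t.size)
        x2 = np.sin(2 * np.pi * 10 * (t - lag)) + 0.01 * rng.standard_normal(t.size)
        rec = Recording(["a", "b"], self.fs, np.vstack([x1, x2]))
        w = estimate_csd(rec, [(0.0, 60.0)], FrequencyGrid(np.arange(8.0, 13.0)), method="multitaper")
        phase = np.angle(w.csd[0, 2, 0, 1])  # 10 Hz bin
        assert phase == pytest.approx(2 * np.pi * 10 * lag, abs=0.05)

    def test_output_passes_csd_invariants(self, rec4):
        grid = FrequencyGrid.default()
        w = estimate_csd(rec4, [(0.0, 2.0), (1.0, 3.0)], grid, method="var")
        assert csd_is_hermitian(w.csd)
        assert w.meta["estimator"] == "var"

    def test_window_too_short(self, rec4):
        with pytest.raises(ValueError, match="short"):
            estimate_csd(rec4, [(0.0, 0.05)], FrequencyGrid.default())

    def test_out_of_bounds_window(self, rec4):
        with pytest.raises(ValueError, match="bounds"):
            estimate_csd(rec4, [(0.0, 100.0)], FrequencyGrid.default())


class TestWindowedCSDContainer:
    def test_hdf5_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        raw = rng.standard_normal((3, 41, 2, 2)) + 1j * rng.standard_normal((3, 41, 2, 2))
        csd = raw + raw.conj().swapaxes(-1, -2)
        w = WindowedCSD(
            csd=csd,
            windows=np.array([[0.0, 2.0], [1.0, 3.0], [2.0, 4.0]]),
            grid=FrequencyGrid.default(),
            labels=["c0", "c1"],
            segments=["pre", "pre", "ictal"],
            meta={"estimator": "var"},
        )
        path = tmp_path / "w.h5"
        w.to_hdf5(path)
        back = WindowedCSD.from_hdf5(path)
        assert np.allclose(back.csd, w.csd)
        assert back.segments == w.segments
        assert back.meta["estimator"] == "var"
        assert np.allclose(back.grid.freqs, w.grid.freqs)

    def test_time_ordering_enforced(self):
        with pytest.raises(ValueError):
            WindowedCSD(
                csd=np.zeros((2, 41, 2, 2), dtype=complex),
                windows=np.array([[1.0, 3.0], [0.0, 2.0]]),
                grid=FrequencyGrid.default(),
                labels=["a", "b"],
            )
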