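import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barrelcircuit import ephys, synthdata as sd
from barrelcircuit.core import ProbeRecording, SpikeUnit, StimulusLog


def _sine_recording(freq, fs=30000.0, dur=2.0, n_channels=1):
    t = np.arange(int(dur * fs)) / fs
    x = np.sin(2 * np.pi * freq * t)
    return ProbeRecording(np.tile(x, (n_channels, 1)), fs, 25.0)


def _band_amplitude(x, freq, fs):
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, 1 / fs)
    return spec[np.argmin(np.abs(freqs - freq))]


class TestSplitBands:
    def test_1khz_survives_mua_attenuated_in_lfp(self):
        rec = _sine_recording(1000.0)
        mua, lfp = ephys.split_bands(rec)
        a_in = _band_amplitude(rec.samples[0], 1000.0, rec.fs)
        a_mua = _band_amplitude(mua[0], 1000.0, rec.fs)
        a_lfp = _band_amplitude(lfp[0], 1000.0, rec.fs)
        assert a_mua > 0.5 * a_in
        assert 20 * np.log10(a_in / a_lfp) >= 40.0

    def test_50hz_notched_in_lfp(self):
        rec = _sine_recording(50.0)
        _, lfp = ephys.split_bands(rec)
        a_in = _band_amplitude(rec.samples[0], 50.0, rec.fs)
        a_lfp = _band_amplitude(lfp[0], 50.0, rec.fs)
        assert 20 * np.log10(a_in / a_lfp) >= 20.0

    def test_dc_removed_from_mua(self):
        rec = ProbeRecording(np.full((1, 60000), 37.0), 30000.0, 25.0)
        mua, _ = ephys.split_bands(rec)
        assert abs(mua.mean()) < 1e-6

    def test_output_lengths_preserved(self):
        rec = _sine_recording(500.0, dur=0.5, n_channels=3)
        mua, lfp = ephys.split_bands(rec)
        assert mua.shape == lfp.shape == rec.samples.shape

    def test_low_fs_rejected(self):
        rec = ProbeRecording(np.zeros((1, 1000)), 10000.0, 25.0)
        with pytest.raises(ValueError, match="too low"):
            ephys.split_bands(rec)


class TestDetectMua:
    def test_constant_trace_errors(self):
        with pytest.raises(ValueError, match="zero"):
            ephys.detect_mua(np.zeros(30000), 30000.0)

    def test_false_positive_rate_below_0p1_per_s(self, rng):
        fs, dur = 30000.0, 20.0
        trace = rng.normal(0, 1, int(fs * dur))
        events = ephys.detect_mua(trace, fs, k=5.0)
        assert events.size / dur < 0.1

    def test_planted_spikes_recovered(self, rng):
        fs, dur = 30000.0, 10.0
        trace = rng.normal(0, 1, int(fs * dur))
        true_times = np.arange(0.5, dur - 0.5, 0.1)
        width = int(0.4e-3 * fs)
        kernel = -10.0 * np.hanning(2 * width)
        for t0 in true_times:
            i = int(t0 * fs)
            trace[i:i + kernel.size] += kernel
        detected = ephys.detect_mua(trace, fs, k=5.0)
        hits = 0
        for t0 in true_times:
            err = np.min(np.abs(detected - t0))
            if err <= 0.5e-3:
                hits += 1
        assert hits / true_times.size >= 0.99


class TestComputeCsd:
    def test_linear_profile_gives_zero(self):
        lfp = (2.0 + 3.0 * np.arange(8))[:, None] * np.ones((1, 10))
        csd = ephys.compute_csd(lfp, spacing=25.0)
        np.testing.assert_allclose(csd.values, 0.0, atol=1e-12)

    def test_quadratic_profile_gives_constant(self):
        c = 1.7
        lfp = (c * np.arange(8) ** 2)[:, None] * np.ones((1, 5))
        csd = ephys.compute_csd(lfp, spacing=10.0)
        np.testing.assert_allclose(csd.values, 2 * c / 100.0, rtol=1e-12)

    def test_too_few_channels(self):
        with pytest.raises(ValueError):
            ephys.compute_csd(np.zeros((2, 10)), 25.0)

    @given(a=st.floats(-5, 5), b=st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_linearity(self, a, b):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 4))
        y = rng.normal(size=(6, 4))
        lhs = ephys.compute_csd(a * x + b * y, 20.0).values
        rhs = a * ephys.compute_csd(x, 20.0).values \
            + b * ephys.compute_csd(y, 20.0).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_edges_dropped(self):
        csd = ephys.compute_csd(np.zeros((10, 4)), 25.0)
        assert csd.values.shape[0] == 8
        assert csd.channels[0] == 1 and csd.channels[-1] == 8


class TestAssignLayers:
    def test_shortest_latency_wins_with_two_sinks(self):
        # channel 8 sinks at 4 ms, channel 20 (deeper) at 9 ms
        n_ch, t = 30, np.arange(0.0, 20.0, 0.5)
        values = np.zeros((n_ch, t.size))
        values[8] = -8.0 * np.exp(-0.5 * ((t - 4.0) / 1.0) ** 2)
        values[20] = -10.0 * np.exp(-0.5 * ((t - 9.0) / 1.0) ** 2)
        from barrelcircuit.core import CsdProfile
        csd = CsdProfile(values=values, channels=np.arange(1, n_ch + 1),
                         times=t, spacing=25.0)
        out = ephys.assign_layers(csd)
        assert out["l4_channel"] == 9  # row 8 -> probe channel 9
        assert out["layers"][5] == "L2/3"
        assert out["layers"][21] == "below-L4"

    def test_flat_csd_errors(self):
        from barrelcircuit.core import CsdProfile
        csd = CsdProfile(values=np.zeros((5, 10)), channels=np.arange(1, 6),
                         times=np.arange(10.0), spacing=25.0)
        with pytest.raises(ValueError, match="no identifiable sink"):
            ephys.assign_layers(csd)

    def test_planted_sink_layer_map(self):
        rec, truth = sd.gen_laminar_lfp(sd.LaminarSimParams(
            sink_channel=12, noise_sd=0.0))
        csd = ephys.compute_csd(rec.samples, rec.channel_spacing,
                                times=rec.times * 1e3)
        out = ephys.assign_layers(csd)
        assert out["l4_channel"] == 12
        superficial = [ch for ch, lab in out["layers"].items() if lab == "L2/3"]
        assert superficial == list(range(1, 12))


class TestClassifyWaveform:
    @staticmethod
    def _unit(waveform, fs):
        return SpikeUnit("u", np.array([0.0]), waveform=waveform, waveform_fs=fs)

    def test_t2p_0p8_is_rs(self):
        u = self._unit(sd._waveform_template(0.8, 30000.0), 30000.0)
        assert ephys.classify_waveform(u) == "RS"

    def test_t2p_0p3_is_fs(self):
        u = self._unit(sd._waveform_template(0.3, 30000.0), 30000.0)
        assert ephys.classify_waveform(u) == "FS"

    def test_boundary_0p5_is_rs(self):
        # at fs=2 kHz one sample is exactly 0.5 ms
        w = np.array([0.0, -1.0, 1.0, 0.0])
        u = self._unit(w, 2000.0)
        t2p = ephys.waveform_trough_to_peak(w, 2000.0)
        assert t2p == pytest.approx(0.5)
        assert ephys.classify_waveform(u) == "RS"

    def test_no_post_trough_peak_errors(self):
        w = np.array([3.0, 2.0, 1.0, 0.0, -1.0])
        with pytest.raises(ValueError, match="post-trough"):
            ephys.waveform_trough_to_peak(w, 30000.0)

    def test_session_labels_recovered_exactly(self, small_ephys_session):
        truth = small_ephys_session.truth.set_index("unit_id")
        for unit in small_ephys_session.units:
            assert ephys.classify_waveform(unit) == truth.loc[unit.unit_id,
                                                              "cell_class"]


class TestClassifyOptotag:
    @staticmethod
    def _log(onsets):
        return StimulusLog.from_arrays(onsets, ["light"] * len(onsets))

    def test_short_latency_reliable_is_tagged(self):
        onsets = [1.0, 2.0, 3.0]
        spikes = np.array([1.002, 2.003, 3.004])
        res = ephys.classify_optotag(SpikeUnit("u", spikes), self._log(onsets))
        assert res.label == "optotagged"
        assert res.mean_latency_ms == pytest.approx(3.0)
        assert res.reliability == 1.0

    def test_long_latency_is_unlabeled(self):
        onsets = [1.0, 2.0, 3.0]
        spikes = np.array([1.006, 2.007, 3.008])
        res = ephys.classify_optotag(SpikeUnit("u", spikes), self._log(onsets))
        assert res.label == "unlabeled"

    def test_no_light_spikes_unlabeled(self):
        res = ephys.classify_optotag(SpikeUnit("u", np.array([10.0])),
                                     self._log([1.0, 2.0]))
        assert res.label == "unlabeled"
        assert np.isnan(res.mean_latency_ms)

    def test_no_light_events_errors(self):
        log = StimulusLog.from_arrays([1.0], ["PW"])
        with pytest.raises(ValueError, match="no light"):
            ephys.classify_optotag(SpikeUnit("u", np.array([1.0])), log)

    def test_unreliable_unit_unlabeled(self):
        onsets = list(np.arange(1.0, 11.0))
        spikes = np.array([1.002, 2.003])  # 2/10 trials
        res = ephys.classify_optotag(SpikeUnit("u", spikes), self._log(onsets))
        assert res.reliability == pytest.approx(0.2)
        assert res.label == "unlabeled"

    def test_session_tags_recovered_exactly(self, small_ephys_session):
        truth = small_ephys_session.truth.set_index("unit_id")
        for unit in small_ephys_session.units:
            res = ephys.classify_optotag(unit, small_ephys_session.log)
            expected = "optotagged" if truth.loc[unit.unit_id, "tagged"] \
                else "unlabeled"
            assert res.label == expected
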