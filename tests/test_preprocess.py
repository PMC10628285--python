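"""QC, referencing, artifact rejection, and the HG/LFS extraction oracles."""

import numpy as np
import pandas as pd
import pytest

import microspeech as ms
from microspeech.bundle import EVENT_COLUMNS
from microspeech.preprocess import (ProcessingError, hg_envelope, load_tensor,
                                    save_tensor)


def _events(n_trials=10, spacing=2.5, fs=2000.0):
    rows, t = [], 1.0
    for i in range(n_trials):
        rows.append(dict(trial_id=i, token="p a p", p1="p", p2="a", p3="p",
                         stim_onset_s=t, stim_offset_s=t + 0.5,
                         utt_onset_s=t + 1.2, utt_offset_s=t + 1.7,
                         p1_onset_s=t + 1.2, p2_onset_s=t + 1.37,
                         p3_onset_s=t + 1.53, correct=True))
        t += spacing
    return pd.DataFrame(rows)[EVENT_COLUMNS], t


def _bundle(voltage, fs=2000.0, n_trials=10, impedance=None):
    ev, _ = _events(n_trials, fs=fs)
    n_ch = voltage.shape[0]
    geom = ms.make_array(1, n_ch, 1.0)
    return ms.RecordingBundle(voltage=voltage.astype(np.float32), fs=fs,
                              geometry=geom, events=ev,
                              impedance=impedance)


def _noise_bundle(n_ch=6, fs=2000.0, seed=0, impedance_kohm=20.0):
    ev, t_end = _events(fs=fs)
    n = int((t_end + 1.0) * fs)
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n_ch, n))
    return _bundle(v, fs=fs, impedance=np.full(n_ch, impedance_kohm))


class TestChannelQC:
    def test_homogeneous_channels_all_included(self):
        b = _noise_bundle()
        qc = ms.qc_channels(b)
        assert qc.n_included == b.n_channels and not qc.reason

    def test_high_impedance_channel_excluded(self):
        b = _noise_bundle()
        b.impedance[2] = 1500.0  # 1.5 MOhm
        qc = ms.qc_channels(b)
        assert not qc.included[2] and qc.reason[2] == "impedance"

    def test_rms_outlier_excluded(self):
        b = _noise_bundle()
        b.voltage[4] *= 1000.0
        qc = ms.qc_channels(b)
        assert not qc.included[4] and qc.reason[4] == "rms"
        assert qc.included.sum() == b.n_channels - 1

    def test_missing_impedance_warns_and_skips_rule(self):
        b = _noise_bundle()
        b.impedance = None
        with pytest.warns(UserWarning, match="impedance"):
            qc = ms.qc_channels(b)
        assert qc.n_included == b.n_channels


class TestCAR:
    def test_identical_channels_cancel_to_zero(self):
        b = _noise_bundle(n_ch=4)
        b.voltage[:] = b.voltage[0]
        out = ms.common_average_reference(b)
        assert np.abs(out).max() < 1e-4

    def test_included_mean_is_zero_at_every_sample(self):
        b = _noise_bundle()
        qc = ms.qc_channels(b)
        out = ms.common_average_reference(b, qc)
        assert np.abs(out[qc.included].mean(axis=0)).max() < 1e-4

    def test_excluded_artifact_channel_does_not_perturb_others(self):
        b = _noise_bundle()
        dirty = _bundle(b.voltage.copy(), impedance=b.impedance.copy())
        dirty.voltage[4] *= 1000.0  # artifact channel, excluded by QC
        out_clean = ms.common_average_reference(
            b, ms.ChannelQC(np.array([1, 1, 1, 1, 0, 1], dtype=bool)))
        out_dirty = ms.common_average_reference(dirty, ms.qc_channels(dirty))
        np.testing.assert_allclose(out_dirty[:4], out_clean[:4], atol=1e-3)

    def test_fewer_than_two_channels_is_an_error(self):
        b = _noise_bundle()
        qc = ms.ChannelQC(np.array([1, 0, 0, 0, 0, 0], dtype=bool))
        with pytest.raises(ProcessingError):
            ms.common_average_reference(b, qc)


class TestEpochRejection:
    def test_clean_trials_all_kept_and_mask_length(self):
        b = _noise_bundle()
        ref = ms.common_average_reference(b)
        keep = ms.reject_epochs(ref, b)
        assert keep.shape == (len(b.events),)
        assert keep.all()

    def test_injected_transient_rejects_exactly_that_trial(self):
        # The 10x criterion compares trial RMS with the whole-recording
        # RMS, which the artifact itself inflates; a transient can only
        # cross it when the recording is much longer than one trial, so
        # use a 150-trial session.
        ev, t_end = _events(n_trials=150)
        fs = 2000.0
        rng = np.random.default_rng(0)
        v = rng.standard_normal((4, int((t_end + 1.0) * fs)))
        b = _bundle(v, n_trials=150, impedance=np.full(4, 20.0))
        ref = ms.common_average_reference(b)
        tr = b.events.iloc[3]
        i0 = int(tr["utt_onset_s"] * fs)
        ref = ref.copy()
        ref[2, i0 : i0 + int(fs)] += 50.0 * ref[2].std()
        keep = ms.reject_epochs(ref, b)
        assert not keep[3]
        assert keep.sum() == len(b.events) - 1


class TestHGExtraction:
    def test_in_band_tone_with_doubled_response_amplitude(self):
        # 100 Hz tone: baseline amplitude A/2, response amplitude A
        # -> subtract-and-divide normalization reads +1.0 in the response
        ev, t_end = _events()
        fs = 2000.0
        n = int((t_end + 1.0) * fs)
        t = np.arange(n) / fs
        amp = np.full(n, 5.0)
        for _, r in ev.iterrows():
            amp[int(r["utt_onset_s"] * fs):int(r["utt_offset_s"] * fs)] = 10.0
        v = np.vstack([amp * np.sin(2 * np.pi * 100.0 * t)] * 2)
        b = _bundle(v)
        hg = ms.extract_hg(v.astype(np.float32), b, alignment="utterance",
                           window_s=(0.05, 0.45))
        assert abs(float(hg.values.mean()) - 1.0) < 0.1

    def test_out_of_band_tone_normalizes_to_zero(self):
        ev, t_end = _events()
        fs = 2000.0
        n = int((t_end + 1.0) * fs)
        t = np.arange(n) / fs
        v = np.vstack([5 * np.sin(2 * np.pi * 40.0 * t)] * 2)
        b = _bundle(v)
        hg = ms.extract_hg(v.astype(np.float32), b, alignment="utterance",
                           window_s=(-0.3, 0.3))
        assert float(np.abs(hg.values).max()) < 0.05

    def test_output_rate_and_window_arithmetic(self, hg_p1):
        hg, _ = hg_p1
        assert hg.fs_env == 200.0
        assert hg.values.shape[2] == 200  # 1 s window at 200 Hz

    def test_baseline_contract_mean_zero_per_electrode(self, session52):
        s = session52
        hg = ms.extract_hg(s["ref"], s["bundle"], alignment="stimulus",
                           window_s=(-0.5, 0.0))
        assert np.abs(hg.values.mean(axis=(0, 2))).max() < 1e-6

    def test_scale_invariance_of_normalized_envelope(self):
        b = _noise_bundle(n_ch=2)
        hg1 = ms.extract_hg(b.voltage, b, alignment="utterance",
                            window_s=(-0.3, 0.3))
        hg2 = ms.extract_hg(b.voltage * 37.0, b, alignment="utterance",
                            window_s=(-0.3, 0.3))
        np.testing.assert_allclose(hg1.values, hg2.values, atol=1e-6)

    def test_envelope_tracks_amplitude_modulation(self):
        fs = 2000.0
        n = int(60 * fs)
        t = np.arange(n) / fs
        env_true = 1.0 + 0.8 * np.sin(2 * np.pi * 1.5 * t)
        x = (env_true * np.sin(2 * np.pi * 100.0 * t))[None, :]
        e = hg_envelope(x.astype(np.float32), fs)
        env_ds = env_true[::10][: e.shape[1]]
        r = np.corrcoef(e[0][100:-100], env_ds[100:-100])[0, 1]
        assert r > 0.95


class TestLFS:
    def _tone_bundle(self, freq, fs=2000.0):
        ev, t_end = _events(fs=fs)
        n = int((t_end + 1.0) * fs)
        t = np.arange(n) / fs
        v = np.vstack([8 * np.sin(2 * np.pi * freq * t)] * 2)
        return _bundle(v, fs=fs), v

    def test_passband_amplitude_preserved(self):
        b, v = self._tone_bundle(10.0)
        lfs = ms.extract_lfs(v.astype(np.float32), b, alignment="utterance",
                             window_s=(-0.3, 0.3))
        assert abs(np.abs(lfs.values).max() - 8.0) < 0.4  # within 5%

    def test_stopband_attenuated_20db(self):
        b, v = self._tone_bundle(60.0)
        lfs = ms.extract_lfs(v.astype(np.float32), b, alignment="utterance",
                             window_s=(-0.3, 0.3))
        assert 20 * np.log10(8.0 / max(np.abs(lfs.values).max(), 1e-12)) >= 20

    def test_zero_phase_no_lag_on_10hz_component(self):
        b, v = self._tone_bundle(10.0)
        lfs = ms.extract_lfs(v.astype(np.float32), b, alignment="utterance",
                             window_s=(-0.25, 0.25))
        fs_env = lfs.fs_env
        t = lfs.times
        ref = 8 * np.sin(2 * np.pi * 10.0 * (t + b.events["utt_onset_s"][0]))
        xc = np.correlate(lfs.values[0, 0] - lfs.values[0, 0].mean(),
                          ref - ref.mean(), "full")
        lag = np.argmax(xc) - (len(ref) - 1)
        assert lag == 0


def test_tensor_hdf5_round_trip(tmp_path, hg_p1):
    hg, _ = hg_p1
    p = tmp_path / "t.h5"
    save_tensor(hg, p, name="hg")
    r = load_tensor(p, name="hg")
    np.testing.assert_allclose(r.values, hg.values, rtol=1e-6)
    assert r.alignment == hg.alignment and r.window_s == hg.window_s
    np.testing.assert_array_equal(r.trial_index, hg.trial_index)
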