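"""Spectrograms, ESNR conventions, permutation statistics, clusters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import microspeech as ms
from microspeech.bundle import EVENT_COLUMNS, ValidationError
from microspeech.preprocess import HGEnvelopeTensor
from microspeech.spectral import Spectrogram, temporal_cluster


def _white_bundle(n_ch=4, fs=2000.0, n_trials=12, seed=0):
    rows, t = [], 1.5
    for i in range(n_trials):
        rows.append(dict(trial_id=i, token="p a p", p1="p", p2="a", p3="p",
                         stim_onset_s=t, stim_offset_s=t + 0.5,
                         utt_onset_s=t + 1.2, utt_offset_s=t + 1.7,
                         p1_onset_s=t + 1.2, p2_onset_s=t + 1.37,
                         p3_onset_s=t + 1.53, correct=True))
        t += 2.6
    ev = pd.DataFrame(rows)[EVENT_COLUMNS]
    n = int((t + 1.0) * fs)
    rng = np.random.default_rng(seed)
    v = (10 * rng.standard_normal((n_ch, n))).astype(np.float32)
    geom = ms.make_array(1, n_ch, 1.0)
    return ms.RecordingBundle(voltage=v, fs=fs, geometry=geom, events=ev,
                              impedance=np.full(n_ch, 25.0))


def _flat_spect(value=1.0, n_elec=3):
    return Spectrogram(power=np.full((n_elec, 21, 41), value),
                       t=np.linspace(-1, 1, 21), f=np.linspace(0, 200, 41),
                       baseline_psd=np.ones((n_elec, 41)))


class TestSpectrogram:
    def test_stationary_noise_normalizes_to_unit_ratio(self):
        b = _white_bundle()
        sp = ms.multitaper_spectrogram(b.voltage, b, alignment="utterance",
                                       window_s=(-1.0, 1.0))
        assert abs(float(sp.power.mean()) - 1.0) < 0.05

    def test_time_step_is_50ms(self):
        b = _white_bundle()
        sp = ms.multitaper_spectrogram(b.voltage, b, alignment="utterance",
                                       window_s=(-1.0, 1.0))
        assert np.allclose(np.diff(sp.t), 0.05)

    def test_response_locked_tone_elevates_only_its_frequency(self):
        b = _white_bundle()
        fs = b.fs
        t = np.arange(b.voltage.shape[1]) / fs
        tone = np.zeros_like(t)
        for _, r in b.events.iterrows():
            sl = slice(int(r["utt_onset_s"] * fs), int(r["utt_offset_s"] * fs))
            tone[sl] = 1.0
        v = b.voltage.copy()
        v[0] += (40.0 * tone * np.sin(2 * np.pi * 100.0 * t)).astype(np.float32)
        sp = ms.multitaper_spectrogram(v, b, alignment="utterance",
                                       window_s=(-1.0, 1.0))
        f100 = np.argmin(np.abs(sp.f - 100.0))
        resp = (sp.t > 0.05) & (sp.t < 0.4)
        base = sp.t < -0.5
        assert sp.power[0, resp, f100].mean() > 3.0
        assert abs(sp.power[0, base, f100].mean() - 1.0) < 0.3

    def test_window_longer_than_epoch_rejected(self):
        b = _white_bundle()
        with pytest.raises(ValidationError):
            ms.multitaper_spectrogram(b.voltage, b, window_s=(-0.1, 0.1),
                                      analysis_window_s=0.5)


class TestESNR:
    def test_unit_ratio_gives_zero_db(self):
        assert np.allclose(ms.esnr(_flat_spect(1.0)).esnr_db, 0.0)

    def test_ratio_ten_gives_twenty_db(self):
        assert np.allclose(ms.esnr(_flat_spect(10.0)).esnr_db, 20.0)

    def test_ratio_two_gives_six_db(self):
        np.testing.assert_allclose(ms.esnr(_flat_spect(2.0)).esnr_db,
                                   20 * np.log10(2.0), rtol=1e-12)

    def test_scaling_response_power_shifts_esnr_additively(self):
        sp = _flat_spect(2.0)
        base = ms.esnr(sp).esnr_db.copy()
        sp.power *= 5.0
        np.testing.assert_allclose(ms.esnr(sp).esnr_db - base,
                                   20 * np.log10(5.0), rtol=1e-10)

    def test_sum_convention_depends_on_bin_count(self):
        db = ms.esnr(_flat_spect(1.0), convention="sum").esnr_db
        assert np.all(db > 0)  # literal bin-sum is nonzero for null data

    def test_missing_band_coverage_rejected(self):
        sp = Spectrogram(power=np.ones((2, 5, 4)), t=np.linspace(-1, 1, 5),
                         f=np.linspace(0, 40, 4), baseline_psd=np.ones((2, 4)))
        with pytest.raises(ValidationError):
            ms.esnr(sp)


def _null_tensor(n_trials=40, n_elec=20, n_t=50, seed=0, effect=0.0):
    rng = np.random.default_rng(seed)
    vals = rng.standard_normal((n_trials, n_elec, n_t))
    vals[:, : n_elec // 2] += effect  # optional planted electrodes
    hg = HGEnvelopeTensor(values=vals, fs_env=200.0, alignment="utterance",
                          window_s=(0.0, n_t / 200.0),
                          trial_index=np.arange(n_trials))
    baseline = rng.standard_normal((n_trials, n_elec))
    return hg, baseline


class TestPermutationTest:
    def test_p_value_lower_bound_is_one_over_n_plus_one(self):
        hg, base = _null_tensor(effect=5.0)
        p, _, _ = ms.significant_electrodes(hg, base, n_permutations=1000)
        assert np.isclose(p.min(), 1.0 / 1001.0)

    def test_null_p_values_are_uniform(self):
        hg, base = _null_tensor(n_trials=30, n_elec=200, seed=3)
        p, _, _ = ms.significant_electrodes(hg, base, n_permutations=500)
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_planted_effect_detected_null_controlled(self):
        hg, base = _null_tensor(n_trials=40, n_elec=40, seed=4, effect=1.5)
        _, _, mask = ms.significant_electrodes(hg, base, n_permutations=2000)
        assert mask[:20].all()          # all planted electrodes found
        assert mask[20:].mean() <= 0.1  # few false alarms after FDR


class TestTemporalCluster:
    def test_pre_onset_rise_recovered(self):
        rng = np.random.default_rng(0)
        n_tr, n_t = 40, 200  # [-0.5, 0.5] s at 200 Hz
        t = -0.5 + np.arange(n_t) / 200.0
        sig = np.clip((t + 0.3) / 0.3, 0, 1)  # rises from -300 ms
        vals = rng.standard_normal((n_tr, 2, n_t)) * 0.5
        vals[:, 0] += 2.0 * sig
        hg = HGEnvelopeTensor(values=vals, fs_env=200.0, alignment="utterance",
                              window_s=(-0.5, 0.5), trial_index=np.arange(n_tr))
        base = np.zeros((n_tr, 2))
        clusters = temporal_cluster(hg, base, n_permutations=300, seed=0)
        assert clusters[0], "no cluster found on the planted electrode"
        onset = clusters[0][0][0]
        assert -0.35 < onset < -0.2
        durations = [c[1] for c in clusters[0]]
        assert max(durations) <= 1.0  # never exceeds the window

    def test_null_electrode_has_no_clusters(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((40, 3, 100))
        hg = HGEnvelopeTensor(values=vals, fs_env=200.0, alignment="utterance",
                              window_s=(-0.25, 0.25), trial_index=np.arange(40))
        clusters = temporal_cluster(hg, np.zeros((40, 3)),
                                    n_permutations=300, seed=1)
        assert sum(len(c) for c in clusters) == 0


class TestCorrVsDistance:
    def test_duplicated_channel_has_unit_correlation(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((30, 2, 100))
        vals[:, 1] = vals[:, 0]  # duplicate
        hg = HGEnvelopeTensor(values=vals, fs_env=200.0, alignment="utterance",
                              window_s=(-0.25, 0.25), trial_index=np.arange(30))
        geom = ms.make_array(1, 2, 1.0)
        d, r, _ = ms.corr_vs_distance(hg, geom)
        assert np.isclose(r[d == 1.0].max(), 1.0)

    def test_independent_envelopes_are_uncorrelated(self):
        rng = np.random.default_rng(2)
        vals = rng.standard_normal((50, 32, 100))
        hg = HGEnvelopeTensor(values=vals, fs_env=200.0, alignment="utterance",
                              window_s=(-0.25, 0.25), trial_index=np.arange(50))
        geom = ms.make_array(4, 8, 1.33)
        d, r, _ = ms.corr_vs_distance(hg, geom)
        assert np.abs(r).max() < 0.05

    def test_constant_channel_skipped_with_warning(self):
        rng = np.random.default_rng(3)
        vals = rng.standard_normal((20, 3, 50))
        vals[:, 2] = 1.0
        hg = HGEnvelopeTensor(values=vals, fs_env=200.0, alignment="utterance",
                              window_s=(0, 0.25), trial_index=np.arange(20))
        with pytest.warns(UserWarning, match="constant"):
            d, r, _ = ms.corr_vs_distance(hg, ms.make_array(1, 3, 1.0))


def test_mann_whitney_matches_hand_computed_u():
    # 5-vs-5 toy: x = {1,2,3,4,5}, y = {3,4,5,6,7}; U(x<y) by hand:
    # pairs with x<y: count = 19, ties = 3 -> U_x = 19 + 3/2 = 20.5
    x = [1, 2, 3, 4, 5]
    y = [3, 4, 5, 6, 7]
    res = stats.mannwhitneyu(y, x, alternative="greater")
    u_hand = sum((yy > xx) + 0.5 * (yy == xx) for xx in x for yy in y)
    assert res.statistic == u_hand == 20.5
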