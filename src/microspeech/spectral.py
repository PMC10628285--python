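"""Trial-averaged spectrograms, evoked SNR, and electrode-level statistics.

The evoked signal-to-noise ratio (ESNR) summarizes the high-gamma power
change around utterance onset relative to the pre-stimulus baseline, in
decibels.  By default the baseline-normalized power ratio is averaged over
the analysis window and band before the log (so a flat ratio of 1 gives
exactly 0 dB); a literal bin-sum convention is available via
``convention="sum"`` for comparability with formulations that accumulate
over time-frequency bins.

Also here: response-vs-baseline permutation tests with BH-FDR across
electrodes, second-level temporal cluster statistics, envelope
correlation versus electrode distance, and the audio-neural
acoustic-contamination audit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .bundle import ArrayGeometry, RecordingBundle, ValidationError
from .preprocess import HGEnvelopeTensor

__all__ = [
    "Spectrogram", "ESNRTable", "ContaminationMatrix",
    "multitaper_spectrogram", "esnr", "significant_electrodes",
    "temporal_cluster", "corr_vs_distance", "contamination",
]


@dataclass
class Spectrogram:
    """Baseline-normalized trial-averaged power: electrodes x time x freq."""

    power: np.ndarray          # ratio to baseline PSD, > 0
    t: np.ndarray              # bin centres, s relative to alignment
    f: np.ndarray              # Hz
    baseline_psd: np.ndarray   # electrodes x freq


@dataclass
class ESNRTable:
    esnr_db: np.ndarray
    band: tuple = (70.0, 150.0)
    window: tuple = (-0.5, 0.5)


@dataclass
class ContaminationMatrix:
    corr: np.ndarray       # electrodes x audio-bins x neural-bins
    f: np.ndarray          # Hz per bin (shared axis)
    diag_stat: np.ndarray  # mean diagonal on 70-150 Hz, per electrode
    p: np.ndarray
    p_fdr: np.ndarray


def _epoch_raw(referenced, fs, times, window_s):
    n_win = int(round((window_s[1] - window_s[0]) * fs))
    rows = []
    for t0 in times:
        i0 = int(round((t0 + window_s[0]) * fs))
        if i0 < 0 or i0 + n_win > referenced.shape[1]:
            continue
        rows.append(referenced[:, i0 : i0 + n_win])
    return np.stack(rows, axis=0)  # trials x channels x samples


def multitaper_spectrogram(
    referenced: np.ndarray,
    bundle: RecordingBundle,
    alignment: str = "utterance",
    window_s: tuple = (-1.0, 1.0),
    analysis_window_s: float = 0.5,
    step_s: float = 0.05,
    freq_smoothing_hz: float = 10.0,
    baseline_s: float = 0.5,
    max_freq_hz: float = 200.0,
) -> Spectrogram:
    """Multitaper PSD in sliding windows, baseline-normalized per electrode.

    A ``freq_smoothing_hz`` total smoothing bandwidth (±half-bandwidth)
    sets the time-bandwidth product ``NW = analysis_window * W/2`` with
    ``2*NW - 1`` DPSS tapers.  Each electrode/frequency is divided by its
    average baseline PSD (500 ms pre-stimulus pooled over trials), then
    ratios are averaged across trials.
    """
    fs = bundle.fs
    if fs < 2 * max_freq_hz:
        max_freq_hz = fs / 2.0
    col = {"utterance": "utt_onset_s", "stimulus": "stim_onset_s",
           "p1": "p1_onset_s", "p2": "p2_onset_s", "p3": "p3_onset_s"}[alignment]
    if window_s[1] - window_s[0] < analysis_window_s:
        raise ValidationError("analysis window longer than trial epoch")
    nper = int(round(analysis_window_s * fs))
    nw = analysis_window_s * freq_smoothing_hz / 2.0
    n_tapers = max(1, int(2 * nw - 1))
    tapers = signal.windows.dpss(nper, nw, n_tapers)

    def _mt_psd(seg):
        # seg: ... x nper -> ... x nfreq, average over tapers
        tap = seg[..., None, :] * tapers  # ... x K x nper
        spec = np.fft.rfft(tap, axis=-1)
        return (np.abs(spec) ** 2).mean(axis=-2) / (fs * nper)

    f = np.fft.rfftfreq(nper, 1.0 / fs)
    fsel = f <= max_freq_hz
    f = f[fsel]

    epochs = _epoch_raw(referenced, fs, bundle.events[col].to_numpy(), window_s)
    step = int(round(step_s * fs))
    starts = np.arange(0, epochs.shape[2] - nper + 1, step)
    t_centers = window_s[0] + (starts + nper / 2) / fs

    # baseline PSD: pre-stimulus windows per trial, pooled and averaged
    if baseline_s < analysis_window_s:
        raise ValidationError("baseline must be at least one analysis window long")
    base = _epoch_raw(referenced, fs, bundle.events["stim_onset_s"].to_numpy(),
                      (-baseline_s, 0.0))
    segs = [_mt_psd(base[..., s0:s0 + nper])
            for s0 in range(0, base.shape[2] - nper + 1, max(1, nper // 2))]
    base_psd = np.mean(segs, axis=0).mean(axis=0)[:, fsel]  # electrodes x freq

    ratios = np.zeros((epochs.shape[1], len(starts), fsel.sum()))
    for k, s0 in enumerate(starts):
        psd = _mt_psd(epochs[..., s0:s0 + nper])[..., fsel]  # trials x ch x f
        ratios[:, k, :] = (psd / (base_psd[None] + 1e-300)).mean(axis=0)
    return Spectrogram(power=ratios, t=t_centers, f=f, baseline_psd=base_psd)


def esnr(
    spect: Spectrogram,
    band: tuple = (70.0, 150.0),
    window: tuple = (-0.5, 0.5),
    convention: str = "mean",
    log_scale: float = 20.0,
) -> ESNRTable:
    """Evoked SNR in dB per electrode from a normalized spectrogram.

    ``convention='mean'`` averages the power ratio over the in-band,
    in-window bins before the log; ``'sum'`` accumulates them (bin-count
    dependent).  ``log_scale`` is the dB multiplier on log10.
    """
    tsel = (spect.t >= window[0]) & (spect.t <= window[1])
    fsel = (spect.f >= band[0]) & (spect.f <= band[1])
    if not tsel.any() or not fsel.any():
        raise ValidationError("spectrogram does not cover the requested band/window")
    block = spect.power[:, tsel][:, :, fsel]
    agg = block.sum(axis=(1, 2)) if convention == "sum" else block.mean(axis=(1, 2))
    return ESNRTable(esnr_db=log_scale * np.log10(agg + 1e-300),
                     band=tuple(band), window=tuple(window))


# ---------------------------------------------------------------------------
# Permutation statistics


def _bh_fdr(p: np.ndarray, alpha: float = 0.05):
    """Benjamini-Hochberg: adjusted p-values and rejection mask."""
    p = np.asarray(p, dtype=float)
    q = stats.false_discovery_control(p, method="bh")
    return q, q <= alpha


def significant_electrodes(
    hg: HGEnvelopeTensor,
    baseline: np.ndarray,
    n_permutations: int = 10000,
    alpha: float = 0.05,
    response_window: tuple | None = None,
    seed: int = 0,
):
    """One-sided response-vs-baseline permutation test per electrode.

    ``baseline`` is trials x electrodes (mean normalized HG in the
    per-trial baseline window).  The observed statistic is the mean over
    trials of (mean response - baseline); the null swaps response and
    baseline labels within trial (sign flips of the per-trial difference).
    Returns (p, p_fdr, mask).
    """
    vals = hg.values
    if response_window is not None:
        tsel = (hg.times >= response_window[0]) & (hg.times < response_window[1])
        vals = vals[:, :, tsel]
    resp = vals.mean(axis=2)                       # trials x electrodes
    diff = resp - np.asarray(baseline)             # trials x electrodes
    n_tr = diff.shape[0]
    if n_tr < 10:
        warnings.warn("fewer than 10 trials; permutation null is coarse")
    obs = diff.mean(axis=0)
    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_permutations, n_tr))
    null = (flips @ diff) / n_tr                   # perms x electrodes
    p = (1.0 + (null >= obs[None, :]).sum(axis=0)) / (n_permutations + 1.0)
    p_fdr, mask = _bh_fdr(p, alpha)
    return p, p_fdr, mask


def temporal_cluster(
    hg: HGEnvelopeTensor,
    baseline: np.ndarray,
    n_permutations: int = 2000,
    alpha: float = 0.05,
    threshold_z: float = 1.645,
    seed: int = 0,
):
    """Second-level cluster test on the per-timepoint response statistic.

    Per electrode and timepoint, a one-sample t-like z of the per-trial
    difference from baseline is thresholded; contiguous supra-threshold
    runs are scored by their summed statistic and compared with the
    max-cluster-mass null from trial sign flips (shared across time to
    preserve autocorrelation).  Returns a list per electrode of
    ``(onset_s, duration_s, mass, p)`` for significant clusters.
    """
    d = hg.values - np.asarray(baseline)[:, :, None]  # trials x elec x time
    n_tr = d.shape[0]

    def _zstat(x):
        return x.mean(axis=0) / (x.std(axis=0, ddof=1) / np.sqrt(n_tr) + 1e-30)

    obs_z = _zstat(d)                                 # elec x time
    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_permutations, n_tr))
    null_max = np.zeros((n_permutations, d.shape[1]))
    for b in range(n_permutations):
        z = _zstat(d * flips[b][:, None, None])
        null_max[b] = _max_cluster_mass(z, threshold_z)
    times = hg.times
    dt = 1.0 / hg.fs_env
    results = []
    for e in range(d.shape[1]):
        clusters = []
        for i0, i1, mass in _clusters(obs_z[e], threshold_z):
            p = (1.0 + (null_max[:, e] >= mass).sum()) / (n_permutations + 1.0)
            if p <= alpha:
                clusters.append((times[i0], (i1 - i0) * dt, mass, p))
        results.append(clusters)
    return results


def _clusters(z: np.ndarray, thr: float):
    above = z > thr
    out = []
    i = 0
    while i < len(z):
        if above[i]:
            j = i
            while j < len(z) and above[j]:
                j += 1
            out.append((i, j, float(z[i:j].sum())))
            i = j
        else:
            i += 1
    return out


def _max_cluster_mass(z: np.ndarray, thr: float) -> np.ndarray:
    out = np.zeros(z.shape[0])
    for e in range(z.shape[0]):
        cl = _clusters(z[e], thr)
        out[e] = max((m for *_, m in cl), default=0.0)
    return out


def corr_vs_distance(
    hg: HGEnvelopeTensor,
    geometry: ArrayGeometry,
    decimals: int = 2,
):
    """Mean pairwise Pearson r of the envelope per unique electrode distance.

    Envelopes are concatenated across trials (response window as epoched);
    pairs are grouped by Euclidean distance rounded to ``decimals``.
    Returns (distances_mm, mean_r, sem_r).
    """
    x = np.transpose(hg.values, (1, 0, 2)).reshape(hg.n_electrodes, -1)
    sd = x.std(axis=1)
    good = sd > 0
    if (~good).any():
        warnings.warn(f"{(~good).sum()} constant channels skipped")
    coords = geometry.coords_mm
    r = np.corrcoef(x[good])
    d = np.linalg.norm(coords[good][:, None] - coords[good][None, :], axis=-1)
    iu = np.triu_indices(good.sum(), k=1)
    dist = np.round(d[iu], decimals)
    rv = r[iu]
    uniq = np.unique(dist)
    mean_r = np.array([rv[dist == u].mean() for u in uniq])
    sem_r = np.array([rv[dist == u].std(ddof=1) / np.sqrt(max((dist == u).sum(), 2) - 1)
                      if (dist == u).sum() > 1 else 0.0 for u in uniq])
    return uniq, mean_r, sem_r


# ---------------------------------------------------------------------------
# Acoustic contamination


def _spectral_envelopes(x: np.ndarray, fs: float, window_s: float = 0.2,
                        max_freq_hz: float = 500.0):
    """Short-time power per frequency bin (Hamming window), bins x frames."""
    nper = int(round(window_s * fs))
    f, t, Z = signal.stft(x, fs=fs, window="hamming", nperseg=nper,
                          noverlap=nper // 2, boundary=None, padded=False)
    sel = f <= max_freq_hz
    return f[sel], np.abs(Z[..., sel, :]) ** 2


def contamination(
    bundle: RecordingBundle,
    n_shuffles: int = 10000,
    alpha: float = 0.05,
    band: tuple = (70.0, 150.0),
    window_s: float = 0.2,
    seed: int = 0,
) -> ContaminationMatrix:
    """Audio-neural spectro-temporal correlation audit per electrode.

    Short-time power envelopes (200 ms Hamming windows) are computed per
    frequency bin for the microphone track and every neural channel; the
    contamination matrix correlates every audio bin with every neural bin
    over time.  The statistic is the mean diagonal restricted to the HG
    band; its null distribution comes from shuffling the neural frequency
    bins of the matrix (``n_shuffles`` draws).  p-values are BH-FDR
    corrected across electrodes.
    """
    if bundle.audio is None:
        raise ValidationError("bundle has no audio track")
    fs = bundle.fs
    audio = np.asarray(bundle.audio, dtype=np.float64)
    if bundle.fs_audio != fs:
        audio = signal.resample_poly(audio, int(fs), int(bundle.fs_audio))
        audio = audio[: bundle.voltage.shape[1]]
    f, a_env = _spectral_envelopes(audio, fs, window_s)
    _, n_env = _spectral_envelopes(bundle.voltage.astype(np.float64), fs, window_s)
    n_frames = min(a_env.shape[-1], n_env.shape[-1])
    a_env, n_env = a_env[..., :n_frames], n_env[..., :n_frames]

    def _standardize(e):
        mu = e.mean(axis=-1, keepdims=True)
        sd = e.std(axis=-1, keepdims=True)
        return (e - mu) / (sd + 1e-30)

    az = _standardize(a_env)                      # fbins x frames
    nz = _standardize(n_env)                      # elec x fbins x frames
    corr = np.einsum("ft,egt->efg", az, nz) / n_frames  # elec x audio-f x neural-f
    corr = np.clip(corr, -1.0, 1.0)

    dband = np.nonzero((f >= band[0]) & (f <= band[1]))[0]
    diag_stat = corr[:, dband, dband].mean(axis=1)

    # null: permute the neural frequency bins within the band, so smooth
    # neuro-behavioural comodulation (shared slow envelopes) cancels and
    # only bin-exact correlation structure -- the leakage signature --
    # exceeds the shuffled diagonals
    rng = np.random.default_rng(seed)
    sub = corr[:, dband][:, :, dband]            # elec x band x band
    null = np.zeros((n_shuffles, corr.shape[0]))
    m = len(dband)
    perms = np.argsort(rng.random((n_shuffles, m)), axis=1)
    for s in range(n_shuffles):
        null[s] = sub[:, np.arange(m), perms[s]].mean(axis=1)
    p = (1.0 + (null >= diag_stat[None, :]).sum(axis=0)) / (n_shuffles + 1.0)
    p_fdr, _ = _bh_fdr(p, alpha)
    return ContaminationMatrix(corr=corr, f=f, diag_stat=diag_stat, p=p, p_fdr=p_fdr)
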