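"""Channel QC, referencing, artifact rejection, and feature extraction.

High-gamma (HG, 70-150 Hz) envelopes are the workhorse feature: each
channel is band-passed into 8 logarithmically spaced sub-bands, the
analytic-signal magnitude of each sub-band is averaged, the result is
anti-alias decimated to 200 Hz and normalized against the mean over the
500 ms pre-stimulus baseline across trials (per electrode,
subtract-and-divide, so values read as fractional change and are
gain-invariant).  Low-frequency signals (LFS, 1-30 Hz) keep their µV
scale and are baseline mean-subtracted only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .bundle import RecordingBundle, ValidationError

__all__ = [
    "ChannelQC", "HGEnvelopeTensor", "ProcessingError",
    "qc_channels", "common_average_reference", "reject_epochs",
    "hg_band_layout", "hg_envelope", "extract_hg", "extract_lfs",
    "save_tensor", "load_tensor",
]

_ALIGNMENT_COLS = {
    "utterance": "utt_onset_s",
    "stimulus": "stim_onset_s",
    "p1": "p1_onset_s",
    "p2": "p2_onset_s",
    "p3": "p3_onset_s",
}


class ProcessingError(RuntimeError):
    pass


@dataclass(frozen=True)
class ChannelQC:
    """Per-channel inclusion flags with exclusion reason codes."""

    included: np.ndarray           # bool per channel
    reason: dict = field(default_factory=dict)  # channel -> "impedance" | "rms"

    @property
    def n_included(self) -> int:
        return int(self.included.sum())


def qc_channels(
    bundle: RecordingBundle,
    impedance_max_kohm: float = 1000.0,
    log_rms_mad_factor: float = 3.0,
) -> ChannelQC:
    """Flag channels unusable for referencing and analysis.

    A channel is excluded when its impedance exceeds 1 MOhm, or when its
    log10 RMS deviates from the median log10 RMS across channels by more
    than ``log_rms_mad_factor`` median absolute deviations (robust,
    scale-free outlier criterion).  Deterministic; computed on the whole
    recording.
    """
    v = bundle.voltage
    included = np.ones(v.shape[0], dtype=bool)
    reason: dict[int, str] = {}
    if bundle.impedance is not None:
        for ch in np.nonzero(bundle.impedance > impedance_max_kohm)[0]:
            included[ch] = False
            reason[int(ch)] = "impedance"
    else:
        warnings.warn("no impedance data; impedance rule skipped")
    log_rms = np.log10(np.sqrt(np.mean(v.astype(np.float64) ** 2, axis=1)) + 1e-30)
    med = np.median(log_rms)
    mad = np.median(np.abs(log_rms - med))
    if mad > 0:
        for ch in np.nonzero(np.abs(log_rms - med) > log_rms_mad_factor * mad)[0]:
            if included[ch]:
                included[ch] = False
                reason[int(ch)] = "rms"
    return ChannelQC(included=included, reason=reason)


def common_average_reference(
    bundle: RecordingBundle, qc: ChannelQC | None = None
) -> np.ndarray:
    """Subtract the mean of included channels from every channel.

    Returns the referenced voltage array (channels x samples).  The mean
    of the included output channels is zero at every sample by
    construction; excluded channels are referenced too but do not
    contribute to the reference signal.
    """
    if qc is None:
        qc = qc_channels(bundle)
    if qc.n_included < 2:
        raise ProcessingError("common average reference needs >= 2 included channels")
    v = bundle.voltage.astype(np.float64)
    car = v[qc.included].mean(axis=0)
    return (v - car[None, :]).astype(np.float32)


def reject_epochs(
    referenced: np.ndarray,
    bundle: RecordingBundle,
    qc: ChannelQC | None = None,
    rms_factor: float = 10.0,
    pre_s: float = 0.5,
    post_s: float = 0.5,
) -> np.ndarray:
    """Boolean keep-mask over trials (True = keep).

    A trial is rejected when any included channel's RMS inside the trial
    window (baseline start to utterance offset + ``post_s``) exceeds
    ``rms_factor`` times that channel's whole-recording RMS.
    """
    if qc is None:
        qc = ChannelQC(np.ones(referenced.shape[0], dtype=bool))
    fs = bundle.fs
    ref_rms = np.sqrt(np.mean(referenced[qc.included].astype(np.float64) ** 2, axis=1))
    keep = np.ones(len(bundle.events), dtype=bool)
    for i, (_, tr) in enumerate(bundle.events.iterrows()):
        i0 = max(0, int((tr["stim_onset_s"] - pre_s) * fs))
        i1 = min(referenced.shape[1], int((tr["utt_offset_s"] + post_s) * fs))
        seg = referenced[qc.included, i0:i1].astype(np.float64)
        seg_rms = np.sqrt(np.mean(seg ** 2, axis=1))
        if np.any(seg_rms > rms_factor * ref_rms):
            keep[i] = False
    return keep


# ---------------------------------------------------------------------------
# HG / LFS feature extraction


def hg_band_layout(lo: float = 70.0, hi: float = 150.0, n_bands: int = 8):
    """Sub-band edges: centres log-spaced on [lo, hi], geometric widths.

    Adjacent bands touch at the geometric midpoints, so bandwidth grows
    proportionally to centre frequency.
    """
    centers = np.geomspace(lo, hi, n_bands)
    q = (hi / lo) ** (1.0 / (2 * (n_bands - 1)))
    return [(c / q, c * q) for c in centers]


def _band_response(f: np.ndarray, lo: float, hi: float, trans_frac: float = 0.15):
    """Zero-phase band-pass magnitude response with raised-cosine edges."""
    w_lo, w_hi = trans_frac * lo, trans_frac * hi
    h = np.zeros_like(f)
    h[(f >= lo) & (f <= hi)] = 1.0
    rise = (f >= lo - w_lo) & (f < lo)
    h[rise] = 0.5 * (1 - np.cos(np.pi * (f[rise] - (lo - w_lo)) / w_lo))
    fall = (f > hi) & (f <= hi + w_hi)
    h[fall] = 0.5 * (1 + np.cos(np.pi * (f[fall] - hi) / w_hi))
    return h


def hg_envelope(
    referenced: np.ndarray,
    fs: float,
    band: tuple = (70.0, 150.0),
    n_bands: int = 8,
    fs_env: float = 200.0,
) -> np.ndarray:
    """Continuous HG envelope per channel, decimated to ``fs_env``.

    Per sub-band the analytic signal is obtained in the frequency domain
    (zero-phase band-pass response applied to the one-sided spectrum), its
    magnitude taken, and magnitudes averaged across the 8 sub-bands before
    polyphase anti-alias decimation.
    """
    from scipy import fft as sfft

    if fs < 2 * band[1] * 0.999:
        raise ValidationError(f"fs={fs} too low for band {band}")
    n = referenced.shape[1]
    nfft = sfft.next_fast_len(n)
    f = np.fft.rfftfreq(nfft, 1.0 / fs)
    responses = [_band_response(f, lo, hi) for lo, hi in hg_band_layout(*band, n_bands)]
    up, down = (np.array([fs_env, fs]) / np.gcd(int(fs_env), int(fs))).astype(int)
    out = []
    for c0 in range(0, referenced.shape[0], 8):  # chunk channels to bound memory
        block = referenced[c0 : c0 + 8].astype(np.float64)
        spec = sfft.rfft(block, n=nfft, axis=1)
        env = np.zeros_like(block)
        full = np.zeros((block.shape[0], nfft), dtype=np.complex128)
        for h in responses:
            # analytic signal: one-sided spectrum doubled, inverse complex FFT
            full[:] = 0.0
            full[:, : len(f)] = spec * h[None, :]
            full[:, 1 : (nfft + 1) // 2] *= 2.0
            env += np.abs(sfft.ifft(full, axis=1)[:, :n])
        env /= n_bands
        out.append(signal.resample_poly(env, up, down, axis=1))
    return np.concatenate(out, axis=0)


@dataclass
class HGEnvelopeTensor:
    """Baseline-normalized envelope epochs: trials x electrodes x time.

    ``values[i, e, k]`` is the normalized envelope of trial ``i`` at
    electrode ``e`` and time ``window_s[0] + k / fs_env`` relative to the
    alignment event.  ``trial_index`` maps rows back to event-table rows;
    ``baseline_mean`` is the per-electrode raw baseline level used for
    normalization.
    """

    values: np.ndarray
    fs_env: float
    alignment: str
    window_s: tuple
    trial_index: np.ndarray
    baseline_mean: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        n = self.values.shape[2]
        return self.window_s[0] + np.arange(n) / self.fs_env

    def flatten_trials(self) -> np.ndarray:
        """Trials x (electrodes * time) design matrix."""
        return self.values.reshape(self.n_trials, -1)

    def select_electrodes(self, idx) -> "HGEnvelopeTensor":
        return HGEnvelopeTensor(self.values[:, idx, :], self.fs_env,
                                self.alignment, self.window_s,
                                self.trial_index,
                                None if self.baseline_mean is None
                                else self.baseline_mean[idx])


def _epoch(env, fs_env, times, window_s):
    n_win = int(round((window_s[1] - window_s[0]) * fs_env))
    rows, kept = [], []
    for i, t0 in enumerate(times):
        start = t0 + window_s[0]
        i0 = int(round(start * fs_env))
        if i0 < 0 or i0 + n_win > env.shape[1]:
            warnings.warn(f"trial {i}: window exceeds recording; excluded")
            continue
        rows.append(env[:, i0 : i0 + n_win])
        kept.append(i)
    if not rows:
        raise ProcessingError("no trial window fits inside the recording")
    return np.stack(rows, axis=0), np.asarray(kept)


def _baseline_mean(env, fs_env, stim_onsets, baseline_s):
    vals = []
    for t0 in stim_onsets:
        i0 = int(round((t0 - baseline_s) * fs_env))
        i1 = int(round(t0 * fs_env))
        if i0 >= 0 and i1 <= env.shape[1] and i1 > i0:
            vals.append(env[:, i0:i1])
    if not vals:
        raise ProcessingError("no baseline window fits inside the recording")
    return np.concatenate(vals, axis=1).mean(axis=1)


def extract_hg(
    referenced: np.ndarray,
    bundle: RecordingBundle,
    alignment: str = "p1",
    window_s: tuple = (-0.5, 0.5),
    band: tuple = (70.0, 150.0),
    n_bands: int = 8,
    fs_env: float = 200.0,
    baseline_s: float = 0.5,
    trial_mask: np.ndarray | None = None,
) -> HGEnvelopeTensor:
    """Epoch the normalized HG envelope around an alignment event.

    ``alignment`` is one of ``utterance``, ``stimulus``, ``p1``, ``p2``,
    ``p3``.  Normalization is (x - mu) / mu with mu the per-electrode mean
    envelope over the 500 ms pre-stimulus baseline pooled across trials.
    """
    if alignment not in _ALIGNMENT_COLS:
        raise ValidationError(f"unknown alignment '{alignment}'")
    env = hg_envelope(referenced, bundle.fs, band, n_bands, fs_env)
    events = bundle.events
    if trial_mask is not None:
        events = events[np.asarray(trial_mask, dtype=bool)].reset_index(drop=True)
    mu = _baseline_mean(env, fs_env, events["stim_onset_s"].to_numpy(), baseline_s)
    norm = (env - mu[:, None]) / (mu[:, None] + 1e-30)
    values, kept = _epoch(norm, fs_env, events[_ALIGNMENT_COLS[alignment]].to_numpy(),
                          window_s)
    return HGEnvelopeTensor(values=values, fs_env=fs_env, alignment=alignment,
                            window_s=tuple(window_s), trial_index=kept,
                            baseline_mean=mu)


def extract_lfs(
    referenced: np.ndarray,
    bundle: RecordingBundle,
    alignment: str = "p1",
    window_s: tuple = (-0.5, 0.5),
    band: tuple = (1.0, 30.0),
    fs_env: float = 200.0,
    baseline_s: float = 0.5,
    trial_mask: np.ndarray | None = None,
) -> HGEnvelopeTensor:
    """Epoch the low-frequency signal (1-30 Hz, µV) around an event.

    Zero-phase FIR band-pass (two-way filtering), polyphase decimation to
    200 Hz, baseline mean subtracted per electrode (values stay in µV).
    """
    if alignment not in _ALIGNMENT_COLS:
        raise ValidationError(f"unknown alignment '{alignment}'")
    fs = bundle.fs
    numtaps = int(3 * fs / band[0]) | 1
    taps = signal.firwin(numtaps, band, fs=fs, pass_zero=False)
    lfs = signal.filtfilt(taps, [1.0], referenced.astype(np.float64), axis=1)
    up, down = (np.array([fs_env, fs]) / np.gcd(int(fs_env), int(fs))).astype(int)
    lfs = signal.resample_poly(lfs, up, down, axis=1)
    events = bundle.events
    if trial_mask is not None:
        events = events[np.asarray(trial_mask, dtype=bool)].reset_index(drop=True)
    mu = _baseline_mean(lfs, fs_env, events["stim_onset_s"].to_numpy(), baseline_s)
    norm = lfs - mu[:, None]
    values, kept = _epoch(norm, fs_env, events[_ALIGNMENT_COLS[alignment]].to_numpy(),
                          window_s)
    return HGEnvelopeTensor(values=values, fs_env=fs_env, alignment=alignment,
                            window_s=tuple(window_s), trial_index=kept,
                            baseline_mean=mu)


def save_tensor(tensor: HGEnvelopeTensor, path, name: str = "hg") -> None:
    """Store an epoch tensor as an HDF5 dataset with alignment metadata."""
    import h5py

    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        g = f.create_group(name)
        d = g.create_dataset("values", data=tensor.values.astype(np.float32))
        d.attrs["fs_env"] = tensor.fs_env
        d.attrs["alignment"] = tensor.alignment
        d.attrs["window_s"] = tensor.window_s
        g.create_dataset("trial_index", data=tensor.trial_index)
        if tensor.baseline_mean is not None:
            g.create_dataset("baseline_mean", data=tensor.baseline_mean)


def load_tensor(path, name: str = "hg") -> HGEnvelopeTensor:
    import h5py

    with h5py.File(path, "r") as f:
        g = f[name]
        d = g["values"]
        return HGEnvelopeTensor(
            values=d[()], fs_env=float(d.attrs["fs_env"]),
            alignment=str(d.attrs["alignment"]),
            window_s=tuple(d.attrs["window_s"]),
            trial_index=g["trial_index"][()],
            baseline_mean=g["baseline_mean"][()] if "baseline_mean" in g else None,
        )
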