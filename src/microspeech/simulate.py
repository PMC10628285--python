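"""Synthetic µECoG speech-task recordings with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage of the pipeline can be exercised and validated
without patient data:

* the 52-token non-word repetition task (26 CVC + 26 VCV over 9 phonemes,
  trials of 3.5-4.5 s, ~0.5 s auditory stimulus, 0.7-1.5 s response
  latency, 0.3-0.7 s utterances, 250 ms inter-trial jitter, three blocks
  of the same shuffled tokens);
* rectangular micro-electrode lattices (8 x 16 at 1.33 mm, 12 x 22 at
  1.72 mm with corner masking down to 256 wired channels);
* trial-locked high-gamma bursts: amplitude-modulated 70-150 Hz narrowband
  carriers whose spatial profile is a millimetre-scale Gaussian around an
  articulator-specific source and whose temporal envelope leads utterance
  onset, with per-position timing so phoneme order is recoverable;
* spatially correlated 1/f background noise plus a common-mode component;
* a synthetic microphone track and optional audio leakage into the neural
  channels for contamination audits.

Each phoneme is a sub-source slightly offset from its articulator centre
with its own gain, which is what makes the 9-way phoneme decoding problem
solvable while preserving articulator-level spatial clustering.

All randomness flows from one integer seed through
``numpy.random.SeedSequence`` child streams (task, carriers, background,
audio), so identical seeds give identical bundles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .bundle import (ArrayGeometry, RecordingBundle, ValidationError,
                     EVENT_COLUMNS, make_array)

__all__ = [
    "VOWELS", "CONSONANTS", "ARTICULATORS", "PHONEME_ARTICULATOR",
    "TaskSpec", "GroundTruth",
    "make_task", "make_array", "synthesize_recording", "inject_contamination",
    "simulate_bundle",
]

VOWELS = ("a", "ae", "i", "u")
CONSONANTS = ("b", "p", "v", "g", "k")

#: Phoneme -> articulator class (vocal-tract effector grouping).
PHONEME_ARTICULATOR = {
    "a": "low", "ae": "low",
    "i": "high", "u": "high",
    "b": "labial", "p": "labial", "v": "labial",
    "g": "dorsal", "k": "dorsal",
}
ARTICULATORS = ("low", "high", "labial", "dorsal")

_PHONEMES = VOWELS + CONSONANTS


class ConfigurationError(ValueError):
    """Task specification cannot produce the requested token inventory."""


@dataclass(frozen=True)
class TaskSpec:
    """Speech repetition task parameters (defaults = the study conditions)."""

    vowels: tuple = VOWELS
    consonants: tuple = CONSONANTS
    n_cvc: int = 26
    n_vcv: int = 26
    n_blocks: int = 3
    trial_duration_s: tuple = (3.5, 4.5)
    stim_duration_s: float = 0.5
    jitter_s: float = 0.25
    response_latency_s: tuple = (0.7, 1.5)
    utterance_duration_s: tuple = (0.3, 0.7)

    @property
    def n_tokens_per_block(self) -> int:
        return self.n_cvc + self.n_vcv


@dataclass
class GroundTruth:
    """Generative parameters stored alongside every synthetic bundle.

    ``source_centers`` maps articulator name -> (x, y) in mm; if None,
    centres are placed at fixed fractions of the array extent.  Phoneme
    sub-sources sit ``phoneme_offset_mm`` from their articulator centre.
    """

    source_centers: dict | None = None
    source_sigma_mm: float = 2.5
    source_gain: float = 1.0
    onset_lead_s: float = 0.3
    noise_corr_length_mm: float = 1.2
    leak_gain: float = 0.0
    phoneme_offset_mm: float = 1.5
    background_rms_uv: float = 10.0

    def __post_init__(self):
        if self.source_gain < 0 or self.leak_gain < 0:
            raise ValidationError("gains must be non-negative")
        if self.source_sigma_mm <= 0:
            raise ValidationError("source_sigma_mm must be positive")
        if not 0.0 <= self.onset_lead_s <= 1.0:
            raise ValidationError("onset_lead_s must lie in [0, 1]")

    def centers_for(self, geom: ArrayGeometry) -> dict:
        if self.source_centers is not None:
            return dict(self.source_centers)
        ex_y, ex_x = geom.extent_mm  # rows span y, cols span x
        frac = {"low": (0.20, 0.30), "high": (0.45, 0.70),
                "labial": (0.70, 0.30), "dorsal": (0.88, 0.70)}
        return {a: (fx * ex_x, fy * ex_y) for a, (fx, fy) in frac.items()}


# ---------------------------------------------------------------------------
# Task / event table


def _balanced_pick(cands: list[tuple], k: int, rng: np.random.Generator) -> list[tuple]:
    """Choose k unique tokens keeping per-slot phoneme usage as even as
    possible (greedy: always extend the least-used phonemes)."""
    usage = [{}, {}, {}]
    chosen: list[tuple] = []
    pool = list(cands)
    for _ in range(k):
        rng.shuffle(pool)
        best, best_cost = None, None
        for tok in pool:
            cost = sum(usage[s].get(ph, 0) for s, ph in enumerate(tok))
            if best_cost is None or cost < best_cost:
                best, best_cost = tok, cost
        chosen.append(best)
        pool.remove(best)
        for s, ph in enumerate(best):
            usage[s][ph] = usage[s].get(ph, 0) + 1
    return chosen


def _token_inventory(spec: TaskSpec, rng: np.random.Generator) -> list[str]:
    v, c = list(spec.vowels), list(spec.consonants)
    cvc = [(c1, v1, c2) for c1 in c for v1 in v for c2 in c]
    vcv = [(v1, c1, v2) for v1 in v for c1 in c for v2 in v]
    if len(cvc) < spec.n_cvc or len(vcv) < spec.n_vcv:
        raise ConfigurationError(
            f"inventories too small: {len(cvc)} CVC / {len(vcv)} VCV possible, "
            f"{spec.n_cvc}/{spec.n_vcv} requested")
    toks = _balanced_pick(cvc, spec.n_cvc, rng) + _balanced_pick(vcv, spec.n_vcv, rng)
    return [" ".join(t) for t in toks]


def make_task(spec: TaskSpec = TaskSpec(), seed: int = 0) -> pd.DataFrame:
    """Generate the trial/event table for ``n_blocks`` blocks.

    Each block is an independently shuffled permutation of the same token
    inventory.  Times are seconds from recording start; phoneme onsets are
    spread across the utterance.  All trials are marked correct.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA5]))
    tokens = _token_inventory(spec, rng)
    rows = []
    t = 1.0  # head-room so the first pre-stimulus baseline is in-recording
    trial_id = 0
    for _ in range(spec.n_blocks):
        order = rng.permutation(len(tokens))
        for idx in order:
            token = tokens[idx]
            p1, p2, p3 = token.split()
            dur = rng.uniform(*spec.trial_duration_s)
            stim_on = t
            stim_off = stim_on + spec.stim_duration_s
            utt_on = stim_off + rng.uniform(*spec.response_latency_s)
            utt_dur = rng.uniform(*spec.utterance_duration_s)
            utt_off = utt_on + utt_dur
            rows.append(dict(
                trial_id=trial_id, token=token, p1=p1, p2=p2, p3=p3,
                stim_onset_s=stim_on, stim_offset_s=stim_off,
                utt_onset_s=utt_on, utt_offset_s=utt_off,
                p1_onset_s=utt_on,
                p2_onset_s=utt_on + utt_dur / 3.0,
                p3_onset_s=utt_on + 2.0 * utt_dur / 3.0,
                correct=True,
            ))
            t += dur + spec.jitter_s
            trial_id += 1
    return pd.DataFrame(rows)[EVENT_COLUMNS]


# ---------------------------------------------------------------------------
# Signal synthesis

# 1/f ("pink") shaping filter (Paul Kellet's economy IIR approximation).
_PINK_B = np.array([0.049922035, -0.095993537, 0.050612699, -0.004408786])
_PINK_A = np.array([1.0, -2.494956002, 2.017265875, -0.522189400])


def _pink_noise(shape: tuple, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(shape).astype(np.float32)
    pink = signal.lfilter(_PINK_B, _PINK_A, white, axis=-1).astype(np.float32)
    pink /= pink.std(axis=-1, keepdims=True) + 1e-12
    return pink


def _narrowband_carrier(n: int, fs: float, band: tuple, rng) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band`` via FFT masking."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    lo, hi = band
    mask = ((f >= lo) & (f <= hi)).astype(float)
    x = np.fft.irfft(spec * mask, n)
    x /= x.std() + 1e-12
    return x.astype(np.float32)


def _raised_cosine_env(t: np.ndarray, start, peak, fall_start, end) -> np.ndarray:
    """Piecewise envelope: cosine rise, hold at 1, cosine fall; 0 outside."""
    env = np.zeros_like(t)
    rise = (t >= start) & (t < peak)
    if peak > start:
        env[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - start) / (peak - start)))
    env[(t >= peak) & (t < fall_start)] = 1.0
    fall = (t >= fall_start) & (t < end)
    if end > fall_start:
        env[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - fall_start) / (end - fall_start)))
    return env


def synthesize_recording(
    task: pd.DataFrame,
    geom: ArrayGeometry,
    truth: GroundTruth = None,
    fs: float = 2000.0,
    seed: int = 0,
) -> RecordingBundle:
    """Render a raw voltage recording for a trial table on a given array.

    voltage = spatially correlated 1/f background + common-mode pink noise
    + per-trial articulator/phoneme-specific amplitude-modulated 70-150 Hz
    carriers.  Each phoneme's spatial profile is a Gaussian of width
    ``source_sigma_mm`` around its (offset) articulator centre; its
    temporal envelope rises before the phoneme onset (``onset_lead_s`` for
    the first position) and falls by utterance offset.  A synthetic
    microphone track covers stimulus playback and the spoken response.
    Ground truth is stored in ``meta``.
    """
    if truth is None:
        truth = GroundTruth()
    if fs < 600:
        raise ValidationError("fs must be >= 600 Hz so the 70-150 Hz band exists")
    ss = np.random.SeedSequence([int(seed), 0x5EED])
    rng_bg, rng_car, rng_audio, rng_imp = (
        np.random.default_rng(s) for s in ss.spawn(4))

    n_ch = geom.n_electrodes
    coords = geom.coords_mm
    dur = float(task["utt_offset_s"].max()) + 2.0
    n = int(round(dur * fs))
    t_ax = np.arange(n) / fs

    # --- background: per-channel pink noise smoothed across the array ----
    bg = _pink_noise((n_ch, n), rng_bg)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    K = np.exp(-(d ** 2) / (2.0 * truth.noise_corr_length_mm ** 2))
    K /= np.linalg.norm(K, axis=1, keepdims=True)  # unit power rows
    voltage = (K.astype(np.float32) @ bg) * truth.background_rms_uv
    # common-mode component (removed downstream by CAR)
    voltage += 0.5 * truth.background_rms_uv * _pink_noise((1, n), rng_bg)

    # background RMS inside the HG band, for calibrating evoked amplitude
    sos = signal.butter(4, [70.0, min(150.0, 0.45 * fs)], "bandpass", fs=fs, output="sos")
    bg_band_rms = float(np.std(signal.sosfiltfilt(sos, voltage[0])))

    # --- evoked sources: one sub-source per phoneme ----------------------
    centers = truth.centers_for(geom)
    art_members = {a: [p for p in _PHONEMES if PHONEME_ARTICULATOR[p] == a]
                   for a in ARTICULATORS}
    src_xy, src_gain = {}, {}
    for art, members in art_members.items():
        cx, cy = centers[art]
        for j, ph in enumerate(members):
            ang = 2.0 * np.pi * j / max(len(members), 1)
            src_xy[ph] = (cx + truth.phoneme_offset_mm * np.cos(ang),
                          cy + truth.phoneme_offset_mm * np.sin(ang))
            src_gain[ph] = 1.0 + 0.2 * np.cos(2.0 * ang + 0.7)

    amp0 = 1.5 * bg_band_rms * truth.source_gain
    band = (70.0, min(150.0, 0.45 * fs))
    onsets = {1: "p1_onset_s", 2: "p2_onset_s", 3: "p3_onset_s"}
    phon_cols = {1: "p1", 2: "p2", 3: "p3"}

    envs = {ph: np.zeros(n, dtype=np.float32) for ph in _PHONEMES}
    for _, tr in task.iterrows():
        utt_off = float(tr["utt_offset_s"])
        utt_dur = utt_off - float(tr["utt_onset_s"])
        hold = utt_dur / 3.0
        for pos in (1, 2, 3):
            ph = tr[phon_cols[pos]]
            o = float(tr[onsets[pos]])
            lead = truth.onset_lead_s if pos == 1 else 0.08
            start, peak = o - lead, o
            fall_start = min(o + hold, utt_off)
            end = min(fall_start + 0.15, utt_off + 0.15)
            i0 = max(0, int(np.floor(start * fs)) - 1)
            i1 = min(n, int(np.ceil(end * fs)) + 1)
            if i1 <= i0:
                continue
            # trial-to-trial amplitude variability (lognormal ~30%):
            # decorrelates distant co-activating sources across trials,
            # as in real recordings
            amp_jit = float(np.exp(rng_car.normal(0.0, 0.3)))
            envs[ph][i0:i1] += amp_jit * _raised_cosine_env(
                t_ax[i0:i1], start, peak, fall_start, end).astype(np.float32)

    for ph in _PHONEMES:
        if not np.any(envs[ph]):
            continue
        carrier = _narrowband_carrier(n, fs, band, rng_car)
        gx = np.exp(-np.sum((coords - np.asarray(src_xy[ph])) ** 2, axis=1)
                    / (2.0 * truth.source_sigma_mm ** 2)).astype(np.float32)
        voltage += (amp0 * src_gain[ph]) * gx[:, None] * (envs[ph] * carrier)[None, :]

    # --- synthetic microphone track --------------------------------------
    audio = 0.01 * rng_audio.standard_normal(n).astype(np.float32)
    for _, tr in task.iterrows():
        s0, s1 = float(tr["stim_onset_s"]), float(tr["stim_offset_s"])
        u0, u1 = float(tr["utt_onset_s"]), float(tr["utt_offset_s"])
        i0, i1 = int(s0 * fs), min(n, int(s1 * fs))
        audio[i0:i1] += 0.4 * np.sin(2 * np.pi * 220.0 * t_ax[i0:i1]).astype(np.float32)
        i0, i1 = int(u0 * fs), min(n, int(u1 * fs))
        seg_t = t_ax[i0:i1]
        env = _raised_cosine_env(seg_t, u0, u0 + 0.05, u1 - 0.1, u1)
        # speech-shaped noise burst: broadband within the analysis band so
        # the audio spectral-correlation profile carries no tonal ridges
        voiced = _narrowband_carrier(len(seg_t), fs, (60.0, min(260.0, 0.45 * fs)),
                                     rng_audio)
        audio[i0:i1] += (0.6 * env * voiced).astype(np.float32)

    impedance = np.abs(rng_imp.normal(25.0, 4.0, n_ch))

    meta = {
        "seed": int(seed),
        "generator": "microspeech.simulate.synthesize_recording",
        "fs": fs,
        "ground_truth": {
            "source_centers": {a: list(map(float, c)) for a, c in centers.items()},
            "phoneme_centers": {p: list(map(float, xy)) for p, xy in src_xy.items()},
            "source_sigma_mm": truth.source_sigma_mm,
            "source_gain": truth.source_gain,
            "onset_lead_s": truth.onset_lead_s,
            "noise_corr_length_mm": truth.noise_corr_length_mm,
            "leak_gain": truth.leak_gain,
        },
    }
    bundle = RecordingBundle(voltage=voltage, fs=fs, geometry=geom,
                             events=task.copy(), impedance=impedance,
                             audio=audio, fs_audio=fs, meta=meta)
    if truth.leak_gain > 0:
        bundle = inject_contamination(bundle, truth.leak_gain)
    return bundle


def inject_contamination(bundle: RecordingBundle, leak_gain: float) -> RecordingBundle:
    """Add band-passed, scaled microphone audio to every neural channel.

    ``leak_gain`` scales the leaked audio to that fraction of the mean
    neural RMS.  Returns a new bundle; ``meta['leak_gain']`` records it.
    """
    if bundle.audio is None:
        raise ValidationError("bundle has no audio track to leak")
    fs = bundle.fs
    audio = np.asarray(bundle.audio, dtype=np.float64)
    if bundle.fs_audio != fs:
        audio = signal.resample_poly(audio, int(fs), int(bundle.fs_audio))
    n = bundle.voltage.shape[1]
    audio = audio[:n] if len(audio) >= n else np.pad(audio, (0, n - len(audio)))
    sos = signal.butter(4, [70.0, min(150.0, 0.45 * fs)], "bandpass", fs=fs, output="sos")
    leak = signal.sosfiltfilt(sos, audio)
    leak_rms = leak.std() + 1e-12
    neural_rms = float(bundle.voltage.std())
    leak = leak * (leak_gain * neural_rms / leak_rms)
    out = bundle.with_voltage(bundle.voltage + leak[None, :].astype(np.float32))
    out.meta["leak_gain"] = float(leak_gain)
    return out


def simulate_bundle(
    spec: TaskSpec = None,
    geom: ArrayGeometry = None,
    truth: GroundTruth = None,
    fs: float = 2000.0,
    seed: int = 0,
) -> RecordingBundle:
    """Convenience wrapper: task + recording with the default study setup."""
    spec = spec or TaskSpec()
    geom = geom or make_array(8, 16, 1.33)
    task = make_task(spec, seed=seed)
    return synthesize_recording(task, geom, truth, fs=fs, seed=seed)
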