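"""Shared fixtures: synthetic recording sessions at test-friendly sizes.

Recordings are generated programmatically with the package's own
generator.  Trial durations are shortened (2.2-2.6 s vs the task's
3.5-4.5 s) and arrays reduced where a property does not depend on the
full 8 x 16 layout, to keep the suite fast; fixtures that need the full
lattice build it explicitly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import microspeech as ms
from microspeech.simulate import (GroundTruth, TaskSpec, make_array,
                                  make_task, synthesize_recording)

FAST_TASK = dict(trial_duration_s=(2.2, 2.6), response_latency_s=(0.7, 1.0))


def make_session(seed=11, n_rows=4, n_cols=8, n_blocks=1, truth=None,
                 fs=2000.0, **task_kw):
    """Synthesize a session and preprocess it once."""
    spec = TaskSpec(n_blocks=n_blocks, **{**FAST_TASK, **task_kw})
    task = make_task(spec, seed=seed)
    geom = make_array(n_rows, n_cols, 1.33)
    bundle = synthesize_recording(task, geom, truth or GroundTruth(),
                                  fs=fs, seed=seed)
    qc = ms.qc_channels(bundle)
    ref = ms.common_average_reference(bundle, qc)
    return {"bundle": bundle, "geom": geom, "qc": qc, "ref": ref}


@pytest.fixture(scope="session")
def session52():
    """One block (52 trials) on a 4 x 8 array."""
    return make_session(seed=11)


@pytest.fixture(scope="session")
def hg_p1(session52):
    s = session52
    hg = ms.extract_hg(s["ref"], s["bundle"], alignment="p1",
                       window_s=(-0.5, 0.5))
    labels = s["bundle"].events["p1"].to_numpy()[hg.trial_index]
    return hg, labels


@pytest.fixture(scope="session")
def hg_utt(session52):
    s = session52
    hg = ms.extract_hg(s["ref"], s["bundle"], alignment="utterance",
                       window_s=(-1.0, 1.0))
    ev = s["bundle"].events.iloc[hg.trial_index]
    labels = {p: ev[p].to_numpy() for p in ("p1", "p2", "p3")}
    return hg, labels


@pytest.fixture(scope="session")
def session_mid():
    """Two blocks (104 trials) on an 8 x 8 array: sources well interior,
    enough trials for direction-of-effect properties."""
    return make_session(seed=21, n_rows=8, n_cols=8, n_blocks=2)


@pytest.fixture(scope="session")
def hg_mid_p1(session_mid):
    s = session_mid
    hg = ms.extract_hg(s["ref"], s["bundle"], alignment="p1",
                       window_s=(-0.5, 0.5))
    labels = s["bundle"].events["p1"].to_numpy()[hg.trial_index]
    return hg, labels


@pytest.fixture(scope="session")
def hg_mid_utt(session_mid):
    s = session_mid
    hg = ms.extract_hg(s["ref"], s["bundle"], alignment="utterance",
                       window_s=(-1.0, 1.0))
    ev = s["bundle"].events.iloc[hg.trial_index]
    labels = {p: ev[p].to_numpy() for p in ("p1", "p2", "p3")}
    return hg, labels


@pytest.fixture(scope="session")
def chance_session():
    """12 blocks (624 trials) on a 4 x 4 array, for chance calibration."""
    s = make_session(seed=7, n_rows=4, n_cols=4, n_blocks=12,
                     trial_duration_s=(2.0, 2.3),
                     response_latency_s=(0.7, 0.9))
    hg = ms.extract_hg(s["ref"], s["bundle"], alignment="p1",
                       window_s=(-0.5, 0.5))
    labels = s["bundle"].events["p1"].to_numpy()[hg.trial_index]
    classes, counts = np.unique(labels, return_counts=True)
    m = int(counts.min())
    rng = np.random.default_rng(1)
    idx = np.concatenate([rng.choice(np.where(labels == c)[0], m, replace=False)
                          for c in classes])
    X = hg.values[idx].reshape(len(idx), -1)
    return {"X": X, "y": labels[idx], "n": len(idx), **s}


def suppress_subsample_warnings():
    ctx = warnings.catch_warnings()
    ctx.__enter__()
    warnings.simplefilter("ignore")
    return ctx
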