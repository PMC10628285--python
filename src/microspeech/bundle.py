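"""Recording container: array geometry, trial/event tables, and HDF5 I/O.

A :class:`RecordingBundle` is the unit every pipeline stage consumes and
produces: raw multichannel voltage plus the electrode-array geometry, the
per-channel impedance, an optional microphone track, the trial/event table,
and free-form provenance metadata.  On disk a bundle is a single HDF5 file
with groups ``/voltage``, ``/geometry``, ``/impedance``, ``/audio``,
``/events`` and ``/meta``; the event table can also be exported as a
BIDS-style TSV.  All times are seconds from recording start and all windows
are half-open ``[t0, t1)``.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ArrayGeometry",
    "RecordingBundle",
    "ValidationError",
    "FormatError",
    "EVENT_COLUMNS",
    "make_array",
    "read_bundle",
    "write_bundle",
    "read_events_tsv",
    "write_events_tsv",
]


class ValidationError(ValueError):
    """An object violates its declared invariants."""


class FormatError(IOError):
    """An on-disk container is missing required structure."""


#: Canonical column order of the trial/event table.
EVENT_COLUMNS = [
    "trial_id", "token", "p1", "p2", "p3",
    "stim_onset_s", "stim_offset_s", "utt_onset_s", "utt_offset_s",
    "p1_onset_s", "p2_onset_s", "p3_onset_s", "correct",
]


@dataclass(frozen=True)
class ArrayGeometry:
    """Rectangular micro-electrode lattice.

    Electrodes are indexed row-major: electrode ``e`` sits at row
    ``e // n_cols``, column ``e % n_cols``, with coordinates
    ``(col * pitch_mm, row * pitch_mm)`` so ``x`` runs along the long axis
    of e.g. an 8 x 16 array.  ``extent_mm`` is the physical footprint
    ``(n_rows * pitch, n_cols * pitch)`` used by the pitch formula
    ``pitch = sqrt(X * Y / n)``.  ``active`` masks lattice sites without a
    recording contact (e.g. the 12 x 22 = 264-site layout wired for 256
    channels).
    """

    n_rows: int
    n_cols: int
    pitch_mm: float
    exposed_diameter_mm: float = 0.2
    active: np.ndarray | None = None

    def __post_init__(self):
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValidationError("array dimensions must be positive")
        if self.pitch_mm <= 0:
            raise ValidationError("pitch must be positive")
        if self.active is not None:
            a = np.asarray(self.active, dtype=bool)
            if a.shape != (self.n_sites,):
                raise ValidationError("active mask length must equal n_rows*n_cols")
            object.__setattr__(self, "active", a)

    @property
    def n_sites(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_electrodes(self) -> int:
        return int(self.active.sum()) if self.active is not None else self.n_sites

    @property
    def site_coords_mm(self) -> np.ndarray:
        """(n_sites, 2) lattice coordinates in mm, row-major."""
        rows, cols = np.divmod(np.arange(self.n_sites), self.n_cols)
        return np.column_stack([cols * self.pitch_mm, rows * self.pitch_mm])

    @property
    def coords_mm(self) -> np.ndarray:
        """(n_electrodes, 2) coordinates of active sites in mm."""
        c = self.site_coords_mm
        return c[self.active] if self.active is not None else c

    @property
    def extent_mm(self) -> tuple[float, float]:
        return (self.n_rows * self.pitch_mm, self.n_cols * self.pitch_mm)


def make_array(
    n_rows: int,
    n_cols: int,
    pitch_mm: float,
    exposed_diameter_mm: float = 0.2,
    mask_corners: int = 0,
) -> ArrayGeometry:
    """Build a rectangular lattice geometry.

    ``mask_corners`` deactivates that many sites at each of the four array
    corners (used to reconcile a 264-site 12 x 22 lattice with its 256
    wired channels: ``mask_corners=2`` removes 8 sites).
    """
    active = None
    if mask_corners:
        active = np.ones(n_rows * n_cols, dtype=bool)
        for r in (0, n_rows - 1):
            for c_ in (0, n_cols - 1):
                cols = range(0, mask_corners) if c_ == 0 else range(n_cols - mask_corners, n_cols)
                for c in cols:
                    active[r * n_cols + c] = False
    return ArrayGeometry(n_rows, n_cols, pitch_mm, exposed_diameter_mm, active)


@dataclass
class RecordingBundle:
    """One recording session: voltage, geometry, events, audio, provenance.

    voltage is (channels, samples) in microvolts at ``fs`` Hz; ``audio`` is
    a 1-D waveform at ``fs_audio`` Hz or None; ``impedance`` is per-channel
    in kOhm or None; ``events`` is a DataFrame with :data:`EVENT_COLUMNS`.
    """

    voltage: np.ndarray
    fs: float
    geometry: ArrayGeometry
    events: pd.DataFrame
    impedance: np.ndarray | None = None
    audio: np.ndarray | None = None
    fs_audio: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voltage = np.asarray(self.voltage)
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if self.voltage.ndim != 2:
            raise ValidationError("voltage must be (channels, samples)")
        if self.voltage.shape[0] != self.geometry.n_electrodes:
            raise ValidationError(
                f"voltage has {self.voltage.shape[0]} channels but geometry "
                f"defines {self.geometry.n_electrodes} electrodes"
            )
        if self.audio is not None and self.fs_audio is None:
            raise ValidationError("audio present but fs_audio missing")
        if self.impedance is not None:
            self.impedance = np.asarray(self.impedance, dtype=float)
            if self.impedance.shape != (self.voltage.shape[0],):
                raise ValidationError("impedance must be per-channel")
        self.validate_events()

    @property
    def duration_s(self) -> float:
        return self.voltage.shape[1] / self.fs

    @property
    def n_channels(self) -> int:
        return self.voltage.shape[0]

    def validate_events(self):
        ev = self.events
        missing = [c for c in EVENT_COLUMNS if c not in ev.columns]
        if missing:
            raise ValidationError(f"event table missing columns {missing}")
        tcols = [c for c in EVENT_COLUMNS if c.endswith("_s")]
        times = ev[tcols].to_numpy(dtype=float)
        if times.size and (times.min() < 0 or times.max() > self.duration_s + 1e-9):
            raise ValidationError("event times fall outside the recording")

    def with_voltage(self, voltage: np.ndarray) -> "RecordingBundle":
        """Copy of this bundle with replaced voltage (same shape contract)."""
        out = RecordingBundle(
            voltage=voltage, fs=self.fs, geometry=self.geometry,
            events=self.events.copy(), impedance=self.impedance,
            audio=self.audio, fs_audio=self.fs_audio, meta=dict(self.meta),
        )
        return out


# ---------------------------------------------------------------------------
# HDF5 container


def _geometry_to_group(g: h5py.Group, geom: ArrayGeometry) -> None:
    g.attrs["n_rows"] = geom.n_rows
    g.attrs["n_cols"] = geom.n_cols
    g.attrs["pitch_mm"] = geom.pitch_mm
    g.attrs["exposed_diameter_mm"] = geom.exposed_diameter_mm
    if geom.active is not None:
        g.create_dataset("active", data=geom.active.astype(np.uint8))


def _geometry_from_group(g: h5py.Group) -> ArrayGeometry:
    active = g["active"][()].astype(bool) if "active" in g else None
    return ArrayGeometry(
        int(g.attrs["n_rows"]), int(g.attrs["n_cols"]),
        float(g.attrs["pitch_mm"]), float(g.attrs["exposed_diameter_mm"]),
        active,
    )


def write_bundle(bundle: RecordingBundle, path: str | os.PathLike) -> None:
    """Write a bundle atomically (temp file + rename) as one HDF5 container."""
    bundle.validate_events()  # re-check before touching disk
    path = os.fspath(path)
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(suffix=".h5", dir=d)
    os.close(fd)
    try:
        with h5py.File(tmp, "w") as f:
            dv = f.create_dataset("voltage", data=bundle.voltage.astype(np.float32))
            dv.attrs["fs"] = float(bundle.fs)
            _geometry_to_group(f.create_group("geometry"), bundle.geometry)
            ev = f.create_group("events")
            for col in EVENT_COLUMNS:
                vals = bundle.events[col].to_numpy()
                if vals.dtype.kind in "OU":
                    vals = vals.astype(h5py.string_dtype())
                ev.create_dataset(col, data=vals)
            if bundle.impedance is not None:
                f.create_dataset("impedance", data=bundle.impedance)
            if bundle.audio is not None:
                da = f.create_dataset("audio", data=np.asarray(bundle.audio, dtype=np.float32))
                da.attrs["fs"] = float(bundle.fs_audio)
            f.create_group("meta").attrs["json"] = json.dumps(bundle.meta, default=str)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.remove(tmp)
        raise


def read_bundle(path: str | os.PathLike) -> RecordingBundle:
    """Read a bundle; absent optional groups become ``None``, never defaults."""
    with h5py.File(path, "r") as f:
        for grp in ("voltage", "geometry", "events"):
            if grp not in f:
                raise FormatError(f"container missing required group '/{grp}'")
        fs = float(f["voltage"].attrs["fs"])
        if fs <= 0:
            raise ValidationError("stored fs must be positive")
        voltage = f["voltage"][()]
        geom = _geometry_from_group(f["geometry"])
        cols = {}
        for col in EVENT_COLUMNS:
            if col not in f["events"]:
                raise FormatError(f"container missing '/events/{col}'")
            v = f["events"][col][()]
            if v.dtype.kind in "SO":
                v = np.array([x.decode() if isinstance(x, bytes) else x for x in v])
            cols[col] = v
        events = pd.DataFrame(cols)[EVENT_COLUMNS]
        impedance = f["impedance"][()] if "impedance" in f else None
        audio = fs_audio = None
        if "audio" in f:
            audio = f["audio"][()]
            fs_audio = float(f["audio"].attrs["fs"])
        meta = {}
        if "meta" in f and "json" in f["meta"].attrs:
            meta = json.loads(f["meta"].attrs["json"])
    return RecordingBundle(voltage=voltage, fs=fs, geometry=geom, events=events,
                           impedance=impedance, audio=audio, fs_audio=fs_audio,
                           meta=meta)


def write_events_tsv(events: pd.DataFrame, path: str | os.PathLike) -> None:
    events[EVENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | os.PathLike) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in ev.columns]
    if missing:
        raise FormatError(f"event TSV missing columns {missing}")
    return ev[EVENT_COLUMNS]
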