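"""Preprocessing of stereo-EEG recordings.

Implements the standard conditioning chain applied before any connectivity
analysis: line-noise notch filtering, re-referencing (bipolar for
stimulation-evoked analyses, common-average for resting-state analyses),
pulse-locked epoching, and baseline correction.

All filters are zero-phase third-order Butterworth designs applied
forward-backward as cascaded second-order sections; direct-form third-order
band-stops with narrow relative bandwidth are numerically fragile, SOS are
not.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger("asmconn")

#: Clinician-assigned tissue classes, ordered most → least pathological.
ZONES = ("SOZ", "EPZ", "IZ", "NIZ")
_ZONE_RANK = {z: i for i, z in enumerate(ZONES)}

CONDITIONS = ("ASM-ON", "ASM-OFF")

#: Line-noise band-stops (Hz): mains fundamental and first two harmonics.
NOTCH_BANDS = ((59.0, 61.0), (119.0, 121.0), (179.0, 181.0))

#: Baseline window (ms relative to pulse onset) for epoch correction.
BASELINE_MS = (-215.0, -15.0)

#: Default epoch span (ms relative to pulse onset).
EPOCH_WINDOW_MS = (-250.0, 500.0)


def ms_to_samples(t_ms: float, fs_hz: float) -> int:
    """Convert milliseconds to a sample count, rounding half away from zero."""
    x = t_ms * fs_hz / 1000.0
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


@dataclass(frozen=True)
class ChannelInfo:
    """Metadata for one recording channel (contact or bipolar pair)."""

    name: str
    shaft: str
    contact_index: int
    zone: str = "NIZ"
    bad: bool = False

    def __post_init__(self) -> None:
        if self.zone not in ZONES:
            raise ValueError(f"zone must be one of {ZONES}, got {self.zone!r}")


@dataclass
class Recording:
    """Continuous multichannel iEEG segment (channels x samples, µV)."""

    samples: np.ndarray
    fs_hz: float
    channels: list[ChannelInfo]
    patient_id: str = "P0"
    condition: str = "ASM-ON"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        if self.samples.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.samples.shape[0]} rows but {len(self.channels)} channels"
            )
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None


@dataclass
class CcepEpochs:
    """Pulse-locked epochs: trials x channels x time (µV).

    ``times_ms`` is the common time axis in milliseconds relative to pulse
    onset (time 0 = onset sample).
    """

    data: np.ndarray
    times_ms: np.ndarray
    fs_hz: float
    channels: list[ChannelInfo]
    stim_pair: str = ""
    patient_id: str = "P0"
    condition: str = "ASM-ON"
    baseline_corrected: bool = False

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def average(self) -> np.ndarray:
        """Across-trial average waveform, channels x time."""
        return self.data.mean(axis=0)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _bandstop_sos(low: float, high: float, fs_hz: float) -> np.ndarray:
    return signal.butter(3, (low, high), btype="bandstop", output="sos", fs=fs_hz)


def notch_filter(rec: Recording, bands: Sequence[tuple[float, float]] = NOTCH_BANDS) -> Recording:
    """Remove mains noise and harmonics with zero-phase Butterworth band-stops.

    Each band is a third-order band-stop applied forward-backward
    (``sosfiltfilt``), so the cascade has zero phase distortion.  Bands whose
    upper edge reaches the Nyquist frequency are dropped with a warning.
    """
    out = rec.samples.copy()
    for low, high in bands:
        if high >= rec.fs_hz / 2:
            warnings.warn(
                f"band-stop {low}-{high} Hz exceeds Nyquist at fs={rec.fs_hz} Hz; skipped",
                stacklevel=2,
            )
            continue
        sos = _bandstop_sos(low, high, rec.fs_hz)
        out = signal.sosfiltfilt(sos, out, axis=-1)
    return replace(rec, samples=out, channels=list(rec.channels))


# ---------------------------------------------------------------------------
# Re-referencing
# ---------------------------------------------------------------------------

def _worse_zone(a: str, b: str) -> str:
    return a if _ZONE_RANK[a] <= _ZONE_RANK[b] else b


def bipolar_reference(rec: Recording) -> Recording:
    """Re-reference to bipolar derivations between adjacent same-shaft contacts.

    Each derived channel is the difference of two neighbouring contacts on
    one electrode shaft (named ``"A1-A2"``), which cancels signals common to
    both contacts (volume-conducted noise, reference drift).  A bipolar
    channel inherits the more pathological of its contacts' zone labels
    (SOZ > EPZ > IZ > NIZ).  Bad contacts are excluded along with every pair
    they would form; a shaft with fewer than two good contacts contributes
    nothing.
    """
    by_shaft: dict[str, list[int]] = {}
    for i, ch in enumerate(rec.channels):
        if not ch.bad:
            by_shaft.setdefault(ch.shaft, []).append(i)

    rows: list[np.ndarray] = []
    infos: list[ChannelInfo] = []
    for shaft, idx in by_shaft.items():
        idx = sorted(idx, key=lambda i: rec.channels[i].contact_index)
        for a, b in zip(idx[:-1], idx[1:]):
            ca, cb = rec.channels[a], rec.channels[b]
            if cb.contact_index != ca.contact_index + 1:
                continue  # gap left by an excluded bad contact
            rows.append(rec.samples[a] - rec.samples[b])
            infos.append(
                ChannelInfo(
                    name=f"{ca.name}-{cb.name}",
                    shaft=shaft,
                    contact_index=ca.contact_index,
                    zone=_worse_zone(ca.zone, cb.zone),
                )
            )
    data = np.array(rows) if rows else np.empty((0, rec.n_samples))
    return replace(rec, samples=data, channels=infos)


def common_average_reference(rec: Recording, exclude: Sequence[str] = ()) -> Recording:
    """Subtract the mean of the included channels from every channel.

    ``exclude`` channels (typically SOZ/EPZ or noisy contacts) do not enter
    the reference but are still re-referenced.  At least two channels must
    remain included.
    """
    excl = set(exclude)
    unknown = excl - set(rec.channel_names)
    if unknown:
        raise KeyError(f"exclude names not in recording: {sorted(unknown)}")
    included = [i for i, c in enumerate(rec.channels) if c.name not in excl and not c.bad]
    if len(included) < 2:
        raise ValueError("common average reference needs >= 2 included channels")
    ref = rec.samples[included].mean(axis=0)
    return replace(rec, samples=rec.samples - ref, channels=list(rec.channels))


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def epoch_and_baseline(
    rec: Recording,
    onsets: Sequence[int],
    window_ms: tuple[float, float] = EPOCH_WINDOW_MS,
    baseline_ms: tuple[float, float] = BASELINE_MS,
    stim_pair: str = "",
) -> CcepEpochs:
    """Cut pulse-locked epochs and subtract the pre-pulse baseline mean.

    Stimulation alters contact impedance, so each trial and channel is
    normalised by subtracting its own mean over ``baseline_ms`` (default
    −215…−15 ms).  Every pulse is retained; onsets whose window would leave
    the recording are dropped with a log entry.
    """
    lo = ms_to_samples(window_ms[0], rec.fs_hz)
    hi = ms_to_samples(window_ms[1], rec.fs_hz)
    n_t = hi - lo + 1
    times_ms = (np.arange(lo, hi + 1) / rec.fs_hz) * 1000.0

    kept: list[np.ndarray] = []
    for k, onset in enumerate(onsets):
        start, stop = onset + lo, onset + hi + 1
        if start < 0 or stop > rec.n_samples:
            logger.warning(
                "dropping trial %d (onset %d): window outside recording", k, onset
            )
            continue
        kept.append(rec.samples[:, start:stop])
    data = np.array(kept) if kept else np.empty((0, rec.n_channels, n_t))

    bmask = (times_ms >= baseline_ms[0]) & (times_ms <= baseline_ms[1])
    if data.size:
        data = data - data[:, :, bmask].mean(axis=2, keepdims=True)
    return CcepEpochs(
        data=data,
        times_ms=times_ms,
        fs_hz=rec.fs_hz,
        channels=list(rec.channels),
        stim_pair=stim_pair,
        patient_id=rec.patient_id,
        condition=rec.condition,
        baseline_corrected=True,
    )


# ---------------------------------------------------------------------------
# I/O: EDF import, channel-metadata TSV, onset JSON, array fixtures
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ("name", "shaft", "contact_index", "zone", "bad")


def read_channel_metadata(path: str | Path) -> list[ChannelInfo]:
    """Read the channel-metadata TSV (columns: name, shaft, contact_index, zone, bad)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"channel metadata TSV not found: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata TSV {path} missing columns: {sorted(missing)}")
    return [
        ChannelInfo(
            name=str(r["name"]),
            shaft=str(r["shaft"]),
            contact_index=int(r["contact_index"]),
            zone=str(r["zone"]),
            bad=bool(r["bad"]),
        )
        for _, r in df.iterrows()
    ]


def read_edf(
    path: str | Path,
    metadata: list[ChannelInfo],
    patient_id: str = "P0",
    condition: str = "ASM-ON",
) -> Recording:
    """Load an EDF recording (via MNE) and attach channel metadata by name."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    by_name = {c.name: c for c in metadata}
    chans, rows = [], []
    for name in raw.ch_names:
        if name in by_name:
            chans.append(by_name[name])
            rows.append(raw.get_data(picks=[name])[0] * 1e6)  # V → µV
    if not chans:
        raise ValueError("no EDF channel matched the metadata table")
    return Recording(
        samples=np.array(rows),
        fs_hz=float(raw.info["sfreq"]),
        channels=chans,
        patient_id=patient_id,
        condition=condition,
    )


def detect_pulse_onsets(
    trace: np.ndarray, fs_hz: float, threshold_sd: float = 8.0, refractory_s: float = 0.5
) -> list[int]:
    """Threshold-crossing stimulation-artifact detector for imported recordings.

    Intended for EDF import where pulse times were not logged; synthetic and
    fixture sessions carry exact onsets and never need it.
    """
    x = np.abs(trace - np.median(trace))
    thr = threshold_sd * (np.median(x) / 0.6745 + 1e-12)
    above = np.flatnonzero(x > thr)
    onsets: list[int] = []
    gap = int(refractory_s * fs_hz)
    for i in above:
        if not onsets or i - onsets[-1] >= gap:
            onsets.append(int(i))
    return onsets


def read_onsets_json(path: str | Path) -> dict[str, list[int]]:
    """Read the onsets file: JSON mapping stim-pair name → sample indices."""
    with open(path) as fh:
        raw = json.load(fh)
    return {str(k): [int(v) for v in vals] for k, vals in raw.items()}


def save_recording(rec: Recording, stem: str | Path) -> None:
    """Write a recording as ``<stem>.npy`` plus a ``<stem>.json`` sidecar."""
    stem = Path(stem)
    np.save(stem.with_suffix(".npy"), rec.samples)
    sidecar = {
        "fs_hz": rec.fs_hz,
        "patient_id": rec.patient_id,
        "condition": rec.condition,
        "channels": [
            {
                "name": c.name,
                "shaft": c.shaft,
                "contact_index": c.contact_index,
                "zone": c.zone,
                "bad": c.bad,
            }
            for c in rec.channels
        ],
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_recording(stem: str | Path) -> Recording:
    """Load a recording written by :func:`save_recording`."""
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    return Recording(
        samples=np.load(stem.with_suffix(".npy")),
        fs_hz=meta["fs_hz"],
        channels=[ChannelInfo(**c) for c in meta["channels"]],
        patient_id=meta["patient_id"],
        condition=meta["condition"],
    )
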