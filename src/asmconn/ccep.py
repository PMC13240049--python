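"""CCEP feature extraction: single-trial N1/N2 peaks and averaged-response RMS.

Two families of effective-connectivity features are measured at every
recording channel for every stimulated pair:

* per-trial peak features — the largest local deflection of the single-trial
  response inside the N1 window (10–30 ms) and the N2 window (85–250 ms),
  reported as absolute amplitude (µV) and latency (ms).  Trials without any
  local peak in a window carry no value for that component.
* RMS of the across-trial average response over 10–300 ms and its early
  (10–50 ms) and late (50–300 ms) portions, evaluated on a 1 ms grid — one
  scalar per (channel, window, condition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .preprocess import CcepEpochs

N1_WINDOW_MS = (10.0, 30.0)
N2_WINDOW_MS = (85.0, 250.0)
RMS_WINDOWS_MS = {
    "rms_10_300": (10.0, 300.0),
    "rms_10_50": (10.0, 50.0),
    "rms_50_300": (50.0, 300.0),
}

TRIAL_FEATURE_COLUMNS = [
    "patient", "stim_pair", "rec_channel", "condition", "trial",
    "n1_latency_ms", "n1_amplitude_uv", "n1_present",
    "n2_latency_ms", "n2_amplitude_uv", "n2_present",
]
RMS_COLUMNS = [
    "patient", "stim_pair", "rec_channel", "condition",
    "rms_10_300", "rms_10_50", "rms_50_300",
]


@dataclass(frozen=True)
class PeakFeature:
    """One detected deflection: latency (ms), absolute amplitude (µV), presence."""

    latency_ms: float = np.nan
    amplitude_uv: float = np.nan
    present: bool = False


def detect_peak(
    trace: np.ndarray,
    times_ms: np.ndarray,
    window_ms: tuple[float, float],
    min_prominence: float = 0.0,
) -> PeakFeature:
    """Largest-|amplitude| strict local peak of a single-trial trace in a window.

    Candidates are strict local maxima of ``|trace|`` strictly inside
    ``window_ms`` (window endpoints are never returned, avoiding edge
    artifacts).  Among candidates the one with the largest absolute
    amplitude wins; ties go to the earliest.  If no local maximum exists the
    feature is absent.  ``min_prominence`` optionally imposes a minimum peak
    prominence (µV); by default none is imposed.
    """
    times_ms = np.asarray(times_ms, float)
    if window_ms[0] < times_ms[0] or window_ms[1] > times_ms[-1]:
        raise ValueError(
            f"window {window_ms} outside trace support [{times_ms[0]}, {times_ms[-1]}] ms"
        )
    mask = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    seg = np.abs(np.asarray(trace, float)[mask])
    t_seg = times_ms[mask]
    kwargs = {"prominence": min_prominence} if min_prominence > 0 else {}
    peaks, _ = find_peaks(seg, **kwargs)  # strict interior by construction
    if peaks.size == 0:
        return PeakFeature()
    amps = seg[peaks]
    best = peaks[np.flatnonzero(amps == amps.max())[0]]  # earliest of the maxima
    return PeakFeature(latency_ms=float(t_seg[best]), amplitude_uv=float(seg[best]), present=True)


def compute_rms(
    avg_trace: np.ndarray,
    times_ms: np.ndarray,
    window_ms: tuple[float, float],
    step_ms: float = 1.0,
) -> float:
    """RMS of the trial-averaged response over a window, on a 1 ms grid.

    The averaged trace is evaluated by linear interpolation at ``step_ms``
    resolution on the half-open interval [start, stop); the half-open grids
    make the early and late sub-windows an exact partition of the full one:
    ``T·RMS²(10–300) = T₁·RMS²(10–50) + T₂·RMS²(50–300)``.
    """
    if window_ms[1] <= window_ms[0]:
        raise ValueError("empty RMS window")
    times_ms = np.asarray(times_ms, float)
    if window_ms[0] < times_ms[0] or window_ms[1] > times_ms[-1] + step_ms:
        raise ValueError(f"window {window_ms} outside trace support")
    grid = np.arange(window_ms[0], window_ms[1] - step_ms / 2, step_ms)
    vals = np.interp(grid, times_ms, np.asarray(avg_trace, float))
    return float(np.sqrt(np.mean(vals**2)))


def extract_features(
    epochs: CcepEpochs,
    n1_window_ms: tuple[float, float] = N1_WINDOW_MS,
    n2_window_ms: tuple[float, float] = N2_WINDOW_MS,
    min_prominence: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract the trial-feature table and the RMS table from one epoch set.

    Channels that belong to the stimulated pair are excluded from the
    recording set.  Returns ``(trial_features, rms_table)`` as tidy
    DataFrames; absent peaks have NaN latency/amplitude and
    ``present=False``.  RMS is computed from the across-trial average
    waveform only.
    """
    if not epochs.baseline_corrected:
        raise ValueError("epochs must be baseline-corrected before feature extraction")
    stim_contacts = set(epochs.stim_pair.split("-")) if epochs.stim_pair else set()

    rec_idx = [
        i for i, ch in enumerate(epochs.channels)
        if ch.name not in stim_contacts
        and not (set(ch.name.split("-")) & stim_contacts)
    ]
    trial_rows: list[dict] = []
    rms_rows: list[dict] = []
    avg = epochs.average() if epochs.n_trials else None
    for i in rec_idx:
        name = epochs.channels[i].name
        for k in range(epochs.n_trials):
            trace = epochs.data[k, i]
            n1 = detect_peak(trace, epochs.times_ms, n1_window_ms, min_prominence)
            n2 = detect_peak(trace, epochs.times_ms, n2_window_ms, min_prominence)
            trial_rows.append(
                {
                    "patient": epochs.patient_id,
                    "stim_pair": epochs.stim_pair,
                    "rec_channel": name,
                    "condition": epochs.condition,
                    "trial": k,
                    "n1_latency_ms": n1.latency_ms,
                    "n1_amplitude_uv": n1.amplitude_uv,
                    "n1_present": n1.present,
                    "n2_latency_ms": n2.latency_ms,
                    "n2_amplitude_uv": n2.amplitude_uv,
                    "n2_present": n2.present,
                }
            )
        if avg is not None:
            row = {
                "patient": epochs.patient_id,
                "stim_pair": epochs.stim_pair,
                "rec_channel": name,
                "condition": epochs.condition,
            }
            for col, win in RMS_WINDOWS_MS.items():
                row[col] = compute_rms(avg[i], epochs.times_ms, win)
            rms_rows.append(row)

    trial_features = pd.DataFrame(trial_rows, columns=TRIAL_FEATURE_COLUMNS)
    rms_table = pd.DataFrame(rms_rows, columns=RMS_COLUMNS)
    return trial_features, rms_table
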