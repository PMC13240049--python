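"""Broadband high-frequency activity (BHA) and functional connectivity.

The resting-state functional-connectivity estimate is built in three steps
from a common-average-referenced recording:

1. time-frequency power at 14 log-spaced frequencies in 70–200 Hz
   (seven-cycle Morlet wavelets, 10 ms hops), log-normalized per frequency
   and averaged across frequencies → the BHA time series at 100 Hz;
2. zero-phase third-order Butterworth band-pass retaining the slow 0.1–1 Hz
   fluctuations of BHA;
3. Pearson correlation of the slow BHA between every pair of channels.

The slow BHA envelope tracks local population spiking, so its cross-channel
correlation is an electrophysiological analogue of fMRI resting-state
functional connectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from mne.time_frequency import tfr_array_morlet
from scipy import signal

from .preprocess import Recording

logger = logging.getLogger("asmconn")

BHA_BAND_HZ = (70.0, 200.0)
N_FREQS = 14
N_CYCLES = 7.0
BHA_FS_HZ = 100.0  # 10 ms hops
SLOW_BAND_HZ = (0.1, 1.0)


@dataclass
class BhaSeries:
    """Channels x time matrix of BHA (z-units) at ``fs_hz`` (default 100 Hz).

    ``band`` is ``"raw"`` after frequency averaging and ``"slow"`` after the
    0.1–1 Hz band-pass.
    """

    data: np.ndarray
    fs_hz: float
    channel_names: list[str]
    band: str = "raw"
    condition: str = "ASM-ON"
    patient_id: str = "P0"

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass
class FcMatrix:
    """Symmetric channels x channels Pearson-correlation matrix."""

    values: np.ndarray
    channel_names: list[str]
    condition: str = "ASM-ON"
    patient_id: str = "P0"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        n = len(self.channel_names)
        if self.values.shape != (n, n):
            raise ValueError("FC matrix shape does not match channel list")


def morlet_frequencies(
    band_hz: tuple[float, float] = BHA_BAND_HZ, n_freqs: int = N_FREQS
) -> np.ndarray:
    """Log-spaced wavelet center frequencies covering the carrier band."""
    return np.logspace(np.log10(band_hz[0]), np.log10(band_hz[1]), n_freqs)


def compute_bha(
    rec: Recording,
    band_hz: tuple[float, float] = BHA_BAND_HZ,
    n_freqs: int = N_FREQS,
    n_cycles: float = N_CYCLES,
    bha_fs_hz: float = BHA_FS_HZ,
    zscore_per_frequency: bool = True,
) -> BhaSeries:
    """Morlet-based broadband high-frequency activity of a recording.

    Per frequency, power = |Morlet coefficient|²; "log normalization" is
    log10 of power followed by a per-frequency z-score over time, which makes
    frequencies commensurate before averaging (with
    ``zscore_per_frequency=False`` only the temporal mean of log power is
    removed per frequency).  Half of the longest wavelet's support is
    trimmed from both ends before normalization, then power is sampled at
    10 ms hops (100 Hz).
    """
    if rec.fs_hz < 2.5 * band_hz[1]:
        raise ValueError(f"fs {rec.fs_hz} Hz too low for a {band_hz[1]} Hz carrier band")
    if rec.duration_s < 10.0:
        raise ValueError("recording shorter than 10 s; filter edges would dominate")
    freqs = morlet_frequencies(band_hz, n_freqs)
    # longest wavelet support (lowest frequency): n_cycles / f seconds
    trim = int(round(0.5 * n_cycles / freqs[0] * rec.fs_hz))
    hop = rec.fs_hz / bha_fs_hz
    n_full = rec.n_samples
    out_idx = np.round(np.arange(trim, n_full - trim, hop)).astype(int)
    t0 = out_idx[0]

    bha = np.zeros((rec.n_channels, out_idx.size))
    for i in range(rec.n_channels):  # per channel to bound memory
        power = tfr_array_morlet(
            rec.samples[i][None, None, :],
            sfreq=rec.fs_hz,
            freqs=freqs,
            n_cycles=n_cycles,
            output="power",
            verbose="error",
        )[0, 0]  # freqs x time
        logp = np.log10(power[:, out_idx] + 1e-300)
        if zscore_per_frequency:
            logp -= logp.mean(axis=1, keepdims=True)
            logp /= logp.std(axis=1, keepdims=True)
        else:
            logp -= logp.mean(axis=1, keepdims=True)
        bha[i] = logp.mean(axis=0)

    return BhaSeries(
        data=bha,
        fs_hz=bha_fs_hz,
        channel_names=rec.channel_names,
        band="raw",
        condition=rec.condition,
        patient_id=rec.patient_id,
    )


def bandpass_slow(
    bha: BhaSeries, band_hz: tuple[float, float] = SLOW_BAND_HZ
) -> BhaSeries:
    """Retain the slow (0.1–1 Hz) fluctuations of BHA.

    Zero-phase third-order Butterworth band-pass; warns when the series is
    shorter than six time constants of the low corner (< 60 s at 0.1 Hz),
    where edge transients bias the estimate.
    """
    n = bha.data.shape[1]
    if n / bha.fs_hz < 6.0 / band_hz[0]:
        logger.warning(
            "BHA duration %.1f s is short for a %.2f Hz corner; edge effects likely",
            n / bha.fs_hz, band_hz[0],
        )
    sos = signal.butter(3, band_hz, btype="bandpass", output="sos", fs=bha.fs_hz)
    out = signal.sosfiltfilt(sos, bha.data, axis=-1)
    return replace(bha, data=out, band="slow", channel_names=list(bha.channel_names))


def fc_matrix(bha_slow: BhaSeries) -> FcMatrix:
    """Pearson correlation of slow BHA between every channel pair.

    Zero-variance channels get NaN correlations (logged); the diagonal is 1.
    """
    if bha_slow.band != "slow":
        raise ValueError("fc_matrix expects slow-band BHA (run bandpass_slow first)")
    if bha_slow.n_channels < 2:
        raise ValueError("need >= 2 channels for a correlation matrix")
    sd = bha_slow.data.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(bha_slow.data)
    for i in dead:
        logger.warning("channel %s has zero variance; correlations set missing",
                       bha_slow.channel_names[i])
        r[i, :] = np.nan
        r[:, i] = np.nan
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return FcMatrix(
        values=(r + r.T) / 2,
        channel_names=list(bha_slow.channel_names),
        condition=bha_slow.condition,
        patient_id=bha_slow.patient_id,
    )
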