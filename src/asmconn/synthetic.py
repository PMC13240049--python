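"""Synthetic two-condition iEEG sessions with known ground truth.

Patient stimulation and resting-state recordings from epilepsy monitoring
units are restricted data, so every downstream stage of this package is
exercised against simulated sessions that emulate their structure:

* stimulation sessions — 1 Hz pulse trains, each pulse evoking a
  cortico-cortical evoked potential (CCEP) at distant channels with an early
  negative N1 deflection (10–30 ms) and a late negative N2 deflection
  (85–250 ms), embedded in pink + white noise, mains interference and a
  brief stimulation artifact;
* resting-state sessions — broadband 70–200 Hz carrier noise whose amplitude
  envelope fluctuates slowly (0.1–1 Hz) with a specified cross-channel
  correlation structure, the substrate of the functional-connectivity
  estimate.

Condition-dependent effects (anti-seizure-medication ON vs OFF) are injected
as amplitude/latency shifts on chosen stimulation→recording pairs and are
recorded in a ground-truth table, so detection sensitivity and false-positive
rates can be measured exactly.

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import ChannelInfo, Recording

ASM_ON = "ASM-ON"
ASM_OFF = "ASM-OFF"


def derive_seed(master_seed: int, *parts: object) -> int:
    """Deterministic per-session seed from a master seed and labels.

    Uses SHA-256 (not Python's ``hash``) so the derivation is stable across
    interpreter runs and platforms.
    """
    key = ":".join([str(master_seed), *map(str, parts)])
    return int.from_bytes(hashlib.sha256(key.encode()).digest()[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# CCEP kernel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CcepKernelSpec:
    """Parameters of one evoked-response kernel: two negative Gaussian bumps.

    Latencies are constrained to the windows in which the components are
    defined: N1 in [10, 30] ms, N2 in [85, 250] ms.  Widths are Gaussian
    standard deviations in ms; amplitudes are the (non-negative) peak depths
    in µV of the negative-going deflections.
    """

    n1_latency_ms: float = 20.0
    n1_amplitude_uv: float = 100.0
    n1_width_ms: float = 4.0
    n2_latency_ms: float = 150.0
    n2_amplitude_uv: float = 40.0
    n2_width_ms: float = 25.0

    def __post_init__(self) -> None:
        if not 10.0 <= self.n1_latency_ms <= 30.0:
            raise ValueError(f"n1_latency_ms must be in [10, 30], got {self.n1_latency_ms}")
        if not 85.0 <= self.n2_latency_ms <= 250.0:
            raise ValueError(f"n2_latency_ms must be in [85, 250], got {self.n2_latency_ms}")
        if self.n1_width_ms <= 0 or self.n2_width_ms <= 0:
            raise ValueError("widths must be > 0")
        if self.n1_amplitude_uv < 0 or self.n2_amplitude_uv < 0:
            raise ValueError("amplitudes must be >= 0")


def make_ccep_kernel(spec: CcepKernelSpec, fs_hz: float, duration_ms: float) -> np.ndarray:
    """Evaluate the kernel waveform on a sample grid starting at t = 0.

    ``waveform(t) = −A1·exp(−(t−l1)²/2σ1²) − A2·exp(−(t−l2)²/2σ2²)``; both
    deflections are negative-going, matching the surface-negative N1/N2
    convention.  Deterministic; no noise.
    """
    if duration_ms < spec.n2_latency_ms + 3 * spec.n2_width_ms:
        raise ValueError(
            "duration_ms must cover the N2 bump: need >= "
            f"{spec.n2_latency_ms + 3 * spec.n2_width_ms} ms, got {duration_ms}"
        )
    t = np.arange(int(round(duration_ms * fs_hz / 1000.0))) * 1000.0 / fs_hz
    w = -spec.n1_amplitude_uv * np.exp(-0.5 * ((t - spec.n1_latency_ms) / spec.n1_width_ms) ** 2)
    w -= spec.n2_amplitude_uv * np.exp(-0.5 * ((t - spec.n2_latency_ms) / spec.n2_width_ms) ** 2)
    return w


# ---------------------------------------------------------------------------
# Stimulation sessions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionEffect:
    """Medication-state effect applied to a (stim pair, recording channel).

    ``delta_amplitude_frac`` is the fractional amplitude change in the
    ASM-OFF condition relative to ASM-ON (−0.3 means OFF amplitude is 30%
    lower); ``delta_latency_ms`` shifts the component latency in OFF.
    ``components`` selects which deflections the effect touches.
    """

    delta_amplitude_frac: float = 0.0
    delta_latency_ms: float = 0.0
    components: tuple[str, ...] = ("n1",)


@dataclass
class StimSessionConfig:
    """Configuration of one single-pulse-stimulation session.

    Pulses are delivered at 1 Hz in trains of 30–120 pulses per stimulated
    pair.  ``kernels`` maps (stim pair name, recording channel name) to the
    evoked kernel at that channel; channels without an entry receive no
    evoked response.  ``condition_effects`` maps the same keys to the
    ASM-OFF modification of that kernel.
    """

    channels: list[ChannelInfo]
    stim_pairs: list[str]
    kernels: Mapping[tuple[str, str], CcepKernelSpec]
    condition_effects: Mapping[tuple[str, str], ConditionEffect] = field(default_factory=dict)
    pulses_per_train: int = 60
    pulse_rate_hz: float = 1.0
    fs_hz: float = 1024.0
    noise_sd_uv: float = 20.0
    line_noise_amp_uv: float = 10.0
    artifact_amp_uv: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 30 <= self.pulses_per_train <= 120:
            raise ValueError("pulses_per_train must be in [30, 120]")
        if self.fs_hz < 1000:
            raise ValueError("fs_hz must be >= 1000 for stimulation sessions")
        names = {c.name for c in self.channels}
        for pair in self.stim_pairs:
            a, b = pair.split("-")
            if a not in names or b not in names:
                raise ValueError(f"stim pair {pair!r} references unknown channels")


def _pink_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    fs_hz: float = 1.0,
    min_freq_hz: float | None = None,
) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping of white noise.

    ``min_freq_hz`` flattens the spectrum below that frequency, emulating the
    hardware high-pass of clinical amplifiers that removes electrode drift.
    """
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(shape[-1], d=1.0 / fs_hz)
    floor = min_freq_hz if min_freq_hz else f[1] if f.size > 1 else 1.0
    scale = 1.0 / np.sqrt(np.maximum(f, floor))
    scale[0] = 0.0
    if min_freq_hz:  # roll off the sub-floor band like a first-order high-pass
        low = f < min_freq_hz
        scale[low] *= (f[low] / min_freq_hz) ** 2
    pink = np.fft.irfft(spec * scale, n=shape[-1], axis=-1)
    return pink / pink.std(axis=-1, keepdims=True)


def _effective_spec(
    base: CcepKernelSpec, eff: ConditionEffect | None, condition: str
) -> CcepKernelSpec:
    if eff is None or condition != ASM_OFF:
        return base
    kw: dict[str, float] = {}
    if "n1" in eff.components:
        kw["n1_amplitude_uv"] = base.n1_amplitude_uv * (1 + eff.delta_amplitude_frac)
        kw["n1_latency_ms"] = base.n1_latency_ms + eff.delta_latency_ms
    if "n2" in eff.components:
        kw["n2_amplitude_uv"] = base.n2_amplitude_uv * (1 + eff.delta_amplitude_frac)
        kw["n2_latency_ms"] = base.n2_latency_ms + eff.delta_latency_ms
    return replace(base, **kw)


def gen_stim_session(
    cfg: StimSessionConfig, condition: str
) -> tuple[Recording, dict[str, list[int]], pd.DataFrame]:
    """Simulate one stimulation session.

    One pulse train per stimulated pair, trains concatenated in time with
    2 s guard intervals.  Each channel receives, per pulse, its kernel for
    the active pair (if any) plus pink background noise, white sensor noise,
    a 60 Hz mains sinusoid with 120/180 Hz harmonics, and a two-sample
    biphasic stimulation artifact at pulse onset.  Condition effects are
    applied only in the ASM-OFF condition.

    Returns the recording, per-pair pulse-onset sample indices, and the
    ground-truth table of the kernel parameters actually used (one row per
    stim pair × recording channel × component).
    """
    if condition not in (ASM_ON, ASM_OFF):
        raise ValueError(f"condition must be {ASM_ON!r} or {ASM_OFF!r}")
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs_hz
    spacing = int(round(fs / cfg.pulse_rate_hz))
    guard = int(round(2.0 * fs))
    train_len = cfg.pulses_per_train * spacing
    n_total = guard + len(cfg.stim_pairs) * (train_len + guard)
    n_ch = len(cfg.channels)
    name_to_idx = {c.name: i for i, c in enumerate(cfg.channels)}

    data = cfg.noise_sd_uv * _pink_noise(
        rng, (n_ch, n_total), fs_hz=fs, min_freq_hz=cfg.pulse_rate_hz
    )
    data += 0.3 * cfg.noise_sd_uv * rng.standard_normal((n_ch, n_total))
    t = np.arange(n_total) / fs
    phases = rng.uniform(0, 2 * np.pi, size=(n_ch, 3))
    for h, (f0, rel) in enumerate(((60.0, 1.0), (120.0, 0.4), (180.0, 0.2))):
        data += (
            cfg.line_noise_amp_uv
            * rel
            * np.sin(2 * np.pi * f0 * t[None, :] + phases[:, h : h + 1])
        )

    kern_dur_ms = 400.0
    onsets: dict[str, list[int]] = {}
    truth_rows: list[dict[str, object]] = []
    start = guard
    for pair in cfg.stim_pairs:
        pair_onsets = [start + k * spacing for k in range(cfg.pulses_per_train)]
        onsets[pair] = pair_onsets
        stim_contacts = set(pair.split("-"))
        for ch in cfg.channels:
            key = (pair, ch.name)
            base = cfg.kernels.get(key)
            if base is not None and ch.name not in stim_contacts:
                spec = _effective_spec(base, cfg.condition_effects.get(key), condition)
                kern = make_ccep_kernel(spec, fs, kern_dur_ms)
                ci = name_to_idx[ch.name]
                for on in pair_onsets:
                    stop = min(on + kern.size, n_total)
                    data[ci, on:stop] += kern[: stop - on]
                for comp, lat, amp in (
                    ("n1", spec.n1_latency_ms, spec.n1_amplitude_uv),
                    ("n2", spec.n2_latency_ms, spec.n2_amplitude_uv),
                ):
                    truth_rows.append(
                        {
                            "stim_pair": pair,
                            "rec_channel": ch.name,
                            "condition": condition,
                            "component": comp,
                            "latency_ms": lat,
                            "amplitude_uv": amp,
                            "has_effect": key in cfg.condition_effects
                            and comp in cfg.condition_effects[key].components,
                        }
                    )
            # stimulation artifact: biphasic 2-sample spike on every channel
            for on in pair_onsets:
                if on + 1 < n_total:
                    data[name_to_idx[ch.name], on] += cfg.artifact_amp_uv
                    data[name_to_idx[ch.name], on + 1] -= cfg.artifact_amp_uv
        start += train_len + guard

    rec = Recording(
        samples=data, fs_hz=fs, channels=list(cfg.channels), condition=condition
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "stim_pair", "rec_channel", "condition", "component",
            "latency_ms", "amplitude_uv", "has_effect",
        ],
    )
    return rec, onsets, truth


# ---------------------------------------------------------------------------
# Resting-state sessions
# ---------------------------------------------------------------------------

@dataclass
class RestSessionConfig:
    """Configuration of one resting-state session.

    ``target_fc`` is the desired cross-channel correlation matrix of the
    slow (0.1–1 Hz) fluctuations of broadband high-frequency amplitude; it
    must be symmetric positive semidefinite with unit diagonal.
    ``modulation_depth`` scales how strongly the slow latent signal
    modulates the 70–200 Hz carrier amplitude.
    """

    n_channels: int
    duration_s: float = 600.0
    fs_hz: float = 500.0
    target_fc: np.ndarray | None = None
    modulation_depth: float = 0.5
    carrier_band_hz: tuple[float, float] = (70.0, 200.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_fc is None:
            self.target_fc = np.eye(self.n_channels)
        self.target_fc = np.asarray(self.target_fc, dtype=float)
        C = self.target_fc
        if C.shape != (self.n_channels, self.n_channels):
            raise ValueError("target_fc shape must be n_channels x n_channels")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("target_fc must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-10):
            raise ValueError("target_fc diagonal must be 1")
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise ValueError("target_fc must be positive semidefinite")
        if self.fs_hz <= 2 * self.carrier_band_hz[1]:
            raise ValueError("fs_hz must exceed twice the carrier band upper edge")


def gen_rest_session(
    cfg: RestSessionConfig,
    condition: str = ASM_ON,
    channels: list[ChannelInfo] | None = None,
    patient_id: str = "P0",
) -> Recording:
    """Simulate a resting-state session with a prescribed slow-envelope FC.

    Correlated latent signals are drawn from N(0, target_fc), band-limited to
    0.1–1 Hz (zero-phase Butterworth) and re-standardised; each channel is
    carrier-band (70–200 Hz) noise amplitude-modulated by
    ``1 + depth·latent`` plus a weak broadband background.  The Pearson
    correlation of the channels' slow high-frequency-amplitude envelopes
    then approximates ``target_fc``.
    """
    if condition not in (ASM_ON, ASM_OFF):
        raise ValueError(f"condition must be {ASM_ON!r} or {ASM_OFF!r}")
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs_hz))
    n_ch = cfg.n_channels

    # latent slow signals at full rate, correlated via Cholesky-like factor
    w, V = np.linalg.eigh(cfg.target_fc)
    L = V * np.sqrt(np.clip(w, 0, None))
    latent = L @ rng.standard_normal((n_ch, n))
    sos_slow = signal.butter(3, (0.1, 1.0), btype="bandpass", output="sos", fs=cfg.fs_hz)
    latent = signal.sosfiltfilt(sos_slow, latent, axis=-1)
    latent /= latent.std(axis=-1, keepdims=True)

    sos_car = signal.butter(
        4, cfg.carrier_band_hz, btype="bandpass", output="sos", fs=cfg.fs_hz
    )
    carrier = signal.sosfiltfilt(sos_car, rng.standard_normal((n_ch, n)), axis=-1)
    carrier /= carrier.std(axis=-1, keepdims=True)

    data = carrier * (1.0 + cfg.modulation_depth * latent)
    data += 0.3 * _pink_noise(rng, (n_ch, n), fs_hz=cfg.fs_hz, min_freq_hz=1.0)
    data *= 20.0  # µV scale

    if channels is None:
        channels = [
            ChannelInfo(name=f"R{i + 1}", shaft="R", contact_index=i + 1)
            for i in range(n_ch)
        ]
    return Recording(
        samples=data, fs_hz=cfg.fs_hz, channels=channels,
        patient_id=patient_id, condition=condition,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class PatientConfig:
    """Per-patient layout: channels with zone labels, stimulated pairs, effects."""

    patient_id: str
    channels: list[ChannelInfo]
    stim_pairs: list[str]
    kernels: Mapping[tuple[str, str], CcepKernelSpec]
    condition_effects: Mapping[tuple[str, str], ConditionEffect] = field(default_factory=dict)
    pulses_per_train: int = 60
    stim_fs_hz: float = 1024.0
    noise_sd_uv: float = 20.0
    rest: RestSessionConfig | None = None

    def __post_init__(self) -> None:
        zones = {c.zone for c in self.channels}
        if len(zones) < 2:
            raise ValueError("each patient needs channels covering >= 2 zone classes")


@dataclass
class PatientBundle:
    """All sessions of one simulated patient, both conditions."""

    patient_id: str
    stim: dict[str, tuple[Recording, dict[str, list[int]], pd.DataFrame]]
    rest: dict[str, Recording]


def gen_cohort(patients: Sequence[PatientConfig], master_seed: int = 0) -> list[PatientBundle]:
    """Simulate a cohort: per patient, ASM-ON and ASM-OFF stimulation (and,
    where configured, resting-state) sessions.

    Per-session seeds are derived deterministically from the master seed and
    the (patient, session) labels, so the cohort is reproducible and any
    single session can be regenerated in isolation.  The stimulation noise
    seed is shared between a patient's ON and OFF sessions' configs only via
    derivation — the two conditions get independent noise.
    """
    if not patients:
        raise ValueError("cohort config is empty")
    bundles: list[PatientBundle] = []
    for p in patients:
        stim_sessions = {}
        for cond in (ASM_ON, ASM_OFF):
            cfg = StimSessionConfig(
                channels=list(p.channels),
                stim_pairs=list(p.stim_pairs),
                kernels=p.kernels,
                condition_effects=p.condition_effects,
                pulses_per_train=p.pulses_per_train,
                fs_hz=p.stim_fs_hz,
                noise_sd_uv=p.noise_sd_uv,
                seed=derive_seed(master_seed, p.patient_id, "stim", cond),
            )
            stim_sessions[cond] = gen_stim_session(cfg, cond)
        rest_sessions: dict[str, Recording] = {}
        if p.rest is not None:
            for cond in (ASM_ON, ASM_OFF):
                rcfg = replace(
                    p.rest, seed=derive_seed(master_seed, p.patient_id, "rest", cond)
                )
                rest_sessions[cond] = gen_rest_session(
                    rcfg, cond, patient_id=p.patient_id
                )
        bundles.append(
            PatientBundle(patient_id=p.patient_id, stim=stim_sessions, rest=rest_sessions)
        )
    return bundles


def default_kernel_grid(
    channels: Iterable[ChannelInfo],
    stim_pairs: Iterable[str],
    rng: np.random.Generator,
    amplitude_uv: float = 100.0,
) -> dict[tuple[str, str], CcepKernelSpec]:
    """Convenience: one jittered kernel per (pair, channel), skipping stim contacts."""
    kernels: dict[tuple[str, str], CcepKernelSpec] = {}
    for pair in stim_pairs:
        contacts = set(pair.split("-"))
        for ch in channels:
            if ch.name in contacts:
                continue
            kernels[(pair, ch.name)] = CcepKernelSpec(
                n1_latency_ms=float(rng.uniform(14, 26)),
                n1_amplitude_uv=float(amplitude_uv * rng.uniform(0.7, 1.3)),
                n1_width_ms=4.0,
                n2_latency_ms=float(rng.uniform(110, 200)),
                n2_amplitude_uv=float(0.4 * amplitude_uv * rng.uniform(0.7, 1.3)),
                n2_width_ms=25.0,
            )
    return kernels
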