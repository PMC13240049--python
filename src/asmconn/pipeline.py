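"""End-to-end orchestration: simulate → preprocess → features → stats → report.

A :class:`RunConfig` (round-trippable to YAML) fully determines a run; every
stochastic step has an explicit seed, so re-running from the written
manifest reproduces the result bundle byte for byte.

The bundle written to the output directory contains tidy CSVs (trial
features, RMS, per-pair permutation results, regression grid, FC matrices,
graph metrics), the 4×4 zone-summary matrices per measure and direction,
and a JSON manifest recording seeds, parameters and stage status.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bha import bandpass_slow, compute_bha, fc_matrix
from .ccep import extract_features
from .graphs import build_adjacency, compute_graph_metrics
from .preprocess import (
    ZONES,
    ChannelInfo,
    Recording,
    bipolar_reference,
    common_average_reference,
    epoch_and_baseline,
    notch_filter,
    read_channel_metadata,
    read_edf,
    read_onsets_json,
)
from .stats import (
    BONFERRONI_ALPHA,
    ccep_permutation_tests,
    fc_perm_test_maxstat,
    rms_regression,
    wilcoxon_signed_rank,
    zone_summary,
)
from .synthetic import (
    ASM_OFF,
    ASM_ON,
    ConditionEffect,
    PatientConfig,
    RestSessionConfig,
    default_kernel_grid,
    derive_seed,
    gen_cohort,
)

logger = logging.getLogger("asmconn")

ALL_STAGES = ("simulate", "preprocess", "ccep", "fc", "graph", "stats", "report")


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(RuntimeError):
    """Missing or malformed input data (CLI exit code 3)."""


@dataclass
class SimulateConfig:
    """Synthetic-cohort parameters for ``mode="simulate"``."""

    n_patients: int = 2
    n_channels: int = 12
    n_stim_pairs: int = 2
    pulses_per_train: int = 60
    stim_fs_hz: float = 1024.0
    noise_sd_uv: float = 20.0
    kernel_amplitude_uv: float = 100.0
    effect_fraction: float = -0.3
    n_effect_pairs: int = 2
    rest_duration_s: float = 300.0
    rest_fs_hz: float = 500.0
    rest_target_r: float = 0.6
    modulation_depth: float = 0.5
    zone_proportions: dict = field(
        default_factory=lambda: {"SOZ": 0.25, "EPZ": 0.25, "IZ": 0.25, "NIZ": 0.25}
    )


@dataclass
class EdfInput:
    """One imported session: EDF path, metadata TSV, optional onsets JSON."""

    edf_path: str
    metadata_tsv: str
    condition: str
    patient_id: str
    onsets_json: str | None = None


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; round-trips losslessly to YAML."""

    mode: str = "simulate"  # "simulate" | "edf"
    output_dir: str = "results"
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    edf_inputs: list[EdfInput] = field(default_factory=list)
    n_perm_trials: int = 5000
    n_perm_fc: int = 10000
    fc_block_s: float = 60.0
    min_trials: int = 10
    fdr_q: float = 0.05
    bonferroni_alpha: float = BONFERRONI_ALPHA
    ccep_reference: str = "none"  # "none" | "bipolar" for the CCEP branch
    n_graph_null: int = 20
    stages: tuple[str, ...] = ALL_STAGES

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            d = yaml.safe_load(Path(path).read_text())
        except FileNotFoundError:
            raise ConfigError(f"config file not found: {path}") from None
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulate" in d and isinstance(d["simulate"], dict):
            d["simulate"] = SimulateConfig(**d["simulate"])
        if "edf_inputs" in d:
            d["edf_inputs"] = [
                EdfInput(**e) if isinstance(e, dict) else e for e in d["edf_inputs"]
            ]
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.mode not in ("simulate", "edf"):
            raise ConfigError(f"mode must be 'simulate' or 'edf', got {cfg.mode!r}")
        bad = set(cfg.stages) - set(ALL_STAGES)
        if bad:
            raise ConfigError(f"unknown stages: {sorted(bad)}")
        return cfg


# ---------------------------------------------------------------------------
# Simulation setup
# ---------------------------------------------------------------------------

def build_patient_configs(cfg: RunConfig) -> list[PatientConfig]:
    """Materialize per-patient synthetic configurations from a run config."""
    sim = cfg.simulate
    zones: list[str] = []
    counts = {z: int(round(sim.zone_proportions.get(z, 0) * sim.n_channels)) for z in ZONES}
    # pad/trim with NIZ so counts sum to n_channels
    while sum(counts.values()) < sim.n_channels:
        counts["NIZ"] += 1
    while sum(counts.values()) > sim.n_channels:
        for z in ("NIZ", "IZ", "EPZ", "SOZ"):
            if counts[z] > 0 and sum(counts.values()) > sim.n_channels:
                counts[z] -= 1
    for z in ZONES:
        zones += [z] * counts[z]

    patients = []
    for pi in range(sim.n_patients):
        pid = f"SIM{pi + 1:02d}"
        rng = np.random.default_rng(derive_seed(cfg.seed, pid, "layout"))
        channels = [
            ChannelInfo(name=f"C{i + 1}", shaft="S", contact_index=i + 1, zone=zones[i])
            for i in range(sim.n_channels)
        ]
        soz = [c.name for c in channels if c.zone == "SOZ"]
        stim_sources = (soz + [c.name for c in channels])[: sim.n_stim_pairs]
        stim_pairs = []
        for s in stim_sources:
            i = next(i for i, c in enumerate(channels) if c.name == s)
            j = i + 1 if i + 1 < len(channels) else i - 1
            stim_pairs.append(f"{channels[i].name}-{channels[j].name}")
        stim_pairs = list(dict.fromkeys(stim_pairs))
        kernels = default_kernel_grid(
            channels, stim_pairs, rng, amplitude_uv=sim.kernel_amplitude_uv
        )
        # injected ASM-OFF effects on SOZ->SOZ-ish pairs, recorded as truth
        effects = {}
        soz_keys = [
            k for k in kernels
            if channels[[c.name for c in channels].index(k[1])].zone == "SOZ"
        ]
        for k in soz_keys[: sim.n_effect_pairs]:
            effects[k] = ConditionEffect(
                delta_amplitude_frac=sim.effect_fraction, components=("n1",)
            )
        target = np.eye(sim.n_channels)
        if sim.n_channels >= 2 and sim.rest_target_r:
            target[0, 1] = target[1, 0] = sim.rest_target_r
        patients.append(
            PatientConfig(
                patient_id=pid,
                channels=channels,
                stim_pairs=stim_pairs,
                kernels=kernels,
                condition_effects=effects,
                pulses_per_train=sim.pulses_per_train,
                stim_fs_hz=sim.stim_fs_hz,
                noise_sd_uv=sim.noise_sd_uv,
                rest=RestSessionConfig(
                    n_channels=sim.n_channels,
                    duration_s=sim.rest_duration_s,
                    fs_hz=sim.rest_fs_hz,
                    target_fc=target,
                    modulation_depth=sim.modulation_depth,
                ),
            )
        )
    return patients


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _preprocess_stim(rec: Recording, onsets: dict[str, list[int]], cfg: RunConfig, pid: str):
    rec = dataclasses.replace(rec, patient_id=pid, channels=list(rec.channels))
    rec = notch_filter(rec)
    if cfg.ccep_reference == "bipolar":
        rec = bipolar_reference(rec)
    epochs = {}
    for pair, ons in onsets.items():
        epochs[pair] = epoch_and_baseline(rec, ons, stim_pair=pair)
    return epochs


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and write the result bundle.

    Returns the manifest dictionary.  A stage failure is recorded in the
    manifest and later stages that depend on it are skipped.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "mode": cfg.mode,
        "stages": {},
        "patients": [],
        "n_sessions": 0,
    }
    cfg.to_yaml(out / "config.yaml")
    state: dict = {}

    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        t0 = time.monotonic()
        try:
            _STAGE_FUNCS[stage](cfg, state, out, manifest)
            manifest["stages"][stage] = {
                "status": "ok", "seconds": round(time.monotonic() - t0, 3),
            }
        except _SkippedStage as exc:
            manifest["stages"][stage] = {"status": "skipped", "reason": str(exc)}
        except Exception as exc:
            logger.error("stage %s failed: %s", stage, exc)
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            break
        logger.info("stage %s: %s", stage, manifest["stages"][stage])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


class _SkippedStage(Exception):
    pass


def _stage_simulate(cfg: RunConfig, state: dict, out: Path, manifest: dict) -> None:
    if cfg.mode != "simulate":
        raise _SkippedStage("EDF mode: nothing to simulate")
    patients = build_patient_configs(cfg)
    bundles = gen_cohort(patients, master_seed=cfg.seed)
    state["bundles"] = bundles
    state["zone_of"] = {
        (b.patient_id, c.name): c.zone
        for b, p in zip(bundles, patients)
        for c in p.channels
    }
    manifest["patients"] = [b.patient_id for b in bundles]
    manifest["n_sessions"] = sum(
        len(b.stim) + len(b.rest) for b in bundles
    )


def _stage_preprocess(cfg: RunConfig, state: dict, out: Path, manifest: dict) -> None:
    epochs_all = []
    if cfg.mode == "simulate":
        if "bundles" not in state:
            raise _SkippedStage("no simulated data")
        for b in state["bundles"]:
            for cond, (rec, onsets, _truth) in b.stim.items():
                epochs_all.extend(
                    _preprocess_stim(rec, onsets, cfg, b.patient_id).values()
                )
    else:
        zone_of = {}
        bundles_rest: dict[tuple[str, str], Recording] = {}
        for inp in cfg.edf_inputs:
            meta = read_channel_metadata(inp.metadata_tsv)
            rec = read_edf(inp.edf_path, meta, patient_id=inp.patient_id,
                           condition=inp.condition)
            for c in meta:
                zone_of[(inp.patient_id, c.name)] = c.zone
            if inp.onsets_json:
                onsets = read_onsets_json(inp.onsets_json)
                epochs_all.extend(
                    _preprocess_stim(rec, onsets, cfg, inp.patient_id).values()
                )
            else:
                bundles_rest[(inp.patient_id, inp.condition)] = rec
        state["zone_of"] = zone_of
        state["edf_rest"] = bundles_rest
    state["epochs"] = epochs_all


def _stage_ccep(cfg: RunConfig, state: dict, out: Path, manifest: dict) -> None:
    if not state.get("epochs"):
        raise _SkippedStage("no stimulation epochs")
    tf_parts, rms_parts = [], []
    for ep in state["epochs"]:
        tf, rms = extract_features(ep)
        tf_parts.append(tf)
        rms_parts.append(rms)
    trial_features = pd.concat(tf_parts, ignore_index=True)
    rms_table = pd.concat(rms_parts, ignore_index=True)
    trial_features.to_csv(out / "trial_features.csv", index=False)
    rms_table.to_csv(out / "rms_table.csv", index=False)
    state["trial_features"] = trial_features
    state["rms_table"] = rms_table


def _rest_fc(cfg: RunConfig, state: dict):
    """Slow-BHA series and FC matrices per (patient, condition)."""
    sessions: dict[tuple[str, str], Recording] = {}
    if cfg.mode == "simulate":
        for b in state.get("bundles", []):
            for cond, rec in b.rest.items():
                sessions[(b.patient_id, cond)] = rec
    else:
        sessions = state.get("edf_rest", {})
    slow, fcs = {}, {}
    for (pid, cond), rec in sessions.items():
        car = common_average_reference(
            rec,
            exclude=[c.name for c in rec.channels if c.zone in ("SOZ", "EPZ") or c.bad]
            if sum(c.zone not in ("SOZ", "EPZ") and not c.bad for c in rec.channels) >= 2
            else [],
        )
        s = bandpass_slow(compute_bha(car))
        s.patient_id, s.condition = pid, cond
        slow[(pid, cond)] = s
        fcs[(pid, cond)] = fc_matrix(s)
    return slow, fcs


def _stage_fc(cfg: RunConfig, state: dict, out: Path, manifest: dict) -> None:
    slow, fcs = _rest_fc(cfg, state)
    if not fcs:
        raise _SkippedStage("no resting-state sessions")
    for (pid, cond), fc in sorted(fcs.items()):
        df = pd.DataFrame(fc.values, index=fc.channel_names, columns=fc.channel_names)
        df.to_csv(out / f"fc_{pid}_{cond}.csv")
    state["bha_slow"] = slow
    state["fc"] = fcs


def _stage_graph(cfg: RunConfig, state: dict, out: Path, manifest: dict) -> None:
    fcs = state.get("fc")
    if not fcs:
        raise _SkippedStage("no FC matrices")
    node_rows, graph_rows = [], []
    state["graph_node"] = {}
    pids = sorted({pid for pid, _ in fcs})
    for pid in pids:
        if (pid, ASM_ON) not in fcs or (pid, ASM_OFF) not in fcs:
            continue
        adj_on, adj_off = build_adjacency(fcs[(pid, ASM_ON)], fcs[(pid, ASM_OFF)])
        for adj in (adj_on, adj_off):
            res = compute_graph_metrics(
                adj, seed=derive_seed(cfg.seed, pid, adj.condition, "graph"),
                n_null=cfg.n_graph_null,
            )
            state["graph_node"][(pid, adj.condition)] = res
            for i, name in enumerate(res.channel_names):
                node_rows.append(
                    {
                        "patient": pid, "condition": adj.condition, "node": name,
                        "degree": int(res.degree[i]),
                        "strength": res.strength[i],
                        "clustering": res.clustering[i],
                        "local_efficiency": res.local_efficiency[i],
                    }
                )
            graph_rows.append(
                {
                    "patient": pid, "condition": adj.condition,
                    "path_length": res.path_length, "modularity": res.modularity,
                    "global_efficiency": res.global_efficiency,
                    "small_worldness": res.small_worldness,
                    "connected": res.connected, "threshold": adj.threshold,
                }
            )
    pd.DataFrame(node_rows).to_csv(out / "graph_node_metrics.csv", index=False)
    pd.DataFrame(graph_rows).to_csv(out / "graph_global_metrics.csv", index=False)


def _stage_stats(cfg: RunConfig, state: dict, out: Path, manifest: dict) -> None:
    zone_of = state.get("zone_of", {})
    did_something = False
    # --- CCEP branch ------------------------------------------------------
    if state.get("trial_features") is not None and len(state["trial_features"]):
        tf = state["trial_features"]
        results = ccep_permutation_tests(
            tf, n_perm=cfg.n_perm_trials, seed=cfg.seed,
            min_trials=cfg.min_trials, q=cfg.fdr_q,
        )
        results.to_csv(out / "ccep_perm_results.csv", index=False)

        def pair_zone(pid: str, pair: str) -> str:
            zones = [zone_of.get((pid, c), "NIZ") for c in pair.split("-")]
            order = {"SOZ": 0, "EPZ": 1, "IZ": 2, "NIZ": 3}
            return min(zones, key=lambda z: order[z])

        stim_zone = {
            (p, s): pair_zone(p, s)
            for p, s in results[["patient", "stim_pair"]].drop_duplicates().itertuples(index=False)
        }
        rec_zone = {
            (p, c): zone_of.get((p, c), "NIZ")
            for p, c in results[["patient", "rec_channel"]].drop_duplicates().itertuples(index=False)
        }
        zs = zone_summary(results, stim_zone, rec_zone)
        zs.to_csv(out / "zone_summary.csv", index=False)
        state["zone_summary"] = zs

        rms = state["rms_table"].melt(
            id_vars=["patient", "stim_pair", "rec_channel", "condition"],
            value_vars=["rms_10_300", "rms_10_50", "rms_50_300"],
            var_name="window", value_name="rms",
        )
        rms["stim_zone"] = [
            pair_zone(p, s) for p, s in zip(rms["patient"], rms["stim_pair"])
        ]
        rms["rec_zone"] = [
            zone_of.get((p, c), "NIZ")
            for p, c in zip(rms["patient"], rms["rec_channel"])
        ]
        reg = rms_regression(rms, alpha=cfg.bonferroni_alpha)
        reg.to_csv(out / "rms_regression.csv", index=False)
        state["rms_regression"] = reg
        did_something = True
    # --- FC branch --------------------------------------------------------
    if state.get("bha_slow"):
        slow = state["bha_slow"]
        fc_rows = []
        pids = sorted({pid for pid, _ in slow})
        for pid in pids:
            if (pid, ASM_ON) not in slow or (pid, ASM_OFF) not in slow:
                continue
            res = fc_perm_test_maxstat(
                slow[(pid, ASM_ON)], slow[(pid, ASM_OFF)],
                n_perm=cfg.n_perm_fc, block_s=cfg.fc_block_s,
                seed=derive_seed(cfg.seed, pid, "fcperm"),
            )
            iu = np.triu_indices(len(res.channel_names), k=1)
            for i, j in zip(*iu):
                fc_rows.append(
                    {
                        "patient": pid,
                        "ch_a": res.channel_names[i], "ch_b": res.channel_names[j],
                        "t_observed": res.t_observed[i, j],
                        "threshold": res.threshold,
                        "significant": bool(res.significant[i, j]),
                    }
                )
        pd.DataFrame(fc_rows).to_csv(out / "fc_perm_results.csv", index=False)
        did_something = True
    # --- node-metric Wilcoxon --------------------------------------------
    if state.get("graph_node"):
        gn = state["graph_node"]
        wil_rows = []
        for pid in sorted({pid for pid, _ in gn}):
            if (pid, ASM_ON) not in gn or (pid, ASM_OFF) not in gn:
                continue
            r_on, r_off = gn[(pid, ASM_ON)], gn[(pid, ASM_OFF)]
            for metric in ("degree", "strength", "clustering", "local_efficiency"):
                p, degen = wilcoxon_signed_rank(
                    getattr(r_on, metric).astype(float),
                    getattr(r_off, metric).astype(float),
                )
                wil_rows.append(
                    {"patient": pid, "metric": metric, "p": p,
                     "degenerate": degen, "significant": bool(p < 0.05)}
                )
        pd.DataFrame(wil_rows).to_csv(out / "graph_wilcoxon.csv", index=False)
        did_something = True
    if not did_something:
        raise _SkippedStage("no upstream results to test")


def _stage_report(cfg: RunConfig, state: dict, out: Path, manifest: dict) -> None:
    write_matrix_report(
        state.get("zone_summary"), state.get("rms_regression"), out / "report"
    )


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "ccep": _stage_ccep,
    "fc": _stage_fc,
    "graph": _stage_graph,
    "stats": _stage_stats,
    "report": _stage_report,
}


def write_matrix_report(
    zone_sum: pd.DataFrame | None,
    regression: pd.DataFrame | None,
    out_dir: str | Path,
) -> list[Path]:
    """Write the 4×4 zone-percentage matrices and the 3×16 regression grid.

    One CSV per measure × direction holds the stim-zone (columns) ×
    rec-zone (rows) percentage matrix with a parallel ``*_flags`` CSV; the
    regression grid CSV always has 48 rows with skipped tests marked.
    Empty inputs produce headers-only files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if zone_sum is not None and len(zone_sum):
        for (measure, direction), g in zone_sum.groupby(["measure", "direction"]):
            mat = g.pivot(index="rec_zone", columns="stim_zone",
                          values="percent_significant").reindex(index=ZONES, columns=ZONES)
            flags = g.pivot(index="rec_zone", columns="stim_zone",
                            values="flagged").reindex(index=ZONES, columns=ZONES)
            p = out_dir / f"zone_{measure}_{direction}.csv"
            mat.to_csv(p)
            flags.to_csv(out_dir / f"zone_{measure}_{direction}_flags.csv")
            written.append(p)
    else:
        p = out_dir / "zone_summary_empty.csv"
        pd.DataFrame(
            columns=["measure", "direction", "stim_zone", "rec_zone",
                     "percent_significant", "flagged"]
        ).to_csv(p, index=False)
        written.append(p)
    p = out_dir / "regression_grid.csv"
    if regression is not None and len(regression):
        regression.to_csv(p, index=False)
    else:
        pd.DataFrame(
            columns=["window", "stim_zone", "rec_zone", "n_obs", "coef_state",
                     "p", "significant", "status"]
        ).to_csv(p, index=False)
    written.append(p)
    return written
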