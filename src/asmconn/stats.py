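"""Inference procedures for the medication-state contrasts.

Three bespoke procedures plus the paired nonparametric comparison:

* trial-label permutation test per stimulation→recording pair and CCEP
  measure (mean OFF − ON difference, 5000 label shuffles, add-one empirical
  two-sided p), Benjamini–Hochberg FDR per measure across all pairs, and
  zone-pair summarization of the significant fractions (cells above 5% are
  flagged as exceeding chance at q = 0.05);
* per-(window, zone-pair) linear regression of averaged-response RMS on
  medication state with a categorical patient term,
  ``RMS ~ StateASM + PatientID`` (OFF = 0, ON = 1), Bonferroni-corrected at
  α = 0.05/48 for 3 windows × 16 zone pairs;
* max-statistic permutation test on the functional-connectivity contrast
  |r_ON − r_OFF| per channel pair, with the family-wise threshold at the
  99th percentile of the max-over-pairs null distribution built by swapping
  time blocks between sessions;
* Wilcoxon signed-rank tests for paired per-node graph-metric comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .bha import BhaSeries
from .preprocess import ZONES

logger = logging.getLogger("asmconn")

N_PERM_TRIALS = 5000
N_PERM_FC = 10000
MIN_TRIALS = 10
FDR_Q = 0.05
ZONE_FLAG_PERCENT = 5.0
#: 3 RMS windows x 16 stim-zone -> rec-zone combinations.
N_RMS_TESTS = 48
BONFERRONI_ALPHA = 0.05 / N_RMS_TESTS

CCEP_MEASURES = ("n1_latency_ms", "n1_amplitude_uv", "n2_latency_ms", "n2_amplitude_uv")


# ---------------------------------------------------------------------------
# Trial-label permutation test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationResult:
    """Outcome of one two-sided permutation test."""

    t_observed: float
    p: float
    n_perm: int
    direction: str  # "increase" / "decrease" / "none": sign of OFF − ON

    def __post_init__(self) -> None:
        assert 1.0 / (self.n_perm + 1) - 1e-12 <= self.p <= 1.0


def empirical_p(t_obs: float, t_perm: np.ndarray) -> float:
    """Add-one empirical two-sided p: (1 + #{|T_perm| ≥ |T_obs|}) / (1 + n_perm).

    The add-one correction keeps p strictly positive, its floor being
    1/(n_perm + 1).
    """
    t_perm = np.asarray(t_perm, float)
    if t_perm.size == 0:
        raise ValueError("empty permutation sample")
    return float((1 + np.sum(np.abs(t_perm) >= np.abs(t_obs))) / (1 + t_perm.size))


def perm_test_trials(
    vals_on: np.ndarray,
    vals_off: np.ndarray,
    n_perm: int = N_PERM_TRIALS,
    seed: int = 0,
    min_trials: int = MIN_TRIALS,
) -> PermutationResult | None:
    """Two-sided trial-label permutation test of mean(OFF) − mean(ON).

    Missing values are dropped; pairs with fewer than ``min_trials`` valid
    values in either condition are skipped (returns None, logged).  The null
    is built by shuffling the pooled values between conditions preserving
    group sizes.
    """
    on = np.asarray(vals_on, float)
    off = np.asarray(vals_off, float)
    on, off = on[~np.isnan(on)], off[~np.isnan(off)]
    if on.size < min_trials or off.size < min_trials:
        logger.info("pair skipped: %d/%d valid trials < %d", on.size, off.size, min_trials)
        return None
    pooled = np.concatenate([off, on])
    n_off = off.size
    t_obs = off.mean() - on.mean()
    rng = np.random.default_rng(seed)
    # row-wise random permutations via argsort of uniforms
    order = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
    perm_vals = pooled[order]
    t_perm = perm_vals[:, :n_off].mean(axis=1) - perm_vals[:, n_off:].mean(axis=1)
    p = empirical_p(t_obs, t_perm)
    direction = "none" if t_obs == 0 else ("increase" if t_obs > 0 else "decrease")
    return PermutationResult(t_observed=float(t_obs), p=p, n_perm=n_perm, direction=direction)


def bh_fdr(p_values: np.ndarray, q: float = FDR_Q) -> np.ndarray:
    """Benjamini–Hochberg step-up significance mask at FDR level ``q``."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def ccep_permutation_tests(
    trial_features: pd.DataFrame,
    n_perm: int = N_PERM_TRIALS,
    seed: int = 0,
    min_trials: int = MIN_TRIALS,
    q: float = FDR_Q,
) -> pd.DataFrame:
    """Permutation tests for every (patient, stim pair, channel, measure).

    ``trial_features`` is the tidy per-trial table from feature extraction
    with both conditions present.  FDR correction is applied separately per
    measure, pooling pairs across patients.  Returns one row per tested
    pair × measure with t_observed, p, direction and the FDR mask.
    """
    rows: list[dict] = []
    keys = ["patient", "stim_pair", "rec_channel"]
    for gi, ((patient, pair, ch), g) in enumerate(trial_features.groupby(keys, sort=True)):
        g_on = g[g["condition"] == "ASM-ON"]
        g_off = g[g["condition"] == "ASM-OFF"]
        for mi, measure in enumerate(CCEP_MEASURES):
            res = perm_test_trials(
                g_on[measure].to_numpy(),
                g_off[measure].to_numpy(),
                n_perm=n_perm,
                seed=(seed + 1_000_003 * gi + mi) % (2**31),
                min_trials=min_trials,
            )
            if res is None:
                continue
            rows.append(
                {
                    "patient": patient, "stim_pair": pair, "rec_channel": ch,
                    "measure": measure, "t_observed": res.t_observed,
                    "p": res.p, "direction": res.direction,
                }
            )
    results = pd.DataFrame(
        rows, columns=["patient", "stim_pair", "rec_channel", "measure",
                       "t_observed", "p", "direction"],
    )
    results["significant"] = False
    for measure in CCEP_MEASURES:
        m = results["measure"] == measure
        if m.any():
            results.loc[m, "significant"] = bh_fdr(results.loc[m, "p"].to_numpy(), q=q)
    return results


def zone_summary(
    results: pd.DataFrame,
    stim_zone: pd.Series | dict,
    rec_zone: pd.Series | dict,
    flag_percent: float = ZONE_FLAG_PERCENT,
) -> pd.DataFrame:
    """Summarize significant pairs per stim-zone × rec-zone cell and direction.

    ``stim_zone`` / ``rec_zone`` map (patient, stim_pair) and
    (patient, rec_channel) — or plain stim_pair / rec_channel names — to
    zone labels.  Each cell holds 100 × significant/tested for that zone
    combination, split by direction of the observed change; cells strictly
    above ``flag_percent`` are flagged.  Zone combinations with no tested
    pair are reported as missing (NaN), not as 0.
    """
    df = results.copy()

    def _lookup(mapping, patient, key):
        if isinstance(mapping, dict):
            return mapping.get((patient, key), mapping.get(key))
        return mapping.loc[(patient, key)]

    df["stim_zone"] = [
        _lookup(stim_zone, p, s) for p, s in zip(df["patient"], df["stim_pair"])
    ]
    df["rec_zone"] = [
        _lookup(rec_zone, p, c) for p, c in zip(df["patient"], df["rec_channel"])
    ]
    rows: list[dict] = []
    for measure, gm in df.groupby("measure"):
        for sz in ZONES:
            for rz in ZONES:
                cell = gm[(gm["stim_zone"] == sz) & (gm["rec_zone"] == rz)]
                n = len(cell)
                for direction in ("increase", "decrease"):
                    if n == 0:
                        pct = float("nan")
                    else:
                        n_sig = int(
                            (cell["significant"] & (cell["direction"] == direction)).sum()
                        )
                        pct = 100.0 * n_sig / n
                    rows.append(
                        {
                            "measure": measure, "stim_zone": sz, "rec_zone": rz,
                            "direction": direction, "n_tested": n,
                            "percent_significant": pct,
                            "flagged": bool(pct > flag_percent) if n else False,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RMS regression
# ---------------------------------------------------------------------------

def rms_regression(
    rms_long: pd.DataFrame,
    alpha: float = BONFERRONI_ALPHA,
) -> pd.DataFrame:
    """OLS of RMS on medication state per (window, stim zone → rec zone).

    ``rms_long`` needs columns patient, stim_zone, rec_zone, condition,
    window, rms.  The model is ``rms ~ StateASM + C(patient)`` with
    StateASM coded OFF = 0, ON = 1; the patient term is dropped (logged)
    when fewer than two patients contribute.  Cells with < 3 observations
    are skipped.  Exactly 48 rows (3 windows × 16 zone pairs) are returned,
    skipped cells marked ``status="skipped"``; a cell is significant iff the
    two-sided StateASM p-value is below ``alpha`` (default 0.05/48).
    """
    import statsmodels.formula.api as smf

    windows = sorted(rms_long["window"].unique())
    rows: list[dict] = []
    for window in windows:
        gw = rms_long[rms_long["window"] == window]
        for sz in ZONES:
            for rz in ZONES:
                cell = gw[(gw["stim_zone"] == sz) & (gw["rec_zone"] == rz)].copy()
                row = {
                    "window": window, "stim_zone": sz, "rec_zone": rz,
                    "n_obs": len(cell), "coef_state": float("nan"),
                    "p": float("nan"), "significant": False, "status": "ok",
                }
                if len(cell) < 3 or cell["condition"].nunique() < 2:
                    row["status"] = "skipped"
                    rows.append(row)
                    continue
                cell["StateASM"] = (cell["condition"] == "ASM-ON").astype(int)
                formula = "rms ~ StateASM"
                if cell["patient"].nunique() >= 2:
                    formula += " + C(patient)"
                else:
                    logger.info(
                        "%s %s->%s: single patient, PatientID term dropped",
                        window, sz, rz,
                    )
                try:
                    fit = smf.ols(formula, data=cell).fit()
                except Exception as exc:  # singular design
                    logger.warning("%s %s->%s: fit failed (%s)", window, sz, rz, exc)
                    row["status"] = "failed"
                    rows.append(row)
                    continue
                row["coef_state"] = float(fit.params.get("StateASM", np.nan))
                row["p"] = float(fit.pvalues.get("StateASM", np.nan))
                row["significant"] = bool(row["p"] < alpha)
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FC max-statistic permutation test
# ---------------------------------------------------------------------------

@dataclass
class FcPermResult:
    """Max-statistic permutation outcome for the FC contrast."""

    t_observed: np.ndarray  # channels x channels |r_ON − r_OFF|
    threshold: float  # 99th percentile of null max statistics
    significant: np.ndarray  # boolean channels x channels mask
    null_max: np.ndarray = field(repr=False, default=None)
    pair_thresholds: np.ndarray | None = field(repr=False, default=None)
    channel_names: list[str] = field(default_factory=list)


def _corr(x: np.ndarray) -> np.ndarray:
    r = np.corrcoef(x)
    np.fill_diagonal(r, 0.0)
    return r


def fc_perm_test_maxstat(
    bha_on: BhaSeries,
    bha_off: BhaSeries,
    n_perm: int = N_PERM_FC,
    block_s: float = 60.0,
    seed: int = 0,
    percentile: float = 99.0,
    guard_s: float = 5.0,
    keep_pair_null: bool = False,
) -> FcPermResult:
    """Family-wise-corrected permutation test of |r_ON − r_OFF| per channel pair.

    The observed statistic per pair is the absolute difference of the slow-BHA
    Pearson correlations between sessions.  The null shuffles session labels
    at the level of non-overlapping ``block_s``-second segments — swapping
    whole blocks preserves the within-session autocorrelation that
    sample-level shuffling would destroy — and recomputes both correlation
    matrices.  The first ``guard_s`` seconds of every block are excluded from
    the correlation computation (observed and permuted alike): without the
    guard, cross-boundary autocorrelation of the slow band inflates the
    observed statistic's variance relative to the block-shuffled null and
    the test runs slightly above its nominal level.  The family-wise
    threshold is the ``percentile``-th percentile of the max-over-pairs null
    distribution, realized through the add-one empirical-p rule so the level
    is exact at finite ``n_perm``; pairs with observed statistics above it
    are significant (p < 0.01 family-wise at the default).
    """
    if bha_on.channel_names != bha_off.channel_names:
        raise ValueError("sessions have different channel sets")
    x, y = bha_on.data, bha_off.data
    if x.shape[1] != y.shape[1]:
        n = min(x.shape[1], y.shape[1])
        logger.warning("sessions of unequal length; truncating to %d samples", n)
        x, y = x[:, :n], y[:, :n]
    n_samp = x.shape[1]
    block = int(round(block_s * bha_on.fs_hz))
    n_blocks = n_samp // block
    if n_blocks < 2:
        raise ValueError("sessions too short for block permutation")
    guard = min(int(round(guard_s * bha_on.fs_hz)), block // 2)
    keep = np.ones(n_blocks * block, dtype=bool)
    for b in range(n_blocks):
        keep[b * block : b * block + guard] = False
    x_b = x[:, : n_blocks * block].reshape(x.shape[0], n_blocks, block)
    y_b = y[:, : n_blocks * block].reshape(y.shape[0], n_blocks, block)

    t_obs = np.abs(_corr(x[:, : n_blocks * block][:, keep])
                   - _corr(y[:, : n_blocks * block][:, keep]))
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    pair_null = np.empty((n_perm,) + t_obs.shape) if keep_pair_null else None
    for k in range(n_perm):
        swap = rng.random(n_blocks) < 0.5
        xp = np.where(swap[None, :, None], y_b, x_b).reshape(x.shape[0], -1)
        yp = np.where(swap[None, :, None], x_b, y_b).reshape(y.shape[0], -1)
        t_k = np.abs(_corr(xp[:, keep]) - _corr(yp[:, keep]))
        null_max[k] = t_k.max()
        if pair_null is not None:
            pair_null[k] = t_k
    # add-one empirical threshold: a pair is significant iff
    # (1 + #{null_max >= T}) / (1 + n_perm) < 1 - percentile/100, i.e. iff T
    # exceeds the K-th largest null max with K = floor(alpha * (n_perm + 1)).
    # This keeps the family-wise level exact at finite n_perm, where the
    # plain interpolated percentile would be slightly anticonservative.
    alpha = 1.0 - percentile / 100.0
    k = max(1, int(np.floor(alpha * (n_perm + 1))))
    thr = float(np.sort(null_max)[-k])
    sig = t_obs > thr
    np.fill_diagonal(sig, False)
    pair_thr = (
        np.sort(pair_null, axis=0)[-k] if pair_null is not None else None
    )
    return FcPermResult(
        t_observed=t_obs,
        threshold=thr,
        significant=sig,
        null_max=null_max,
        pair_thresholds=pair_thr,
        channel_names=list(bha_on.channel_names),
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Two-sided Wilcoxon signed-rank p for paired samples.

    Zero differences are dropped first.  Uses the exact null distribution
    for n ≤ 25 remaining pairs and the normal approximation with continuity
    correction above.  If every difference is zero the test is undefined and
    ``(1.0, True)`` is returned, the flag marking degeneracy.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return 1.0, True
    method = "exact" if d.size <= 25 else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method, correction=True)
    return float(res.pvalue), False
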