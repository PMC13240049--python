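"""Inference procedures: permutation tests, FDR, regression, Wilcoxon."""

import itertools

import numpy as np
import pandas as pd
import pytest

from asmconn.bha import BhaSeries
from asmconn.stats import (
    bh_fdr,
    ccep_permutation_tests,
    empirical_p,
    fc_perm_test_maxstat,
    perm_test_trials,
    rms_regression,
    wilcoxon_signed_rank,
    zone_summary,
)


class TestEmpiricalP:
    def test_printed_formula(self):
        assert empirical_p(5.0, np.array([1, 2, 3, 6])) == pytest.approx(2 / 5)

    def test_zero_statistic_gives_one(self):
        assert empirical_p(0.0, np.array([0.1, -0.2, 0.0])) == 1.0

    def test_add_one_floor(self):
        perms = np.full(5000, 0.001)
        assert empirical_p(10.0, perms) == pytest.approx(1 / 5001)

    def test_never_zero_and_monotone(self):
        rng = np.random.default_rng(0)
        null = rng.standard_normal(500)
        ps = [empirical_p(t, null) for t in (0.0, 0.5, 1.0, 2.0, 5.0)]
        assert all(p > 0 for p in ps)
        assert ps == sorted(ps, reverse=True)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_p(1.0, np.array([]))


class TestPermTestTrials:
    def test_identical_groups_null(self):
        res = perm_test_trials(np.full(12, 7.0), np.full(12, 7.0), n_perm=200, seed=0)
        assert res.t_observed == 0.0 and res.p == 1.0 and res.direction == "none"

    def test_exhaustive_enumeration_oracle(self):
        # groups {0,0} vs {10,10}: of the C(4,2)=6 assignments, 2 give
        # |mean diff| = 10 and 4 give 0, so p → (1 + n·(2/6))/(1 + n) → 1/3
        on = np.array([0.0, 0.0])
        off = np.array([10.0, 10.0])
        pooled = np.concatenate([off, on])
        stats = []
        for pick in itertools.combinations(range(4), 2):
            grp_off = pooled[list(pick)]
            grp_on = pooled[[i for i in range(4) if i not in pick]]
            stats.append(abs(grp_off.mean() - grp_on.mean()))
        exact_frac = np.mean([s >= 10.0 for s in stats])
        assert exact_frac == pytest.approx(1 / 3)
        res = perm_test_trials(on, off, n_perm=20000, seed=1, min_trials=2)
        assert res.p == pytest.approx(1 / 3, abs=0.02)
        assert res.direction == "increase"

    def test_min_trials_skip(self):
        assert perm_test_trials(np.ones(3), np.ones(20), n_perm=10, seed=0) is None

    def test_missing_values_dropped(self):
        on = np.array([1.0, np.nan] * 10)
        off = np.array([1.0] * 10 + [np.nan] * 5)
        res = perm_test_trials(on, off, n_perm=100, seed=0)
        assert res is not None and res.t_observed == 0.0

    def test_type_one_error_rate(self):
        # 200 null pairs at alpha=0.05 uncorrected: rejection rate 5% +/- 2%
        rng = np.random.default_rng(2)
        rej = 0
        for _ in range(200):
            res = perm_test_trials(
                rng.standard_normal(30), rng.standard_normal(30),
                n_perm=500, seed=int(rng.integers(2**31)),
            )
            rej += res.p < 0.05
        assert 0.03 <= rej / 200 <= 0.07


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr(np.array([0.01])).tolist() == [True]
        assert bh_fdr(np.array([0.06])).tolist() == [False]

    def test_step_up_hand_oracle(self):
        p = np.array([0.01, 0.02, 0.03, 0.5])
        # thresholds i*q/m: 0.0125, 0.025, 0.0375, 0.05 → first three pass
        m = len(p)
        order = np.argsort(p)
        passed = np.flatnonzero(np.sort(p) <= (np.arange(1, m + 1) * 0.05 / m))
        expected = np.zeros(m, bool)
        if passed.size:
            expected[order[: passed.max() + 1]] = True
        assert expected.tolist() == [True, True, True, False]
        np.testing.assert_array_equal(bh_fdr(p), expected)

    def test_all_ones_none_significant(self):
        assert not bh_fdr(np.ones(10)).any()

    def test_empty_input(self):
        assert bh_fdr(np.array([])).size == 0

    def test_monotone_in_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 50)
        base = bh_fdr(p)
        p2 = p.copy()
        p2[base] = p2[base] / 2  # lowering significant ps
        after = bh_fdr(p2)
        assert (after[base]).all()  # nothing previously significant is lost

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))


class TestZoneSummary:
    def _results(self):
        rows = []
        for k in range(10):  # 10 SOZ->SOZ pairs, 2 significant increases
            rows.append({"patient": "P1", "stim_pair": "s", "rec_channel": f"r{k}",
                         "measure": "n1_amplitude_uv", "t_observed": 1.0,
                         "p": 0.01, "direction": "increase",
                         "significant": k < 2})
        return pd.DataFrame(rows)

    def test_percentage_and_flag(self):
        res = self._results()
        stim_zone = {("P1", "s"): "SOZ"}
        rec_zone = {("P1", f"r{k}"): "SOZ" for k in range(10)}
        zs = zone_summary(res, stim_zone, rec_zone)
        cell = zs.query(
            "stim_zone == 'SOZ' and rec_zone == 'SOZ' and direction == 'increase'"
        ).iloc[0]
        assert cell["percent_significant"] == pytest.approx(20.0)
        assert cell["flagged"]

    def test_untested_cells_missing_not_zero(self):
        res = self._results()
        zs = zone_summary(res, {("P1", "s"): "SOZ"},
                          {("P1", f"r{k}"): "SOZ" for k in range(10)})
        niz = zs.query("stim_zone == 'NIZ' and rec_zone == 'NIZ'")
        assert niz["percent_significant"].isna().all()
        assert not niz["flagged"].any()

    def test_flag_boundary_strictly_above_five(self):
        rows = []
        for k in range(1000):
            rows.append({"patient": "P1", "stim_pair": "s", "rec_channel": f"r{k}",
                         "measure": "m", "t_observed": 1.0, "p": 0.01,
                         "direction": "increase", "significant": k < 50})
        res = pd.DataFrame(rows)
        zs = zone_summary(res, {("P1", "s"): "SOZ"},
                          {("P1", f"r{k}"): "SOZ" for k in range(1000)})
        cell = zs.query("stim_zone=='SOZ' and rec_zone=='SOZ' and direction=='increase'").iloc[0]
        assert cell["percent_significant"] == pytest.approx(5.0)
        assert not cell["flagged"]  # exactly 5.0% is NOT flagged
        res.loc[res["rec_channel"] == "r50", "significant"] = True  # 5.1%
        zs2 = zone_summary(res, {("P1", "s"): "SOZ"},
                           {("P1", f"r{k}"): "SOZ" for k in range(1000)})
        assert zs2.query(
            "stim_zone=='SOZ' and rec_zone=='SOZ' and direction=='increase'"
        ).iloc[0]["flagged"]

    def test_no_significant_pairs_no_flags(self):
        res = self._results()
        res["significant"] = False
        zs = zone_summary(res, {("P1", "s"): "SOZ"},
                          {("P1", f"r{k}"): "SOZ" for k in range(10)})
        tested = zs[zs["n_tested"] > 0]
        assert (tested["percent_significant"] == 0).all()
        assert not zs["flagged"].any()


class TestRmsRegression:
    def _table(self, effect=0.0, noise=0.0, n_per=20, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for patient, offset in (("P1", 0.0), ("P2", 1.0)):
            for k in range(n_per):
                for cond, state in (("ASM-ON", 1), ("ASM-OFF", 0)):
                    rows.append({
                        "patient": patient, "stim_zone": "SOZ", "rec_zone": "SOZ",
                        "window": "rms_10_300", "condition": cond,
                        "rms": 5.0 + effect * state + offset + noise * rng.standard_normal(),
                    })
        return pd.DataFrame(rows)

    def test_null_effect(self):
        reg = rms_regression(self._table(effect=0.0, noise=0.0))
        cell = reg.query("stim_zone == 'SOZ' and rec_zone == 'SOZ'").iloc[0]
        assert cell["coef_state"] == pytest.approx(0.0, abs=1e-10)
        assert not cell["significant"]

    def test_effect_recovery(self):
        reg = rms_regression(self._table(effect=2.0, noise=0.5, n_per=10, seed=1))
        cell = reg.query("stim_zone == 'SOZ' and rec_zone == 'SOZ'").iloc[0]
        assert 1.5 <= cell["coef_state"] <= 2.5
        assert cell["significant"]

    def test_grid_has_48_rows(self):
        reg = rms_regression(self._table())
        assert len(reg) == 16  # one window present -> 16 zone pairs
        full = self._table()
        frames = [full]
        for w in ("rms_10_50", "rms_50_300"):
            f = full.copy()
            f["window"] = w
            frames.append(f)
        reg3 = rms_regression(pd.concat(frames, ignore_index=True))
        assert len(reg3) == 48
        assert (reg3.query("stim_zone != 'SOZ' or rec_zone != 'SOZ'")["status"]
                == "skipped").all()

    def test_bonferroni_threshold_matches_declared(self):
        from asmconn.stats import BONFERRONI_ALPHA

        assert BONFERRONI_ALPHA == 0.05 / 48
        assert round(BONFERRONI_ALPHA, 5) == 0.00104


class TestFcMaxStat:
    def _series(self, data, cond):
        return BhaSeries(data=data, fs_hz=100.0, band="slow", condition=cond,
                         channel_names=[f"c{i}" for i in range(data.shape[0])])

    def test_identical_sessions_nothing_significant(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((4, 18000))
        res = fc_perm_test_maxstat(self._series(x, "ASM-ON"),
                                   self._series(x.copy(), "ASM-OFF"),
                                   n_perm=100, seed=0)
        np.testing.assert_allclose(res.t_observed, 0.0, atol=1e-12)
        assert not res.significant.any()

    def test_unequal_lengths_truncated(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((3, 18000))
        y = rng.standard_normal((3, 24000))
        res = fc_perm_test_maxstat(self._series(x, "ASM-ON"),
                                   self._series(y, "ASM-OFF"),
                                   n_perm=50, seed=0)
        assert res.t_observed.shape == (3, 3)

    def test_maxstat_more_conservative_than_uncorrected(self):
        # the FWE-significant set is a subset of per-pair uncorrected calls
        rng = np.random.default_rng(6)
        x = rng.standard_normal((5, 24000))
        y = rng.standard_normal((5, 24000))
        y[0] += 0.5 * x[1]  # induce one genuine difference
        res = fc_perm_test_maxstat(self._series(x, "ASM-ON"),
                                   self._series(y, "ASM-OFF"),
                                   n_perm=200, seed=1, keep_pair_null=True)
        assert res.threshold >= res.pair_thresholds.max() - 1e-12
        uncorrected = res.t_observed > res.pair_thresholds
        assert (~res.significant | uncorrected).all()

    def test_too_short_sessions_rejected(self):
        x = np.zeros((2, 3000))
        with pytest.raises(ValueError):
            fc_perm_test_maxstat(self._series(x, "ASM-ON"),
                                 self._series(x, "ASM-OFF"), n_perm=10, seed=0)


class TestWilcoxon:
    def test_identical_pairs_degenerate(self):
        p, degen = wilcoxon_signed_rank(np.arange(8.0), np.arange(8.0))
        assert p == 1.0 and degen

    def test_exact_enumeration_oracle(self):
        # all 5 differences positive: enumerate the 2^5 sign patterns of the
        # signed-rank statistic; only the all-plus and all-minus patterns are
        # as extreme, so the exact two-sided p is 2/32
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        w_obs = x.sum()  # ranks 1..5 all positive
        count = 0
        for signs in itertools.product((0, 1), repeat=5):
            w_plus = sum(r for r, s in zip((1, 2, 3, 4, 5), signs) if s)
            if min(w_plus, 15 - w_plus) <= min(w_obs, 15 - w_obs):
                count += 1
        assert count / 32 == pytest.approx(0.0625)
        p, degen = wilcoxon_signed_rank(x + 10.0, np.full(5, 10.0))
        assert not degen
        assert p == pytest.approx(0.0625)

    def test_large_sample_type_one_error(self):
        rng = np.random.default_rng(7)
        rej = 0
        n_rep = 1000
        for _ in range(n_rep):
            x = rng.standard_normal(50)
            y = rng.standard_normal(50)
            p, _ = wilcoxon_signed_rank(x, y)
            rej += p < 0.05
        assert 0.03 <= rej / n_rep <= 0.07

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.ones(3), np.ones(4))


class TestCcepPermutationPipeline:
    def test_specificity_of_flagged_cells(self):
        # effects injected only on some channels; flags stay on those
        rng = np.random.default_rng(8)
        rows = []
        for pair_id in range(24):
            affected = pair_id < 6
            for cond in ("ASM-ON", "ASM-OFF"):
                shift = 3.0 if (affected and cond == "ASM-OFF") else 0.0
                for k in range(30):
                    base = {"patient": "P1", "stim_pair": "s",
                            "rec_channel": f"r{pair_id}", "condition": cond,
                            "trial": k}
                    for m in ("n1_latency_ms", "n1_amplitude_uv",
                              "n2_latency_ms", "n2_amplitude_uv"):
                        base[m] = rng.standard_normal() + (
                            shift if m == "n1_amplitude_uv" else 0.0
                        )
                    rows.append(base)
        tf = pd.DataFrame(rows)
        res = ccep_permutation_tests(tf, n_perm=500, seed=0)
        sig = res[res["significant"]]
        assert set(sig["rec_channel"]) <= {f"r{i}" for i in range(6)}
        assert (sig["measure"] == "n1_amplitude_uv").all()
        assert len(sig) >= 5
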