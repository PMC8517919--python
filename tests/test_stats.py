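"""Statistics tests: rank-sum oracle, BH, Spearman, battery structure."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from burstnet.stats import (bh_fdr, run_group_battery, spearman,
                            ttest_two_sided, wilcoxon_rank_sum)


def brute_force_ranksum_p(x, y):
    """Exact two-sided p by enumerating all rank assignments (tie-free)."""
    from scipy.stats import rankdata

    nx = len(x)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w_obs = ranks[:nx].sum()
    ws = [sum(c) for c in itertools.combinations(sorted(ranks), nx)]
    ws = np.asarray(ws)
    lo = np.mean(ws <= w_obs + 1e-9)
    hi = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


class TestRankSum:
    def test_worked_example(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_samples(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_symmetry_under_swap(self, rng):
        x = rng.standard_normal(8)
        y = rng.standard_normal(6) + 0.5
        _, p1 = wilcoxon_rank_sum(x, y)
        _, p2 = wilcoxon_rank_sum(y, x)
        assert p1 == pytest.approx(p2)

    def test_degenerate_all_identical(self):
        _, p = wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    @pytest.mark.parametrize("nx,ny,seed", [(3, 3, 0), (4, 5, 1), (6, 6, 2),
                                            (2, 9, 3), (5, 7, 4)])
    def test_exact_p_matches_enumeration(self, nx, ny, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(nx)
        y = rng.standard_normal(ny) + rng.uniform(-1, 1)
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(brute_force_ranksum_p(x, y), abs=1e-12)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1.0], [2.0, 3.0])


class TestBH:
    def test_worked_example_three_rejections(self):
        p_adj, rej = bh_fdr([0.01, 0.02, 0.03], q=0.05)
        assert rej.all()
        assert p_adj[2] == pytest.approx(0.03)

    def test_all_ones_none_rejected(self):
        _, rej = bh_fdr([1.0, 1.0, 1.0])
        assert not rej.any()

    def test_single_p(self):
        _, rej = bh_fdr([0.04], q=0.05)
        assert rej[0]
        _, rej = bh_fdr([0.06], q=0.05)
        assert not rej[0]

    def test_adjusted_monotone_in_sorted_order(self, rng):
        p = rng.uniform(0, 1, 20)
        p_adj, _ = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(p_adj[order]) >= -1e-12)

    def test_bonferroni_rejections_subset_of_bh(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 0.2, 10)
            q = 0.05
            p_adj, bh_rej = bh_fdr(p, q)
            bonf = p <= q / len(p)
            assert np.all(bh_rej[bonf])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([])


class TestSpearman:
    def test_monotone_limits(self):
        x = [1.0, 2.0, 3.0, 4.0]
        rho, _ = spearman(x, [2.0, 4.0, 6.0, 8.0])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman(x, [8.0, 6.0, 4.0, 2.0])
        assert rho == pytest.approx(-1.0)

    def test_worked_example_rho(self):
        # d^2 = (1, 1, 1, 1, 0): rho = 1 - 6*4/(5*24) = 0.8
        rho, p = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)
        # independent enumeration of the exact two-sided p at n = 5
        count = 0
        base = np.arange(5)
        for perm in itertools.permutations(range(5)):
            d2 = np.sum((base - np.array(perm)) ** 2)
            r = 1 - 6 * d2 / (5 * 24)
            count += abs(r) >= 0.8 - 1e-12
        assert p == pytest.approx(count / 120)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_ttest_convenience(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30) + 2.0
        _, p = ttest_two_sided(x, y)
        assert p < 1e-6


class TestBattery:
    def _table(self, rng, n=20, families=("resting_global",), effect=0.0):
        rows = []
        metrics = {"resting_global": ["burst_amplitude", "nonburst_amplitude",
                                      "total_burst_time"],
                   "connectivity_global": ["global_mean_connectivity"],
                   "task": [f"{c}:{m}" for c in ("L:lpress", "L:rpress",
                                                 "R:lpress", "R:rpress")
                            for m in ("pmbr_probability", "pmbr_amplitude",
                                      "modulation")]}
        for fam in families:
            for metric in metrics[fam]:
                for g, shift in (("control", effect), ("patient", 0.0)):
                    for i in range(n):
                        rows.append(dict(subject=f"{g}{i}", group=g,
                                         family=fam, metric=metric,
                                         value=rng.standard_normal() + shift))
        return pd.DataFrame(rows)

    def test_family_structure(self, rng):
        table = self._table(rng, families=("resting_global", "task",
                                           "connectivity_global"))
        comps, _ = run_group_battery(table)
        fams = pd.Series([c.family for c in comps]).value_counts()
        assert fams["resting_global"] == 3
        assert fams["task"] == 12
        assert fams["connectivity_global"] == 1
        for c in comps:
            assert c.p_adjusted >= c.p_raw - 1e-12

    def test_missing_cells_skipped(self, rng):
        table = self._table(rng)
        table = table[~((table.metric == "total_burst_time")
                        & (table.group == "patient"))]
        comps, _ = run_group_battery(table)
        assert len([c for c in comps if c.family == "resting_global"]) == 2

    def test_combined_spearman_flagged(self, rng):
        table = self._table(rng)
        sym = table[table.metric == "burst_amplitude"][
            ["subject", "group", "metric", "value"]].copy()
        sym["score"] = rng.uniform(0, 20, len(sym))
        _, corrs = run_group_battery(table, symptom_table=sym)
        combined = [c for c in corrs if c.scope == "combined"]
        assert combined and all("group difference" in c.note for c in combined)
        patients = [c for c in corrs if c.scope == "patients"]
        assert patients

    def test_null_task_battery_familywise_calibration(self):
        """Under the global null the 12-test family rarely rejects anything."""
        rng = np.random.default_rng(0)
        n_seeds, any_rej = 300, 0
        for _ in range(n_seeds):
            table = self._table(rng, n=20, families=("task",))
            comps, _ = run_group_battery(table)
            any_rej += any(c.rejected for c in comps)
        rate = any_rej / n_seeds
        # nominal 0.05 plus binomial 95% margin at 300 draws
        assert rate <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / n_seeds)

    def test_planted_effect_detected(self, rng):
        table = self._table(rng, effect=1.5)
        comps, _ = run_group_battery(table)
        amp = [c for c in comps if c.test == "burst_amplitude"][0]
        assert amp.rejected and amp.mean_control > amp.mean_patient
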