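"""Classification tests: rRF-FS behaviour, CV leakage, permutation logic."""

from __future__ import annotations

import numpy as np
import pytest

from burstnet.classify import (ClassifierConfig, FeatureTable,
                               interhemispheric_fraction, permutation_test,
                               rrf_select, selected_edge_report, svm_cv)
from burstnet.connectivity import connectome, global_mean_connectivity
from burstnet.containers import BurstTrain, Connectome


FAST = dict(n_trees=50, n_resamples=3, importance="impurity",
            max_recursion=4)


def _table(X, y):
    return FeatureTable(X=X, y=np.asarray(y),
                        feature_names=[f"f{i}" for i in range(X.shape[1])],
                        subject_ids=[f"s{i}" for i in range(X.shape[0])])


class TestRrfSelect:
    def test_perfect_feature_survives_every_recursion(self, rng):
        X = rng.standard_normal((24, 30))
        y = np.arange(24) % 2
        X[:, 7] = y
        cfg = ClassifierConfig(seed=0, **FAST)
        sel = rrf_select(X, y, cfg)
        assert 7 in sel

    def test_planted_informative_set_recovered(self, rng):
        X = rng.standard_normal((40, 120))
        y = np.arange(40) % 2
        planted = [3, 17, 40, 77, 111]
        for f in planted:
            X[:, f] += 2.5 * y          # single-feature AUC ~ 0.96
        cfg = ClassifierConfig(seed=1, **FAST)
        sel = set(rrf_select(X, y, cfg))
        assert len(sel.intersection(planted)) >= 4

    def test_deterministic_under_seed(self, rng):
        X = rng.standard_normal((20, 25))
        y = np.arange(20) % 2
        cfg = ClassifierConfig(seed=5, **FAST)
        np.testing.assert_array_equal(rrf_select(X, y, cfg),
                                      rrf_select(X, y, cfg))

    def test_too_few_subjects_rejected(self, rng):
        X = rng.standard_normal((3, 5))
        with pytest.raises(ValueError):
            rrf_select(X, np.array([0, 1, 1]), ClassifierConfig(**FAST))


class TestSvmCv:
    def test_perfect_feature_gives_auc_one(self, rng):
        X = rng.standard_normal((30, 40))
        y = np.arange(30) % 2
        X[:, 11] = y + 0.01 * rng.standard_normal(30)
        cfg = ClassifierConfig(n_folds=5, seed=0, **FAST)
        res = svm_cv(_table(X, y), cfg)
        assert res.mean_auc == 1.0
        assert len(res.fold_aucs) == 5

    def test_planted_subnetwork_high_auc(self, rng):
        hits = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.standard_normal((30, 100))
            y = np.arange(30) % 2
            X[:, :20] += 2.0 * y[:, None]
            cfg = ClassifierConfig(n_folds=5, seed=seed, **FAST)
            hits += svm_cv(_table(X, y), cfg).mean_auc > 0.9
        assert hits >= 4

    def test_fewer_subjects_than_folds_rejected(self, rng):
        X = rng.standard_normal((6, 5))
        y = np.arange(6) % 2
        with pytest.raises(ValueError):
            svm_cv(_table(X, y), ClassifierConfig(n_folds=10, **FAST))

    def test_selection_runs_inside_folds_only(self, rng, monkeypatch):
        """No held-out subject row ever reaches the selection call."""
        import burstnet.classify as mod

        X = rng.standard_normal((20, 15))
        y = np.arange(20) % 2
        seen = []
        orig = mod.rrf_select

        def spy(Xtr, ytr, cfg, seed=None):
            seen.append(np.asarray(Xtr).shape[0])
            return orig(Xtr, ytr, cfg, seed)

        monkeypatch.setattr(mod, "rrf_select", spy)
        cfg = ClassifierConfig(n_folds=5, seed=0, **FAST)
        svm_cv(_table(X, y), cfg)
        assert seen and all(n == 16 for n in seen)   # 4/5 of 20 subjects


class TestPermutation:
    def test_p_formula_and_floor(self, rng):
        X = rng.standard_normal((20, 30))
        y = np.arange(20) % 2
        X[:, 3] = y                          # observed AUC = 1
        cfg = ClassifierConfig(n_folds=4, seed=0, **FAST)
        res = permutation_test(_table(X, y), cfg, n_perm=10)
        assert res.permutation_p >= 1 / 11
        expected = (1 + np.sum(res.permutation_null >=
                               res.mean_auc - 1e-12)) / 11
        assert res.permutation_p == pytest.approx(expected)

    def test_strong_signal_beats_all_nulls(self, rng):
        X = rng.standard_normal((20, 20))
        y = np.arange(20) % 2
        X[:, 0] = y
        cfg = ClassifierConfig(n_folds=4, seed=0, **FAST)
        res = permutation_test(_table(X, y), cfg, n_perm=10)
        assert res.mean_auc == 1.0
        assert res.permutation_p == pytest.approx(1 / 11)


class TestReport:
    def _connectomes(self, rng, n=8):
        labels = ["Precentral_L", "Precentral_R", "Parietal_Sup_L",
                  "Parietal_Sup_R"]
        conns, groups, ids = [], [], []
        for i in range(n):
            J = rng.uniform(0, 1, (4, 4))
            J = (J + J.T) / 2
            np.fill_diagonal(J, 0)
            conns.append(Connectome(labels=labels, J=J))
            groups.append("patient" if i % 2 else "control")
            ids.append(f"s{i}")
        return conns, groups, ids

    def test_consensus_all_edges_equals_global_mean(self, rng):
        conns, groups, ids = self._connectomes(rng)
        ft = FeatureTable.from_connectomes(conns, groups, ids)
        from burstnet.classify import ClassificationResult
        res = ClassificationResult(
            fold_aucs=[1.0], mean_auc=1.0, sd_auc=0.0, fold_features=[],
            consensus_features=np.arange(ft.X.shape[1]))
        frame = selected_edge_report(res, ft)
        for i, c in enumerate(conns):
            assert frame.mean_selected_connectivity[i] == pytest.approx(
                global_mean_connectivity(c))

    def test_interhemispheric_bookkeeping(self):
        assert interhemispheric_fraction(
            ["Precentral_L--Precentral_R",
             "Parietal_Sup_L--Parietal_Sup_R"]) == 1.0
        assert interhemispheric_fraction(
            ["Precentral_L--Parietal_Sup_L"]) == 0.0

    def test_symptom_correlation_reported(self, rng):
        conns, groups, ids = self._connectomes(rng, n=12)
        ft = FeatureTable.from_connectomes(conns, groups, ids)
        from burstnet.classify import ClassificationResult
        res = ClassificationResult(
            fold_aucs=[1.0], mean_auc=1.0, sd_auc=0.0, fold_features=[],
            consensus_features=np.arange(ft.X.shape[1]))
        mean_conn = ft.X.mean(axis=1)
        scores = {sid: 20.0 - 10.0 * m + 0.01 * i
                  for i, (sid, m) in enumerate(zip(ids, mean_conn))}
        frame = selected_edge_report(res, ft, symptom_scores=scores)
        assert frame.attrs["spearman_patients"]["rho"] < 0
        assert frame.attrs["spearman_combined"]["rho"] < 0

    def test_empty_consensus_rejected(self, rng):
        conns, groups, ids = self._connectomes(rng)
        ft = FeatureTable.from_connectomes(conns, groups, ids)
        from burstnet.classify import ClassificationResult
        res = ClassificationResult(fold_aucs=[], mean_auc=0.5, sd_auc=0.0,
                                   fold_features=[],
                                   consensus_features=np.array([], dtype=int))
        with pytest.raises(ValueError, match="consensus"):
            selected_edge_report(res, ft)


def test_feature_table_from_connectomes_width(rng):
    trains = [BurstTrain(f"R{i:02d}", (rng.uniform(0, 1, 100) < 0.2
                                       ).astype(np.uint8), 100.0)
              for i in range(10)]
    c = connectome(trains)
    ft = FeatureTable.from_connectomes([c, c], ["patient", "control"],
                                       ["a", "b"])
    assert ft.X.shape == (2, 45)
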