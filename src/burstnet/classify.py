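"""Connectome classification: recursive random-forest feature selection
with consensus voting, linear-SVM cross-validation, and a label-permutation
significance test.

Each subject contributes the vectorized upper triangle of their burst-
coincidence connectome (R(R-1)/2 edge features). Feature selection runs
*inside* each training fold only, so no information from held-out subjects
leaks into the selected edge set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .containers import Connectome

logger = logging.getLogger(__name__)


@dataclass
class FeatureTable:
    """Subjects x edge-features matrix with labels and edge names."""

    X: np.ndarray
    y: np.ndarray                 # 1 = patient, 0 = control
    feature_names: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValueError("feature table shape mismatch")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("missing values in feature table")

    @classmethod
    def from_connectomes(cls, connectomes: list[Connectome],
                         groups: list[str],
                         subject_ids: list[str]) -> "FeatureTable":
        labels = connectomes[0].labels
        iu = np.triu_indices(len(labels), k=1)
        names = [f"{labels[i]}--{labels[j]}" for i, j in zip(*iu)]
        X = np.stack([c.J[iu] for c in connectomes])
        y = np.array([1 if g == "patient" else 0 for g in groups])
        return cls(X=X, y=y, feature_names=names, subject_ids=list(subject_ids))


@dataclass
class ClassifierConfig:
    """Constants of the rRF-FS + SVM pipeline (all exposed, all logged)."""

    n_folds: int = 10
    n_trees: int = 500
    importance: str = "permutation"      # or "impurity"
    importance_repeats: int = 5
    n_resamples: int = 10                # internal resamples for consensus
    resample_fraction: float = 0.8
    consensus_fraction: float = 0.5
    min_features: int = 5
    max_recursion: int = 10
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.importance not in ("permutation", "impurity"):
            raise ValueError("importance must be 'permutation' or 'impurity'")
        if not 0 < self.consensus_fraction <= 1:
            raise ValueError("consensus_fraction must lie in (0, 1]")


@dataclass
class ClassificationResult:
    """Cross-validated performance plus the per-fold and consensus features."""

    fold_aucs: list[float]
    mean_auc: float
    sd_auc: float
    fold_features: list[np.ndarray]
    consensus_features: np.ndarray
    permutation_null: np.ndarray | None = None
    permutation_p: float | None = None


def _importances(X: np.ndarray, y: np.ndarray, cfg: ClassifierConfig,
                 rng: np.random.Generator) -> np.ndarray:
    rf = RandomForestClassifier(n_estimators=cfg.n_trees,
                                random_state=int(rng.integers(2 ** 31)))
    rf.fit(X, y)
    if cfg.importance == "impurity":
        return rf.feature_importances_
    imp = permutation_importance(rf, X, y, n_repeats=cfg.importance_repeats,
                                 random_state=int(rng.integers(2 ** 31)))
    return imp.importances_mean


def _recursive_prune(X: np.ndarray, y: np.ndarray, cfg: ClassifierConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """One recursion chain: drop below-mean-importance features until stable."""
    keep = np.arange(X.shape[1])
    for _ in range(cfg.max_recursion):
        if len(keep) <= cfg.min_features:
            break
        imp = _importances(X[:, keep], y, cfg, rng)
        thr = imp.mean()
        survivors = keep[imp > thr]
        if len(survivors) < cfg.min_features:
            order = np.argsort(imp)[::-1]
            survivors = keep[np.sort(order[: cfg.min_features])]
        if len(survivors) == len(keep):
            break
        keep = survivors
    return keep


def rrf_select(X: np.ndarray, y: np.ndarray, cfg: ClassifierConfig,
               seed: int | None = None) -> np.ndarray:
    """Recursive random-forest feature selection with consensus voting.

    ``n_resamples`` stratified subsamples of the training data each run a
    recursive importance-pruning chain; the consensus set is the features
    kept in at least ``consensus_fraction`` of the chains. If the consensus
    is empty, falls back to the top ``min_features`` by vote count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    for cls in (0, 1):
        if (y == cls).sum() < 2:
            raise ValueError("need >= 2 subjects per class for selection")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    votes = np.zeros(X.shape[1])
    for _ in range(cfg.n_resamples):
        idx = []
        for cls in (0, 1):
            members = np.flatnonzero(y == cls)
            k = max(2, int(round(cfg.resample_fraction * len(members))))
            idx.append(rng.choice(members, size=min(k, len(members)),
                                  replace=False))
        idx = np.concatenate(idx)
        kept = _recursive_prune(X[idx], y[idx], cfg, rng)
        votes[kept] += 1
    consensus = np.flatnonzero(votes >= cfg.consensus_fraction * cfg.n_resamples)
    if consensus.size == 0:
        logger.info("rrf_select: empty consensus; falling back to top-%d by vote",
                    cfg.min_features)
        consensus = np.sort(np.argsort(votes)[::-1][: cfg.min_features])
    return consensus


def svm_cv(features: FeatureTable, cfg: ClassifierConfig | None = None,
           seed: int | None = None) -> ClassificationResult:
    """Stratified k-fold linear-SVM evaluation with in-fold rRF-FS.

    Feature selection and standardisation are fit on each training fold
    only; the ROC-AUC is computed on the held-out fold from the SVM
    decision function. The reported consensus set is the intersection-by-
    vote over folds (features selected in at least half the folds).
    """
    cfg = cfg or ClassifierConfig()
    seed = cfg.seed if seed is None else seed
    X, y = features.X, features.y
    if len(y) < cfg.n_folds:
        raise ValueError("fewer subjects than folds")
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=seed)
    ss = np.random.SeedSequence(seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                  ss.spawn(cfg.n_folds)]
    aucs: list[float] = []
    fold_feats: list[np.ndarray] = []
    votes = np.zeros(X.shape[1])
    for (train, test), fs in zip(skf.split(X, y), fold_seeds):
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            raise ValueError("a fold contains a single class")
        sel = rrf_select(X[train], y[train], cfg, seed=fs)
        votes[sel] += 1
        fold_feats.append(sel)
        scaler = StandardScaler().fit(X[np.ix_(train, sel)])
        clf = SVC(kernel="linear", C=cfg.svm_c)
        clf.fit(scaler.transform(X[np.ix_(train, sel)]), y[train])
        scores = clf.decision_function(scaler.transform(X[np.ix_(test, sel)]))
        aucs.append(float(roc_auc_score(y[test], scores)))
    consensus = np.flatnonzero(votes >= 0.5 * cfg.n_folds)
    if consensus.size == 0:
        consensus = np.sort(np.argsort(votes)[::-1][: cfg.min_features])
    return ClassificationResult(
        fold_aucs=aucs, mean_auc=float(np.mean(aucs)),
        sd_auc=float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
        fold_features=fold_feats, consensus_features=consensus)


def permutation_test(features: FeatureTable, cfg: ClassifierConfig | None = None,
                     n_perm: int = 100, seed: int | None = None
                     ) -> ClassificationResult:
    """Label-permutation significance test of the full CV pipeline.

    ``p = (1 + #{null AUC >= observed}) / (1 + n_perm)``; the whole
    pipeline (selection inside folds) is re-run for every permutation.
    """
    cfg = cfg or ClassifierConfig()
    seed = cfg.seed if seed is None else seed
    observed = svm_cv(features, cfg, seed=seed)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(features.y)
        perm_table = FeatureTable(X=features.X, y=y_perm,
                                  feature_names=features.feature_names,
                                  subject_ids=features.subject_ids)
        null[i] = svm_cv(perm_table, cfg,
                         seed=int(rng.integers(2 ** 31))).mean_auc
    p = (1 + int((null >= observed.mean_auc - 1e-12).sum())) / (1 + n_perm)
    observed.permutation_null = null
    observed.permutation_p = float(p)
    return observed


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _hemisphere(label: str) -> str | None:
    for suffix, h in (("_L", "L"), ("_R", "R")):
        if label.endswith(suffix):
            return h
    return None


def interhemispheric_fraction(edge_names: list[str]) -> float:
    """Fraction of edges connecting left- and right-hemisphere regions."""
    flags = []
    for name in edge_names:
        a, b = name.split("--")
        ha, hb = _hemisphere(a), _hemisphere(b)
        if ha and hb:
            flags.append(ha != hb)
    return float(np.mean(flags)) if flags else np.nan


def selected_edge_report(result: ClassificationResult, features: FeatureTable,
                         symptom_scores: dict[str, float] | None = None,
                         q: float = 0.05) -> pd.DataFrame:
    """Per-subject mean connectivity over the consensus edges, plus tests.

    Returns a tidy frame with one row per subject (subject, group,
    mean_selected_connectivity) and attaches, as frame attrs, the group
    rank-sum comparison, the patient-only and combined Spearman
    correlations with symptoms, and the interhemispheric fraction of the
    selected edges.
    """
    from .stats import spearman, wilcoxon_rank_sum

    sel = result.consensus_features
    if sel.size == 0:
        raise ValueError("empty consensus feature set")
    mean_conn = features.X[:, sel].mean(axis=1)
    groups = np.where(features.y == 1, "patient", "control")
    frame = pd.DataFrame(dict(subject=features.subject_ids, group=groups,
                              mean_selected_connectivity=mean_conn))
    W, p = wilcoxon_rank_sum(mean_conn[features.y == 1],
                             mean_conn[features.y == 0])
    frame.attrs["group_test"] = dict(statistic=W, p=p, rejected=p <= q)
    names = [features.feature_names[i] for i in sel]
    frame.attrs["selected_edges"] = names
    frame.attrs["interhemispheric_fraction"] = interhemispheric_fraction(names)
    if symptom_scores is not None:
        scores = np.array([symptom_scores[s] for s in features.subject_ids])
        pat = features.y == 1
        if pat.sum() >= 3:
            rho, pp = spearman(scores[pat], mean_conn[pat])
            frame.attrs["spearman_patients"] = dict(rho=rho, p=pp)
        rho, pp = spearman(scores, mean_conn)
        frame.attrs["spearman_combined"] = dict(
            rho=rho, p=pp,
            note="likely driven solely by a group difference")
    return frame
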