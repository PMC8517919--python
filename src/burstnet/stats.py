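"""Group statistics: rank-sum tests, FDR correction, Spearman correlations.

The battery mirrors the study design this pipeline serves: global resting
burst metrics compared between groups with a Wilcoxon rank-sum test and
Benjamini-Hochberg correction across the three measures; a 12-test task
battery (left/right cortex x left/right press x three metrics); a single
test on global connectivity; and Spearman correlations of MEG metrics
with symptom severity, reported separately for the patient group alone
and for the combined cohort (where a significant correlation is likely
driven solely by the group difference).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

EXACT_RANKSUM_MAX_N = 20
EXACT_SPEARMAN_MAX_N = 9


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when ``n_x + n_y <= 20`` and the data
    are tie-free, otherwise the normal approximation with tie and
    continuity corrections. Returns ``(W, p)`` where ``W`` is the rank sum
    of ``x``. Fully degenerate input (all values identical) yields p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    pooled = np.concatenate([x, y])
    W = float(sps.rankdata(pooled)[: len(x)].sum())
    if np.all(pooled == pooled[0]):
        logger.info("rank-sum: degenerate (all values identical); p = 1")
        return W, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = ("exact" if (len(pooled) <= EXACT_RANKSUM_MAX_N and not has_ties)
              else "asymptotic")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return W, float(res.pvalue)


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns ``(p_adjusted, rejected)``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, rejected


def _exact_spearman_p(rho: float, n: int) -> float:
    """Two-sided permutation p for Spearman rho by full enumeration."""
    base = np.arange(1, n + 1, dtype=float)
    denom = n * (n ** 2 - 1)
    count = 0
    total = 0
    target = abs(rho) - 1e-12
    for perm in itertools.permutations(range(n)):
        d2 = float(np.sum((base - base[list(perm)]) ** 2))
        r = 1.0 - 6.0 * d2 / denom
        if abs(r) >= target:
            count += 1
        total += 1
    return count / total


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    p is exact (full permutation enumeration) for tie-free samples with
    n <= 9, otherwise the t-approximation. Constant input raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    rho, p_t = sps.spearmanr(x, y)
    tie_free = (len(np.unique(x)) == n and len(np.unique(y)) == n)
    if tie_free and n <= EXACT_SPEARMAN_MAX_N:
        return float(rho), _exact_spearman_p(float(rho), n)
    return float(rho), float(p_t)


def ttest_two_sided(x, y) -> tuple[float, float]:
    """Convenience two-sided independent-samples T-test (demographics)."""
    res = sps.ttest_ind(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# battery
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """One group-comparison test with its family-corrected result."""

    family: str
    test: str
    n_patient: int
    n_control: int
    mean_patient: float
    mean_control: float
    sd_patient: float
    sd_control: float
    statistic: float
    p_raw: float
    p_adjusted: float = np.nan
    rejected: bool = False

    def as_dict(self) -> dict:
        return dict(family=self.family, test=self.test,
                    n_patient=self.n_patient, n_control=self.n_control,
                    mean_patient=self.mean_patient,
                    mean_control=self.mean_control,
                    sd_patient=self.sd_patient, sd_control=self.sd_control,
                    statistic=self.statistic, p_raw=self.p_raw,
                    p_adjusted=self.p_adjusted, rejected=bool(self.rejected))


@dataclass
class CorrelationResult:
    """One Spearman correlation (symptom severity vs an MEG metric)."""

    family: str
    test: str
    scope: str                   # "patients" or "combined"
    n: int
    rho: float
    p_raw: float
    p_adjusted: float = np.nan
    rejected: bool = False
    note: str = ""

    def as_dict(self) -> dict:
        return dict(family=self.family, test=self.test, scope=self.scope,
                    n=self.n, rho=self.rho, p_raw=self.p_raw,
                    p_adjusted=self.p_adjusted, rejected=bool(self.rejected),
                    note=self.note)


RESTING_GLOBAL_METRICS = ("burst_amplitude", "nonburst_amplitude",
                          "total_burst_time")
TASK_METRICS = ("pmbr_probability", "pmbr_amplitude", "modulation")
COMBINED_NOTE = ("combined-group correlation: a significant value is likely "
                 "driven solely by the group difference")


def _compare(values: pd.DataFrame, family: str, test: str) -> GroupComparison | None:
    pat = values.loc[values["group"] == "patient", "value"].to_numpy()
    ctl = values.loc[values["group"] == "control", "value"].to_numpy()
    pat = pat[np.isfinite(pat)]
    ctl = ctl[np.isfinite(ctl)]
    if len(pat) < 2 or len(ctl) < 2:
        logger.info("battery: skipping %s/%s (missing cells)", family, test)
        return None
    W, p = wilcoxon_rank_sum(pat, ctl)
    return GroupComparison(
        family=family, test=test, n_patient=len(pat), n_control=len(ctl),
        mean_patient=float(pat.mean()), mean_control=float(ctl.mean()),
        sd_patient=float(pat.std(ddof=1)), sd_control=float(ctl.std(ddof=1)),
        statistic=W, p_raw=p)


def _adjust(comps: list[GroupComparison], q: float) -> None:
    if not comps:
        return
    p_adj, rej = bh_fdr([c.p_raw for c in comps], q)
    for c, pa, r in zip(comps, p_adj, rej):
        c.p_adjusted = float(pa)
        c.rejected = bool(r)


def run_group_battery(table: pd.DataFrame, q: float = 0.05,
                      symptom_table: pd.DataFrame | None = None
                      ) -> tuple[list[GroupComparison], list[CorrelationResult]]:
    """Execute the full statistical battery on a tidy metric table.

    ``table`` columns: subject, group, family, metric, value. Families:

    - ``resting_global``: the three global burst metrics, BH-corrected
      across the three tests.
    - ``task``: up to 12 tests (cortex x press-side x metric), BH-corrected
      across the family.
    - ``connectivity_global``: a single uncorrected test.

    ``symptom_table`` (subject, group, metric, value, score) adds Spearman
    correlations per metric, patient-only and combined, BH-corrected within
    the patient-only family.
    """
    required = {"subject", "group", "family", "metric", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    comps: list[GroupComparison] = []

    fam = table[table["family"] == "resting_global"]
    family_tests = [c for m in RESTING_GLOBAL_METRICS
                    if (c := _compare(fam[fam["metric"] == m],
                                      "resting_global", m)) is not None]
    _adjust(family_tests, q)
    comps.extend(family_tests)

    fam = table[table["family"] == "task"]
    task_tests = []
    for metric in sorted(fam["metric"].unique()):
        c = _compare(fam[fam["metric"] == metric], "task", metric)
        if c is not None:
            task_tests.append(c)
    _adjust(task_tests, q)
    comps.extend(task_tests)

    fam = table[table["family"] == "connectivity_global"]
    for metric in sorted(fam["metric"].unique()):
        c = _compare(fam[fam["metric"] == metric], "connectivity_global", metric)
        if c is not None:
            c.p_adjusted = c.p_raw
            c.rejected = c.p_raw <= q
            comps.append(c)

    corrs: list[CorrelationResult] = []
    if symptom_table is not None:
        patient_corrs = []
        for metric in sorted(symptom_table["metric"].unique()):
            sub = symptom_table[symptom_table["metric"] == metric]
            pat = sub[sub["group"] == "patient"]
            if len(pat) >= 3:
                rho, p = spearman(pat["score"], pat["value"])
                patient_corrs.append(CorrelationResult(
                    family="symptoms", test=metric, scope="patients",
                    n=len(pat), rho=rho, p_raw=p))
            if len(sub) >= 3:
                rho, p = spearman(sub["score"], sub["value"])
                corrs.append(CorrelationResult(
                    family="symptoms", test=metric, scope="combined",
                    n=len(sub), rho=rho, p_raw=p, p_adjusted=p,
                    rejected=p <= q, note=COMBINED_NOTE))
        if patient_corrs:
            p_adj, rej = bh_fdr([c.p_raw for c in patient_corrs], q)
            for c, pa, r in zip(patient_corrs, p_adj, rej):
                c.p_adjusted = float(pa)
                c.rejected = bool(r)
        corrs = patient_corrs + corrs
    return comps, corrs


def battery_to_frame(comps: list[GroupComparison],
                     corrs: list[CorrelationResult] | None = None
                     ) -> pd.DataFrame:
    rows = [c.as_dict() for c in comps]
    if corrs:
        rows += [c.as_dict() for c in corrs]
    return pd.DataFrame(rows)
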