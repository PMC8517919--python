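"""End-to-end workflows tying the stages together.

``run_pipeline`` executes simulate -> condition -> HMM -> burst detection
-> (connectome | trial dynamics) -> statistics [-> classification] and
writes every artifact, stamped with the config hash, to a results
directory.
"""

from __future__ import annotations

import json
import logging

from pathlib import Path

import numpy as np
import pandas as pd

from . import bursts, connectivity, task
from .classify import FeatureTable, permutation_test, svm_cv
from .conditioning import condition
from .config import RunConfig
from .containers import RegionalRecording
from .hmm import fit as hmm_fit
from .io import (write_connectome_csv, write_courses_tsv, write_edges_tsv,
                 write_results_tsv, write_subject, write_summaries_tsv,
                 write_trains_tsv)
from .simulate import (attach_symptom_scores, sample_symptom_scores,
                       simulate_resting, simulate_task)
from .stats import battery_to_frame, run_group_battery

logger = logging.getLogger(__name__)


def analyse_subject(rec: RegionalRecording, cfg: RunConfig):
    """Condition one subject and run HMM burst detection on every region."""
    cond = cfg.conditioning
    out = condition(rec, cond.low_hz, cond.high_hz, cond.order,
                    cond.target_fs, cond.orthogonalize)
    trains, envs, summaries = [], [], []
    for r, label in enumerate(out.region_labels):
        post = hmm_fit(out.data[r], out.fs, cfg.hmm, epochs=out.epochs,
                       region_id=label)
        env = bursts.beta_envelope(out.data[r], out.fs, cfg.envelope.band,
                                   cfg.envelope.cycles,
                                   cfg.envelope.freq_step, region_id=label)
        train, _, _ = bursts.detect_bursts(post, env, cfg.burst_threshold,
                                           epochs=out.epochs)
        trains.append(train)
        envs.append(env)
        summaries.append(bursts.summarize(train, env))
    return out, trains, envs, summaries


def _resting_tables(recs, per_subject, cfg: RunConfig):
    metric_rows, conn_rows, connectomes = [], [], []
    for rec, (cond_rec, trains, envs, summaries) in zip(recs, per_subject):
        means, _ = bursts.global_collapse(summaries)
        for m in ("burst_amplitude", "nonburst_amplitude", "total_burst_time"):
            metric_rows.append(dict(subject=rec.subject_id, group=rec.group,
                                    family="resting_global", metric=m,
                                    value=means[m]))
        c = connectivity.connectome(trains, cond_rec.region_labels)
        connectomes.append(c)
        conn_rows.append(dict(subject=rec.subject_id, group=rec.group,
                              family="connectivity_global",
                              metric="global_mean_connectivity",
                              value=connectivity.global_mean_connectivity(c)))
    return pd.DataFrame(metric_rows + conn_rows), connectomes


def _task_tables(recs, per_subject, cfg: RunConfig):
    rows, course_rows = [], []
    motor = list(cfg.motor_regions)
    for rec, (cond_rec, trains, envs, _) in zip(recs, per_subject):
        idx = {lb: i for i, lb in enumerate(cond_rec.region_labels)}
        present = [m for m in motor if m in idx]
        if len(present) < 2:
            present = cond_rec.region_labels[:2]
        tensors = {}
        for lb in present:
            i = idx[lb]
            t = task.epoch_trials(trains[i], envs[i], cond_rec.events)
            tensors[lb] = t
            ws = task.window_burst_stats(t, cfg.windows)
            for m in ("pmbr_probability", "pmbr_amplitude", "modulation"):
                rows.append(dict(subject=rec.subject_id, group=rec.group,
                                 family="task", metric=f"{lb}:{m}",
                                 value=getattr(ws, m)))
            course = task.burst_probability_course(t)
            course_rows += [dict(subject=rec.subject_id, group=rec.group,
                                 region=lb, time_s=ts, value=v)
                            for ts, v in zip(t.trial_time_axis, course)]
        a, b = present[:2]
        rows.append(dict(subject=rec.subject_id, group=rec.group,
                         family="task",
                         metric=f"{a}--{b}:pmbr_coincidence",
                         value=task.window_coincidence(tensors[a], tensors[b],
                                                       cfg.windows.pmbr)))
    return pd.DataFrame(rows), pd.DataFrame(course_rows)


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Run a full workflow; returns a manifest of written artifacts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h = cfg.hash
    cfg.to_yaml(out_dir / "config.yaml")

    if cfg.workflow == "resting":
        recs, truth = simulate_resting(cfg.simulation, cfg.n_per_group)
    else:
        recs, truth = simulate_task(cfg.simulation, cfg.n_trials,
                                    cfg.n_per_group)
    scores = sample_symptom_scores(truth, slope=4.0, noise_sd=3.0,
                                   seed=cfg.seed + 1)
    recs = attach_symptom_scores(recs, scores)
    for rec in recs:
        write_subject(out_dir / f"subject_{rec.subject_id}.h5", rec, h)

    per_subject = [analyse_subject(rec, cfg) for rec in recs]

    summary_rows = [(rec.subject_id, rec.group, s)
                    for rec, (c, t, e, summaries) in zip(recs, per_subject)
                    for s in summaries]
    write_summaries_tsv(summary_rows, out_dir / "burst_metrics.tsv", h)
    for rec, (c, trains, e, s) in zip(recs, per_subject):
        write_trains_tsv(trains, out_dir / f"trains_{rec.subject_id}.tsv", h)

    manifest = dict(config_hash=h, out_dir=str(out_dir),
                    n_subjects=len(recs), workflow=cfg.workflow)

    if cfg.workflow == "resting":
        table, connectomes = _resting_tables(recs, per_subject, cfg)
        for rec, c in zip(recs, connectomes):
            write_connectome_csv(c, out_dir / f"connectome_{rec.subject_id}.csv", h)
        mean_c = connectivity.Connectome(
            labels=connectomes[0].labels,
            J=np.mean([c.J for c in connectomes], axis=0))
        write_edges_tsv(connectivity.top_fraction(mean_c, 0.05),
                        out_dir / "top_edges.tsv", h)
        score_map = {r.subject_id: r.symptom_score for r in recs}
        symptom_table = table[["subject", "group", "metric", "value"]].copy()
        symptom_table["score"] = symptom_table["subject"].map(score_map)
        comps, corrs = run_group_battery(table, cfg.stats.q, symptom_table)
        write_results_tsv(battery_to_frame(comps, corrs),
                          out_dir / "group_stats.tsv", h)
        manifest["n_tests"] = len(comps)
        if cfg.run_classification and len(recs) >= cfg.classifier.n_folds:
            ft = FeatureTable.from_connectomes(
                connectomes, [r.group for r in recs],
                [r.subject_id for r in recs])
            if cfg.n_permutations > 0:
                res = permutation_test(ft, cfg.classifier, cfg.n_permutations,
                                       seed=cfg.seed)
            else:
                res = svm_cv(ft, cfg.classifier, seed=cfg.seed)
            manifest["mean_auc"] = res.mean_auc
            manifest["permutation_p"] = res.permutation_p
            (out_dir / "classification.json").write_text(json.dumps(dict(
                mean_auc=res.mean_auc, sd_auc=res.sd_auc,
                fold_aucs=res.fold_aucs,
                consensus_features=[ft.feature_names[i]
                                    for i in res.consensus_features],
                permutation_p=res.permutation_p, config_hash=h)))
    else:
        table, courses = _task_tables(recs, per_subject, cfg)
        write_courses_tsv(courses, out_dir / "burst_probability_courses.tsv", h)
        comps, _ = run_group_battery(table, cfg.stats.q)
        write_results_tsv(battery_to_frame(comps),
                          out_dir / "group_stats.tsv", h)
        manifest["n_tests"] = len(comps)

    (out_dir / "manifest.json").write_text(json.dumps(manifest, default=float))
    return manifest
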