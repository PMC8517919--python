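"""Canonical subject container and tabular exports.

A subject is stored as an HDF5 container (``/data`` R x T float64,
``/epochs``, ``/events``, attributes ``fs``, ``subject_id``, ``group``,
``region_labels``, optional ``symptom_score``) or ingested from a
delimited text matrix plus a JSON sidecar carrying the same attributes.
All tabular exports are UTF-8 TSV/CSV with mandatory headers and a
leading comment line naming the config hash that produced them.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import BurstSummary, BurstTrain, Connectome, RegionalRecording

REQUIRED_ATTRS = ("fs", "subject_id", "group", "region_labels")


def aal78_labels() -> list[str]:
    """The 78 cortical AAL region labels (left/right interleaved by pair)."""
    text = resources.files("burstnet.data").joinpath("aal78_labels.txt").read_text()
    labels = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if len(labels) != 78:
        raise RuntimeError("label fixture corrupted")
    return labels


def write_subject(path: str | Path, rec: RegionalRecording,
                  config_hash: str = "") -> None:
    """Write a subject container; float64 payload round-trips bitwise."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, dtype="f8")
        f.create_dataset("epochs", data=np.asarray(rec.epochs, dtype="i8"))
        if rec.events is not None:
            f.create_dataset("events", data=np.asarray(rec.events, dtype="i8"))
        f.attrs["fs"] = rec.fs
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["group"] = rec.group
        f.attrs["region_labels"] = [s.encode() for s in rec.region_labels]
        if rec.symptom_score is not None:
            f.attrs["symptom_score"] = rec.symptom_score
        if config_hash:
            f.attrs["config_hash"] = config_hash


def read_subject(path: str | Path) -> RegionalRecording:
    with h5py.File(path, "r") as f:
        for attr in REQUIRED_ATTRS:
            if attr not in f.attrs:
                raise ValueError(f"container missing attribute {attr!r}")
        labels = [s.decode() if isinstance(s, bytes) else str(s)
                  for s in f.attrs["region_labels"]]
        data = f["data"][()]
        if len(labels) != data.shape[0]:
            raise ValueError("label count does not match data rows")
        epochs = [tuple(map(int, e)) for e in f["epochs"][()]]
        events = [int(e) for e in f["events"][()]] if "events" in f else None
        score = float(f.attrs["symptom_score"]) if "symptom_score" in f.attrs \
            else None
        return RegionalRecording(
            subject_id=str(f.attrs["subject_id"]), group=str(f.attrs["group"]),
            fs=float(f.attrs["fs"]), region_labels=labels, data=data,
            epochs=epochs, events=events, symptom_score=score)


def read_subject_text(matrix_path: str | Path,
                      sidecar_path: str | Path | None = None
                      ) -> RegionalRecording:
    """Ingest a delimited R x T matrix plus a JSON sidecar of attributes."""
    matrix_path = Path(matrix_path)
    if sidecar_path is None:
        sidecar_path = matrix_path.with_suffix(".json")
    meta = json.loads(Path(sidecar_path).read_text())
    for attr in REQUIRED_ATTRS:
        if attr not in meta:
            raise ValueError(f"sidecar missing attribute {attr!r}")
    data = np.loadtxt(matrix_path, delimiter="\t", ndmin=2)
    return RegionalRecording(
        subject_id=meta["subject_id"], group=meta["group"],
        fs=float(meta["fs"]), region_labels=list(meta["region_labels"]),
        data=data, epochs=[tuple(e) for e in meta.get("epochs", [])],
        events=meta.get("events"), symptom_score=meta.get("symptom_score"))


def write_subject_text(matrix_path: str | Path, rec: RegionalRecording) -> None:
    matrix_path = Path(matrix_path)
    np.savetxt(matrix_path, rec.data, delimiter="\t")
    meta = dict(subject_id=rec.subject_id, group=rec.group, fs=rec.fs,
                region_labels=rec.region_labels,
                epochs=[list(e) for e in rec.epochs], events=rec.events,
                symptom_score=rec.symptom_score)
    matrix_path.with_suffix(".json").write_text(json.dumps(meta))


# ---------------------------------------------------------------------------
# tabular exports
# ---------------------------------------------------------------------------

def _write_frame(df: pd.DataFrame, path: str | Path, sep: str,
                 config_hash: str) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as f:
        f.write(f"# config_hash={config_hash or 'unset'}\n")
        df.to_csv(f, sep=sep, index=False)


def write_connectome_csv(c: Connectome, path: str | Path,
                         config_hash: str = "") -> None:
    df = pd.DataFrame(c.J, index=c.labels, columns=c.labels)
    path = Path(path)
    with open(path, "w", encoding="utf-8") as f:
        f.write(f"# config_hash={config_hash or 'unset'}\n")
        df.to_csv(f)


def read_connectome_csv(path: str | Path) -> Connectome:
    df = pd.read_csv(path, index_col=0, comment="#")
    return Connectome(labels=list(df.columns), J=df.to_numpy())


def write_trains_tsv(trains: list[BurstTrain], path: str | Path,
                     config_hash: str = "") -> None:
    rows = [(t.region_id, lo, hi) for t in trains for lo, hi in t.visits]
    df = pd.DataFrame(rows, columns=["region_label", "start_sample",
                                     "end_sample"])
    _write_frame(df, path, "\t", config_hash)


def write_summaries_tsv(rows: list[tuple[str, str, BurstSummary]],
                        path: str | Path, config_hash: str = "") -> None:
    """Tidy metric export: (subject, group, summary) triples in long form."""
    from .bursts import GLOBAL_METRICS
    records = [dict(subject=subject, group=group, region=s.region_id,
                    metric=m, value=getattr(s, m))
               for subject, group, s in rows for m in GLOBAL_METRICS]
    _write_frame(pd.DataFrame(records), path, "\t", config_hash)


def write_edges_tsv(edges: list[tuple[str, str, float, int]],
                    path: str | Path, config_hash: str = "") -> None:
    df = pd.DataFrame(edges, columns=["region_a", "region_b", "value", "rank"])
    _write_frame(df, path, "\t", config_hash)


def write_courses_tsv(df: pd.DataFrame, path: str | Path,
                      config_hash: str = "") -> None:
    _write_frame(df, path, "\t", config_hash)


def write_results_tsv(df: pd.DataFrame, path: str | Path,
                      config_hash: str = "") -> None:
    _write_frame(df, path, "\t", config_hash)
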