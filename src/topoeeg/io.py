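"""Serialization: EEG cohort bundles, PI archives, checkpoints, reports.

Cohorts are stored as one compressed numeric-array bundle per subject
(.npz with the channels x samples matrix) plus a JSON sidecar (subject id,
sampling rate, label, generator amplitudes), and a cohort-level clinical CSV
with header subject_id,panss_total,panss_positive,panss_negative.  PI
archives and model checkpoints are .npz files with an embedded JSON metadata
string.  All round-trips are exact for metadata and bit-exact for floats.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import ClinicalScores, EEGRecording, SyntheticSubject

__all__ = [
    "save_cohort",
    "load_cohort",
    "save_pi_archive",
    "load_pi_archive",
    "save_checkpoint",
    "load_checkpoint",
    "save_report",
    "load_report",
]

_CLINICAL_COLUMNS = ["subject_id", "panss_total", "panss_positive", "panss_negative"]


def save_cohort(directory, subjects: list[SyntheticSubject]) -> None:
    """One npz + JSON sidecar per subject, plus clinical.csv for patients."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        rec = s.recording
        np.savez_compressed(directory / f"{rec.subject_id}.npz", data=rec.data)
        sidecar = {
            "subject_id": rec.subject_id,
            "fs": rec.fs,
            "label": rec.label,
            "band_amplitudes": s.band_amplitudes,
        }
        (directory / f"{rec.subject_id}.json").write_text(
            json.dumps(sidecar, indent=2))
        if s.scores is not None:
            sc = s.scores
            rows.append([sc.subject_id, sc.panss_total, sc.panss_positive,
                         sc.panss_negative])
    if rows:
        pd.DataFrame(rows, columns=_CLINICAL_COLUMNS).to_csv(
            directory / "clinical.csv", index=False)


def load_cohort(directory) -> list[SyntheticSubject]:
    directory = Path(directory)
    sidecars = sorted(directory.glob("*.json"))
    if not sidecars:
        raise FileNotFoundError(f"no subject sidecars found in {directory}")
    clinical_path = directory / "clinical.csv"
    scores_by_id: dict[str, ClinicalScores] = {}
    if clinical_path.exists():
        df = pd.read_csv(clinical_path)
        for _, row in df.iterrows():
            scores_by_id[row["subject_id"]] = ClinicalScores(
                row["subject_id"], float(row["panss_total"]),
                float(row["panss_positive"]), float(row["panss_negative"]))
    subjects = []
    for sidecar_path in sidecars:
        meta = json.loads(sidecar_path.read_text())
        npz_path = directory / f"{meta['subject_id']}.npz"
        if not npz_path.exists():
            raise FileNotFoundError(f"missing array bundle {npz_path}")
        with np.load(npz_path) as npz:
            data = npz["data"]
        rec = EEGRecording(meta["subject_id"], data, float(meta["fs"]),
                           meta["label"])
        subjects.append(SyntheticSubject(
            rec, {k: float(v) for k, v in meta["band_amplitudes"].items()},
            scores_by_id.get(meta["subject_id"])))
    return subjects


def _key_to_str(key: tuple[str, str]) -> str:
    return f"{key[0]}|{key[1]}"


def save_pi_archive(path, sequences: dict[tuple[str, str], np.ndarray],
                    meta: dict) -> None:
    """npz of (T, R, R) stacks keyed "subject|band" with JSON metadata."""
    arrays = {_key_to_str(k): np.asarray(v, dtype=float)
              for k, v in sequences.items()}
    np.savez_compressed(Path(path), _meta=np.asarray(json.dumps(meta)), **arrays)


def load_pi_archive(path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["_meta"]))
        sequences = {}
        for k in npz.files:
            if k == "_meta":
                continue
            sid, band = k.split("|", 1)
            sequences[(sid, band)] = npz[k]
    return sequences, meta


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def save_checkpoint(path, model, config: dict | None = None) -> None:
    """Serialized parameter archive + class/shape metadata for strict loading."""
    meta = {
        "model_class": type(model).__name__,
        "resolution": model.resolution,
        "config_hash": config_hash(config or {}),
    }
    np.savez_compressed(Path(path), _meta=np.asarray(json.dumps(meta)),
                        **model.state_dict())


def load_checkpoint(path, model) -> dict:
    """Load parameters into ``model`` with shape/name validation; returns meta."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["_meta"]))
        if meta["model_class"] != type(model).__name__:
            raise ValueError(
                f"checkpoint holds a {meta['model_class']}, "
                f"not a {type(model).__name__}")
        state = {k: npz[k] for k in npz.files if k != "_meta"}
    model.load_state_dict(state)
    return meta


def save_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))


def load_report(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return json.loads(path.read_text())
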