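"""HDF5 and CSV interchange for cohorts and labeled window sets.

Cohort layout: one HDF5 group per subject, one subgroup per trial holding
``hand_q``/``forearm_q`` (n x 4, scalar-first) and ``emg_fcr``/``emg_ecr``
datasets, with sampling rates and design labels stored as attributes. The
generation manifest travels as a JSON string attribute on the root.

Real recordings enter through the CSV readers with the same schema:
quaternions as ``t, qw, qx, qy, qz`` per sensor, signals as ``t, value``.
"""

from __future__ import annotations

import json
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .synthetic import Cohort, CohortRecording
from .config import CohortConfig, SubjectParams, draw_subject_params
from .types import LabeledWindowSet, QuaternionStream, SignalRecording


def save_cohort(path: str, cohort: Cohort) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["manifest"] = json.dumps(cohort.manifest())
        for rec in cohort.recordings:
            g = f.require_group(rec.params.subject_id).create_group(
                f"trial{rec.trial:03d}")
            g.attrs["design_label"] = rec.params.design_label
            k = g.create_group("kinematics")
            k.attrs["fs"] = rec.kinematics.fs
            k.create_dataset("hand_q", data=rec.kinematics.hand_q)
            k.create_dataset("forearm_q", data=rec.kinematics.forearm_q)
            for name, sig in (("emg_fcr", rec.emg_fcr), ("emg_ecr", rec.emg_ecr)):
                d = g.create_dataset(name, data=sig.samples)
                d.attrs["fs"] = sig.fs
                d.attrs["modality"] = sig.modality
                d.attrs["channel"] = sig.channel


def load_cohort(path: str) -> Cohort:
    with h5py.File(path, "r") as f:
        manifest = json.loads(f.attrs["manifest"])
        cfg = CohortConfig.from_dict(manifest["config"])
        subjects = [SubjectParams(**s) for s in manifest["subjects"]]
        by_id = {s.subject_id: s for s in subjects}
        recordings = []
        # preserve generation order (patients first), not HDF5 name order
        for sid in (s.subject_id for s in subjects):
            for tname in sorted(f[sid]):
                g = f[sid][tname]
                trial = int(tname.replace("trial", ""))
                label = g.attrs["design_label"]
                k = g["kinematics"]
                kin = QuaternionStream(
                    hand_q=k["hand_q"][()], forearm_q=k["forearm_q"][()],
                    fs=float(k.attrs["fs"]), subject_id=sid,
                    design_label=label, trial=trial)
                emgs = {}
                for name, ch in (("emg_fcr", "FCR"), ("emg_ecr", "ECR")):
                    d = g[name]
                    emgs[ch] = SignalRecording(
                        samples=d[()], fs=float(d.attrs["fs"]),
                        modality=str(d.attrs["modality"]), channel=ch,
                        subject_id=sid, design_label=label, trial=trial)
                recordings.append(CohortRecording(
                    params=by_id[sid], trial=trial, kinematics=kin,
                    emg_fcr=emgs["FCR"], emg_ecr=emgs["ECR"]))
    return Cohort(config=cfg, subjects=subjects, recordings=recordings)


def save_labeled_windows(path: str, lws: LabeledWindowSet,
                         threshold_value: Optional[float] = None,
                         norm_stats: Optional[tuple] = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("windows", data=lws.windows)
        f.create_dataset("labels", data=lws.labels)
        f.create_dataset("design_labels", data=lws.design_labels)
        f.create_dataset("starts", data=lws.starts)
        f.create_dataset("trials", data=lws.trials)
        f.create_dataset("subject_ids",
                         data=np.asarray(lws.subject_ids, dtype="S16"))
        f.attrs["fs"] = lws.fs
        f.attrs["modality"] = lws.modality
        if threshold_value is not None:
            f.attrs["label_threshold"] = threshold_value
        if norm_stats is not None:
            f.attrs["norm_min"], f.attrs["norm_max"] = norm_stats


def load_labeled_windows(path: str) -> LabeledWindowSet:
    with h5py.File(path, "r") as f:
        return LabeledWindowSet(
            windows=f["windows"][()], fs=float(f.attrs["fs"]),
            modality=str(f.attrs["modality"]),
            subject_ids=f["subject_ids"][()].astype(str).astype(object),
            starts=f["starts"][()], trials=f["trials"][()],
            design_labels=f["design_labels"][()], labels=f["labels"][()])


def read_quaternion_csv(hand_path: str, forearm_path: str, fs: float,
                        subject_id: str = "user",
                        design_label: str = "") -> QuaternionStream:
    """Read paired sensor CSVs with columns ``t, qw, qx, qy, qz``."""
    cols = ["qw", "qx", "qy", "qz"]
    hand = pd.read_csv(hand_path)[cols].to_numpy(float)
    forearm = pd.read_csv(forearm_path)[cols].to_numpy(float)
    return QuaternionStream(hand_q=hand, forearm_q=forearm, fs=fs,
                            subject_id=subject_id, design_label=design_label)


def read_signal_csv(path: str, fs: float, modality: str = "emg-raw",
                    channel: str = "FCR", subject_id: str = "user",
                    design_label: str = "") -> SignalRecording:
    """Read a single-channel recording CSV with columns ``t, value``."""
    df = pd.read_csv(path)
    return SignalRecording(samples=df["value"].to_numpy(float), fs=fs,
                           modality=modality, channel=channel,
                           subject_id=subject_id, design_label=design_label)


def quality_reports_to_csv(reports, path: str) -> None:
    pd.DataFrame([{
        "subject_id": r.subject_id, "channel": r.channel,
        "snr_db": r.snr_estimate, "artifacts": ";".join(r.artifact_flags),
        "accepted": r.accepted,
    } for r in reports]).to_csv(path, index=False)
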