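"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .config import TREMOR, NO_TREMOR

#: design label code for windows of unknown provenance (user data)
UNKNOWN = -1

_MODALITIES = ("kinematic-angle", "emg-raw", "emg-envelope")
_CHANNELS = ("wrist", "FCR", "ECR")


@dataclass
class QuaternionStream:
    """Paired hand/forearm unit-quaternion streams (scalar-first, w,x,y,z)."""

    hand_q: np.ndarray  # (n, 4)
    forearm_q: np.ndarray  # (n, 4)
    fs: float
    subject_id: str
    design_label: str
    trial: int = 0

    def __post_init__(self) -> None:
        self.hand_q = np.asarray(self.hand_q, dtype=float)
        self.forearm_q = np.asarray(self.forearm_q, dtype=float)
        if self.hand_q.shape != self.forearm_q.shape or self.hand_q.ndim != 2 \
                or self.hand_q.shape[1] != 4:
            raise ValueError("hand and forearm streams must both be (n, 4)")

    def validate_norms(self, tol: float = 1e-6) -> None:
        for q in (self.hand_q, self.forearm_q):
            err = np.abs(np.linalg.norm(q, axis=1) - 1.0)
            if err.max(initial=0.0) > tol:
                raise ValueError(
                    f"non-unit quaternion (max norm deviation {err.max():.3g})"
                )

    def __len__(self) -> int:
        return self.hand_q.shape[0]


@dataclass
class SignalRecording:
    """A single-channel sampled series with its provenance."""

    samples: np.ndarray
    fs: float
    modality: str  # kinematic-angle | emg-raw | emg-envelope
    channel: str  # wrist | FCR | ECR
    subject_id: str
    design_label: str
    trial: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.modality not in _MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.channel not in _CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    def __len__(self) -> int:
        return self.samples.shape[0]


@dataclass
class AngleSeries:
    """Wrist flexion-extension angle in degrees at the IMU rate."""

    angle: np.ndarray  # degrees
    fs: float
    subject_id: str = ""
    design_label: str = ""
    trial: int = 0

    def __post_init__(self) -> None:
        self.angle = np.asarray(self.angle, dtype=float)

    def __len__(self) -> int:
        return self.angle.shape[0]


@dataclass
class WindowSet:
    """Fixed-length windows with per-window provenance.

    ``design_labels`` carries the generator's hidden ground truth (1 tremor,
    0 no-tremor, -1 unknown); it is never shown to the classifiers.
    """

    windows: np.ndarray  # (n_windows, window_len)
    fs: float
    modality: str
    subject_ids: np.ndarray  # (n,) str
    starts: np.ndarray  # (n,) int, start sample within source recording
    trials: np.ndarray  # (n,) int
    design_labels: np.ndarray  # (n,) int

    def __post_init__(self) -> None:
        self.windows = np.atleast_2d(np.asarray(self.windows, dtype=float))
        n = self.windows.shape[0]
        self.subject_ids = np.asarray(self.subject_ids)
        self.starts = np.asarray(self.starts, dtype=int)
        self.trials = np.asarray(self.trials, dtype=int)
        self.design_labels = np.asarray(self.design_labels, dtype=int)
        for name in ("subject_ids", "starts", "trials", "design_labels"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have one entry per window")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def window_len(self) -> int:
        return self.windows.shape[1]

    @staticmethod
    def concatenate(parts: Sequence["WindowSet"]) -> "WindowSet":
        if not parts:
            raise ValueError("cannot concatenate an empty list of window sets")
        fs = parts[0].fs
        modality = parts[0].modality
        if any(p.fs != fs or p.modality != modality for p in parts):
            raise ValueError("window sets differ in fs or modality")
        return WindowSet(
            windows=np.concatenate([p.windows for p in parts], axis=0),
            fs=fs,
            modality=modality,
            subject_ids=np.concatenate([p.subject_ids for p in parts]),
            starts=np.concatenate([p.starts for p in parts]),
            trials=np.concatenate([p.trials for p in parts]),
            design_labels=np.concatenate([p.design_labels for p in parts]),
        )

    def take(self, idx: np.ndarray) -> "WindowSet":
        return WindowSet(
            windows=self.windows[idx],
            fs=self.fs,
            modality=self.modality,
            subject_ids=self.subject_ids[idx],
            starts=self.starts[idx],
            trials=self.trials[idx],
            design_labels=self.design_labels[idx],
        )


@dataclass
class LabeledWindowSet(WindowSet):
    """Windows plus the PSD-threshold labels (1 Tremor, 0 No Tremor)."""

    labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        super().__post_init__()
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (self.n_windows,):
            raise ValueError("labels must have one entry per window")
        if self.labels.size and not np.isin(self.labels, (TREMOR, NO_TREMOR)).all():
            raise ValueError("labels must be binary (Tremor/No Tremor)")

    def take(self, idx: np.ndarray) -> "LabeledWindowSet":
        base = super().take(idx)
        return LabeledWindowSet(
            windows=base.windows, fs=base.fs, modality=base.modality,
            subject_ids=base.subject_ids, starts=base.starts,
            trials=base.trials, design_labels=base.design_labels,
            labels=self.labels[idx],
        )

    def class_counts(self) -> Tuple[int, int]:
        """(n_no_tremor, n_tremor)"""
        return int((self.labels == NO_TREMOR).sum()), int((self.labels == TREMOR).sum())


@dataclass(frozen=True)
class SpectralSummary:
    """Periodogram of one window with the tremor-band peak."""

    freqs: np.ndarray
    psd: np.ndarray
    band: Tuple[float, float]
    peak_freq: float
    peak_power: float


@dataclass(frozen=True)
class LabelThreshold:
    """Global PSD-peak threshold separating Tremor from No Tremor windows."""

    value: float
    calibration_method: str
    calibration_quantile: float
    n_calibration: int
    calibration_stats: dict


@dataclass(frozen=True)
class SplitSpec:
    """Dataset partitioning scheme.

    ``scheme='ml'`` is a stratified 70/30 train/test split (classical
    models); ``scheme='lstm'`` is 70/15/15 train/val/test.
    """

    scheme: str = "ml"
    stratified: bool = True
    seed: int = 0

    def fractions(self) -> dict:
        if self.scheme == "ml":
            return {"train": 0.70, "test": 0.30}
        if self.scheme == "lstm":
            return {"train": 0.70, "val": 0.15, "test": 0.15}
        raise ValueError(f"unknown split scheme {self.scheme!r}")


@dataclass(frozen=True)
class QualityReport:
    """Automated stand-in for visual EMG quality inspection."""

    subject_id: str
    channel: str
    snr_estimate: float  # dB
    artifact_flags: Tuple[str, ...]
    accepted: bool


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with Tremor as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The five evaluation scores for one model x modality pair."""

    counts: ConfusionCounts
    precision: float
    accuracy: float
    recall: float
    specificity: float
    f1: float
    model: str = ""
    modality: str = ""
    zero_division_flags: Tuple[str, ...] = ()
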