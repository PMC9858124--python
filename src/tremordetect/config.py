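"""Cohort-level configuration for the synthetic tremor study.

A virtual cohort mirrors the acquisition protocol of a postural-tremor
recording session: paired hand/forearm IMUs streaming unit quaternions at
50 Hz, and bipolar surface EMG from the wrist flexor (FCR) and extensor
(ECR) muscles sampled at 2042 Hz, recorded for 60-s trials from essential
tremor patients and healthy controls.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Tuple

import numpy as np

#: Window label for the positive (tremor) class.
TREMOR = 1
#: Window label for the negative class.
NO_TREMOR = 0

#: Design-label strings used on generated recordings.
CLASS_TREMOR = "tremor"
CLASS_NO_TREMOR = "no-tremor"

#: Frequency band of pathological tremor, Hz.
TREMOR_BAND = (4.0, 10.0)


class ConfigError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of a virtual tremor cohort.

    Defaults reproduce the study conditions: 12 essential-tremor patients,
    11 healthy controls, 60-s trials, IMU quaternions at 50 Hz and bipolar
    sEMG at 2042 Hz. ``n_trials`` is the number of repeated recordings per
    subject; 14 repetitions yield enough 1-s windows per class to assemble
    the balanced datasets (9,000 kinematic and 4,000 EMG windows per class).
    """

    n_patients: int = 12
    n_healthy: int = 11
    n_trials: int = 14
    trial_duration: float = 60.0  # seconds
    tremor_freq_range: Tuple[float, float] = TREMOR_BAND  # Hz
    tremor_amp_range_deg: Tuple[float, float] = (3.0, 12.0)  # wrist angle, deg
    tremor_depth_range: Tuple[float, float] = (0.5, 0.9)  # EMG modulation depth
    physio_tremor_band: Tuple[float, float] = (8.0, 12.0)  # Hz
    physio_amp: float = 0.05  # fraction of mean tremor amplitude/depth
    emg_fs: float = 2042.0  # Hz
    imu_fs: float = 50.0  # Hz
    emg_carrier_band: Tuple[float, float] = (20.0, 450.0)  # Hz
    snr_db: float = 20.0  # additive measurement noise on EMG
    mvc_fraction: float = 0.10  # healthy isometric activation level
    burst_mvc_fraction: float = 0.20  # tremor burst peak activation level
    angle_noise_deg: float = 0.1  # IMU orientation noise, deg RMS
    drift_amp_deg: float = 2.0  # postural drift RMS, deg
    cycle_jitter: float = 0.05  # cycle-to-cycle tremor freq/amp jitter
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0 or self.n_healthy < 0 or self.n_trials < 1:
            raise ConfigError("cohort sizes must be non-negative, n_trials >= 1")
        if self.trial_duration <= 0:
            raise ConfigError("trial_duration must be positive")
        lo, hi = self.tremor_freq_range
        env_fs = 50.0  # EMG envelopes are resampled to 50 Hz downstream
        if not (0 < lo < hi < min(self.imu_fs, env_fs) / 2):
            raise ConfigError(
                "tremor_freq_range must lie strictly inside (0, Nyquist) of "
                "both the IMU rate and the 50 Hz envelope rate"
            )
        for name in ("tremor_amp_range_deg", "tremor_depth_range",
                     "physio_tremor_band"):
            a, b = getattr(self, name)
            if a < 0 or b < a:
                raise ConfigError(f"{name} must be a non-negative interval")
        if self.tremor_amp_range_deg[1] > 90.0:
            raise ConfigError("tremor amplitude exceeds anatomical range (90 deg)")
        if self.physio_amp < 0 or self.angle_noise_deg < 0 or self.drift_amp_deg < 0:
            raise ConfigError("amplitudes must be non-negative")
        if self.emg_carrier_band[1] >= self.emg_fs / 2:
            raise ConfigError("emg_carrier_band upper edge must be < emg_fs/2")
        if self.emg_carrier_band[0] <= 0:
            raise ConfigError("emg_carrier_band lower edge must be > 0")
        if not (0 <= self.tremor_depth_range[0] <= self.tremor_depth_range[1] <= 1):
            raise ConfigError("tremor_depth_range must lie in [0, 1]")
        if self.mvc_fraction < 0 or self.burst_mvc_fraction < 0:
            raise ConfigError("activation levels must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("tremor_freq_range", "tremor_amp_range_deg",
                    "tremor_depth_range", "physio_tremor_band",
                    "emg_carrier_band"):
            if key in d:
                d[key] = tuple(d[key])  # JSON stores intervals as lists
        return cls(**d)


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject generative parameters, logged for recovery tests."""

    subject_id: str
    design_label: str  # CLASS_TREMOR or CLASS_NO_TREMOR
    tremor_freq: float  # Hz (pathological band; unused for healthy)
    tremor_amp_deg: float
    tremor_depth: float
    physio_freq: float  # Hz (physiological band)
    snr_db: float

    def to_dict(self) -> dict:
        return asdict(self)


def draw_subject_params(cfg: CohortConfig) -> list[SubjectParams]:
    """Draw the per-subject parameters deterministically from ``cfg.seed``.

    Patients come first (``P01`` ...), then healthy controls (``H01`` ...).
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xC040]))
    out: list[SubjectParams] = []
    for i in range(cfg.n_patients + cfg.n_healthy):
        patient = i < cfg.n_patients
        sid = f"P{i + 1:02d}" if patient else f"H{i - cfg.n_patients + 1:02d}"
        out.append(SubjectParams(
            subject_id=sid,
            design_label=CLASS_TREMOR if patient else CLASS_NO_TREMOR,
            tremor_freq=float(rng.uniform(*cfg.tremor_freq_range)),
            tremor_amp_deg=float(rng.uniform(*cfg.tremor_amp_range_deg)),
            tremor_depth=float(rng.uniform(*cfg.tremor_depth_range)),
            physio_freq=float(rng.uniform(*cfg.physio_tremor_band)),
            snr_db=cfg.snr_db,
        ))
    return out
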