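"""Virtual cohort generator.

Emulates a postural-tremor recording session. Each subject holds a posture
for ``trial_duration`` seconds while two IMUs (hand, forearm) stream unit
quaternions at 50 Hz and bipolar surface EMG is recorded from the wrist
flexor (FCR) and extensor (ECR) at 2042 Hz.

Kinematics. The forearm sensor carries slow postural drift (a low-pass
filtered random walk below 1 Hz). The hand sensor is the forearm
orientation composed with a rotation about the flexion-extension axis,
``q_hand = q_forearm * q_rel`` with the relative rotation expressed in the
forearm frame. For patients the flexion angle is a 4-10 Hz sinusoid whose
frequency and amplitude are jittered a few percent cycle-to-cycle
(pathological tremor is variable and non-stationary); healthy subjects get
drift, sensor noise and a low-amplitude 8-12 Hz physiological-tremor
oscillation instead.

EMG. The interference-pattern sEMG is surrogated by band-limited Gaussian
noise (20-450 Hz carrier) amplitude-modulated, for patients, by a
non-negative tremor burst train (half-wave-rectified sinusoid at the
subject's tremor frequency over a baseline) with FCR and ECR bursts in
antiphase. Healthy subjects produce a constant-activation isometric analog
at 10% MVC, optionally with a small physiological-tremor modulation.
White measurement noise is added at ``snr_db``.

All generation is a pure function of :class:`~tremordetect.config.CohortConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation

from .config import (CLASS_NO_TREMOR, CLASS_TREMOR, CohortConfig, ConfigError,
                     SubjectParams, draw_subject_params)
from .types import QuaternionStream, SignalRecording

_ANATOMICAL_LIMIT_DEG = 90.0

# stream-kind tags entering the per-recording seed, so every recording has
# an independent, reproducible substream
_KIND_KIN = 1
_KIND_EMG = {"FCR": 2, "ECR": 3}


def _rng(cfg: CohortConfig, subject_id: str, trial: int, kind: int) -> np.random.Generator:
    sub_key = int.from_bytes(subject_id.encode(), "little") % (2 ** 31)
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed, sub_key, trial, kind]))


def _default_params(cfg: CohortConfig, subject_class: str,
                    subject_id: str) -> SubjectParams:
    """Single-subject parameters for direct calls outside generate_cohort."""
    mid = lambda ab: 0.5 * (ab[0] + ab[1])
    return SubjectParams(
        subject_id=subject_id,
        design_label=subject_class,
        tremor_freq=mid(cfg.tremor_freq_range),
        tremor_amp_deg=mid(cfg.tremor_amp_range_deg),
        tremor_depth=mid(cfg.tremor_depth_range),
        physio_freq=mid(cfg.physio_tremor_band),
        snr_db=cfg.snr_db,
    )


def _slow_noise(rng: np.random.Generator, n: int, fs: float,
                cutoff_hz: float = 1.0) -> np.ndarray:
    """Unit-RMS noise band-limited below ``cutoff_hz`` (postural drift shape)."""
    w = np.cumsum(rng.standard_normal(n))
    if fs > 4 * cutoff_hz:
        sos = signal.butter(2, cutoff_hz, "lowpass", fs=fs, output="sos")
        w = signal.sosfiltfilt(sos, w)
    w = w - w.mean()
    rms = np.sqrt(np.mean(w ** 2))
    return w / rms if rms > 0 else w


def _jittered_sinusoid(rng: np.random.Generator, n: int, fs: float,
                       freq: float, amp: float, jitter: float) -> np.ndarray:
    """Sinusoid with slowly varying frequency and amplitude (tremor-like)."""
    phase0 = rng.uniform(0, 2 * np.pi)
    if jitter > 0:
        f_inst = freq * (1.0 + jitter * _slow_noise(rng, n, fs, cutoff_hz=freq / 4))
        a_inst = amp * (1.0 + jitter * _slow_noise(rng, n, fs, cutoff_hz=freq / 4))
    else:
        t = np.arange(n) / fs
        return amp * np.sin(2 * np.pi * freq * t + phase0)
    phase = phase0 + 2 * np.pi * np.cumsum(f_inst) / fs
    return a_inst * np.sin(phase)


def simulate_kinematics(cfg: CohortConfig, subject_class: str,
                        subject_id: str = "S01", trial: int = 0,
                        params: Optional[SubjectParams] = None) -> QuaternionStream:
    """Generate one paired hand/forearm quaternion recording.

    ``params`` overrides the per-subject tremor parameters (frequency,
    amplitude); when omitted, mid-range defaults are used.
    """
    cfg.validate()
    if subject_class not in (CLASS_TREMOR, CLASS_NO_TREMOR):
        raise ValueError(f"unknown subject class {subject_class!r}")
    if params is None:
        params = _default_params(cfg, subject_class, subject_id)
    fs = cfg.imu_fs
    n = int(round(cfg.trial_duration * fs))
    rng = _rng(cfg, subject_id, trial, _KIND_KIN)

    # forearm: slow 3-axis postural drift below 1 Hz
    if cfg.drift_amp_deg > 0:
        drift = np.stack([cfg.drift_amp_deg * _slow_noise(rng, n, fs)
                          for _ in range(3)], axis=1)
    else:
        drift = np.zeros((n, 3))
        rng.standard_normal(3 * n)  # keep the stream position class-independent
    r_forearm = Rotation.from_euler("xyz", drift, degrees=True)

    # relative flexion-extension angle about the forearm x (mediolateral) axis
    theta = np.zeros(n)
    if subject_class == CLASS_TREMOR:
        theta = theta + _jittered_sinusoid(
            rng, n, fs, params.tremor_freq, params.tremor_amp_deg, cfg.cycle_jitter)
    elif cfg.physio_amp > 0:
        physio_amp_deg = cfg.physio_amp * 0.5 * sum(cfg.tremor_amp_range_deg)
        theta = theta + _jittered_sinusoid(
            rng, n, fs, params.physio_freq, physio_amp_deg, cfg.cycle_jitter)
    if cfg.drift_amp_deg > 0:  # the hand wanders slightly relative to the forearm
        theta = theta + 0.25 * cfg.drift_amp_deg * _slow_noise(rng, n, fs)
    if cfg.angle_noise_deg > 0:
        theta = theta + cfg.angle_noise_deg * rng.standard_normal(n)

    if np.abs(theta).max(initial=0.0) > _ANATOMICAL_LIMIT_DEG:
        raise ConfigError(
            "configured tremor amplitude drives the wrist angle outside the "
            f"anatomical range (+-{_ANATOMICAL_LIMIT_DEG} deg)")

    r_rel = Rotation.from_euler("x", theta[:, None], degrees=True)
    r_hand = r_forearm * r_rel

    def _wxyz(r: Rotation) -> np.ndarray:
        q = r.as_quat()  # scipy is (x, y, z, w)
        return np.column_stack([q[:, 3], q[:, 0], q[:, 1], q[:, 2]])

    return QuaternionStream(hand_q=_wxyz(r_hand), forearm_q=_wxyz(r_forearm),
                            fs=fs, subject_id=subject_id,
                            design_label=subject_class, trial=trial)


def kinematics_from_angle(theta_deg: np.ndarray, fs: float = 50.0,
                          forearm: Optional[Rotation] = None,
                          subject_id: str = "S01",
                          design_label: str = CLASS_TREMOR) -> QuaternionStream:
    """Build a quaternion stream from a known flexion-extension angle series.

    Useful for exact round-trip checks: the returned stream, inverted by the
    kinematic preprocessing, reproduces ``theta_deg``.
    """
    theta_deg = np.asarray(theta_deg, dtype=float)
    n = theta_deg.shape[0]
    if forearm is None:
        forearm = Rotation.identity(n)
    r_hand = forearm * Rotation.from_euler("x", theta_deg[:, None], degrees=True)

    def _wxyz(r: Rotation) -> np.ndarray:
        q = np.atleast_2d(r.as_quat())
        return np.column_stack([q[:, 3], q[:, 0], q[:, 1], q[:, 2]])

    return QuaternionStream(hand_q=_wxyz(r_hand), forearm_q=_wxyz(forearm),
                            fs=fs, subject_id=subject_id,
                            design_label=design_label)


def _halfwave(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def simulate_emg(cfg: CohortConfig, subject_class: str, channel: str,
                 subject_id: str = "S01", trial: int = 0,
                 params: Optional[SubjectParams] = None) -> SignalRecording:
    """Generate one bipolar sEMG recording for the FCR or ECR channel."""
    cfg.validate()
    if channel not in ("FCR", "ECR"):
        raise ValueError("channel must be 'FCR' or 'ECR'")
    if subject_class not in (CLASS_TREMOR, CLASS_NO_TREMOR):
        raise ValueError(f"unknown subject class {subject_class!r}")
    if params is None:
        params = _default_params(cfg, subject_class, subject_id)
    fs = cfg.emg_fs
    n = int(round(cfg.trial_duration * fs))
    rng = _rng(cfg, subject_id, trial, _KIND_EMG[channel])

    carrier = rng.standard_normal(n)
    sos = signal.butter(4, cfg.emg_carrier_band, "bandpass", fs=fs, output="sos")
    carrier = signal.sosfiltfilt(sos, carrier)
    carrier /= np.sqrt(np.mean(carrier ** 2))

    t = np.arange(n) / fs
    phase0 = rng.uniform(0, 2 * np.pi)
    if subject_class == CLASS_TREMOR:
        # antiphase flexor/extensor burst trains at the tremor frequency
        ph = phase0 + (np.pi if channel == "ECR" else 0.0)
        if cfg.cycle_jitter > 0:
            f_inst = params.tremor_freq * (
                1.0 + cfg.cycle_jitter * _slow_noise(rng, n, fs, params.tremor_freq / 4))
            phase = ph + 2 * np.pi * np.cumsum(f_inst) / fs
        else:
            phase = ph + 2 * np.pi * params.tremor_freq * t
        depth = params.tremor_depth
        # bursts peak at burst_mvc_fraction activation; the inter-burst
        # baseline sits at (1 - depth) of that, so total power stays
        # comparable to the healthy isometric level while the bursts carry
        # the larger amplitude excursions seen in real tremor EMG
        mod = cfg.burst_mvc_fraction * (
            (1.0 - depth) + depth * _halfwave(np.sin(phase)))
    else:
        # isometric analog at mvc_fraction, small physiological modulation
        physio_depth = cfg.physio_amp * 0.5 * sum(cfg.tremor_depth_range)
        mod = cfg.mvc_fraction * (1.0 + physio_depth * _halfwave(
            np.sin(phase0 + 2 * np.pi * params.physio_freq * t)))

    s = mod * carrier
    sig_rms = np.sqrt(np.mean(s ** 2))
    noise_rms = sig_rms * 10.0 ** (-params.snr_db / 20.0)
    samples = s + noise_rms * rng.standard_normal(n)

    return SignalRecording(samples=samples, fs=fs, modality="emg-raw",
                           channel=channel, subject_id=subject_id,
                           design_label=subject_class, trial=trial)


@dataclass
class CohortRecording:
    """One trial of one subject: a quaternion stream plus two EMG channels."""

    params: SubjectParams
    trial: int
    kinematics: QuaternionStream
    emg_fcr: SignalRecording
    emg_ecr: SignalRecording


@dataclass
class Cohort:
    """A fully materialised virtual cohort with its generation manifest."""

    config: CohortConfig
    subjects: list[SubjectParams]
    recordings: list[CohortRecording]

    @property
    def kinematic_streams(self) -> list[QuaternionStream]:
        return [r.kinematics for r in self.recordings]

    @property
    def emg_recordings(self) -> list[SignalRecording]:
        out: list[SignalRecording] = []
        for r in self.recordings:
            out.extend([r.emg_fcr, r.emg_ecr])
        return out

    def manifest(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "subjects": [s.to_dict() for s in self.subjects],
            "n_recordings": len(self.recordings),
        }


def iter_cohort(cfg: CohortConfig) -> Iterator[CohortRecording]:
    """Yield cohort recordings one trial at a time (constant memory).

    The per-recording random substream is keyed by (seed, subject, trial),
    so iteration order never changes the generated data.
    """
    subjects = draw_subject_params(cfg)
    for params in subjects:
        for trial in range(cfg.n_trials):
            kin = simulate_kinematics(cfg, params.design_label,
                                      params.subject_id, trial, params)
            fcr = simulate_emg(cfg, params.design_label, "FCR",
                               params.subject_id, trial, params)
            ecr = simulate_emg(cfg, params.design_label, "ECR",
                               params.subject_id, trial, params)
            yield CohortRecording(params=params, trial=trial, kinematics=kin,
                                  emg_fcr=fcr, emg_ecr=ecr)


def generate_cohort(cfg: CohortConfig) -> Cohort:
    """Materialise the whole cohort (use :func:`iter_cohort` for large runs)."""
    return Cohort(config=cfg, subjects=draw_subject_params(cfg),
                  recordings=list(iter_cohort(cfg)))
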