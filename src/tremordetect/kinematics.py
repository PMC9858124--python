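"""Kinematic preprocessing: quaternions -> wrist angle -> 1-s windows.

The wrist flexion-extension angle is the first angle of the intrinsic
X-Y'-Z'' Euler decomposition of the relative hand-vs-forearm orientation,
``q_rel = conj(q_forearm) * q_hand``, with flexion-extension assigned to the
forearm mediolateral (x) axis — the same convention the synthetic generator
uses, so the inversion is exact.
"""

from __future__ import annotations

import warnings
from typing import Optional, Tuple, Union

import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation

from .config import TREMOR_BAND
from .types import AngleSeries, QuaternionStream, SignalRecording, WindowSet, UNKNOWN
from .config import CLASS_TREMOR, CLASS_NO_TREMOR

_GIMBAL_TOL_RAD = 1e-3


def quaternions_to_wrist_angle(qs: QuaternionStream) -> AngleSeries:
    """Wrist flexion-extension angle (degrees) from paired IMU quaternions.

    Raises if any quaternion norm deviates from 1 by more than 1e-6; warns
    (but still returns values) near the gimbal singularity of the Euler
    decomposition (second angle within 1e-3 rad of +-pi/2).
    """
    qs.validate_norms(tol=1e-6)

    def _rot(q_wxyz: np.ndarray) -> Rotation:
        return Rotation.from_quat(
            np.column_stack([q_wxyz[:, 1], q_wxyz[:, 2], q_wxyz[:, 3], q_wxyz[:, 0]]))

    r_rel = _rot(qs.forearm_q).inv() * _rot(qs.hand_q)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # scipy's own gimbal warning
        eul = r_rel.as_euler("XYZ", degrees=False)
    if np.any(np.abs(np.abs(eul[:, 1]) - np.pi / 2) < _GIMBAL_TOL_RAD):
        warnings.warn("Euler decomposition near gimbal singularity; "
                      "flexion-extension angle may be ill-conditioned",
                      RuntimeWarning, stacklevel=2)
    return AngleSeries(angle=np.degrees(eul[:, 0]), fs=qs.fs,
                       subject_id=qs.subject_id, design_label=qs.design_label,
                       trial=qs.trial)


def bandpass_tremor(samples: np.ndarray, fs: float,
                    band: Tuple[float, float] = TREMOR_BAND,
                    order: int = 2) -> np.ndarray:
    """Zero-lag tremor-band filter (2nd-order Butterworth, forward-backward).

    Bidirectional application doubles the effective order and cancels the
    phase response, so tremor peaks are not displaced in time.
    """
    samples = np.asarray(samples, dtype=float)
    if fs <= 2 * band[1]:
        raise ValueError(f"sampling rate {fs} Hz too low for band {band}")
    sos = signal.butter(order, band, "bandpass", fs=fs, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if samples.shape[-1] <= padlen:
        raise ValueError(
            f"input length {samples.shape[-1]} too short for zero-lag "
            f"filtering (needs > {padlen} samples)")
    return signal.sosfiltfilt(sos, samples, axis=-1)


def segment_windows(series: Union[AngleSeries, SignalRecording, np.ndarray],
                    fs: Optional[float] = None,
                    window_seconds: float = 1.0,
                    overlap: float = 0.0,
                    modality: str = "kinematic-angle") -> WindowSet:
    """Cut a series into consecutive fixed-length windows.

    Windows never cross the recording boundary; the trailing remainder is
    discarded. ``overlap`` is the fraction of a window shared by neighbours
    (0 = non-overlapping, the default used throughout).
    """
    subject_id, design_label, trial = "", UNKNOWN, 0
    if isinstance(series, AngleSeries):
        x, fs = series.angle, series.fs
        subject_id, trial = series.subject_id, series.trial
        design_label = {CLASS_TREMOR: 1, CLASS_NO_TREMOR: 0}.get(
            series.design_label, UNKNOWN)
    elif isinstance(series, SignalRecording):
        x, fs = series.samples, series.fs
        modality = series.modality
        subject_id, trial = series.subject_id, series.trial
        design_label = {CLASS_TREMOR: 1, CLASS_NO_TREMOR: 0}.get(
            series.design_label, UNKNOWN)
    else:
        x = np.asarray(series, dtype=float)
        if fs is None:
            raise ValueError("fs is required when passing a bare array")

    wl = int(round(fs * window_seconds))
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    step = max(1, int(round(wl * (1 - overlap))))
    n = x.shape[0]
    if n < wl:
        warnings.warn("series shorter than one window; empty window set",
                      RuntimeWarning, stacklevel=2)
        starts = np.empty(0, dtype=int)
    else:
        starts = np.arange(0, n - wl + 1, step, dtype=int)
    windows = np.stack([x[s:s + wl] for s in starts]) if starts.size \
        else np.empty((0, wl))
    k = starts.size
    return WindowSet(windows=windows, fs=fs, modality=modality,
                     subject_ids=np.full(k, subject_id, dtype=object),
                     starts=starts,
                     trials=np.full(k, trial, dtype=int),
                     design_labels=np.full(k, design_label, dtype=int))


def normalize_global(ws: WindowSet,
                     stats: Optional[Tuple[float, float]] = None
                     ) -> Tuple[WindowSet, Tuple[float, float]]:
    """Map amplitudes to [0, 1] by the global min/max affine transform.

    When ``stats`` is given (e.g. computed on the training pool only), the
    stored mapping is applied unchanged; held-out samples with larger
    excursions may then fall outside [0, 1] — no clipping is applied.
    """
    if stats is None:
        mn = float(ws.windows.min())
        mx = float(ws.windows.max())
    else:
        mn, mx = float(stats[0]), float(stats[1])
    if mx <= mn:
        raise ValueError("degenerate amplitude range: max must exceed min")
    out = ws.take(np.arange(ws.n_windows))
    out.windows = (ws.windows - mn) / (mx - mn)
    return out, (mn, mx)
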