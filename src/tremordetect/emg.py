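"""EMG preprocessing: quality screening, downsampling, envelope extraction.

The raw 2042 Hz recordings are screened for low SNR and clipping (an
automated stand-in for visual inspection), resampled rationally to exactly
510 Hz, and turned into 50 Hz tremor-band envelopes by full-wave
rectification followed by the shared 4-10 Hz zero-lag Butterworth filter.
"""

from __future__ import annotations

from dataclasses import replace
from fractions import Fraction
from typing import Tuple

import numpy as np
from scipy import signal

from .config import TREMOR_BAND
from .kinematics import bandpass_tremor
from .types import QualityReport, SignalRecording

#: default acceptance threshold for the SNR screen, dB
SNR_MIN_DB = 6.0


def quality_screen(rec: SignalRecording, snr_min_db: float = SNR_MIN_DB,
                   carrier_band: Tuple[float, float] = (20.0, 450.0),
                   tremor_band: Tuple[float, float] = TREMOR_BAND
                   ) -> QualityReport:
    """Screen a raw EMG recording for low SNR and clipping artifacts.

    SNR is estimated as 10*log10 of the ratio of integrated Welch-PSD power
    inside the EMG carrier band to the power outside it, excluding the
    tremor band (where legitimate modulation sidebands live). Clipping is
    flagged when >= 3 consecutive samples sit at the amplitude extreme.
    A report is always returned; nothing is raised.
    """
    if rec.modality != "emg-raw":
        raise ValueError("quality_screen expects a raw EMG recording")
    x = rec.samples
    f, pxx = signal.welch(x, fs=rec.fs, nperseg=min(len(x), 4096))
    df = f[1] - f[0]
    in_band = (f >= carrier_band[0]) & (f <= carrier_band[1])
    excl = (f >= tremor_band[0]) & (f <= tremor_band[1])
    out_band = ~in_band & ~excl
    p_in = float(pxx[in_band].sum() * df)
    p_out = float(pxx[out_band].sum() * df)
    snr = 10.0 * np.log10(p_in / p_out) if p_out > 0 else np.inf

    flags = []
    for extreme in (x.max(), x.min()):
        at = np.concatenate([[False], x == extreme, [False]])
        edges = np.flatnonzero(np.diff(at.astype(int)))
        if edges.size and (edges[1::2] - edges[::2]).max(initial=0) >= 3:
            flags.append("clipping")
            break

    accepted = snr >= snr_min_db and not flags
    return QualityReport(subject_id=rec.subject_id, channel=rec.channel,
                         snr_estimate=float(snr),
                         artifact_flags=tuple(flags), accepted=accepted)


def resample_to(samples: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    """Polyphase anti-aliased resampling to exactly ``target_fs``."""
    frac = Fraction(target_fs / fs).limit_denominator(10000)
    return signal.resample_poly(np.asarray(samples, dtype=float),
                                frac.numerator, frac.denominator)


def downsample_emg(rec: SignalRecording, target_fs: float = 510.0) -> SignalRecording:
    """Downsample raw EMG (2042 -> 510 Hz by default, ratio 255/1021).

    The polyphase resampler low-passes below ``target_fs/2`` before
    decimation, so no aliasing of high-frequency EMG content occurs.
    """
    if target_fs >= rec.fs:
        raise ValueError("target_fs must be below the recording rate "
                         "(upsampling not supported here)")
    y = resample_to(rec.samples, rec.fs, target_fs)
    return replace(rec, samples=y, fs=target_fs)


def emg_envelope(rec: SignalRecording, envelope_fs: float = 50.0,
                 band: Tuple[float, float] = TREMOR_BAND) -> SignalRecording:
    """Tremor-band EMG envelope at 50 Hz.

    Full-wave rectification, the shared 4-10 Hz zero-lag band-pass at the
    input rate, then polyphase downsampling to ``envelope_fs``. The 4-10 Hz
    content sits far below the 25 Hz post-decimation Nyquist, so the tremor
    component is preserved.
    """
    if rec.modality != "emg-raw":
        raise ValueError("emg_envelope expects a raw EMG recording")
    env = bandpass_tremor(np.abs(rec.samples), rec.fs, band=band)
    env = resample_to(env, rec.fs, envelope_fs)
    return replace(rec, samples=env, fs=envelope_fs, modality="emg-envelope")
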