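"""Window labeling by tremor-band PSD peak, dataset balancing and splits.

Each 1-s window is summarised by the maximum of its power spectral density
over the tremor band [4, 10] Hz (single-taper Hann periodogram, density
scaling; a 1-s window gives ~1 Hz resolution at 50 Hz). A global threshold
— the 99th percentile of the no-tremor peak-power distribution, calibrated
from healthy-subject windows — separates *Tremor* from *No Tremor*. Windows
whose peak power equals the threshold exactly are labeled No Tremor (the
tie rule is strictly-greater).

Raw-EMG windows are not labeled from their own spectrum: they inherit the
label of their time-aligned tremor-band envelope window.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal
from sklearn.model_selection import train_test_split

from .config import NO_TREMOR, TREMOR, TREMOR_BAND
from .types import (LabelThreshold, LabeledWindowSet, SpectralSummary,
                    SplitSpec, WindowSet)


def window_psd(window: np.ndarray, fs: float,
               band: Tuple[float, float] = TREMOR_BAND) -> SpectralSummary:
    """Hann periodogram of one window with the tremor-band peak."""
    window = np.asarray(window, dtype=float)
    freqs, psd = signal.periodogram(window, fs=fs, window="hann",
                                    scaling="density")
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError(f"no frequency bins inside band {band} at fs={fs}")
    i = np.argmax(psd[mask])
    return SpectralSummary(freqs=freqs, psd=psd, band=band,
                           peak_freq=float(freqs[mask][i]),
                           peak_power=float(psd[mask][i]))


def band_peak_powers(windows: np.ndarray, fs: float,
                     band: Tuple[float, float] = TREMOR_BAND
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised tremor-band PSD peaks for a stack of windows.

    Returns (peak_power, peak_freq) arrays, identical to mapping
    :func:`window_psd` over the rows.
    """
    windows = np.atleast_2d(np.asarray(windows, dtype=float))
    freqs, psd = signal.periodogram(windows, fs=fs, window="hann",
                                    scaling="density", axis=-1)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError(f"no frequency bins inside band {band} at fs={fs}")
    sub = psd[:, mask]
    idx = np.argmax(sub, axis=1)
    return sub[np.arange(sub.shape[0]), idx], freqs[mask][idx]


def calibrate_threshold(no_tremor_peaks: Sequence[float] | np.ndarray,
                        quantile: float = 0.99,
                        min_windows: int = 30) -> LabelThreshold:
    """Global threshold = the given quantile of no-tremor peak powers.

    Mirrors the practice of estimating detection thresholds from data
    recorded from healthy subjects; the quantile keeps the false-positive
    rate on the calibration class at ~(1 - quantile).
    """
    peaks = np.asarray(no_tremor_peaks, dtype=float)
    if peaks.size == 0:
        raise ValueError("empty calibration set")
    if peaks.size < min_windows:
        raise ValueError(
            f"need >= {min_windows} no-tremor windows to calibrate "
            f"(got {peaks.size})")
    if not 0 <= quantile <= 1:
        raise ValueError("quantile must be in [0, 1]")
    value = float(np.quantile(peaks, quantile))
    return LabelThreshold(
        value=value, calibration_method="no-tremor-peak-quantile",
        calibration_quantile=quantile, n_calibration=int(peaks.size),
        calibration_stats={
            "median": float(np.median(peaks)),
            "max": float(peaks.max()),
        })


def label_windows(ws: WindowSet, th: LabelThreshold,
                  peak_powers: Optional[np.ndarray] = None) -> LabeledWindowSet:
    """Assign Tremor/No Tremor labels by the PSD-peak threshold.

    Labels are a pure function of (windows, threshold): Tremor iff the
    tremor-band peak power is strictly greater than the threshold.
    ``peak_powers`` may be supplied to reuse precomputed statistics; for
    raw-EMG windows they MUST come from the aligned envelope windows (use
    :func:`inherit_labels` for that path).
    """
    if peak_powers is None:
        if ws.modality == "emg-raw":
            raise ValueError(
                "raw-EMG windows are labeled from their aligned envelope; "
                "pass the envelope peak powers or use inherit_labels()")
        peak_powers, _ = band_peak_powers(ws.windows, ws.fs)
    peak_powers = np.asarray(peak_powers, dtype=float)
    if peak_powers.shape != (ws.n_windows,):
        raise ValueError("need one peak power per window")
    labels = np.where(peak_powers > th.value, TREMOR, NO_TREMOR)
    return LabeledWindowSet(
        windows=ws.windows, fs=ws.fs, modality=ws.modality,
        subject_ids=ws.subject_ids, starts=ws.starts, trials=ws.trials,
        design_labels=ws.design_labels, labels=labels)


def inherit_labels(raw_ws: WindowSet, env_lws: LabeledWindowSet) -> LabeledWindowSet:
    """Label raw-EMG windows from their time-aligned envelope windows.

    Windows must correspond one-to-one in order (same subject, trial and
    1-s slot) — the preprocessing pipeline guarantees this because both
    modalities are cut on the same second boundaries.
    """
    if raw_ws.n_windows != env_lws.n_windows:
        raise ValueError(
            f"raw ({raw_ws.n_windows}) and envelope ({env_lws.n_windows}) "
            "window counts differ; alignment lost")
    same_subject = np.array_equal(raw_ws.subject_ids, env_lws.subject_ids)
    same_trial = np.array_equal(raw_ws.trials, env_lws.trials)
    if not (same_subject and same_trial):
        raise ValueError("raw and envelope windows are not aligned")
    return LabeledWindowSet(
        windows=raw_ws.windows, fs=raw_ws.fs, modality=raw_ws.modality,
        subject_ids=raw_ws.subject_ids, starts=raw_ws.starts,
        trials=raw_ws.trials, design_labels=raw_ws.design_labels,
        labels=env_lws.labels.copy())


def assemble_balanced(lws: LabeledWindowSet, n_per_class: int,
                      seed: int = 0) -> LabeledWindowSet:
    """Uniform random class-balanced subsample without replacement."""
    rng = np.random.default_rng(seed)
    picked = []
    for cls in (TREMOR, NO_TREMOR):
        idx = np.flatnonzero(lws.labels == cls)
        if idx.size < n_per_class:
            name = "Tremor" if cls == TREMOR else "No Tremor"
            raise ValueError(
                f"class {name} has only {idx.size} windows; "
                f"{n_per_class} requested (deficit {n_per_class - idx.size})")
        picked.append(rng.choice(idx, size=n_per_class, replace=False))
    order = np.sort(np.concatenate(picked))
    return lws.take(order)


def split(lws: LabeledWindowSet, spec: SplitSpec) -> dict[str, np.ndarray]:
    """Stratified random partition into train/test (ml) or train/val/test (lstm).

    Returns index arrays into ``lws``; partitions are disjoint, exhaustive
    and class-balanced within +-1. Persist these indices to reuse the same
    partition across model families.
    """
    n = lws.n_windows
    fr = spec.fractions()
    for name, f in fr.items():
        if f * n < 1:
            raise ValueError(f"partition {name!r} would be empty at n={n}")
    strat = lws.labels if spec.stratified else None
    idx = np.arange(n)
    if spec.scheme == "ml":
        tr, te = train_test_split(idx, test_size=fr["test"],
                                  random_state=spec.seed, stratify=strat)
        return {"train": np.sort(tr), "test": np.sort(te)}
    tr, rest = train_test_split(idx, test_size=fr["val"] + fr["test"],
                                random_state=spec.seed, stratify=strat)
    strat_rest = lws.labels[rest] if spec.stratified else None
    va, te = train_test_split(rest, test_size=0.5, random_state=spec.seed,
                              stratify=strat_rest)
    return {"train": np.sort(tr), "val": np.sort(va), "test": np.sort(te)}
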